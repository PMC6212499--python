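"""Scan a proteome for arginylation-favorable N-termini.

Trains a predictor, scans a synthetic proteome in which 3% of proteins
carry an arginylation-favorable MD/ME start, estimates the class prior
from the score distributions and reports the arginylome fraction, then
applies the conservation-intersection filter to a candidate table.
"""

import numpy as np
import pandas as pd

import arginylome as ag
from arginylome.features import extract_features
from arginylome.peptides import Peptide
from arginylome.scan import extract_site_windows

peptides, _ = ag.generate_dataset(n_pos=300, n_unl=600, seed=7)
data = ag.to_training_set(peptides)
model = ag.train_ensemble(data, n_members=30, seed=7)
pos_scores = ag.predict_scores(model, data.X[data.y == 1])

proteome, truth = ag.generate_proteome(2000, signal_fraction=0.03, seed=3)
windows = [w for rec in proteome for w in extract_site_windows(rec, "nterm_conservative")]
X = np.vstack([extract_features(Peptide(w.window)).values for w in windows])
prior = ag.estimate_alpha(pos_scores, ag.predict_scores(model, X))

result = ag.scan_proteome(proteome, model, prior, mode="nterm_conservative")
print(f"windows scanned:      {result.n_sites}")
print(f"estimated alpha:      {prior.alpha:.3f}")
print(f"arginylome fraction:  {result.fraction:.3f} (planted truth {truth.mean():.3f})")

# intersect the top candidates with (precomputed) conservation evidence
top = result.table.nlargest(5, "posterior")
cons = pd.DataFrame(
    {
        "id": top.protein.values,
        "branch_length": [0.6, 0.5, 0.3, 0.7, 0.5],
        "phylocsf": [12.0, 4.0, 8.0, -1.0, 6.0],
        "residue_conserved": [True, True, True, True, False],
        "consensus_score": top.score.values,
    }
)
kept = ag.conservation_filter(cons, branch_min=0.4, score_min=0.0)
print(f"\ntop candidates surviving the conservation filter: {len(kept)}/5")
print(kept[["id", "branch_length", "phylocsf", "consensus_score"]].to_string(index=False))
print("\nThe fraction estimate is the mean posterior over all scanned D/E")
print("windows; the filter keeps well-aligned, conserved, coding candidates.")
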