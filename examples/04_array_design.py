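"""Design peptide arrays: score bins, single-site sets, shuffle pairs.

Scores a candidate pool with a trained ensemble, samples validation
peptides from low/medium/high tertiles, builds a single-D/E array and a
batch of original/shuffled control pairs.
"""

import arginylome as ag

peptides, _ = ag.generate_dataset(n_pos=200, n_unl=400, seed=1)
model = ag.train_ensemble(ag.to_training_set(peptides), n_members=20, seed=1)

pool = ag.generate_background_peptides(1500, seed=2)
_, X = ag.featurize(pool)
scores = ag.predict_scores(model, X)

selection = ag.select_by_score_bins(pool, scores, n_per_bin=10, seed=3)
for name in ("low", "medium", "high"):
    vals = [scores[i] for i, b in zip(selection.indices, selection.bins) if b == name]
    print(f"{name:6s} bin: {len(vals)} peptides, scores {min(vals):.3f}-{max(vals):.3f}")

single = ag.design_single_site_set(pool, n=222)
print(f"\nsingle-site array: {len(single)} peptides, each with its only D/E first")

batch = ag.generate_background_peptides(38, seed=4)
pairs = ag.make_shuffled_pairs(batch, seed=5)
orig, shuf = pairs[0]
print(f"shuffle array: {len(pairs)} original/shuffled pairs, e.g.")
print(f"  original {orig.sequence}")
print(f"  shuffled {shuf.sequence}  (same residues, scrambled order)")
print("\nIdentical arginylation of both pair members would show the enzyme")
print("reads composition around the site rather than exact residue order.")
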