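# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the `arginylome` package.

## Problem setting

ATE1-mediated arginylation canonically modifies N-terminally exposed D
or E residues. Training data for a site predictor is
positive–unlabeled (PU): known arginylated peptides on one side, and
peptides of unknown status on the other — there is no bona fide
negative set, and some "positives" may themselves be mislabeled
(assay noise, wrong site localization). Every component of the package
is built around this PU structure.

Site windows are 12-mers anchored at the candidate residue (1-based
position 1 of the window), right-padded with `-` where a protein's
C-terminus truncates them. Position 1 is constrained to D/E in
canonical positives and therefore carries no discriminative
information; it is excluded from positional features and from motif
scoring but retained in composition and charge features.

## Feature roster (294)

| block | count | content |
|---|---|---|
| positional indicators | 220 | offsets +1..+11 × 20 residues |
| global composition | 20 | residue frequencies over the window |
| proximal composition | 20 | frequencies over offsets +1..+5 |
| distal composition | 20 | frequencies over offsets +6..+11 |
| scalars | 14 | charge, hydropathy, residue-class fractions |

Charge convention: K, R count +1 and D, E count −1 (His is not counted
as charged); `net_charge = #KR − #DE`, `total_charge = #KR + #DE`.
Hydropathy uses the Kyte–Doolittle scale (configurable). Residue-class
fractions use aromatic {F,W,Y}, aliphatic {A,V,L,I}, uncharged polar
{N,Q,S,T,Y,C,H}, and Taylor's "small" class {A,C,D,G,N,P,S,T,V}.
Pads contribute nothing: indicators at padded offsets are zero and
compositions are renormalized over non-pad residues (an all-pad region
yields a zero block).

Note that the proximal and distal composition blocks are
*position-dependent* by construction: permuting the window tail moves
residues between the two regions. Only the global composition block and
the scalars are invariant under the shuffle-pair design below.

## Motif predictor

A position-specific scoring matrix over offsets +1..+11:

    log_odds[o][a] = log((count(o,a) + λ·b_a) / ((N_o + λ)·b_a))

with pseudocount λ = 1 and background `b` defaulting to the residue
frequencies of the unlabeled set (uniform if none is supplied). The raw
score of a window is the sum of its log-odds over non-pad offsets;
calibration maps it through `logistic((raw − mean)/sd)` with moments
fitted on the training positives (sd 0 falls back to 1), so motif and
ensemble scores share the (0,1) scale. Per-position enrichment
(two-sample logo) uses Fisher's exact test per (offset, residue), one
tail in the direction of the observed frequency difference, uncorrected
by default to match common logo practice; the caller can correct
afterwards.

## Logistic-regression ensemble

Unlabeled instances are treated as class 0 (the standard non-traditional
PU classifier); the class-prior machinery corrects the scores
afterwards. Each of B = 100 members is fitted on a bootstrap of the
positives plus an equal-size uniform subsample of the unlabeled pool
(without replacement when the pool allows), z-scored on the bag, with
L2-regularized logistic regression (λ = 1, lbfgs, tolerance 1e-6, max
1000 iterations). Balanced bags make single-class bags impossible in
practice; a retry loop guards the degenerate path. Prediction averages
member sigmoids; out-of-bag scores average only members whose bag
excludes the instance (NaN when no member qualifies). All resampling
derives from one seed via spawned generators, so training is
reproducible bit-for-bit; the resampling plan is defined over class
pools in row order, so reordering rows reorders the plan with them.

## Class-prior estimation (α, β)

The unlabeled score histogram (50 equal-width bins on [0,1]) is modeled
as `α·f_pos + (1−α)·f_neg`. For each α on a 0.01 grid the log-likelihood
is profiled over the densities. Both histograms are treated as samples
and fitted *jointly*:

    max over simplices f, q of  Σ m_b log f_b + Σ n_b log(α f_b + (1−α) q_b)

where `m` are positive and `n` unlabeled counts. The objective is
jointly concave; alternating exact block maximizations (each a
one-dimensional water-filling / per-bin KKT problem solved by
bisection) converge quickly and are warm-started along the grid.
Fitting `f` jointly instead of plugging in the raw positive histogram
matters: singleton tail bins of the positive sample would otherwise
masquerade as evidence against large mixture weights and bias α̂ down
when the true proportion is high.

The profile curve is flat (within noise) up to the identifiable
proportion and falls beyond it. The estimate is taken at the elbow,
implemented as the largest grid α whose deficit from the curve maximum
stays within 3 nats — the point of departure from flat. A fixed
likelihood-deficit criterion was chosen over literal curvature scans
(second differences, two-segment line fits) because those are dominated
by the much larger likelihood drop near α → 1 and mislocate the elbow;
the 3-nat tolerance is a likelihood-ratio-scale constant, and parameter
recovery under the generator's study conditions (n = 5000 per side,
two-logit component separation) lands within ±0.05 of the truth in
≥ 96% of seeds for α ∈ {0.05, 0.10, 0.30}.

Two boundary regimes are handled explicitly. If even the full-weight
(α = 1) fit is consistent with two-sample multinomial noise — its
likelihood-ratio deficit below the χ²(0.999) bound on the occupied
bins — the two samples are statistically indistinguishable, α is
unidentifiable at the upper boundary, and the estimator returns the
boundary with `unstable=True`. Samples smaller than 50 on either side
are also flagged. Known bias: for identifiable but large proportions
(α ≳ 0.8) the fixed tolerance stops early and α̂ is biased down; the
package's use cases (small proteome-scale fractions) sit far from that
regime.

β (the mislabeled fraction among labeled positives) is estimated by the
symmetric run: the negative density is recovered from the mixture as
`clip((f_unl − α·f_pos)/(1−α))`, renormalized, and the positive
histogram is modeled as `(1−β)·f_truepos + β·f_neg` with `f_truepos`
profiled out (here the known component is a derived density, not a
sample, so the simpler fixed-component profile is used). α ≥ 0.99 makes
the recovery ill-posed and is an error.

The posterior transform maps a score in bin b to
`clip(α·f_pos[b]/f_unl[b], 0, 1)`; queries in bins with no unlabeled
mass borrow the nearest non-empty bin. Evaluated on the same sample
used for estimation, the mean posterior equals α̂ up to clipping, and
its mean over a scanned population is the fraction-of-positives
estimate.

## Evaluation and baselines

AUC is computed in the Mann–Whitney rank form (ties 0.5). Stratified
k-fold CV (k = 10 default) refits the chosen predictor per fold and
reports both the mean of fold AUCs (headline) and the pooled AUC.
Transfer evaluation fits once on one provenance tag and tests on a
disjoint one, flagging shared sequences. Feature association uses
Kendall tau-b with asymptotic p-values and Bonferroni correction at
0.05 by default (constant features get τ = 0, p = 1).

Three baseline protocols measure how much apparent CV performance a
model-guided campaign would report in the absence of real signal:

* `random_labels` keeps the literature-analogue positives and permutes
  the outcomes of the designed-array subset;
* `random_design` additionally replaces the designed array peptides
  with uniform background draws (labels permuted);
* `random_initial` reruns the whole protocol from a random initial set
  with random outcomes, including the score-binned follow-up design.

The expected ordering `random_design ≤ random_labels ≤ full CV` arises
because a *designed* array is score-enriched: against a large unlabeled
background, its positive-labeled rows keep ranking high even with
permuted labels, so the AUC does not collapse to 0.5 — precisely the
design bias the baselines exist to expose. The effect requires the
campaign structure (small genuine positive set, large unlabeled
background, array selected by a model trained on the former); it is
weak or absent when the array subset is not score-selected.

## Array design

Score-guided selection rank-splits the pool at score tertiles and
samples uniformly without replacement from each bin (identical boundary
scores are degenerate and an error). The single-site design keeps
peptides whose only D/E is position 1, so array signals localize
unambiguously. Shuffle pairs fix position 1 and permute positions 2–12,
requiring Hamming distance ≥ 9 of the 11 shuffled positions ("highly
dissimilar" made concrete; strict but satisfiable for typical
compositions, configurable); draws retry with spawned sub-seeds up to
1000 times before declaring the constraint unsatisfiable (e.g.
homopolymer tails).

## Proteome scanning

`all_DE` mode scores every D/E residue; `nterm_conservative` keeps only
protein positions 1 and 2 — the position-2 case is an MD/ME start whose
initiator Met is assumed cleaved (no cleavage prediction is attempted).
Windows with masked residues (X) are skipped. The fraction estimate is
the mean posterior over scanned windows and is invariant to protein
order. The conservation filter consumes precomputed alignment metrics
(branch length score, PhyloCSF, residue conservation) — it never
computes them — and retains one transcript per gene (highest consensus
score, ties broken lexicographically by id).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with exact per-instance truth. Positives are D/E-anchored 12-mers with
signal planted at five cells — H or C at +1 (probability 0.6) and +2
(0.6), Y at +3 (0.4) and +4 (0.4), M at +7 (0.5) — over a background
residue distribution that is uniform by default (making enrichment
power analytically computable) and charge-shifted in positives (K/R
draw probability doubled, D/E halved) to reproduce the mildly-positive
net-charge signature. Unlabeled peptides are background windows with an
α fraction replaced by signal peptides; a β fraction of positives is
replaced by background (mislabeling). Score mixtures draw unit-variance
normal logits separated by a configurable gap (default 2) and squash
them to [0,1]. Synthetic proteomes start every protein with Met plus a
D/E window (signal-carrying at a configurable rate) and keep tails free
of D/E so the conservative scan sees exactly one candidate per protein.

The campaign generator reproduces the model-guided design loop: 40
literature positives against 600 unlabeled background peptides train an
initial 10-member ensemble; a 480-peptide pool carrying signal at rate
0.5 is scored, and 40 peptides per tertile are selected as the array,
labeled by their true signal status.

What passing these tests shows — and does not show. The generator
plants independent per-position enrichments over an exchangeable
background; real peptides have correlated residues, non-uniform
composition, batch effects between assay formats, and signal that is
not exactly positional. Recovery of planted parameters therefore
validates the estimators' correctness, not their field performance on
any particular proteome.

## Numerical choices and degenerate inputs

* Histogram bins 50, grid step 0.01, elbow tolerance 3 nats,
  block-maximization convergence 1e-4 nats with 60-iteration bisections.
* Logistic members: tolerance 1e-6, max 1000 iterations, per-bag
  standardization with zero-variance features given unit scale.
* Motif calibration sd of 0 (single training peptide) falls back to 1;
  zero counts with zero pseudocount floor log-odds at −30.
* Empty peptide sets, single-class folds or training sets, all-pad
  scalar inputs, dimension mismatches, and missing conservation columns
  raise errors naming the offending quantity.
* All stochastic routines take integer seeds and spawn per-component
  generators; identical seeds reproduce results exactly.

Default problem sizes used by the test suite and the acceptance script
(n = 300/600 training peptides, 5000-score mixtures, 2000-protein
proteomes, 30–50 baseline runs with 10-member ensembles) were chosen as
the smallest sizes at which the estimators' sampling noise is
comfortably below the effect sizes being demonstrated.

## Known limitations

* The predictor sees only the 12-mer window: no whole-protein features,
  no structure, no cleavage-site prediction for N-terminal exposure.
* α̂ is biased downward for large identifiable proportions (see above).
* The exact 294-feature roster is a reconstruction honoring the named
  feature families and the count; published applications of this
  protocol did not print their full roster, so feature-level
  comparisons with other implementations are not meaningful.
* Shuffle-pair invariance holds for global composition and scalar
  features only; regional compositions legitimately differ within a
  pair.
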