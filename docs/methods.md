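# Methods

This note records the model, the procedures, the parameter choices, and the
design decisions behind `salqsar`, in enough detail that a maintainer can
tell which behaviors are contracts and which are conventions.

## The classifier

The encoder maps a heavy-atom molecular graph to a 128-dimensional neural
fingerprint through three convolutional units, a per-atom dense layer, and
a gather. One convolutional unit computes

    conv:  h'_v = relu(W_self h_v + W_nbr * sum_{u in N(v)} h_u + b)
    pool:  h''_v = elementwise max over { h'_u : u in N(v) or u = v }

with degree-agnostic sum aggregation and separate self/neighbor weight
matrices — the simplest form that preserves permutation equivariance and a
fixed receptive-field growth per unit. The per-atom dense relu layer
produces the saliency tensor S (n_atom × 128); the gather is a plain column
sum followed by tanh, so `tanh(colsum(S))` equals the fingerprint exactly
(asserted to 1e-6 in the tests). This exact decomposition is the point of
the architecture: each row of S is an additive atomic contribution, which
is what licenses reading the rows as per-atom importance.

A note on receptive fields: the convolution propagates information one
bond and the neighborhood max-pool another, so each unit widens an atom's
receptive field by two bonds and the full encoder by six. The saliency
*neighborhood* radius is nevertheless fixed at three bonds — the scale the
three successive convolutions are organized around and the radius at which
fragments stay small enough to read. The tests pin the true six-bond
horizon (features beyond it cannot change a saliency row) separately from
the three-bond reporting radius.

The classifier head is a 64-unit relu layer and a 2-logit softmax on the
fingerprint; o is the active-class probability. Training minimizes
cross-entropy plus `l2 * sum of squared weights` (weights only, biases
excluded; the penalty gradient is applied per Adam update) for 50 epochs,
batch size 64, learning rate 1e-3, Adam. Everything is NumPy with
hand-derived gradients (max-pool gradients route to the argmax atom, ties
to the lowest index), so two runs with the same seed are bitwise
identical. Two presets are exposed: the default (64, 64, 64) with L2 5e-4,
and a contracted shape (36, 50, 16) with L2 6e-4 obtained by shrinking the
three layers by 44%, 21% and 75% — derived reductions, not independently
meaningful absolutes. Molecules that fail SMILES parsing at fit time are
dropped with a logged count.

## Saliency ranking

Per fingerprint column, the atom with the largest saliency amplitude wins
the column (a configurable top-m per column is exposed; default m=1).
Columns that are exactly zero everywhere carry no evidence and are
skipped; an all-zero tensor yields an empty candidate list rather than an
arbitrary pick. Each winning atom gets frequency (columns won), amplitude
(mean winning amplitude), and score = frequency × softmax(amplitude),
where the softmax (temperature 1) runs over the atoms that won at least
one column. Ties break toward the lower atom index. The top five scored
atoms (k < 5 when fewer exist) are materialized as radius-3 neighborhoods
with canonical fragment SMILES. The exact weighting form — frequency
times softmax of mean amplitude — is one defensible reading of
"frequency-weighted amplitude modulated by a standard softmax"; it is
isolated in `rank_neighborhoods` so an alternative weighting is a one-line
change, and the brute-force oracle tests pin the current semantics.

## Highlight maps

A selected neighborhood with center c and score s contributes
`s * 0.8^d(c,a)` to every atom a within three bonds of c and nothing
beyond; overlapping neighborhoods sum, with no clipping. A constant
per-bond factor is geometric rather than linear, and both readings of
"decaying by a factor per bond" are implemented: the multiplicative
default and an `additive` ramp `s * max(0, 1 - 0.2 d)` behind a switch.
Color is presentation-only: amplitudes are normalized to the per-molecule
maximum at render time and drawn as a white-to-orange ramp, one SVG
ellipse per highlighted atom; numerical outputs never depend on rendering.

## Chronological splitting and similarity diagnostics

Records sort stably by (date, id) — ties fall back to lexicographic id —
and cut at floor(f·N) for f = 0.7, 0.8, 0.9. Hyperparameter search trains
on the first 70% and validates on 70–80%; final models retrain on the full
earliest 80% (a flag keeps the 70% slice instead). Duplicate SMILES across
the boundary are allowed. The similarity report computes mean
nearest-neighbor Tanimoto over 2048-bit ECFP4: train–train and test–test
with self-exclusion, train–test, and each test time slice against the
earliest-70% train set.

## Substructure clustering

Salient fragments are fingerprinted (ECFP4; fragments whose SMILES breaks
ring aromaticity are parsed leniently with kekulization skipped) and
clustered per confusion quadrant. The o = 0.5 boundary counts as
predicted-negative, since strict inequalities leave it open. Density peak
clustering follows Rodriguez–Laio: ρ_i counts neighbors within d_c, δ_i is
the distance to the nearest higher-density point (global max for the
densest), γ = ρδ, centers are the points above the largest relative gap in
sorted γ, everyone else joins their nearest higher-density neighbor.
Two numerical choices matter in practice and were set after watching the
procedure fail without them:

* d_c defaults to the 2nd percentile of the strictly positive pairwise
  distances — the canonical 1–2% neighbor-fraction rule. Fragment Tanimoto
  distances concentrate near 0.85–0.9, so a looser cutoff (say the 10th
  percentile of all distances) makes nearly every point every other's
  neighbor and erases the density structure entirely. Zero distances are
  excluded from the percentile because duplicate fragment groups would
  otherwise drag the cutoff to zero.
* the γ-gap search is confined to the top ⌈√n⌉ positions; in the γ→0 tail
  the relative gap is spuriously close to 1 and would shatter the data
  into singletons.

Fewer than 8 fragments, or all-zero densities at the chosen d_c, triggers
the fallback: k-means with k=2 on the fingerprints as 0/1 vectors,
farthest-pair initialization, deterministic. Clusters are ranked by
population, ties by smallest member id. All four quadrants are computable;
the utilities default to true positives, the quadrant whose clusters are
directly interpretable as activity-relevant chemistry.

## Hyperparameter search

The "greedy Gaussian" search is literal Gaussian perturbation sampling
around a greedy incumbent — not a Gaussian-process surrogate, despite the
similarity of names. Per iteration, 80 candidates are drawn around the
seed (relative σ = 0.2 per dimension; L2 multiplicatively on the log
scale; conv sizes rounded and clamped to [4, 256] — all configurable), the
best of candidates-plus-incumbent seeds the next iteration, and the
incumbent is retained without re-evaluation, making its objective trace
non-decreasing by construction. Ten iterations by default. The QSAR
objective is the mean validation-slice AUC across datasets, training on
the earliest 70%; per-dataset failures are skipped and logged.

## Evaluation

AUROC uses midrank tie handling (via scikit-learn; an independent
pairwise-counting oracle in the tests pins the semantics). The
heterogeneous confidence half-width over per-dataset AUCs is
1.96 · sd / √n with the sample (n−1) standard deviation — analogous to a
95% interval but not a true one when the datasets are heterogeneous. The
baseline is a scikit-learn random forest, 100 trees, other
hyperparameters at library defaults (recorded in each report), trained on
2048-bit ECFP4 of the chronological training slice.

## The synthetic-data generator

The generator emulates the statistical shape of curated public
bioactivity archives: per-target datasets of a few hundred to a few
thousand molecules, binary labels, deposition dates spanning years, and
chemotype turnover over time. Defaults, chosen once: n = 600 molecules,
active fraction 0.5, label noise 0, drift 1.0, a ten-year date window,
sulfonamide motif S(=O)(=O)N.

Molecules are assembled, not sampled as strings, so validity is
guaranteed: a ring scaffold from one of nine families (benzenoid,
naphthalene, azine, quinoline, piperidine/piperazine, morpholine/oxane,
5-ring heteroaryl, carbocycle, azole) plus 2–4 decorations joined by
single bonds at free-valence C/N sites. Actives receive the motif grafted
through a two-carbon linker — pharmacophores hang off scaffolds through
linkers in real leads, and the linker keeps the motif's radius-3
environment consistent across actives, which is what makes salient
fragments of one motif family resemble each other. With zero label noise
the label equals motif presence exactly (verified by subgraph match);
noise flips labels independently.

Temporal drift has four coupled components, each mirroring a real
archive phenomenon: (1) scaffold families carry Gaussian time windows
(softmax of −drift·((u−c)/0.2)² over date rank u) whose centers extend
past the end of the window, so chemotype turnover continues through the
latest slice instead of saturating; (2) the decoration palette drifts the
same way; (3) molecular size inflates (2 + Binomial(2, p(u)) decorations
with p rising over u); and (4) a late-era methylsulfone decoration acts
as a decoy — it shares circular-fingerprint environments with the
sulfonamide motif without containing it, so models trained on early data
genuinely lose accuracy on late molecules rather than merely seeing lower
similarity. At drift 2.0 the validation ≥ early ≥ late train-similarity
ordering holds in ≈19 of 20 replicates across independent seed blocks; at
drift 0 it occurs at chance rates.

What the generator does **not** emulate: realistic property
distributions (logP, MW profiles), activity cliffs, stereochemistry,
assay-specific noise structure, or correlated label errors. Passing tests
on this data shows the pipeline's machinery — splitting, training,
attribution, clustering — behaves as designed when a real motif-activity
relationship exists; it does not certify predictive performance on real
assay data.

## Problem sizes in the test suite

The suite trains full models where the property under test requires it:
the planted-motif recovery check runs five complete 50-epoch trainings on
n = 600 datasets with the contracted architecture, and the drift check
runs twenty similarity replicates plus one gCNN and one RF training.
Smaller fixtures (n = 200, 15 epochs, 16-wide layers) back the structural
and clustering tests, sized so the whole suite completes in a few minutes
on one CPU.

## Known limitations

* The saliency weighting and the per-column top-1 reduction are one
  interpretation of a procedure with several defensible readings; both are
  parameterized.
* DPC cluster counts are sensitive to d_c on fragment fingerprints whose
  distance distributions are strongly bimodal; the γ-gap rule with the
  √n cap is a heuristic, and a fixed-count override is exposed.
* The NumPy trainer is single-threaded per molecule and sized for
  datasets up to a few thousand molecules; it is not a GPU-scale trainer.
* Fragment SMILES of aromatic-ring cutouts are written with the parent's
  aromatic flags and are not guaranteed to be independently valid
  molecules; they are identifiers for fingerprinting and display, not
  synthesis proposals.
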