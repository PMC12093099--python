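# Methods

## Representation: the heteroduplex-proximal nanoenvironment

A snapshot is one conformation of an sgRNA–dsDNA–Cas9 complex reduced to
protein Cα atoms plus the C4′ pseudo-atoms of the 20 heteroduplex base
pairs (positions +1 PAM-proximal … +20 PAM-distal). The model's feature
space is the outer product of

- the **HPR set** *H*: residues whose Cα lies within [3, 7] Å of *any*
  heteroduplex C4′ atom in at least one training snapshot, and
- the descriptor set *S* (residue-level physico-chemical/structural
  descriptors; names follow `Cas9_<residue>_<slug>[_<GN|SW|WNA|VD>]`).

Assumptions: the relevant structural signal is carried by the residues
lining the heteroduplex; a trajectory's snapshots share one activity label;
train and test snapshots from the same trajectory are distributed
similarly, so a per-trajectory tail holdout is a fair test of conformational
generalization (generalization to unseen guide–target pairs is probed
separately by trajectory-holdout CV and is known to be much harder).

Both distance bounds are treated as **inclusive** — the boundary belongs to
the shell, the conservative reading of a "3 to 7 Å" specification. The HPR
computation is restricted to training snapshots to prevent leakage; a
construction test asserts that a residue entering the shell only in
held-out snapshots never reaches *H*.

Missing descriptor values are handled by **dropping the whole feature
column** (and logging it), never by imputation: imputation statistics would
have to be computed somewhere, and any choice other than train-only
statistics leaks; dropping is auditable and order-independent.

## Prediction pipeline

`StandardScaler` → surrogate *m₁* feature ranking → final regressor *m₂*
on the top *f* columns. Choices that the pipeline contract leaves open:

- **Importance definition per family.** |coefficient| for linear and ridge
  (coefficients of standardized features are comparable), impurity-gain
  `feature_importances_` for the tree ensembles — each family's native
  notion, nothing exotic layered on top.
- **Tie-breaking.** Feature ranking uses a stable sort, so ties resolve to
  the lower column index; the model-pair rule resolves exact ties to the
  earlier-declared pair; both are logged and deterministic.
- **Model families.** *m₁* ∈ {linear, ridge, XGBoost, extra trees,
  LightGBM}; *m₂* adds scikit-learn's `GradientBoostingRegressor` as the
  sixth family, a third, independently implemented boosting ensemble. All
  families run with library-default hyperparameters plus a fixed seed,
  recorded in the model's provenance.
- **Zero-variance features** keep scale 1 after centering (the
  `StandardScaler` convention), so constant columns pass through as zeros
  rather than NaNs.
- **Degenerate labels** (all activities equal) trigger a warning rather
  than an error: rank metrics are undefined there, but the fit itself is
  well posed.

Splits: the last 4 snapshots of every trajectory form the test partition;
the remaining rows are shuffled once (seeded) into five near-equal CV
folds. Grid search fits each surrogate once per fold and reuses its ranking
for every (m₂, f) cell — mathematically identical to refitting per cell. A
failed cell is recorded as missing and the run continues.

Feature-size rule: *f** = min{f : ρ(f+5) − ρ(f) ≤ Δρ_S}, Δρ_S = 2×10⁻³
by default. When every increment beats the threshold the largest candidate
is kept (with a log notice) — the curve is still rising, so truncating
earlier would discard validated signal.

One simplification relative to a fully nested protocol: the descriptor
matrix is assembled once from the training-partition HPR set, and CV folds
reuse those columns rather than recomputing a per-fold HPR set. The
per-fold shells differ from the full training shell by at most a handful of
residues, and the scaler is refit per fold, so the residual optimism is
limited to column *membership*; the held-out test partition never
influences the shell at all. Recomputing per-fold shells is possible with
the public API if exactness is needed.

## Shapley interpretation

Three attribution back-ends, routed by final-model family:

- linear/ridge: the closed form φ_j = w_j (x_j − r_j) against a reference
  point r (exact);
- XGBoost / LightGBM: the libraries' built-in exact path-dependent tree
  Shapley contributions;
- anything else: a seeded **permutation-sampling estimator** against a
  single reference point. Marginal contributions along one permutation
  telescope to f(x) − f(r), so additivity is exact at any sample count;
  with few features (f! ≤ sample budget) all permutations are enumerated
  and the estimate is exact. Default 256 permutations — at hotspot-report
  granularity the Monte-Carlo error is far below the differences between
  groups, and additivity does not depend on the count.

The default reference point is the training mean (the origin of the
standardized space). The additivity contract |base + Σφ − prediction| is
enforced on every report at 1e-6 (the XGBoost back-end computes
contributions in float32 and is checked at 1e-4).

The per-feature importance uses the absolute value, I_j = mean|φ_j|, i.e.
the singleton case of the group formula I_J = mean|Σ_{j∈J} φ_j|. Without
the absolute value, attributions of opposite sign across datapoints cancel
and every importance collapses toward zero, which would make the ranking
meaningless.

Residue hotspots: mean pairwise Cα distances (averaged over all snapshots)
are clustered with **complete linkage** cut at 12 Å, because the stated
constraint — no two residues in a cluster further apart than the ceiling —
is precisely the complete-linkage merge criterion. Multi-residue clusters
become "Group 1, 2, …" ordered by smallest member; singletons pool into
"other".

Cas9 domain annotations (REC/RuvC/HNH/BH/PI and contiguous segments such as
RuvC-II) ship as an editable YAML following the canonical SpCas9
architecture; the descriptor-slug → parent-class lookup is likewise a YAML
resolved by longest keyword match, with unknown slugs annotated as
`unknown` plus a warning rather than a hard failure.

## Stability analysis

Per-site RMSD against frame 1 of the trajectory, optionally after
least-squares superposition of each frame onto frame 1 using **all protein
Cα atoms** (rigid drift removed; the invariance under per-frame rigid
motions is property-tested). Atom selections: Cα (default) or backbone
heavy atoms for protein sites; C4′, nucleic backbone + ring anchors
(C4/N9 for purines, C6/N1 for pyrimidines), or P + N9/N1 for bases —
richer selections require parsing with the full atom table retained.

Mutant vs reference comparison assumes normal RMSD distributions and uses
the closed-form Gaussian KL divergence (sample sd with the n−1
denominator). Verdicts: `similar` below a KL threshold (default 0.25 — at
equal means this corresponds to roughly a 1.9-fold sd ratio, a deliberately
conservative boundary; configurable), otherwise `more_mobile` /
`more_stable` by the sd comparison. Zero-variance series are rejected as
degenerate rather than silently producing infinite divergences.

## Synthetic data generator

The generator emulates the *shape* of the real study, not its physics:

- 28 trajectories × 24 snapshots; a 20-bp heteroduplex as two parallel
  straight C4′ strands 6 Å apart with a 5 Å rise (straight-ladder geometry
  makes every distance assertion exact — no helical realism is attempted);
- exactly `n_proximal_residues` residues placed with nearest-C4′ distance
  inside the shell (with a jitter-proportional safety margin) and the rest
  beyond 9 Å; snapshots are the template plus isotropic Gaussian jitter;
- one latent z_t ~ N(0,1) per trajectory; planted features take
  z_t + N(0, noise_sd) per snapshot, all other cells are N(0,1) noise;
  activity is the affine-clipped map
  a = clip(0.5 + 0.3·(Σ w z)/(Σ|w|) + ε, 0, 1), shared by the trajectory's
  snapshots. The latent is shared across planted features so that, noise
  free, any single planted feature is rank-perfectly related to activity.
- every off-target trajectory carries one random PAM-distal (positions
  11–20) target-strand substitution from which the guide:DNA interface
  label is derived; snapshot ids follow the four-character scheme
  (start structure, mutation code 0–9A–Z, two-digit snapshot number).

Defaults are the benchmark conditions used throughout the tests: 40
proximal residues × 50 descriptors = 2000 columns, 20 planted features
with equal weights, noise_sd = 1/3 (per-feature signal-to-noise 3),
label_noise_sd = 0, jitter_sd = 0.25 Å. All randomness flows from one seed
through named `SeedSequence` substreams (geometry, truth, latents, jitter,
descriptors, labels, metadata), so each stage is independently
reproducible.

What passing tests on this generator do **not** show: robustness to real
descriptor distributions (heavy tails, inter-descriptor correlation
structure), to heteroduplex geometry changes that correlate with activity,
to label noise between replicate assays, or to distribution shift between
guide–target pairs. The trajectory-holdout CV utility exists precisely
because the tail-holdout split does not measure the last of these.

## Problem sizes and runtime choices

The test suite runs the full-width (380 × 1671 = 634,980 column) assembly
with two snapshots of constant values — column count is a pure bookkeeping
property — and the recovery benchmark at the default 672 × 2000 scale with
the fixed xgboost → extra-trees pipeline at f = 30 over five seeds per
noise level; the grid machinery itself is exercised on reduced grids where
the full 300-cell sweep would add nothing but wall-clock time. The
worked-example grid in `examples/03` spans 2 × 2 × 3 cells for the same
reason.

## Known limitations

- Per-fold HPR recomputation inside CV is not performed by default (see
  above).
- PDB input only (no mmCIF); solvent/ions must be mapped to ignored chains;
  alternate locations beyond the first are discarded.
- No computation of the descriptor values themselves — tables are consumed
  (or synthesized), never derived from structures.
- The permutation Shapley back-end prices in prediction calls:
  permutations × (f+1) batched predicts; for very wide final models prefer
  a boosted-tree final (native contributions) or lower the permutation
  count (additivity is unaffected).
- Trajectory-holdout generalization is reported, not solved: with 28
  single-mismatch trajectories, folds whose mismatch positions are absent
  from training are expected to generalize poorly.
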