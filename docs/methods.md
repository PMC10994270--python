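# Methods

`morphoscreen` analyses morphological-profiling (Cell Painting style)
drug screens in which a mutant cell line is compared against its
isogenic wild-type control and compounds are sought that shift the
mutant morphological signature back toward wild-type.  The concrete
setting is a neural-progenitor-cell screen around an Alzheimer's-risk
sorting receptor: three knock-out sub-clones, each screened against a
330-compound annotated library at 100, 300 and 1000 nM, one plate per
(sub-clone, concentration) pair, with 24 wild-type vehicle wells
(positive controls), 16 knock-out vehicle wells (negative controls) and
6 untreated knock-out wells per 384-well plate, and 4 image fields per
well.  Because the real screen's feature tables are not publicly
retrievable, the package ships a generative model of such screens with
known ground truth; every stage is validated against planted effects.

## Synthetic screens

Each image record is a vector of `n_features = 1100` features named
`Compartment_Class_Index` over nine feature classes (colocalization,
adjacency, size, shape, area, texture, radial distribution, granularity,
intensity).  For feature f and record r,

    x[r,f] = mu_f + s_f * ( shift(group, f)
                            + plate + well + latent factors + field noise )

* `shift` is 0 for wild-type wells; `delta * g_f` for knock-out vehicle
  and untreated wells, where g is a 0/1 mask over a fraction
  `affected_fraction = 0.2` of features and `delta = 1` is the
  standardized per-feature genotype displacement; and
  `(1 - rho_eff) * delta * g_f + eta_c * d_c[f]` for knock-out wells
  treated with compound c.
* `rho_c in [0,1]` is the compound's reversion strength.  Ten compounds
  are planted as true reverters with `rho >= 0.8` (both salt-form pairs
  are always among them, so the salt collapse is exercised end to end);
  the rest draw `rho ~ U(0, 0.2)`.  By default `rho_eff = rho * dose/1000`
  (monotone dose response); a dose-independent mode is available.
* `eta_c ~ |N(0, 0.25)|` is an off-target displacement along a random
  unit direction `d_c`, resampled per compound but fixed across its
  wells and concentrations — a reproducible drug effect.
* Correlated noise comes from 20 latent factors loading 0.6 on
  contiguous feature blocks, plus Gaussian plate (sd 0.3), well (sd 0.3)
  and field components; the field sd is chosen so the total image-level
  within-group sd is 1, making `delta` a standardized effect.
* `mu_f ~ N(0,2)` and `s_f ~ U(0.5,2)` are arbitrary per-feature
  baselines and scales; the robust normalization must remove them.

What the generator does *not* emulate: spatial plate gradients and edge
effects, optical artefacts, cell-count-dependent feature noise,
non-Gaussian feature marginals, and compound fluorescence interference.
Passing tests therefore demonstrate the statistical machinery under a
faithful layout and covariance structure, not robustness to every
artefact of real imaging.

## Feature QC

Fixed order: aggregate -> normalize -> drop degenerate -> drop redundant
-> ANOVA filter; the chain is idempotent on its own output.

* Image fields collapse to the well-level median (missing fields
  ignored).
* Normalization is a per-plate robust z-score, `(x - median) /
  (1.4826 * MAD)`, anchored on the knock-out vehicle wells.  Anchoring
  on the mutant baseline makes "reversion toward wild-type" a signed
  displacement from zero; a wild-type-anchored mode is provided.
  Features with zero MAD on any plate are flagged degenerate and never
  divided.
* Degenerate removal drops zero-variance columns, then columns linearly
  dependent on earlier retained ones (sequential Gram-Schmidt with a
  relative tolerance, default 1e-8).
* Redundancy removal iterates: among pairs with |Pearson r| >= 0.95 the
  member with the larger mean absolute correlation to all other active
  features is dropped (ties drop the lexicographically later name).
* The per-feature one-way ANOVA runs across treatment classes at well
  level — not image level, to avoid pseudo-replicating fields within a
  well — with Benjamini-Hochberg FDR across testable features.

## Signature space

Correlation-matrix PCA (eigenvalues sum to the feature count) with the
component count selected by a fixed rule (default k = 50, the screen's
working dimensionality), Kaiser's criterion (eigenvalues strictly > 1)
or a scree elbow (maximum second difference).  The retained loading
matrix is obliquely rotated by direct oblimin with `gamma = 0` (direct
quartimin) — the standard default when no gamma is stated — and scores
are computed by the ten Berge correlation-preserving construction

    Lt = Lambda Phi^{1/2}
    W  = R^{-1/2} [ R^{-1/2} Lt (Lt' R^{-1} Lt)^{-1/2} ] Phi^{1/2}

so that the scores' sample correlation matrix equals the factor
correlation Phi exactly (verified to 1e-8 on every fitted model).  The
rotation is minimized by the gradient-projection algorithm over oblique
rotation matrices with unit-length columns, followed by a quasi-Newton
(L-BFGS) polish on the normalized-column parameterization: plain
gradient projection crawls on the long shallow plateaus that a 50-factor
rotation of weakly structured loadings produces, while the polish
reaches a projected-gradient norm below 1e-6 in seconds.  Random mixes
of exact simple-structure loadings are recovered to better than 1e-6
(up to column sign and permutation).  Reduction is fit on all wells
jointly (labels never enter the fit); a controls-only fit mode exists,
in which held-out wells are projected with training standardization
parameters only.

## Separation statistic

The separation of two labelled groups is `D = mean between-group
dissimilarity / mean within-group dissimilarity` with a
label-permutation p-value, `p = (1 + #{D_perm >= D_obs}) / (n_perm + 1)`
(default 999 permutations).  Bray-Curtis requires non-negative inputs,
so each component is min-max rescaled to [0,1] across the compared
profiles first; the rescaling depends only on the pooled profiles and is
therefore fixed under permutation.  D is a ratio and can exceed 1; on
the default screen's control wells it is ~1.16 with p = 0.001 (the
add-one floor).  The hierarchical-clustering view (Ward linkage on
min-max scaled scores) orders the control wells into two clean genotype
blocks.

## Classification and scoring

A three-layer neural network (one hidden layer, logistic output; L2
weight decay) is trained on the vehicle-treated control images in
component space, wild-type as the focus class.  Hidden size and decay
are chosen by two-fold cross-validated accuracy over a small grid
(sizes 3/5/10, decays 1e-4/1e-2/1), ties preferring the smaller size and
then the larger decay; training uses scikit-learn's L-BFGS solver with
tolerance 1e-6 and at most 500 iterations, fully seeded.  The 24:16
class imbalance is handled by inverse-frequency weighting, realized for
the network as deterministic minority-class oversampling (the MLP
implementation accepts no class weights); the random-forest and SVM
comparators use `class_weight="balanced"` and share the identical
split/evaluate/score interfaces.  The 80/20 train/test split is
stratified by class and grouped by well, so a well's four fields never
straddle the split.  Evaluation reports the confusion matrix on held-out
controls with sensitivity TP/(TP+FN), specificity TN/(TN+FP) and
detection rate TP/total.  Every compound-treated image receives the
focus-class probability; the well score is the median over its fields
(1.0 = fully wild-type-like).

## Hit calling

A compound is a hit when its score strictly exceeds `tau = 0.505` in
every sub-clone at one or more concentrations.  The default replication
mode (`any_conc`) lets each sub-clone qualify at a different
concentration, the plausible reading of replication "at one or more of
the concentrations tested"; a stricter `same_conc` mode (one single
concentration exceeding tau in all sub-clones) is provided, and its hit
sets are provably nested inside the default's.  Missing wells (e.g.
simulated toxic cell loss) count as non-exceeding — conservative.  Hits
sharing a parent drug (salt formulations) collapse to unique drug
treatments keeping the best score; drugs are then grouped by annotated
mechanism class, with unannotated drugs in an explicit bucket.

## Enrichment

Gene-set over-representation uses the hypergeometric upper tail
P(X >= x) with parameters N (background), K (set within background),
n (query), x (overlap); BH FDR across tested sets; and enrichment
strength log10(observed/expected), defined only for x > 0.  The
background is the expressed-gene list, not the whole annotation
universe: padding the background with genes absent from the query and
the sets strictly shrinks every p-value (the expected overlap shrinks
while the observed one does not), so an unexpressed-gene-inflated
background manufactures significance.  A property test pins down this
direction.  Gene sets ship as small GMT fixtures (GO/KEGG-style sets
including a deliberately synthetic "Alzheimer-like" toy pathway) so no
test queries a live database.

## Pipeline and reproducibility

One root seed deterministically derives per-stage seeds
(`numpy.random.SeedSequence.spawn`), so a single integer reproduces a
whole screen; identical config and seed give identical hit lists.  The
configuration object rejects unknown keys.  Problem sizes used by the
test suite and the acceptance script: the full default screen (9 plates,
13,536 image records, 1100 features, 50 components) for end-to-end
recovery across five seeds; 400 replicates (199 permutations each) for
null calibration of the separation test; 100 replicates of m = 1000
features at the screen's control group sizes (216 vs 144 wells) for the
FDR check; exhaustive enumeration up to N = 30 for the hypergeometric
oracle.

## Known limitations

* The redundancy threshold (0.95) and the normalization anchor are
  package choices; the upstream screen's proprietary pre-processing is
  unspecified, so retained-feature counts are reported, not targeted.
* The Bray-Curtis separation statistic is a between/within ratio on
  min-max rescaled component scores; other software may scale or define
  the score differently, so only its qualitative behaviour (D > 1 with
  small p for separated groups, D ~ 1 under exchangeability) transfers.
* The scree elbow (maximum second difference) is one of several elbow
  conventions; the default pipeline uses the fixed-k rule.
* Oblimin minimization is non-convex; different starts can reach
  different local minima.  `n_starts` adds random orthonormal starts and
  keeps the lowest criterion; the default single start from the
  unrotated solution is the conventional choice.
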