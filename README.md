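# morphoscreen

Analysis pipeline for morphological-profiling (Cell Painting) drug
screens that look for **phenotypic reversion**: compounds that shift a
mutant cell line's morphological signature back toward its isogenic
wild-type control.  The motivating setting is a neural-progenitor-cell
screen around an Alzheimer's-risk sorting-receptor knock-out — three
knock-out sub-clones screened against a 330-compound annotated
anti-cancer library at three concentrations (one 384-well plate per
sub-clone x concentration, so 9 plates), with 24 wild-type vehicle
wells, 16 knock-out vehicle wells and 4 image fields per well.

The pipeline, for people running or re-analysing such screens:

1. **Synthetic screens with ground truth** — a generative model of
   feature tables (correlated features, plate/well/field variance
   components, a planted genotype effect δ·g on a feature subset, and a
   per-compound reversion strength ρ ∈ [0,1]) so every downstream stage
   is verifiable without any data download.
2. **Feature QC** — well-level median aggregation, per-plate robust
   z-scoring against the knock-out vehicle wells
   (x → (x − median)/(1.4826·MAD)), removal of degenerate and redundant
   variables, and a per-feature one-way ANOVA with Benjamini–Hochberg
   FDR across treatment classes.
3. **Signature space** — correlation-matrix PCA (k = 50 components by
   default; Kaiser and scree rules available), direct-oblimin rotation
   (gradient projection, γ = 0) and **ten Berge
   correlation-preserving factor scores**: corr(scores) = Φ exactly.
4. **Separation** — Bray–Curtis (Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ) on min–max rescaled
   scores) and Euclidean between/within dissimilarity ratios D with
   label-permutation p-values, plus a hierarchical-clustering view.
5. **Classifier scoring** — a three-layer neural network (hidden size
   and weight decay tuned by two-fold CV; RF and SVM comparators)
   trained on vehicle-treated control images, wild-type as focus class;
   each treated well scores the median probability of classifying as
   wild-type (1.0 = fully wild-type-like).
6. **Hit calling** — hit ⇔ score > 0.505 in **all** sub-clones at one
   or more concentrations; salt formulations collapse to unique drugs;
   hits group by mechanism class.
7. **Enrichment** — hypergeometric over-representation of hit-drug
   targets against expressed-gene-background GMT gene sets, with BH FDR
   and strength = log10(observed/expected).

## Worked example

One command runs the whole default screen (a few tens of seconds):

```bash
morphoscreen run-all --seed 1 --out results/run1
```

or stage by stage, with narrative output:

```bash
python analysis/01_simulate_screen.py --seed 1
python analysis/02_feature_qc.py
python analysis/03_reduce_dimensions.py --seed 1
python analysis/04_test_separation.py --seed 1
python analysis/05_classify_and_score.py --seed 1
python analysis/06_call_hits.py
python analysis/07_enrichment.py
```

which prints, at seed 1:

```
screen: 9 plates x 376 wells x 4 fields = 13536 image records, 1100 features
planted reverters (10): C005, C062, C071, C101, C102, C177, C201, C202, C260, C269
features: 1100 in -> 1100 retained (0 degenerate, 0 redundant dropped)
ANOVA across treatment classes: 221 features significant at q < 0.05
retained k = 50 components (37.7% of variance); Kaiser criterion alone would keep 264
bray_curtis: D = 1.1577 (between/within ratio), permutation p = 0.001 (999 permutations)
held-out confusion matrix: TP=172 FP=0 TN=116 FN=0
sensitivity=1.0000 specificity=1.0000 detection rate=0.5972 accuracy=1.0000
mean wild-type probability: WT wells 0.9996, KO wells 0.0004
hits (> 0.505, any_conc, replicated in 3 sub-clones): 10 compounds -> 8 unique drugs
vs ground truth: 10/10 planted reverters recovered, 0 false positives among 320
```

Reading the numbers: the control classes separate cleanly in the
50-component space (D > 1 at the permutation floor p = 1/1000); held-out
control images classify perfectly, with mean wild-type probability
0.9996 for wild-type wells and 0.0004 for knock-out wells; all ten
planted reverters — including both salt-form pairs, which collapse
10 → 8 unique drugs — are called with no false positives among the 320
non-reverters.

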