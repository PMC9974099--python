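# Methods

This note records the models, parameter choices, numerical decisions, and
known limitations behind `gbmcaf`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## The scoring model

A cell's CAF probability score is a mean of per-gene evidence terms over a
marker panel. For a panel gene g with log-normalized expression
`u_g = ln(1 + count·scale/total)` and a Gaussian kernel
`k(u) = exp(−u²/2h²)`:

* positive markers contribute `1 − k(u_g)` (evidence of expression),
* negative markers contribute `k(u_g)` (evidence of absence),

and `p` is the sum divided by `n`, the number of panel genes actually
present in the matrix. Each term lies in [0, 1], so `p` does too; the final
clamp is numerical insurance only. Useful exact limits (all asserted in
tests): a fully silent cell scores `|neg|/n` (5/14 for the default CAF
panel); as `h → ∞` every cell scores `|neg|/n`; as `h → 0⁺` the score
degenerates to the zero/nonzero detection pattern. The score is monotone
increasing in every positive marker and decreasing in every negative one.

**Bandwidth.** `h = 1.0` on the natural-log scale. After LogNormalize at
scale 10⁴ and a typical library of a few thousand UMI, a single detected
count gives `u ≈ 1–3`, so `h = 1` places the kernel's half-mass right at
the detected/undetected divide: one detected count of a negative marker
already halves its absence credit, while positive markers need expression
well above one count for full credit. `h` is exposed everywhere.

**Missing panel genes** are dropped from both the sum and `n`, reported,
and never imputed: `p` stays a mean of observed evidence.

**"Expressed" means count ≥ 1** (`detect_min`, exposed) for negative
selection, prevalence, coverage, and lineage rules — the least-assumption
reading of detection in UMI data.

**The astrocyte panel** (GFAP, AQP4, SLC1A3, SLC1A2, S100B, ALDH1L1, GJA1,
SOX9, NDRG2, FGFR3) is a stand-in list of canonical astrocyte markers: an
all-positive panel whose negative sum is empty.

## QC semantics

Filters are strict exclusions: mito fraction > 0.20 removed, UMI < 200 or
> 20,000 removed; cells at exactly 0.20, 200, or 20,000 are retained, and
zero-depth cells always fail. This boundary reading is load-bearing — an
off-by-one here changes every downstream count, so it is pinned by a
dedicated boundary suite. Genes are never filtered. Mitochondrial genes
are recognized by the name prefix `MT-` (configurable).

## CNV inference

Genes are partitioned by start position into fixed 1 Mb half-open bins per
chromosome (names normalized by stripping a `chr` prefix); a cell's bin
value is the mean log-normalized expression of the member genes; bins are
centered by subtracting a reference value per bin; centered values are
smoothed along each chromosome with a moving average spanning 5 Mb
(`scipy.ndimage.uniform_filter1d`, nearest-edge mode, so smoothed values
never leave the raw [min, max] envelope).

**Centering statistic.** The reference value is the per-bin *mean* across
reference cells (`center_stat="median"` is available). With roughly one
gene per bin and single-digit counts, per-bin values are nearly discrete
log1p levels; the across-cell median then sits a fixed ~0.2 log-units away
from the mean, which both mis-centers the neutral baseline and destroys the
interpretability of the shift magnitude. Against the mean, a planted fold
change f shifts the profile by approximately ln f (compressed somewhat by
log1p at low counts — the recovered chr7 shift is ≈ 0.37 vs ln 1.5 ≈ 0.41).

**Reference population.** Default is reference-free (all cells). The
pipeline runs two passes: a first reference-free pass calls malignant
cells, a second pass recenters against the non-malignant cells and
re-calls. This removes the baseline drag a 20% malignant fraction exerts
on the reference and lifts call sensitivity from ≈ 0.90 to ≈ 0.96 on the
default synthetic mixture. A mask of known-diploid cells can be passed
directly for sharper synthetic experiments.

**Calls.** A chromosome is gained for a cell when ≥ 50% of its bins exceed
+0.15 (loss symmetric at −0.15); malignant = chr7 gain AND chr10 loss.
Whole-chromosome events are large targets, so these thresholds are
forgiving; both are exposed. Whole-chromosome calls only — no
segmentation, no arm-level events — because the hallmark genotype is
whole-chromosome. Absence of chr7 or chr10 from the annotation is a hard
error: the genotype is undefined, not neutral.

## Cell typing

Precedence: (1) CNV malignant flag; else (2) myeloid if AIF1 or PTPRC
detected; (3) oligodendrocyte if OLIG1; (4) endothelial if PECAM1;
(5) pericyte if CSPG4 or RGS5; (6) epithelial/immune if EPCAM or CD3D;
(7) CAF if `p ≥ cutoff` (default 0.6); else (8) unassigned. Malignancy
outranks everything because CNV-positive cells must be removed from the
high-score pool; marker detections outrank the score because negative
selection precedes scoring in the method's logic. Labeling is a pure
function of its inputs; raising the cutoff can only shrink the CAF set.

Stage scoring contrasts the early signature (EVA1B, DDIT4) with the late
one (ACTA2, SRGN) as a difference of mean log expressions — a deliberate
two-signature reduction of a full pseudotime reconstruction, which is out
of scope.

## Crosstalk

Strict thresholds, verbatim semantics: ligand FPKM > 0.05 on the sender
and receptor read counts > 10 on the receiver; boundary values are
excluded. The mixed units (FPKM vs counts) are intentional and are the
caller's contract. Database pairs are case-normalized and deduplicated;
pairs with a gene absent from its profile are dropped and tallied. The
edge set is monotone in both thresholds and always a subset of the
database. No interaction database is redistributed; any TSV with
`ligand`/`receptor` columns is accepted.

## Spatial analysis

Source spots are the top decile (exposed) of the source type's probability
field, ties included. Every spot's distance to its nearest source spot
(Euclidean, k-d tree) is cut into 20 equal-width bins over [0, max]; the
curve reports the mean target probability and spot count per bin, leaving
empty bins empty. Because every spot lands in exactly one bin, the
spot-count-weighted mean of bin means equals the global mean target
probability to machine precision — a conservation identity the tests check
at 1e-9. Physical distance is used directly (the open design question of
rank-transformed "relative distance" was resolved in favor of physical
distance with the bin index as the normalized axis). No hex-grid
adjacency; rigid motions of the coordinates leave the curve unchanged.

## The synthetic generator

The generator supplies what every downstream stage assumes, with planted
truth; its defaults are the study conditions under which all recovery
guarantees are stated.

* **Gene universe:** 2,000 autosomal genes spread over the 22 autosomes in
  proportion to physical length (one gene per ≈ 1.4 Mb, evenly spaced)
  plus the 13 `MT-` genes. Named marker genes replace evenly spaced slots
  on autosomes other than 7 and 10, so marker programs never confound the
  planted CNV.
* **Counts:** negative binomial per gene with variance μ + 0.5 μ²
  (dispersion exposed). Per-cell library size is lognormal(ln 5000, 0.35);
  the mitochondrial fraction is Beta(2, 38) (mean 5%) of the library; the
  remaining depth is distributed over autosomal genes in proportion to the
  population's relative rates, so realized totals match the drawn depth —
  the regime the 200–20,000 UMI QC window was written for.
* **Marker programs are lineage-exclusive:** a marker gene's relative rate
  is `marker_fold_change × baseline` (8 × 0.2 by default) in the owning
  population and zero elsewhere. This is the realistic behavior of
  canonical lineage markers (AIF1, EPCAM, PECAM1 are effectively absent
  outside their lineage) and the regime in which detection-based negative
  selection is a meaningful operation at all: with markers merely
  fold-elevated over a shared baseline, spurious single-count detections
  would mislabel a third of all cells and no composition could be
  recovered. Populations named in the marker map but absent from the
  fraction map contribute no cells, so their markers stay silent — which
  is how the default four-population run keeps the exclusion genes clean.
* **CNV plant:** malignant cells' chr7 rates × 1.5, chr10 rates × 0.5.
* **Determinism:** one `numpy` Generator seeded from the config; identical
  config + seed reproduces outputs bit for bit.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real tissue: biological co-expression structure
and continuous cell states, doublets, ambient RNA, batch effects, gene
length/GC biases, focal or subclonal CNVs, and marker leakage across
lineages. Real data will sit between the clean synthetic regime and the
worst case; the exposed thresholds (`detect_min`, score cutoff, CNV call
thresholds) are the knobs that absorb that gap.

## Problem sizes and tolerances

The default study condition is 5,000 cells at fractions
0.52/0.22/0.20/0.06, seed 1 — large enough that composition recovery
(±0.03), score AUC (≥ 0.95), malignant-call sensitivity/specificity
(≥ 0.95) and the chr7 shift (within 15% of ln 1.5, referenced to planted
normals) are stable across seeds, and small enough that the whole suite
runs in well under a minute per full pipeline pass. Secondary experiments
(negative selection, stage scoring, monotone CNV sensitivity) use 800–2,000
cells. Exact identities (score formula vs an independent transcription,
kernel closed forms, proximity conservation) are checked at 1e-12/1e-9;
statistical recoveries against exact binomial 99% intervals or analytic
negative-binomial detection probabilities computed independently of the
implementation path.

## Known limitations

* The CNV caller is a deliberately simple windowed averager: no Bayesian
  segmentation, no aneuploidy clustering, no mitochondrial-SNV lineage
  evidence. Cells with partial or subclonal events will be called neutral.
* The log1p compression biases the recovered log-fold shift toward zero at
  low counts; calls are robust to this, but the profile magnitudes are not
  unbiased fold-change estimates.
* The score's functional form satisfies the verbal constraints it was
  built from (Gaussian kernel, credit for expressed positives and absent
  negatives, mean over n genes) and is isolated behind one function so an
  alternative algebra can be swapped in.
* Bulk crosstalk uses scalar per-gene values; no significance testing or
  cell-type-resolved expression backs the edges.
* Spot probability fields are consumed as given; deconvolution is upstream
  and out of scope.
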