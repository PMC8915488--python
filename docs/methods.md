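# Methods

This note documents the models, numerical choices and limitations behind
`hiphoptools`, in the order the pipeline runs.

## Scoring model

Both scoring branches treat a screen as a vector of per-strain abundance
log-ratios and standardize it with a robust z:
`FD = (log2ratio − screen median) / screen MAD`. The MAD is the **raw**
median absolute deviation, without the 1.4826 normal-consistency factor:
the downstream significance rule maps FD directly onto standard-normal
quantiles (FD ≥ Φ⁻¹(0.999) = 3.0902 at α = 0.001), which treats the
MAD-standardized score as approximately standard normal in the bulk. A
`mad_scaled` switch on `AnalysisConfig` applies the consistency factor for
users who prefer calibrated units; the significance thresholds are then
interpreted on that scale. Screens with MAD = 0 carry no usable contrast
and are excluded rather than imputed; every exclusion appears in the
machine-readable QC report.

The sign conventions differ by site and are tracked explicitly: a
`ScreenMatrix` carries an `orientation` flag, and
`harmonize_orientation` is the single operation allowed to change it
(multiplying by −1 and flipping the flag; idempotent). Every other
transform preserves the flag it receives.

### Array-level normalization

*Median polish with batch correction* models
`log2 signal = overall + array + batch + residual` and removes the array
and batch terms by alternating median sweeps (array sweep, then
re-centering of array effects into their batch means), stopping when the
largest update falls below 1e-6 or after 20 sweeps. There is no row
(strain) term: strain level is signal, not nuisance, and stays in the
residual. Effects are estimated from strain-tag features only and the
correction applied to all features of an array. A single-array table is
returned unchanged with a warning.

*Study-wise quantile normalization* maps each array's log2 signal
distribution onto the mean empirical distribution of its study; no
cross-study adjustment is applied. Studies with one array are left alone.

*Background filtering* thresholds each array at
median + 5·MAD of its unused (non-strain) features' raw signals; a tag
must clear the threshold on **every** control array to pass. With no
unused features present, all tags pass and a warning is recorded.

*Best-tag selection* ranks a strain's passing tags by robust CV
(MAD/median of raw control-array signals) and takes the minimum, ties to
the uptag. *Tag averaging* (the alternative convention) takes the
arithmetic mean of the passing tags per array.

### Replicate adjustment and gene-wise standardization

The replicate shrinkage multiplies each MADL entry by `min(0.05/p, 1)`,
with p a two-sided Welch t-test between the strain's treatment-replicate
and control log2 signals. Scores backed by consistent replicates
(p ≤ 0.05) are untouched; inconsistent ones shrink toward zero, and the
factor never exceeds 1, so the adjustment never inflates a score. An
alternative that multiplies by p itself is available
(`madl_adjustment="pvalue"`); the capped form is the default because it
is the explicitly printed formula of the source pipeline.

Gene-wise z divides each strain's a_MADL values by σ, the SD of the
values lying within the strain's own 15th–85th percentiles
(inclusive, linear interpolation) — the "middle 70%" — so a handful of
genuine hits do not inflate the strain's scale estimate. For standard
normal data this truncated SD is ≈ 0.5376, which the test suite verifies
by Monte Carlo. Strains with σ = 0 are flagged invariant and excluded.

## Clearance and HIP hits

Strains are ranked by FD descending (ties lexicographic by strain id);
the gap after rank *i* is `FD_(i) − FD_(i+1)`, defined at every rank.
`clearance_max` is the largest gap at a positive-FD rank — the published
definition restricts hits to "strains exhibiting FD scores greater than
zero", read here as restricting the gap *search*, with
`clearance_positive_only=False` widening it to all ranks. When several
gaps tie, the one at the highest FD wins (the most specific reading).
Every strain with FD ≥ the FD at the maximal gap inherits
`clearance_max` — a deliberate feature that credits tight groups of
co-targets (e.g. a multi-subunit complex) sitting above one wide gap.
Hits require significance *and* assigned clearance ≥ 5.75. The threshold
is a config value; it was originally optimized against gold-standard
compounds that are not redistributable, so no re-optimization is
attempted here. On null standard-normal profiles of ~1000 strains, the
5.75 gap fires in well under 1% of screens (measured, not assumed).

## Similarity

Correlations are pairwise-complete Pearson with a floor of 30 shared
observations (configurable); below the floor, and for constant profiles,
the pair is *missing*, never NaN-propagated. For clustering, missing
pairs enter the distance matrix at d = 1 (zero similarity) — a neutral
placement chosen for screens that share too few strains (the dropout
block), rather than forcing them together (d→0) or apart (d→2).
Insignificant scores are zeroed before the clustering correlation so that
structure is carried by confident interactions; raw-profile correlation
remains available (`zero=False`) for pairwise profile comparisons, since
the source analyses are ambiguous about which was used outside
clustering.

## Ward clustering and dynamic branch cutting

Ward agglomeration runs on the precomputed dissimilarity `1 − r` via the
Lance–Williams update applied to the dissimilarity itself (the "Ward.D"
convention) — appropriate because the input is a correlation-derived
distance, not squared Euclidean coordinates. Implementation detail: scipy's
Ward routine applies the update to squared distances, so it is fed
`sqrt(d)` and the merge heights are squared back; the tests verify exact
agreement with a naive O(n³) Lance–Williams implementation. Ties follow
scipy's nearest-neighbor-chain visit order (deterministic; ties have
measure zero on correlation-derived input).

Dynamic branch cutting proceeds in two stages. First, merges above
`cut_height` (default: the 99th percentile of merge heights, which
detaches the topmost join; the published absolute values like
`cutHeight = 20` are supported directly) are cut, yielding candidate
branches, each remembered together with its detachment height. Second,
each candidate is dissected recursively: a branch is one cluster when no
internal merge jumps by more than `min_gap × (candidate height)` above
its children, and is otherwise split at its top merge. Two asymmetries
matter and were found necessary on synthetic data:

* the gap threshold is normalized by the **candidate branch's own
  height**, not the whole tree's range — a single outlier screen joining
  far above everything else otherwise inflates the range and masks real
  cluster boundaries;
* a candidate whose internal height is below `min_gap ×` its detachment
  height is emitted whole — within-cluster noise is self-similar, and
  without this guard a tight replicate block would be dissected at its
  own scale.

`deep_split` (0–4) maps to default gap fractions
{0.45, 0.35, 0.25, 0.15, 0.05}; an explicit `min_gap` overrides the
mapping. Split parts smaller than `min_cluster_size` become unassigned
(label 0) — outlier screens shed from an otherwise tight branch — and a
branch none of whose parts could stand alone is kept whole. Under this
scheme the cluster count is non-decreasing in `deep_split` (checked as a
property over random trees), labels are invariant to input order up to
renumbering, and planted partitions are recovered exactly at default
noise. Exact numerical agreement with the reference dynamic-tree-cut
implementation is **not** promised: that algorithm has many undocumented
internals, and the scientific claims this package supports rest on
recovering block structure, which is what the acceptance properties test.

## Signatures, enrichment, matching

A cluster's median profile takes per-gene medians over member screens
(pairwise-complete). Signature genes are those with median FD ≥
Φ⁻¹(1−α), α = 0.001 within one dataset and 0.05 for the merged dataset
(where averaging across sites shrinks medians). Signatures with fewer
than two genes and no enriched set are dropped. Enrichment is the
hypergeometric upper tail with BH correction — the community default, as
the source method is unstated — against user-supplied GMT sets
intersected with the analyzed matrix's strain universe (not the whole
genome: strains absent from the matrix could never appear in a
signature). Signature matching uses the Szymkiewicz–Simpson overlap
coefficient with best-partner semantics (detection, not bijection) at a
0.5 threshold; the full overlap matrix is always reported so any
threshold can be applied post hoc, and pairs sharing an enriched set are
listed as an annotation-level alternative view.

One calibration subtlety: the hypergeometric p of a discrete statistic is
sub-uniform (conservative), so the null-calibration check uses the
randomized probability integral transform
`u = P(X > k) + V·P(X = k)`, `V ~ U(0,1)`, which is exactly uniform iff
the null model is correct; the plain p is additionally checked to be
conservative at fixed levels. A plain KS test on discrete p-values
rejects even for a correct implementation.

## Synthetic-data generator

`generate_fd_dataset` plants, per site, `n_classes` response classes of
replicate screens: signature genes (disjoint across classes, sizes
uniform on 5–15) score Normal(effect, σ) and everything else
Normal(0, σ), with effect = 8 and σ = 1 by default — class structure well
above the 3.09 significance threshold, as in real screens where
signatures are defined by strongly responding strains. Unstructured
screens carry one planted single-gene HIP target (FD 12) drawn from a
small reusable pool, so target-frequency ranking is testable. The
NIBR-like site is sign-flipped (`sensitivity_negative`) and loses
`dropout_count` strains sampled uniformly from non-target genes,
emulating the slow growers lost from overnight-grown pools (the real
datasets differ by 309 strains; the `paperlike` preset drops 60 of 1200
— the same order of fraction). Replicates are independent noise draws
around the class template: dose is metadata only, mirroring the
observation that practical replicates at different doses still cluster.
The `paperlike` preset plants 9 classes per site with 6 shared
(planted concordance 66.7%).

`generate_tag_intensities` models raw arrays: per-(strain, tag) baselines
log-normal around 2^10 with 0.3 log2-unit tag-to-tag spread,
multiplicative log-normal measurement noise (0.15 log2 units ≈ 11% CV,
typical for barcode arrays), a planted sensitive strain per treatment
screen attenuated by 2^(−defect), a `bad_tag_fraction` of tags with
5-fold inflated control variance (what best-tag selection must avoid),
unused background features at 2^6, and batch offsets (SD 0.3 log2 units)
that the median polish must remove.

What the generator does **not** emulate: dose–response and growth
kinetics, correlated (non-disjoint) signatures, heavy-tailed or
spatially structured array noise, and chemical-structure information.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure under realistic noise — not
performance on any particular real dataset.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes — hundreds to a
thousand strains, tens of screens, 20–50 seed replicates — chosen so the
full property suite exercises every stage end-to-end in well under a
minute per property while keeping Monte-Carlo margins comfortable. All
generators and the pipeline are deterministic given a seed; the
acceptance script derives every stage's RNG from one `--seed` via
`SeedSequence` spawning.

## Known limitations

* The dynamic cut is this package's own algorithm satisfying the
  published parameters' semantics and the recovery contracts; cluster
  counts on real data will differ in detail from the reference
  implementation (whose own published counts for the same data disagree
  across 96/56/42/41 depending on parameters and filtering).
* The merged real datasets are reported as 5894 strains although the
  larger site alone lists 5905; the discrepancy is unexplained upstream,
  so `merge_datasets` takes the strain universe as given and makes no
  attempt to reproduce 5894.
* Correlations are Pearson throughout, as in the source analyses; no
  robust/rank variants are provided.
* GO enrichment runs only against user-supplied GMT files; there is no
  ontology client, web application, or chemical-structure analysis.
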