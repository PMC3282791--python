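# Methods

## Admixture model and back-calculation

A tumor sample is modelled as a two-population mixture: an aberrant clone
(proportion P₁) and normal diploid cells. At a locus where the clone carries
b₁ B alleles on n₁ copies and the normal genotype is heterozygous (1 of 2),
the expected BAF is (b₁P₁ + P₂)/(n₁P₁ + 2P₂) and the expected total CN is
n₁P₁ + 2P₂. The model is deliberately two-population: subclonal mixtures of
three or more populations are out of scope, as are sex chromosomes (the
analysis is restricted to autosomes, where the diploid reference is
unambiguous).

Inversion is by exhaustive grid search: all integer clones 0 ≤ b₁ ≤ n₁ ≤
`max_copies` (default 4 — one doubling beyond diploid; higher amplification
saturates the array response anyway) crossed with P₁ in `grid_step` = 0.01
steps (estimates are conventionally reported to the nearest 5%, so a 1% grid
is conservative). Each candidate is scored by

    residual = w·|upper(B_exp) − upper observed band| + |CN_exp − observed CN|

with w = 2.0: BAF is measured on a 0–1 scale and CN on a 0–4 scale, so the
weight roughly equalises the two error magnitudes; upper(·) folds the A/B
label symmetry (b₁ and n₁−b₁ predict mirrored bands and are reported as one
candidate — no attempt is made to resolve which parental allele is affected).

Numerical choices:

- **Ties.** The model is aliased: clone (3,4) at P/2 predicts exactly the
  same (bands, CN) as clone (2,3) at P. Residuals are quantised to 1e-9
  before comparison so float jitter cannot break exact ties, then parsimony
  decides: smaller |n₁ − 2| first (prefer the least aberrant karyotype), then
  smaller P₁.
- **Detection floor.** A best fit with P₁ < 0.05 is reported as NORMAL: at
  realistic noise a sub-5% admixture is indistinguishable from a diploid
  segment, and without the floor any CN wobble around 2.0 would be "explained"
  by a 1–2% mosaic event. Consequently the forward–inverse round-trip is
  exact (within one grid step) only for P₁ ≥ 0.05, which is what the tests
  assert.
- **Mosaic monosomy.** A monosomic clone (n₁ = 1) with estimated fraction
  above 0.95 — observed CN ≈ 1 — is labelled MOSAIC_MONOSOMY rather than
  MONOALLELIC_DEL: at that point the "mosaic" is effectively the whole
  sample and the lesion is whole-copy loss.
- **Degenerate inputs.** An empty band list yields INDETERMINATE; observed
  CN outside (0, max_copies] is an input error; a nullisomic mixture has no
  defined BAF and raises.

## Band detection

Only markers heterozygous in the matched normal are informative (homozygous
markers stay at 0/1 under every mechanism considered), selected by the
normal's BAF in [0.4, 0.6] or a genotype flag when available. Values are
folded as f = |BAF − 0.5|, making the estimator invariant under allele
relabelling. Under the no-split null, f is half-normal with mean
σ√(2/π); a split is declared when the 10%-trimmed mean of f exceeds that
expectation by more than 3 standard errors (σ√(1−2/π)/√n). When split,
d = trimmed mean, band centers {0.5−d, 0.5+d}. A trimmed mean was chosen over
mixture EM: for mirrored two-band structure it is deterministic, robust and,
against an exhaustive mixture-likelihood scan oracle, unbiased within ±0.01
for d ≥ 0.05 at σ ≤ 0.05 and n ≥ 100 (folding bias only matters for
d ≲ 2σ and stays below 0.01 in that regime). Segments with fewer than 10 het
markers are flagged indeterminate. The per-sample noise σ is estimated from
the normal's het markers (floor 0.01).

The qualitative split classes are NO_SPLIT (d < 0.04), MODERATE
(0.04 ≤ d < 0.22) and LARGE (d ≥ 0.22). The published interpretation table is
qualitative; these boundaries were set so the canonical figure exemplars
(d ≈ 0.16 moderate amplification split, d ≈ 0.33 large deletion split) fall
in their stated rows, and both are configurable. The split class is
descriptive; the model-fit mechanism is authoritative (e.g. cnLOH at 50%
mosaicism, d = 0.25, sits just above the MODERATE band's top while remaining
a clean (2,2) model fit).

## Paired copy number and segmentation

CN per marker is 2·2^(LRR_t − LRR_n) — the matched normal is the reference,
so germline CNVs cancel. Whether one differences LRRs or ratios normalized
intensities is mathematically equivalent up to normalisation; the LRR form is
used. Segmentation is recursive binary splitting on log₂(CN): at each step
the breakpoint maximising the Welch t statistic between flanks is accepted
iff both flanks hold ≥ `min_markers` (25 for ~620k-marker maps, 10 for ~300k)
and the two-sided p < 0.001, then both sides are recursed. This reimplements
the contract of the commercial segmentation tool originally used for this
kind of analysis (same minimum-marker and significance settings); it is not
bit-identical to that closed-source implementation. The scan is O(n) per
level via cumulative sums; zero-variance flanks are handled exactly (a true
step is infinitely significant, but means are compared with a 1e-9 relative
tolerance so constant runs are never split on round-off). Segment summaries
use the geometric mean CN, exp(mean(log CN)). States: AMPLIFIED ≥ 2.5,
DELETED ≤ 1.5, NEUTRAL only within the conservative 1.9–2.1 band; the gaps
(1.5, 1.9) and (2.1, 2.5) are INDETERMINATE. Downstream analyses use only
segments ≥ 500 kb.

## Recurrent regions

A recurrent region is a maximal interval where the number of samples whose
qualifying segments cover *every base* is at least ⌈min_fraction·N⌉ (10% by
default; 9 of 86 in the motivating cohort). Pointwise coverage was chosen
over any-overlap clustering, which is ill-defined for chains of staggered
segments. The sweep over segment endpoints is exact; a per-base counting
oracle validates it on ≤ 10 Mb instances. cnLOH regions stack segments that
are copy-neutral by the conservative band *and* show at least a moderate
split. Because segmentation is CN-driven, a cnLOH event strictly interior to
a larger copy-neutral segment is diluted rather than isolated; whole-arm or
whole-chromosome cnLOH — the commonly observed presentation — is detected.
This is a known limitation.

## Association

Per region and sample, a state (Amplification / Deletion / Unchanged)
requires a qualifying segment of that state covering ≥ 50% of the region;
unanalyzable samples are excluded per-region. Categorical phenotypes are
tested with Pearson chi-square after dropping all-zero rows/columns (the df
comes from the reduced table — necessary because recurrent-region tables
routinely have an empty Amplification or Deletion column). Region tables use
no continuity correction; 2×2 patient-characteristic tables use Yates. Both
conventions reproduce the respective published p-value sets, which is how
they were identified, and are recorded as an assumption. Continuous
phenotypes use one-way ANOVA. Raw p-values are the primary output (no
multiple-testing adjustment, matching the original analysis); a
Benjamini–Hochberg column is emitted for convenience. Analyses stratify by
MSI status by default, since chromosomal instability differs systematically
between MSI and MSS tumors.

## Annotation

Gene-region membership is by overlap fraction of the gene: 1.0 (fully
contained) for the headline gene lists, 0.9 exposed for grade-style analyses;
both are parameters. Amplified regions match drugs typed antagonist /
antibody / inhibitor; deleted regions match agonist / activator / inducer;
discontinued- and unknown-status records are excluded from the "available"
report but retained in the full report. The shipped fixture carries the 29
approved drug-gene records used by the tests; gene coordinates are not part
of the fixture (the source tables carry only cytobands), so tests lay genes
out on a synthetic toy coordinate system.

## Synthetic data

The generator runs the admixture model forwards. Germline genotypes are
Binomial(2, 0.5) per marker (a heterozygosity-rich map maximises informative
markers; configurable); normal BAF is the genotype value plus truncated
normal noise (σ = 0.03, clipped to [0, 1]); LRR noise is normal (σ = 0.15).
Within an event the tumor BAF is the expected mixture BAF conditioned on the
germline genotype (the clone carries only the germline allele at homozygous
markers) and the tumor LRR is shifted by log₂(CN_exp/2); outside events the
tumor is drawn from the normal's distribution. The default map is a scaled
2-chromosome genome (2,500 markers over 50 Mb each) so a cohort runs in
seconds; density is a parameter for 610k-like maps. Noise sds match the band
widths visible on Infinium-class data. What the generator does *not* emulate:
GC waves, genotyping error, probe-specific variance, segmental artefacts —
so passing recovery tests demonstrates correctness of the inference under the
stated noise model, not robustness to platform artefacts.

Problem sizes used in the recovery tests: the mechanism × fraction sweep
(5 mechanisms × P ∈ {0.3, 0.5, 0.65, 0.8, 0.9} × 100 replicates) runs each
replicate through the full pipeline on a 600-marker single-chromosome pair
with a whole-chromosome event — whole-chromosome because cnLOH boundaries are
not CN-detectable (above), and because arm/chromosome-scale events are the
relevant regime; recovery requires the correct mechanism and |P̂ − P| ≤ 0.05
in ≥ 95 of 100 replicates per cell. Segmentation recovery uses 400–450-marker
tracks at LRR-scale noise 0.15; recurrence uses noise-free planted intervals
plus randomized ≤ 10 Mb oracle comparisons.

## Known limitations

- Two populations only; no subclonal deconvolution.
- cnLOH interior to a copy-neutral segment is not boundary-detected.
- Translocations are invisible to SNP arrays; not attempted.
- The segmentation is contract-equivalent, not bit-identical, to the
  commercial tool it replaces.
- Aberrant fractions below 5% are reported as normal by design.
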