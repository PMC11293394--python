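# Methods

## Scope and data model

`nfkbdep` analyses a genotype-contrast stimulation study in macrophage-like
cells: nascent (chromatin-associated) transcript time courses at 0, 0.5, 1,
2 and 6 h after stimulation with lipid A or TNF, in wild-type and knockout
genotypes (*Nfkb1*⁻/⁻, *Nfkbiz*⁻/⁻, *Bcl3*⁻/⁻, *Nfkbid*⁻/⁻), two biological
replicates per condition; ChIP-seq peak tables for p50, RelA and IκBζ over
0–2 h; an unstimulated ATAC-seq table; and 200 bp sequence windows under
peaks. All quantification is RPKM (count / (kb × million mapped reads)),
computed identically for gene transcripts (gene length) and peaks (peak
width). Intervals are 0-based half-open; two intervals overlap when they
share at least one base.

## Dependence classification

The ratio statistic is deliberately simple: replicate-averaged KO:WT RPKM at
the timepoint where it is smallest, among timepoints with WT RPKM above the
3 RPKM expression floor. The denominator is floored at 0.5 RPKM so the ratio
is defined everywhere; the floor is far below the expression filter, so it
never affects an eligible timepoint's eligibility, only guards degenerate
arithmetic. A gene is dependent when min ratio < 0.33 **and** BH-adjusted
p < 0.01 (both strict). The 0.5 h screen is run separately from the 1/2/6 h
screen because primary-response genes can only reveal dependence early while
secondary-response genes appear from 1 h; BH adjustment is applied within
each screen across genes.

Significance uses a conditional negative-binomial exact test: with replicate
sums S₁ ~ NB(n₁/α, p) and S₂ ~ NB(n₂/α, p) under a common mean, the
distribution of S₁ given S₁ + S₂ is free of the mean and depends only on the
dispersion α. The two-sided p-value sums the conditional probabilities of
all splits no more likely than the observed one. α is estimated once per
contrast as the across-gene mean of nonnegative per-gene method-of-moments
values (var − mean)/mean², floored at 0.01. With two replicates per arm the
per-gene estimates are individually useless but their pooled mean is stable;
the test's empirical type-I error at α = 0.01 is computed by
`scripts/acceptance.py` on a 10 000-gene null.

Codependence requires the full call — ratio *and* significance — under each
knockout separately; a gene below the ratio line in one contrast but without
significance there is labelled dependent only on the other regulator.

## Peak kinetics

Reproducibility: a location passes when peak score > 19 and RPKM > 3 in at
least k of n replicates at one or more timepoints (k-of-n configurable:
2-of-2 default, 2-of-3 supported). Merged locations take min start / max end
of contributors; a location contributed by a single upstream peak id keeps
that id.

Clustering input is one profile per (factor, reproducible peak): the
replicate-averaged RPKM at 0/0.5/1/2 h. Each profile is divided by its own
maximum before k-means, so clusters encode shape, not amplitude (all-zero
rows are left as zeros). k-means runs 50 restarts under a fixed seed; since
k-means labels are arbitrary, clusters are renumbered by (centroid argmax
timepoint, then descending 0 h level), making cluster 1 the constitutive
archetype and cluster 6 the late archetype regardless of restart order.

## Preference, binding dependence and binning

Both ratio statistics use a 0.1 RPKM pseudocount on numerator and
denominator. The pseudocount sits far below the 3 RPKM floor, so it cannot
reorder expressed peaks; it exists to give zero-signal peaks finite, extreme
ratios. Band boundaries follow the inclusive mild-band convention:
strong r < 0.33, mild 0.33 ≤ r ≤ 1, independent r > 1.

The preference universe is all reproducible p50 sites plus the top-N RelA
sites ranked by maximum 1 h RPKM, N = p50 set size (shared locations count
once). Ordered lists are cut into contiguous equal bins; with remainder r the
first r bins take one extra item, so sizes differ by at most one.

Peak-to-gene annotation links each peak centre to the nearest TSS within the
window (5 kb promoter-proximal, 30 kb for the dependence-enrichment
analysis, optionally restricted to genes expressed above 3 RPKM); exact
distance ties take the lexicographically smaller gene id. The one-peak-per-
gene rule keeps, among a gene's linked peaks, the one with the smallest KO:WT
ratio (greatest binding change), ties again by smaller peak id.

## Motif analysis

The p50-homodimer element is encoded literally as `GGGNNNNNCCC` on the plus
strand: three G:C base pairs per half-site, 5 bp spacer. This pattern class
equals its own reverse complement, so each matching position is reported on
both strands; `N` in the input never satisfies a constrained position but is
accepted in the spacer. PWM scanning scores log₂ odds against a uniform
background (matrices supplied in JASPAR position-frequency format; the
matrices packaged for tests are synthetic), with a default call threshold of
80 % of the matrix's maximal score. Per-bin enrichment is a one-sided
hypergeometric test of one bin's windows against the union of all other
bins, reported as −log₁₀ p.

## Stimulus differential

Genes induced more than 3-fold by lipid A (a looser filter than the 5-fold
induction class, matching the differential analysis) and expressed above
3 RPKM are tiered by the minimum TNF:lipidA ratio across post-0 timepoints:
strong ≤ 1/60 ⊂ differential ≤ 1/3, boundaries inclusive. The crosstab
against dependence classes accepts externally supplied labels (e.g. an
IRF3/IFNAR annotation) identically to the pipeline's own classes, and takes
the differential table and the dependence table as separate arguments
because the two axes may come from different assays (mRNA vs nascent
transcription).

## The synthetic study generator

The generator's defaults are the study conditions: 2000 genes, 3000 disjoint
peaks on two 80 Mb chromosomes, two replicates everywhere, NB dispersion
0.05 for counts, lognormal σ = 0.25 per replicate for peak RPKM, knockout
effect ratio 0.15 at affected timepoints, class mixture 2 % codependent /
2 % p50-only / 3 % IκBζ-only / 8 % induced-independent / 5 % repressed /
80 % weak-unaffected (the scale of tens of dependent genes among thousands).
Induced folds are log-uniform on [8, 100]; primary genes peak at 0.5 h,
secondary genes rise from 1 h. Stored RPKM is recomputed from the sampled
counts and the sampled library sizes, so count↔RPKM consistency is exact by
construction. TNF trajectories equal lipid A times a planted per-gene
factor (log-uniform around 1/60 for most IκBζ-target-like genes).

Peak kinetics are factor-specific at shared locations: IκBζ follows the late
archetype at essentially all of its sites, while p50/RelA binding at those
same locations is assigned an earlier archetype — NF-κB dimers precede IκBζ.
One strongly p50-dependent IκBζ/RelA peak is planted within 30 kb of each
codependent gene's TSS, plus a small fraction of unlinked late peaks; all
other peaks get KO factors lognormal around 1. Sequence windows are i.i.d.
uniform A/C/G/T with at most one planted homodimer instance.

What the generator does **not** emulate: read-level sampling, fragment-length
and GC bias, mappability, overlapping genes, correlated replicate batches,
mRNA stability (the TNF differential is planted directly at the
transcription level), and any dispersion trend with expression. Passing
recovery tests therefore demonstrates the pipeline's correctness under the
stated noise model, not robustness to every artefact of real sequencing
data.

## Numerical and design choices

* Thresholds are strict inequalities everywhere except the mild-band edges
  (0.33 and 1.0 → mild) and the differential-tier edges (1/3, 1/60 →
  inside the tier).
* BH adjustment is applied uniformly in every screen.
* Degenerate inputs: all-zero contrasts give p = 1 (flagged); zero 0 h
  baselines use a 0.5 RPKM pseudocount (flagged); genes never expressed are
  excluded as `not_expressed`; induced genes lacking a primary/secondary
  annotation are labelled `not_induced` because the kinetic class cannot be
  assigned without the protein-synthesis-inhibition experiment.
* Interval union uses a sorted sweep with provenance tags, validated against
  an O(n²) pairwise-merge oracle in the test suite.
* Sequential-ChIP panels are represented purely as rank-ordered signal
  matrices (descending reference column, ties by peak id); no
  antibody-efficiency model is attempted.
* Problem sizes in `scripts/acceptance.py` (2000 genes, 3000 peaks, 1200
  clustering profiles, 10 000 null genes, 1000 motif windows) are the
  package's chosen defaults for a desk-scale validation run.

## Known limitations

* The exact test's calibration relies on the pooled dispersion being
  representative; strongly expression-dependent dispersion would need a
  trended estimator.
* The homodimer motif is the strictest literal reading of the half-site
  description; degenerate or mismatched sites are not matched (a PWM can be
  supplied where that is too strict).
* Peak-to-gene annotation is nearest-TSS only; enhancer–promoter assignment
  by contact data is out of scope.
* Primary/secondary response classes are taken as input metadata, not
  inferred.
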