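# nfkbdep

Genotype-contrast genomics of NF-κB p50 / IκBζ codependent transcription.

In stimulated macrophages, induction of a small set of key immunoregulatory
genes (the *Il6*-like secondary-response program) requires **both** the NF-κB
p50 subunit (*Nfkb1*) and the nuclear IκB protein IκBζ (*Nfkbiz*). Detecting
this codependence takes an integrative analysis: nascent-transcript RNA-seq
time courses contrasted across knockout genotypes, ChIP-seq peak kinetics for
p50/RelA/IκBζ, p50-vs-RelA binding-preference scoring, κB-motif content, the
p50 dependence of IκBζ and RelA binding, and the lipid A vs TNF
stimulus-differential response. `nfkbdep` implements that pipeline as a
tested, reusable library with a synthetic-study generator that plants ground
truth for every classifier, so each stage can be validated by recovery.

## The core statistics

* **Gene dependence.** For gene *g* under knockout genotype *K*, the
  replicate-averaged ratio r\_g(t) = RPKM\_K(t) / RPKM\_WT(t) is evaluated at
  every post-stimulation timepoint with WT RPKM > 3; the minimum-ratio
  timepoint is selected, and *g* is dependent iff r\_g < 0.33 with
  BH-adjusted p < 0.01. The 0.5 h timepoint is screened separately (early,
  primary-response dependence) from 1/2/6 h (late dependence). Significance
  comes from a conditional negative-binomial exact test on the replicate read
  counts with a pooled method-of-moments dispersion. **Codependence** =
  dependent under both *Nfkb1*⁻/⁻ and *Nfkbiz*⁻/⁻, each call meeting both
  thresholds on its own.
* **Peak kinetics.** Reproducible binding sites (peak score > 19 and
  RPKM > 3 in ≥ k of n replicates at ≥ 1 timepoint) are merged across
  factors; each factor's 0/0.5/1/2 h profile, scaled to its own maximum, is
  clustered by k-means into six kinetic archetypes (cluster 1 constitutive …
  cluster 6 late).
* **Binding preference and dependence.** ρ = (p50 + ε)/(RelA + ε) at 1 h
  orders the combined p50 + top-N RelA peak set; r = (KO + ε)/(WT + ε) at 2 h
  bands each IκBζ/RelA site as independent (r > 1), mild (0.33 ≤ r ≤ 1) or
  strongly p50-dependent (r < 0.33), with ε = 0.1 RPKM. Ordered peaks are cut
  into equal bins and per-bin fractions of annotated properties (linkage to
  codependent genes within 30 kb of a TSS, κB-motif content, co-binding) are
  reported.
* **Homodimer motif.** The κB site most supportive of p50 homodimer binding
  carries three G:C pairs in each half-site separated by 5 bp —
  `GGGNNNNNCCC` — scanned over the 200 bp window centred on each peak, both
  strands. Per-bin PWM enrichment uses a one-sided hypergeometric test.
* **Stimulus differential.** Genes induced > 3-fold by lipid A are tiered by
  their minimum TNF:lipidA RPKM ratio at 1:3 and 1:60, then crossed with the
  dependence classes.

## Worked example

```bash
nfkbdep simulate --seed 1 --out data
nfkbdep report --data data --out results --seed 1
```

prints one structured log line per stage:

```
[nfkbdep] stage=simulate seed=1 genes=2000 peaks=3000 out=data
[nfkbdep] stage=classify-expression genes=2000 screen=late ratio_cut=0.33 p_cut=0.01 dependent=167 codependent=34
[nfkbdep] stage=peaks ps_cut=19.0 rpkm_cut=3.0 reproducible={'p50': 1357, 'RelA': 2113, 'IkBz': 385} union=2608 clustered=3855
[nfkbdep] stage=preference peaks=2390 bins=20 out=results/preference.tsv
[nfkbdep] stage=dependence factor=IkBz peaks=446 bands={'independent': 202, 'mild': 199, 'strong': 45} out=results/ikbz_dependence.tsv
[nfkbdep] stage=motif windows=3000 with_motif=420 out=results/motif_hits.tsv
[nfkbdep] stage=stimulus included=1075 thresholds=(0.3333333333333333, 0.016666666666666666) strong=37
```

Reading: of 2000 simulated genes, 167 gene × regulator dependence calls pass
the ratio-and-significance screen and 34 genes are *Nfkb1*/*Nfkbiz*
codependent (the generator planted 34 — see `data/truth_genes.tsv`). Of 446
IκBζ binding sites, 45 lose > 67 % of their signal in p50-deficient cells
(the strong band); the remaining stages write per-bin preference,
motif-content and differential-expression tables under `results/`.

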