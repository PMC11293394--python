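"""Synthetic macrophage stimulation study with planted ground truth.

The generator emulates the data layout of a lipid A / TNF stimulation
study in bone marrow-derived macrophages: nascent-transcript expression
time courses (0/0.5/1/2/6 h, two replicates) across WT and four knockout
genotypes, ChIP-seq peak tables for p50, RelA and IkBzeta over a
0/0.5/1/2 h time course, an unstimulated ATAC-seq accessibility table,
and 200 bp sequence windows under each peak. Every gene and peak carries
a planted label (dependence class, kinetic archetype, motif presence,
genotype-dependence band), so each downstream classifier can be scored
against known truth.

Model in brief
--------------
* Gene classes are drawn from a mixture (codependent / p50-only /
  IkBzeta-only / induced-independent / repressed / weak-unaffected).
  Induced genes follow a primary (peak at 0.5 h) or secondary (rise from
  1 h) kinetic shape scaled by a log-uniform fold-induction; dependent
  genes have their knockout mean multiplied by the effect ratio (default
  0.15) at the affected timepoints (all post-0 timepoints for primary
  genes, 1/2/6 h for secondary genes). Bcl3 and Nfkbid knockouts never
  carry effects. Read counts are negative binomial around the mean;
  stored RPKM is recomputed from the sampled counts, so count-to-RPKM
  consistency holds by construction.
* TNF responses equal the lipid A trajectory times a planted per-gene
  differential factor (1 for most genes; log-uniform around 1/60 for the
  strongly differential IkBzeta-target-like genes).
* Peaks are disjoint genomic intervals assigned one of six kinetic
  archetypes; replicate RPKMs are lognormal around archetype mean x
  amplitude, peak scores track signal. IkBzeta membership is essentially
  confined to the late archetype (cluster 6). Peaks planted as
  p50-dependent get their knockout-genotype IkBzeta/RelA signal scaled
  into the strong band, and one such peak is placed within 30 kb of each
  codependent gene's TSS.
* Sequences are i.i.d. uniform A/C/G/T with a single GGGNNNNNCCC
  homodimer motif planted in flagged windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CHIP_TIMEPOINTS_H, RunConfig, TIMEPOINTS_H
from .io import ExpressionTable, PeakRecord

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "SimulatedStudy",
    "generate_genome",
    "generate_expression",
    "generate_peaks",
    "generate_sequences",
    "simulate",
    "simulate_null_counts",
    "GENE_CLASSES",
    "ARCHETYPE_SHAPES",
]

GENE_CLASSES = ("codependent", "p50_only", "ikbz_only", "independent", "repressed", "weak")

#: kinetic archetype means over 0/0.5/1/2 h (cluster 1 = constitutive,
#: cluster 6 = late), normalised to their own maximum
ARCHETYPE_SHAPES = np.array(
    [
        [1.00, 0.90, 0.75, 0.60],
        [0.10, 1.00, 0.45, 0.15],
        [0.10, 1.00, 0.95, 0.85],
        [0.05, 0.25, 1.00, 0.35],
        [0.05, 0.20, 0.70, 1.00],
        [0.03, 0.05, 0.10, 1.00],
    ]
)

_PRIMARY_SHAPE = {0.0: 0.0, 0.5: 1.00, 1.0: 0.85, 2.0: 0.55, 6.0: 0.25}
_SECONDARY_SHAPE = {0.0: 0.0, 0.5: 0.05, 1.0: 0.30, 2.0: 0.75, 6.0: 1.00}
_REPRESSED_SHAPE = {0.0: 1.0, 0.5: 0.75, 1.0: 0.55, 2.0: 0.40, 6.0: 0.30}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 2000
    n_peaks: int = 3000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 80_000_000, "chr2": 80_000_000}
    )
    #: mixture over GENE_CLASSES (codependent, p50_only, ikbz_only,
    #: independent, repressed, weak)
    class_proportions: tuple[float, ...] = (0.02, 0.02, 0.03, 0.08, 0.05, 0.80)
    #: KO:WT mean ratio at affected timepoints for dependent genes
    effect_ratio: float = 0.15
    #: negative-binomial dispersion of read counts
    nb_dispersion: float = 0.05
    #: lognormal sigma of replicate peak RPKM around its mean
    peak_sigma: float = 0.25
    n_expr_replicates: int = 2
    n_peak_replicates: int = 2
    expr_library_millions: float = 20.0
    motif_window_bp: int = 200
    #: motif planting probabilities
    motif_p_dependent: float = 0.6
    motif_p_p50_constitutive: float = 0.5
    motif_p_background: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must not be empty")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if len(self.class_proportions) != len(GENE_CLASSES):
            raise ValueError(f"need {len(GENE_CLASSES)} class proportions")
        if self.nb_dispersion <= 0 or self.peak_sigma <= 0:
            raise ValueError("dispersion parameters must be positive")
        if self.motif_window_bp % 2:
            raise ValueError("motif_window_bp must be even")
        if self.motif_window_bp < 11:
            raise ValueError("motif_window_bp smaller than the 11 bp homodimer motif")


@dataclass
class SyntheticTruth:
    """Planted labels sufficient to score every downstream classifier."""

    gene_class: pd.Series
    gene_kinetics: pd.Series
    tnf_factor: pd.Series
    irf3_dependent: pd.Series
    peak_archetype: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    peak_dependence: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    motif_planted: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    accessible_0h: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    #: planted peak -> codependent gene linkage
    peak_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))


def _rng(params: GeneratorParams, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(params.rng_seed)


def assign_gene_truth(
    params: GeneratorParams, rng: np.random.Generator | None = None
) -> SyntheticTruth:
    """Draw gene classes, kinetic type and stimulus-differential factors."""
    rng = _rng(params, rng)
    n = params.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    cls = rng.choice(GENE_CLASSES, size=n, p=params.class_proportions)
    # probability an induced gene of each class is a secondary response gene
    p_secondary = {"codependent": 0.8, "p50_only": 0.5, "ikbz_only": 0.7, "independent": 0.5}
    kinetics = np.where(
        [rng.random() < p_secondary.get(c, 0.0) for c in cls], "secondary", "primary"
    )
    phi = np.ones(n)
    irf3 = np.zeros(n, dtype=bool)
    for i, c in enumerate(cls):
        if c in ("codependent", "ikbz_only"):
            if rng.random() < 0.7:
                phi[i] = np.exp(rng.uniform(np.log(1 / 120), np.log(1 / 30)))
            else:
                phi[i] = np.exp(rng.uniform(np.log(1 / 20), np.log(1 / 4)))
        elif c == "independent" and rng.random() < 0.1:
            # IRF3/IFNAR-dependent-like: differential but IkBzeta-independent
            phi[i] = np.exp(rng.uniform(np.log(1 / 100), np.log(1 / 10)))
            irf3[i] = True
    idx = pd.Index(gene_ids, name="gene_id")
    return SyntheticTruth(
        gene_class=pd.Series(cls, index=idx, name="gene_class"),
        gene_kinetics=pd.Series(kinetics, index=idx, name="gene_kinetics"),
        tnf_factor=pd.Series(phi, index=idx, name="tnf_factor"),
        irf3_dependent=pd.Series(irf3, index=idx, name="irf3_dependent"),
    )


def generate_genome(
    params: GeneratorParams,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene annotation: TSS uniformly placed, lognormal lengths.

    Induced genes carry their kinetic type as the primary/secondary
    response class; weak and repressed genes are ``unclassified`` (they do
    not reach the response-class thresholds).
    """
    rng = _rng(params, rng)
    if truth is None:
        truth = assign_gene_truth(params, rng)
    chroms = list(params.chrom_sizes)
    chrom = rng.choice(chroms, size=params.n_genes)
    tss = np.array([rng.integers(0, params.chrom_sizes[c]) for c in chrom])
    length_kb = np.exp(rng.normal(np.log(2.0), 0.6, size=params.n_genes))
    strand = rng.choice(["+", "-"], size=params.n_genes)
    induced = truth.gene_class.isin(["codependent", "p50_only", "ikbz_only", "independent"])
    response = np.where(induced, truth.gene_kinetics, "unclassified")
    return pd.DataFrame(
        {
            "gene_id": truth.gene_class.index,
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "length_kb": length_kb,
            "response_class": response,
        }
    )


def _wt_mean_rpkm(
    baseline: np.ndarray, fold: np.ndarray, cls: np.ndarray, kinetics: np.ndarray
) -> np.ndarray:
    """WT lipid A mean RPKM per gene x timepoint."""
    n = baseline.size
    out = np.empty((n, len(TIMEPOINTS_H)))
    for j, t in enumerate(TIMEPOINTS_H):
        shape_p, shape_s, shape_r = _PRIMARY_SHAPE[t], _SECONDARY_SHAPE[t], _REPRESSED_SHAPE[t]
        induced_shape = np.where(kinetics == "secondary", shape_s, shape_p)
        out[:, j] = np.where(
            cls == "repressed",
            baseline * shape_r,
            baseline * (1.0 + (fold - 1.0) * induced_shape),
        )
    return out


_AFFECTED = {
    "primary": (0.5, 1.0, 2.0, 6.0),
    "secondary": (1.0, 2.0, 6.0),
}


def generate_expression(
    params: GeneratorParams,
    annotation: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Counts + RPKM for all genotypes, stimuli, timepoints and replicates.

    Returns the table and a per-sample library-size frame (millions of
    reads), which together reproduce the stored RPKMs exactly.
    """
    rng = _rng(params, rng)
    n = params.n_genes
    cls = truth.gene_class.to_numpy()
    kin = truth.gene_kinetics.to_numpy()
    baseline = np.exp(rng.normal(np.log(5.0), 1.0, size=n))
    fold = np.exp(rng.uniform(np.log(8.0), np.log(100.0), size=n))
    fold = np.where(cls == "weak", rng.uniform(1.5, 4.5, size=n), fold)
    fold = np.where(cls == "repressed", 1.0, fold)
    wt = _wt_mean_rpkm(baseline, fold, cls, kin)

    affected_by_class = {
        "codependent": ("Nfkb1KO", "NfkbizKO"),
        "p50_only": ("Nfkb1KO",),
        "ikbz_only": ("NfkbizKO",),
    }
    genotypes = ("WT", "Nfkb1KO", "NfkbizKO", "Bcl3KO", "NfkbidKO")
    means: dict[tuple[str, str], np.ndarray] = {}
    for gt in genotypes:
        mult = np.ones_like(wt)
        for i in range(n):
            if gt in affected_by_class.get(cls[i], ()):
                for j, t in enumerate(TIMEPOINTS_H):
                    if t in _AFFECTED[kin[i] if kin[i] in _AFFECTED else "primary"]:
                        mult[i, j] = params.effect_ratio
        lip = wt * mult
        means[(gt, "lipidA")] = lip
        tnf = lip * truth.tnf_factor.to_numpy()[:, None]
        tnf[:, 0] = lip[:, 0]  # unstimulated baseline is stimulus-free
        means[(gt, "TNF")] = tnf

    length_kb = annotation.set_index("gene_id")["length_kb"].reindex(truth.gene_class.index).to_numpy()
    disp = params.nb_dispersion
    rows = []
    lib_rows = []
    for (gt, stim), mean_rpkm in means.items():
        for j, t in enumerate(TIMEPOINTS_H):
            for rep in range(1, params.n_expr_replicates + 1):
                lib = params.expr_library_millions * np.exp(rng.normal(0.0, 0.1))
                lib_rows.append({"genotype": gt, "stimulus": stim, "timepoint": t, "replicate": rep, "library_millions": lib})
                mean_counts = mean_rpkm[:, j] * length_kb * lib
                r = 1.0 / disp
                counts = rng.negative_binomial(r, r / (r + np.maximum(mean_counts, 1e-12)))
                counts = np.where(mean_counts <= 0, 0, counts)
                rpkm = counts / (length_kb * lib)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": truth.gene_class.index,
                            "genotype": gt,
                            "stimulus": stim,
                            "timepoint": t,
                            "replicate": rep,
                            "count": counts,
                            "rpkm": rpkm,
                        }
                    )
                )
    values = pd.concat(rows, ignore_index=True)
    meta = annotation[["gene_id", "chrom", "tss", "strand", "length_kb", "response_class"]].copy()
    return ExpressionTable(meta, values), pd.DataFrame(lib_rows)


@dataclass
class PeakSim:
    """Generated peak universe plus everything the peak pipeline consumes."""

    peaks: list[PeakRecord]
    #: (factor, timepoint) -> list of per-replicate PeakRecord lists
    replicate_tables: dict[tuple[str, float], list[list[PeakRecord]]]
    #: peaks x samples RPKM; columns "factor:tp:rep:genotype"
    signal: pd.DataFrame
    atac_0h: list[PeakRecord]
    membership: pd.DataFrame
    #: per-factor kinetic archetype at each location (peaks x factors)
    factor_archetype: pd.DataFrame


def _sample_column(factor: str, tp: float, rep: int, genotype: str) -> str:
    return f"{factor}:{tp:g}h:r{rep}:{genotype}"


def generate_peaks(
    params: GeneratorParams,
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> PeakSim:
    """Disjoint peak universe with factor membership, kinetics and signal.

    Updates ``truth`` in place with peak_archetype, peak_dependence,
    accessible_0h, motif_planted and the planted peak->gene links.
    """
    rng = _rng(params, rng)
    n = params.n_peaks
    chroms = list(params.chrom_sizes)

    # one strongly p50-dependent IkBzeta/RelA peak near each codependent gene
    codep_genes = truth.gene_class.index[truth.gene_class == "codependent"]
    anno = annotation.set_index("gene_id")
    planted = []
    for g in codep_genes:
        offset = int(rng.integers(1_000, 25_000)) * int(rng.choice([-1, 1]))
        center = int(np.clip(anno.loc[g, "tss"] + offset, 500, params.chrom_sizes[anno.loc[g, "chrom"]] - 500))
        planted.append((anno.loc[g, "chrom"], center, g))

    n_free = n - len(planted)
    if n_free < 0:
        raise ValueError("n_peaks smaller than number of codependent genes")
    free_chrom = rng.choice(chroms, size=n_free)
    free_center = np.array([rng.integers(500, params.chrom_sizes[c] - 500) for c in free_chrom])

    chrom_all = np.concatenate([free_chrom, [c for c, _, _ in planted]])
    center_all = np.concatenate([free_center, [p for _, p, _ in planted]])
    gene_link = np.array([None] * n_free + [g for _, _, g in planted], dtype=object)

    # enforce disjoint intervals: sort per chromosome and nudge collisions
    width = rng.integers(200, 601, size=n)
    order = np.lexsort((center_all, chrom_all))
    chrom_all, center_all, width, gene_link = (
        chrom_all[order], center_all[order], width[order], gene_link[order]
    )
    starts = center_all - width // 2
    ends = starts + width
    for i in range(1, n):
        if chrom_all[i] == chrom_all[i - 1] and starts[i] < ends[i - 1]:
            shift = ends[i - 1] - starts[i] + int(rng.integers(50, 500))
            starts[i] += shift
            ends[i] += shift
    peak_ids = [f"pk{i:05d}" for i in range(n)]
    idx = pd.Index(peak_ids, name="peak_id")

    # archetypes: planted peaks are late (cluster 6); free peaks mixed
    arch_props = np.array([0.10, 0.15, 0.20, 0.20, 0.20, 0.15])
    archetype = rng.choice(np.arange(1, 7), size=n, p=arch_props)
    archetype[gene_link != None] = 6  # noqa: E711

    member_p = {
        "p50": {1: 0.90, 2: 0.50, 3: 0.50, 4: 0.50, 5: 0.50, 6: 0.30},
        "RelA": {1: 0.30, 2: 0.85, 3: 0.85, 4: 0.85, 5: 0.85, 6: 0.60},
        "IkBz": {1: 0.001, 2: 0.001, 3: 0.001, 4: 0.001, 5: 0.001, 6: 0.90},
    }
    membership = pd.DataFrame(index=idx)
    for factor, probs in member_p.items():
        p = np.array([probs[a] for a in archetype])
        membership[factor] = rng.random(n) < p
    is_planted = gene_link != None  # noqa: E711
    membership.loc[is_planted, ["p50", "RelA", "IkBz"]] = True
    none = ~membership.any(axis=1)
    membership.loc[none, "RelA"] = True

    # p50 dependence of late-factor binding: planted peaks strong, plus a
    # small fraction of the remaining late peaks
    dependence = np.where(is_planted, "ikbz_p50_dependent", "independent").astype(object)
    extra = (~is_planted) & (archetype == 6) & membership["IkBz"].to_numpy() & (rng.random(n) < 0.03)
    dependence[extra] = "ikbz_p50_dependent"
    # p50-dependent RelA binding co-occurs with p50-dependent IkBzeta binding
    rela_dep = (dependence == "ikbz_p50_dependent") & membership["RelA"].to_numpy()
    dependence[rela_dep & ~is_planted & (rng.random(n) < 0.5)] = "rela_p50_dependent"
    dependence[is_planted] = "ikbz_p50_dependent"

    # factor-specific kinetics: IkBzeta follows the late archetype at its
    # sites, while p50/RelA binding at those same locations arrives earlier
    # (the NF-kB dimers precede IkBzeta)
    factor_arch = pd.DataFrame(
        {f: archetype.copy() for f in ("p50", "RelA", "IkBz")}, index=idx
    )
    late = archetype == 6
    for f in ("p50", "RelA"):
        early = rng.integers(2, 6, size=n)  # archetypes 2..5
        keep_late = rng.random(n) < 0.02
        factor_arch.loc[late & ~keep_late, f] = early[late & ~keep_late]
    factor_arch.loc[late, "IkBz"] = 6

    acc_p = {1: 0.95, 2: 0.55, 3: 0.55, 4: 0.55, 5: 0.55, 6: 0.75}
    accessible = rng.random(n) < np.array([acc_p[a] for a in archetype])

    motif_p = np.full(n, params.motif_p_background)
    motif_p[(dependence != "independent")] = params.motif_p_dependent
    motif_p[(archetype == 1) & membership["p50"].to_numpy()] = params.motif_p_p50_constitutive
    motif = rng.random(n) < motif_p

    truth.peak_archetype = pd.Series(archetype, index=idx, name="peak_archetype")
    truth.peak_dependence = pd.Series(dependence, index=idx, name="peak_dependence")
    truth.accessible_0h = pd.Series(accessible, index=idx, name="accessible_0h")
    truth.motif_planted = pd.Series(motif, index=idx, name="motif_planted")
    truth.peak_gene = pd.Series(gene_link, index=idx, name="peak_gene")

    amplitude = np.exp(rng.normal(np.log(8.0), 0.8, size=n))
    ko_factor = {}
    for factor, dep_label in (("IkBz", "ikbz_p50_dependent"), ("RelA", ("ikbz_p50_dependent", "rela_p50_dependent"))):
        labels = (dep_label,) if isinstance(dep_label, str) else dep_label
        strong = np.isin(dependence, labels)
        f = np.exp(rng.normal(0.0, 0.15, size=n))
        f[strong] = np.exp(rng.uniform(np.log(0.08), np.log(0.25), size=int(strong.sum())))
        ko_factor[factor] = f

    sigma = params.peak_sigma
    signal_cols = {}
    replicate_tables: dict[tuple[str, float], list[list[PeakRecord]]] = {}
    for factor in ("p50", "RelA", "IkBz"):
        member = membership[factor].to_numpy()
        shapes = ARCHETYPE_SHAPES[factor_arch[factor].to_numpy() - 1]  # n x 4
        for j, tp in enumerate(CHIP_TIMEPOINTS_H):
            mean = amplitude * shapes[:, j] * member
            reps: list[list[PeakRecord]] = []
            for rep in range(1, params.n_peak_replicates + 1):
                rpkm = mean * np.exp(rng.normal(0.0, sigma, size=n))
                score = rpkm * 12.0 * np.exp(rng.normal(0.0, 0.2, size=n))
                signal_cols[_sample_column(factor, tp, rep, "WT")] = rpkm
                reps.append(
                    [
                        PeakRecord(chrom_all[i], int(starts[i]), int(ends[i]), peak_ids[i],
                                   float(score[i]), {f"{factor}_r{rep}": float(rpkm[i])})
                        for i in range(n)
                        if member[i]
                    ]
                )
            replicate_tables[(factor, tp)] = reps
            if factor in ("IkBz", "RelA"):
                ko_mean = mean * ko_factor[factor]
                for rep in range(1, params.n_peak_replicates + 1):
                    rpkm = ko_mean * np.exp(rng.normal(0.0, sigma, size=n))
                    signal_cols[_sample_column(factor, tp, rep, "Nfkb1KO")] = rpkm
    signal = pd.DataFrame(signal_cols, index=idx)

    atac = [
        PeakRecord(chrom_all[i], int(starts[i]), int(ends[i]), f"atac{i:05d}",
                   float(np.exp(rng.normal(np.log(50.0), 0.5))), {})
        for i in range(n)
        if accessible[i]
    ]
    peaks = [
        PeakRecord(chrom_all[i], int(starts[i]), int(ends[i]), peak_ids[i],
                   float(amplitude[i]), {})
        for i in range(n)
    ]
    return PeakSim(peaks, replicate_tables, signal, atac, membership, factor_arch)


def generate_sequences(
    peaks: Sequence[PeakRecord],
    truth: SyntheticTruth,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Uniform-background windows with one planted homodimer motif each.

    Windows are ``motif_window_bp`` long, centred on each peak; flagged
    peaks receive a single GGGNNNNNCCC instance (random spacer, random
    offset). No overlapping plants: exactly zero or one instance is
    inserted per window.
    """
    rng = _rng(params, rng)
    w = params.motif_window_bp
    if w < 11:
        raise ValueError("window smaller than the 11 bp homodimer motif")
    bases = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for p in peaks:
        seq = bases[rng.integers(0, 4, size=w)]
        if bool(truth.motif_planted.get(p.peak_id, False)):
            off = int(rng.integers(0, w - 11 + 1))
            spacer = bases[rng.integers(0, 4, size=5)]
            seq[off : off + 11] = list("GGG") + list(spacer) + list("CCC")
        out[p.peak_id] = "".join(seq)
    return out


@dataclass
class SimulatedStudy:
    """Everything one seeded simulation produces."""

    params: GeneratorParams
    truth: SyntheticTruth
    annotation: pd.DataFrame
    expression: ExpressionTable
    expr_libraries: pd.DataFrame
    peaks: PeakSim
    sequences: dict[str, str]


def simulate(params: GeneratorParams | None = None) -> SimulatedStudy:
    """Run the full generator under one seed."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)
    truth = assign_gene_truth(params, rng)
    annotation = generate_genome(params, truth, rng)
    expression, libraries = generate_expression(params, annotation, truth, rng)
    peaks = generate_peaks(params, truth, annotation, rng)
    sequences = generate_sequences(peaks.peaks, truth, params, rng)
    return SimulatedStudy(params, truth, annotation, expression, libraries, peaks, sequences)


def simulate_null_counts(
    n_genes: int,
    dispersion: float = 0.05,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two equal-mean NB count matrices (genes x replicates) for null tests.

    Per-gene means are lognormal around a few hundred reads, spanning the
    count range the expression generator produces for expressed genes.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mean = np.exp(rng.normal(np.log(300.0), 1.0, size=n_genes))
    r = 1.0 / dispersion
    shape = (n_genes, n_replicates)
    a = rng.negative_binomial(r, r / (r + mean[:, None]), size=shape)
    b = rng.negative_binomial(r, r / (r + mean[:, None]), size=shape)
    return a.astype(float), b.astype(float)
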