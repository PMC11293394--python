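"""Run-wide analysis thresholds.

All classification steps in the pipeline share a small set of constants:
the knockout:WT ratio below which a gene or binding site counts as
dependent, the significance cutoff, the expression floor, and the peak
reproducibility thresholds. They are collected here so that every module
reads the same numbers and so a CLI run can override them in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Thresholds and sizes used across the pipeline.

    Attributes
    ----------
    dependence_ratio : float
        A gene/peak is dependent when the KO:WT ratio falls strictly below
        this value (0.33, i.e. <33% of wild type).
    p_cut : float
        Adjusted p-value cutoff for the expression dependence screen.
    expressed_rpkm : float
        RPKM floor for a gene to count as expressed (WT RPKM > 3).
    ps_cut : float
        Peak-score floor for reproducible ChIP-seq peaks (PS > 19).
    peak_rpkm_cut : float
        RPKM floor for reproducible peaks (RPKM > 3).
    induced_fc : float
        Fold-change above which a gene counts as stimulus-induced (> 5).
    weak_fc_range : tuple
        Fold-change band labelled weakly induced ([1, 5]).
    tss_window_kb : float
        Peak-to-gene annotation window; 5 kb for promoter-proximal
        analyses, 30 kb for the dependence enrichment analysis.
    diff_ratios : tuple
        TNF:lipid A ratio thresholds defining the differential (1/3) and
        strongly differential (1/60) expression tiers.
    n_clusters : int
        Number of kinetic k-means clusters.
    n_bins_coarse, n_bins_fine : int
        Bin counts used by the rank-and-bin analyses (15 and 20).
    preference_bin_size : int
        Size of the top/middle/bottom preference slices (300 peaks).
    motif_window_bp : int
        Window centred on each peak that is scanned for motifs (200 bp).
    ratio_pseudocount : float
        RPKM pseudocount stabilising KO:WT and p50:RelA ratios.
    rng_seed : int
        Seed for every stochastic step (k-means restarts, simulation).
    """

    dependence_ratio: float = 0.33
    p_cut: float = 0.01
    expressed_rpkm: float = 3.0
    ps_cut: float = 19.0
    peak_rpkm_cut: float = 3.0
    induced_fc: float = 5.0
    weak_fc_range: tuple[float, float] = (1.0, 5.0)
    tss_window_kb: float = 5.0
    diff_ratios: tuple[float, float] = (1.0 / 3.0, 1.0 / 60.0)
    n_clusters: int = 6
    n_bins_coarse: int = 15
    n_bins_fine: int = 20
    preference_bin_size: int = 300
    motif_window_bp: int = 200
    ratio_pseudocount: float = 0.1
    dispersion_floor: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dependence_ratio",
            "p_cut",
            "expressed_rpkm",
            "induced_fc",
            "ratio_pseudocount",
            "dispersion_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ps_cut < 0 or self.peak_rpkm_cut < 0:
            raise ValueError("peak thresholds must be nonnegative")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_bins_coarse < 2 or self.n_bins_fine < 2:
            raise ValueError("bin counts must be >= 2")
        if any(r <= 0 for r in self.diff_ratios):
            raise ValueError("diff_ratios must be positive")


TIMEPOINTS_H: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 6.0)
"""Expression time course (hours after stimulation)."""

CHIP_TIMEPOINTS_H: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
"""ChIP-seq time course (hours after stimulation)."""

GENOTYPES: tuple[str, ...] = ("WT", "Nfkb1KO", "NfkbizKO", "Bcl3KO", "NfkbidKO")
STIMULI: tuple[str, ...] = ("lipidA", "TNF")
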