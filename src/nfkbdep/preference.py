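"""Dimer binding preference, genotype dependence of binding, and the
rank-and-bin bookkeeping that links both to gene classes.

The p50:RelA preference score orders a combined peak set (all reproducible
p50 sites plus an equal number of top RelA sites) by the 1 h RPKM ratio;
the ordered list is cut into equal contiguous bins and per-bin fractions
of annotated properties (induced-gene linkage, motif content, co-bound
factors) are reported.

Genotype dependence of a factor's binding compares its signal in wild-type
versus Nfkb1-knockout cells peak by peak; the KO:WT ratio r places each
site in one of three bands: independent (r > 100%), mild (33-100%) and
strong (< 33%). Band boundaries follow the inclusive 33%-100% convention
for the mild band.

Both ratios use a 0.1 RPKM pseudocount on numerator and denominator, well
below the 3 RPKM expression floor, so zero-signal peaks get finite ratios
without reordering expressed ones.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import PeakRecord

__all__ = [
    "preference_ratio",
    "partition_bins",
    "annotate_peaks",
    "bin_fraction",
    "binding_dependence",
    "band_of",
    "one_peak_per_gene",
    "dependence_enrichment",
]

BANDS = ("strong", "mild", "independent")


def preference_ratio(
    signal: pd.DataFrame,
    p50_cols: Sequence[str],
    rela_cols: Sequence[str],
    p50_members: Iterable[str],
    rela_members: Iterable[str],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """p50:RelA 1 h RPKM ratio over the combined preference peak set.

    The universe is all reproducible p50 sites plus the top-N RelA sites
    by maximum 1 h RPKM, where N equals the p50 set size (locations in
    both sets count once). Returns one row per peak sorted by descending
    ratio ``rho = (p50 + eps) / (RelA + eps)``.
    """
    config = config or RunConfig()
    missing = [c for c in list(p50_cols) + list(rela_cols) if c not in signal.columns]
    if missing:
        raise ValueError(f"1 h sample columns missing from signal matrix: {missing}")
    p50_members = [m for m in p50_members if m in signal.index]
    rela_members = [m for m in rela_members if m in signal.index]
    n = len(p50_members)
    rela_rank = (
        signal.loc[rela_members, rela_cols].max(axis=1).sort_values(ascending=False)
    )
    top_rela = list(rela_rank.index[:n])
    universe = list(dict.fromkeys(list(p50_members) + top_rela))
    eps = config.ratio_pseudocount
    p50_1h = signal.loc[universe, p50_cols].mean(axis=1)
    rela_1h = signal.loc[universe, rela_cols].mean(axis=1)
    out = pd.DataFrame(
        {
            "peak_id": universe,
            "p50_rpkm_1h": p50_1h.values,
            "rela_rpkm_1h": rela_1h.values,
            "ratio": ((p50_1h + eps) / (rela_1h + eps)).values,
        }
    )
    return out.sort_values(["ratio", "peak_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def partition_bins(sorted_items: Sequence[str], n_bins: int) -> pd.Series:
    """Cut a pre-sorted list into contiguous equal bins (1-based index).

    With remainder r, the first r bins receive one extra item; sizes
    differ by at most one and sum to the item count.
    """
    items = list(sorted_items)
    if n_bins > len(items):
        raise ValueError(f"n_bins ({n_bins}) exceeds number of items ({len(items)})")
    labels = np.concatenate(
        [np.full(len(chunk), i + 1) for i, chunk in enumerate(np.array_split(items, n_bins))]
    )
    return pd.Series(labels, index=items, name="bin")


def annotate_peaks(
    peaks: Sequence[PeakRecord],
    annotation: pd.DataFrame,
    window_kb: float,
    expressed_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Link each peak to its nearest TSS within ``window_kb``.

    ``annotation`` needs columns gene_id / chrom / tss. When
    ``expressed_genes`` is given, only those genes are annotation
    candidates (the expressed-gene restriction of the 30 kb analysis).
    Peaks whose nearest candidate TSS lies beyond the window are dropped;
    an exact distance tie picks the lexicographically smaller gene_id.
    """
    candidates = annotation
    if expressed_genes is not None:
        expressed_genes = set(expressed_genes)
        candidates = annotation[annotation["gene_id"].isin(expressed_genes)]
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, grp in candidates.groupby("chrom")
    }
    window_bp = window_kb * 1000.0
    rows = []
    for p in peaks:
        grp = by_chrom.get(p.chrom)
        if grp is None or grp.empty:
            continue
        tss = grp["tss"].to_numpy()
        dist = np.abs(tss - p.center)
        best = dist.min()
        if best > window_bp:
            continue
        tied = grp.loc[dist == best, "gene_id"]
        rows.append(
            {
                "peak_id": p.peak_id,
                "gene_id": tied.min(),
                "distance_bp": int(best),
                "window_kb": window_kb,
            }
        )
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance_bp", "window_kb"])


def bin_fraction(bins: pd.Series, predicate: pd.Series) -> pd.Series:
    """Per-bin fraction of items satisfying a boolean predicate.

    ``bins`` maps item -> bin index; ``predicate`` must cover every item.
    """
    missing = bins.index.difference(predicate.index)
    if len(missing):
        raise ValueError(f"predicate undefined for {len(missing)} items")
    pred = predicate.reindex(bins.index).astype(bool)
    return pred.groupby(bins).mean().rename("fraction")


def band_of(ratio: float) -> str:
    """Dependence band for a KO:WT ratio (strict < 0.33; inclusive 33-100%)."""
    if ratio < 0.33:
        return "strong"
    if ratio <= 1.0:
        return "mild"
    return "independent"


def binding_dependence(
    wt_rpkm: pd.Series,
    ko_rpkm: pd.Series,
    factor: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-peak KO:WT binding ratio with its dependence band.

    Both series must cover the same peak universe (replicate-averaged
    RPKM at the comparison timepoint, 2 h for the late-binding factors).
    """
    config = config or RunConfig()
    if set(wt_rpkm.index) != set(ko_rpkm.index):
        raise ValueError("WT and KO matrices must quantify the same peak universe")
    ko = ko_rpkm.reindex(wt_rpkm.index)
    eps = config.ratio_pseudocount
    ratio = (ko + eps) / (wt_rpkm + eps)
    out = pd.DataFrame(
        {
            "peak_id": wt_rpkm.index,
            "factor": factor,
            "wt_rpkm": wt_rpkm.values,
            "ko_rpkm": ko.values,
            "ratio": ratio.values,
        }
    )
    out["band"] = [band_of(r) for r in out["ratio"]]
    return out


def one_peak_per_gene(links: pd.DataFrame, dependence: pd.DataFrame) -> pd.DataFrame:
    """Among each gene's linked peaks keep the most KO-dependent one.

    Minimum KO:WT ratio wins (the peak with the greatest change in
    binding); ties pick the smallest peak_id. Result has at most one row
    per gene.
    """
    merged = links.merge(
        dependence[["peak_id", "ratio"]], on="peak_id", how="left"
    ).sort_values(["gene_id", "ratio", "peak_id"])
    return merged.groupby("gene_id", as_index=False).first()[links.columns.tolist()]


def dependence_enrichment(
    bins: pd.Series,
    links: pd.DataFrame,
    gene_classes: Mapping[str, str] | pd.Series,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentage of peaks per bin annotating to each gene class.

    ``bins`` maps peak_id -> bin; ``links`` provides peak -> gene;
    ``gene_classes`` maps gene -> class label. Unlinked peaks and genes
    without a class count toward the bin size but no class, so per-bin
    percentages sum to at most 100.
    """
    gene_classes = pd.Series(gene_classes)
    if classes is None:
        classes = sorted(gene_classes.unique())
    link_map = links.set_index("peak_id")["gene_id"]
    peak_class = link_map.map(gene_classes).reindex(bins.index)
    out = {}
    for cls in classes:
        out[cls] = (peak_class == cls).groupby(bins).mean() * 100.0
    result = pd.DataFrame(out)
    result["any_listed"] = result.sum(axis=1)
    result.index.name = "bin"
    return result
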