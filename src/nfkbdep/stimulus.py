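"""Stimulus-differential expression: lipid A versus TNF.

TLR4 engagement (lipid A) and TNF-receptor engagement activate NF-kB with
similar early kinetics, yet a subset of genes — headed by Nfkbiz itself
and most IkBzeta targets — is induced far more strongly by lipid A. Each
induced, expressed gene (lipid A fold-induction > 3 and WT RPKM > 3) gets
a per-timepoint TNF:lipidA RPKM ratio; the minimum ratio across the time
course places the gene in one of three nested tiers: not differential
(> 1/3), differential (<= 1/3) and strongly differential (<= 1/60).

The tier is then crossed with regulator-dependence labels (from the
nascent-transcript classification, plus externally supplied IRF3/IFNAR
labels) to count how much of the differential response each pathway can
account for. mRNA ratios and nascent-transcript dependence live in
different tables; the crosstab takes both explicitly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import ExpressionTable

__all__ = ["stimulus_ratio", "classify_differential", "crosstab_dependence"]

TIERS = ("not_differential", "differential", "strong")


def stimulus_ratio(
    table: ExpressionTable,
    config: RunConfig | None = None,
    induced_fc: float = 3.0,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Per-gene TNF:lipidA RPKM ratios at each timepoint, plus the minimum.

    Only genes induced by lipid A more than ``induced_fc`` (3, the
    differential-analysis filter, distinct from the stricter 5x induction
    class) with WT lipid A RPKM above the expression floor are included;
    excluded genes are returned flagged with ``included=False``. Ratios
    use replicate-averaged RPKM with a 0.1 pseudocount on both terms.
    """
    config = config or RunConfig()
    tps = [t for t in table.timepoints() if t > 0]
    eps = config.ratio_pseudocount
    lip0 = table.rpkm(genotype, "lipidA", 0.0)
    lip = pd.concat([table.rpkm(genotype, "lipidA", t) for t in tps], axis=1)
    tnf = pd.concat([table.rpkm(genotype, "TNF", t) for t in tps], axis=1)
    lip.columns = tnf.columns = tps
    max_fc = lip.max(axis=1) / lip0.clip(lower=0.5)
    included = (max_fc > induced_fc) & (lip.max(axis=1) > config.expressed_rpkm)
    ratios = (tnf + eps) / (lip + eps)
    out = pd.DataFrame(
        {"gene_id": ratios.index, "included": included.values, "max_lipidA_fc": max_fc.values}
    )
    for t in tps:
        out[f"ratio_{t:g}h"] = ratios[t].values
    out["min_ratio"] = ratios.min(axis=1).values
    out["min_timepoint"] = ratios.idxmin(axis=1).values
    return out.reset_index(drop=True)


def classify_differential(
    ratios: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Assign each included gene a differential tier from its minimum ratio.

    ``strong`` when min_ratio <= 1/60, ``differential`` when <= 1/3
    (boundary values inclusive), else ``not_differential``. Tiers nest:
    every strong gene is also differential; the ``strong`` label reports
    the innermost tier.
    """
    config = config or RunConfig()
    weak_cut, strong_cut = config.diff_ratios
    out = ratios.loc[ratios["included"]].copy()
    out["tier"] = np.select(
        [out["min_ratio"] <= strong_cut, out["min_ratio"] <= weak_cut],
        ["strong", "differential"],
        default="not_differential",
    )
    return out.reset_index(drop=True)


def crosstab_dependence(
    differential_calls: pd.DataFrame,
    dependence_labels: Mapping[str, str] | pd.Series,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts of genes per differential tier x dependence class.

    ``dependence_labels`` maps gene_id to a class label (codependence
    labels, an IRF3/IFNAR annotation column, ...); genes without a label
    count as ``unlabeled``. Adds per-tier totals and tier-conditional
    percentages per class.
    """
    labels = pd.Series(dependence_labels)
    calls = differential_calls.copy()
    calls["class"] = calls["gene_id"].map(labels).fillna("unlabeled")
    if classes is None:
        classes = [c for c in calls["class"].unique() if c != "unlabeled"]
    counts = (
        calls.groupby(["tier", "class"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=[t for t in TIERS if t in counts.index], fill_value=0)
    for cls in list(classes) + ["unlabeled"]:
        if cls not in counts.columns:
            counts[cls] = 0
    counts["total"] = counts.sum(axis=1)
    for cls in classes:
        counts[f"{cls}_pct"] = np.where(
            counts["total"] > 0, counts[cls] / counts["total"] * 100.0, 0.0
        )
    counts.index.name = "tier"
    return counts
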