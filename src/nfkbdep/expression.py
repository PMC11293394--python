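"""Genotype-contrast classification of regulator-dependent transcription.

A gene is *dependent* on a regulator when its nascent transcription in the
knockout collapses relative to wild type: the replicate-averaged KO:WT RPKM
ratio at some post-stimulation timepoint (with WT RPKM > 3) falls below
0.33 with an adjusted p-value below 0.01. The timepoint used for each gene
is the one with the minimum KO:WT ratio. The 0.5 h timepoint is screened
separately (early dependence) from the 1/2/6 h timepoints (late
dependence), matching the two-stage structure of the time course: primary
response genes can only show early dependence, secondary response genes
appear from 1 h onward.

Significance comes from a negative-binomial exact test on the replicate
read counts, conditioning on the total count of the two arms; the
conditional null distribution depends only on the dispersion, which is
estimated once per contrast by pooled method-of-moments across genes.

*Codependence* on two regulators (the p50/IkBzeta signature) requires the
full dependence call — ratio AND significance — under each knockout
separately.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import ExpressionTable

__all__ = [
    "compute_rpkm",
    "estimate_dispersion",
    "test_contrast",
    "classify_dependence",
    "classify_induction",
    "codependence_join",
    "REGULATOR_GENOTYPE",
    "SCREEN_TIMEPOINTS",
]

REGULATOR_GENOTYPE: Mapping[str, str] = {
    "Nfkb1": "Nfkb1KO",
    "Nfkbiz": "NfkbizKO",
    "Bcl3": "Bcl3KO",
    "Nfkbid": "NfkbidKO",
}

SCREEN_TIMEPOINTS: Mapping[str, tuple[float, ...]] = {
    "early": (0.5,),
    "late": (1.0, 2.0, 6.0),
    "all": (0.5, 1.0, 2.0, 6.0),
}


def compute_rpkm(counts, gene_length_kb, library_size_millions):
    """Reads per kilobase per million: count / (length_kb * library_millions).

    Accepts scalars or aligned arrays; used for both gene transcripts
    (gene length) and peak signal (peak width).
    """
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_kb, dtype=float)
    lib = np.asarray(library_size_millions, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene_length_kb must be positive")
    if np.any(lib <= 0):
        raise ValueError("library_size_millions must be positive")
    out = counts / (length * lib)
    return float(out) if out.ndim == 0 else out


def estimate_dispersion(
    counts_a: np.ndarray, counts_b: np.ndarray, floor: float = 0.01
) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    ``counts_a``/``counts_b`` are genes x replicates matrices for the two
    arms of a contrast. For each gene and arm with positive mean the
    moment estimate (var - mean) / mean^2 is computed; the pooled estimate
    is the across-gene mean of the nonnegative per-gene values, floored.
    With two replicates per arm the per-gene estimates are individually
    noisy but their average over thousands of genes is stable.
    """
    est: list[np.ndarray] = []
    for arm in (np.asarray(counts_a, float), np.asarray(counts_b, float)):
        m = arm.mean(axis=1)
        v = arm.var(axis=1, ddof=1)
        ok = m > 0
        est.append(np.clip((v[ok] - m[ok]) / m[ok] ** 2, 0.0, None))
    pooled = np.concatenate(est)
    if pooled.size == 0:
        return floor
    return max(float(pooled.mean()), floor)


def test_contrast(
    counts_ko: Sequence[float],
    counts_wt: Sequence[float],
    dispersion: float,
) -> float:
    """Two-sided NB exact p-value for a KO vs WT count contrast.

    Conditions on the total count ``s`` of both arms. Replicate sums are
    NB-distributed with size parameters ``n_reps / dispersion``; the
    conditional distribution of the KO sum given ``s`` is free of the mean
    and depends only on the dispersion. The two-sided p-value sums the
    conditional probabilities of every split as or less likely than the
    observed one (the standard exact-test convention for count data).

    Degenerate all-zero input returns 1.0.
    """
    ko = np.asarray(counts_ko, dtype=float)
    wt = np.asarray(counts_wt, dtype=float)
    if ko.size < 2 or wt.size < 2:
        raise ValueError("need >=2 replicates per arm")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    s = int(round(ko.sum() + wt.sum()))
    if s == 0:
        return 1.0
    r_ko = ko.size / dispersion
    r_wt = wt.size / dispersion
    k = np.arange(s + 1, dtype=float)
    # log of the p-free part of nbinom.pmf(k; r_ko) * nbinom.pmf(s-k; r_wt)
    logw = (
        gammaln(k + r_ko)
        - gammaln(k + 1.0)
        + gammaln(s - k + r_wt)
        - gammaln(s - k + 1.0)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    k_obs = int(round(ko.sum()))
    p = float(w[w <= w[k_obs] * (1 + 1e-12)].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def classify_induction(
    table: ExpressionTable, config: RunConfig | None = None, stimulus: str = "lipidA"
) -> pd.DataFrame:
    """Label each gene's WT response to the stimulus.

    ``induced`` means the maximum WT fold-change over the 0 h baseline
    strictly exceeds ``config.induced_fc`` (5); induced genes carry their
    annotated primary/secondary response class. Genes with fold-change at
    or below the threshold (including repressed genes) are
    ``weak_or_repressed``. Genes never expressed above the RPKM floor, and
    induced genes lacking a primary/secondary annotation, are
    ``not_induced``. A zero 0 h baseline is replaced by a 0.5 RPKM
    pseudocount and flagged.
    """
    config = config or RunConfig()
    tps = [t for t in table.timepoints() if t > 0]
    wt0 = table.rpkm("WT", stimulus, 0.0)
    wt_post = pd.concat([table.rpkm("WT", stimulus, t) for t in tps], axis=1)
    wt_post.columns = tps
    zero_baseline = wt0 == 0
    denom = wt0.where(~zero_baseline, 0.5)
    max_fc = wt_post.max(axis=1) / denom
    expressed = (wt_post.max(axis=1) > config.expressed_rpkm) | (
        wt0 > config.expressed_rpkm
    )
    response = table.meta.set_index("gene_id")["response_class"].reindex(max_fc.index)
    cls = pd.Series("weak_or_repressed", index=max_fc.index, name="induction_class")
    induced = max_fc > config.induced_fc
    cls[induced] = response[induced].where(
        response[induced].isin(["primary", "secondary"]), "not_induced"
    )
    cls[~expressed] = "not_induced"
    return pd.DataFrame(
        {
            "gene_id": max_fc.index,
            "max_fold_change": max_fc.values,
            "induction_class": cls.values,
            "zero_baseline": zero_baseline.values,
        }
    ).reset_index(drop=True)


def classify_dependence(
    table: ExpressionTable,
    regulator: str,
    config: RunConfig | None = None,
    screen: str = "late",
    stimulus: str = "lipidA",
) -> pd.DataFrame:
    """Call regulator dependence for every gene from a KO vs WT time course.

    For each gene, the replicate-averaged KO:WT RPKM ratio is evaluated at
    every screen timepoint where WT RPKM exceeds the expression floor; the
    minimum-ratio timepoint is selected and the NB exact test applied to
    its replicate counts. P-values are Benjamini-Hochberg adjusted across
    the genes in the screen. A gene is dependent when
    ``min_ratio < dependence_ratio`` and ``adjusted_p < p_cut`` (strict).

    Genes with no eligible timepoint are returned with
    ``status='not_expressed'`` and are never dependent.
    """
    config = config or RunConfig()
    if regulator not in REGULATOR_GENOTYPE:
        raise ValueError(f"unknown regulator {regulator!r}; one of {sorted(REGULATOR_GENOTYPE)}")
    if screen not in SCREEN_TIMEPOINTS:
        raise ValueError(f"unknown screen {screen!r}; one of {sorted(SCREEN_TIMEPOINTS)}")
    genotype = REGULATOR_GENOTYPE[regulator]
    tps = [t for t in SCREEN_TIMEPOINTS[screen] if t in table.timepoints()]
    if not tps:
        raise ValueError(f"no screen timepoints present in table for screen {screen!r}")

    genes = table.gene_ids
    wt = pd.concat([table.rpkm("WT", stimulus, t) for t in tps], axis=1)
    ko = pd.concat([table.rpkm(genotype, stimulus, t) for t in tps], axis=1)
    wt.columns = ko.columns = tps
    # denominator guard: WT RPKM floored at 0.5 so the ratio is defined
    # everywhere; eligibility still requires WT > expressed_rpkm
    ratio = ko / wt.clip(lower=0.5)
    eligible = wt > config.expressed_rpkm
    ratio_masked = ratio.where(eligible)

    min_ratio = ratio_masked.min(axis=1)
    has_tp = eligible.any(axis=1)
    sel_tp = pd.Series(np.nan, index=min_ratio.index, dtype=object)
    if has_tp.any():
        sel_tp[has_tp] = ratio_masked.loc[has_tp].idxmin(axis=1)

    # dispersion pooled across all genes and screen timepoints of this contrast
    ko_counts = {t: table.counts(genotype, stimulus, t) for t in tps}
    wt_counts = {t: table.counts("WT", stimulus, t) for t in tps}
    disp = estimate_dispersion(
        np.vstack([ko_counts[t].to_numpy() for t in tps]),
        np.vstack([wt_counts[t].to_numpy() for t in tps]),
        floor=config.dispersion_floor,
    )

    pvals = np.full(len(genes), np.nan)
    for i, g in enumerate(genes):
        if not has_tp.iloc[i]:
            continue
        t = sel_tp.iloc[i]
        pvals[i] = test_contrast(
            ko_counts[t].loc[g].to_numpy(), wt_counts[t].loc[g].to_numpy(), disp
        )

    adj = np.full(len(genes), np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    induction = classify_induction(table, config, stimulus=stimulus)
    calls = pd.DataFrame(
        {
            "gene_id": genes,
            "regulator": regulator,
            "screen": screen,
            "min_ratio": min_ratio.values,
            "selected_timepoint": sel_tp.values,
            "p_value": pvals,
            "adjusted_p": adj,
            "status": np.where(has_tp.values, "tested", "not_expressed"),
        }
    )
    calls["dependent"] = (
        has_tp.values
        & (calls["min_ratio"] < config.dependence_ratio)
        & (calls["adjusted_p"] < config.p_cut)
    )
    calls = calls.merge(induction[["gene_id", "induction_class"]], on="gene_id")
    calls["dispersion_used"] = disp
    return calls


def codependence_join(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Cross two dependence-call tables into a per-gene codependence label.

    Labels are ``codependent`` (dependent under both regulators, each with
    its own ratio and significance), ``<regA>_only``, ``<regB>_only`` or
    ``neither``. Genes present in only one table are ``neither`` and
    flagged ``incomplete``.
    """
    reg_a = calls_a["regulator"].iloc[0]
    reg_b = calls_b["regulator"].iloc[0]
    a = calls_a.set_index("gene_id")["dependent"]
    b = calls_b.set_index("gene_id")["dependent"]
    universe = a.index.union(b.index)
    dep_a = a.reindex(universe)
    dep_b = b.reindex(universe)
    incomplete = (dep_a.isna() | dep_b.isna()).to_numpy()
    da = (dep_a == True).to_numpy()  # noqa: E712  (NaN-safe boolean)
    db = (dep_b == True).to_numpy()  # noqa: E712
    label = np.select(
        [incomplete, da & db, da & ~db, ~da & db],
        ["neither", "codependent", f"{reg_a}_only", f"{reg_b}_only"],
        default="neither",
    )
    return pd.DataFrame(
        {"gene_id": universe, "label": label, "incomplete": incomplete}
    ).reset_index(drop=True)
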