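"""Peak reproducibility, union, quantification and kinetic clustering.

ChIP-seq peaks enter as per-replicate BED-like tables for each factor and
timepoint. Reproducible binding sites are locations passing the peak-score
and RPKM thresholds (PS > 19, RPKM > 3) in at least k of n replicates at
one or more timepoints. Reproducible sites from multiple factors are
merged into a union of genomic locations, quantified as a peaks x samples
RPKM matrix, and clustered into six kinetic archetypes over the
0/0.5/1/2 h time course with k-means on max-normalised profiles.

All intervals are 0-based half-open; two intervals overlap when they share
at least one base.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import RunConfig
from .io import PeakRecord

__all__ = [
    "filter_reproducible",
    "union_peaksets",
    "quantify",
    "kinetic_kmeans",
    "KineticClustering",
    "cluster_composition",
    "accessibility_overlay",
    "overlaps_any",
    "rank_order_matrix",
]


def _merge_intervals(intervals: list[tuple[str, int, int, object]]):
    """Sweep-merge tagged intervals; >=1 bp shared merges two intervals.

    Yields (chrom, start, end, [tags...]) for each merged location.
    """
    intervals = sorted(intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
    merged: list[list] = []
    for chrom, start, end, tag in intervals:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3].append(tag)
        else:
            merged.append([chrom, start, end, [tag]])
    return merged


def filter_reproducible(
    peak_replicates: Mapping[float, Sequence[Sequence[PeakRecord]]],
    config: RunConfig | None = None,
    min_replicates: int = 2,
) -> list[PeakRecord]:
    """Keep locations with PS > ps_cut and RPKM > rpkm_cut in >=k replicates.

    Parameters
    ----------
    peak_replicates : mapping timepoint -> sequence of replicate peak lists.
        Each record's first RPKM value is the replicate's own signal.
    min_replicates : k in the k-of-n rule (2-of-2 by default; pass tables
        with three replicates for the 2-of-3 variant).

    A location passes if at *one or more* timepoints at least k replicates
    contribute a peak meeting both thresholds. Output locations are the
    merged (min start / max end) intervals of all contributing peaks, with
    the maximum observed score and per-sample RPKMs averaged over
    contributors.
    """
    config = config or RunConfig()
    chrom_sets = []
    tagged: list[tuple[str, int, int, tuple]] = []
    for tp, replicates in peak_replicates.items():
        for rep_idx, records in enumerate(replicates):
            chrom_sets.append(frozenset(p.chrom for p in records))
            for p in records:
                rpkm = next(iter(p.rpkm.values())) if p.rpkm else 0.0
                passing = p.score > config.ps_cut and rpkm > config.peak_rpkm_cut
                tagged.append((p.chrom, p.start, p.end, (tp, rep_idx, passing, p)))
    nonempty = [s for s in chrom_sets if s]
    if nonempty and len(set(nonempty)) > 1:
        raise ValueError(
            "replicate tables cover different chromosome sets; mixed assemblies?"
        )
    kept: list[PeakRecord] = []
    for chrom, start, end, tags in _merge_intervals(tagged):
        per_tp: dict[float, set[int]] = defaultdict(set)
        for tp, rep_idx, passing, _ in tags:
            if passing:
                per_tp[tp].add(rep_idx)
        if not any(len(reps) >= min_replicates for reps in per_tp.values()):
            continue
        contributors = [t[3] for t in tags]
        rpkm_acc: dict[str, list[float]] = defaultdict(list)
        for p in contributors:
            for label, v in p.rpkm.items():
                rpkm_acc[label].append(v)
        ids = {p.peak_id for p in contributors}
        kept.append(
            PeakRecord(
                chrom=chrom,
                start=start,
                end=end,
                # a location contributed by a single upstream peak id keeps it
                peak_id=ids.pop() if len(ids) == 1 else f"{chrom}:{start}-{end}",
                score=max(p.score for p in contributors),
                rpkm={k: float(np.mean(v)) for k, v in rpkm_acc.items()},
            )
        )
    return kept


def union_peaksets(peaksets: Mapping[str, Sequence[PeakRecord]]) -> pd.DataFrame:
    """Merge peak sets from several factors into unique genomic locations.

    Returns a frame with one row per merged location (chrom/start/end/
    peak_id) and one boolean provenance column per input set recording
    which factors contributed a peak.
    """
    if not peaksets:
        raise ValueError("need at least one peak set")
    tagged = [
        (p.chrom, p.start, p.end, name)
        for name, records in peaksets.items()
        for p in records
    ]
    rows = []
    for chrom, start, end, tags in _merge_intervals(tagged):
        row = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "peak_id": f"{chrom}:{start}-{end}",
        }
        for name in peaksets:
            row[name] = name in tags
        rows.append(row)
    return pd.DataFrame(rows)


def quantify(
    merged_peaks: pd.DataFrame,
    sample_counts: pd.DataFrame,
    library_sizes_millions: Mapping[str, float],
) -> pd.DataFrame:
    """Peaks x samples RPKM matrix from raw read counts per location.

    ``sample_counts`` is indexed by peak_id with one column per sample;
    RPKM normalises each count by peak width (kb) and library depth
    (million reads).
    """
    widths_bp = (
        merged_peaks.set_index("peak_id")["end"] - merged_peaks.set_index("peak_id")["start"]
    )
    if (widths_bp <= 0).any():
        raise ValueError("zero-width location in merged peaks")
    counts = sample_counts.reindex(widths_bp.index)
    if counts.isna().any().any():
        raise ValueError("sample counts missing for some merged peaks")
    libs = pd.Series({s: library_sizes_millions[s] for s in counts.columns})
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(widths_bp / 1000.0, axis=0).div(libs, axis=1)


class KineticClustering:
    """k-means result: per-peak cluster labels plus relabelled centroids.

    Cluster numbers follow the kinetic convention: clusters are ordered by
    the timepoint at which their centroid peaks (earliest first), ties
    broken by higher 0 h signal — so cluster 1 holds sites already bound
    in unstimulated cells and cluster 6 sites that stay low until 2 h.
    """

    def __init__(self, assignments: pd.Series, centroids: pd.DataFrame):
        self.assignments = assignments
        self.centroids = centroids

    def __getitem__(self, peak_id: str) -> int:
        return int(self.assignments[peak_id])

    def assign(self, profile) -> int:
        """Nearest-centroid cluster for a new kinetic profile.

        The profile is max-normalised exactly like the training rows.
        """
        v = np.asarray(profile, dtype=float)
        if v.max() > 0:
            v = v / v.max()
        d = ((self.centroids.to_numpy() - v) ** 2).sum(axis=1)
        return int(self.centroids.index[int(np.argmin(d))])


def kinetic_kmeans(
    matrix: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_init: int = 50,
) -> KineticClustering:
    """Cluster peak kinetic profiles (timepoint columns) into k archetypes.

    Each row is first scaled to its own maximum so clusters encode shape
    rather than amplitude; all-zero rows are left as zeros. k-means runs
    ``n_init`` restarts under a fixed seed, and the arbitrary k-means
    labels are renumbered 1..k by (centroid argmax timepoint, then
    descending 0 h level).
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of peaks ({len(matrix)})")
    values = matrix.to_numpy(dtype=float)
    row_max = values.max(axis=1, keepdims=True)
    scaled = np.divide(values, row_max, out=np.zeros_like(values), where=row_max > 0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(scaled)
    centroids = km.cluster_centers_
    order = sorted(
        range(k), key=lambda c: (int(np.argmax(centroids[c])), -centroids[c][0])
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series(
        [relabel[c] for c in raw_labels], index=matrix.index, name="cluster"
    )
    centroid_frame = pd.DataFrame(
        centroids[order], index=range(1, k + 1), columns=matrix.columns
    )
    centroid_frame.index.name = "cluster"
    return KineticClustering(assignments, centroid_frame)


def cluster_composition(
    clustering: KineticClustering, per_factor_membership: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Percentage of each factor's peaks falling in each kinetic cluster.

    Rows are factors, columns cluster numbers; each row sums to 100 (rows
    for factors with no clustered peaks are all-NaN).
    """
    clusters = sorted(clustering.centroids.index)
    rows = {}
    for factor, members in per_factor_membership.items():
        members = [m for m in members if m in clustering.assignments.index]
        if not members:
            rows[factor] = pd.Series(np.nan, index=clusters)
            continue
        counts = clustering.assignments.loc[members].value_counts()
        rows[factor] = counts.reindex(clusters, fill_value=0) / len(members) * 100.0
    out = pd.DataFrame(rows).T
    out.columns.name = "cluster"
    return out


def _interval_arrays(peaks: Sequence[PeakRecord]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append((p.start, p.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        # running max of ends handles contained intervals
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        out[chrom] = (starts, ends)
    return out


def overlaps_any(
    query: Sequence[PeakRecord], subject: Sequence[PeakRecord]
) -> pd.Series:
    """For each query peak: does it share >=1 bp with any subject peak?"""
    subj = _interval_arrays(subject)
    flags = {}
    for p in query:
        hit = False
        if p.chrom in subj:
            starts, ends = subj[p.chrom]
            # candidate subjects starting before the query ends
            i = int(np.searchsorted(starts, p.end, side="left"))
            hit = i > 0 and ends[i - 1] > p.start
        flags[p.peak_id] = hit
    return pd.Series(flags, name="overlap")


def accessibility_overlay(
    peaks: Sequence[PeakRecord], atac_0h_peaks: Sequence[PeakRecord]
) -> pd.Series:
    """Flag each peak accessible when it overlaps a called 0 h ATAC peak."""
    out = overlaps_any(peaks, atac_0h_peaks)
    out.name = "accessible_0h"
    return out


def rank_order_matrix(matrix: pd.DataFrame, reference_column: str) -> pd.DataFrame:
    """Sort rows by descending reference signal; ties by peak_id.

    This is the ordering behind ranked signal heat maps (binding strength
    in one reference sample; sequential-ChIP panels reuse the first
    immunoprecipitation's order).
    """
    if reference_column not in matrix.columns:
        raise KeyError(f"reference column {reference_column!r} not in matrix")
    key = matrix[reference_column]
    order = sorted(matrix.index, key=lambda pid: (-key[pid], pid))
    return matrix.loc[order]
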