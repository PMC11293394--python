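"""Readers and writers for the tabular formats the pipeline touches.

Peak tables are BED-like TSV: ``chrom  start  end  peak_id  score`` followed
by one RPKM column per sample. The sample labels either come from an
optional ``#``-prefixed header line in the file or are supplied by the
caller. Coordinates are 0-based half-open throughout; interval length is
always ``end - start``.

Expression tables are wide TSV with one row per gene. Metadata columns
(``gene_id  chrom  tss  strand  length_kb  response_class``) are followed by
one column per (kind, genotype, stimulus, timepoint, replicate) cell, with
headers like ``rpkm:WT:lipidA:0.5:1`` and ``count:WT:lipidA:0.5:1``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import TIMEPOINTS_H

__all__ = [
    "PeakRecord",
    "ExpressionTable",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "read_expression_table",
    "write_expression_table",
    "peaks_to_frame",
]

#: float formatting used by every writer (6 significant digits)
_FLOAT_FMT = "%.6g"


class PeakTableError(ValueError):
    """Raised for malformed peak table input, with the offending line."""


@dataclass
class PeakRecord:
    """One ChIP/ATAC peak: an interval with a score and per-sample RPKMs.

    ``score`` is the upstream peak caller's confidence value (PS), carried
    through as-is; reproducibility filtering requires PS > 19.
    """

    chrom: str
    start: int
    end: int
    peak_id: str
    score: float
    rpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PeakTableError(
                f"peak {self.peak_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.score < 0:
            raise PeakTableError(f"peak {self.peak_id}: negative score")
        for label, value in self.rpkm.items():
            if value < 0:
                raise PeakTableError(f"peak {self.peak_id}: negative RPKM for {label}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def read_peak_table(
    path: str | Path, sample_labels: Sequence[str] | None = None
) -> list[PeakRecord]:
    """Read a BED-like peak table.

    Parameters
    ----------
    path : path to a TSV file with columns chrom/start/end/peak_id/score
        plus one RPKM column per sample.
    sample_labels : labels for the RPKM columns; overridden by a
        ``#chrom\tstart\t...`` header line if the file carries one.
    """
    path = Path(path)
    records: list[PeakRecord] = []
    labels = list(sample_labels) if sample_labels is not None else None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                if len(header) > 5:
                    labels = header[5:]
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PeakTableError(
                    f"{path.name}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                peak_id = fields[3]
                score = float(fields[4]) if len(fields) > 4 else 0.0
                rpkm_values = [float(v) for v in fields[5:]]
            except ValueError as exc:
                raise PeakTableError(f"{path.name}:{lineno}: {exc}") from exc
            if labels is None:
                labels = [f"s{i + 1}" for i in range(len(rpkm_values))]
            if len(rpkm_values) != len(labels):
                raise PeakTableError(
                    f"{path.name}:{lineno}: {len(rpkm_values)} RPKM values for "
                    f"{len(labels)} sample labels"
                )
            try:
                records.append(
                    PeakRecord(chrom, start, end, peak_id, score, dict(zip(labels, rpkm_values)))
                )
            except PeakTableError as exc:
                raise PeakTableError(f"{path.name}:{lineno}: {exc}") from exc
    return records


def write_peak_table(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    """Write peaks as BED-like TSV with a ``#`` header declaring samples."""
    peaks = list(peaks)
    labels: list[str] = []
    for p in peaks:
        for label in p.rpkm:
            if label not in labels:
                labels.append(label)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tpeak_id\tscore" + "".join(f"\t{s}" for s in labels) + "\n")
        for p in peaks:
            rpkms = "".join("\t" + _FLOAT_FMT % p.rpkm.get(s, 0.0) for s in labels)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t" + _FLOAT_FMT % p.score + rpkms + "\n")


def peaks_to_frame(peaks: Iterable[PeakRecord]) -> pd.DataFrame:
    """Tabular view of a peak list (one RPKM column per sample)."""
    rows = []
    for p in peaks:
        row = {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "peak_id": p.peak_id,
            "score": p.score,
        }
        row.update(p.rpkm)
        rows.append(row)
    return pd.DataFrame(rows)


_META_COLUMNS = ["gene_id", "chrom", "tss", "strand", "length_kb", "response_class"]
_RESPONSE_CLASSES = {"primary", "secondary", "unclassified"}


class ExpressionTable:
    """Gene-level expression across genotype x stimulus x timepoint x replicate.

    Holds two aligned frames: ``meta`` (one row per gene: TSS, length,
    primary/secondary response class) and ``values`` (long format, one row
    per measured cell with both the raw read count and the RPKM).
    """

    def __init__(self, meta: pd.DataFrame, values: pd.DataFrame):
        if meta["gene_id"].duplicated().any():
            dupes = meta.loc[meta["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id(s): {dupes}")
        if (meta["length_kb"] <= 0).any():
            raise ValueError("gene length_kb must be positive")
        bad_tp = set(values["timepoint"].unique()) - set(TIMEPOINTS_H)
        if bad_tp:
            raise ValueError(f"unknown timepoint(s): {sorted(bad_tp)}; expected {TIMEPOINTS_H}")
        if (values["rpkm"] < 0).any() or (values["count"] < 0).any():
            raise ValueError("negative expression values")
        bad_rc = set(meta["response_class"].unique()) - _RESPONSE_CLASSES
        if bad_rc:
            raise ValueError(f"unknown response_class(es): {sorted(bad_rc)}")
        self.meta = meta.reset_index(drop=True)
        self.values = values.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return self.meta["gene_id"].tolist()

    def rpkm(
        self, genotype: str, stimulus: str, timepoint: float, replicate: int | None = None
    ) -> pd.Series:
        """Per-gene RPKM for one sample, or the replicate average."""
        v = self.values
        sel = (
            (v["genotype"] == genotype)
            & (v["stimulus"] == stimulus)
            & (v["timepoint"] == timepoint)
        )
        if replicate is not None:
            sel &= v["replicate"] == replicate
        return v.loc[sel].groupby("gene_id")["rpkm"].mean().reindex(self.gene_ids)

    def counts(self, genotype: str, stimulus: str, timepoint: float) -> pd.DataFrame:
        """Genes x replicates read-count matrix for one condition."""
        v = self.values
        sel = (
            (v["genotype"] == genotype)
            & (v["stimulus"] == stimulus)
            & (v["timepoint"] == timepoint)
        )
        return (
            v.loc[sel]
            .pivot_table(index="gene_id", columns="replicate", values="count")
            .reindex(self.gene_ids)
        )

    def timepoints(self) -> list[float]:
        return sorted(self.values["timepoint"].unique())


def _cell_column(kind: str, genotype: str, stimulus: str, timepoint: float, replicate: int) -> str:
    tp = f"{timepoint:g}"
    return f"{kind}:{genotype}:{stimulus}:{tp}:{replicate}"


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    wide = table.values.copy()
    wide["col_rpkm"] = [
        _cell_column("rpkm", g, s, t, r)
        for g, s, t, r in zip(wide["genotype"], wide["stimulus"], wide["timepoint"], wide["replicate"])
    ]
    rpkm = wide.pivot(index="gene_id", columns="col_rpkm", values="rpkm")
    wide["col_count"] = wide["col_rpkm"].str.replace("rpkm:", "count:", regex=False)
    counts = wide.pivot(index="gene_id", columns="col_count", values="count")
    out = table.meta.set_index("gene_id").join(rpkm).join(counts).reset_index()
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing metadata columns: {missing}")
    meta = df[_META_COLUMNS].copy()
    long_rows = []
    for col in df.columns:
        if ":" not in col:
            continue
        parts = col.split(":")
        if len(parts) != 5:
            raise ValueError(f"malformed sample column {col!r}")
        kind, genotype, stimulus, tp_str, rep_str = parts
        if kind not in ("rpkm", "count"):
            raise ValueError(f"unknown value kind in column {col!r}")
        try:
            timepoint = float(tp_str)
            replicate = int(rep_str)
        except ValueError as exc:
            raise ValueError(f"malformed sample column {col!r}: {exc}") from exc
        if timepoint not in TIMEPOINTS_H:
            raise ValueError(f"unknown timepoint {tp_str!r} in column {col!r}")
        long_rows.append((col, kind, genotype, stimulus, timepoint, replicate))
    cols = pd.DataFrame(
        long_rows, columns=["col", "kind", "genotype", "stimulus", "timepoint", "replicate"]
    )
    melted = df.melt(id_vars=["gene_id"], value_vars=cols["col"].tolist(), var_name="col")
    melted = melted.merge(cols, on="col").drop(columns="col")
    values = (
        melted.pivot_table(
            index=["gene_id", "genotype", "stimulus", "timepoint", "replicate"],
            columns="kind",
            values="value",
        )
        .reset_index()
    )
    if values[["rpkm", "count"]].isna().any().any():
        raise ValueError("missing cells in expression table (every sample needs rpkm and count)")
    values["count"] = values["count"].round().astype(int)
    values.columns.name = None
    return ExpressionTable(meta, values)
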