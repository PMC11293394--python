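"""kB motif scanning: the p50-homodimer pattern and PWM enrichment.

The p50 homodimer selects kB sites whose two half-sites each present three
G:C base pairs, separated by a 5 bp spacer. On the plus strand this is the
literal 11-mer pattern ``GGGNNNNNCCC`` (GGG, any five bases, CCC). The
pattern class is its own reverse complement, so every matching position is
reported on both strands. ``N`` in the input never matches a constrained
position.

PWM scanning scores log-odds against a uniform background; matrices are
user-supplied in JASPAR position-frequency format (the packaged test
matrices are synthetic). Per-bin enrichment of motif-containing peaks is a
one-sided hypergeometric test of one bin's windows against all others,
reported as -log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Seq import Seq
from scipy.stats import hypergeom

__all__ = [
    "MotifHit",
    "scan_homodimer",
    "HOMODIMER_LENGTH",
    "PWM",
    "pwm_scan",
    "motif_enrichment",
    "enrichment_matrix",
]

HOMODIMER_LENGTH = 11
_HALF = 3
_SPACER = 5

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    """One motif match: leftmost plus-strand offset, strand, matched 11-mer."""

    offset: int
    strand: str
    matched: str


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_homodimer(sequence: str) -> list[MotifHit]:
    """All p50-homodimer matches (GGG NNNNN CCC) in a window, both strands.

    Because the pattern class equals its own reverse complement, each
    matching position yields a hit on each strand; offsets are always
    plus-strand leftmost coordinates. Sequences shorter than 11 bp give no
    hits.
    """
    seq = sequence.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for i in range(n - HOMODIMER_LENGTH + 1):
        if seq[i : i + _HALF] == "GGG" and seq[i + _HALF + _SPACER : i + HOMODIMER_LENGTH] == "CCC":
            window = seq[i : i + HOMODIMER_LENGTH]
            hits.append(MotifHit(i, "+", window))
            hits.append(MotifHit(i, "-", _revcomp(window)))
    return hits


class PWM:
    """Log-odds position weight matrix with a call threshold.

    Built from position counts (or a JASPAR ``.pfm`` file via
    :meth:`read`); weights are log2 odds of the pseudocounted position
    frequencies against a uniform background. The default call threshold
    is 80% of the maximal attainable score.
    """

    def __init__(
        self,
        name: str,
        weights: np.ndarray,
        threshold: float | None = None,
    ):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != 4:
            raise ValueError("weights must be positions x 4 (A,C,G,T)")
        if not np.isfinite(weights).all():
            raise ValueError("weights must be finite")
        self.name = name
        self.weights = weights
        self.max_score = float(weights.max(axis=1).sum())
        self.threshold = self.max_score * 0.8 if threshold is None else float(threshold)

    def __len__(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: Mapping[str, Sequence[float]],
        pseudocount: float = 0.5,
        threshold: float | None = None,
    ) -> "PWM":
        motif = bio_motifs.Motif(
            alphabet="ACGT", counts={b: list(counts[b]) for b in "ACGT"}
        )
        motif.pseudocounts = pseudocount
        pssm = motif.pssm  # log2 odds vs uniform background
        weights = np.column_stack([pssm[b] for b in "ACGT"])
        return cls(name, weights, threshold)

    @classmethod
    def read(cls, path: str | Path, threshold: float | None = None) -> "PWM":
        """Read a position-frequency matrix in JASPAR format."""
        with open(path, encoding="utf-8") as fh:
            motif = bio_motifs.read(fh, "jaspar")
        counts = {b: list(motif.counts[b]) for b in "ACGT"}
        return cls.from_counts(motif.name or Path(path).stem, counts, threshold=threshold)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=1))


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def _strand_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    m = weights.shape[0]
    n = codes.size
    if n < m:
        return np.empty(0)
    scores = np.zeros(n - m + 1)
    valid = np.ones(n - m + 1, dtype=bool)
    for j in range(m):
        c = codes[j : j + n - m + 1]
        ok = c >= 0
        valid &= ok
        scores += np.where(ok, weights[j, np.clip(c, 0, 3)], 0.0)
    scores[~valid] = -np.inf
    return scores


def pwm_scan(sequence: str, pwm: PWM) -> tuple[float, list[MotifHit]]:
    """Best log-odds score over positions and strands, plus threshold hits.

    Positions containing ``N`` (or any non-ACGT symbol) score -inf and
    never produce hits. Returns ``(best_score, hits)``; ``best_score`` is
    -inf when no position is scoreable.
    """
    seq = sequence.upper()
    m = len(pwm)
    if m > len(seq):
        return float("-inf"), []
    plus = _strand_scores(_encode(seq), pwm.weights)
    rc = _revcomp(seq)
    minus_rc = _strand_scores(_encode(rc), pwm.weights)
    # position i on the reverse complement corresponds to plus-strand
    # leftmost offset len(seq) - m - i
    minus = minus_rc[::-1]
    best = float(max(plus.max(initial=-np.inf), minus.max(initial=-np.inf)))
    hits: list[MotifHit] = []
    for i in np.flatnonzero(plus >= pwm.threshold):
        hits.append(MotifHit(int(i), "+", seq[i : i + m]))
    for i in np.flatnonzero(minus >= pwm.threshold):
        hits.append(MotifHit(int(i), "-", _revcomp(seq[i : i + m])))
    return best, sorted(hits, key=lambda h: (h.offset, h.strand))


def motif_enrichment(
    foreground_has_motif: Sequence[bool], background_has_motif: Sequence[bool]
) -> float:
    """-log10 one-sided hypergeometric p for motif excess in the foreground.

    Foreground is one bin's windows, background every other bin's. Returns
    0-ish values (p near 1) when the rates match.
    """
    fg = np.asarray(foreground_has_motif, dtype=bool)
    bg = np.asarray(background_has_motif, dtype=bool)
    if fg.size == 0:
        raise ValueError("empty foreground")
    total = fg.size + bg.size
    positives = int(fg.sum() + bg.sum())
    p = float(hypergeom.sf(int(fg.sum()) - 1, total, positives, fg.size))
    return -np.log10(max(p, np.finfo(float).tiny))


def enrichment_matrix(
    bins: pd.Series, motif_presence: pd.DataFrame
) -> pd.DataFrame:
    """Bin x motif matrix of -log10 enrichment p-values.

    ``bins`` maps peak_id -> bin index; ``motif_presence`` is a boolean
    peaks x motifs frame. Each bin is tested as foreground against the
    union of the other bins.
    """
    presence = motif_presence.reindex(bins.index)
    out = {}
    for bin_idx in sorted(bins.unique()):
        in_bin = bins == bin_idx
        row = {}
        for motif in presence.columns:
            row[motif] = motif_enrichment(
                presence.loc[in_bin, motif].to_numpy(),
                presence.loc[~in_bin, motif].to_numpy(),
            )
        out[bin_idx] = row
    result = pd.DataFrame(out).T
    result.index.name = "bin"
    return result
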