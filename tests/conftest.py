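import numpy as np
import pandas as pd
import pytest

from nfkbdep.config import TIMEPOINTS_H
from nfkbdep.io import ExpressionTable
from nfkbdep.simulate import GeneratorParams, simulate


@pytest.fixture(scope="session")
def default_study():
    """One default-scale simulation shared by recovery-style tests."""
    return simulate(GeneratorParams(rng_seed=0))


@pytest.fixture(scope="session")
def small_study():
    return simulate(GeneratorParams(n_genes=250, n_peaks=350, rng_seed=5))


def make_expression_table(
    gene_rpkm, length_kb=1.0, lib_millions=20.0, response_class=None, jitters=(1.0, 1.02)
):
    """Build a two-replicate WT/KO expression table from mean RPKM dicts.

    ``gene_rpkm`` maps gene_id -> {genotype: [rpkm at 0, 0.5, 1, 2, 6 h]}.
    Counts are derived exactly from the RPKMs, with a deterministic
    per-replicate factor (``jitters``) so variance estimates are defined.
    """
    meta_rows, value_rows = [], []
    response_class = response_class or {}
    for gene, per_gt in gene_rpkm.items():
        meta_rows.append(
            {
                "gene_id": gene,
                "chrom": "chr1",
                "tss": 1000,
                "strand": "+",
                "length_kb": length_kb,
                "response_class": response_class.get(gene, "unclassified"),
            }
        )
        for gt, series in per_gt.items():
            for t, rpkm in zip(TIMEPOINTS_H, series):
                for rep, jitter in enumerate(jitters, start=1):
                    count = round(rpkm * length_kb * lib_millions * jitter)
                    value_rows.append(
                        {
                            "gene_id": gene,
                            "genotype": gt,
                            "stimulus": "lipidA",
                            "timepoint": t,
                            "replicate": rep,
                            "count": count,
                            "rpkm": count / (length_kb * lib_millions),
                        }
                    )
    return ExpressionTable(pd.DataFrame(meta_rows), pd.DataFrame(value_rows))


def random_peak_sets(rng, n_sets=2, n_peaks=30, chroms=("chr1", "chr2"), span=10_000):
    """Random interval fixtures for overlap-oracle comparisons."""
    from nfkbdep.io import PeakRecord

    sets = {}
    for s in range(n_sets):
        records = []
        for i in range(int(rng.integers(1, n_peaks + 1))):
            chrom = str(rng.choice(list(chroms)))
            start = int(rng.integers(0, span))
            end = start + int(rng.integers(1, 400))
            records.append(PeakRecord(chrom, start, end, f"s{s}p{i}", 1.0, {}))
        sets[f"set{s}"] = records
    return sets
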