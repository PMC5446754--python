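import numpy as np
import pandas as pd
import pytest

from pathforge import GeneAnnotation, GeneSet, GeneSetCollection, GenotypePanel, SumStats


@pytest.fixture
def toy_sumstats() -> SumStats:
    df = pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
            "chrom": ["1"] * 6,
            "pos": [1000, 2000, 3000, 101_000, 102_000, 500_000],
            "p": [1e-8, 1e-3, 0.2, 0.04, 0.5, 0.9],
        }
    )
    return SumStats(df, cohort_label="toy")


@pytest.fixture
def toy_genes() -> GeneAnnotation:
    df = pd.DataFrame(
        {
            "gene": ["GA", "GB", "GC"],
            "chrom": ["1", "1", "1"],
            "start": [500, 100_500, 480_000],
            "end": [2500, 103_000, 490_000],
        }
    )
    return GeneAnnotation(df)


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add(GeneSet("S1", "d", frozenset({"GA", "GB"})))
    coll.add(GeneSet("S2", "d", frozenset({"GC"})))
    coll.add(GeneSet("S3", "d", frozenset({"GA", "GB", "GC"})))
    return coll


def panel_from_dosages(dosages, positions=None, chrom="1") -> GenotypePanel:
    """Build a small panel from a list of per-variant dosage columns."""
    arr = np.asarray(dosages, dtype=float).T  # individuals x variants
    n_var = arr.shape[1]
    pos = np.asarray(positions if positions is not None else np.arange(1, n_var + 1) * 1000)
    return GenotypePanel(
        dosages=arr,
        snp_ids=np.array([f"v{i}" for i in range(n_var)], dtype=object),
        chrom=np.array([chrom] * n_var, dtype=object),
        pos=pos,
    )
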