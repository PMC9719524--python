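import numpy as np
import pandas as pd
import pytest

from sexlinkscan.io import (
    HET, HOM_ALT, HOM_REF, MISSING, PRESENT, ABSENT,
    PaMatrix, SampleSheet, SnpMatrix,
)
from sexlinkscan.simulate import SimConfig, simulate_dataset


def make_snp(calls, locus_ids=None, sample_ids=None, meta=None) -> SnpMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    locus_ids = locus_ids or [f"L{i}" for i in range(calls.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(calls.shape[1])]
    return SnpMatrix(locus_ids=np.array(locus_ids, dtype=object),
                     sample_ids=np.array(sample_ids, dtype=object),
                     calls=calls, meta=meta)


def make_pa(calls, locus_ids=None, sample_ids=None) -> PaMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    locus_ids = locus_ids or [f"P{i}" for i in range(calls.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(calls.shape[1])]
    return PaMatrix(locus_ids=np.array(locus_ids, dtype=object),
                    sample_ids=np.array(sample_ids, dtype=object),
                    calls=calls)


def make_sheet(sample_ids, sexes, clusters=None) -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": list(sample_ids),
        "sex": list(sexes),
        "site": "site_1",
        "cluster": pd.array(clusters if clusters is not None
                            else [pd.NA] * len(sample_ids), dtype="Int64"),
    }))


def random_snp_calls(rng, n_loci, n_samples, missing_rate=0.0):
    g = rng.integers(0, 3, size=(n_loci, n_samples)).astype(np.int8)
    g[g == 1] = HOM_ALT
    if missing_rate:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return g


@pytest.fixture(scope="session")
def zero_noise_xy():
    """Small strict-mode dataset: 5M/3F, XY, no discordance, no missing."""
    cfg = SimConfig(n_males=5, n_females=3, n_sexlinked_snp=12,
                    n_sexlinked_pa=12, n_autosomal=0, n_autosomal_pa=0,
                    system="XY", discordance=0.0, missing_rate=0.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def two_cluster_dataset():
    """Two diverged clusters, autosomal only, for structure analyses."""
    cfg = SimConfig(n_males=10, n_females=10, n_clusters=2, fst_target=0.24,
                    n_autosomal=2000, seed=11)
    return simulate_dataset(cfg)
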