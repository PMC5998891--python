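import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from lncora.annotations import GenomicFeature
from lncora.diffexp import ExpressionTable
from lncora.simulate import SimulationConfig, write_fixture


def make_feature(fid, start, end, chrom="chr1", strand="+", biotype="protein_coding"):
    return GenomicFeature(fid, chrom, start, end, strand, biotype)


@pytest.fixture
def feature_factory():
    return make_feature


def random_features(rng, n, prefix, n_chroms=3, span=100_000, biotype="protein_coding"):
    feats = []
    for i in range(n):
        start = int(rng.integers(1, span))
        length = int(rng.integers(1, 3000))
        feats.append(
            GenomicFeature(
                f"{prefix}{i}",
                f"chr{int(rng.integers(1, n_chroms + 1))}",
                start,
                start + length,
                "+" if rng.random() < 0.5 else "-",
                biotype,
            )
        )
    return feats


@pytest.fixture
def random_feature_sets():
    def make(seed, n_lnc=50, n_genes=50):
        rng = np.random.default_rng(seed)
        return (
            random_features(rng, n_lnc, "L", biotype="lncRNA"),
            random_features(rng, n_genes, "G"),
        )

    return make


def make_table(rows: dict[str, tuple]) -> ExpressionTable:
    """rows: feature_id -> (case values..., control values...), half each."""
    samples = None
    data = {}
    for fid, vals in rows.items():
        half = len(vals) // 2
        if samples is None:
            samples = [f"case_rep{i+1}" for i in range(half)] + [
                f"ctrl_rep{i+1}" for i in range(len(vals) - half)
            ]
        data[fid] = list(vals)
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    values.index.name = "feature_id"
    conditions = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionTable(values=values, conditions=conditions)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """One shared synthetic fixture directory (seed 7, defaults)."""
    outdir = tmp_path_factory.mktemp("fixture")
    config = SimulationConfig(seed=7)
    truth = write_fixture(config, outdir)
    return outdir, config, truth
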