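import numpy as np
import pandas as pd
import pytest

from atrimir.data_io import (
    CountMatrix,
    read_count_matrix,
    read_gmt,
    read_sample_table,
    read_target_db,
)
from atrimir.synthetic_data import SimulationConfig, simulate

TINY_DIR = None  # resolved via fixture


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory):
    import pathlib

    return pathlib.Path(__file__).parent / "data" / "tiny"


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dir):
    """The committed 50-miRNA x 500-gene fixture, loaded through data_io."""
    return {
        "mirna": read_count_matrix(tiny_dir / "mirna_counts.tsv", "miRNA"),
        "gene": read_count_matrix(tiny_dir / "gene_counts.tsv", "gene"),
        "samples": read_sample_table(tiny_dir / "samples.tsv"),
        "targets": read_target_db(tiny_dir / "targets.tsv"),
        "gene_sets": read_gmt(tiny_dir / "gene_sets.gmt"),
        "truth_features": pd.read_csv(tiny_dir / "truth_features.tsv", sep="\t"),
        "truth_pairs": pd.read_csv(tiny_dir / "truth_direct_pairs.tsv", sep="\t"),
    }


#: generator conditions for the planted-truth recovery suite: statistical
#: defaults (phi, effect size, coupling, 3 per group) at a reduced feature
#: count so the whole suite runs on a laptop
RECOVERY_CONFIG = SimulationConfig(
    n_mirna=300,
    n_gene=3000,
    n_aa_mirna=20,
    n_aa_gene=80,
    n_direct_pairs=30,
    seed=2026,
)


@pytest.fixture(scope="session")
def recovery_bundle():
    return simulate(RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def recovery_result(recovery_bundle):
    from atrimir.pipeline import run_full

    mirna_cm, gene_cm, samples, targetdb, truth = recovery_bundle
    return run_full(mirna_cm, gene_cm, samples, targetdb), truth


@pytest.fixture
def six_samples():
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
            "group": ["SR40"] * 3 + ["SR60"] * 3,
            "age": [40] * 3 + [60] * 3,
            "sex": ["F", "M", "M"] * 2,
        }
    )


def make_cm(counts: dict, index=None, kind="gene") -> CountMatrix:
    return CountMatrix(pd.DataFrame(counts, index=index), feature_kind=kind)


@pytest.fixture
def null_nb_counts():
    """5000 null NB features (phi = 0.1) over 3+3 samples, seed-fixed."""
    rng = np.random.default_rng(7)
    F, phi = 5000, 0.1
    mu = np.exp(rng.normal(np.log(50), 1.0, F))
    lib = rng.uniform(0.8e6, 1.2e6, 6)
    base = mu[:, None] * lib[None, :] / 1e6
    r = 1 / phi
    Y = rng.negative_binomial(r, r / (r + base))
    return CountMatrix(
        pd.DataFrame(
            Y, index=[f"g{i}" for i in range(F)],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
    )
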