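import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from dropqc.pipeline import call_cells
from dropqc.synthetic import SimulationConfig, simulate_experiment
from dropqc.tenx_io import GeneCellMatrix

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_matrix(dense, barcodes=None, names=None):
    """Build a GeneCellMatrix from a dense list-of-lists."""
    dense = np.asarray(dense)
    n_feat, n_bc = dense.shape
    names = names or [f"G{i}" for i in range(n_feat)]
    barcodes = barcodes or [f"BC{j:04d}-1" for j in range(n_bc)]
    return GeneCellMatrix(
        counts=sp.csc_matrix(dense),
        feature_names=list(names),
        feature_ids=[f"ID{i}" for i in range(n_feat)],
        barcodes=list(barcodes),
    )


@pytest.fixture(scope="session")
def strong_sim():
    """The default strong-signal three-type experiment (fixed seed)."""
    return simulate_experiment(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def strong_calls(strong_sim):
    """Curve + enrichment for the strong-signal experiment."""
    curve, result = call_cells(strong_sim.matrix, strong_sim.collection,
                               seed=7)
    return curve, result


@pytest.fixture(scope="session")
def small_runs(tmp_path_factory):
    """Three small simulated samples run end to end (for report/CLI tests)."""
    from dropqc.pipeline import run_sample
    from dropqc.reference_sets import read_gmt
    from dropqc.synthetic import write_sample_dir

    root = tmp_path_factory.mktemp("samples")
    runs = {}
    for i in range(3):
        sim = simulate_experiment(SimulationConfig(
            seed=50 + i, cells_per_type=80, n_empty_droplets=800,
            n_background_genes=200))
        d = write_sample_dir(sim, root / f"s{i + 1}", sample_id=f"s{i + 1}")
        coll = read_gmt(d / "reference_sets.gmt")
        runs[f"s{i + 1}"] = run_sample(d, coll, sample_id=f"s{i + 1}",
                                       seed=50 + i)
    return root, runs


@pytest.fixture
def gex_vdj_metadata():
    from dropqc.tenx_io import SampleMetadata
    return SampleMetadata(table=pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "library_type": ["GEX", "GEX", "VDJ"],
        "batch": ["b1", "b1", "b2"],
    }))
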