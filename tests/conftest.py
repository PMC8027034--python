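import numpy as np
import pandas as pd
import pytest

from modevol.config import PipelineConfig
from modevol.io import SampleDesign, CountTable, read_newick
from modevol.pipeline import analyze
from modevol.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def study_tree():
    return read_newick("(((lacE,lacJ),shas),shim);")


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale synthetic dataset (300 orthogroups, fixed seed)."""
    return simulate_dataset(SimConfig(n_orthogroups=300, rng_seed=7))


@pytest.fixture(scope="session")
def small_result(small_sim):
    """Full pipeline run on the desk-scale dataset."""
    return analyze(small_sim.counts, small_sim.tree, small_sim.similarity,
                   small_sim.annotations, PipelineConfig())


def make_count_table(counts: np.ndarray, strain: str = "st",
                     conditions: list[str] | None = None) -> CountTable:
    """Small helper: wrap a matrix into a CountTable with a matching design."""
    n = counts.shape[1]
    if conditions is None:
        conditions = (["spruce", "pine", "SCD"] * n)[:n]
    reps: dict[str, int] = {}
    rows = []
    for i, cond in enumerate(conditions):
        reps[cond] = reps.get(cond, 0) + 1
        rows.append({"sample_id": f"s{i}", "strain": strain,
                     "condition": cond, "replicate": reps[cond]})
    design = SampleDesign(pd.DataFrame(rows))
    frame = pd.DataFrame(counts,
                         index=[f"g{i}" for i in range(counts.shape[0])],
                         columns=[f"s{i}" for i in range(n)])
    return CountTable(frame, design)
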