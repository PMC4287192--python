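import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from durmap import simdata
from durmap.linkage import SegregationMatrix
from durmap.panel import PanelData

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def true_map():
    """3 groups x 10 markers over 150 cM."""
    return simdata.simulate_true_map(3, 150.0, 10, seed=11)


@pytest.fixture(scope="session")
def ril_seg(true_map):
    cfg = simdata.SimConfig(pop_type="RIL", n_lines=300, missing_rate=0.03,
                            error_rate=0.0, seed=5)
    return simdata.simulate_population(true_map, cfg)


@pytest.fixture(scope="session")
def clean_panel():
    """Small structured panel: 2 subpops, binary loci only, no missing."""
    tm = simdata.simulate_true_map(2, 100.0, 12, seed=3)
    cfg = simdata.PanelConfig(
        subpop_sizes=(40, 40), ne=25, generations=6, admixture=0.05,
        ssr_fraction=0.0, missing_rate=0.0, seed=21,
    )
    return tm, simdata.simulate_panel(tm, cfg)


def make_seg(calls, pop_type="DH", markers=None, lines=None):
    """Convenience constructor from a small call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    markers = markers or [f"m{i + 1}" for i in range(calls.shape[0])]
    lines = lines or [f"l{j + 1}" for j in range(calls.shape[1])]
    return SegregationMatrix(tuple(markers), tuple(lines), calls, pop_type)


def make_panel(calls, locus_types=None, subpops=None):
    calls = np.asarray(calls, dtype=np.int16)
    n, L = calls.shape
    accessions = tuple(f"a{i + 1}" for i in range(n))
    loci = tuple(f"x{j + 1}" for j in range(L))
    types = tuple(locus_types or ["SSR"] * L)
    sp = None
    if subpops is not None:
        sp = pd.Series(list(subpops), index=list(accessions), name="subpop")
    return PanelData(accessions, loci, calls, types, sp)
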