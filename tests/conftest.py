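import numpy as np
import pandas as pd
import pytest

from twinmeth import BetaMatrix, MethSimConfig, TwinDesign, simulate_twin_methylation


def make_design(n_pairs: int = 7) -> TwinDesign:
    rows, idx = [], []
    for i in range(n_pairs):
        pair = f"P{i + 1}"
        for aff in (True, False):
            idx.append(f"{pair}_{'A' if aff else 'U'}")
            rows.append({"pair_id": pair, "affected": aff})
    return TwinDesign(pd.DataFrame(rows, index=pd.Index(idx, name="sample_id")))


@pytest.fixture
def design7() -> TwinDesign:
    return make_design(7)


@pytest.fixture
def small_cohort():
    """Small spiked cohort shared by several module tests (fixed seed)."""
    cfg = MethSimConfig(
        n_probes=3000, n_dmp_singletons=30, n_regions=5, seed=1
    )
    return simulate_twin_methylation(cfg)


def make_beta_matrix(beta: np.ndarray, detp: np.ndarray | None = None,
                     probes=None, samples=None) -> BetaMatrix:
    beta = np.asarray(beta, float)
    if detp is None:
        detp = np.zeros_like(beta)
    probes = probes or [f"cg{i:07d}" for i in range(beta.shape[0])]
    samples = samples or [f"S{j}" for j in range(beta.shape[1])]
    idx = pd.Index(probes, name="probe_id")
    cols = pd.Index(samples, name="sample_id")
    return BetaMatrix(
        pd.DataFrame(beta, index=idx, columns=cols),
        pd.DataFrame(np.asarray(detp, float), index=idx, columns=cols),
    )
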