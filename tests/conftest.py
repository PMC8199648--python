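import numpy as np
import pytest

from cernet.config import RunConfig
from cernet.simulate import CohortTruth, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default planted cohort, shared across tests (seed 1)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A complete pipeline run on the default planted cohort (seed 1)."""
    from cernet.pipeline import run_all

    outdir = tmp_path_factory.mktemp("run_seed1")
    report = run_all(RunConfig(seed=1), outdir, simulate=SimulationConfig(seed=1))
    truth = CohortTruth.from_yaml(outdir / "truth.yaml")
    return outdir, report, truth


def correlated_vectors(r_xy, r_xz, r_yz, n=8):
    """Vectors (x, y, z) whose sample correlations are exactly as requested.

    Built from an orthonormal basis orthogonal to the constant vector, so
    sample means are 0 and sample correlations equal the construction
    coefficients.
    """
    rng = np.random.default_rng(12345)
    basis = []
    ones = np.ones(n) / np.sqrt(n)
    while len(basis) < 3:
        v = rng.standard_normal(n)
        for u in [ones, *basis]:
            v = v - (v @ u) * u
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    e1, e2, e3 = basis
    x = e1
    z = r_xz * e1 + np.sqrt(1 - r_xz**2) * e2
    if abs(r_xz) < 1:
        b = (r_yz - r_xy * r_xz) / np.sqrt(1 - r_xz**2)
    else:
        b = 0.0
    c2 = 1 - r_xy**2 - b**2
    assert c2 >= -1e-12, "requested correlations are not realizable"
    y = r_xy * e1 + b * e2 + np.sqrt(max(c2, 0.0)) * e3
    return x, y, z
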