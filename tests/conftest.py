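import numpy as np
import pytest

from twinsleep.biometric import VarianceComponents
from twinsleep.datatypes import ComponentSpec
from twinsleep.simulate import SimulationConfig, generate


def univariate_ae(h2: float = 0.4) -> VarianceComponents:
    return VarianceComponents("AE", A=np.array([[h2]]), CorD=None,
                              E=np.array([[1.0 - h2]]), trait_names=("x",))


def make_univariate_config(h2=0.4, n_mz=500, n_dz=500, complete_frac=1.0, seed=0,
                           ordinal=False, thresholds=(-0.5, 0.4, 1.2)):
    spec = ComponentSpec("ordinal", 4) if ordinal else ComponentSpec("continuous")
    return SimulationConfig(
        group_sizes={"MZm": (n_mz, int(n_mz * complete_frac)),
                     "DZm": (n_dz, int(n_dz * complete_frac))},
        components_true=univariate_ae(h2),
        thresholds_true={"x": tuple(thresholds)} if ordinal else {},
        specs={"x": spec}, skew_traits=(), seed=seed)


@pytest.fixture(scope="session")
def cohort_liabilities():
    """Reference-architecture cohort on the liability scale (no skew or
    thresholding), at the emulated group sizes."""
    return generate(SimulationConfig(liability_scale=True, seed=1234))


@pytest.fixture(scope="session")
def cohort_full():
    """Reference cohort with skewed continuous traits and ordinal scoring."""
    return generate(SimulationConfig(seed=4321))


def random_ae_components(rng: np.random.Generator, p: int) -> VarianceComponents:
    """Random AE components with PSD total covariance (A may be indefinite,
    mimicking the direct-symmetric parameterization)."""
    la = rng.normal(size=(p, p)) * 0.4
    le = rng.normal(size=(p, p)) * 0.5
    A = la @ la.T
    E = le @ le.T + 0.3 * np.eye(p)
    return VarianceComponents("AE", A=A, CorD=None, E=E)
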