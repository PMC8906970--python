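import numpy as np
import pytest

from wanscfd.params import MaterialRatios, PhysicalParams


@pytest.fixture
def neutral_params() -> PhysicalParams:
    """Pure base fluid (phi = 0): A=2, C=0, F=0.04, L=1.5."""
    return PhysicalParams(phi=0.0, gamma=1.0, M_mag=0.5, K_perm=1.0, Pr=25.0, Gr=0.0)


@pytest.fixture
def cnt_ratios() -> MaterialRatios:
    """Explicit CNT-like property ratios (no preset dependence)."""
    return MaterialRatios(
        rho_ratio=2.469, sigma_ratio=1.25e6, rhobeta_ratio=0.370,
        rhocp_ratio=0.292, k_c=6600.0, k_f=0.492,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
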