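import numpy as np
import pytest

from owc.ld import LDMatrix
from owc.simulate import synthetic_ld, synthetic_maf


@pytest.fixture(scope="session")
def ar1_ld() -> LDMatrix:
    """The 11-SNP AR(1) LD matrix (param 0.5) used across the study designs."""
    return synthetic_ld("ar1", 11, 0.5)


@pytest.fixture(scope="session")
def maf11() -> np.ndarray:
    """Common-variant MAFs on the post-QC range for the 11-SNP gene."""
    return synthetic_maf(11, seed=1)


@pytest.fixture()
def r_half() -> LDMatrix:
    """2-SNP LD matrix with correlation 0.5 (hand-checkable algebra)."""
    return LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))


def random_correlation(M: int, rng: np.random.Generator) -> LDMatrix:
    """A random well-conditioned correlation matrix (for property tests)."""
    X = rng.standard_normal((4 * M, M))
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return LDMatrix([f"s{i}" for i in range(M)], R)
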