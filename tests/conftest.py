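import numpy as np
import pytest

from stabval.synthetic import StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return StudyDesign(seed=7)


def normal_equations_fit(x, y):
    """Independent OLS oracle: direct 2x2 normal-equations solve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[0]), float(beta[1])


def two_pass_sd(values):
    """Independent sample-sd oracle (two-pass algorithm, ddof=1)."""
    v = [float(x) for x in values]
    m = sum(v) / len(v)
    return (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5
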