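import math

import numpy as np
import pytest


def brute_force_condensation_ratio(image: np.ndarray, cutoff: float, pad: int) -> float:
    """Direct-DFT condensation ratio (no FFT): explicit DFT matrix product."""
    img = np.asarray(image, dtype=float)
    img = img - img.mean()
    padded = np.zeros((pad, pad))
    padded[: img.shape[0], : img.shape[1]] = img
    k = np.arange(pad)
    w = np.exp(-2j * np.pi * np.outer(k, k) / pad)
    f = w @ padded @ w
    f = np.fft.fftshift(f)  # recentering only; the transform itself is direct
    power = np.abs(f) ** 2
    c = pad // 2
    yy, xx = np.ogrid[:pad, :pad]
    r = np.hypot(yy - c, xx - c)
    nondc = r > 0
    return power[nondc & (r > cutoff)].sum() / power[nondc].sum()


def fisher_p_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x: int) -> float:
        # hypergeometric pmf at x for margins (r1, c1, n)
        return (
            math.comb(c1, x)
            * math.comb(n - c1, r1 - x)
            / math.comb(n, r1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
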