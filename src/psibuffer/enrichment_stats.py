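"""Small-sample statistics for protein-set enrichment claims.

Covers the three tests used on adaptation-proteome tables: Fisher's exact
test on the overlap of two protein sets given the detected universe, the
one-proportion z-test against a background proportion (e.g. the overall
fraction of phosphosites falling in disordered regions), and
Benjamini–Hochberg adjustment for multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinSetTable",
    "ProportionTest",
    "overlap_enrichment",
    "proportion_z_test",
    "bh_adjust",
]


@dataclass
class ProteinSetTable:
    """Two protein sets within a detected universe; overlap is derived."""

    universe_size: int
    set_a: frozenset
    set_b: frozenset

    def __post_init__(self) -> None:
        self.set_a = frozenset(self.set_a)
        self.set_b = frozenset(self.set_b)
        if len(self.set_a) > self.universe_size or len(self.set_b) > self.universe_size:
            raise ValueError("sets cannot exceed the universe")

    @property
    def overlap(self) -> int:
        return len(self.set_a & self.set_b)

    def contingency(self) -> np.ndarray:
        """2x2 table [[overlap, a-only], [b-only, neither]]."""
        k = self.overlap
        a_only = len(self.set_a) - k
        b_only = len(self.set_b) - k
        neither = self.universe_size - k - a_only - b_only
        table = np.array([[k, a_only], [b_only, neither]])
        if (table < 0).any():
            raise ValueError("inconsistent table: universe smaller than the union")
        return table


@dataclass
class ProportionTest:
    successes: int
    trials: int
    reference_p: float
    z: float
    p: float


def overlap_enrichment(table: ProteinSetTable) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for the set overlap."""
    odds, p = stats.fisher_exact(table.contingency(), alternative="two-sided")
    return float(odds), float(p)


def proportion_z_test(k: int, n: int, reference_p: float) -> ProportionTest:
    """One-proportion z-test of k/n against a background proportion p0.

    z = (k/n - p0) / sqrt(p0 (1 - p0) / n), two-sided normal p, no
    continuity correction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 < reference_p < 1.0:
        raise ValueError("reference proportion must lie strictly in (0, 1)")
    phat = k / n
    z = (phat - reference_p) / np.sqrt(reference_p * (1 - reference_p) / n)
    p = 2 * stats.norm.sf(abs(z))
    return ProportionTest(successes=k, trials=n, reference_p=reference_p, z=float(z), p=float(p))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
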