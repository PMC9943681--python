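"""Concordance and colocalization statistics.

Used to validate sequencing-derived remaining fractions and P0 estimates
against orthogonal measurements (northern-blot quantification, smFISH
colocalization counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .io import ColocError


@dataclass
class PairedMeasurements:
    """Paired values of the same quantity from two methods."""

    labels: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ColocError("labels, x and y must have equal length")
        if len(self.x) < 2:
            raise ColocError("need at least 2 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ColocError("non-finite measurements")


def spearman(pm: PairedMeasurements) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; two-sided p-value.

    A constant vector leaves the rank correlation undefined and is reported
    as an error rather than NaN-propagated.
    """
    if np.all(pm.x == pm.x[0]) or np.all(pm.y == pm.y[0]):
        raise ColocError("rank correlation undefined for a constant vector")
    if len(pm.x) < 3:
        raise ColocError("p-value requires n >= 3")
    rho, p = sps.spearmanr(pm.x, pm.y)
    return float(rho), float(p)


def within_tolerance_fraction(pm: PairedMeasurements, tol: float = 0.3) -> float:
    """Fraction of pairs with |x - y| <= tol (boundary inclusive)."""
    if tol < 0:
        raise ColocError("tolerance must be >= 0")
    return float(np.mean(np.abs(pm.x - pm.y) <= tol))


def proportion_ci(successes: int, trials: int, level: float = 0.95,
                  method: str = "wilson") -> tuple[float, float, float]:
    """Binomial proportion with a 95% (by default) confidence interval.

    ``method`` is "wilson" (score interval, default) or "clopper_pearson"
    (exact).  Returns (p_hat, lo, hi), clipped to [0, 1].
    """
    if not (isinstance(successes, (int, np.integer)) and isinstance(trials, (int, np.integer))):
        raise ColocError("successes and trials must be integers")
    if trials < 1 or not 0 <= successes <= trials:
        raise ColocError(f"invalid counts: {successes}/{trials}")
    if method not in ("wilson", "clopper_pearson"):
        raise ColocError(f"unknown CI method {method!r}")
    sm_method = "wilson" if method == "wilson" else "beta"
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method=sm_method)
    p_hat = successes / trials
    return p_hat, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
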