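"""Linear solubility models and PMF minimum extraction.

The solubility model is ``sol = c1 * desc + c2 * q + c3`` where ``desc``
is one extra descriptor (dipole moment p, nSAP or SAPmax) and ``q`` the
net charge.  ``coefficient_ratio`` reports ``c2 / c1``, the single number
that fixes relative solubilities.  ``contact_minimum`` reads the bound
minimum closest to contact off a tabulated potential-of-mean-force curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegressionModel",
    "PMFCurve",
    "NoBoundMinimumError",
    "fit_lr",
    "coefficient_ratio",
    "pearson",
    "contact_minimum",
    "round_sig",
]


class NoBoundMinimumError(ValueError):
    """Raised when a PMF curve has no bound minimum near contact."""


@dataclass(frozen=True)
class RegressionModel:
    """``sol = c1 * desc + c2 * q + c3`` with fit statistics."""

    descriptor: str
    c1: float
    c2: float
    c3: float
    r2: float
    p_value: float
    n_obs: int


@dataclass(frozen=True)
class PMFCurve:
    """Tabulated free-energy curve: separation (A) vs energy (kJ/mol)."""

    separations: np.ndarray
    free_energy: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        r = np.asarray(self.separations, dtype=float)
        g = np.asarray(self.free_energy, dtype=float)
        if len(r) < 5:
            raise ValueError("PMF curve needs at least 5 points")
        if len(r) != len(g):
            raise ValueError("separation / energy length mismatch")
        if not np.all(np.diff(r) > 0):
            raise ValueError("separations must be strictly increasing")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(g))):
            raise ValueError("PMF curve contains non-finite values")
        object.__setattr__(self, "separations", r)
        object.__setattr__(self, "free_energy", g)
        if self.errors is not None:
            e = np.asarray(self.errors, dtype=float)
            if len(e) != len(r):
                raise ValueError("error bars length mismatch")
            object.__setattr__(self, "errors", e)


def fit_lr(desc: np.ndarray, q: np.ndarray, sol: np.ndarray, descriptor: str = "desc") -> RegressionModel:
    """Ordinary least squares for ``sol = c1*desc + c2*q + c3``.

    ``r2`` is the coefficient of determination and ``p_value`` the overall
    F-test of the full model against the intercept-only model with
    (2, n-3) degrees of freedom.
    """
    desc = np.asarray(desc, dtype=float)
    q = np.asarray(q, dtype=float)
    sol = np.asarray(sol, dtype=float)
    n = len(sol)
    if not (len(desc) == len(q) == n):
        raise ValueError("input vectors must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations for a 3-parameter fit")
    X = np.column_stack([desc, q, np.ones(n)])
    if np.linalg.cond(X) > 1e10:
        raise ValueError("design matrix is collinear or rank-deficient")
    coef, *_ = np.linalg.lstsq(X, sol, rcond=None)
    fitted = X @ coef
    ss_res = float(((sol - fitted) ** 2).sum())
    ss_tot = float(((sol - sol.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_model, df_resid = 2, n - 3
    if ss_res <= 0:
        p_value = np.finfo(float).tiny  # perfect fit
    else:
        f_stat = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
        p_value = float(stats.f.sf(f_stat, df_model, df_resid))
    return RegressionModel(
        descriptor=descriptor,
        c1=float(coef[0]),
        c2=float(coef[1]),
        c3=float(coef[2]),
        r2=r2,
        p_value=p_value,
        n_obs=n,
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def coefficient_ratio(m: RegressionModel) -> float:
    """``c2 / c1``: the net-charge coefficient over the descriptor one."""
    if m.c1 == 0:
        raise ValueError("descriptor coefficient c1 is zero; ratio undefined")
    return m.c2 / m.c1


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def contact_minimum(c: PMFCurve) -> tuple[float, float]:
    """Separation and depth of the local minimum closest to contact.

    Scans from the smallest separation outward for a point strictly lower
    than both neighbors; an endpoint minimum at the contact end counts.
    Raises :class:`NoBoundMinimumError` when the curve has no such
    minimum.
    """
    r, g = c.separations, c.free_energy
    if g[0] < g[1]:
        return float(r[0]), float(g[0])
    for i in range(1, len(g) - 1):
        if g[i] < g[i - 1] and g[i] < g[i + 1]:
            return float(r[i]), float(g[i])
    raise NoBoundMinimumError("no bound minimum near contact")
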