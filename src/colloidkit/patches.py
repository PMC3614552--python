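"""Local surface-patch descriptors for charge topologies.

For a surface atom *i* with charge ``q_i`` the two descriptors are

* local sum of squared charges:
  ``lssc_i = q_i^2 + sum_{j != i, r_ij < d_cut} (r0 / r_ij)^n * q_j^2``
* local sum of charges:
  ``lsc_i  = q_i   + sum_{j != i, r_ij < d_cut} (r0 / r_ij)^n * q_j``

Only surface atoms enter the sums; the central atom is interior and is
excluded.  Summary scalars: ``mlssc = min(lssc)`` (a small value marks a
large weakly-charged, hydrophobic-like patch) and
``mlsc = max(lsc) * min(lsc)`` (a large negative value marks coexisting
strong positive and negative patches).  The default reporting parameters
are ``d_cut = 5.0`` Angstrom and ``n = 0``, where the distance weighting
is inert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PatchParams",
    "PatchProfile",
    "lssc_profile",
    "lsc_profile",
    "summarize_patches",
    "descriptor_sensitivity_scan",
]


@dataclass(frozen=True)
class PatchParams:
    """Patch definition: cutoff radius, distance exponent, reference length."""

    d_cut: float = 5.0
    n: int = 0
    r0: float = 1.0

    def __post_init__(self):
        if not self.d_cut > 0:
            raise ValueError("d_cut must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not self.r0 > 0:
            raise ValueError("r0 must be positive")


@dataclass(frozen=True)
class PatchProfile:
    """Per-atom lssc/lsc values plus summary scalars for one topology."""

    params: PatchParams
    lssc: np.ndarray
    lsc: np.ndarray
    mlssc: float  # min(lssc), e^2
    mlsc: float  # max(lsc) * min(lsc), e^2
    hi_product: float  # product of the two largest lsc values, e^2
    lo_product: float  # product of the two smallest lsc values, e^2


def _weight_matrix(top, params: PatchParams) -> np.ndarray:
    """Off-diagonal weights (r0/r)^n masked by r < d_cut; diagonal zero."""
    r = squareform(pdist(top.geometry.surface_positions))
    mask = (r < params.d_cut)
    np.fill_diagonal(mask, False)
    w = np.zeros_like(r)
    if params.n == 0:
        w[mask] = 1.0
    else:
        w[mask] = (params.r0 / r[mask]) ** params.n
    return w


def lssc_profile(top, params: PatchParams = PatchParams()) -> np.ndarray:
    """Per-surface-atom local sum of squared charges (e^2)."""
    q2 = top.surface_charges**2
    return q2 + _weight_matrix(top, params) @ q2


def lsc_profile(top, params: PatchParams = PatchParams()) -> np.ndarray:
    """Per-surface-atom local sum of charges (e)."""
    q = top.surface_charges
    return q + _weight_matrix(top, params) @ q


def summarize_patches(top, params: PatchParams = PatchParams()) -> PatchProfile:
    """Compute both profiles and all summary scalars for one topology."""
    if top.geometry.n_surface < 2:
        raise ValueError("need at least 2 surface atoms")
    lssc = lssc_profile(top, params)
    lsc = lsc_profile(top, params)
    srt = np.sort(lsc)
    return PatchProfile(
        params=params,
        lssc=lssc,
        lsc=lsc,
        mlssc=float(lssc.min()),
        mlsc=float(lsc.max() * lsc.min()),
        hi_product=float(srt[-1] * srt[-2]),
        lo_product=float(srt[0] * srt[1]),
    )


def descriptor_sensitivity_scan(tops, d_values, n_values) -> dict[str, pd.DataFrame]:
    """Cross-parameter Pearson correlations of mlssc and mlsc vectors.

    For every (d_cut, n) setting the per-topology descriptor vector is
    computed; the result maps each descriptor name to a symmetric
    correlation matrix indexed by the parameter settings.  Constant
    descriptor vectors give NaN (undefined correlation), not zero.
    """
    tops = list(tops)
    if len(tops) < 3:
        raise ValueError("need at least 3 topologies for a meaningful correlation")
    settings = [(float(d), int(n)) for d in d_values for n in n_values]
    vectors = {"mlssc": {}, "mlsc": {}}
    for d, n in settings:
        params = PatchParams(d_cut=d, n=n)
        profiles = [summarize_patches(t, params) for t in tops]
        vectors["mlssc"][(d, n)] = np.array([p.mlssc for p in profiles])
        vectors["mlsc"][(d, n)] = np.array([p.mlsc for p in profiles])

    out = {}
    index = pd.MultiIndex.from_tuples(settings, names=["d_cut", "n"])
    for name, vecs in vectors.items():
        mat = np.full((len(settings), len(settings)), np.nan)
        for i, si in enumerate(settings):
            for j, sj in enumerate(settings):
                x, y = vecs[si], vecs[sj]
                if x.std() == 0 or y.std() == 0:
                    continue
                mat[i, j] = np.corrcoef(x, y)[0, 1]
        out[name] = pd.DataFrame(mat, index=index, columns=index)
    return out
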