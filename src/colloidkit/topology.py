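"""Protein-like random charge topologies on spherical shells.

A *topology* is an assignment of partial charges to the surface atoms of a
:class:`~colloidkit.shell.ShellGeometry` (plus an optional central charge).
Charges are drawn from a SASA-weighted charge distribution so that, on
average, the surface charge pattern resembles that of a small globular
protein, and are then shifted uniformly so the net charge hits an exact
target.  Selection helpers pick descriptor-diverse subsets (constant net
charge and dipole, varying patch descriptors) or dipole series (constant
net charge, varying dipole).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from colloidkit.shell import ShellGeometry

__all__ = [
    "ChargeDistribution",
    "Topology",
    "build_charge_histogram",
    "default_charge_distribution",
    "sample_topology",
    "dipole_moment",
    "set_central_charge",
    "generate_ensemble",
    "select_varied_set",
    "select_dipole_series",
]

#: validation ranges for protein-like pseudo-proteins: net charge (e) and
#: dipole moment (eA) of small globular proteins.
Q_RANGE = (-10.0, 0.0)
P_RANGE = (0.0, 70.0)


@dataclass(frozen=True)
class ChargeDistribution:
    """Histogram of per-atom partial charges (e), SASA-weighted.

    ``bin_edges`` has one more entry than ``weights``; weights are
    normalized to 1.
    """

    bin_edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if len(edges) != len(w) + 1:
            raise ValueError("bin_edges must have len(weights)+1 entries")
        if len(w) == 0:
            raise ValueError("empty charge distribution")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "weights", w / total)


@dataclass(frozen=True)
class Topology:
    """Per-atom charges on a shell geometry.

    ``q`` is the net charge (surface + central) in e; ``p`` the dipole
    moment magnitude about the central position in eA.
    """

    geometry: ShellGeometry
    surface_charges: np.ndarray
    central_charge: float = 0.0
    label: str = ""
    seed: int | None = None
    descriptors: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        charges = np.asarray(self.surface_charges, dtype=float)
        if len(charges) != self.geometry.n_surface:
            raise ValueError("one surface charge per surface atom required")
        object.__setattr__(self, "surface_charges", charges)

    @property
    def q(self) -> float:
        return float(self.surface_charges.sum() + self.central_charge)

    @property
    def p(self) -> float:
        return dipole_moment(self)


def build_charge_histogram(structures, atom_sasa, bin_width: float = 0.02) -> ChargeDistribution:
    """SASA-weighted histogram of atomic partial charges.

    Parameters
    ----------
    structures:
        Iterable of structures whose atoms carry a ``charge``.
    atom_sasa:
        Matching iterable of per-atom SASA arrays (A^2); atoms with zero
        SASA contribute nothing.
    bin_width:
        Histogram bin width in e.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    charges, weights = [], []
    for s, sas in zip(structures, atom_sasa):
        sas = np.asarray(sas, dtype=float)
        if len(sas) != len(s.atoms):
            raise ValueError("per-atom SASA length mismatch")
        for atom, a in zip(s.atoms, sas):
            if atom.charge is None:
                raise ValueError(f"atom {atom.serial} has no charge")
            charges.append(atom.charge)
            weights.append(a)
    charges = np.asarray(charges)
    weights = np.asarray(weights)
    if weights.sum() <= 0:
        raise ValueError("no solvent-exposed atoms")
    lo = np.floor(charges.min() / bin_width) * bin_width
    hi = np.ceil(charges.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    hist, _ = np.histogram(charges, bins=edges, weights=weights)
    return ChargeDistribution(bin_edges=edges, weights=hist / hist.sum())


def default_charge_distribution(bin_width: float = 0.02) -> ChargeDistribution:
    """Calibratable stand-in for the protein surface charge distribution.

    Mixture of 60% Normal(0, 0.10), 20% Normal(+0.35, 0.15) and 20%
    Normal(-0.35, 0.15), truncated to [-1, 1] e and discretized at
    ``bin_width``.  Regenerate with :func:`build_charge_histogram` when
    charged reference structures are available.
    """
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    comps = [(0.60, 0.0, 0.10), (0.20, 0.35, 0.15), (0.20, -0.35, 0.15)]
    cdf = np.zeros_like(edges)
    for w, mu, sd in comps:
        cdf += w * norm.cdf(edges, loc=mu, scale=sd)
    weights = np.diff(cdf)
    return ChargeDistribution(bin_edges=edges, weights=weights)


def sample_topology(
    geom: ShellGeometry,
    dist: ChargeDistribution,
    q_target: float,
    seed: int,
    label: str = "",
) -> Topology:
    """Draw one random topology with an exact net charge.

    Each surface charge is drawn independently from ``dist`` (uniform
    within the selected bin); a uniform shift then enforces
    ``sum(charges) == q_target`` exactly.  The central charge is zero.
    """
    if not np.isfinite(q_target):
        raise ValueError("q_target must be finite")
    rng = np.random.default_rng(seed)
    n = geom.n_surface
    bins = rng.choice(len(dist.weights), size=n, p=dist.weights)
    left = dist.bin_edges[bins]
    width = dist.bin_edges[bins + 1] - left
    raw = left + rng.random(n) * width
    raw += (q_target - raw.sum()) / n
    return Topology(
        geometry=geom,
        surface_charges=raw,
        central_charge=0.0,
        label=label or f"top-{seed}",
        seed=seed,
    )


def dipole_moment(top: Topology, origin: np.ndarray | None = None) -> float:
    """Dipole moment magnitude |sum_i q_i (r_i - origin)| in eA.

    The central charge is included; the default origin is the central
    position (geometric center of the surface atoms), where it contributes
    nothing.
    """
    if origin is None:
        origin = top.geometry.central_position
    origin = np.asarray(origin, dtype=float)
    vec = top.surface_charges @ (top.geometry.surface_positions - origin)
    vec = vec + top.central_charge * (top.geometry.central_position - origin)
    return float(np.linalg.norm(vec))


def set_central_charge(top: Topology, qc: float) -> Topology:
    """Return a copy with the central charge set to ``qc``.

    Surface charges are untouched, so the net charge shifts by
    ``qc - old_qc`` while the dipole about the central position and all
    surface-patch descriptors are unchanged.
    """
    return replace(top, central_charge=float(qc))


def generate_ensemble(
    geom: ShellGeometry,
    dist: ChargeDistribution,
    n: int,
    q_target: float,
    seed: int,
    annotate: bool = True,
) -> list[Topology]:
    """Generate ``n`` reproducible topologies from sequential sub-seeds.

    Each topology is labeled ``PP<index>`` and, when ``annotate`` is true,
    carries default-parameter patch descriptors plus an ``in_range`` flag
    marking whether (q, p) fall inside the protein-like validation ranges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from colloidkit.patches import PatchParams, summarize_patches

    out = []
    for i in range(n):
        top = sample_topology(geom, dist, q_target, seed=seed + i, label=f"PP{i:05d}")
        if annotate:
            prof = summarize_patches(top, PatchParams())
            q, p = top.q, top.p
            top.descriptors.update(
                mlssc=prof.mlssc,
                mlsc=prof.mlsc,
                q=q,
                p=p,
                in_range=(Q_RANGE[0] <= q <= Q_RANGE[1]) and (P_RANGE[0] <= p <= P_RANGE[1]),
            )
        out.append(top)
    return out


def _descriptor_matrix(cands: list[Topology]) -> np.ndarray:
    from colloidkit.patches import PatchParams, summarize_patches

    rows = []
    for t in cands:
        if "mlssc" in t.descriptors and "mlsc" in t.descriptors:
            rows.append((t.descriptors["mlssc"], t.descriptors["mlsc"]))
        else:
            prof = summarize_patches(t, PatchParams())
            rows.append((prof.mlssc, prof.mlsc))
    return np.asarray(rows)


def select_varied_set(
    cands: list[Topology],
    q_target: float,
    p_target: float,
    p_tol: float,
    k: int,
) -> list[Topology]:
    """Pick ``k`` descriptor-diverse topologies at fixed net charge and dipole.

    Eligible candidates satisfy ``q == q_target`` (within 1e-6) and
    ``|p - p_target| <= p_tol``.  Selection is greedy max-min in
    standardized (mlssc, mlsc) space, seeded with the pair of extreme-mlssc
    candidates; ties are broken by ascending label.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    eligible = [
        t for t in cands
        if abs(t.q - q_target) <= 1e-6 and abs(t.p - p_target) <= p_tol
    ]
    eligible.sort(key=lambda t: t.label)
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} of {len(cands)} candidates satisfy "
            f"q={q_target}, |p-{p_target}|<={p_tol}; need {k}"
        )
    desc = _descriptor_matrix(eligible)
    std = desc.std(axis=0)
    std[std == 0] = 1.0
    z = (desc - desc.mean(axis=0)) / std

    mlssc = desc[:, 0]
    selected = [int(np.argmin(mlssc)), int(np.argmax(mlssc))]
    if selected[0] == selected[1]:  # all identical mlssc
        selected = [0, 1]
    while len(selected) < k:
        rest = [i for i in range(len(eligible)) if i not in selected]
        dmin = np.array([min(np.linalg.norm(z[i] - z[j]) for j in selected) for i in rest])
        best = rest[int(np.argmax(dmin))]  # argmax keeps first (label order) on ties
        selected.append(best)
    return [eligible[i] for i in selected]


def select_dipole_series(
    cands: list[Topology],
    q_target: float,
    p_bins: list[tuple[float, float]],
) -> list[Topology]:
    """Pick one topology per dipole bin at fixed net charge, ordered by p.

    From each ``[lo, hi)`` bin the candidate whose dipole is closest to the
    bin midpoint is taken.  Empty bins raise an error naming them.
    """
    eligible = [t for t in cands if abs(t.q - q_target) <= 1e-6]
    chosen = []
    empty = []
    for lo, hi in p_bins:
        inside = [t for t in eligible if lo <= t.p < hi]
        if not inside:
            empty.append((lo, hi))
            continue
        mid = 0.5 * (lo + hi)
        inside.sort(key=lambda t: (abs(t.p - mid), t.label))
        chosen.append(inside[0])
    if empty:
        raise ValueError(f"no candidate with q={q_target} in dipole bins {empty}")
    chosen.sort(key=lambda t: t.p)
    return chosen
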