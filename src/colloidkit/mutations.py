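"""Single charge-flip mutation scans on protein structures.

Candidate mutations swap a charged residue for one of opposite charge
(R->D, K->D for negatively charged proteins; D->R, E->R otherwise), which
under the pH-7 formal-charge model changes the net charge by exactly +-2 e.
The mutant is modeled in place: the wildtype charge site loses its formal
charge and the mutant charge appears at the mutant residue type's site
position (same backbone, no rebuilding), so the dipole change is a pure
charge-redistribution effect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from colloidkit.structure import (
    CHARGE_SITES,
    THREE_TO_ONE,
    MolecularStructure,
    Residue,
    charge_site_position,
    net_charge,
)

__all__ = [
    "MutationEffect",
    "enumerate_charge_flips",
    "mutation_effect",
    "best_mutation",
    "summarize_effects",
]

# charge-flip partners observed in practice; HIS is neutral at pH 7 and
# is never mutated
FLIP_TO_NEGATIVE = {"ARG": "ASP", "LYS": "ASP"}
FLIP_TO_POSITIVE = {"ASP": "ARG", "GLU": "ARG"}

_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationEffect:
    """Effect of one charge-flip mutation on net charge and dipole."""

    structure_id: str
    mutation: str  # e.g. "R134D"
    q0: float  # wildtype net charge, e
    dq: float  # mutant - wildtype net charge, e
    p0: float  # wildtype dipole moment, eA
    dp: float  # mutant - wildtype dipole moment, eA
    category: str = "other"  # cytokine | antibody | other

    @property
    def residue_number(self) -> int:
        return int(_LABEL_RE.match(self.mutation).group(2))


def _mass_center(s: MolecularStructure) -> np.ndarray:
    masses = np.array([a.mass for a in s.atoms])
    return masses @ s.positions() / masses.sum()


def _dipole_with_extra(s: MolecularStructure, extra: list[tuple[np.ndarray, float]]) -> float:
    """Dipole about the (unchanged) mass center with extra point charges."""
    origin = _mass_center(s)
    vec = s.charges() @ (s.positions() - origin)
    for pos, q in extra:
        vec = vec + q * (np.asarray(pos) - origin)
    return float(np.linalg.norm(vec))


def enumerate_charge_flips(s: MolecularStructure) -> list[str]:
    """All candidate charge-flip mutation labels for a structure.

    Negatively charged proteins offer R->D and K->D; neutral or positive
    ones D->R and E->R.  Returns labels like ``"R134D"``; empty when no
    charged residue of the relevant types exists.
    """
    q0 = net_charge(s)
    table = FLIP_TO_NEGATIVE if q0 < 0 else FLIP_TO_POSITIVE
    labels = []
    for res in s.residues():
        if res.res_name in table:
            wt = THREE_TO_ONE[res.res_name]
            mut = THREE_TO_ONE[table[res.res_name]]
            labels.append(f"{wt}{res.res_num}{mut}")
    return labels


def _find_residue(s: MolecularStructure, res_num: int, wt_type: str) -> Residue:
    matches = [r for r in s.residues() if r.res_num == res_num]
    if not matches:
        raise ValueError(f"no residue numbered {res_num}")
    typed = [r for r in matches if r.res_name == wt_type]
    if not typed:
        found = ", ".join(r.res_name for r in matches)
        raise ValueError(
            f"residue {res_num} is {found}, not the stated wildtype {wt_type}"
        )
    return typed[0]


def mutation_effect(
    s: MolecularStructure,
    mutation: str,
    structure_id: str = "",
    category: str = "other",
) -> MutationEffect:
    """Compute (dq, dp) for one charge-flip mutation label like ``"R15D"``.

    The structure must already carry charges (formal or PQR).  The
    wildtype residue's formal charge site is neutralized and the opposite
    charge placed at the mutant type's site position; atom positions are
    unchanged.
    """
    m = _LABEL_RE.match(mutation)
    if m is None:
        raise ValueError(f"malformed mutation label {mutation!r}")
    wt_letter, num, mut_letter = m.group(1), int(m.group(2)), m.group(3)
    wt_type = {v: k for k, v in THREE_TO_ONE.items()}[wt_letter]
    mut_type = {v: k for k, v in THREE_TO_ONE.items()}[mut_letter]
    if wt_type not in CHARGE_SITES or mut_type not in CHARGE_SITES:
        raise ValueError(f"{mutation}: both residues must be charged types")

    res = _find_residue(s, num, wt_type)
    wt_q = CHARGE_SITES[wt_type][1]
    mut_q = CHARGE_SITES[mut_type][1]
    wt_pos = charge_site_position(s, res, wt_type)
    mut_pos = charge_site_position(s, res, mut_type)

    q0 = net_charge(s)
    p0 = _dipole_with_extra(s, [])
    # remove the wildtype formal charge, add the mutant one
    extra = [(wt_pos, -wt_q), (mut_pos, mut_q)]
    q_mut = q0 - wt_q + mut_q
    p_mut = _dipole_with_extra(s, extra)
    return MutationEffect(
        structure_id=structure_id or s.identifier,
        mutation=mutation,
        q0=q0,
        dq=q_mut - q0,
        p0=p0,
        dp=p_mut - p0,
        category=category,
    )


def best_mutation(effects: list[MutationEffect]) -> MutationEffect:
    """The mutation with the largest dipole reduction (most negative dp).

    Ties are broken by the lowest residue number.
    """
    if not effects:
        raise ValueError("empty effect list")
    return min(effects, key=lambda e: (e.dp, e.residue_number))


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def summarize_effects(table: list[MutationEffect]) -> dict:
    """Aggregate mutation effects per category.

    Per category: mean |dp| (rounded half-away-from-zero to integer eA),
    max |dp| and max |dq|; plus the overall maximum dipole reduction.
    """
    if not table:
        raise ValueError("empty mutation-effect table")
    out: dict = {"per_class": {}}
    classes = sorted({e.category for e in table})
    for cls in classes:
        sub = [e for e in table if e.category == cls]
        abs_dp = [abs(e.dp) for e in sub]
        out["per_class"][cls] = {
            "n": len(sub),
            "mean_abs_dp": _round_half_away(float(np.mean(abs_dp))),
            "max_abs_dp": max(abs_dp),
            "max_abs_dq": max(abs(e.dq) for e in sub),
        }
    out["max_reduction"] = max(abs(e.dp) for e in table)
    return out
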