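"""Published reference benchmarks used for validation.

Three small tables of literature values are shipped so that validation
checks and the acceptance report can run fully offline:

* ``PSEUDO_PROTEIN_SETS`` -- properties (net charge q in e, dipole p in
  eA, minimum local-sum-of-squared-charges, minimum local-sum-of-charges,
  association free-energy minimum in kJ/mol with bootstrap error) of the
  three published pseudo-protein benchmark sets: ``varHP`` (constant q and
  p, varying patch descriptors), ``varQ`` (varying q via the central
  charge) and ``varD`` (varying p).
* ``MUTATION_BENCHMARK`` -- single charge-flip mutation effects (wildtype
  net charge and dipole, mutation-induced changes) for 22 cytokines and 3
  IgG antibodies, identified by PDB id.
* ``SOLUBILITY_MODELS`` -- published coefficients (c1, c2, c3), r^2 and
  P-values of the linear solubility models ``sol = c1*desc + c2*q + c3``
  for two literature solubility sets (18 monomeric E. coli proteins, and
  the RNase SA wildtype plus 19 point mutants).
"""

from __future__ import annotations

import pandas as pd

from colloidkit.mutations import MutationEffect
from colloidkit.solubility import RegressionModel

__all__ = [
    "PSEUDO_PROTEIN_SETS",
    "MUTATION_BENCHMARK",
    "SOLUBILITY_MODELS",
    "pseudo_protein_frame",
    "mutation_benchmark_effects",
    "solubility_model",
]

# columns: name, q (e), p (eA), lssc_min (e^2), lsc_min (e), dg_min (kJ/mol), error
PSEUDO_PROTEIN_SETS: dict[str, list[tuple]] = {
    "varHP": [
        ("PP01", -2, 18.07, 0.59, -6.7, -37.7, 5.0),
        ("PP02", -2, 18.14, 0.56, -5.7, -36.1, 3.6),
        ("PP03", -2, 18.04, 0.37, -12.2, -34.5, 4.9),
        ("PP04", -2, 17.98, 0.58, -14.0, -28.9, 4.8),
        ("PP05", -2, 18.00, 0.66, -13.1, -34.1, 4.6),
        ("PP06", -2, 18.32, 0.45, -9.2, -36.2, 4.2),
        ("PP07", -2, 17.86, 0.59, -4.1, -31.7, 1.9),
        ("PP08", -2, 18.08, 0.67, -3.9, -29.4, 2.0),
        ("PP09", -2, 18.15, 0.61, -11.5, -17.6, 4.5),
        ("PP10", -2, 18.20, 0.31, -8.4, -30.1, 3.9),
        ("PP11", -2, 17.76, 0.54, -10.9, -30.8, 4.3),
        ("PP12", -2, 17.92, 0.58, -4.8, -28.7, 1.6),
    ],
    "varQ": [
        ("PP07", -2, 17.86, 0.59, -4.1, -31.3, 1.7),
        ("PP13", -6, 18.27, 0.59, -4.1, -7.7, 3.9),
        ("PP14", -10, 18.71, 0.59, -4.1, 16.0, 1.8),
    ],
    "varD": [
        ("PP15", -2, 0.65, 0.57, -1.9, -31.4, 1.4),
        ("PP07", -2, 17.86, 0.59, -4.1, -31.8, 1.7),
        ("PP16", -2, 35.08, 0.55, -8.9, -33.9, 1.6),
        ("PP17", -2, 55.53, 0.72, -11.5, -36.5, 4.1),
        ("PP18", -2, 65.75, 0.80, -17.1, -52.1, 5.8),
        ("PP19", -2, 71.95, 0.68, -32.6, -79.0, 10.3),
    ],
}

# columns: structure id, mutation, q0 (e), dq (e), p0 (eA), dp (eA), class
MUTATION_BENCHMARK: list[tuple] = [
    ("1AXI", "R134D", -5.0, -2.0, 94.8, -43.5, "cytokine"),
    ("1IL6", "R15D", -1.0, -2.0, 82.5, -57.0, "cytokine"),
    ("1RW5", "R16D", -3.0, -2.0, 99.0, -46.1, "cytokine"),
    ("1CNT", "R189D", -3.0, -2.0, 67.8, -48.0, "cytokine"),
    ("1BGC", "R51D", -2.0, -2.0, 45.9, -23.5, "cytokine"),
    ("1F6F", "D162R", 4.0, 2.0, 140.5, -53.5, "cytokine"),
    ("2ILK", "D44R", 1.0, 2.0, 154.4, -51.1, "cytokine"),
    ("1AU1", "E107R", 4.0, 2.0, 65.6, -22.2, "cytokine"),
    ("1BBN", "E110R", 7.0, 2.0, 64.2, -27.5, "cytokine"),
    ("1M4R", "E124R", 1.0, 2.0, 85.3, -39.8, "cytokine"),
    ("1D9C", "E13R", 8.0, 2.0, 265.9, -54.8, "cytokine"),
    ("1LKI", "E154R", 7.0, 2.0, 101.6, -50.6, "cytokine"),
    ("1HUL", "E29R", 0.0, 3.0, 72.8, -32.3, "cytokine"),
    ("1EER", "E37R", 3.0, 2.0, 87.4, -36.6, "cytokine"),
    ("1JLI", "E43R", 0.0, 2.0, 47.5, -14.9, "cytokine"),
    ("1GA3", "E58R", 3.0, 2.0, 22.4, -6.8, "cytokine"),
    ("1EVS", "E99R", 12.0, 2.0, 201.5, -56.4, "cytokine"),
    ("1B5L", "K164D", -8.0, -2.0, 126.8, -26.0, "cytokine"),
    ("2HYM", "K31D", -2.0, -2.0, 114.5, -42.4, "cytokine"),
    ("1AX8", "K5D", -3.0, -2.0, 43.7, -10.0, "cytokine"),
    ("2GMF", "K72D", -5.0, -2.0, 143.5, -28.7, "cytokine"),
    ("1IRL", "K76D", -0.0, -2.0, 101.0, -41.1, "cytokine"),
    ("1HZH", "D423R", 26.0, 2.0, 345.5, -133.1, "antibody"),
    ("1IGT", "D31R", 5.0, 1.0, 264.8, -82.3, "antibody"),
    ("1IGY", "D352R", 4.0, 0.0, 763.2, -128.1, "antibody"),
]

# published linear solubility models: set -> descriptor -> (c1, c2, c3, r2, P)
SOLUBILITY_MODELS: dict[str, dict[str, tuple]] = {
    "setA": {
        "p": (-0.329, 4.339, 91.09, 0.63, 5.82e-04),
        "nsap": (992.9, 2.396, 31.30, 0.33, 4.91e-02),
        "sapmax": (7.819, 1.714, 37.35, 0.31, 6.37e-02),
    },
    "setB": {
        "p": (-2.671, 57.43, 226.3, 0.62, 2.58e-04),
        "nsap": (-1317.5, 14.29, 51.68, 0.41, 1.16e-02),
        "sapmax": (-8.403, 18.02, 33.51, 0.29, 5.13e-02),
    },
}


def pseudo_protein_frame(set_name: str) -> pd.DataFrame:
    """One benchmark pseudo-protein set as a DataFrame."""
    rows = PSEUDO_PROTEIN_SETS[set_name]
    return pd.DataFrame(
        rows, columns=["name", "q", "p", "lssc_min", "lsc_min", "dg_min", "error"]
    )


def mutation_benchmark_effects() -> list[MutationEffect]:
    """The mutation benchmark as :class:`MutationEffect` records."""
    return [
        MutationEffect(structure_id=pid, mutation=mut, q0=q0, dq=dq, p0=p0, dp=dp,
                       category=cls)
        for pid, mut, q0, dq, p0, dp, cls in MUTATION_BENCHMARK
    ]


def solubility_model(set_name: str, descriptor: str) -> RegressionModel:
    """A published solubility model as a :class:`RegressionModel`.

    ``n_obs`` is the published sample size (18 for setA, 20 for setB).
    """
    c1, c2, c3, r2, p = SOLUBILITY_MODELS[set_name][descriptor]
    n_obs = {"setA": 18, "setB": 20}[set_name]
    return RegressionModel(descriptor=descriptor, c1=c1, c2=c2, c3=c3,
                           r2=r2, p_value=p, n_obs=n_obs)
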