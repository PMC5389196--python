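"""Synthetic descriptor table and adsorption energies for the congener set.

The original study computed 26 semi-empirical (PM6) molecular descriptors
per congener and DFT (M06-2X) adsorption energies on C60 for a 32-congener
subset.  Quantum chemistry is out of scope here; this module emulates the
*statistical structure* of those data so the downstream workflow
(Kennard-Stone selection, GA-PLS, validation, applicability domain) can be
exercised and its parameter-recovery behaviour verified.

The four informative descriptors mirror the ones the published model uses:

``nH``
    number of hydrogen atoms (8 minus the halogen count);
``TE``
    total molecular energy, emulated as an atom-additive sum (a.u.-like
    arbitrary scale), so it carries the Br/Cl composition signal;
``Dx``, ``Dy``
    in-plane dipole components from idealized bond-dipole vector addition,
    x being the long axis through the ring oxygens and y the short in-plane
    axis.  Bond dipoles follow the electronegativity ordering mu_Cl > mu_Br.

Twenty-two further nuisance descriptors (``d05``..``d26``) are seeded
Gaussian noise with optional correlation to the informative block.  The
ground-truth adsorption energy is linear in (nH, TE, Dx, Dy) plus Gaussian
noise, in kcal/mol, with the convention that more negative means more
favourable adsorption.  Default coefficients span roughly -22 to +1
kcal/mol over the 1,701 congeners, with hydrogen-rich congeners lowest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .congeners import (
    POSITIONS,
    CongenerState,
    congener_name,
    validate_state,
)

#: Column names of the four informative descriptors, in model order.
INFORMATIVE_DESCRIPTORS: tuple[str, ...] = ("nH", "TE", "Dx", "Dy")

#: Column names of the 22 nuisance descriptors.
NUISANCE_DESCRIPTORS: tuple[str, ...] = tuple(f"d{i:02d}" for i in range(5, 27))

#: All 26 descriptor columns.
ALL_DESCRIPTORS: tuple[str, ...] = INFORMATIVE_DESCRIPTORS + NUISANCE_DESCRIPTORS

_SQ3_2 = math.sqrt(3.0) / 2.0

# Idealized in-plane C-X bond directions (unit vectors), hexagonal geometry:
# 1,4,6,9 point along +-y, lateral 2,3,7,8 predominantly along +-x.  The set
# is equivariant under the skeleton symmetry group (mirror across x negates
# y-components and permutes 1<->4 etc.).
DEFAULT_POSITION_UNIT_VECTORS: dict[int, tuple[float, float]] = {
    1: (0.0, 1.0),
    2: (_SQ3_2, 0.5),
    3: (_SQ3_2, -0.5),
    4: (0.0, -1.0),
    6: (0.0, -1.0),
    7: (-_SQ3_2, -0.5),
    8: (-_SQ3_2, 0.5),
    9: (0.0, 1.0),
}


@dataclass
class GeneratorParams:
    """Parameters of the synthetic descriptor/energy generator.

    ``true_coefficients`` is the 5-vector (intercept, nH, TE, Dx, Dy) of the
    linear ground truth for E_ads in kcal/mol; ``noise_sd`` is the standard
    deviation of the additive Gaussian noise in kcal/mol.
    """

    atom_energy_contributions: dict[str, float] = field(
        default_factory=lambda: {
            "C": -38.06,
            "O": -75.00,
            "H": -0.58,
            "Cl": -460.15,
            "Br": -2573.50,
        }
    )
    bond_dipole_magnitudes: dict[str, float] = field(
        default_factory=lambda: {"Cl": 1.6, "Br": 1.3}
    )
    position_unit_vectors: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_UNIT_VECTORS)
    )
    true_coefficients: tuple[float, ...] = (2.2, -3.0, 4.0e-4, 0.6, -0.4)
    noise_sd: float = 0.3
    nuisance_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        mu = self.bond_dipole_magnitudes
        if not mu["Cl"] > mu["Br"]:
            raise ValueError(
                "bond dipole of Cl must exceed that of Br "
                "(electronegativity Cl 3.16 > Br 2.96)"
            )
        if len(self.true_coefficients) != 5:
            raise ValueError("true_coefficients must be (intercept, nH, TE, Dx, Dy)")
        if not 0.0 <= abs(self.nuisance_correlation) < 1.0:
            raise ValueError("nuisance_correlation must lie in (-1, 1)")


def count_hydrogens(state: Sequence[str]) -> int:
    """Number of ring hydrogens: 8 minus the number of halogens."""
    state = validate_state(state)
    return sum(1 for s in state if s == "H")


def total_energy(state: Sequence[str], params: GeneratorParams | None = None) -> float:
    """Atom-additive total energy of the congener (arbitrary a.u.-like scale).

    12 skeleton carbons + 2 oxygens + per-substituent increments; depends
    only on composition, hence invariant within a symmetry orbit.
    """
    state = validate_state(state)
    params = params or GeneratorParams()
    a = params.atom_energy_contributions
    # summed per composition count so that orbit members agree exactly
    return (
        12.0 * a["C"]
        + 2.0 * a["O"]
        + state.count("H") * a["H"]
        + state.count("Cl") * a["Cl"]
        + state.count("Br") * a["Br"]
    )


def dipole_components(
    state: Sequence[str], params: GeneratorParams | None = None
) -> tuple[float, float]:
    """In-plane dipole (Dx, Dy) by bond-dipole vector addition.

    Halogen dipoles are measured relative to C-H, so hydrogens contribute
    zero; fully symmetric patterns (parent, 2,3,7,8-tetrahalo with one
    halogen type, octa-substituted with one type) give (0, 0).
    """
    state = validate_state(state)
    params = params or GeneratorParams()
    dx = dy = 0.0
    for pos, s in zip(POSITIONS, state):
        if s == "H":
            continue
        mu = params.bond_dipole_magnitudes[s]
        ux, uy = params.position_unit_vectors[pos]
        dx += mu * ux
        dy += mu * uy
    return dx, dy


def _informative_block(
    congeners: Sequence[CongenerState], params: GeneratorParams
) -> np.ndarray:
    rows = np.empty((len(congeners), 4))
    for i, state in enumerate(congeners):
        dx, dy = dipole_components(state, params)
        rows[i] = (count_hydrogens(state), total_energy(state, params), dx, dy)
    return rows


def generate_descriptor_table(
    congeners: Sequence[CongenerState],
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One 26-descriptor row per congener; reproducible for a fixed seed.

    Nuisance columns are standard-normal draws; with
    ``params.nuisance_correlation = rho != 0`` each nuisance column j is
    correlated (population rho) with the standardized informative column
    ``j mod 4``.
    """
    if len(congeners) == 0:
        raise ValueError("congener list must be nonempty")
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    info = _informative_block(congeners, params)
    n = len(congeners)
    noise = rng.standard_normal((n, len(NUISANCE_DESCRIPTORS)))
    rho = params.nuisance_correlation
    if rho != 0.0:
        sd = info.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        z = (info - info.mean(axis=0)) / sd
        for j in range(noise.shape[1]):
            noise[:, j] = rho * z[:, j % 4] + math.sqrt(1.0 - rho**2) * noise[:, j]
    table = pd.DataFrame(info, columns=list(INFORMATIVE_DESCRIPTORS))
    table[list(NUISANCE_DESCRIPTORS)] = noise
    table.insert(0, "name", [congener_name(s) for s in congeners])
    table.insert(0, "index", np.arange(n))
    return table


@dataclass(frozen=True)
class AdsorptionRecord:
    """Adsorption energy of one congener on C60, in kcal/mol.

    ``provenance`` is ``"ground_truth"`` for generator output (standing in
    for DFT-calculated values) or ``"predicted"`` for model output.  More
    negative means more favourable adsorption.
    """

    congener_index: int
    E_ads: float
    provenance: str


def true_adsorption_energy(
    nH: float, TE: float, Dx: float, Dy: float, params: GeneratorParams
) -> float:
    c0, c1, c2, c3, c4 = params.true_coefficients
    return c0 + c1 * nH + c2 * TE + c3 * Dx + c4 * Dy


def generate_adsorption_energies(
    table: pd.DataFrame,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> list[AdsorptionRecord]:
    """Ground-truth E_ads: linear in (nH, TE, Dx, Dy) plus N(0, noise_sd^2)."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    c0, c1, c2, c3, c4 = params.true_coefficients
    mean = (
        c0
        + c1 * table["nH"].to_numpy()
        + c2 * table["TE"].to_numpy()
        + c3 * table["Dx"].to_numpy()
        + c4 * table["Dy"].to_numpy()
    )
    eps = rng.normal(0.0, params.noise_sd, size=len(table)) if params.noise_sd > 0 else 0.0
    values = mean + eps
    return [
        AdsorptionRecord(int(i), float(v), "ground_truth")
        for i, v in zip(table["index"], values)
    ]


def attach_energies(table: pd.DataFrame, records: Sequence[AdsorptionRecord]) -> pd.DataFrame:
    """Return a copy of *table* with an ``E_ads`` column joined by index."""
    by_index = {r.congener_index: r.E_ads for r in records}
    out = table.copy()
    out["E_ads"] = [by_index[int(i)] for i in out["index"]]
    return out


#: Header contract of the descriptor-table CSV (user-supplied or synthetic).
TABLE_COLUMNS: tuple[str, ...] = ("index", "name") + ALL_DESCRIPTORS + ("E_ads",)


def write_descriptor_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_descriptor_table(path) -> pd.DataFrame:
    """Load a descriptor/energy CSV honouring the declared header contract.

    This is the entry point for user-supplied real descriptor tables (e.g.
    semi-empirical descriptors with DFT energies); the pipeline treats such
    a table exactly like a synthetic one.
    """
    table = pd.read_csv(path)
    missing = [c for c in ("index", "name") + INFORMATIVE_DESCRIPTORS if c not in table.columns]
    if missing:
        raise ValueError(f"descriptor table missing required columns: {missing}")
    return table
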