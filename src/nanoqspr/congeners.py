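"""Symmetry-aware enumeration of halogenated dibenzo-p-dioxin congeners.

Dibenzo-p-dioxin has eight substitutable ring positions, labelled 1,2,3,4 on
one benzene ring and 6,7,8,9 on the other (5 and 10 are the bridging
oxygens).  A congener is an assignment of H, Cl or Br to each position.  The
planar skeleton has a four-element symmetry group (identity, two in-plane
mirrors, and the two-fold rotation that swaps the rings), so substitution
patterns related by a symmetry operation are the same molecule.  Enumerating
one representative per symmetry orbit of {H,Cl,Br}^8 yields 1,701 distinct
congeners, which Burnside's lemma confirms: (3^8 + 3*3^4)/4 = 1701.

Positions 2,3,7,8 ("lateral") form one orbit of the group and 1,4,6,9 form
the other; lateral halogenation is the structural motif associated with
AhR-mediated dioxin toxicity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

#: IUPAC ring positions carrying substituents, in the fixed storage order.
POSITIONS: tuple[int, ...] = (1, 2, 3, 4, 6, 7, 8, 9)

#: Allowed substituent states, in canonical sort order (H < Cl < Br).
STATES: tuple[str, ...] = ("H", "Cl", "Br")

LATERAL_POSITIONS: tuple[int, ...] = (2, 3, 7, 8)
AXIAL_POSITIONS: tuple[int, ...] = (1, 4, 6, 9)

_STATE_RANK = {"H": 0, "Cl": 1, "Br": 2}
_POS_INDEX = {p: i for i, p in enumerate(POSITIONS)}

CongenerState = tuple[str, str, str, str, str, str, str, str]


@dataclass(frozen=True)
class SymmetryGroup:
    """The order-4 point-group action on the eight position labels.

    ``permutations`` maps each element to a dict ``{position: image}``;
    ``index_maps`` holds the same elements as index permutations acting on
    state tuples stored in ``POSITIONS`` order: applying element ``m`` to a
    state ``s`` gives ``tuple(s[j] for j in m)``.
    """

    permutations: tuple[dict[int, int], ...]
    index_maps: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.index_maps)

    def apply(self, state: Sequence[str], element: int) -> CongenerState:
        m = self.index_maps[element]
        return tuple(state[j] for j in m)  # type: ignore[return-value]

    def orbit(self, state: Sequence[str]) -> set[CongenerState]:
        validate_state(state)
        return {self.apply(state, k) for k in range(len(self))}


def _perm_to_index_map(perm: dict[int, int]) -> tuple[int, ...]:
    # involutions: the image of position p in the new tuple is read from
    # slot perm[p] of the old tuple
    return tuple(_POS_INDEX[perm[p]] for p in POSITIONS)


def dioxin_symmetry_group() -> SymmetryGroup:
    """Return the order-4 symmetry group of the dibenzo-p-dioxin skeleton.

    The elements are the identity, the mirror across the long (x) axis
    (1 4)(2 3)(6 9)(7 8), the mirror across the short (y) axis
    (1 9)(2 8)(3 7)(4 6), and their composition, the ring-swapping two-fold
    rotation (1 6)(2 7)(3 8)(4 9).  All non-identity elements are
    involutions with no fixed positions.
    """
    identity = {p: p for p in POSITIONS}
    mirror_x = {1: 4, 4: 1, 2: 3, 3: 2, 6: 9, 9: 6, 7: 8, 8: 7}
    mirror_y = {1: 9, 9: 1, 2: 8, 8: 2, 3: 7, 7: 3, 4: 6, 6: 4}
    rotation = {1: 6, 6: 1, 2: 7, 7: 2, 3: 8, 8: 3, 4: 9, 9: 4}
    perms = (identity, mirror_x, mirror_y, rotation)
    return SymmetryGroup(
        permutations=perms,
        index_maps=tuple(_perm_to_index_map(p) for p in perms),
    )


def validate_state(state: Sequence[str]) -> CongenerState:
    """Check that *state* is a valid 8-tuple over {H, Cl, Br} and return it."""
    if len(state) != 8:
        raise ValueError(f"congener state must have 8 entries, got {len(state)}")
    for s in state:
        if s not in _STATE_RANK:
            raise ValueError(f"invalid substituent {s!r}; allowed: H, Cl, Br")
    return tuple(state)  # type: ignore[return-value]


def _rank_key(state: Sequence[str]) -> tuple[int, ...]:
    return tuple(_STATE_RANK[s] for s in state)


def canonicalize(state: Sequence[str], group: SymmetryGroup | None = None) -> CongenerState:
    """Return the lexicographically smallest symmetry image of *state*.

    The ordering is H < Cl < Br position-wise, so the canonical
    representative of an orbit is unique and ``canonicalize`` is idempotent.
    """
    state = validate_state(state)
    if group is None:
        group = dioxin_symmetry_group()
    return min(group.orbit(state), key=_rank_key)


def enumerate_congeners(
    group: SymmetryGroup | None = None,
    alphabet: Sequence[str] = STATES,
) -> list[CongenerState]:
    """Enumerate one canonical representative per symmetry orbit.

    With the full {H, Cl, Br} alphabet this yields the 1,701 distinct
    brominated/chlorinated/mixed congeners (parent included); restricting
    the alphabet to {H, Cl} yields the 76 chlorinated congeners.  Output is
    sorted lexicographically, giving stable, reproducible congener indices.
    """
    if group is None:
        group = dioxin_symmetry_group()
    for s in alphabet:
        if s not in _STATE_RANK:
            raise ValueError(f"invalid alphabet entry {s!r}")
    seen: set[CongenerState] = set()
    for state in product(alphabet, repeat=8):
        seen.add(canonicalize(state, group))
    return sorted(seen, key=_rank_key)


def burnside_count(n_states: int) -> int:
    """Orbit count of an n-letter alphabet on the 8 positions by Burnside.

    Each of the three non-identity elements is a product of four 2-cycles
    and so fixes exactly n^4 patterns; the identity fixes n^8.
    """
    return (n_states**8 + 3 * n_states**4) // 4


_MULTIPLIER = {1: "", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa", 7: "hepta", 8: "octa"}


def _locant_key(state: Sequence[str]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    all_loc = tuple(p for p, s in zip(POSITIONS, state) if s != "H")
    bromo_loc = tuple(p for p, s in zip(POSITIONS, state) if s == "Br")
    return all_loc, bromo_loc


def congener_name(state: Sequence[str]) -> str:
    """IUPAC-style name of a congener; constant on symmetry orbits.

    The orbit representative with the lowest locant set names the molecule
    (so the canonical tuple, which prefers high positions, may not be the
    one named: 2,3,7,8,9-penta maps to the familiar 1,2,3,7,8 numbering).
    Locants are listed ascending per halogen, substituent prefixes in
    alphabetical order (bromo before chloro); the parent is plain
    ``dibenzo-p-dioxin``.
    """
    state = validate_state(state)
    group = dioxin_symmetry_group()
    named = min(group.orbit(state), key=_locant_key)
    locants = {"Br": [], "Cl": []}
    for pos, s in zip(POSITIONS, named):
        if s != "H":
            locants[s].append(pos)
    parts = []
    for halogen, stem in (("Br", "bromo"), ("Cl", "chloro")):
        locs = locants[halogen]
        if locs:
            prefix = _MULTIPLIER[len(locs)]
            parts.append(f"{','.join(map(str, locs))}-{prefix}{stem}")
    if not parts:
        return "dibenzo-p-dioxin"
    return "-".join(parts) + "dibenzo-p-dioxin"


def is_laterally_substituted(state: Sequence[str]) -> bool:
    """True iff all four lateral positions (2,3,7,8) carry a halogen."""
    state = validate_state(state)
    return all(state[_POS_INDEX[p]] != "H" for p in LATERAL_POSITIONS)


def is_axially_substituted_only(state: Sequence[str]) -> bool:
    """True iff halogens occur only at 1,4,6,9 and at least one is present."""
    state = validate_state(state)
    lateral_free = all(state[_POS_INDEX[p]] == "H" for p in LATERAL_POSITIONS)
    any_axial = any(state[_POS_INDEX[p]] != "H" for p in AXIAL_POSITIONS)
    return lateral_free and any_axial


# The ring template walks O10, C10a, C1..C4, C4a, O5, C5a, C6..C9, C9a; the
# eight substituted carbons appear in storage order 1,2,3,4,6,7,8,9.
_SMILES_TEMPLATE = "O1c2c{0}c{1}c{2}c{3}c2Oc2c{4}c{5}c{6}c{7}c21"


def to_smiles(state: Sequence[str]) -> str:
    """SMILES of the congener from a fixed dibenzo-p-dioxin template."""
    state = validate_state(state)
    subs = ["" if s == "H" else f"({s})" for s in state]
    return _SMILES_TEMPLATE.format(*subs)


def halogen_counts(state: Sequence[str]) -> dict[str, int]:
    state = validate_state(state)
    return {s: state.count(s) for s in STATES}


def congener_table_rows(congeners: Iterable[CongenerState]) -> list[dict]:
    """Rows of the congener table (one dict per congener, pipeline order)."""
    rows = []
    for i, state in enumerate(congeners):
        counts = halogen_counts(state)
        rows.append(
            {
                "index": i,
                "canonical_tuple": ",".join(state),
                "name": congener_name(state),
                "smiles": to_smiles(state),
                "n_Br": counts["Br"],
                "n_Cl": counts["Cl"],
                "n_H": counts["H"],
                "lateral_flag": is_laterally_substituted(state),
            }
        )
    return rows


def write_congener_table(congeners: Iterable[CongenerState], path) -> None:
    """Write the congener table as RFC-4180 CSV with a header row."""
    rows = congener_table_rows(congeners)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def parse_canonical_tuple(text: str) -> CongenerState:
    """Inverse of the ``canonical_tuple`` CSV serialization."""
    return validate_state(tuple(text.split(",")))
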