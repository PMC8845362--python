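"""Core domain model for apo/holo structure comparison.

The analysis operates on pairs of crystal structures of the same protein,
one ligand-free (apo) and one ligand-bound (holo), or two structures in the
same state.  These classes hold only what the downstream geometry needs:
heavy-atom coordinates grouped into residues and ligands, plus the metadata
(resolution, bound ligands) that drives filtering and pair categorisation.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: The 20 standard amino acids, in conventional alphabetical one-letter order.
AA_ORDER = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
STANDARD_AA = frozenset(AA_ORDER)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Water residue names are always treated as crystallographic additives.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Pairing categories.
APO_APO = "apo_apo"
APO_HOLO = "apo_holo"
HOLO_HOLO_DIFF = "holo_holo_diff"
HOLO_HOLO_SAME = "holo_holo_same"
CATEGORIES = (APO_APO, APO_HOLO, HOLO_HOLO_DIFF, HOLO_HOLO_SAME)

_HYDROGENS = frozenset({"H", "D"})


@dataclass
class Atom:
    """A single heavy atom with orthogonal coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGENS


@dataclass
class Residue:
    """One polymer residue: chain id, author numbering and its heavy atoms."""

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_name} {self.seq_id}: no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the residue inside one structure (chain, number, icode)."""
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_id}{self.icode}"

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.get_atom("CA")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float).reshape(-1, 3)


@dataclass
class Ligand:
    """A bound small molecule (heavy atoms only, additives already removed)."""

    comp_id: str
    chain_id: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"ligand {self.comp_id}: needs at least one heavy atom")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.comp_id, self.chain_id, self.seq_id)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass
class Structure:
    """A single-model crystal structure after filtering.

    ``state`` is derived, never stored: a structure is holo exactly when it
    retains at least one non-additive ligand.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Ligand] = field(default_factory=list)
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"structure {self.id}: resolution must be positive")

    @property
    def state(self) -> str:
        return "holo" if self.ligands else "apo"

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain; 'X' marks non-standard residues."""
        return "".join(THREE_TO_ONE.get(r.res_name, "X") for r in self.chains[chain_id])

    def heavy_coords(self) -> np.ndarray:
        """Protein heavy-atom coordinates (ligands excluded), shape (n, 3)."""
        pts = [a.coords for r in self.residues() for a in r.heavy_atoms()]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def heavy_elements(self) -> list[str]:
        return [a.element for r in self.residues() for a in r.heavy_atoms()]

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)


@dataclass
class StructurePair:
    """Two structures of the same protein plus their residue correspondence.

    ``residue_map`` lists matched residues (first, second); residues absent
    from either member are excluded from every downstream RMSD.
    """

    first: Structure
    second: Structure
    category: str
    residue_map: list[tuple[Residue, Residue]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown pair category {self.category!r}")
        if self.category == APO_HOLO:
            states = {self.first.state, self.second.state}
            if states != {"apo", "holo"}:
                raise ValueError("apo_holo pair must contain exactly one holo member")
        firsts = [ra.key for ra, _ in self.residue_map]
        seconds = [rb.key for _, rb in self.residue_map]
        if len(set(firsts)) != len(firsts) or len(set(seconds)) != len(seconds):
            raise ValueError("residue_map must be one-to-one")

    @property
    def pair_id(self) -> str:
        return f"{self.first.id}|{self.second.id}"

    def swapped(self) -> "StructurePair":
        return StructurePair(
            first=self.second,
            second=self.first,
            category=self.category,
            residue_map=[(rb, ra) for ra, rb in self.residue_map],
        )
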