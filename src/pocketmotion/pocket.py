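"""Pocket residues and grid-based pocket volume.

Two notions of "pocket" are used.  For residue statistics a pocket residue is
any residue whose minimum heavy-atom distance to a ligand heavy atom is
strictly below a cutoff (5.0 Å for motion analysis, 2.0–6.0 Å scanned for
composition).  For motion classification the pocket is modelled geometrically:
a cubic grid is laid over a spherical site around the ligand, grid cells
blocked by protein atoms (probe-inflated van der Waals spheres) are removed,
cells that communicate with bulk solvent are removed, and the remaining cavity
cells — partitioned into face-connected components ("sub-pockets") — give the
pocket volume and topology.

Solvent exclusion uses the convex hull of the site's protein atoms: any empty
cell outside the hull is bulk solvent, and every empty cell connected to one
through face-adjacent empty cells drains away with it.  What survives is
enclosed volume, which is deterministic and order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structures import Ligand, Structure

#: Van der Waals radii (Å) by element; unknown elements fall back to carbon.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

DEFAULT_SPACING = 0.8
DEFAULT_PROBE = 1.4
DEFAULT_SITE_RADIUS = 8.0

#: 6-connectivity structuring element (face adjacency only).
_CONN6 = ndimage.generate_binary_structure(3, 1)


class FrameError(ValueError):
    """Two pocket models were built on different grid frames."""


@dataclass
class PocketResidueSet:
    """Residues lining a ligand at a distance cutoff."""

    ligand_ref: tuple[str, str, int]
    cutoff: float
    residues: set[tuple[str, int, str]] = field(default_factory=set)
    min_distances: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def __contains__(self, key) -> bool:
        return key in self.residues

    def __len__(self) -> int:
        return len(self.residues)


def pocket_residues(
    s: Structure,
    lig: Ligand,
    cutoff: float = 5.0,
    ligand_coords: Optional[np.ndarray] = None,
) -> PocketResidueSet:
    """Residues of ``s`` with minimum heavy-atom distance to the ligand < ``cutoff``.

    ``ligand_coords`` overrides the ligand's own coordinates — used when the
    ligand belongs to the holo partner and has been transformed into this
    structure's frame through the pair superposition.
    """
    coords = np.asarray(ligand_coords if ligand_coords is not None else lig.coords(), float)
    if coords.size == 0:
        raise ValueError(f"ligand {lig.comp_id}: no heavy atoms")
    tree = cKDTree(coords)
    out = PocketResidueSet(ligand_ref=lig.key, cutoff=cutoff)
    if cutoff <= 0:
        return out
    for res in s.residues():
        d, _ = tree.query(res.heavy_coords())
        dmin = float(np.min(d))
        if dmin < cutoff:
            out.residues.add(res.key)
            out.min_distances[res.key] = dmin
    return out


@dataclass
class PocketModel:
    """Grid cavity model of one ligand site.

    ``cells`` are integer grid indices of cavity cells; ``sub_pockets``
    partitions them into maximal 6-connected components, largest first.
    """

    grid_spacing: float
    origin: np.ndarray
    shape: tuple[int, int, int]
    cells: frozenset[tuple[int, int, int]]
    sub_pockets: list[frozenset[tuple[int, int, int]]]

    @property
    def volume(self) -> float:
        return len(self.cells) * self.grid_spacing**3

    @property
    def sub_volumes(self) -> list[float]:
        return [len(sp) * self.grid_spacing**3 for sp in self.sub_pockets]

    @property
    def n_sub_pockets(self) -> int:
        return len(self.sub_pockets)

    def same_frame(self, other: "PocketModel", tol: float = 1e-9) -> bool:
        return (
            abs(self.grid_spacing - other.grid_spacing) < tol
            and np.allclose(self.origin, other.origin, atol=tol)
            and self.shape == other.shape
        )

    def cell_centers(self, cells=None) -> np.ndarray:
        idx = np.array(sorted(cells if cells is not None else self.cells), float).reshape(-1, 3)
        return self.origin + (idx + 0.5) * self.grid_spacing

    def volumes_json(self) -> str:
        return json.dumps(
            {"total": self.volume, "per_sub_pocket": self.sub_volumes}, indent=2
        )

    def write_cells_pdb(self, path: str | Path) -> None:
        """Dump cavity cells as dummy HETATM pseudo-atoms for visualisation."""
        lines = []
        serial = 1
        for comp, cells in enumerate(self.sub_pockets, start=1):
            for x, y, z in self.cell_centers(cells):
                lines.append(
                    f"HETATM{serial:5d}  DU  POC A{comp:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          DU"
                )
                serial += 1
        Path(path).write_text("\n".join(lines) + ("\nEND\n" if lines else "END\n"))


def build_pocket_model(
    s: Structure,
    site_center: np.ndarray,
    site_radius: float = DEFAULT_SITE_RADIUS,
    spacing: float = DEFAULT_SPACING,
    probe: float = DEFAULT_PROBE,
) -> PocketModel:
    """Grid cavity model of the sphere of ``site_radius`` around ``site_center``.

    Only protein heavy atoms occlude the grid; a bound ligand never counts
    against its own pocket volume.
    """
    if spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {spacing}")
    if probe < 0:
        raise ValueError(f"probe radius must be non-negative, got {probe}")
    if site_radius <= 0:
        raise ValueError(f"site radius must be positive, got {site_radius}")
    center = np.asarray(site_center, dtype=float)

    n = int(np.ceil(2 * site_radius / spacing))
    origin = center - site_radius
    shape = (n, n, n)
    steps = (np.arange(n) + 0.5) * spacing
    gx, gy, gz = np.meshgrid(
        origin[0] + steps, origin[1] + steps, origin[2] + steps, indexing="ij"
    )
    centers = np.stack([gx, gy, gz], axis=-1)
    inside = ((centers - center) ** 2).sum(axis=-1) <= site_radius**2

    coords = s.heavy_coords()
    elements = s.heavy_elements()
    occupied = np.zeros(shape, dtype=bool)
    max_r = max(VDW_RADII.get(e.upper(), DEFAULT_VDW) for e in set(elements)) + probe
    # consider only atoms that can reach the grid
    reach = np.linalg.norm(coords - center, axis=1) <= site_radius + max_r + spacing
    for xyz, elem in zip(coords[reach], np.asarray(elements)[reach]):
        r = VDW_RADII.get(elem.upper(), DEFAULT_VDW) + probe
        lo = np.maximum(np.floor((xyz - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((xyz + r - origin) / spacing).astype(int), n)
        if np.any(lo >= hi):
            continue
        sub = centers[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        mask = ((sub - xyz) ** 2).sum(axis=-1) <= r * r
        occupied[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= mask

    empty = inside & ~occupied

    # bulk-solvent removal: empty cells outside the convex hull of the site's
    # protein atoms are solvent seeds; their connected components drain away
    hull_atoms = coords[np.linalg.norm(coords - center, axis=1) <= site_radius + 2.0]
    outside_hull = np.ones(shape, dtype=bool)
    if len(hull_atoms) >= 4:
        try:
            tri = Delaunay(hull_atoms)
            outside_hull = tri.find_simplex(centers.reshape(-1, 3)).reshape(shape) < 0
        except QhullError:
            pass  # degenerate atom cloud: everything stays solvent
    labels, n_comp = ndimage.label(empty, structure=_CONN6)
    cavity = np.zeros(shape, dtype=bool)
    solvent_labels = set(np.unique(labels[empty & outside_hull])) - {0}
    for lab in range(1, n_comp + 1):
        if lab not in solvent_labels:
            cavity |= labels == lab

    cav_labels, n_cav = ndimage.label(cavity, structure=_CONN6)
    subs: list[frozenset[tuple[int, int, int]]] = []
    for lab in range(1, n_cav + 1):
        idx = np.argwhere(cav_labels == lab)
        subs.append(frozenset(map(tuple, idx)))
    subs.sort(key=lambda sp: (-len(sp), min(sp) if sp else ()))
    cells = frozenset().union(*subs) if subs else frozenset()
    return PocketModel(
        grid_spacing=spacing, origin=origin, shape=shape, cells=cells, sub_pockets=subs
    )


def match_pockets(
    model_a: PocketModel, model_b: PocketModel
) -> dict[str, dict[int, dict[int, float]]]:
    """Cell-overlap fractions between the sub-pockets of two models.

    Returns ``{"a_to_b": {i: {j: frac}}, "b_to_a": {j: {i: frac}}}`` where
    ``frac`` is the fraction of the source sub-pocket's cells shared with the
    target sub-pocket.  Both models must be built on the same grid frame.
    """
    if not model_a.same_frame(model_b):
        raise FrameError("pocket models were built on different grid frames")

    def direction(src: PocketModel, dst: PocketModel) -> dict[int, dict[int, float]]:
        out: dict[int, dict[int, float]] = {}
        for i, sp in enumerate(src.sub_pockets):
            row = {}
            for j, tp in enumerate(dst.sub_pockets):
                shared = len(sp & tp)
                if shared:
                    row[j] = shared / len(sp)
            out[i] = row
        return out

    return {"a_to_b": direction(model_a, model_b), "b_to_a": direction(model_b, model_a)}
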