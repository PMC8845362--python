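"""Synthetic apo/holo structure pairs with exact ground truth.

Real corpora of paired crystal structures are large and uncontrolled; every
stage of this pipeline is instead exercised on generated fixtures whose true
motions are known by construction:

* helix scaffolds with designed rigid-body motions, designed flexible
  displacement fields (target overall Cα RMSD), and designed per-residue
  displacements realised exactly;
* lattice "protein blocks" with carved cavities realising each of the five
  pocket-motion classes (PC, PE, PF, PS, OM), plus a placed ligand and a
  displaced gate residue;
* radially arranged binding-site structures with controlled amino-acid
  composition per distance shell, for the preference statistics.

The generator's bookkeeping (the truth records) uses a quaternion closed-form
RMSD, a different algorithm from the SVD-based fit in :mod:`superpose`, so
recovery tests compare two independent routes.

Geometry is idealised: bond lengths and contacts are plausible, not
force-field relaxed.  Determinism: every random choice flows from the seed of
a ``numpy`` Generator, so a fixed seed reproduces fixtures bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure_io import build_pair
from .structures import (
    AA_ORDER,
    APO_APO,
    APO_HOLO,
    HOLO_HOLO_DIFF,
    HOLO_HOLO_SAME,
    Atom,
    Ligand,
    Residue,
    Structure,
    StructurePair,
)

#: Side-chain heavy-atom names per residue type (standard PDB nomenclature).
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

POCKET_CLASSES = ("PC", "PE", "PF", "PS", "OM")

_HELIX_RADIUS = 2.28  # Å, gives 3.80 Å Cα-Cα for 100°/1.5 Å rise
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)

_LATTICE_SPACING = 3.0  # Å between residue sites in the block scaffold
_ATOM_CLUSTER = 0.3  # Å: lattice residue atoms stay this close to their site
_OCCLUSION = 3.1  # Å: carbon vdW (1.7) + probe (1.4); sets carve radii


def _element_of(atom_name: str) -> str:
    return atom_name[0]


# ---------------------------------------------------------------------------
# specification of one synthetic pair


@dataclass
class ResidueMotion:
    """One designed residue displacement.

    ``mode='translate'`` moves every atom of the residue by the displacement,
    so the residue's heavy-atom RMSD equals it exactly.  ``mode='side_chain'``
    moves only side-chain atoms, scaled so the all-heavy-atom RMSD still
    equals the requested displacement while the backbone (and hence the global
    Cα fit) stays put.  ``mode='flip'`` rotates the side chain about the
    Cα–Cβ axis by ``angle_deg``.
    """

    index: int
    displacement: float = 0.0
    mode: str = "translate"
    angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise ValueError("displacements must be non-negative")
        if self.mode not in ("translate", "side_chain", "flip"):
            raise ValueError(f"unknown motion mode {self.mode!r}")


@dataclass
class PocketPlan:
    """Carved-cavity design for one pocket-motion class.

    ``r_apo``/``r_holo`` are nominal cavity radii (None = no cavity, solid
    block); ``separation`` is the centre distance of the two lobes of a
    fusing pocket.  The carve radius adds the occlusion distance, so the
    realised cavity always contains the nominal sphere; lattice discreteness
    can only enlarge it.  Class geometries therefore leave wide margins
    around the classification thresholds.
    """

    pocket_class: str
    r_apo: Optional[float]
    r_holo: Optional[float]
    separation: float = 0.0
    gate_displacement: float = 3.0

    @staticmethod
    def for_class(pocket_class: str, gate_displacement: float = 3.0) -> "PocketPlan":
        designs = {
            "PC": dict(r_apo=None, r_holo=3.0),
            "PE": dict(r_apo=2.2, r_holo=5.0),
            "PF": dict(r_apo=2.5, r_holo=2.5, separation=16.5),
            "PS": dict(r_apo=5.0, r_holo=2.2),
            "OM": dict(r_apo=3.0, r_holo=3.0),
        }
        if pocket_class not in designs:
            raise ValueError(f"unknown pocket class {pocket_class!r}")
        return PocketPlan(
            pocket_class=pocket_class,
            gate_displacement=gate_displacement,
            **designs[pocket_class],
        )

    def nominal_volumes(self) -> tuple[float, float]:
        def vol(r: Optional[float]) -> float:
            if r is None:
                return 0.0
            v = 4.0 / 3.0 * np.pi * r**3
            if self.pocket_class == "PF":
                v *= 2  # two lobes
            return v

        v_apo = vol(self.r_apo)
        v_holo = vol(self.r_holo)
        if self.pocket_class == "PF":
            # merged capsule: cylinder of length `separation` plus end caps
            r = self.r_holo
            v_holo = np.pi * r**2 * self.separation + 4.0 / 3.0 * np.pi * r**3
        return v_apo, v_holo


@dataclass
class LigandPlan:
    comp_id: str = "LIG"
    n_atoms: int = 8
    radius: float = 2.5  # radial spread of the fragment's atoms


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic structure pair."""

    seed: int = 0
    n_residues: int = 60
    scaffold: str = "helix"
    composition: Optional[dict[str, float]] = None
    motion_plan: list[ResidueMotion] = field(default_factory=list)
    rigid_angle_deg: float = 0.0
    rigid_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_overall_rmsd: Optional[float] = None
    pocket_plan: Optional[PocketPlan] = None
    ligand_plan: Optional[LigandPlan] = None
    block_half_widths: tuple[float, float, float] = (10.5, 10.5, 10.5)

    def __post_init__(self) -> None:
        if self.scaffold not in ("helix", "slab", "lattice"):
            raise ValueError(f"unknown scaffold {self.scaffold!r}")
        if self.n_residues < 30:
            raise ValueError("need at least 30 residues for a usable pair")
        if self.composition is not None:
            bad = set(self.composition) - set(AA_ORDER)
            if bad:
                raise ValueError(f"unsupported residue types: {sorted(bad)}")
            if abs(sum(self.composition.values()) - 1.0) > 1e-9:
                raise ValueError("composition fractions must sum to 1")


@dataclass
class PairTruth:
    """Ground truth recorded while building a pair."""

    pair_id: str
    category: str
    overall_rmsd: float
    pocket_class: Optional[str]
    per_residue_rmsd: dict[str, float] = field(default_factory=dict)
    vol_apo_nominal: Optional[float] = None
    vol_holo_nominal: Optional[float] = None


# ---------------------------------------------------------------------------
# quaternion closed-form RMSD (generator bookkeeping)


def quaternion_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum RMSD between two point sets via the quaternion eigen method.

    Independent of the SVD route: builds the 4x4 key matrix of the
    cross-correlation and takes its largest eigenvalue.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = len(x)
    p = x - x.mean(axis=0)
    q = y - y.mean(axis=0)
    g = float((p**2).sum() + (q**2).sum())
    r = p.T @ q
    k = np.array(
        [
            [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
            [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
            [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
            [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0], r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
        ]
    )
    lam = float(np.linalg.eigvalsh(k)[-1])
    return float(np.sqrt(max(0.0, (g - 2.0 * lam) / n)))


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * kmat + (1 - np.cos(angle_rad)) * (kmat @ kmat)


# ---------------------------------------------------------------------------
# scaffolds


def _sample_sequence(rng: np.random.Generator, n: int, composition: Optional[dict[str, float]]) -> list[str]:
    if composition is None:
        return list(rng.choice(AA_ORDER, size=n))
    names = list(composition)
    probs = np.array([composition[a] for a in names], float)
    probs = probs / probs.sum()
    return list(rng.choice(names, size=n, p=probs))


def _helix_residue(i: int, res_name: str) -> Residue:
    theta = i * _HELIX_TURN
    ca = np.array([_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), i * _HELIX_RISE])
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    theta_next = (i + 1) * _HELIX_TURN
    ca_next = np.array(
        [_HELIX_RADIUS * np.cos(theta_next), _HELIX_RADIUS * np.sin(theta_next), (i + 1) * _HELIX_RISE]
    )
    u = ca_next - ca
    u /= np.linalg.norm(u)
    atoms = [
        Atom("N", "N", ca + 1.46 * (-0.75 * u + 0.66 * radial)),
        Atom("CA", "C", ca),
        Atom("C", "C", ca + 1.52 * (0.75 * u + 0.66 * radial)),
        Atom("O", "O", ca + 1.52 * (0.75 * u + 0.66 * radial) + 1.23 * radial),
    ]
    side_dir = radial - 0.3 * u
    side_dir /= np.linalg.norm(side_dir)
    perp = np.cross(side_dir, u)
    perp /= np.linalg.norm(perp)
    for k, name in enumerate(SIDE_CHAIN_ATOMS[res_name]):
        pos = ca + (1.53 + 1.35 * k) * side_dir + 0.45 * ((-1) ** k) * perp
        atoms.append(Atom(name, _element_of(name), pos))
    return Residue(chain_id="A", seq_id=i + 1, res_name=res_name, atoms=atoms)


def _slab_residue(i: int, res_name: str, ncol: int) -> Residue:
    row, col = divmod(i, ncol)
    base = np.array([col * 4.8, row * 4.8, 0.0])
    atoms = [
        Atom("N", "N", base + np.array([-0.9, 0.5, 0.0])),
        Atom("CA", "C", base),
        Atom("C", "C", base + np.array([0.9, 0.5, 0.0])),
        Atom("O", "O", base + np.array([1.4, 1.3, 0.3])),
    ]
    up = np.array([0.0, 0.0, 1.0])
    perp = np.array([1.0, 0.0, 0.0])
    for k, name in enumerate(SIDE_CHAIN_ATOMS[res_name]):
        atoms.append(
            Atom(name, _element_of(name), base + (1.53 + 1.35 * k) * up + 0.45 * ((-1) ** k) * perp)
        )
    return Residue(chain_id="A", seq_id=i + 1, res_name=res_name, atoms=atoms)


def _lattice_structure(
    spec: SyntheticSpec, rng: np.random.Generator, structure_id: str
) -> Structure:
    """Dense block of small residues on a cubic lattice.

    Each residue is a tight 4-atom cluster (N, CA, C, O) at one lattice site;
    the block is solid to the probe everywhere until cavities are carved.
    """
    hx, hy, hz = spec.block_half_widths
    names: list[str] = []
    sites: list[np.ndarray] = []
    xs = np.arange(-hx, hx + 1e-9, _LATTICE_SPACING)
    ys = np.arange(-hy, hy + 1e-9, _LATTICE_SPACING)
    zs = np.arange(-hz, hz + 1e-9, _LATTICE_SPACING)
    for x in xs:
        for y in ys:
            for z in zs:
                sites.append(np.array([x, y, z]))
    names = _sample_sequence(rng, len(sites), spec.composition)
    chains: dict[str, list[Residue]] = {"A": []}
    offsets = {
        "N": np.array([-_ATOM_CLUSTER, 0.1, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([_ATOM_CLUSTER, 0.1, 0.0]),
        "O": np.array([0.0, -_ATOM_CLUSTER, 0.15]),
    }
    for i, (site, name) in enumerate(zip(sites, names)):
        atoms = [Atom(an, _element_of(an), site + off) for an, off in offsets.items()]
        chains["A"].append(Residue(chain_id="A", seq_id=i + 1, res_name=name, atoms=atoms))
    return Structure(id=structure_id, chains=chains, resolution=1.5)


def make_scaffold(spec: SyntheticSpec, structure_id: str = "SYN") -> Structure:
    """Build the undisturbed scaffold structure for a spec (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    if spec.scaffold == "lattice":
        return _lattice_structure(spec, rng, structure_id)
    names = _sample_sequence(rng, spec.n_residues, spec.composition)
    if spec.scaffold == "helix":
        residues = [_helix_residue(i, nm) for i, nm in enumerate(names)]
    else:  # slab
        ncol = int(np.ceil(np.sqrt(spec.n_residues)))
        residues = [_slab_residue(i, nm, ncol) for i, nm in enumerate(names)]
    return Structure(id=structure_id, chains={"A": residues}, resolution=1.5)


# ---------------------------------------------------------------------------
# motions


def _translate_residue(res: Residue, vec: np.ndarray) -> None:
    for a in res.atoms:
        a.coords = a.coords + vec


def _residue_rmsd_between(ra: Residue, rb: Residue) -> float:
    pa = ra.heavy_coords()
    pb = rb.heavy_coords()
    return float(np.sqrt(((pa - pb) ** 2).sum() / len(pa)))


def _apply_residue_motion(res: Residue, plan: ResidueMotion, rng: np.random.Generator) -> None:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    side_names = set(SIDE_CHAIN_ATOMS[res.res_name])
    if plan.mode == "translate":
        _translate_residue(res, plan.displacement * direction)
        return
    side_atoms = [a for a in res.atoms if a.name in side_names]
    if not side_atoms:
        raise ValueError(f"residue {res.res_name} has no side chain for mode {plan.mode!r}")
    if plan.mode == "side_chain":
        n_all = len(res.heavy_atoms())
        magnitude = plan.displacement * np.sqrt(n_all / len(side_atoms))
        for a in side_atoms:
            a.coords = a.coords + magnitude * direction
        return
    # flip: rigid rotation of the side chain about the Cα–Cβ axis
    ca, cb = res.get_atom("CA"), res.get_atom("CB")
    if ca is None or cb is None:
        raise ValueError(f"residue {res.res_name} lacks CA/CB for a flip")
    axis = cb.coords - ca.coords
    rot = _rotation_matrix(axis, np.deg2rad(plan.angle_deg))
    for a in side_atoms:
        a.coords = ca.coords + rot @ (a.coords - ca.coords)


def _project_out_rigid(disp: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Remove net translation and the linearised rotation from a displacement field."""
    d = disp - disp.mean(axis=0)
    r = ca - ca.mean(axis=0)
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for ri, di in zip(r, d):
        a += np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri)
        b += np.cross(ri, di)
    omega = np.linalg.solve(a, b)
    return d - np.cross(omega, r)


def _flexible_field(
    ca: np.ndarray, target_rmsd: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth per-residue displacement field with an exact optimal-fit RMSD.

    The field is projected free of rigid modes and rescaled iteratively until
    the quaternion RMSD of the displaced Cα trace hits the target.
    """
    n = len(ca)
    raw = rng.normal(size=(n, 3))
    kernel = np.ones(5) / 5.0
    smooth = np.column_stack([np.convolve(raw[:, k], kernel, mode="same") for k in range(3)])
    d = _project_out_rigid(smooth, ca)
    d *= target_rmsd / np.sqrt((d**2).sum() / n)
    for _ in range(60):
        current = quaternion_rmsd(ca, ca + d)
        if abs(current - target_rmsd) < 1e-9:
            break
        d *= target_rmsd / current
    return d


# ---------------------------------------------------------------------------
# carving and ligands (lattice pocket fixtures)


def _carve(s: Structure, centers: Sequence[np.ndarray], radius: float) -> None:
    """Remove residues whose site lies within the carve radius of any centre.

    The carve radius already includes the occlusion distance, so every grid
    point of the nominal cavity ends up farther than probe + vdW from all
    remaining atoms.
    """
    carve_r = radius + _OCCLUSION + _ATOM_CLUSTER + 0.05
    for cid, residues in s.chains.items():
        kept = []
        for res in residues:
            site = res.get_atom("CA").coords
            if all(np.linalg.norm(site - c) >= carve_r for c in centers):
                kept.append(res)
        s.chains[cid] = kept


def _pocket_ligand(plan: PocketPlan, lig_plan: LigandPlan) -> Ligand:
    """Rigid fragment filling the holo cavity (and reaching the pocket walls)."""
    removal_max = max(r for r in (plan.r_apo, plan.r_holo) if r is not None) + _OCCLUSION
    r_lig = max(0.8, removal_max - 3.5)
    atoms: list[Atom] = []
    if plan.pocket_class == "PF":
        half = plan.separation / 2.0
        for k, x in enumerate(np.linspace(-half, half, 7)):
            atoms.append(Atom(f"C{k+1}", "C", np.array([x, 0.0, 0.0])))
        r_perp = max(0.8, plan.r_apo + _OCCLUSION - 3.5)
        atoms.append(Atom("C8", "C", np.array([0.0, r_perp, 0.0])))
        atoms.append(Atom("C9", "C", np.array([0.0, -r_perp, 0.0])))
    else:
        for k, axis in enumerate(np.eye(3)):
            atoms.append(Atom(f"C{2*k+1}", "C", r_lig * axis))
            atoms.append(Atom(f"C{2*k+2}", "C", -r_lig * axis))
        atoms.append(Atom("C7", "C", np.array([0.0, 0.0, 0.4])))
        atoms.append(Atom("C8", "C", np.array([0.0, 0.0, -0.4])))
    return Ligand(comp_id=lig_plan.comp_id, chain_id="X", seq_id=900, atoms=atoms)


def _pick_gate_residue(
    holo: Structure, apo: Structure, lig: Ligand, lo: float = 3.2, hi: float = 4.8
) -> int:
    """Index (seq_id) of a residue present in both states whose minimum distance
    to the ligand lies in (lo, hi): the designated moving pocket residue."""
    apo_ids = {r.seq_id for r in apo.residues()}
    lig_coords = lig.coords()
    best: tuple[float, int] | None = None
    for res in holo.residues():
        if res.seq_id not in apo_ids:
            continue
        d = float(np.min(np.linalg.norm(res.heavy_coords()[:, None, :] - lig_coords[None, :, :], axis=2)))
        if lo < d < hi:
            score = abs(d - 0.5 * (lo + hi))
            if best is None or score < best[0]:
                best = (score, res.seq_id)
    if best is None:
        raise ValueError("pocket plan infeasible: no residue in gate distance range")
    return best[1]


_BLOCK_WIDTHS = {
    "PC": (10.5, 10.5, 10.5),
    "PE": (12.0, 12.0, 12.0),
    "PF": (17.0, 9.0, 9.0),
    "PS": (12.0, 12.0, 12.0),
    "OM": (10.5, 10.5, 10.5),
}


# ---------------------------------------------------------------------------
# pair assembly


def apply_motion(scaffold: Structure, spec: SyntheticSpec) -> tuple[Structure, Structure, PairTruth]:
    """Realise a spec's motions on a scaffold: returns (apo, holo, truth).

    The first returned structure is the reference state; the second carries
    the ligand (when a ligand plan is present), the designed residue motions,
    the designed flexible field, and finally the rigid transform.
    """
    rng = np.random.default_rng(spec.seed + 1)
    first = scaffold.copy()
    second = scaffold.copy()
    first.id = scaffold.id + "A"
    second.id = scaffold.id + "B"
    truth = PairTruth(
        pair_id=f"{first.id}|{second.id}",
        category=APO_APO,
        overall_rmsd=0.0,
        pocket_class=None,
    )

    # --- pocket carving ----------------------------------------------------
    gate_seq_id: Optional[int] = None
    if spec.pocket_plan is not None:
        plan = spec.pocket_plan
        lig_plan = spec.ligand_plan or LigandPlan()
        if plan.pocket_class == "PF":
            half = plan.separation / 2.0
            lobes = [np.array([-half, 0.0, 0.0]), np.array([half, 0.0, 0.0])]
            if plan.r_apo is not None:
                _carve(first, lobes, plan.r_apo)
            # fused state: carve along the whole segment (endpoints included)
            xs = np.linspace(-half, half, int(np.ceil(plan.separation)) + 1)
            _carve(second, [np.array([x, 0.0, 0.0]) for x in xs], plan.r_holo)
        else:
            center = [np.zeros(3)]
            if plan.r_apo is not None:
                _carve(first, center, plan.r_apo)
            if plan.r_holo is not None:
                _carve(second, center, plan.r_holo)
        lig = _pocket_ligand(plan, lig_plan)
        second.ligands.append(lig)
        gate_seq_id = _pick_gate_residue(second, first, lig)
        truth.pocket_class = plan.pocket_class
        truth.vol_apo_nominal, truth.vol_holo_nominal = plan.nominal_volumes()

    # --- ligands for the pairing categories --------------------------------
    if spec.pocket_plan is None and spec.ligand_plan is not None:
        _attach_surface_ligands(first, second, spec.ligand_plan, spec, rng)

    # --- designed residue motions -------------------------------------------
    by_id_first = {r.seq_id: r for r in first.residues()}
    by_id_second = {r.seq_id: r for r in second.residues()}
    plans = list(spec.motion_plan)
    if gate_seq_id is not None:
        plans.append(ResidueMotion(index=gate_seq_id, displacement=spec.pocket_plan.gate_displacement))
    for rm in plans:
        res = by_id_second.get(rm.index)
        if res is None:
            raise ValueError(f"motion plan names residue {rm.index}, absent from the pair")
        if rm.mode == "translate" and spec.pocket_plan is not None and rm.index == gate_seq_id:
            # gate residues move away from the ligand so the cavity is unaffected
            lig_centroid = second.ligands[0].centroid
            direction = res.get_atom("CA").coords - lig_centroid
            direction /= np.linalg.norm(direction)
            _translate_residue(res, rm.displacement * direction)
        else:
            _apply_residue_motion(res, rm, rng)
        if rm.index in by_id_first:
            truth.per_residue_rmsd[by_id_first[rm.index].label] = _residue_rmsd_between(
                by_id_first[rm.index], res
            )

    # --- designed flexible field --------------------------------------------
    common_ids = sorted(set(by_id_first) & set(by_id_second))
    ca_first = np.array([by_id_first[i].get_atom("CA").coords for i in common_ids])
    if spec.target_overall_rmsd is not None:
        d = _flexible_field(ca_first, spec.target_overall_rmsd, rng)
        for i, vec in zip(common_ids, d):
            _translate_residue(by_id_second[i], vec)

    # --- exact overall-RMSD bookkeeping --------------------------------------
    ca_second = np.array([by_id_second[i].get_atom("CA").coords for i in common_ids])
    truth.overall_rmsd = quaternion_rmsd(ca_first, ca_second)

    # --- rigid transform of the whole second structure ----------------------
    if spec.rigid_angle_deg or any(spec.rigid_translation):
        axis = rng.normal(size=3)
        rot = _rotation_matrix(axis, np.deg2rad(spec.rigid_angle_deg))
        t = np.asarray(spec.rigid_translation, float)
        for res in second.residues():
            for a in res.atoms:
                a.coords = rot @ a.coords + t
        for lig in second.ligands:
            for a in lig.atoms:
                a.coords = rot @ a.coords + t

    truth.category = _category_of(first, second)
    return first, second, truth


def _category_of(a: Structure, b: Structure) -> str:
    if not a.ligands and not b.ligands:
        return APO_APO
    if bool(a.ligands) != bool(b.ligands):
        return APO_HOLO
    return (
        HOLO_HOLO_SAME
        if {l.comp_id for l in a.ligands} & {l.comp_id for l in b.ligands}
        else HOLO_HOLO_DIFF
    )


def _attach_surface_ligands(
    first: Structure,
    second: Structure,
    lig_plan: LigandPlan,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> None:
    """Place small surface fragments to realise the holo/holo pairing categories.

    ``lig_plan.comp_id`` may be 'LIG|LG2' to give the two members different
    ligands; a leading '-' on either side leaves that member apo.
    """
    comp_a, _, comp_b = lig_plan.comp_id.partition("|")
    comp_b = comp_b or comp_a
    mid = spec.n_residues // 2
    for s, comp in ((first, comp_a), (second, comp_b)):
        if comp == "-":
            continue
        res = list(s.residues())[mid]
        ca = res.get_atom("CA").coords
        radial = ca - np.array([0.0, 0.0, ca[2]])
        radial = radial / np.linalg.norm(radial) if np.linalg.norm(radial) > 0 else np.array([1.0, 0, 0])
        center = ca + 4.5 * radial
        atoms = []
        for k in range(max(4, lig_plan.n_atoms)):
            off = 0.9 * np.eye(3)[k % 3] * (1 if k % 2 else -1)
            atoms.append(Atom(f"C{k+1}", "C", center + off))
        s.ligands.append(Ligand(comp_id=comp, chain_id="X", seq_id=901, atoms=atoms))


# ---------------------------------------------------------------------------
# high-level builders


def make_pocket_pair(
    pocket_class: str, seed: int = 0, gate_displacement: float = 3.0
) -> tuple[StructurePair, PairTruth]:
    """A lattice-block apo/holo pair realising one pocket-motion class."""
    spec = SyntheticSpec(
        seed=seed,
        scaffold="lattice",
        pocket_plan=PocketPlan.for_class(pocket_class, gate_displacement),
        ligand_plan=LigandPlan(),
        block_half_widths=_BLOCK_WIDTHS[pocket_class],
    )
    scaffold = make_scaffold(spec, structure_id=f"{pocket_class}{seed:03d}")
    first, second, truth = apply_motion(scaffold, spec)
    pair = build_pair(first, second)
    return pair, truth


def make_overall_pair(
    category: str,
    target_rmsd: float,
    seed: int = 0,
    n_residues: int = 80,
    rigid_angle_deg: float = 25.0,
    rigid_translation: tuple[float, float, float] = (4.0, -2.0, 1.0),
) -> tuple[StructurePair, PairTruth]:
    """A helix pair of one pairing category with a designed overall Cα RMSD."""
    ligand_comp = {
        APO_APO: None,
        APO_HOLO: "-|LIG",
        HOLO_HOLO_DIFF: "LIG|LG2",
        HOLO_HOLO_SAME: "LIG|LIG",
    }[category]
    spec = SyntheticSpec(
        seed=seed,
        scaffold="helix",
        n_residues=n_residues,
        target_overall_rmsd=target_rmsd if target_rmsd > 0 else None,
        rigid_angle_deg=rigid_angle_deg,
        rigid_translation=rigid_translation,
        ligand_plan=LigandPlan(comp_id=ligand_comp) if ligand_comp else None,
    )
    scaffold = make_scaffold(spec, structure_id=f"OV{seed:03d}")
    first, second, truth = apply_motion(scaffold, spec)
    pair = build_pair(first, second)
    if pair.category != category:
        raise RuntimeError(f"built category {pair.category}, wanted {category}")
    return pair, truth


def make_corpus(
    n_pairs: int = 10,
    class_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[StructurePair], list[PairTruth], pd.DataFrame]:
    """Reproducible fixture corpus with a truth table.

    ``class_mix`` maps pocket classes (PC/PE/PF/PS/OM) and/or pairing
    categories to fractions summing to 1; pocket classes yield lattice
    apo/holo pairs, categories yield helix pairs with designed overall RMSD
    alternating between a motionless (1.2 Å) and a moving (3.2 Å) design.
    """
    mix = class_mix or {c: 0.2 for c in POCKET_CLASSES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    # largest-remainder allocation of n_pairs
    keys = sorted(mix)
    raw = {k: n_pairs * mix[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    remainder = n_pairs - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:remainder]:
        counts[k] += 1

    pairs: list[StructurePair] = []
    truths: list[PairTruth] = []
    i = 0
    for key in keys:
        for j in range(counts[key]):
            pair_seed = seed * 10007 + i
            if key in POCKET_CLASSES:
                disp = 2.6 + 0.8 * (j % 3)
                pair, truth = make_pocket_pair(key, seed=pair_seed, gate_displacement=disp)
            else:
                target = 1.2 if j % 2 == 0 else 3.2
                pair, truth = make_overall_pair(key, target_rmsd=target, seed=pair_seed)
            pairs.append(pair)
            truths.append(truth)
            i += 1
    table = pd.DataFrame(
        [
            {
                "pair_id": t.pair_id,
                "category": t.category,
                "designed_overall_rmsd": t.overall_rmsd,
                "designed_class": t.pocket_class or "none",
                "designed_vol_apo": t.vol_apo_nominal,
                "designed_vol_holo": t.vol_holo_nominal,
                "residue_displacements": ";".join(
                    f"{k}:{v:.3f}" for k, v in sorted(t.per_residue_rmsd.items())
                ),
            }
            for t in truths
        ]
    )
    return pairs, truths, table


def write_corpus(
    pairs: Sequence[StructurePair],
    table: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write the corpus as PDB files plus the truth TSV."""
    from .structure_io import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        write_pdb(pair.first, out / f"{pair.first.id}.pdb")
        write_pdb(pair.second, out / f"{pair.second.id}.pdb")
    table.to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# analytic cavity fixtures


def _fibonacci_sphere(n: int) -> np.ndarray:
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * idx
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_cavity_shell(
    radii: Sequence[float] | float,
    centers: Optional[Sequence[np.ndarray]] = None,
    wall_point_spacing: float = 0.8,
    probe: float = 1.4,
    structure_id: str = "SHELL",
) -> Structure:
    """Hollow-shell structures whose enclosed cavity is an analytic ball.

    Carbon atoms tile a sphere of radius ``r + probe + vdW(C)`` around each
    centre, so the region farther than the occlusion distance from every atom
    is the ball of radius ``r`` up to O(spacing²) boundary error — the
    analytic oracle for grid-volume accuracy and sub-pocket topology tests.
    """
    if np.isscalar(radii):
        radii = [float(radii)]
    centers = centers if centers is not None else [np.zeros(3)] * len(radii)
    occ = probe + 1.70  # carbon vdW
    residues = []
    seq = 1
    for r, c in zip(radii, centers):
        wall_r = r + occ
        n_pts = max(32, int(np.ceil(4 * np.pi * wall_r**2 / wall_point_spacing**2)))
        for p in _fibonacci_sphere(n_pts) * wall_r + np.asarray(c, float):
            residues.append(
                Residue(chain_id="A", seq_id=seq, res_name="GLY", atoms=[Atom("CA", "C", p)])
            )
            seq += 1
    return Structure(id=structure_id, chains={"A": residues}, resolution=1.5)


# ---------------------------------------------------------------------------
# composition-controlled binding sites (for the preference statistics)


def make_binding_site_structure(
    shells: Sequence[tuple[float, Sequence[str]]],
    structure_id: str = "SITE",
    seed: int = 0,
    bulk: Sequence[str] = (),
    bulk_distance: float = 9.0,
) -> Structure:
    """One holo structure whose residues sit at controlled minimum distances.

    ``shells`` lists (min-distance, residue names); each residue's nearest
    atom lands within 0.02 Å of the stated distance from the compact ligand,
    so pocket membership at half-integer shell distances is analytically
    known for every integer cutoff.  ``bulk`` residues sit at
    ``bulk_distance``, outside every scanned cutoff, and only contribute to
    the overall composition.
    """
    rng = np.random.default_rng(seed)
    lig_atoms = [
        Atom(f"C{k+1}", "C", 0.01 * (k + 1) * v)
        for k, v in enumerate([*np.eye(3), *(-np.eye(3))])
    ]
    lig = Ligand(comp_id="LIG", chain_id="X", seq_id=900, atoms=lig_atoms)
    placements: list[tuple[float, str]] = []
    for dist, names in shells:
        placements.extend((dist, nm) for nm in names)
    placements.extend((bulk_distance, nm) for nm in bulk)

    n = len(placements)
    # quasi-uniform directions (Fibonacci sphere), randomly rotated by seed
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * idx
    dirs = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    dirs = dirs @ _rotation_matrix(rng.normal(size=3), rng.uniform(0, 2 * np.pi)).T

    residues = []
    for i, ((dist, name), u) in enumerate(zip(placements, dirs)):
        base = (dist + 0.01) * u  # innermost atom defines the minimum distance
        atoms = [
            Atom("N", "N", base),
            Atom("CA", "C", base + 0.45 * u),
            Atom("C", "C", base + 0.90 * u),
            Atom("O", "O", base + 1.35 * u),
        ]
        residues.append(Residue(chain_id="A", seq_id=i + 1, res_name=name, atoms=atoms))
    return Structure(
        id=structure_id, chains={"A": residues}, ligands=[lig], resolution=1.5
    )


def make_composition_corpus(
    n_structures: int = 6,
    seed: int = 0,
    enriched: Optional[dict[str, float]] = None,
    base: Optional[dict[str, float]] = None,
) -> tuple[list[Structure], dict[str, dict[str, int]]]:
    """Holo corpus whose pocket composition is most distinct at the 3.0 Å shell.

    Residues between 2.0 and 3.0 Å of the ligand follow the ``enriched``
    composition; every other shell and the bulk follow ``base``.  Returns the
    structures plus exact per-context counts (the analytic oracle for the
    frequency tables).
    """
    rng = np.random.default_rng(seed)
    base = base or {aa: 0.05 for aa in AA_ORDER}
    enriched = enriched or {"ARG": 0.5, "TRP": 0.3, "HIS": 0.2}
    shell_spec = [(1.6, 5, base), (2.5, 12, enriched), (3.5, 8, base), (4.5, 8, base), (5.5, 8, base)]
    structures = []
    counts: dict[str, dict[str, int]] = {
        ctx: {aa: 0 for aa in AA_ORDER}
        for ctx in ("overall", "2.0", "3.0", "4.0", "5.0", "6.0")
    }
    cutoffs = [2.0, 3.0, 4.0, 5.0, 6.0]
    for s_i in range(n_structures):
        shells = []
        for dist, n_res, comp in shell_spec:
            names = _sample_sequence(rng, n_res, comp)
            shells.append((dist, names))
            for nm in names:
                counts["overall"][nm] += 1
                for c in cutoffs:
                    if dist < c:
                        counts[f"{c:.1f}"][nm] += 1
        bulk = _sample_sequence(rng, 40, base)
        for nm in bulk:
            counts["overall"][nm] += 1
        structures.append(
            make_binding_site_structure(
                shells, structure_id=f"SITE{s_i:03d}", seed=seed * 997 + s_i, bulk=bulk
            )
        )
    return structures, counts


def sample_null_tables(
    rng: np.random.Generator,
    n_overall: int = 5000,
    n_pocket: int = 400,
    composition: Optional[dict[str, float]] = None,
):
    """Overall and pocket count tables with pocket drawn from the overall law.

    Both tables are multinomial draws from the same composition — the null
    model for calibrating the two-proportion test.
    """
    from .preference import FrequencyTable

    composition = composition or {aa: 0.05 for aa in AA_ORDER}
    names = list(composition)
    p = np.array([composition[a] for a in names])
    p = p / p.sum()
    draw_o = rng.multinomial(n_overall, p)
    draw_p = rng.multinomial(n_pocket, p)
    overall = FrequencyTable(counts=dict(zip(names, draw_o)), context="overall")
    pocket = FrequencyTable(counts=dict(zip(names, draw_p)), context="pocket(null)")
    return overall, pocket
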