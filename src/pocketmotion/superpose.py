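"""Rigid-body superposition and RMSD profiles.

The overall motion measure is the Cα root-mean-square deviation after
least-squares rigid superposition (Kabsch, via SVD with a determinant
correction so the fit is always a proper rotation).  Local motion is measured
per residue: heavy-atom RMSD under the single global transform, with no
per-residue refit, so a side-chain flip in an otherwise rigid protein shows up
at full magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .structures import StructurePair

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Point sets too degenerate (collinear/coincident) for a unique fit."""


@dataclass
class SuperpositionResult:
    """Optimal rigid map of the second member onto the first.

    ``apply`` sends coordinates x of the second structure to ``x @ R.T + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    overall_rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass
class ProfileEntry:
    residue_label: str
    res_name: str
    chain_id: str
    seq_id: int
    rmsd: float
    n_atoms: int


@dataclass
class ResidueRMSDProfile:
    """Per-residue heavy-atom RMSDs under one global superposition."""

    entries: list[ProfileEntry] = field(default_factory=list)

    @property
    def max_rmsd(self) -> float:
        return max((e.rmsd for e in self.entries), default=0.0)

    @property
    def mean_rmsd(self) -> float:
        if not self.entries:
            return 0.0
        return float(np.mean([e.rmsd for e in self.entries]))

    def rmsd_of(self, residue_label: str) -> Optional[float]:
        for e in self.entries:
            if e.residue_label == residue_label:
                return e.rmsd
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": e.chain_id,
                    "seq_id": e.seq_id,
                    "res_name": e.res_name,
                    "n_atoms": e.n_atoms,
                    "rmsd_A": e.rmsd,
                }
                for e in self.entries
            ],
            columns=["chain", "seq_id", "res_name", "n_atoms", "rmsd_A"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def kabsch_fit(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``moving`` onto ``target`` (both (n, 3)).

    Returns (rotation, translation, rmsd) with ``moving @ R.T + t ≈ target``.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    p = moving - cm
    q = target - ct
    # collinear or coincident sets leave the rotation under-determined
    sv_p = np.linalg.svd(p, compute_uv=False)
    sv_q = np.linalg.svd(q, compute_uv=False)
    if sv_p[1] < 1e-8 or sv_q[1] < 1e-8:
        raise DegenerateGeometryError("points are (near-)collinear; rotation is not unique")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - rot @ cm
    diff = (moving @ rot.T + t) - target
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return rot, t, rmsd


def _mapped_ca_coords(pair: StructurePair) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for ra, rb in pair.residue_map:
        ca_a, ca_b = ra.ca, rb.ca
        if ca_a is not None and ca_b is not None:
            xs.append(ca_a.coords)
            ys.append(ca_b.coords)
    return np.array(xs).reshape(-1, 3), np.array(ys).reshape(-1, 3)


def kabsch_superpose(pair: StructurePair) -> SuperpositionResult:
    """Superpose the pair on the Cα atoms of all mapped residues.

    Mutated positions keep their Cα in the fit; only the heavy-atom profile
    excludes them (their side chains are not comparable).
    """
    target, moving = _mapped_ca_coords(pair)
    rot, t, rmsd = kabsch_fit(moving, target)
    return SuperpositionResult(rotation=rot, translation=t, overall_rmsd=rmsd, n_atoms=len(moving))


def per_residue_rmsd(
    pair: StructurePair,
    transform: SuperpositionResult,
    residue_subset: Optional[Iterable[tuple[str, int, str]]] = None,
) -> ResidueRMSDProfile:
    """Heavy-atom RMSD of each mapped residue under the global transform.

    ``residue_subset`` restricts the profile to the given first-structure
    residue keys (e.g. the pocket residues).  Residue pairs that differ in
    identity, or share fewer than two heavy atoms by name, are skipped.
    """
    subset = set(residue_subset) if residue_subset is not None else None
    entries: list[ProfileEntry] = []
    for ra, rb in pair.residue_map:
        if subset is not None and ra.key not in subset:
            continue
        if ra.res_name != rb.res_name:
            logger.debug("skipping mutated position %s (%s vs %s)",
                         ra.label, ra.res_name, rb.res_name)
            continue
        atoms_b = {a.name: a for a in rb.heavy_atoms()}
        pa, pb = [], []
        for a in ra.heavy_atoms():
            if a.name in atoms_b:
                pa.append(a.coords)
                pb.append(atoms_b[a.name].coords)
        if len(pa) < 2:
            logger.debug("skipping residue %s: only %d common heavy atoms", ra.label, len(pa))
            continue
        pa_arr = np.array(pa)
        pb_arr = transform.apply(np.array(pb))
        rmsd = float(np.sqrt(((pa_arr - pb_arr) ** 2).sum() / len(pa)))
        entries.append(
            ProfileEntry(
                residue_label=ra.label,
                res_name=ra.res_name,
                chain_id=ra.chain_id,
                seq_id=ra.seq_id,
                rmsd=rmsd,
                n_atoms=len(pa),
            )
        )
    return ResidueRMSDProfile(entries=entries)
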