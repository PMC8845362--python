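"""Motion classification for structure pairs.

Overall motion: a pair whose Cα RMSD after superposition is below 2.0 Å is
motionless; 2.0 Å and above counts as motion (the boundary itself is assigned
to motion).  Pairs are tracked in four categories — apo & apo, apo & holo,
holo & holo with different ligands, holo & holo with the same ligand.

Pocket-residue motion: when at least one pocket residue (within 5.0 Å of the
ligand) moves by more than 2.0 Å heavy-atom RMSD, the pair's pocket motion is
assigned to exactly one of five classes by comparing the grid pocket models of
the two states, in priority order

* PC (pocket-creating)  — no pocket in the apo state, a pocket in the holo state;
* PF (pocket-fusing)    — two or more sub-pockets merge into fewer;
* PE (pocket-expanding) — relative volume gain at least ``f_exp``;
* PS (pocket-shrinking) — relative volume loss at least ``f_shr``;
* OM (other motion)     — a residue moves but volume and topology barely change.

Topology changes (creation, fusion) are tested before volume changes because a
fusion usually also expands the total volume; the more specific signature wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pocket import PocketModel, match_pockets
from .structures import CATEGORIES, StructurePair
from .superpose import ResidueRMSDProfile, SuperpositionResult

OVERALL_RMSD_THRESHOLD = 2.0
POCKET_RMSD_THRESHOLD = 2.0

POCKET_CLASSES = ("PC", "PE", "PF", "PS", "OM")


class ClassificationError(ValueError):
    """Pocket models are required but missing for a moving pocket."""


@dataclass
class PocketMotionParams:
    """Thresholds of the five-class scheme.

    ``v_min`` is the volume below which a site does not count as a pocket
    (about the smallest ligandable cavity); ``f_exp``/``f_shr`` are the
    relative volume changes separating breathing noise from expansion and
    shrinkage; ``min_merge_overlap`` is the fraction of an apo sub-pocket's
    cells that must land in one holo sub-pocket to count toward a fusion;
    ``site_dist`` is how close (Å) a sub-pocket cell must come to a ligand
    atom for the sub-pocket to count as part of the ligand site.
    """

    v_min: float = 50.0
    f_exp: float = 0.25
    f_shr: float = 0.25
    residue_threshold: float = POCKET_RMSD_THRESHOLD
    min_merge_overlap: float = 0.5
    site_dist: float = 2.0


@dataclass
class MotionRecord:
    """Classified motion of one structure pair."""

    pair_id: str
    category: str
    overall_rmsd: float
    motionless: bool
    pocket_max_rmsd: Optional[float] = None
    pocket_mean_rmsd: Optional[float] = None
    pocket_class: Optional[str] = None
    vol_apo: Optional[float] = None
    vol_holo: Optional[float] = None
    pocket_residues: list[tuple[str, str, float]] = field(default_factory=list)
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.pocket_class is not None and self.pocket_class not in POCKET_CLASSES:
            raise ValueError(f"unknown pocket class {self.pocket_class!r}")

    @property
    def moving_residues(self) -> list[tuple[str, str, float]]:
        """Pocket residues with RMSD above the moving-residue threshold."""
        return [t for t in self.pocket_residues if t[2] > POCKET_RMSD_THRESHOLD]


def classify_overall(
    pair: StructurePair,
    sup: SuperpositionResult,
    threshold: float = OVERALL_RMSD_THRESHOLD,
) -> tuple[bool, str]:
    """(motionless, category): motionless iff overall RMSD < threshold."""
    return sup.overall_rmsd < threshold, pair.category


def _subpockets_at_site(
    model: PocketModel, ligand_coords: Optional[np.ndarray], site_dist: float
) -> list[int]:
    """Indices of sub-pockets with a cell within ``site_dist`` of a ligand atom."""
    if ligand_coords is None:
        return list(range(model.n_sub_pockets))
    lig = np.asarray(ligand_coords, float)
    out = []
    for i, sp in enumerate(model.sub_pockets):
        centers = model.cell_centers(sp)
        d2 = ((centers[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if d2.min() < site_dist**2:
            out.append(i)
    return out


def classify_pocket_motion(
    profile: ResidueRMSDProfile,
    apo_model: Optional[PocketModel],
    holo_model: Optional[PocketModel],
    params: PocketMotionParams | None = None,
    ligand_coords: Optional[np.ndarray] = None,
) -> Optional[str]:
    """Assign one of PC/PE/PF/PS/OM, or None when no pocket residue moves.

    ``profile`` must already be restricted to the pocket residues; the two
    models must share a grid frame (holo coordinates pre-transformed through
    the pair superposition).  When ``ligand_coords`` (in the same frame) are
    given, fusion counts only sub-pockets touching the ligand site, so
    incidental cavities far from the ligand cannot fake a topology change.
    """
    params = params or PocketMotionParams()
    if profile.max_rmsd <= params.residue_threshold:
        return None
    if apo_model is None or holo_model is None:
        raise ClassificationError(
            "pocket residues move but pocket models are missing"
        )
    v_apo, v_holo = apo_model.volume, holo_model.volume

    # PC: the pocket only exists in the holo state
    if v_apo < params.v_min and v_holo >= params.v_min:
        return "PC"
    # PF: sub-pockets at the ligand site merge — fewer components there, and
    # one holo component absorbs (>= min_merge_overlap of) at least two
    apo_site = _subpockets_at_site(apo_model, ligand_coords, params.site_dist)
    holo_site = _subpockets_at_site(holo_model, ligand_coords, params.site_dist)
    if len(apo_site) >= 2 and len(holo_site) < len(apo_site):
        overlap = match_pockets(apo_model, holo_model)["a_to_b"]
        absorbed: dict[int, int] = {}
        for i in apo_site:
            for j, frac in overlap[i].items():
                if frac >= params.min_merge_overlap:
                    absorbed[j] = absorbed.get(j, 0) + 1
        if any(count >= 2 for count in absorbed.values()):
            return "PF"
    # PE / PS: relative volume change
    if v_apo > 0:
        rel = (v_holo - v_apo) / v_apo
        if rel >= params.f_exp:
            return "PE"
        if rel <= -params.f_shr:
            return "PS"
    return "OM"


def select_typical_pair(records: Sequence[MotionRecord]) -> MotionRecord:
    """The representative among redundant records of one protein and motion type.

    Pocket motions are ranked by the largest pocket-residue RMSD, overall
    motions by overall RMSD; ties break to the lexicographically smaller
    pair id, so the choice is independent of input order.
    """
    if not records:
        raise ValueError("cannot select a typical pair from an empty group")

    def sort_key(r: MotionRecord):
        if r.pocket_class is not None and r.pocket_max_rmsd is not None:
            return (-r.pocket_max_rmsd, r.pair_id)
        return (-r.overall_rmsd, r.pair_id)

    return min(records, key=sort_key)


def summarize_corpus(records: Sequence[MotionRecord]) -> pd.DataFrame:
    """Per-category summary: counts, motionless proportion, RMSD means/maxima."""
    cols = [
        "n", "n_motionless", "prop_motionless",
        "overall_rmsd_mean", "overall_rmsd_max",
        "pocket_rmsd_mean", "pocket_rmsd_max",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    rows = {}
    for cat in CATEGORIES:
        group = [r for r in records if r.category == cat]
        if not group:
            continue
        overall = np.array([r.overall_rmsd for r in group])
        pocket = np.array([r.pocket_max_rmsd for r in group if r.pocket_max_rmsd is not None])
        rows[cat] = {
            "n": len(group),
            "n_motionless": int(sum(r.motionless for r in group)),
            "prop_motionless": float(np.mean([r.motionless for r in group])),
            "overall_rmsd_mean": float(overall.mean()),
            "overall_rmsd_max": float(overall.max()),
            "pocket_rmsd_mean": float(pocket.mean()) if pocket.size else np.nan,
            "pocket_rmsd_max": float(pocket.max()) if pocket.size else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def records_to_frame(records: Sequence[MotionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "pair_id": r.pair_id,
                "category": r.category,
                "overall_rmsd_A": r.overall_rmsd,
                "motionless": r.motionless,
                "pocket_max_rmsd_A": r.pocket_max_rmsd,
                "pocket_class": r.pocket_class if r.pocket_class is not None else "none",
                "vol_apo_A3": r.vol_apo,
                "vol_holo_A3": r.vol_holo,
                "moving_residues": ";".join(
                    f"{rid}:{rmsd:.2f}" for rid, _aa, rmsd in r.moving_residues
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "category", "overall_rmsd_A", "motionless",
            "pocket_max_rmsd_A", "pocket_class", "vol_apo_A3", "vol_holo_A3",
            "moving_residues",
        ],
    )


def write_records_tsv(records: Sequence[MotionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_summary_json(records: Sequence[MotionRecord], path: str | Path) -> None:
    df = summarize_corpus(records)
    Path(path).write_text(json.dumps(df.to_dict(orient="index"), indent=2))
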