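"""End-to-end analysis of one structure pair.

Chains the pipeline stages: superposition on mapped Cα atoms, pocket-residue
selection around the ligand, per-residue RMSD profile, grid pocket models of
both states in a common frame, and motion classification.  The ligand of the
first structure defines the site frame; if only the second member is bound,
its ligand is carried into the first member's frame through the superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .motion import MotionRecord, PocketMotionParams, classify_overall, classify_pocket_motion
from .pocket import (
    DEFAULT_PROBE,
    DEFAULT_SPACING,
    PocketModel,
    PocketResidueSet,
    build_pocket_model,
    pocket_residues,
)
from .structures import Structure, StructurePair
from .superpose import ResidueRMSDProfile, SuperpositionResult, kabsch_superpose, per_residue_rmsd

POCKET_CUTOFF = 5.0
#: Margin added to the ligand extent when sizing the site sphere, so the grid
#: covers the full cavity beyond the ligand's own reach.
SITE_MARGIN = 6.0
MIN_SITE_RADIUS = 8.0


@dataclass
class PairAnalysis:
    """Everything computed for one pair, with the summary record."""

    record: MotionRecord
    superposition: SuperpositionResult
    profile: Optional[ResidueRMSDProfile] = None
    pocket_set: Optional[PocketResidueSet] = None
    apo_model: Optional[PocketModel] = None
    holo_model: Optional[PocketModel] = None


def _transformed_copy(s: Structure, sup: SuperpositionResult) -> Structure:
    out = s.copy()
    for res in out.residues():
        for a in res.atoms:
            a.coords = sup.apply(a.coords[None, :])[0]
    for lig in out.ligands:
        for a in lig.atoms:
            a.coords = sup.apply(a.coords[None, :])[0]
    return out


def analyze_pair(
    pair: StructurePair,
    pocket_cutoff: float = POCKET_CUTOFF,
    spacing: float = DEFAULT_SPACING,
    probe: float = DEFAULT_PROBE,
    params: PocketMotionParams | None = None,
    protein_id: Optional[str] = None,
) -> PairAnalysis:
    """Run the full motion analysis on one pair."""
    sup = kabsch_superpose(pair)
    motionless, category = classify_overall(pair, sup)

    record = MotionRecord(
        pair_id=pair.pair_id,
        category=category,
        overall_rmsd=sup.overall_rmsd,
        motionless=motionless,
        protein_id=protein_id,
    )
    analysis = PairAnalysis(record=record, superposition=sup)

    # pick the ligand defining the site: the first structure's ligand when
    # present, otherwise the second's carried through the superposition
    if pair.first.ligands:
        lig = pair.first.ligands[0]
        lig_coords = lig.coords()
    elif pair.second.ligands:
        lig = pair.second.ligands[0]
        lig_coords = sup.apply(lig.coords())
    else:
        return analysis  # apo/apo pair: no pocket analysis possible

    pocket_set = pocket_residues(pair.first, lig, cutoff=pocket_cutoff, ligand_coords=lig_coords)
    profile = per_residue_rmsd(pair, sup, residue_subset=pocket_set.residues)
    analysis.pocket_set = pocket_set
    analysis.profile = profile

    record.pocket_residues = [
        (e.residue_label, e.res_name, e.rmsd) for e in profile.entries
    ]
    record.pocket_max_rmsd = profile.max_rmsd if profile.entries else None
    record.pocket_mean_rmsd = profile.mean_rmsd if profile.entries else None

    center = lig_coords.mean(axis=0)
    extent = float(np.max(np.linalg.norm(lig_coords - center, axis=1)))
    site_radius = max(MIN_SITE_RADIUS, extent + SITE_MARGIN)

    second_in_frame = _transformed_copy(pair.second, sup)
    model_first = build_pocket_model(pair.first, center, site_radius, spacing, probe)
    model_second = build_pocket_model(second_in_frame, center, site_radius, spacing, probe)

    # orient the comparison apo -> holo when the states differ; otherwise the
    # first structure plays the "before" role
    if pair.first.state == "holo" and pair.second.state == "apo":
        apo_model, holo_model = model_second, model_first
    else:
        apo_model, holo_model = model_first, model_second
    analysis.apo_model = apo_model
    analysis.holo_model = holo_model
    record.vol_apo = apo_model.volume
    record.vol_holo = holo_model.volume
    record.pocket_class = classify_pocket_motion(
        profile, apo_model, holo_model, params, ligand_coords=lig_coords
    )
    return analysis
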