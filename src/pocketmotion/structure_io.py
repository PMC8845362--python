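"""Reading, filtering and pairing of crystal structures.

PDB / mmCIF parsing is delegated to gemmi; this module converts parsed files
into the domain model, applies the corpus filters (resolution better than the
cutoff, monomer or homo-multimer only, crystallographic additives removed),
derives the apo/holo state, and builds the residue correspondence between two
structures of the same protein.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
from Bio import Align

from .structures import (
    APO_APO,
    APO_HOLO,
    HOLO_HOLO_DIFF,
    HOLO_HOLO_SAME,
    STANDARD_AA,
    WATER_NAMES,
    Atom,
    Ligand,
    Residue,
    Structure,
    StructurePair,
)

logger = logging.getLogger(__name__)

#: Minimum heavy-atom count for a HETATM group to count as a real ligand.
#: Single atoms and very small fragments (ions, waterlike species) do not
#: define the holo state by default.
MIN_LIGAND_ATOMS = 4

#: Minimum number of mapped residues for a usable pair.
MIN_MAPPED_RESIDUES = 30


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


class PairingError(ValueError):
    """Raised when two structures share too little common structure."""


def load_additive_list(path: str | Path) -> frozenset[str]:
    """Read an additive exclusion list: one component code per line, '#' comments."""
    codes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if line:
            codes.add(line)
    return frozenset(codes | WATER_NAMES)


def default_additives() -> frozenset[str]:
    """The shipped additive list (common PEGs, cryoprotectants, buffer ions)."""
    ref = resources.files("pocketmotion").joinpath("data/additives.txt")
    with resources.as_file(ref) as p:
        return load_additive_list(p)


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or (a.occupancy, _neg_altloc(a.altloc)) > (
            prev.occupancy,
            _neg_altloc(prev.altloc),
        ):
            by_name[a.name] = a
    return list(by_name.values())


def _neg_altloc(altloc: str) -> tuple[int, ...]:
    # lexicographically earlier altloc wins a tie -> compare on negated bytes
    return tuple(-ord(c) for c in altloc)


def parse_structure(
    path: str | Path,
    additive_list: Optional[Iterable[str]] = None,
    min_ligand_atoms: int = MIN_LIGAND_ATOMS,
    structure_id: Optional[str] = None,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens are dropped, alternate locations collapsed to the
    highest-occupancy conformer, waters and listed additives removed from the
    ligand set, and HETATM groups below ``min_ligand_atoms`` heavy atoms
    discarded so that ions never flip a structure to holo.
    """
    additives = (
        frozenset(c.upper() for c in additive_list) | WATER_NAMES
        if additive_list is not None
        else default_additives()
    )
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - message depends on gemmi
        raise StructureError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: file contains no model")
    st.setup_entities()
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    ligands: list[Ligand] = []
    n_nonstandard = 0
    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc or "",
                        is_hetero=res.het_flag == "H",
                    )
                )
            atoms = _collapse_altlocs(atoms)
            if not atoms:
                continue
            name = res.name.upper()
            if name in STANDARD_AA:
                chains.setdefault(chain.name, []).append(
                    Residue(
                        chain_id=chain.name,
                        seq_id=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        res_name=name,
                        atoms=atoms,
                    )
                )
            elif name in additives:
                continue
            elif res.entity_type == gemmi.EntityType.Polymer:
                # modified / non-standard polymer residue: not part of the
                # 20-residue statistics and never a ligand
                n_nonstandard += 1
            else:
                if len(atoms) < min_ligand_atoms:
                    logger.debug("%s: dropping small hetero group %s (%d atoms)",
                                 path, name, len(atoms))
                    continue
                ligands.append(
                    Ligand(comp_id=name, chain_id=chain.name, seq_id=res.seqid.num, atoms=atoms)
                )
    if n_nonstandard:
        logger.info("%s: skipped %d non-standard polymer residues", path, n_nonstandard)
    if not chains:
        raise StructureError(f"{path}: no protein residues after filtering")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return Structure(
        id=structure_id or (st.name or Path(path).stem),
        chains=chains,
        ligands=ligands,
        resolution=resolution,
    )


def check_resolution(s: Structure, cutoff: float = 3.0) -> bool:
    """True iff the resolution is recorded and strictly better (lower) than ``cutoff``."""
    if s.resolution is None:
        logger.info("structure %s: no recorded resolution, rejected", s.id)
        return False
    return s.resolution < cutoff


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity, normalised by the longer sequence."""
    if not seq_a or not seq_b:
        return 0.0
    if seq_a == seq_b:
        return 1.0
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=0.0,
        extend_gap_score=0.0,
    )
    matches = aligner.score(seq_a, seq_b)
    return float(matches) / max(len(seq_a), len(seq_b))


def classify_oligomer(s: Structure, identity_threshold: float = 0.95) -> str:
    """``monomer`` (one chain), ``homo-multimer`` (all chains near-identical) or ``hetero``."""
    chain_ids = list(s.chains)
    if not chain_ids:
        raise StructureError(f"{s.id}: no protein chains")
    if len(chain_ids) == 1:
        return "monomer"
    seqs = [s.chain_sequence(c) for c in chain_ids]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if sequence_identity(seqs[i], seqs[j]) < identity_threshold:
                return "hetero"
    return "homo-multimer"


def _match_chains(a: Structure, b: Structure) -> list[tuple[str, str]]:
    """Greedy one-to-one chain assignment by descending sequence identity."""
    scored = []
    for ca in a.chains:
        for cb in b.chains:
            scored.append((sequence_identity(a.chain_sequence(ca), b.chain_sequence(cb)), ca, cb))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out = []
    for ident, ca, cb in scored:
        if ident <= 0.0 or ca in used_a or cb in used_b:
            continue
        out.append((ca, cb))
        used_a.add(ca)
        used_b.add(cb)
    return out


def _map_by_numbering(res_a: list[Residue], res_b: list[Residue]) -> list[tuple[Residue, Residue]]:
    index_b = {(r.seq_id, r.icode): r for r in res_b}
    return [(ra, index_b[(ra.seq_id, ra.icode)]) for ra in res_a if (ra.seq_id, ra.icode) in index_b]


def _map_by_alignment(res_a: list[Residue], res_b: list[Residue]) -> list[tuple[Residue, Residue]]:
    from .structures import THREE_TO_ONE

    seq_a = "".join(THREE_TO_ONE.get(r.res_name, "X") for r in res_a)
    seq_b = "".join(THREE_TO_ONE.get(r.res_name, "X") for r in res_b)
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2.0,
        mismatch_score=-1.0,
        open_gap_score=-5.0,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (sa, ea), (sb, _eb) in zip(aln.aligned[0], aln.aligned[1]):
        for off in range(ea - sa):
            pairs.append((res_a[sa + off], res_b[sb + off]))
    return pairs


def build_residue_map(a: Structure, b: Structure) -> list[tuple[Residue, Residue]]:
    """Residue correspondence: matched chains, then author numbering, with a
    sequence-alignment fallback when the numbering schemes disagree."""
    mapping: list[tuple[Residue, Residue]] = []
    for ca, cb in _match_chains(a, b):
        res_a, res_b = a.chains[ca], b.chains[cb]
        pairs = _map_by_numbering(res_a, res_b)
        if len(pairs) < 0.5 * min(len(res_a), len(res_b)):
            pairs = _map_by_alignment(res_a, res_b)
        mapping.extend(pairs)
    return mapping


def pair_category(a: Structure, b: Structure) -> str:
    if a.state == "apo" and b.state == "apo":
        return APO_APO
    if a.state != b.state:
        return APO_HOLO
    comp_a = {l.comp_id for l in a.ligands}
    comp_b = {l.comp_id for l in b.ligands}
    return HOLO_HOLO_SAME if comp_a & comp_b else HOLO_HOLO_DIFF


def build_pair(a: Structure, b: Structure, min_mapped: int = MIN_MAPPED_RESIDUES) -> StructurePair:
    """Pair two structures of the same protein.

    The caller is responsible for having applied the resolution and oligomer
    filters; this function only maps residues and assigns the category.
    """
    mapping = build_residue_map(a, b)
    if len(mapping) < min_mapped:
        raise PairingError(
            f"{a.id} / {b.id}: only {len(mapping)} mapped residues (< {min_mapped})"
        )
    return StructurePair(first=a, second=b, category=pair_category(a, b), residue_map=mapping)


# ---------------------------------------------------------------------------
# writing


def to_gemmi(s: Structure, model_num: int = 1) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    if s.resolution is not None:
        st.resolution = s.resolution
    model = gemmi.Model(model_num)
    lig_by_chain: dict[str, list[Ligand]] = {}
    for lig in s.ligands:
        lig_by_chain.setdefault(lig.chain_id, []).append(lig)
    chain_ids = list(s.chains) + [c for c in lig_by_chain if c not in s.chains]
    for cid in chain_ids:
        chain = gemmi.Chain(cid)
        for res in s.chains.get(cid, []):
            chain.add_residue(_gemmi_residue(res.res_name, res.seq_id, res.icode, res.atoms, "A"))
        for lig in lig_by_chain.get(cid, []):
            chain.add_residue(_gemmi_residue(lig.comp_id, lig.seq_id, "", lig.atoms, "H"))
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _gemmi_residue(name: str, seq_id: int, icode: str, atoms: list[Atom], het_flag: str) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(seq_id, icode or " ")
    res.het_flag = het_flag
    for a in atoms:
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = a.occupancy
        at.altloc = "\0" if not a.altloc else a.altloc
        res.add_atom(at)
    return res


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a structure back to PDB (coordinates to the format's 3 decimals)."""
    st = to_gemmi(s)
    st.write_pdb(str(path))


def write_pair_pdb(pair: StructurePair, path: str | Path, transform=None) -> None:
    """Write an aligned pair as a two-model PDB (model 1 = first, model 2 = second).

    ``transform`` is an optional superposition result whose ``apply`` maps the
    second member's coordinates into the first member's frame.
    """
    second = pair.second
    if transform is not None:
        second = second.copy()
        for res in second.residues():
            for a in res.atoms:
                a.coords = transform.apply(a.coords[None, :])[0]
        for lig in second.ligands:
            for a in lig.atoms:
                a.coords = transform.apply(a.coords[None, :])[0]
    st = to_gemmi(pair.first, model_num=1)
    st2 = to_gemmi(second, model_num=2)
    st.add_model(st2[0])
    st.write_pdb(str(path))
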