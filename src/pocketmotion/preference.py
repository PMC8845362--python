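"""Amino-acid composition of binding pockets versus the overall structure.

For a corpus of holo structures, the frequency of each of the 20 standard
amino acids is counted over whole structures and over pocket residues at a
series of distance cutoffs.  The mean unsigned error (MUE) between a pocket
frequency vector and the overall vector,

    MUE(c) = (1/20) * sum_aa | f_pocket,c(aa) - f_overall(aa) |,

identifies the cutoff at which pocket composition is most distinct.  Residues
enriched in pockets at 3.0 Å (short-range interactors) or at 5.0 Å
(long-range interactors) are "pocketphilic"; residues depleted at both
cutoffs are "pocketphobic".  Enrichment per amino acid is tested with a
two-sided two-proportion z-test (pooled variance, no continuity correction),
which is equivalent to a 2x2 Pearson chi-square.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .motion import POCKET_RMSD_THRESHOLD, MotionRecord
from .pocket import pocket_residues
from .structures import AA_ORDER, Structure

logger = logging.getLogger(__name__)

POCKETPHILIC = "pocketphilic"
POCKETPHOBIC = "pocketphobic"


@dataclass
class FrequencyTable:
    """Counts and frequencies of the 20 standard amino acids in one context."""

    counts: dict[str, int]
    context: str
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {aa: int(self.counts.get(aa, 0)) for aa in AA_ORDER}
        self.n_total = sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        if self.n_total == 0:
            return {aa: 0.0 for aa in AA_ORDER}
        return {aa: c / self.n_total for aa, c in self.counts.items()}

    def freq_vector(self) -> np.ndarray:
        f = self.freqs
        return np.array([f[aa] for aa in AA_ORDER])


def residue_frequencies(
    structures: Sequence[Structure],
    pocket_cutoff: Optional[float] = None,
) -> FrequencyTable:
    """Amino-acid frequencies over a corpus.

    With ``pocket_cutoff=None`` every standard residue of every structure is
    counted once per occurrence.  With a cutoff, only residues within that
    distance of a ligand count (union over the structure's ligands), and every
    structure must be holo.  Non-standard residues are excluded and logged.
    """
    if not structures:
        raise ValueError("empty corpus")
    counts = {aa: 0 for aa in AA_ORDER}
    n_nonstandard = 0
    for s in structures:
        if pocket_cutoff is None:
            keys = {r.key for r in s.residues()}
        else:
            if s.state != "holo":
                raise ValueError(f"structure {s.id} is apo: pocket context requires holo")
            keys = set()
            for lig in s.ligands:
                keys |= pocket_residues(s, lig, cutoff=pocket_cutoff).residues
        by_key = {r.key: r for r in s.residues()}
        for k in keys:
            res = by_key[k]
            if res.is_standard:
                counts[res.res_name] += 1
            else:  # pragma: no cover - parser already drops non-standard residues
                n_nonstandard += 1
    if n_nonstandard:
        logger.info("excluded %d non-standard residues from frequency table", n_nonstandard)
    context = "overall" if pocket_cutoff is None else f"pocket({pocket_cutoff:g} A)"
    table = FrequencyTable(counts=counts, context=context)
    if table.n_total == 0:
        logger.warning("frequency table %s is empty (degenerate cutoff?)", context)
    return table


def mue(table_a: FrequencyTable, table_b: FrequencyTable) -> float:
    """Mean unsigned error between two frequency vectors over the 20 amino acids."""
    if set(table_a.counts) != set(table_b.counts):
        raise ValueError("frequency tables use different amino-acid universes")
    return float(np.abs(table_a.freq_vector() - table_b.freq_vector()).mean())


def mue_profile(
    overall: FrequencyTable, pockets: dict[float, FrequencyTable]
) -> dict[float, float]:
    """MUE against the overall composition for each pocket cutoff."""
    return {cutoff: mue(tab, overall) for cutoff, tab in pockets.items()}


def test_frequency_difference(
    aa: str, overall: FrequencyTable, pocket: FrequencyTable
) -> float:
    """Two-sided two-proportion z-test p-value for one amino acid's frequency."""
    if overall.n_total == 0 or pocket.n_total == 0:
        raise ValueError("both tables need n_total > 0")
    k1, n1 = pocket.counts[aa], pocket.n_total
    k2, n2 = overall.counts[aa], overall.n_total
    if k1 == 0 and k2 == 0:
        warnings.warn(f"{aa}: zero counts in both contexts, p-value set to 1")
        return 1.0
    if k1 == n1 and k2 == n2:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    if np.isnan(p):  # degenerate pooled proportion
        return 1.0
    return float(p)


def classify_philic_phobic(freq_overall: float, freq_3a: float, freq_5a: float) -> str:
    """Pocketphobic iff depleted at both 3.0 and 5.0 Å; otherwise pocketphilic."""
    if freq_3a < freq_overall and freq_5a < freq_overall:
        return POCKETPHOBIC
    return POCKETPHILIC


def preference_table(
    overall: FrequencyTable,
    pocket_3a: FrequencyTable,
    pocket_5a: FrequencyTable,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-amino-acid preference summary (frequencies, p-values, label).

    ``bonferroni=True`` multiplies p-values by 20 (capped at 1); the default
    reports raw per-test p-values.
    """
    rows = []
    fo, f3, f5 = overall.freqs, pocket_3a.freqs, pocket_5a.freqs
    for aa in AA_ORDER:
        p3 = test_frequency_difference(aa, overall, pocket_3a)
        p5 = test_frequency_difference(aa, overall, pocket_5a)
        if bonferroni:
            p3, p5 = min(1.0, 20 * p3), min(1.0, 20 * p5)
        rows.append(
            {
                "aa": aa,
                "freq_overall": fo[aa],
                "freq_3A": f3[aa],
                "freq_5A": f5[aa],
                "p_3A": p3,
                "p_5A": p5,
                "label": classify_philic_phobic(fo[aa], f3[aa], f5[aa]),
            }
        )
    return pd.DataFrame(rows)


def motion_frequency_by_residue(
    records: Sequence[MotionRecord],
    class_filter: Optional[str] = None,
    normalize: str = "per_residue",
) -> dict[str, float]:
    """How often each amino acid moves when it lines a pocket.

    ``normalize="per_residue"``: for each amino acid, the fraction of its
    pocket occurrences with RMSD above 2.0 Å.  ``normalize="all_moving"``:
    each amino acid's share of all moving pocket residues.  ``class_filter``
    restricts to records of one pocket-motion class.
    """
    if normalize not in ("per_residue", "all_moving"):
        raise ValueError(f"unknown normalization {normalize!r}")
    total = {aa: 0 for aa in AA_ORDER}
    moving = {aa: 0 for aa in AA_ORDER}
    for rec in records:
        if class_filter is not None and rec.pocket_class != class_filter:
            continue
        for _rid, aa, rmsd in rec.pocket_residues:
            if aa not in total:
                continue
            total[aa] += 1
            if rmsd > POCKET_RMSD_THRESHOLD:
                moving[aa] += 1
    if normalize == "per_residue":
        return {aa: (moving[aa] / total[aa] if total[aa] else 0.0) for aa in AA_ORDER}
    n_moving = sum(moving.values())
    return {aa: (moving[aa] / n_moving if n_moving else 0.0) for aa in AA_ORDER}


def plot_preference(table: pd.DataFrame, path) -> None:
    """Grouped bar chart of overall vs pocket frequencies per amino acid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(table))
    width = 0.27
    fig, ax = plt.subplots(figsize=(11, 4))
    ax.bar(x - width, table["freq_overall"], width, label="overall", color="#4878d0")
    ax.bar(x, table["freq_3A"], width, label="pocket 3.0 Å", color="#ee854a")
    ax.bar(x + width, table["freq_5A"], width, label="pocket 5.0 Å", color="#6acc64")
    ax.set_xticks(x)
    ax.set_xticklabels(table["aa"], rotation=45)
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
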