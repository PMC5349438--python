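"""Ligand-occupancy census over a collection of structures.

How are ligands in deposited structures actually modelled?  For each
structure, the first instance of each ligand chemical code is kept; codes
with fewer than five non-hydrogen atoms, or appearing in more than fifty
structures, are excluded (small and ubiquitous molecules — ions, buffers,
cryoprotectants — would otherwise dominate).  Where a ligand has alternate
conformers, its *total* occupancy over the conformers is used.  The
remaining instances are classified by occupancy and by the presence of a
conformer ID; over-unitary totals are counted, never clamped — they are a
real (and worrying) feature of deposited models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .model import WATER_NAMES, StructureModel

__all__ = ["CensusRecord", "CensusSummary", "census", "classify", "CLASSES"]

#: standard polymer residues never counted as ligands
STANDARD_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
    TYR VAL MSE SEC PYL A C G U DA DC DG DT DU""".split()
) | WATER_NAMES

CLASSES = (
    "unitary_no_altloc",
    "partial_no_altloc",
    "with_altloc_sum_unitary",
    "with_altloc_partial",
    "over_unitary",
)

UNITY_TOL = 1e-6
HISTOGRAM_BIN = 0.05


@dataclass
class CensusRecord:
    """One ligand instance with its occupancy bookkeeping."""

    structure_id: str
    ligand_code: str
    total_occupancy: float
    has_altloc: bool
    n_non_h_atoms: int
    excluded_reason: str = "none"  # none | small_ligand | common_ligand | duplicate_instance

    @property
    def excluded(self) -> bool:
        return self.excluded_reason != "none"


@dataclass
class CensusSummary:
    """Aggregate view: class counts, occupancy histogram, exclusions."""

    class_counts: dict[str, int]
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    n_over_unitary: int
    n_excluded: dict[str, int]
    n_kept: int

    def as_dict(self) -> dict:
        return {
            "class_counts": dict(self.class_counts),
            "n_over_unitary": self.n_over_unitary,
            "n_excluded": dict(self.n_excluded),
            "n_kept": self.n_kept,
        }


def classify(record: CensusRecord) -> str:
    """Occupancy/altloc class of a non-excluded census record."""
    if record.excluded:
        raise ValueError(f"record {record.ligand_code} is excluded ({record.excluded_reason})")
    occ = record.total_occupancy
    if occ > 1 + UNITY_TOL:
        return "over_unitary"
    unitary = abs(occ - 1.0) <= UNITY_TOL
    if record.has_altloc:
        return "with_altloc_sum_unitary" if unitary else "with_altloc_partial"
    return "unitary_no_altloc" if unitary else "partial_no_altloc"


def _ligand_records(structure_id: str, model: StructureModel, exclude: frozenset):
    """CensusRecords for each ligand residue of one structure, in file order."""
    out = []
    for (_chain, _seq, _icode), atoms in model.residues().items():
        res_name = atoms[0].res_name
        if res_name in exclude:
            continue
        if not atoms[0].is_hetero:
            continue
        non_h = {a.name for a in atoms if a.element.upper() not in ("H", "D")}
        # total occupancy over conformers: each conformer contributes its
        # atoms' mean occupancy once
        by_alt: dict[str, list[float]] = {}
        for a in atoms:
            by_alt.setdefault(a.altloc, []).append(a.occupancy)
        total = float(sum(np.mean(v) for v in by_alt.values()))
        out.append(
            CensusRecord(
                structure_id=structure_id,
                ligand_code=res_name,
                total_occupancy=total,
                has_altloc=any(alt for alt in by_alt),
                n_non_h_atoms=len(non_h),
            )
        )
    return out


def census(
    structures: Iterable[tuple[str, StructureModel]],
    common_threshold: int = 50,
    min_atoms: int = 5,
    exclude_residues: frozenset = STANDARD_RESIDUES,
) -> tuple[list[CensusRecord], CensusSummary]:
    """Apply the three census filter rules and classify the survivors.

    Rules, in order: (1) only the first instance (file order) of each ligand
    code per structure; (2) drop codes with fewer than ``min_atoms`` non-H
    atoms; (3) drop codes whose kept-instance count across the whole
    collection exceeds ``common_threshold``.  Returns every record (excluded
    ones carry their reason) plus the aggregate summary.
    """
    records: list[CensusRecord] = []
    for structure_id, model in structures:
        seen: set[str] = set()
        for rec in _ligand_records(structure_id, model, exclude_residues):
            if rec.ligand_code in seen:
                rec.excluded_reason = "duplicate_instance"
            else:
                seen.add(rec.ligand_code)
            records.append(rec)
    for rec in records:
        if rec.excluded_reason == "none" and rec.n_non_h_atoms < min_atoms:
            rec.excluded_reason = "small_ligand"
    counts: dict[str, int] = {}
    for rec in records:
        if rec.excluded_reason == "none":
            counts[rec.ligand_code] = counts.get(rec.ligand_code, 0) + 1
    for rec in records:
        if rec.excluded_reason == "none" and counts[rec.ligand_code] > common_threshold:
            rec.excluded_reason = "common_ligand"

    kept = [r for r in records if not r.excluded]
    class_counts = {c: 0 for c in CLASSES}
    for r in kept:
        class_counts[classify(r)] += 1
    occs = np.array([r.total_occupancy for r in kept]) if kept else np.zeros(0)
    top = max(1.0, float(occs.max()) if len(occs) else 1.0)
    edges = np.arange(0.0, top + HISTOGRAM_BIN, HISTOGRAM_BIN)
    hist, edges = np.histogram(occs, bins=edges) if len(occs) else (np.zeros(len(edges) - 1, int), edges)
    n_excl: dict[str, int] = {}
    for r in records:
        if r.excluded:
            n_excl[r.excluded_reason] = n_excl.get(r.excluded_reason, 0) + 1
    summary = CensusSummary(
        class_counts=class_counts,
        histogram_edges=edges,
        histogram_counts=hist,
        n_over_unitary=class_counts["over_unitary"],
        n_excluded=n_excl,
        n_kept=len(kept),
    )
    return records, summary


def plot_census(summary: CensusSummary, out_path: str) -> None:
    """Occupancy histogram figure (SVG) with an inset for sub-unitary bins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (summary.histogram_edges[:-1] + summary.histogram_edges[1:])
    ax.bar(centers, summary.histogram_counts, width=HISTOGRAM_BIN * 0.9)
    ax.set_xlabel("total ligand occupancy")
    ax.set_ylabel("ligand instances")
    sub = centers < 1.0 - HISTOGRAM_BIN / 2
    if np.any(sub) and summary.histogram_counts[sub].sum() > 0:
        inset = ax.inset_axes([0.15, 0.45, 0.45, 0.45])
        inset.bar(centers[sub], summary.histogram_counts[sub], width=HISTOGRAM_BIN * 0.9)
        inset.set_title("sub-unitary", fontsize=8)
    fig.savefig(out_path, format="svg", bbox_inches="tight")
    plt.close(fig)
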