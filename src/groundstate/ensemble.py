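"""Build ground+bound multi-conformer ensembles with sum-to-unity occupancies.

A crystal soaked with a partially occupied ligand is a superposition: a
fraction ``q`` of unit cells holds the ligand-bound state, the remaining
``1-q`` the ground state (which may contain substrate mimetics, ordered
solvent or alternate side chains).  Both states are placed in one model by
labelling state-specific atoms with conformer IDs *not used anywhere else in
the structure* — with alternate conformers A and B in use elsewhere, all
ground-only atoms become conformer C and all bound-only atoms conformer D —
and constraining the two groups' occupancies to sum to unity in refinement.
The labelling is applied only to the region affected by binding, so either
state can later be recovered by selecting its conformer.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import AtomRecord, CapacityError, StructureModel, select

__all__ = [
    "EnsembleModel",
    "OccupancyConstraintSet",
    "EnsembleReport",
    "LabellingError",
    "BranchingError",
    "find_unused_conformer_ids",
    "identify_binding_region",
    "merge_states",
    "extract_state",
    "build_occupancy_groups",
    "bound_only_model",
    "ground_only_model",
    "validate_ensemble",
    "write_refmac_constraints",
    "write_phenix_constraints",
]

#: occupancy assigned to the bound state when it is refined without a
#: superposed ground state; sub-unitary to trigger automated occupancy
#: refinement in the refinement program
BOUND_ONLY_OCCUPANCY = 0.95

DEFAULT_PROXIMITY_RADIUS = 5.0  # A, first contact shell around the ligand
DEFAULT_MOVE_TOL = 0.5  # A, displacement marking a reordered residue
DEFAULT_IDENTITY_TOL = 0.05  # A, below this a matched atom is "the same atom"


class LabellingError(ValueError):
    """Conformer-ID collision or inconsistent state labelling."""


class BranchingError(ValueError):
    """A state carries more than one conformer for a residue; the single-
    conformer-per-state merge semantics cannot represent this."""


@dataclass
class EnsembleModel:
    """Merged two-state model with its state-to-conformer mapping."""

    model: StructureModel
    state_map: dict[str, str]
    region: set[tuple[str, int]]
    initial_bound_occupancy: float = 0.5

    def __post_init__(self) -> None:
        if set(self.state_map) != {"ground", "bound"}:
            raise ValueError("state_map must have exactly the keys 'ground' and 'bound'")
        ids = list(self.state_map.values())
        if len(set(ids)) != 2 or any(len(i) != 1 for i in ids):
            raise ValueError(f"state conformer IDs must be two distinct characters, got {ids}")

    def state_atoms(self, state: str) -> list[AtomRecord]:
        cid = self.state_map[state]
        return [a for a in self.model.atoms if a.altloc == cid]


@dataclass
class OccupancyConstraintSet:
    """Two disjoint refinement selections whose occupancies sum to unity.

    Selections are per-residue-per-conformer: (chain, res_seq, altloc).
    """

    ground_selection: list[tuple[str, int, str]]
    bound_selection: list[tuple[str, int, str]]
    initial_bound_occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_bound_occupancy < 1.0:
            raise ValueError(
                f"initial bound occupancy {self.initial_bound_occupancy} outside (0, 1)"
            )
        if set(self.ground_selection) & set(self.bound_selection):
            raise ValueError("occupancy groups overlap")


# ------------------------------------------------------------------ labelling

def find_unused_conformer_ids(
    ground: StructureModel, bound: StructureModel, n: int = 2
) -> tuple[str, ...]:
    """First ``n`` letters A, B, C, ... used as altloc in neither model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    used = ground.altlocs_used() | bound.altlocs_used()
    free = [c for c in string.ascii_uppercase if c not in used]
    if len(free) < n:
        raise CapacityError(f"alphabet exhausted: only {len(free)} unused conformer IDs")
    return tuple(free[:n])


def _atom_index(model: StructureModel) -> dict[tuple, AtomRecord]:
    return {(a.chain, a.res_seq, a.icode, a.name, a.altloc): a for a in model.atoms}


def identify_binding_region(
    ground: StructureModel,
    bound: StructureModel,
    proximity_radius: float = DEFAULT_PROXIMITY_RADIUS,
    move_tol: float = DEFAULT_MOVE_TOL,
) -> set[tuple[str, int]]:
    """Residues affected by binding.

    The region is the union of (i) residues containing any bound-only atom
    (the ligand itself), (ii) residues of either model with any atom within
    ``proximity_radius`` of a bound-only atom (the contact shell, including
    displaced ground-state solvent), and (iii) residues whose matched atoms
    move by more than ``move_tol`` between the models (reordered side
    chains).  Distances are plain Cartesian: toy and real binding sites are
    compact within the cell.
    """
    gidx = _atom_index(ground)
    bidx = _atom_index(bound)
    region: set[tuple[str, int]] = set()

    bound_only = [a for a in bound.atoms if (a.chain, a.res_seq, a.icode, a.name, a.altloc) not in gidx]
    for a in bound_only:
        region.add((a.chain, a.res_seq))
    if bound_only:
        pos = np.array([a.pos for a in bound_only])
        for model in (ground, bound):
            for (chain, res_seq, _icode), atoms in model.residues().items():
                if (chain, res_seq) in region:
                    continue
                xyz = np.array([a.pos for a in atoms])
                d2 = ((xyz[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
                if np.min(d2) <= proximity_radius**2:
                    region.add((chain, res_seq))
    for key, ga in gidx.items():
        ba = bidx.get(key)
        if ba is not None and np.linalg.norm(ga.pos - ba.pos) > move_tol:
            region.add((key[0], key[1]))
    if not region:
        warnings.warn("no bound-only atoms and no displaced residues: empty binding region")
    return region


def _check_single_conformer(model: StructureModel, region: set, label: str) -> None:
    for key, recs in model.sites().items():
        if (key[0], key[1]) in region and len(recs) > 1:
            raise BranchingError(
                f"{label} model has {len(recs)} conformers at site {key}; "
                "single-conformer-per-state merging cannot represent branching"
            )


def merge_states(
    ground: StructureModel,
    bound: StructureModel,
    region: set[tuple[str, int]] | None = None,
    initial_bound_occupancy: float = 0.5,
    *,
    proximity_radius: float = DEFAULT_PROXIMITY_RADIUS,
    move_tol: float = DEFAULT_MOVE_TOL,
    identity_tol: float = DEFAULT_IDENTITY_TOL,
    conformer_ids: tuple[str, str] | None = None,
) -> EnsembleModel:
    """Combine a ground-state and a bound-state model into one ensemble.

    Outside the binding region the bound model is taken unchanged.  Inside
    it, atoms matched between the models within ``identity_tol`` stay single
    (bound copy wins; refinement jitter must not split atoms); ground-only
    atoms get the ground conformer ID at occupancy ``1-q``; bound-only atoms
    the bound conformer ID at occupancy ``q``, with
    ``q = initial_bound_occupancy``.  Pre-existing altlocs elsewhere are
    untouched.
    """
    q = initial_bound_occupancy
    if not 0.0 < q < 1.0:
        raise ValueError(f"initial bound occupancy {q} outside (0, 1)")
    if region is None:
        region = identify_binding_region(ground, bound, proximity_radius, move_tol)
    if conformer_ids is None:
        conformer_ids = find_unused_conformer_ids(ground, bound, 2)
    ground_id, bound_id = conformer_ids
    used = ground.altlocs_used() | bound.altlocs_used()
    for cid in (ground_id, bound_id):
        if cid in used:
            raise LabellingError(f"conformer ID {cid!r} already used in a source model")
    _check_single_conformer(ground, region, "ground")
    _check_single_conformer(bound, region, "bound")

    gidx = _atom_index(ground)
    bidx = _atom_index(bound)
    atoms: list[AtomRecord] = []
    for a in bound.atoms:
        key = (a.chain, a.res_seq, a.icode, a.name, a.altloc)
        if (a.chain, a.res_seq) not in region:
            atoms.append(a.copy())
            continue
        ga = gidx.get(key)
        if ga is not None and np.linalg.norm(ga.pos - a.pos) <= identity_tol:
            atoms.append(a.copy())  # shared atom, stays single (blank altloc)
        else:
            atoms.append(a.copy(altloc=bound_id, occupancy=q))
    for a in ground.atoms:
        if (a.chain, a.res_seq) not in region:
            continue
        key = (a.chain, a.res_seq, a.icode, a.name, a.altloc)
        ba = bidx.get(key)
        if ba is not None and np.linalg.norm(ba.pos - a.pos) <= identity_tol:
            continue  # represented by the shared (bound) copy
        atoms.append(a.copy(altloc=ground_id, occupancy=1.0 - q))

    merged = StructureModel(atoms=atoms, cell=bound.cell, spacegroup=bound.spacegroup)
    return EnsembleModel(
        model=merged,
        state_map={"ground": ground_id, "bound": bound_id},
        region=set(region),
        initial_bound_occupancy=q,
    )


def extract_state(ensemble: EnsembleModel, state: str) -> StructureModel:
    """Recover one state from the ensemble by conformer selection.

    Atoms of the other state's conformer are removed; shared atoms and
    altlocs unrelated to binding are kept.  A state-conformer atom whose site
    has no remaining sibling conformers gets its altloc cleared, restoring a
    plain single-conformer model.
    """
    if state not in ("ground", "bound"):
        raise ValueError(f"unknown state {state!r}; expected 'ground' or 'bound'")
    keep_id = ensemble.state_map[state]
    drop_id = ensemble.state_map["bound" if state == "ground" else "ground"]
    kept = [a for a in ensemble.model.atoms if a.altloc != drop_id]
    sites: dict[tuple, int] = {}
    for a in kept:
        sites[a.site_key] = sites.get(a.site_key, 0) + 1
    out = []
    for a in kept:
        if a.altloc == keep_id and sites[a.site_key] == 1:
            out.append(a.copy(altloc=""))
        else:
            out.append(a.copy())
    return StructureModel(
        atoms=out, cell=ensemble.model.cell, spacegroup=ensemble.model.spacegroup
    )


# ------------------------------------------------------------------ occupancy groups

def _residue_selection(atoms: list[AtomRecord]) -> list[tuple[str, int, str]]:
    seen = []
    for a in atoms:
        key = (a.chain, a.res_seq, a.altloc)
        if key not in seen:
            seen.append(key)
    return sorted(seen)


def build_occupancy_groups(ensemble: EnsembleModel) -> OccupancyConstraintSet:
    """Sum-to-unity occupancy constraint groups for the two states."""
    g_atoms = ensemble.state_atoms("ground")
    b_atoms = ensemble.state_atoms("bound")
    if not g_atoms or not b_atoms:
        raise LabellingError("ensemble must contain atoms of both state conformers")
    for a in g_atoms + b_atoms:
        if (a.chain, a.res_seq) not in ensemble.region:
            raise LabellingError(
                f"state-labelled atom {a.chain}/{a.res_seq}/{a.name} lies outside "
                "the binding region; labelling is inconsistent"
            )
    return OccupancyConstraintSet(
        ground_selection=_residue_selection(g_atoms),
        bound_selection=_residue_selection(b_atoms),
        initial_bound_occupancy=ensemble.initial_bound_occupancy,
    )


def bound_only_model(ensemble: EnsembleModel) -> StructureModel:
    """Bound state alone, at occupancy 0.95 to trigger occupancy refinement.

    This is the conventional single-state modelling path: the superposed
    ground state is discarded and only the formerly bound-conformer atoms
    keep a sub-unitary occupancy.
    """
    model = extract_state(ensemble, "bound")
    bound_keys = {
        (a.chain, a.res_seq, a.icode, a.name)
        for a in ensemble.state_atoms("bound")
    }
    for a in model.atoms:
        if (a.chain, a.res_seq, a.icode, a.name) in bound_keys:
            a.occupancy = BOUND_ONLY_OCCUPANCY
    return model


def ground_only_model(ensemble: EnsembleModel) -> StructureModel:
    """Ground state alone at occupancy 1.0 (the normal no-ligand model)."""
    model = extract_state(ensemble, "ground")
    ground_keys = {
        (a.chain, a.res_seq, a.icode, a.name)
        for a in ensemble.state_atoms("ground")
    }
    for a in model.atoms:
        if (a.chain, a.res_seq, a.icode, a.name) in ground_keys:
            a.occupancy = 1.0
    return model


# ------------------------------------------------------------------ validation

@dataclass
class EnsembleReport:
    """Violation report; empty lists mean a valid ensemble."""

    over_unitary: list[str] = field(default_factory=list)
    collisions: list[str] = field(default_factory=list)
    branching: list[str] = field(default_factory=list)

    def ok(self) -> bool:
        return not (self.over_unitary or self.collisions or self.branching)

    def __str__(self) -> str:
        if self.ok():
            return "ensemble valid: no violations"
        lines = []
        for title, items in (
            ("occupancy sums > 1", self.over_unitary),
            ("conformer-ID collisions", self.collisions),
            ("branching", self.branching),
        ):
            for it in items:
                lines.append(f"{title}: {it}")
        return "\n".join(lines)


def validate_ensemble(ensemble: EnsembleModel) -> EnsembleReport:
    """Report occupancy-sum, collision and branching violations.

    Refinement programs have been observed to permit altloc occupancies that
    sum to more than unity; this check catches exactly that, plus state
    conformer IDs leaking outside the binding region and duplicated
    state conformers at one site (unsupported branching).
    """
    report = EnsembleReport()
    state_ids = set(ensemble.state_map.values())
    for key, recs in ensemble.model.sites().items():
        total = sum(r.occupancy for r in recs)
        if len(recs) > 1 and total > 1 + 1e-6:
            report.over_unitary.append(f"site {key}: occupancy sum {total:.4f}")
        alts = [r.altloc for r in recs]
        dup_states = {a for a in alts if a in state_ids and alts.count(a) > 1}
        for a in sorted(dup_states):
            report.branching.append(f"site {key}: conformer {a} appears {alts.count(a)} times")
    for a in ensemble.model.atoms:
        if a.altloc in state_ids and (a.chain, a.res_seq) not in ensemble.region:
            report.collisions.append(
                f"atom {a.chain}/{a.res_seq}/{a.name}: state conformer {a.altloc} "
                "used outside the binding region"
            )
    return report


# ------------------------------------------------------------------ writers

def write_refmac_constraints(groups: OccupancyConstraintSet, path: str) -> None:
    """REFMAC occupancy keyword file for the sum-to-unity group pair."""
    lines = []
    gid = 0
    for selection in (groups.ground_selection, groups.bound_selection):
        gid += 1
        for chain, res_seq, altloc in selection:
            lines.append(
                f"occupancy group id {gid} chain {chain} residue {res_seq} alt {altloc}"
            )
    lines.append("occupancy group alts complete 1 2")
    lines.append("occupancy refine")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_phenix_constraints(groups: OccupancyConstraintSet, path: str) -> None:
    """Phenix-style parameter block with a constrained occupancy group pair.

    One ``selection`` line per state inside a single ``constrained_group``:
    the refinement program constrains the listed selections' occupancies to
    sum to unity.
    """

    def state_selection(selection: list[tuple[str, int, str]]) -> str:
        clauses = [
            f"(chain {chain} and resseq {res_seq} and altid {altloc})"
            for chain, res_seq, altloc in selection
        ]
        return "          selection = " + " or ".join(clauses)

    lines = ["refinement {", "  refine {", "    occupancies {", "      constrained_group {"]
    lines.append(state_selection(groups.ground_selection))
    lines.append(state_selection(groups.bound_selection))
    lines += ["      }", "    }", "  }", "}"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
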