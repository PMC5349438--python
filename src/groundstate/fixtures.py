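"""Deterministic toy crystals and census collections for offline testing.

The toy "protein" is a zig-zag chain of pseudo-residues (three backbone-like
atoms N/CA/C plus one side-chain-like CB) in a 20-30 A P1 cell: big enough
to give a ligand a 4 A B-factor neighbourhood and a pocket, small enough for
sub-second FFTs.  Four two-state archetypes emulate the recurring
experimental situations:

- ``substrate_overlap``: a strongly bound substrate mimetic occupies the
  site in the ground state; the soaked ligand binds at the same site in a
  perpendicular orientation, with one side chain reordering.
- ``solvent_displacement``: ordered waters in the ground state are displaced
  by the ligand.
- ``sidechain_overlap``: the ligand superposes on the ground-state
  conformation of a side chain, which reorders on binding.
- ``high_occupancy``: solvent displacement at high ligand occupancy, where
  only traces of the ground state remain.

Everything is a pure function of the spec (including its seed), and all
generated models round-trip through the PDB/mmCIF writers.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np

from . import density
from .ensemble import EnsembleModel, identify_binding_region, merge_states
from .model import AtomRecord, StructureModel

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "ARCHETYPES",
    "make_toy_protein",
    "make_two_state_scenario",
    "make_census_fixture",
]

ARCHETYPES = ("substrate_overlap", "solvent_displacement", "sidechain_overlap", "high_occupancy")

CLASH_DISTANCE = 1.0  # A; a ligand closer than this to an immovable atom is invalid


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulated two-state crystal."""

    archetype: str = "substrate_overlap"
    cell_size: float = 22.0
    n_protein_residues: int = 8
    q_true: float = 0.4
    resolution: float = 1.5
    noise_frac: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}")
        if not 0.0 <= self.q_true <= 1.0:
            raise ValueError(f"q_true {self.q_true} outside [0, 1]")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class Scenario:
    """Generated two-state crystal: models, truth ensemble, observed data."""

    spec: ScenarioSpec
    ground: StructureModel
    bound: StructureModel
    ensemble: EnsembleModel
    observed: density.ReflectionSet
    region: set[tuple[str, int]]
    ligand_residue: tuple[str, int]
    ground_residue: tuple[str, int]


def _atom(name, element, res_name, chain, res_seq, pos, occ=1.0, b=15.0, het=False, alt=""):
    return AtomRecord(
        name=name, element=element, altloc=alt, res_name=res_name, chain=chain,
        res_seq=res_seq, pos=np.asarray(pos, float), occupancy=occ, b_factor=b, is_hetero=het,
    )


def make_toy_protein(n_residues: int = 8, cell_size: float = 22.0) -> StructureModel:
    """Zig-zag pseudo-protein chain A with N/CA/C/CB per residue."""
    atoms = []
    for i in range(n_residues):
        base = np.array([4.0 + 1.9 * i, 9.0 + 1.2 * (i % 2), 9.0])
        b = 14.0 + 2.0 * (i % 3)
        seq = i + 1
        atoms += [
            _atom("N", "N", "GLY", "A", seq, base, b=b),
            _atom("CA", "C", "GLY", "A", seq, base + [0.7, 0.9, 0.2], b=b),
            _atom("C", "C", "GLY", "A", seq, base + [1.4, 0.0, 0.4], b=b + 1.0),
            _atom("CB", "C", "GLY", "A", seq, base + [0.7, 0.9, 1.6], b=b + 2.0),
        ]
    cell = (cell_size, cell_size, cell_size, 90.0, 90.0, 90.0)
    return StructureModel(atoms=atoms, cell=cell, spacegroup="P 1")


def _ligand_atoms(center: np.ndarray, axis: np.ndarray, res_name: str, chain: str,
                  b: float = 18.0, occ: float = 1.0) -> list[AtomRecord]:
    """Six-atom rod-like ligand along ``axis`` with a small kink (not
    chemically realistic; geometry only)."""
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    offsets = [-2.8, -1.4, 0.0, 1.4, 2.8]
    elements = ["O", "C", "C", "C", "N"]
    atoms = [
        _atom(f"{el}{i+1}", el, res_name, chain, 1, center + t * axis, occ=occ, b=b)
        for i, (t, el) in enumerate(zip(offsets, elements))
    ]
    atoms.append(_atom("C6", "C", res_name, chain, 1, center + 1.3 * perp, occ=occ, b=b))
    return atoms


def make_two_state_scenario(spec: ScenarioSpec) -> Scenario:
    """Generate ground and bound models, the truth ensemble, and observed data."""
    protein = make_toy_protein(spec.n_protein_residues, spec.cell_size)
    site = np.array([11.0, 11.0, 13.6])  # pocket above the chain
    ground = protein.copy()
    bound = protein.copy()
    ligand_res = ("L", 1)

    pocket_seq = 4  # residue whose CB points toward the pocket
    if spec.archetype == "substrate_overlap":
        ground.atoms += _ligand_atoms(site, np.array([1.0, 0.0, 0.0]), "NOG", "S", b=16.0)
        bound.atoms += _ligand_atoms(site, np.array([0.0, 1.0, 0.0]), "LIG", "L", b=18.0)
        ground_res = ("S", 1)
        _move_sidechain(bound, pocket_seq, np.array([0.9, -0.7, 0.6]))
    elif spec.archetype in ("solvent_displacement", "high_occupancy"):
        for j, off in enumerate([[-1.6, 0.4, 0.1], [0.2, -1.4, 0.3], [1.5, 1.1, -0.2]]):
            ground.atoms.append(
                _atom("O", "O", "HOH", "W", j + 1, site + np.asarray(off), b=22.0, het=True)
            )
        bound.atoms += _ligand_atoms(site, np.array([1.0, 1.0, 0.0]), "LIG", "L", b=18.0)
        ground_res = ("W", 1)
    else:  # sidechain_overlap: ligand sits on the ground-state CB rotamer
        cb_pos = _sidechain_pos(ground, pocket_seq) + np.array([0.3, 0.2, 1.2])
        _set_sidechain(ground, pocket_seq, cb_pos)
        bound.atoms += _ligand_atoms(cb_pos + [0.0, 0.3, 0.9], np.array([0.0, 1.0, 0.2]),
                                     "LIG", "L", b=18.0)
        _move_sidechain(bound, pocket_seq, np.array([-1.2, -0.9, -0.4]))
        ground_res = ("A", pocket_seq)

    # mark hetero flags on ligand/substrate residues
    for m in (ground, bound):
        for a in m.atoms:
            if a.res_name in ("LIG", "NOG"):
                a.is_hetero = True

    _check_clashes(ground, bound)
    region = identify_binding_region(ground, bound)
    q = spec.q_true if 0.0 < spec.q_true < 1.0 else min(max(spec.q_true, 1e-3), 1 - 1e-3)
    ensemble = merge_states(ground, bound, region, initial_bound_occupancy=q)
    observed = density.simulate_two_state(
        ground, bound, spec.q_true, spec.resolution, spec.noise_frac, spec.seed
    )
    return Scenario(
        spec=spec, ground=ground, bound=bound, ensemble=ensemble, observed=observed,
        region=region, ligand_residue=ligand_res, ground_residue=ground_res,
    )


def _sidechain_pos(model: StructureModel, res_seq: int) -> np.ndarray:
    for a in model.atoms:
        if a.chain == "A" and a.res_seq == res_seq and a.name == "CB":
            return a.pos.copy()
    raise KeyError(f"residue A/{res_seq} has no CB")


def _set_sidechain(model: StructureModel, res_seq: int, pos: np.ndarray) -> None:
    for a in model.atoms:
        if a.chain == "A" and a.res_seq == res_seq and a.name == "CB":
            a.pos = np.asarray(pos, float).copy()
            return
    raise KeyError(f"residue A/{res_seq} has no CB")


def _move_sidechain(model: StructureModel, res_seq: int, shift: np.ndarray) -> None:
    _set_sidechain(model, res_seq, _sidechain_pos(model, res_seq) + shift)


def _check_clashes(ground: StructureModel, bound: StructureModel) -> None:
    """Ligand atoms must keep >= 1 A from atoms shared by both states."""
    shared = {
        (a.chain, a.res_seq, a.icode, a.name, a.altloc): a.pos for a in ground.atoms
    }
    immovable = []
    for a in bound.atoms:
        p = shared.get((a.chain, a.res_seq, a.icode, a.name, a.altloc))
        if p is not None and np.linalg.norm(p - a.pos) < 1e-9:
            immovable.append(a.pos)
    if not immovable:
        return
    immovable = np.array(immovable)
    for a in bound.atoms:
        if not a.is_hetero:
            continue
        d = np.linalg.norm(immovable - a.pos, axis=1)
        if np.min(d) < CLASH_DISTANCE:
            raise ValueError(
                f"ligand atom {a.name} clashes with an immovable protein atom "
                f"({np.min(d):.2f} A < {CLASH_DISTANCE} A)"
            )


# ------------------------------------------------------------------ census fixtures

from .census import CLASSES  # noqa: E402


def _ligand_code(i: int) -> str:
    letters = string.ascii_uppercase
    combos = itertools.product(letters, repeat=3)
    return "".join(next(itertools.islice(combos, i, None)))


def _census_ligand(code: str, cls: str, rng: np.random.Generator) -> list[AtomRecord]:
    """Five-atom hetero ligand realizing one occupancy/altloc class."""
    base = np.array([5.0, 5.0, 5.0])
    offs = [[0, 0, 0], [1.4, 0, 0], [0, 1.4, 0], [0, 0, 1.4], [1.0, 1.0, 0.4]]

    def conformer(alt: str, occ: float, shift: float = 0.0) -> list[AtomRecord]:
        return [
            _atom(f"C{i+1}", "C", code, "X", 1, base + np.asarray(o) + shift,
                  occ=round(occ, 2), b=20.0, het=True, alt=alt)
            for i, o in enumerate(offs)
        ]

    if cls == "unitary_no_altloc":
        return conformer("", 1.0)
    if cls == "partial_no_altloc":
        return conformer("", float(rng.uniform(0.25, 0.90)))
    if cls == "with_altloc_sum_unitary":
        q = round(float(rng.uniform(0.2, 0.8)), 2)
        return conformer("A", q) + conformer("B", 1.0 - q, shift=0.5)
    if cls == "with_altloc_partial":
        return conformer("A", float(rng.uniform(0.2, 0.5))) + conformer(
            "B", float(rng.uniform(0.1, 0.4)), shift=0.5
        )
    if cls == "over_unitary":
        return conformer("A", 0.7) + conformer("B", 0.7, shift=0.5)
    raise ValueError(f"unknown class {cls!r}")


def make_census_fixture(
    n_structures: int,
    class_mix: dict[str, float],
    seed: int = 0,
) -> tuple[list[tuple[str, StructureModel]], dict[str, int]]:
    """Collection of single-ligand toy structures with known class truth.

    ``class_mix`` maps class names to fractions summing to 1; counts are
    apportioned by largest remainder so the truth is exact, then shuffled.
    Returns (structures, truth class counts); the census applied to the
    structures must reproduce the truth exactly.
    """
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")
    fractions = {c: class_mix.get(c, 0.0) for c in CLASSES}
    total = sum(fractions.values())
    if n_structures and abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mix fractions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    # largest-remainder apportionment
    raw = {c: fractions[c] * n_structures for c in CLASSES}
    counts = {c: int(np.floor(raw[c])) for c in CLASSES}
    short = n_structures - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng.shuffle(labels)
    structures = []
    cell = (12.0, 12.0, 12.0, 90.0, 90.0, 90.0)
    for i, cls in enumerate(labels):
        code = _ligand_code(i)
        atoms = [_atom("CA", "C", "GLY", "A", 1, [1.0, 1.0, 1.0], b=10.0)]
        atoms += _census_ligand(code, cls, rng)
        structures.append(
            (f"TOY{i:04d}", StructureModel(atoms=atoms, cell=cell, spacegroup="P 1"))
        )
    truth = {c: counts[c] for c in CLASSES}
    return structures, truth
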