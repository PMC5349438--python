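"""Atomic-model container with faithful altloc, occupancy and B-factor semantics.

Crystal structures that superpose a ligand-bound state on a ground (unbound)
state are represented with alternate conformers: each atom carries a
single-character conformer ID (*altloc*), an occupancy in [0, 1] and an
isotropic B factor.  This module provides a flat, order-preserving atom list
(:class:`StructureModel`) plus PDB/mmCIF round-trip IO (via gemmi) and the
selection utilities every other module builds on.

A blank altloc means "present in all states of the crystal" and is never
rewritten implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "FormatError",
    "ValidationError",
    "CapacityError",
    "read_structure",
    "write_structure",
    "select",
]

#: residue names treated as water everywhere in the package
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: backbone atom names of standard polymer residues; everything else in a
#: protein residue counts as side chain (used by the B-factor-ratio metric)
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class FormatError(ValueError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(ValueError):
    """A model violates a hard physical invariant (e.g. occupancy > 1)."""


class CapacityError(ValueError):
    """A model cannot be represented in the requested output dialect."""


@dataclass
class AtomRecord:
    """One atom site instance (one altloc of one atom position).

    ``altloc`` is ``""`` for a blank (all-states) atom.  ``res_seq`` together
    with ``icode`` identifies the residue within the chain.
    """

    name: str
    element: str
    altloc: str
    res_name: str
    chain: str
    res_seq: int
    pos: np.ndarray
    occupancy: float
    b_factor: float
    is_hetero: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError(f"pos must be a 3-vector, got shape {self.pos.shape}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(
                f"occupancy {self.occupancy} outside [0, 1] for atom "
                f"{self.chain}/{self.res_seq}{self.icode}/{self.name} altloc {self.altloc!r}"
            )
        if self.b_factor < 0:
            raise ValidationError(f"negative B factor {self.b_factor} for atom {self.name}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Key of the atom *site*; altlocs of the same site share it."""
        return (self.chain, self.res_seq, self.icode, self.name)

    @property
    def atomic_number(self) -> int:
        return gemmi.Element(self.element).atomic_number

    def copy(self, **changes) -> "AtomRecord":
        rec = replace(self, **changes)
        rec.pos = rec.pos.copy()
        return rec


@dataclass
class StructureModel:
    """Ordered atom collection plus unit cell and space group."""

    atoms: list[AtomRecord] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] = (1, 1, 1, 90, 90, 90)
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValidationError(f"non-positive cell length in {self.cell}")
        if not all(0 < ang < 180 for ang in (al, be, ga)):
            raise ValidationError(f"cell angle outside (0, 180) in {self.cell}")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def copy(self) -> "StructureModel":
        return StructureModel(
            atoms=[a.copy() for a in self.atoms], cell=self.cell, spacegroup=self.spacegroup
        )

    def sites(self) -> dict[tuple, list[AtomRecord]]:
        """Group atoms by site; each value lists the site's altloc instances."""
        out: dict[tuple, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.site_key, []).append(a)
        return out

    def residues(self) -> dict[tuple, list[AtomRecord]]:
        """Group atoms by (chain, res_seq, icode), preserving atom order."""
        out: dict[tuple, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def residue(self, chain: str, res_seq: int, icode: str = "") -> list[AtomRecord]:
        atoms = [a for a in self.atoms if a.residue_key == (chain, res_seq, icode)]
        if not atoms:
            raise KeyError(f"residue {chain}/{res_seq}{icode} not in model")
        return atoms

    def altlocs_used(self) -> set[str]:
        return {a.altloc for a in self.atoms if a.altloc}

    def validate(self) -> list[str]:
        """Report soft-invariant violations (altloc duplication, occupancy sums).

        Over-unitary occupancy sums are reported, never clamped: real PDB
        entries contain them and the census must be able to count them.
        """
        problems = []
        for key, recs in self.sites().items():
            alts = [r.altloc for r in recs]
            if len(alts) != len(set(alts)):
                problems.append(f"site {key}: duplicate altloc IDs {sorted(alts)}")
            total = sum(r.occupancy for r in recs)
            if total > 1 + 1e-6:
                problems.append(f"site {key}: occupancy sum {total:.4f} > 1")
        return problems


# ------------------------------------------------------------------ gemmi IO

def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    # group atoms by chain and residue (first-appearance order) before
    # touching gemmi: its containers copy on add, so interleaved appends
    # through stale references would silently lose atoms
    chain_order: list[str] = []
    residues: dict[str, dict[tuple, list[AtomRecord]]] = {}
    for a in model.atoms:
        if a.chain not in residues:
            residues[a.chain] = {}
            chain_order.append(a.chain)
        residues[a.chain].setdefault(a.residue_key + (a.res_name,), []).append(a)

    st = gemmi.Structure()
    st.cell = model.gemmi_cell
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    for chain_name in chain_order:
        ch = gemmi.Chain(chain_name)
        for (_c, res_seq, icode, res_name), atoms in residues[chain_name].items():
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(res_seq, icode or " ")
            res.het_flag = "H" if atoms[0].is_hetero else "A"
            for a in atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.altloc = a.altloc if a.altloc else "\0"
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                res.add_atom(ga)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def _from_gemmi(st: gemmi.Structure, path: str) -> StructureModel:
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    if st.cell.a == 0 or not st.cell.is_crystal():
        warnings.warn(f"{path}: no unit cell found; defaulting to P1 unit cube")
        cell = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
        sg = "P 1"
    else:
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        sg = st.spacegroup_hm or "P 1"
    atoms: list[AtomRecord] = []
    bad: list[str] = []
    for ch in st[0]:
        for res in ch:
            for at in res:
                altloc = "" if at.altloc == "\0" else at.altloc
                if not (0.0 <= at.occ <= 1.0):
                    bad.append(
                        f"{ch.name}/{res.seqid.num}/{at.name} altloc {altloc!r}: occ {at.occ}"
                    )
                    continue
                atoms.append(
                    AtomRecord(
                        name=at.name,
                        element=at.element.name,
                        altloc=altloc,
                        res_name=res.name,
                        chain=ch.name,
                        res_seq=res.seqid.num,
                        icode="" if res.seqid.icode == " " else res.seqid.icode,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        is_hetero=res.het_flag == "H",
                    )
                )
    if bad:
        raise ValidationError(f"{path}: occupancy outside [0, 1] for atoms: " + "; ".join(bad))
    return StructureModel(atoms=atoms, cell=cell, spacegroup=sg)


def read_structure(path: str, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All atoms are retained, including zero-occupancy ones; blank altlocs stay
    blank.  ``dialect`` may be ``"pdb"`` or ``"mmcif"``; if omitted it is
    inferred from the extension.
    """
    path = str(path)
    if dialect is None:
        dialect = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    return _from_gemmi(st, path)


def write_structure(model: StructureModel, path: str, dialect: str | None = None) -> None:
    """Write a model to PDB (3-decimal coordinates) or mmCIF (exact)."""
    path = str(path)
    if dialect is None:
        dialect = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if dialect == "pdb" and len(model.altlocs_used()) > 26:
        raise CapacityError(
            f"{len(model.altlocs_used())} distinct altloc IDs exceed the "
            "single-character capacity of the pdb dialect"
        )
    st = _to_gemmi(model)
    if dialect == "pdb":
        st.write_pdb(path)
    elif dialect == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ------------------------------------------------------------------ selection

def select(
    model: StructureModel,
    chain: str | None = None,
    res_seq: int | tuple[int, int] | None = None,
    altlocs: set[str] | None = None,
    hetero: bool | None = None,
    res_name: str | None = None,
) -> StructureModel:
    """Return the subset of atoms matching every given predicate, in order.

    ``res_seq`` may be a single number or an inclusive ``(lo, hi)`` range;
    ``altlocs`` is a set of conformer IDs with ``""`` meaning blank.  The
    original model is not modified; an empty selection is legal.
    """

    def keep(a: AtomRecord) -> bool:
        if chain is not None and a.chain != chain:
            return False
        if res_seq is not None:
            if isinstance(res_seq, tuple):
                lo, hi = res_seq
                if not (lo <= a.res_seq <= hi):
                    return False
            elif a.res_seq != res_seq:
                return False
        if altlocs is not None and a.altloc not in altlocs:
            return False
        if hetero is not None and a.is_hetero != hetero:
            return False
        if res_name is not None and a.res_name != res_name:
            return False
        return True

    return StructureModel(
        atoms=[a.copy() for a in model.atoms if keep(a)],
        cell=model.cell,
        spacegroup=model.spacegroup,
    )
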