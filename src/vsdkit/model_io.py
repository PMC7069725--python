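"""Coordinate and restraint-table I/O plus the core structural types.

Coordinates live in plain-text PDB files (multi-model ensembles use
MODEL/ENDMDL blocks) and are read and written through :mod:`gemmi`.
Distance restraints use the XPLOR/CNS ``assign`` table dialect::

    assign (resid 160 and name HN)(resid 237 and name HN) 3.15 1.35 1.35

which maps to a flat-well interval ``[d - dminus, d + dplus]``.

Author (PDB) residue numbering is authoritative throughout the package;
nothing is re-indexed internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "ResidueRangeSelection",
    "AtomSelection",
    "DistanceRestraint",
    "read_structure",
    "write_structure",
    "read_distance_restraints",
    "write_distance_restraints",
    "ParseError",
    "TopologyError",
]

BACKBONE_HEAVY = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """Malformed input file (carries a line number where possible)."""


class TopologyError(ValueError):
    """Models of one ensemble do not share an identical atom set."""


def _normalize_atom_name(name: str) -> str:
    # amide proton appears as HN in XPLOR tables and H in PDB v3
    return "H" if name.upper() == "HN" else name.upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom: author residue numbering, Å coordinates."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.atom_name)


class StructureModel:
    """A single coordinate model: an ordered list of atoms.

    Provides fast lookup by (residue_number, atom_name) for the default
    (first) chain and a cached ``(n_atoms, 3)`` coordinate array.
    """

    def __init__(self, atoms: Sequence[AtomRecord], model_id: int = 1):
        if len(atoms) == 0:
            raise ValueError("StructureModel requires at least one atom")
        self.atoms = list(atoms)
        self.model_id = int(model_id)
        keys = [a.key() for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom {dup} in model {model_id}")
        self._index = {k: i for i, k in enumerate(keys)}
        self._xyz = np.array([a.xyz for a in self.atoms], dtype=float)
        if not np.all(np.isfinite(self._xyz)):
            raise ValueError("non-finite coordinates")
        self.chains = tuple(dict.fromkeys(a.chain for a in self.atoms))

    # -- access -----------------------------------------------------------
    @property
    def xyz(self) -> np.ndarray:
        return self._xyz

    def topology(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(self._index)

    def atom_index(self, residue_number: int, atom_name: str,
                   chain: str | None = None) -> int:
        chain = chain or self.chains[0]
        key = (chain, int(residue_number), _normalize_atom_name(atom_name))
        if key not in self._index:
            raise KeyError(f"atom {key} not in model")
        return self._index[key]

    def has_atom(self, residue_number: int, atom_name: str,
                 chain: str | None = None) -> bool:
        chain = chain or self.chains[0]
        return (chain, int(residue_number),
                _normalize_atom_name(atom_name)) in self._index

    def coord(self, residue_number: int, atom_name: str,
              chain: str | None = None) -> np.ndarray:
        return self._xyz[self.atom_index(residue_number, atom_name, chain)]

    def residue_numbers(self, chain: str | None = None) -> list[int]:
        chain = chain or self.chains[0]
        return sorted({a.residue_number for a in self.atoms if a.chain == chain})

    def residue_name(self, residue_number: int,
                     chain: str | None = None) -> str:
        chain = chain or self.chains[0]
        for a in self.atoms:
            if a.chain == chain and a.residue_number == residue_number:
                return a.residue_name
        raise KeyError(residue_number)

    def with_xyz(self, xyz: np.ndarray, model_id: int | None = None) -> "StructureModel":
        """Copy of this model with replaced coordinates (same topology)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != self._xyz.shape:
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.chain, a.residue_number, a.residue_name, a.atom_name,
                       a.element, tuple(p))
            for a, p in zip(self.atoms, xyz)
        ]
        return StructureModel(atoms, self.model_id if model_id is None else model_id)

    def __len__(self) -> int:
        return len(self.atoms)


class Ensemble:
    """Ordered list of models sharing an identical atom topology."""

    def __init__(self, models: Sequence[StructureModel]):
        if len(models) == 0:
            raise ValueError("empty ensemble")
        topo = models[0].topology()
        for m in models[1:]:
            if m.topology() != topo:
                raise TopologyError(
                    f"model {m.model_id} atom set differs from model "
                    f"{models[0].model_id}"
                )
        self.models = list(models)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]


@dataclass(frozen=True)
class ResidueRangeSelection:
    """Inclusive residue ranges plus an atom class.

    ``atom_class`` is one of ``backbone_heavy`` (N, CA, C, O), ``calpha``,
    or ``all_heavy`` (every non-hydrogen atom).
    """

    ranges: tuple[tuple[int, int], ...]
    atom_class: str = "backbone_heavy"

    def __post_init__(self):
        if self.atom_class not in ("backbone_heavy", "calpha", "all_heavy"):
            raise ValueError(f"unknown atom class {self.atom_class!r}")
        spans = sorted(self.ranges)
        for (a, b) in spans:
            if a > b:
                raise ValueError(f"range start {a} > end {b}")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if a2 <= b:
                raise ValueError("overlapping residue ranges")

    def contains(self, residue_number: int) -> bool:
        return any(a <= residue_number <= b for a, b in self.ranges)

    def atom_indices(self, model: StructureModel,
                     chain: str | None = None) -> np.ndarray:
        chain = chain or model.chains[0]
        idx = []
        for i, atom in enumerate(model.atoms):
            if atom.chain != chain or not self.contains(atom.residue_number):
                continue
            if self.atom_class == "calpha" and atom.atom_name != "CA":
                continue
            if self.atom_class == "backbone_heavy" and atom.atom_name not in BACKBONE_HEAVY:
                continue
            if self.atom_class == "all_heavy" and atom.element == "H":
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)


# -- atom selections and distance restraints ------------------------------

AtomSelection = tuple  # tuple of (residue_number, atom_name) pairs


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-well distance bound between two (possibly ambiguous) selections."""

    sel_a: tuple[tuple[int, str], ...]
    sel_b: tuple[tuple[int, str], ...]
    d_low: float
    d_high: float
    klass: str = "unclassified"
    provenance: str = ""

    def __post_init__(self):
        if not (0 < self.d_low <= self.d_high):
            raise ValueError(
                f"invalid bounds ({self.d_low}, {self.d_high}) in {self.provenance or 'restraint'}"
            )

    @property
    def residue_a(self) -> int:
        return self.sel_a[0][0]

    @property
    def residue_b(self) -> int:
        return self.sel_b[0][0]

    def sequence_separation(self) -> int:
        return abs(self.residue_a - self.residue_b)


# -- PDB I/O ---------------------------------------------------------------

def read_structure(path: str | Path, keep_altloc: str = "A") -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    First alternate location is kept; insertion codes are rejected because
    the package works in plain author numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    models = []
    for mi, gmodel in enumerate(st, start=1):
        atoms: list[AtomRecord] = []
        for chain in gmodel:
            for res in chain:
                if res.seqid.icode not in (" ", ""):
                    raise ParseError(
                        f"insertion code {res.seqid.icode!r} at residue "
                        f"{res.seqid.num} not supported"
                    )
                for atom in res:
                    if atom.altloc not in ("\x00", "", " ", keep_altloc):
                        continue
                    atoms.append(AtomRecord(
                        chain=chain.name or "A",
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=_normalize_atom_name(atom.name),
                        element=atom.element.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    ))
        if atoms:
            models.append(StructureModel(atoms, model_id=mi))
    if not models:
        raise ParseError(f"no atoms read from {path}")
    return Ensemble(models)


def write_structure(ensemble: Ensemble | StructureModel, path: str | Path,
                    wrap_single_model: bool = False) -> None:
    """Write an ensemble as a PDB file (one MODEL block per member).

    A single-model ensemble is written without the MODEL/ENDMDL wrapper
    unless ``wrap_single_model`` is set.
    """
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble([ensemble])
    st = gemmi.Structure()
    st.name = Path(path).stem
    for model in ensemble:
        gmodel = gemmi.Model(model.model_id)
        chains: dict[str, gemmi.Chain] = {}
        for atom in model.atoms:
            ch = chains.get(atom.chain)
            if ch is None:
                ch = gemmi.Chain(atom.chain)
                chains[atom.chain] = ch
            if (len(ch) == 0 or ch[-1].seqid.num != atom.residue_number
                    or ch[-1].name != atom.residue_name):
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_number, " ")
                ch.add_residue(res)
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.xyz)
            ga.occ = 1.0
            ch[-1].add_atom(ga)
        for ch in chains.values():
            gmodel.add_chain(ch)
        st.add_model(gmodel)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.minimal_file = True
    st.write_pdb(str(path), opts)
    if len(ensemble) == 1 and not wrap_single_model:
        # strip the MODEL/ENDMDL wrapper gemmi emits
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if not (ln.startswith("MODEL") or ln.startswith("ENDMDL"))]
        Path(path).write_text("\n".join(lines) + "\n")


# -- XPLOR/CNS assign-table I/O -------------------------------------------

_SEL_TOKEN = re.compile(
    r"resid\s+(\d+)\s+and\s+name\s+(\S+)", re.IGNORECASE)


def _parse_selection(text: str, line_no: int,
                     model: StructureModel | None) -> tuple[tuple[int, str], ...]:
    m = _SEL_TOKEN.search(text)
    if m is None:
        raise ParseError(
            f"line {line_no}: cannot parse selection {text!r} "
            "(expected 'resid N and name X')"
        )
    resid = int(m.group(1))
    name = m.group(2).upper()
    if "*" in name or "#" in name:
        if model is None:
            # keep the wildcard symbolically when no model is available
            return ((resid, _normalize_atom_name(name)),)
        pat = re.compile(
            "^" + name.replace("*", ".*").replace("#", r"\d") + "$")
        chain = model.chains[0]
        matches = tuple(
            (resid, a.atom_name) for a in model.atoms
            if a.chain == chain and a.residue_number == resid
            and pat.match(a.atom_name)
        )
        if not matches:
            raise ParseError(
                f"line {line_no}: wildcard {name!r} matches no atom of residue {resid}")
        return matches
    return ((resid, _normalize_atom_name(name)),)


def read_distance_restraints(path: str | Path,
                             model: StructureModel | None = None,
                             klass: str = "unclassified") -> list[DistanceRestraint]:
    """Parse an XPLOR/CNS ``assign`` distance-restraint table.

    ``model``, when given, is used to expand wildcard selections such as
    ``name HB*`` into explicit ambiguous atom sets.
    """
    path = Path(path)
    restraints = []
    buffer = ""
    start_line = 0
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.lower().startswith("assign"):
            if buffer:
                restraints.append(
                    _finish_assign(buffer, start_line, model, klass))
            buffer = line
            start_line = line_no
        elif buffer:
            buffer += " " + line
    if buffer:
        restraints.append(_finish_assign(buffer, start_line, model, klass))
    return restraints


_ASSIGN = re.compile(
    r"assign\s*\(([^)]*)\)\s*\(([^)]*)\)\s*"
    r"([-\d.eE]+)\s+([-\d.eE]+)\s+([-\d.eE]+)",
    re.IGNORECASE,
)


def _finish_assign(text: str, line_no: int, model: StructureModel | None,
                   klass: str) -> DistanceRestraint:
    if text.count("(") != text.count(")"):
        raise ParseError(f"line {line_no}: unbalanced parentheses")
    m = _ASSIGN.match(text)
    if m is None:
        raise ParseError(f"line {line_no}: malformed assign statement: {text!r}")
    sel_a = _parse_selection(m.group(1), line_no, model)
    sel_b = _parse_selection(m.group(2), line_no, model)
    d, dminus, dplus = (float(m.group(i)) for i in (3, 4, 5))
    return DistanceRestraint(
        sel_a=sel_a, sel_b=sel_b,
        d_low=d - dminus, d_high=d + dplus,
        klass=klass, provenance=f"line {line_no}",
    )


def write_distance_restraints(restraints: Iterable[DistanceRestraint],
                              path: str | Path) -> None:
    """Write restraints in the XPLOR ``assign`` dialect (ambiguous sets use
    ``or`` within the selection)."""
    lines = []
    for r in restraints:
        d = 0.5 * (r.d_low + r.d_high)
        dminus = d - r.d_low
        dplus = r.d_high - d
        sa = _format_selection(r.sel_a)
        sb = _format_selection(r.sel_b)
        lines.append(f"assign ({sa})({sb}) {d:.3f} {dminus:.3f} {dplus:.3f}"
                     f" ! {r.klass}")
    Path(path).write_text("\n".join(lines) + "\n")


def _format_selection(sel: tuple[tuple[int, str], ...]) -> str:
    if len(sel) == 1:
        resid, name = sel[0]
        return f"resid {resid} and name {name}"
    # ambiguous sets from wildcard expansion share residue and name stem
    resid = sel[0][0]
    names = [name for _, name in sel]
    stem = names[0].rstrip("0123456789")
    if all(n.startswith(stem) for n in names):
        return f"resid {resid} and name {stem}*"
    return " or ".join(f"resid {r} and name {n}" for r, n in sel)
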