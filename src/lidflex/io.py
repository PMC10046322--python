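"""Domain types and structure/trajectory I/O.

The package works at the resolution the analyses need: a :class:`Structure`
is a flat list of atoms with author (PDB) residue numbering, and an
:class:`Ensemble` is an ``(F, N, 3)`` coordinate stack sharing one topology.
Residue numbers are 1-based author numbering throughout the API, because
that is how functional residues of lid-gated hydrolases are cited in the
literature (e.g. the catalytic serine S146, the lid 182-199).

Supported formats: PDB (ATOM/HETATM/MODEL/ENDMDL) and DCD (CHARMM/NAMD
dialect, read/written through :mod:`mdtraj`'s low-level reader in native
angstrom units).

Selection mini-grammar
----------------------
``select(structure, expr)`` evaluates a boolean expression over atoms::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | primary
    primary  := "(" expr ")" | "within" FLOAT "of" unary | term
    term     := "all" | "ca" | "heavy" | "hydrogen" | "backbone" | "ligand"
              | "protein" | "name" NAME+ | "resname" NAME+ | "chain" ID+
              | "element" SYMBOL+ | "resid" RANGE+      (RANGE: "146" or "182-199")

``ca`` means the alpha-carbon atom CA; ``heavy`` means not hydrogen;
``ligand`` means HETATM records that are not water. ``within r of <sub>``
selects atoms within ``r`` angstroms of any atom matched by ``<sub>``,
including those atoms themselves; it is evaluated on the structure's own
coordinates unless per-frame coordinates are supplied via ``coords=``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__

__all__ = [
    "Structure",
    "Ensemble",
    "SelectionMask",
    "RegionDefinition",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_ensemble",
    "select",
]

# masses (u) used for mass-weighted radius of gyration
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
    "NA": 22.990, "K": 39.098, "MN": 54.938,
}

_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL", "H2O"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class PDBParseError(ValueError):
    """Raised for malformed or unsupported PDB records."""


class SelectionError(ValueError):
    """Raised for invalid selection expressions or unmatched identifiers."""


@dataclass
class Structure:
    """Static topology + coordinates of one conformer.

    Parallel arrays over atoms; ``(chain, resid, name)`` triples are unique,
    coordinates are finite, and residue numbers within a chain appear in
    non-decreasing record order.
    """

    chain_ids: np.ndarray          # (N,) str
    res_ids: np.ndarray            # (N,) int, author numbering
    res_names: np.ndarray          # (N,) str, 3-letter
    atom_names: np.ndarray         # (N,) str
    elements: np.ndarray           # (N,) str, upper-case symbols
    coords: np.ndarray             # (N, 3) float, angstrom
    is_hetero: np.ndarray = None   # (N,) bool, from HETATM records
    title: str = ""

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.is_hetero is None:
            self.is_hetero = np.zeros(len(self.res_ids), dtype=bool)
        else:
            self.is_hetero = np.asarray(self.is_hetero, dtype=bool)
        n = len(self.res_ids)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        triples = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(triples)) != n:
            seen, dup = set(), None
            for t in triples:
                if t in seen:
                    dup = t
                    break
                seen.add(t)
            raise ValueError(f"duplicate (chain, resid, atom name) triple: {dup}")
        for ch in dict.fromkeys(self.chain_ids):
            rid = self.res_ids[self.chain_ids == ch]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue numbers decrease within chain {ch!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    def residue_ids(self, mask: "SelectionMask | None" = None) -> np.ndarray:
        """Residue numbers in first-appearance order (optionally restricted)."""
        rid = self.res_ids if mask is None else self.res_ids[mask.indices]
        return np.array(list(dict.fromkeys(rid.tolist())), dtype=int)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.011) for e in self.elements])

    def copy(self) -> "Structure":
        return Structure(
            self.chain_ids.copy(), self.res_ids.copy(), self.res_names.copy(),
            self.atom_names.copy(), self.elements.copy(), self.coords.copy(),
            self.is_hetero.copy(), self.title,
        )


@dataclass
class Ensemble:
    """F frames x N atoms of coordinates sharing one topology (angstrom)."""

    topology: Structure
    frames: np.ndarray                       # (F, N, 3)
    frame_metadata: list | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class SelectionMask:
    """Ordered atom indices into a Structure plus the expression that made them."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("mask indices must be 1-D")
        if len(self.indices) != len(np.unique(self.indices)):
            raise ValueError("mask indices must be unique")
        if np.any(np.diff(self.indices) < 0):
            raise ValueError("mask indices must be sorted ascending")
        if len(self.indices) and self.indices[0] < 0:
            raise ValueError("negative atom index")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RegionDefinition:
    """A named set of residues (author numbering) on an optional chain."""

    name: str
    residues: tuple
    chain: str | None = None

    def __post_init__(self):
        self.residues = tuple(int(r) for r in self.residues)
        if not self.residues:
            raise ValueError(f"region {self.name!r} has no residues")

    def validate(self, structure: Structure) -> None:
        present = set(structure.res_ids.tolist())
        missing = [r for r in self.residues if r not in present]
        if missing:
            raise ValueError(
                f"region {self.name!r}: residues {missing} not in structure"
            )

    def mask(self, structure: Structure, atom_level: str = "all") -> SelectionMask:
        """Atom mask for this region: atom_level in {'all', 'ca', 'heavy'}."""
        self.validate(structure)
        sel = np.isin(structure.res_ids, self.residues)
        if self.chain is not None:
            sel &= structure.chain_ids == self.chain
        if atom_level == "ca":
            sel &= structure.atom_names == "CA"
        elif atom_level == "heavy":
            sel &= structure.elements != "H"
        elif atom_level != "all":
            raise ValueError(f"unknown atom_level {atom_level!r}")
        return SelectionMask(np.flatnonzero(sel),
                             f"region {self.name} ({atom_level})")


# ---------------------------------------------------------------------------
# PDB reading/writing

def _guess_element(atom_name: str, res_name: str) -> str:
    name = atom_name.strip()
    if res_name.strip().upper() in _WATER_NAMES:
        return "O" if name.startswith("O") else "H"
    stripped = name.lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "SE"):
        return stripped[:2].upper()
    return stripped[:1].upper()


def _parse_pdb_lines(lines, path="<string>"):
    """Parse ATOM/HETATM records; returns list of atom dicts with altlocs kept."""
    atoms = []
    for lineno, line in lines:
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"{path}:{lineno}: truncated {rec.strip()} record")
        icode = line[26]
        if icode not in (" ", ""):
            raise PDBParseError(
                f"{path}:{lineno}: insertion code {icode!r} not supported"
            )
        try:
            x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            resid = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"{path}:{lineno}: malformed record: {exc}") from None
        occ = 1.0
        if len(line) >= 60 and line[54:60].strip():
            try:
                occ = float(line[54:60])
            except ValueError:
                raise PDBParseError(
                    f"{path}:{lineno}: malformed occupancy field"
                ) from None
        name = line[12:16].strip()
        resname = line[17:20].strip()
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(line[12:16], resname)
        atoms.append(dict(
            hetero=(rec == "HETATM"), name=name, altloc=line[16],
            resname=resname, chain=line[21], resid=resid,
            xyz=(x, y, z), occ=occ, element=element, lineno=lineno,
        ))
    return atoms


def _resolve_altlocs(atoms):
    """Keep one atom per (chain, resid, name): highest occupancy, tie first-listed."""
    best = {}
    order = []
    for a in atoms:
        key = (a["chain"], a["resid"], a["name"])
        if key not in best:
            best[key] = a
            order.append(key)
        elif a["altloc"] != " " and a["occ"] > best[key]["occ"]:
            best[key] = a
        elif a["altloc"] == " " and best[key]["altloc"] == " ":
            raise PDBParseError(
                f"line {a['lineno']}: duplicate atom {key} without altloc labels"
            )
    return [best[k] for k in order]


def _atoms_to_structure(atoms, title=""):
    atoms = _resolve_altlocs(atoms)
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    return Structure(
        chain_ids=np.array([a["chain"] for a in atoms], dtype=object),
        res_ids=np.array([a["resid"] for a in atoms]),
        res_names=np.array([a["resname"] for a in atoms], dtype=object),
        atom_names=np.array([a["name"] for a in atoms], dtype=object),
        elements=np.array([a["element"] for a in atoms], dtype=object),
        coords=np.array([a["xyz"] for a in atoms]),
        is_hetero=np.array([a["hetero"] for a in atoms]),
        title=title,
    )


def read_structure(path) -> Structure:
    """Read one conformer from a PDB file (first MODEL if several)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"{path}: empty file")
    title = ""
    lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("TITLE"):
            title = (title + " " + line[10:].strip()).strip()
        if line.startswith("ENDMDL"):
            break
        lines.append((lineno, line))
    atoms = _parse_pdb_lines(lines, str(path))
    return _atoms_to_structure(atoms, title=title)


def _format_pdb_atom(i, chain, resid, resname, name, element, xyz, bfac, hetero):
    rec = "HETATM" if hetero else "ATOM  "
    # atom-name column convention: 1/2-letter elements start at col 14/13
    if len(name) >= 4:
        namef = name[:4]
    elif len(element) == 2:
        namef = f"{name:<4s}"[:4]
    else:
        namef = f" {name:<3s}"
    return (
        f"{rec}{i:5d} {namef}{' '}{resname:>3s} {chain:1s}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{bfac:6.2f}"
        f"          {element:>2s}"
    )


def write_structure(structure: Structure, path, bfactors=None) -> None:
    """Write a Structure as a PDB file; optional per-atom B-factor column."""
    if bfactors is None:
        bfactors = np.zeros(structure.n_atoms)
    bfactors = np.asarray(bfactors, dtype=float)
    if bfactors.shape != (structure.n_atoms,):
        raise ValueError("bfactors must be per-atom")
    lines = [f"REMARK   4 GENERATED BY LIDFLEX {__version__}"]
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    for i in range(structure.n_atoms):
        lines.append(_format_pdb_atom(
            i + 1, str(structure.chain_ids[i]), int(structure.res_ids[i]),
            str(structure.res_names[i]), str(structure.atom_names[i]),
            str(structure.elements[i]), structure.coords[i],
            float(bfactors[i]), bool(structure.is_hetero[i]),
        ))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ensemble (trajectory) reading/writing

def _read_multimodel_pdb(path):
    text = Path(path).read_text()
    models, current = [], []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("MODEL"):
            in_model = True
            current = []
        elif line.startswith("ENDMDL"):
            models.append(current)
            current = []
            in_model = False
        elif line[:6] in ("ATOM  ", "HETATM"):
            current.append((lineno, line))
    if not in_model and current and not models:
        models.append(current)  # plain single-model file
    return [_parse_pdb_lines(m, str(path)) for m in models if m]


def read_ensemble(topology_path, traj_path) -> Ensemble:
    """Read an ensemble from a topology PDB plus a multi-model PDB or DCD.

    DCD coordinates are interpreted as angstroms (CHARMM/NAMD convention).
    """
    topology = read_structure(topology_path)
    traj_path = Path(traj_path)
    if traj_path.suffix.lower() == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(traj_path)) as fh:
            xyz, _, _ = fh.read()
        frames = np.asarray(xyz, dtype=float)
        if frames.size == 0:
            raise ValueError(f"{traj_path}: zero frames")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"atom-count mismatch: trajectory has {frames.shape[1]} atoms, "
                f"topology has {topology.n_atoms}"
            )
    else:
        models = _read_multimodel_pdb(traj_path)
        if not models:
            raise ValueError(f"{traj_path}: zero frames")
        frames = []
        for m in models:
            resolved = _resolve_altlocs(m)
            if len(resolved) != topology.n_atoms:
                raise ValueError(
                    f"atom-count mismatch: model has {len(resolved)} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            frames.append([a["xyz"] for a in resolved])
        frames = np.asarray(frames, dtype=float)
    return Ensemble(topology=topology, frames=frames)


def write_ensemble(ensemble: Ensemble, traj_path, topology_path=None) -> None:
    """Write frames as DCD (angstrom) or multi-model PDB by file extension."""
    traj_path = Path(traj_path)
    if topology_path is not None:
        write_structure(ensemble.topology, topology_path)
    if traj_path.suffix.lower() == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(traj_path), "w") as fh:
            fh.write(np.asarray(ensemble.frames, dtype=np.float32))
        return
    top = ensemble.topology
    lines = [f"REMARK   4 GENERATED BY LIDFLEX {__version__}"]
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i in range(top.n_atoms):
            lines.append(_format_pdb_atom(
                i + 1, str(top.chain_ids[i]), int(top.res_ids[i]),
                str(top.res_names[i]), str(top.atom_names[i]),
                str(top.elements[i]), ensemble.frames[f, i], 0.0,
                bool(top.is_hetero[i]),
            ))
        lines.append("ENDMDL")
    lines.append("END")
    traj_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection grammar

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORD_TERMS = {"all", "ca", "heavy", "hydrogen", "backbone", "ligand",
                  "protein", "water"}
_MULTI_TERMS = {"name", "resname", "chain", "element", "resid"}
_RESERVED = _KEYWORD_TERMS | _MULTI_TERMS | {"and", "or", "not", "within", "of",
                                             "(", ")"}


class _Parser:
    def __init__(self, tokens, structure, coords):
        self.tokens = tokens
        self.pos = 0
        self.s = structure
        self.coords = coords

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, tok):
        got = self.take()
        if got != tok:
            raise SelectionError(f"expected {tok!r}, got {got!r}")

    def parse(self):
        out = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return out

    def or_expr(self):
        out = self.and_expr()
        while self.peek() == "or":
            self.take()
            out = out | self.and_expr()
        return out

    def and_expr(self):
        out = self.unary()
        while self.peek() == "and":
            self.take()
            out = out & self.unary()
        return out

    def unary(self):
        if self.peek() == "not":
            self.take()
            return ~self.unary()
        return self.primary()

    def primary(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        if tok == "(":
            self.take()
            out = self.or_expr()
            self.expect(")")
            return out
        if tok == "within":
            self.take()
            try:
                radius = float(self.take())
            except (TypeError, ValueError):
                raise SelectionError("'within' needs a numeric radius") from None
            self.expect("of")
            ref = self.unary()
            return self._within(radius, ref)
        return self.term()

    def _within(self, radius, ref_bool):
        from scipy.spatial import cKDTree

        ref_idx = np.flatnonzero(ref_bool)
        if len(ref_idx) == 0:
            raise SelectionError("'within' reference selection matched no atoms")
        tree = cKDTree(self.coords[ref_idx])
        d, _ = tree.query(self.coords, k=1)
        return d <= radius

    def term(self):
        tok = self.take()
        n = self.s.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "ca":
            return (self.s.atom_names == "CA") & ~self.s.is_hetero
        if tok == "heavy":
            return self.s.elements != "H"
        if tok == "hydrogen":
            return self.s.elements == "H"
        if tok == "backbone":
            return np.isin(self.s.atom_names, list(_BACKBONE_NAMES)) \
                & ~self.s.is_hetero
        if tok == "water":
            return np.isin(self.s.res_names, list(_WATER_NAMES))
        if tok == "ligand":
            return self.s.is_hetero & ~np.isin(self.s.res_names,
                                               list(_WATER_NAMES))
        if tok == "protein":
            return ~self.s.is_hetero
        if tok in ("name", "resname", "chain", "element"):
            values = self._take_values(tok)
            attr = {"name": self.s.atom_names, "resname": self.s.res_names,
                    "chain": self.s.chain_ids, "element": self.s.elements}[tok]
            universe = set(attr.tolist())
            missing = [v for v in values if v not in universe]
            if missing:
                raise SelectionError(f"{tok} {missing[0]!r} matches no atom")
            return np.isin(attr, values)
        if tok == "resid":
            sel = np.zeros(n, dtype=bool)
            present = set(self.s.res_ids.tolist())
            for spec in self._take_values(tok):
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", spec)
                if not m:
                    raise SelectionError(f"bad resid range {spec!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if not any(lo <= r <= hi for r in present):
                    raise SelectionError(
                        f"resid {spec!r} matches no residue in the structure"
                    )
                sel |= (self.s.res_ids >= lo) & (self.s.res_ids <= hi)
            return sel
        raise SelectionError(f"unknown selection term {tok!r}")

    def _take_values(self, keyword):
        values = []
        while self.peek() is not None and self.peek() not in _RESERVED:
            values.append(self.take())
        if not values:
            raise SelectionError(f"{keyword!r} needs at least one value")
        return values


def select(structure: Structure, expression: str, coords=None,
           frame: int | None = None) -> SelectionMask:
    """Evaluate a selection expression; returns a deterministic atom mask.

    Distance terms ('within r of ...') use ``coords`` when given (e.g. one
    ensemble frame); the mask provenance records the frame index used.
    """
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (structure.n_atoms, 3):
        raise ValueError("coords must match structure atom count")
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, structure, coords).parse()
    provenance = expression if frame is None else f"{expression} [frame {frame}]"
    return SelectionMask(np.flatnonzero(mask), provenance)
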