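"""Structures, coordinate ensembles and tabular NMR input.

The in-memory model is deliberately small: an :class:`Ensemble` is an
ordered list of :class:`Frame` objects sharing one topology (atom names,
residues, chains, in identical order), each frame carrying Cartesian
coordinates in Angstrom.  Multi-model PDB and multi-frame XYZ are the two
mandatory on-disk dialects; both round-trip coordinates at PDB precision
(three decimals).

A minimal selection language over ``chain`` / ``residue_name`` /
``residue_id`` / ``atom_name`` with ``and`` / ``or`` / ``not`` and
parentheses is provided for all analysis modules, together with compact
single-atom addresses of the form ``"L:2:H5"`` (chain:resid:name).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from glycostd.errors import ParseError, SelectionError, TopologyError, ValidationError

__all__ = [
    "Atom", "Frame", "Ensemble", "StdTable",
    "read_pdb", "write_pdb", "read_xyz", "write_xyz",
    "read_std_table", "write_std_table",
    "select", "resolve_address",
]


@dataclass(frozen=True)
class Atom:
    """One atom: PDB-style identity plus a position in Angstrom."""

    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValidationError(f"atom {self.name}: element must be non-empty")

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity tuple used for topology comparison (position excluded)."""
        return (self.name, self.residue_name, self.residue_id, self.chain_id)


@dataclass
class Frame:
    """An ordered list of atoms at one time point."""

    atoms: list[Atom]
    time_label: float | None = None  # ns

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray, time_label: float | None = None) -> "Frame":
        """Copy of this frame with positions replaced (identity preserved)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape does not match atom count")
        atoms = [
            Atom(a.name, a.element, a.residue_name, a.residue_id, a.chain_id, p)
            for a, p in zip(self.atoms, xyz)
        ]
        return Frame(atoms, time_label)


def _topology_hash(atoms: Sequence[Atom]) -> str:
    h = hashlib.sha256()
    for a in atoms:
        h.update(repr(a.key).encode())
    return h.hexdigest()


class Ensemble:
    """Ordered frames over one fixed topology.

    Raises :class:`TopologyError` if any frame disagrees with the first
    on atom identity or order.
    """

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValidationError("an Ensemble requires at least one frame")
        ref = [a.key for a in frames[0].atoms]
        for i, fr in enumerate(frames[1:], start=1):
            if [a.key for a in fr.atoms] != ref:
                raise TopologyError(
                    f"frame {i} does not match the topology of frame 0 "
                    f"({len(fr)} atoms vs {len(frames[0])})"
                )
        self.frames: list[Frame] = frames
        self.topology_hash: str = _topology_hash(frames[0].atoms)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    @property
    def topology(self) -> list[Atom]:
        return self.frames[0].atoms

    def coords(self) -> np.ndarray:
        """All coordinates as an array of shape (n_frames, n_atoms, 3)."""
        return np.stack([fr.coords for fr in self.frames])

    def subset_frames(self, indices: Iterable[int]) -> "Ensemble":
        return Ensemble([self.frames[i] for i in indices])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    # PDB atom names: element is the first alphabetic character except for
    # two-letter elements left-justified in 4-char names (not needed here).
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _parse_pdb_atom(line: str, lineno: int) -> Atom | None:
    """Parse one ATOM/HETATM record; returns None for dropped altlocs."""
    try:
        name = line[12:16].strip()
        altloc = line[16:17]
        resname = line[17:21].strip()
        chain = line[21:22]
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if altloc not in (" ", "", "A"):
        return None
    if not element:
        element = _guess_element(name)
    return Atom(name, element, resname, resid, chain, np.array([x, y, z]))


def read_pdb(path: str | Path) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an :class:`Ensemble`.

    ATOM and HETATM records are both retained; alternate locations other
    than 'A'/blank are dropped.  Each MODEL block becomes one frame; a
    file without MODEL records yields a single frame.  Residue numbering
    is kept exactly as found in the file.
    """
    path = Path(path)
    frames: list[Frame] = []
    current: list[Atom] = []
    in_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    frames.append(Frame(current))
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                frames.append(Frame(current))
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_pdb_atom(line.rstrip("\n"), lineno)
                if atom is not None:
                    current.append(atom)
    if current:
        frames.append(Frame(current))
    if not frames or all(len(fr) == 0 for fr in frames):
        raise ParseError(f"{path}: no atoms found")
    frames = [fr for fr in frames if len(fr) > 0]
    try:
        return Ensemble(frames)
    except TopologyError as exc:
        raise TopologyError(f"{path}: MODEL blocks differ in topology: {exc}") from exc


def write_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (HETATM for waters)."""
    path = Path(path)
    multi = len(ensemble) > 1
    with path.open("w") as fh:
        for imodel, fr in enumerate(ensemble.frames, start=1):
            if multi:
                fh.write(f"MODEL {imodel:8d}\n")
            for iat, a in enumerate(fr.atoms, start=1):
                rec = "HETATM" if a.residue_name in ("HOH", "WAT") else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                fh.write(
                    f"{rec}{iat % 100000:5d} {name:<4.4s} {a.residue_name:<4.4s}"
                    f"{a.chain_id:1.1s}{a.residue_id % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ I/O (multi-frame).  Atom identity is encoded in the comment-free XYZ
# name column as chain:resname:resid:name so that topology survives the
# round trip.
# ---------------------------------------------------------------------------

def write_xyz(ensemble: Ensemble, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for fr in ensemble.frames:
            fh.write(f"{len(fr)}\n")
            fh.write(f"t={fr.time_label if fr.time_label is not None else ''}\n")
            for a in fr.atoms:
                tag = f"{a.chain_id}:{a.residue_name}:{a.residue_id}:{a.name}:{a.element}"
                x, y, z = a.position
                fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path) -> Ensemble:
    path = Path(path)
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: bad atom count at line {i + 1}") from exc
        comment = lines[i + 1]
        tlab: float | None = None
        if comment.startswith("t=") and comment[2:].strip():
            try:
                tlab = float(comment[2:])
            except ValueError:
                tlab = None
        atoms = []
        for j in range(nat):
            parts = lines[i + 2 + j].split()
            tag, xyz = parts[0], [float(v) for v in parts[1:4]]
            fields = tag.split(":")
            if len(fields) == 5:
                chain, resname, resid, name, element = fields
            else:  # plain XYZ: element-only names
                chain, resname, resid, name, element = "A", "UNK", "1", tag, tag
            atoms.append(Atom(name, element, resname, int(resid), chain, np.array(xyz)))
        frames.append(Frame(atoms, tlab))
        i += 2 + nat
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Ensemble(frames)


# ---------------------------------------------------------------------------
# STD tables
# ---------------------------------------------------------------------------

@dataclass
class StdTable:
    """Off-/on-resonance intensities per proton for one condition.

    Intensity units are arbitrary but must be consistent within a table;
    only the ratio (I0 - Isat)/I0 is ever used downstream.
    """

    condition_label: str
    rows: dict[str, tuple[float, float]] = field(default_factory=dict)  # label -> (I0, Isat)

    def __post_init__(self) -> None:
        for label, (i0, isat) in self.rows.items():
            if i0 <= 0:
                raise ValidationError(f"proton {label}: I0 must be positive, got {i0}")
            if isat > i0:
                warnings.warn(
                    f"proton {label}: Isat > I0 gives a negative STD intensity",
                    stacklevel=2,
                )

    @property
    def protons(self) -> list[str]:
        return list(self.rows)


def read_std_table(path: str | Path, condition_label: str | None = None) -> StdTable:
    """Read a delimited table with columns ``proton``, ``I0``, ``Isat``.

    Column order is free; comma- and tab-separated files are both accepted.
    Duplicate proton labels are an error (merged/overlapping signals must be
    combined into a single label upstream).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    required = {"proton", "I0", "Isat"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    labels = df["proton"].astype(str).str.strip()
    dup = labels[labels.duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate proton label(s) {sorted(set(dup))}")
    rows = {
        lab: (float(i0), float(isat))
        for lab, i0, isat in zip(labels, df["I0"], df["Isat"])
    }
    return StdTable(condition_label or path.stem, rows)


def write_std_table(table: StdTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(p, i0, isat) for p, (i0, isat) in table.rows.items()],
        columns=["proton", "I0", "Isat"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_FIELDS = {
    "chain": lambda a: a.chain_id,
    "residue_name": lambda a: a.residue_name,
    "resname": lambda a: a.residue_name,
    "residue_id": lambda a: str(a.residue_id),
    "resid": lambda a: str(a.residue_id),
    "atom_name": lambda a: a.name,
    "name": lambda a: a.name,
    "element": lambda a: a.element,
}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    """Recursive-descent parser: or < and < not < (field value | parens)."""

    def __init__(self, tokens: list[str], atoms: Sequence[Atom]):
        self.tokens = tokens
        self.pos = 0
        self.atoms = atoms

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return result

    def expr(self) -> set[int]:
        left = self.term()
        while self.peek() == "or":
            self.take()
            left = left | self.term()
        return left

    def term(self) -> set[int]:
        left = self.factor()
        while self.peek() == "and":
            self.take()
            left = left & self.factor()
        return left

    def factor(self) -> set[int]:
        tok = self.peek()
        if tok == "not":
            self.take()
            return set(range(len(self.atoms))) - self.factor()
        if tok == "(":
            self.take()
            inner = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return inner
        return self.primary()

    def primary(self) -> set[int]:
        fieldname = self.take()
        if fieldname not in _FIELDS:
            raise SelectionError(f"unknown selection field {fieldname!r}")
        value = self.take()
        getter = _FIELDS[fieldname]
        return {i for i, a in enumerate(self.atoms) if getter(a) == value}


def select(ensemble_or_atoms: Ensemble | Sequence[Atom], expression: str) -> list[int]:
    """Resolve a selection expression to a sorted list of atom indices."""
    atoms = (
        ensemble_or_atoms.topology
        if isinstance(ensemble_or_atoms, Ensemble)
        else list(ensemble_or_atoms)
    )
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    return sorted(_SelParser(tokens, atoms).parse())


def resolve_address(ensemble_or_atoms: Ensemble | Sequence[Atom], address: str) -> int:
    """Resolve a compact single-atom address to exactly one atom index.

    Accepted forms: ``"name"``, ``"chain:name"``, ``"chain:resid:name"``.
    Ambiguity (zero or several matches) raises :class:`SelectionError`
    listing the matches.
    """
    atoms = (
        ensemble_or_atoms.topology
        if isinstance(ensemble_or_atoms, Ensemble)
        else list(ensemble_or_atoms)
    )
    parts = address.split(":")
    if len(parts) == 1:
        pred = lambda a: a.name == parts[0]  # noqa: E731
    elif len(parts) == 2:
        pred = lambda a: a.chain_id == parts[0] and a.name == parts[1]  # noqa: E731
    elif len(parts) == 3:
        pred = (  # noqa: E731
            lambda a: a.chain_id == parts[0]
            and str(a.residue_id) == parts[1]
            and a.name == parts[2]
        )
    else:
        raise SelectionError(f"bad address {address!r}")
    hits = [i for i, a in enumerate(atoms) if pred(a)]
    if len(hits) != 1:
        detail = [f"{atoms[i].chain_id}:{atoms[i].residue_id}:{atoms[i].name}" for i in hits]
        raise SelectionError(
            f"address {address!r} resolves to {len(hits)} atoms {detail}; need exactly one"
        )
    return hits[0]
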