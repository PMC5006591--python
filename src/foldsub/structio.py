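"""Readers and writers for the formats the pipeline touches.

Three kinds of input are handled here:

* PDB Cα traces of single protein domains, already superposed into a common
  coordinate frame by a multiple-structure-alignment program such as Mustang.
  Only ``ATOM``/``HETATM`` records of the first model are read; we never
  superpose anything ourselves.
* Gapped FASTA alignments (the sequence alignment a structure aligner emits
  alongside the superposition).
* NCBI BLAST-style substitution matrix files, used both for generic anchor
  matrices (e.g. BLOSUM62) and for the matrices this package exports.

The two are tied together by :func:`load_msta`, which cross-checks a gapped
alignment against the structures it claims to align and produces a
column-indexed :class:`MultiStructureAlignment`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino acid alphabet in NCBI matrix order.
AA20 = "ARNDCQEGHILKMFPSTWYV"
#: Gap character used in alignments and as the 21st count-table label.
GAP = "-"
#: Standard NCBI 24-letter matrix alphabet (20 aa + ambiguity codes + stop).
NCBI24 = "ARNDCQEGHILKMFPSTWYVBZX*"

AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AA20)}

# Three-letter codes of the 20 standard residues; anything else becomes 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"


class StructIOError(ValueError):
    """Base class for all structured-input errors raised by this module."""


class PDBFormatError(StructIOError):
    """The PDB file contains no usable Cα trace."""


class MatrixFormatError(StructIOError):
    """A substitution matrix file is malformed."""


class ConsistencyError(StructIOError):
    """An alignment row disagrees with the structure it claims to describe."""


@dataclass(frozen=True)
class StructureChain:
    """Ordered Cα trace of one domain in a shared superposition frame.

    Parameters
    ----------
    id : str
        Identifier, unique within one alignment bundle.
    sequence : str
        One-letter residue codes over the 20-letter alphabet plus ``'X'``
        for non-standard residues.
    coords : (n, 3) ndarray of float
        Cα coordinates in Å, one row per residue, in chain order.
    resseq : tuple of int
        Original PDB residue numbers, retained as metadata only.
    """

    id: str
    sequence: str
    coords: np.ndarray
    resseq: tuple = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.sequence) == 0:
            raise StructIOError(f"structure {self.id!r}: empty residue list")
        if coords.shape != (len(self.sequence), 3):
            raise StructIOError(
                f"structure {self.id!r}: {len(self.sequence)} residues but "
                f"coordinate array of shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise StructIOError(f"structure {self.id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residues(self):
        """List of ``(one_letter_code, ca_coordinate)`` pairs."""
        return list(zip(self.sequence, self.coords))


@dataclass(frozen=True)
class GappedAlignment:
    """One gapped sequence alignment: equal-length rows over ``AA20 + 'X-'``."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.ids) != len(self.rows):
            raise StructIOError("ids and rows differ in length")
        if len(self.rows) == 0:
            raise StructIOError("empty alignment")
        ncol = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ConsistencyError(
                    f"row {rid!r} has length {len(row)}, expected {ncol}"
                )
        if len(set(self.ids)) != len(self.ids):
            raise StructIOError("duplicate sequence ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class MatrixFile:
    """A labeled square substitution matrix, NCBI-file-backed.

    ``values`` may be integer (classic BLAST matrices) or real (working
    matrices before export scaling).
    """

    name: str
    alphabet: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        n = len(self.alphabet)
        if values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix {self.name!r}: alphabet of {n} labels but value "
                f"table of shape {values.shape}"
            )
        missing = sorted(set(AA20) - set(self.alphabet))
        if missing:
            raise MatrixFormatError(
                f"matrix {self.name!r}: missing standard residues {missing}"
            )

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.values - self.values.T) <= tol))

    def index(self, residue: str) -> int:
        i = self.alphabet.find(residue)
        if i < 0:
            raise KeyError(residue)
        return i

    def block(self, letters: str = AA20) -> np.ndarray:
        """Return the sub-matrix over ``letters`` (default: the 20 aa)."""
        idx = [self.index(c) for c in letters]
        return self.values[np.ix_(idx, idx)].astype(float)


@dataclass(frozen=True)
class MultiStructureAlignment:
    """Column-indexed residue correspondence across ≥2 superposed structures.

    ``index[i, c]`` is the 0-based residue index of structure ``i`` at
    alignment column ``c``, or ``-1`` at a gap.
    """

    chains: tuple
    alignment: GappedAlignment
    index: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "chains", tuple(self.chains))
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructIOError("duplicate structure ids in alignment bundle")
        if tuple(ids) != tuple(self.alignment.ids):
            raise ConsistencyError("chain order does not match alignment row order")
        index = np.full((len(self.chains), self.alignment.n_columns), -1, dtype=np.int64)
        for i, (chain, row) in enumerate(zip(self.chains, self.alignment.rows)):
            k = 0
            for c, ch in enumerate(row):
                if ch == GAP:
                    continue
                if k >= len(chain) or chain.sequence[k] != ch:
                    pos = c + 1
                    raise ConsistencyError(
                        f"structure {chain.id!r}: alignment row disagrees with "
                        f"the Cα sequence at alignment column {pos} "
                        f"(row has {ch!r}, structure has "
                        f"{chain.sequence[k] if k < len(chain) else 'nothing'!r})"
                    )
                index[i, c] = k
                k += 1
            if k != len(chain):
                raise ConsistencyError(
                    f"structure {chain.id!r}: ungapped row length {k} != "
                    f"structure length {len(chain)}"
                )
        object.__setattr__(self, "index", index)

    @property
    def n_structures(self) -> int:
        return len(self.chains)

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns


def read_pdb_ca(path, chain_id: str | None = None, id: str | None = None) -> StructureChain:
    """Read one chain's Cα trace from a PDB file.

    Only MODEL 1 is read (a warning is logged if more models are present).
    Residues without a Cα atom are skipped with a logged warning, and
    residues outside the 20 standard types map to ``'X'``.

    Parameters
    ----------
    path : path-like
        PDB file with ATOM records.
    chain_id : str, optional
        Chain to extract; defaults to the first chain encountered
        (CATH-style domain files are single-chain extracts).
    id : str, optional
        Identifier for the returned chain; defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text()
    if not any(line.startswith("ATOM") for line in text.splitlines()):
        raise PDBFormatError(f"{path}: no ATOM records")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if len(models) > 1:
        logger.info("%s: %d models present; only MODEL 1 read", path, len(models))
    model = models[0]

    chain = None
    for c in model:
        if chain_id is None or c.id == chain_id:
            chain = c
            break
    if chain is None:
        raise PDBFormatError(f"{path}: chain {chain_id!r} not found")

    seq, coords, resseq = [], [], []
    for residue in chain:
        resname = residue.get_resname().strip()
        if resname == "HOH":
            continue
        if "CA" not in residue:
            # Ligands and residues with missing backbone atoms carry no Cα.
            logger.warning(
                "%s: residue %s %s lacks a CA atom; skipped",
                path, resname, residue.get_id()[1],
            )
            continue
        seq.append(THREE_TO_ONE.get(resname, "X"))
        coords.append(residue["CA"].get_coord())
        resseq.append(int(residue.get_id()[1]))

    if not seq:
        raise PDBFormatError(f"{path}: no residues with CA atoms")
    return StructureChain(
        id=id or path.stem,
        sequence="".join(seq),
        coords=np.asarray(coords, dtype=float),
        resseq=tuple(resseq),
    )


def write_pdb_ca(chain: StructureChain, path, chain_id: str = "A") -> None:
    """Write a Cα-only PDB file for a structure chain."""
    with open(path, "w") as fh:
        for k, (aa, ca) in enumerate(zip(chain.sequence, chain.coords), start=1):
            resname = ONE_TO_THREE.get(aa, "UNK")
            resseq = chain.resseq[k - 1] if chain.resseq else k
            fh.write(
                f"ATOM  {k:5d}  CA  {resname:>3s} {chain_id}{resseq:4d}    "
                f"{ca[0]:8.3f}{ca[1]:8.3f}{ca[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("TER\nEND\n")


def read_matrix(path) -> MatrixFile:
    """Read an NCBI BLAST-format substitution matrix file.

    The format is the classic whitespace-separated table with ``#`` comment
    lines, a header row of residue labels and one labeled row per residue.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    header = lines[0].split()
    row_labels = [ln.split()[0] for ln in lines[1:]]
    missing = [h for h in header if h not in row_labels]
    if missing:
        raise MatrixFormatError(f"{path}: missing matrix row(s) for label(s) {missing}")
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:
        raise MatrixFormatError(_diagnose_matrix_file(path, exc)) from exc
    alphabet = "".join(arr.alphabet)
    values = np.asarray(arr)
    if np.all(values == np.round(values)):
        values = values.astype(np.int64)
    return MatrixFile(name=path.stem, alphabet=alphabet, values=values)


def _diagnose_matrix_file(path: Path, exc: Exception) -> str:
    """Build a row-naming error message for a malformed matrix file."""
    try:
        lines = [
            ln for ln in path.read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
    except OSError:
        return f"{path}: unreadable matrix file ({exc})"
    if not lines:
        return f"{path}: empty matrix file"
    header = lines[0].split()
    row_labels = [ln.split()[0] for ln in lines[1:]]
    missing = [h for h in header if h not in row_labels]
    if missing:
        return f"{path}: missing matrix row(s) for label(s) {missing}"
    return f"{path}: malformed matrix file ({exc})"


def write_matrix(matrix: MatrixFile, path, comments: Iterable[str] = ()) -> None:
    """Write a matrix in NCBI BLAST format.

    Integer matrices are written as integers (exact round trip); real-valued
    matrices with 6 decimals.
    """
    path = Path(path)
    values = matrix.values
    integral = np.issubdtype(values.dtype, np.integer) or np.all(
        values == np.round(values)
    )
    if integral:
        cells = [[f"{int(round(v))}" for v in row] for row in values]
    else:
        cells = [[f"{v:.6f}" for v in row] for row in values]
    width = max(max(len(c) for c in row) for row in cells)
    width = max(width, 2)
    with open(path, "w") as fh:
        fh.write(f"# {matrix.name}\n")
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write(" " + "".join(f" {c:>{width}}" for c in matrix.alphabet) + "\n")
        for label, row in zip(matrix.alphabet, cells):
            fh.write(label + "".join(f" {c:>{width}}" for c in row) + "\n")


def load_blosum62() -> MatrixFile:
    """The standard BLOSUM62 matrix (24-letter NCBI alphabet)."""
    arr = substitution_matrices.load("BLOSUM62")
    return MatrixFile(
        name="BLOSUM62",
        alphabet="".join(arr.alphabet),
        values=np.asarray(arr).astype(np.int64),
    )


def read_fasta(path) -> dict:
    """Read a (possibly gapped) FASTA file into an ``{id: sequence}`` dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise StructIOError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def load_msta(alignment_fasta, structure_paths: Sequence) -> MultiStructureAlignment:
    """Load a Mustang-style bundle: gapped FASTA + superposed Cα traces.

    Every FASTA record id must match the id of one structure (the file
    stem), and the ungapped row must equal that structure's Cα sequence;
    otherwise a :class:`ConsistencyError` names the first mismatch.
    """
    rows = read_fasta(alignment_fasta)
    chains = {c.id: c for c in (read_pdb_ca(p) for p in structure_paths)}
    missing = sorted(set(rows) - set(chains))
    if missing:
        raise ConsistencyError(
            f"alignment records with no matching structure file: {missing}"
        )
    ordered = [chains[rid] for rid in rows]
    alignment = GappedAlignment(ids=tuple(rows), rows=tuple(rows.values()))
    return MultiStructureAlignment(chains=tuple(ordered), alignment=alignment)


def write_json_sidecar(meta: Mapping, path) -> None:
    Path(path).write_text(json.dumps(dict(meta), indent=2, sort_keys=True) + "\n")


def read_json_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
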