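"""Sequence and matrix I/O: the core containers shared by every analysis stage.

Genomes are held as :class:`GenomeRecord` (one or more contigs, never
concatenated across contig joins), and pairwise comparison results as
:class:`SymMatrix`, a label-indexed symmetric table of ANI values,
percent similarities, or distances.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "GenomeRecord",
    "SymMatrix",
    "FastaParseError",
    "MatrixError",
    "read_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

#: IUPAC nucleotide one-letter codes mapped to the set of bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_VALID_CHARS = frozenset(IUPAC_CODES) | {"-"}

MatrixKind = Literal["ani", "similarity", "distance"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class MatrixError(ValueError):
    """Raised when a matrix violates symmetry, range or shape constraints."""


@dataclass
class GenomeRecord:
    """An assembled nucleotide sequence, possibly split over several contigs.

    Contigs are stored upper-case and validated against the IUPAC alphabet.
    Draft assemblies keep their contigs separate: no operation in this
    package ever joins contigs into one artificial sequence.
    """

    id: str
    contigs: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord requires a non-empty id")
        if not self.contigs:
            raise ValueError(f"genome {self.id!r} has no contigs")
        clean = []
        for i, contig in enumerate(self.contigs):
            seq = contig.upper()
            if not seq:
                raise ValueError(f"genome {self.id!r}: contig {i} is empty")
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ValueError(
                    f"genome {self.id!r}: contig {i} contains non-IUPAC symbols {sorted(bad)}"
                )
            clean.append(seq)
        self.contigs = clean

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def sequence(self) -> str:
        """Single-contig convenience accessor; errors on multi-contig records."""
        if len(self.contigs) != 1:
            raise ValueError(
                f"genome {self.id!r} has {len(self.contigs)} contigs; "
                "per-contig access required"
            )
        return self.contigs[0]


@dataclass
class SymMatrix:
    """A symmetric, label-indexed table of pairwise values.

    ``kind`` controls validation: ANI and similarity values live in
    [0, 100] with a 100.0 diagonal; distances are non-negative with a zero
    diagonal. Missing comparisons are held as NaN.
    """

    labels: list[str]
    values: np.ndarray
    kind: MatrixKind

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixError("duplicate labels")
        if self.values.shape != (n, n):
            raise MatrixError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.kind not in ("ani", "similarity", "distance"):
            raise MatrixError(f"unknown matrix kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        v = self.values
        finite = v[np.isfinite(v)]
        if np.isinf(finite).any():
            raise MatrixError("non-finite matrix values")
        asym = np.nanmax(np.abs(v - v.T), initial=0.0)
        if asym > 1e-9:
            raise MatrixError(f"matrix not symmetric (max deviation {asym:g})")
        diag_expected = 0.0 if self.kind == "distance" else 100.0
        if not np.allclose(np.diag(v), diag_expected, atol=1e-9):
            raise MatrixError(f"diagonal must be {diag_expected} for kind={self.kind}")
        if self.kind in ("ani", "similarity"):
            if finite.size and (finite.min() < 0.0 or finite.max() > 100.0):
                raise MatrixError(f"{self.kind} values must lie in [0, 100]")
        else:
            if finite.size and finite.min() < 0.0:
                raise MatrixError("distances must be >= 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def set_value(self, a: str, b: str, x: float) -> None:
        i, j = self.index(a), self.index(b)
        self.values[i, j] = x
        self.values[j, i] = x

    def offdiagonal(self) -> list[tuple[str, str, float]]:
        """All unordered off-diagonal pairs as (label_a, label_b, value)."""
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                out.append((self.labels[i], self.labels[j], float(self.values[i, j])))
        return out

    def submatrix(self, labels: Sequence[str]) -> "SymMatrix":
        idx = [self.index(x) for x in labels]
        return SymMatrix(list(labels), self.values[np.ix_(idx, idx)].copy(), self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def identity(cls, labels: Sequence[str], kind: MatrixKind = "ani") -> "SymMatrix":
        n = len(labels)
        fill = 0.0 if kind == "distance" else 100.0
        v = np.full((n, n), np.nan)
        np.fill_diagonal(v, fill)
        return cls(list(labels), v, kind)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_fasta_structure(path: str | Path) -> None:
    """Cheap structural pre-scan so malformed input fails with a line number."""
    with _open_text(path) as fh:
        header_line = None
        seq_seen = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not seq_seen:
                    raise FastaParseError(
                        f"{path}: header at line {header_line} has no sequence"
                    )
                if len(stripped) == 1:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                seq_seen = False
            else:
                if header_line is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                seq_seen = True
        if header_line is None:
            raise FastaParseError(f"{path}: no FASTA records found")
        if not seq_seen:
            raise FastaParseError(f"{path}: header at line {header_line} has no sequence")


def read_fasta(
    path: str | Path,
    mode: Literal["records", "genome"] = "records",
    genome_id: str | None = None,
) -> list[GenomeRecord]:
    """Read a (possibly gzip-compressed) FASTA file into genome records.

    mode="records"
        One :class:`GenomeRecord` per FASTA entry (each entry is a
        single-contig record).
    mode="genome"
        The whole file is one genome; every entry becomes a contig. The
        record id defaults to the first header token's text before the
        first ``.``, or to ``genome_id`` when given. This is the mode for
        multi-contig draft assemblies.
    """
    _check_fasta_structure(path)
    with _open_text(path) as fh:
        entries = [(rec.id, rec.description, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if mode == "records":
        return [
            GenomeRecord(id=rid, contigs=[seq], description=desc)
            for rid, desc, seq in entries
        ]
    if mode == "genome":
        rid = genome_id or entries[0][0].split(".")[0]
        return [
            GenomeRecord(
                id=rid,
                contigs=[seq for _, _, seq in entries],
                description=entries[0][1],
            )
        ]
    raise ValueError(f"unknown FASTA read mode {mode!r}")


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write genome records to FASTA; multi-contig records emit one entry per contig."""
    seqrecs = []
    for rec in records:
        if rec.n_contigs == 1:
            seqrecs.append(SeqRecord(Seq(rec.contigs[0]), id=rec.id, description=rec.description))
        else:
            for i, contig in enumerate(rec.contigs):
                seqrecs.append(
                    SeqRecord(Seq(contig), id=f"{rec.id}.contig{i + 1}", description=rec.description)
                )
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_matrix_tsv(path: str | Path, kind: MatrixKind) -> SymMatrix:
    """Read a labelled square TSV, mirroring whichever triangle is present.

    The first header cell is empty; rows are labelled. A blank cell in one
    triangle is filled from the other; if both triangles carry conflicting
    values (beyond 1e-9) a :class:`MatrixError` is raised. The diagonal is
    filled per ``kind`` when blank.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False,
                     comment="#")
    labels = [str(x) for x in df.columns]
    row_labels = [str(x) for x in df.index]
    if row_labels != labels:
        raise MatrixError(
            f"{path}: row labels {row_labels} do not match column labels {labels}"
        )
    n = len(labels)
    raw = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            cell = str(df.iat[i, j]).strip()
            if cell not in ("", "nan", "NA"):
                raw[i, j] = float(cell)
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            a, b = raw[i, j], raw[j, i]
            if not math.isnan(a) and not math.isnan(b):
                if abs(a - b) > 1e-9:
                    raise MatrixError(
                        f"{path}: conflicting entries for ({labels[i]}, {labels[j]}): "
                        f"{a} vs {b}"
                    )
                values[i, j] = a
            elif not math.isnan(a):
                values[i, j] = values[j, i] = a
            elif not math.isnan(b):
                values[i, j] = values[j, i] = b
    np.fill_diagonal(values, 0.0 if kind == "distance" else 100.0)
    return SymMatrix(labels, values, kind)


def write_matrix_tsv(matrix: SymMatrix, path: str | Path, decimals: int = 1) -> None:
    """Write the full square matrix as TSV with a fixed number of decimals."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for i, label in enumerate(matrix.labels):
            cells = []
            for j in range(matrix.n):
                v = matrix.values[i, j]
                cells.append("" if math.isnan(v) else f"{v:.{decimals}f}")
            fh.write(label + "\t" + "\t".join(cells) + "\n")
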