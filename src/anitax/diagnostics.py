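"""Diagnostic signatures, genome summary statistics and trait keys.

Three small utilities that turn raw sequence and phenotype data into the
evidence used to tell closely related taxa apart:

* :func:`scan_probe` — find all occurrences of a short oligonucleotide
  signature (IUPAC-aware, both strands, optional mismatches), e.g. the
  16S probe that defines the PnecC species complex.
* :func:`genome_stats` — assembly size (Mbp) and G+C content (mol%).
* :func:`diagnostic_key` — from a taxon × trait table, the traits whose
  value is unique to one taxon, plus the differing traits for every taxon
  pair (or a report that a pair is indistinguishable).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .align import revcomp
from .seqio import IUPAC_CODES, GenomeRecord

__all__ = [
    "SignatureProbe",
    "ProbeHit",
    "TraitTable",
    "scan_probe",
    "genome_stats",
    "diagnostic_key",
    "load_trait_table",
    "packaged_table",
    "PNECC_16S_PROBE",
    "ITS_DIAGNOSTIC_PROBE",
]

_BITS = {base: 1 << i for i, base in enumerate("ACGT")}
_IUPAC_BITS = {
    code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_CODES.items()
}
_IUPAC_BITS["-"] = 0


@dataclass(frozen=True)
class SignatureProbe:
    """A short diagnostic oligonucleotide."""

    name: str
    sequence: str
    expected_region: str | None = None
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("probe sequence is empty")
        bad = set(seq) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"probe {self.name!r} has non-IUPAC symbols {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


#: 16S rRNA signature of the PnecC species complex (cf. E. coli 445 region).
PNECC_16S_PROBE = SignatureProbe("PnecC-16S-445", "GAGCCGGTGTTTCTTCCC",
                                 expected_region="16S rRNA, E. coli positions 445-463")
#: 16S-23S ITS signature diagnostic below the species-complex level.
ITS_DIAGNOSTIC_PROBE = SignatureProbe("ITS-diagnostic", "ACTAAGCGATCTAATGATTGTTTA",
                                      expected_region="16S-23S ITS")


@dataclass(frozen=True)
class ProbeHit:
    position: int       # 0-based start on the forward strand
    strand: str         # '+' or '-'
    mismatches: int


def _bits_array(seq: str) -> np.ndarray:
    arr = np.zeros(len(seq), dtype=np.uint8)
    for code, bits in _IUPAC_BITS.items():
        mask = np.frombuffer(seq.encode(), dtype="S1") == code.encode()
        arr[mask] = bits
    return arr


def _scan_one_strand(seq_bits: np.ndarray, probe_bits: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    k = probe_bits.size
    n = seq_bits.size
    if n < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, k)
    compatible = (windows & probe_bits[None, :]) != 0
    mismatches = k - compatible.sum(axis=1)
    idx = np.flatnonzero(mismatches <= max_mm)
    return [(int(i), int(mismatches[i])) for i in idx]


def scan_probe(
    seq: str,
    probe: SignatureProbe,
    search_revcomp: bool = True,
    max_mismatches: int | None = None,
) -> list[ProbeHit]:
    """All probe occurrences within the allowed mismatch count.

    Matching is IUPAC-aware on both sides: a column matches when the base
    sets of the probe symbol and the sequence symbol intersect (so probe R
    matches sequence A, and sequence N matches anything). Reverse-strand
    hits are reported at their forward-strand start coordinate.
    """
    seq = seq.upper()
    max_mm = probe.max_mismatches if max_mismatches is None else max_mismatches
    seq_bits = _bits_array(seq)
    hits = [
        ProbeHit(pos, "+", mm)
        for pos, mm in _scan_one_strand(seq_bits, _bits_array(probe.sequence), max_mm)
    ]
    if search_revcomp:
        rc_bits = _bits_array(revcomp(probe.sequence))
        hits.extend(
            ProbeHit(pos, "-", mm)
            for pos, mm in _scan_one_strand(seq_bits, rc_bits, max_mm)
        )
    return sorted(hits, key=lambda h: (h.position, h.strand))


def genome_stats(genome: GenomeRecord) -> dict:
    """Assembly size (Mbp, 2 d.p.), G+C content (mol%, 1 d.p.), contig count.

    G+C is computed over unambiguous bases only: N and other ambiguity
    codes are excluded from numerator and denominator.
    """
    counts = {b: 0 for b in "ACGT"}
    for contig in genome.contigs:
        for b in "ACGT":
            counts[b] += contig.count(b)
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        raise ValueError(f"genome {genome.id!r} has no unambiguous bases")
    gc = 100.0 * (counts["G"] + counts["C"]) / unambiguous
    return {
        "id": genome.id,
        "size_mbp": round(genome.total_length / 1e6, 2),
        "gc_molpct": round(gc, 1),
        "n_contigs": genome.n_contigs,
    }


class TraitTable:
    """A rectangular taxon × trait table of categorical or numeric values.

    Values are kept as strings; ``normalize()`` maps the usual phenotype
    notation (+/−/w, en-dashes, numeric percentages) onto the three-state
    alphabet {positive, weak, negative}, binarizing numeric abundances at
    detected (> 0). The raw table is preserved.
    """

    NEGATIVE_SYMBOLS = {"-", "−", "–", "", "nd", "ND", "0"}
    WEAK_SYMBOLS = {"w", "W", "weak", "(+)"}

    def __init__(self, df: pd.DataFrame):
        if df.isna().any().any():
            raise ValueError("trait table has unpopulated cells")
        self.df = df.astype(str)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def traits(self) -> list[str]:
        return list(self.df.columns)

    def value(self, taxon: str, trait: str) -> str:
        return self.df.at[taxon, trait]

    def numeric(self) -> pd.DataFrame:
        """Numeric view with non-numeric (absent) cells as 0."""
        def conv(x: str) -> float:
            try:
                return float(x)
            except ValueError:
                return 0.0
        return self.df.map(conv)

    def normalize(self) -> "TraitTable":
        def norm(x: str) -> str:
            x = x.strip()
            if x in self.NEGATIVE_SYMBOLS:
                return "negative"
            if x in self.WEAK_SYMBOLS:
                return "weak"
            if x == "+":
                return "positive"
            try:
                return "positive" if float(x) > 0 else "negative"
            except ValueError:
                return x  # free-text categorical state, kept verbatim
        return TraitTable(self.df.map(norm))


def load_trait_table(path: str | Path, taxa_as: str = "columns") -> TraitTable:
    """Read a trait TSV (``#`` comment lines allowed).

    ``taxa_as="columns"`` matches the printed-table orientation (one row
    per trait, one column per taxon) and is transposed on load.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str,
                     keep_default_na=False)
    if taxa_as == "columns":
        df = df.T
    elif taxa_as != "rows":
        raise ValueError("taxa_as must be 'rows' or 'columns'")
    return TraitTable(df)


def packaged_table(name: str) -> Path:
    """Path to one of the packaged trait/matrix fixtures (data/*.tsv)."""
    return Path(str(resources.files("anitax").joinpath("data", name)))


def diagnostic_key(table: TraitTable) -> dict:
    """Uniquely discriminating traits per taxon, and pairwise differences.

    A trait discriminates a taxon when that taxon's value occurs in no
    other row. For every taxon pair the differing traits are listed (any
    one of them is a minimal discriminating set); pairs with identical
    rows are reported as indistinguishable.
    """
    df = table.df
    unique: dict[str, list[tuple[str, str]]] = {t: [] for t in table.taxa}
    for trait in table.traits:
        col = df[trait]
        counts = col.value_counts()
        for taxon, value in col.items():
            if counts[value] == 1:
                unique[taxon].append((trait, value))
    pair_differences: dict[tuple[str, str], list[str]] = {}
    indistinguishable: list[tuple[str, str]] = []
    taxa = table.taxa
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            diff = [t for t in table.traits if df.at[taxa[i], t] != df.at[taxa[j], t]]
            pair_differences[(taxa[i], taxa[j])] = diff
            if not diff:
                indistinguishable.append((taxa[i], taxa[j]))
    return {
        "unique_traits": unique,
        "pair_differences": pair_differences,
        "indistinguishable_pairs": indistinguishable,
    }
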