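"""Multilocus sequence analysis: concatenated housekeeping-locus profiles and
pairwise percent similarity.

Taxa are compared over an ordered panel of loci (conventionally eight
housekeeping genes, ~6 kbp concatenated). Sequences must arrive aligned or
equal-length per locus; columns where either sequence of a pair carries a
gap or ambiguity code are excluded from that pair's comparison
(pairwise deletion), so each pair reports its own number of compared sites
together with the integer count of nucleotide differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import GenomeRecord, SymMatrix, read_fasta

__all__ = [
    "ConcatProfile",
    "PairwiseSim",
    "concat_profiles",
    "pairwise_similarity",
    "similarity_matrix",
    "format_similarity",
    "extract_locus",
]

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class ConcatProfile:
    """Ordered locus sequences for one taxon plus their concatenation."""

    taxon_id: str
    loci: list[tuple[str, str]]  # (locus_name, sequence), fixed order

    def __post_init__(self) -> None:
        self.loci = [(name, seq.upper()) for name, seq in self.loci]

    @property
    def locus_names(self) -> list[str]:
        return [name for name, _ in self.loci]

    @property
    def concat(self) -> str:
        return "".join(seq for _, seq in self.loci)

    @property
    def concat_length(self) -> int:
        return sum(len(seq) for _, seq in self.loci)


@dataclass(frozen=True)
class PairwiseSim:
    """Similarity of one taxon pair over the compared (unambiguous) columns."""

    taxon_a: str
    taxon_b: str
    compared_sites: int
    differences: int

    @property
    def similarity_pct(self) -> float:
        if self.compared_sites == 0:
            raise ValueError(
                f"no comparable sites between {self.taxon_a} and {self.taxon_b}"
            )
        return 100.0 * (self.compared_sites - self.differences) / self.compared_sites


def format_similarity(pct: float) -> str:
    """Render a percent similarity: one decimal, two decimals at >= 99.9.

    The extra decimal near 100 % keeps single-nucleotide differences on a
    ~6 kbp concatenate visible (1 difference in 6087 sites is 99.98 %, which
    one-decimal rounding would report as a spurious 100.0 %).
    """
    return f"{pct:.2f}" if pct >= 99.9 else f"{pct:.1f}"


def concat_profiles(
    locus_seqs: Mapping[str, Mapping[str, str]] | Mapping[str, str | Path],
    order: Sequence[str] | None = None,
) -> list[ConcatProfile]:
    """Build one profile per taxon from per-locus sequence sets.

    ``locus_seqs`` maps locus name to either a {taxon_id: sequence} mapping
    or a FASTA path (one entry per taxon). Locus order is lexicographic
    unless ``order`` is given. Every taxon must be present in every locus,
    and per-locus sequences must have equal length across taxa (aligned or
    unaligned-but-equal); otherwise a descriptive error is raised.
    """
    resolved: dict[str, dict[str, str]] = {}
    for locus, source in locus_seqs.items():
        if isinstance(source, (str, Path)):
            recs = read_fasta(source, mode="records")
            resolved[locus] = {r.id: r.contigs[0] for r in recs}
        else:
            resolved[locus] = {t: s.upper() for t, s in source.items()}

    locus_order = list(order) if order is not None else sorted(resolved)
    missing_loci = set(locus_order) - set(resolved)
    if missing_loci:
        raise ValueError(f"loci in order but not provided: {sorted(missing_loci)}")

    taxa = sorted(set().union(*(set(v) for v in resolved.values())))
    for locus in locus_order:
        absent = [t for t in taxa if t not in resolved[locus]]
        if absent:
            raise ValueError(
                f"taxa missing from locus {locus!r}: {absent}"
            )
        lengths = {len(resolved[locus][t]) for t in taxa}
        if len(lengths) > 1:
            raise ValueError(
                f"locus {locus!r} has unequal sequence lengths {sorted(lengths)}; "
                "align the locus before concatenation"
            )
    return [
        ConcatProfile(taxon_id=t, loci=[(locus, resolved[locus][t]) for locus in locus_order])
        for t in taxa
    ]


def pairwise_similarity(a: ConcatProfile, b: ConcatProfile) -> PairwiseSim:
    """Count differences between two aligned concatenates.

    Columns where either sequence holds a gap or any IUPAC ambiguity code
    are dropped from ``compared_sites``; differences are counted over the
    remaining unambiguous columns only.
    """
    sa, sb = a.concat, b.concat
    if len(sa) != len(sb):
        raise ValueError(
            f"concatenate length mismatch: {a.taxon_id} has {len(sa)} bp, "
            f"{b.taxon_id} has {len(sb)} bp"
        )
    xa = np.frombuffer(sa.encode(), dtype="S1")
    xb = np.frombuffer(sb.encode(), dtype="S1")
    ok_a = np.isin(xa, [c.encode() for c in _UNAMBIGUOUS])
    ok_b = np.isin(xb, [c.encode() for c in _UNAMBIGUOUS])
    keep = ok_a & ok_b
    compared = int(keep.sum())
    diffs = int((xa[keep] != xb[keep]).sum())
    return PairwiseSim(a.taxon_id, b.taxon_id, compared, diffs)


def similarity_matrix(profiles: Sequence[ConcatProfile]) -> SymMatrix:
    """All-pairs percent similarity over a panel of aligned profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    orders = {tuple(p.locus_names) for p in profiles}
    if len(orders) > 1:
        raise ValueError("profiles have inconsistent locus orders")
    labels = [p.taxon_id for p in profiles]
    m = SymMatrix.identity(labels, kind="similarity")
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            sim = pairwise_similarity(profiles[i], profiles[j])
            m.set_value(labels[i], labels[j], sim.similarity_pct)
    m.validate()
    return m


def extract_locus(
    genome: GenomeRecord,
    reference: str,
    min_identity: float = 0.90,
) -> str | None:
    """Pull the best-matching copy of a reference locus out of an assembly.

    Each contig (both strands) is searched for the reference by semi-global
    alignment; the best hit is returned as the matched genome substring when
    its identity reaches ``min_identity``, else None. Used to harvest
    housekeeping loci from genome sequences for multilocus comparison.
    """
    from .align import best_infix_hit  # local import: keeps alignment backend optional

    hit = best_infix_hit(reference.upper(), genome)
    if hit is None or hit.identity < min_identity:
        return None
    return hit.matched_subject
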