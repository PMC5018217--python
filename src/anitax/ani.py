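"""Fragment-based average nucleotide identity (the BLAST-fragment flavour).

The query genome is cut into consecutive non-overlapping ~1020 bp windows
per contig; each fragment is locally aligned against the whole subject on
both strands, and fragments passing the conventional retention filter
(>= 30 % identity over >= 70 % of their length) contribute their percent
identity to the one-way ANI. The symmetric ANI of a pair is the arithmetic
mean of the two one-way values. Identity counts gap columns as
non-matches throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .align import best_fragment_hit
from .seqio import GenomeRecord, SymMatrix

__all__ = ["AniParams", "Fragment", "AniResult", "fragment", "ani_oneway", "ani_pairwise"]


@dataclass(frozen=True)
class AniParams:
    """Fragmentation and retention settings for the ANI estimator."""

    fragment_len: int = 1020
    min_identity: float = 0.30
    min_aln_cov: float = 0.70
    backend: str = "edlib"

    def __post_init__(self) -> None:
        if self.fragment_len <= 0:
            raise ValueError("fragment_len must be positive")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0.0 < self.min_aln_cov <= 1.0):
            raise ValueError("min_aln_cov must be in (0, 1]")


@dataclass(frozen=True)
class Fragment:
    """One query window; coordinates are 0-based half-open on its contig."""

    contig_index: int
    start: int
    end: int
    seq: str
    is_remainder: bool

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AniResult:
    """One-way (and optionally symmetrized) ANI for a genome pair."""

    query_id: str
    subject_id: str
    oneway_ani: float | None      # % identity over retained fragments; None if none retained
    n_fragments: int
    n_retained: int
    symmetric_ani: float | None = None
    fragment_identities: list[float] = field(default_factory=list, repr=False)

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_fragments if self.n_fragments else 0.0


def fragment(genome: GenomeRecord, fragment_len: int = 1020) -> list[Fragment]:
    """Cut every contig into consecutive non-overlapping windows.

    The terminal remainder shorter than ``fragment_len`` is kept and
    flagged; windows never span contig joins.
    """
    out = []
    for ci, contig in enumerate(genome.contigs):
        for start in range(0, len(contig), fragment_len):
            end = min(start + fragment_len, len(contig))
            out.append(
                Fragment(
                    contig_index=ci,
                    start=start,
                    end=end,
                    seq=contig[start:end],
                    is_remainder=(end - start) < fragment_len,
                )
            )
    return out


def ani_oneway(
    query: GenomeRecord,
    subject: GenomeRecord,
    params: AniParams = AniParams(),
) -> AniResult:
    """One-way ANI of ``query`` against ``subject``.

    Every query fragment is aligned to its best location in the subject
    (each contig, both strands); a fragment is retained when its identity
    reaches ``min_identity`` over at least ``min_aln_cov`` of its own
    length (so remainder fragments are judged against their own length,
    not the nominal window). When no fragment passes, ``oneway_ani`` is
    None — an absent value, never 0.
    """
    frags = fragment(query, params.fragment_len)
    identities: list[float] = []
    n_retained = 0
    for frag in frags:
        hit = best_fragment_hit(frag.seq, subject, backend=params.backend)
        if hit is None:
            continue
        if hit.identity >= params.min_identity and hit.query_cov >= params.min_aln_cov:
            identities.append(100.0 * hit.identity)
            n_retained += 1
    oneway = float(np.mean(identities)) if identities else None
    return AniResult(
        query_id=query.id,
        subject_id=subject.id,
        oneway_ani=oneway,
        n_fragments=len(frags),
        n_retained=n_retained,
        fragment_identities=identities,
    )


def symmetric_ani(a: AniResult, b: AniResult) -> float | None:
    """Mean of the two one-way values; None when either direction is missing."""
    if a.oneway_ani is None or b.oneway_ani is None:
        return None
    return (a.oneway_ani + b.oneway_ani) / 2.0


def ani_pairwise(
    genomes: Sequence[GenomeRecord],
    params: AniParams = AniParams(),
) -> tuple[SymMatrix, list[AniResult]]:
    """Symmetric ANI for every unordered genome pair.

    Pairs where either one-way estimate is undefined (no retained
    fragments) are left as missing matrix cells with a warning.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    labels = [g.id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("genome ids must be unique")
    matrix = SymMatrix.identity(labels, kind="ani")
    results: list[AniResult] = []
    for ga, gb in combinations(genomes, 2):
        fwd = ani_oneway(ga, gb, params)
        rev = ani_oneway(gb, ga, params)
        sym = symmetric_ani(fwd, rev)
        fwd.symmetric_ani = sym
        rev.symmetric_ani = sym
        results.extend([fwd, rev])
        if sym is None:
            warnings.warn(
                f"no retained fragments between {ga.id} and {gb.id}; "
                "cell left missing",
                stacklevel=2,
            )
        else:
            matrix.set_value(ga.id, gb.id, sym)
    matrix.validate()
    return matrix, results
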