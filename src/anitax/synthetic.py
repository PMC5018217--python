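"""Synthetic genomes, divergent genome pairs and multilocus panels.

The generator emulates the statistical structure the downstream estimators
assume: i.i.d. base composition at a target G+C content, Jukes–Cantor-like
substitutions (uniform over the three alternative bases, no transition
bias), and geometric-length indels. Every operation is seeded and
deterministic, and every mutation is recorded in a machine-readable
:class:`MutationLog`, so tests can recompute true per-window identities
independently of any aligner.

A joint generator derives genomes and housekeeping-locus panels from one
shared ancestor with a per-taxon divergence gradient, reproducing the
monotone relationship between multilocus similarity and genome-wide ANI
that the calibration stage fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mlsa import ConcatProfile
from .seqio import GenomeRecord

__all__ = [
    "DivergenceSpec",
    "MutationLog",
    "generate_genome",
    "mutate_genome",
    "generate_mlsa_panel",
    "generate_joint_panel",
    "DEFAULT_LOCUS_LENGTHS",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Eight housekeeping-locus lengths summing to 6087 bp, the concatenated
#: length used throughout the multilocus examples.
DEFAULT_LOCUS_LENGTHS: tuple[int, ...] = (720, 690, 801, 762, 747, 783, 774, 810)


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-site divergence parameters for one mutation pass."""

    substitution_rate: float
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must be in [0, 1)")
        if self.substitution_rate + self.indel_rate >= 1.0:
            raise ValueError("substitution_rate + indel_rate must be < 1")
        if self.indel_mean_len <= 0:
            raise ValueError("indel_mean_len must be positive")


@dataclass
class ContigLog:
    """True mutation record for one contig, in ancestral coordinates."""

    length: int
    substituted: np.ndarray   # bool, ancestral positions that were substituted
    deleted: np.ndarray       # bool, ancestral positions removed
    insertions: dict[int, int]  # ancestral position -> inserted length (before that position)

    def aligned_stats(self, start: int, end: int) -> tuple[int, int]:
        """(matches, aligned_columns) for the ancestral window [start, end).

        Columns count every surviving ancestral site plus gap columns from
        deletions and insertions that fall inside the window — the true
        alignment implied by the mutation process.
        """
        window = slice(start, end)
        n = end - start
        n_del = int(self.deleted[window].sum())
        n_sub = int((self.substituted[window] & ~self.deleted[window]).sum())
        n_ins = sum(l for p, l in self.insertions.items() if start < p < end)
        matches = n - n_del - n_sub
        columns = n + n_ins
        return matches, columns

    def true_identity(self, start: int | None = None, end: int | None = None) -> float:
        start = 0 if start is None else start
        end = self.length if end is None else end
        m, c = self.aligned_stats(start, end)
        return m / c if c else float("nan")


@dataclass
class MutationLog:
    """Per-contig truth for one mutated genome."""

    spec: DivergenceSpec
    contigs: list[ContigLog]

    @property
    def n_substitutions(self) -> int:
        return sum(int((c.substituted & ~c.deleted).sum()) for c in self.contigs)

    @property
    def n_sites(self) -> int:
        return sum(c.length for c in self.contigs)

    def true_identity(self) -> float:
        m = c = 0
        for log in self.contigs:
            mi, ci = log.aligned_stats(0, log.length)
            m += mi
            c += ci
        return m / c if c else float("nan")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(raw.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT symbols; generator requires plain bases")
    return codes


def generate_genome(
    length: int,
    gc: float = 0.45,
    n_contigs: int = 1,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> GenomeRecord:
    """Generate an i.i.d. random genome at a target G+C fraction.

    Base probabilities are P(G)=P(C)=gc/2 and P(A)=P(T)=(1−gc)/2; contigs
    are near-equal slices of the total length.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must lie strictly inside (0, 1), got {gc}")
    if n_contigs < 1 or length < n_contigs:
        raise ValueError("need length >= n_contigs >= 1")
    rng = np.random.default_rng(seed)
    codes = _random_bases(rng, length, gc)
    base_len, extra = divmod(length, n_contigs)
    contigs, pos = [], 0
    for i in range(n_contigs):
        l = base_len + (1 if i < extra else 0)
        contigs.append(_codes_to_str(codes[pos : pos + l]))
        pos += l
    return GenomeRecord(id=genome_id, contigs=contigs)


def _mutate_codes(
    codes: np.ndarray, spec: DivergenceSpec, rng: np.random.Generator
) -> tuple[np.ndarray, ContigLog]:
    n = codes.size
    sub_mask = rng.random(n) < spec.substitution_rate
    # uniform over the three alternative bases
    shifts = rng.integers(1, 4, size=int(sub_mask.sum()), dtype=np.uint8)
    mutated = codes.copy()
    mutated[sub_mask] = (mutated[sub_mask] + shifts) % 4

    deleted = np.zeros(n, dtype=bool)
    insertions: dict[int, int] = {}
    ins_seqs: dict[int, np.ndarray] = {}
    if spec.indel_rate > 0:
        indel_sites = np.flatnonzero(rng.random(n) < spec.indel_rate)
        for pos in indel_sites:
            length = int(rng.geometric(1.0 / spec.indel_mean_len))
            if rng.random() < 0.5:  # deletion of [pos, pos+length)
                deleted[pos : pos + length] = True
            else:  # insertion before pos
                seq = rng.integers(0, 4, size=length, dtype=np.uint8)
                insertions[int(pos)] = insertions.get(int(pos), 0) + length
                ins_seqs[int(pos)] = (
                    np.concatenate([ins_seqs[int(pos)], seq]) if int(pos) in ins_seqs else seq
                )

    if insertions or deleted.any():
        pieces = []
        cut_positions = sorted(ins_seqs)
        prev = 0
        for pos in cut_positions:
            seg = mutated[prev:pos]
            pieces.append(seg[~deleted[prev:pos]])
            pieces.append(ins_seqs[pos])
            prev = pos
        seg = mutated[prev:]
        pieces.append(seg[~deleted[prev:]])
        out = np.concatenate(pieces)
    else:
        out = mutated
    log = ContigLog(length=n, substituted=sub_mask, deleted=deleted, insertions=insertions)
    return out, log


def mutate_genome(
    genome: GenomeRecord,
    spec: DivergenceSpec,
    mutated_id: str | None = None,
) -> tuple[GenomeRecord, MutationLog]:
    """Apply one round of substitutions and indels to every contig.

    Each site is substituted independently with probability
    ``substitution_rate`` (to a uniformly chosen different base) and hit by
    an indel with probability ``indel_rate`` (insertion or deletion with
    equal odds, geometric length). Returns the mutated copy and the full
    truth log; the input genome is never modified.
    """
    rng = np.random.default_rng(spec.seed)
    out_contigs, logs = [], []
    for contig in genome.contigs:
        codes, log = _mutate_codes(_str_to_codes(contig), spec, rng)
        if codes.size == 0:
            raise ValueError("mutation deleted an entire contig; lower indel_rate")
        out_contigs.append(_codes_to_str(codes))
        logs.append(log)
    mutated = GenomeRecord(
        id=mutated_id or f"{genome.id}_div{spec.substitution_rate:g}",
        contigs=out_contigs,
        description=genome.description,
    )
    return mutated, MutationLog(spec=spec, contigs=logs)


def generate_mlsa_panel(
    n_taxa: int,
    locus_lengths: Sequence[int] = DEFAULT_LOCUS_LENGTHS,
    divergence_gradient: Sequence[float] | None = None,
    seed: int = 0,
    gc: float = 0.45,
    taxon_ids: Sequence[str] | None = None,
) -> tuple[list[ConcatProfile], dict[str, MutationLog]]:
    """Generate an aligned housekeeping-locus panel along a divergence gradient.

    A single ancestral panel is drawn, then each taxon receives independent
    substitution-only mutations at its own rate (no indels, so the panel
    stays aligned without an alignment step). Returns the profiles and, per
    taxon, the truth log over the concatenated panel (one pseudo-contig per
    locus).
    """
    if any(l <= 0 for l in locus_lengths):
        raise ValueError("locus lengths must be positive")
    if len(locus_lengths) != 8:
        warnings.warn(
            f"{len(locus_lengths)} loci requested; the conventional panel has 8",
            stacklevel=2,
        )
    if divergence_gradient is None:
        divergence_gradient = np.linspace(0.0, 0.15, n_taxa)
    if len(divergence_gradient) != n_taxa:
        raise ValueError("divergence_gradient length must equal n_taxa")
    ids = list(taxon_ids) if taxon_ids is not None else [f"taxon{i+1}" for i in range(n_taxa)]
    if len(ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")

    rng = np.random.default_rng(seed)
    names = [f"locus{i+1}" for i in range(len(locus_lengths))]
    ancestor = [_random_bases(rng, l, gc) for l in locus_lengths]

    profiles, logs = [], {}
    child_seeds = rng.integers(0, 2**31 - 1, size=n_taxa)
    for tid, rate, child_seed in zip(ids, divergence_gradient, child_seeds):
        spec = DivergenceSpec(substitution_rate=float(rate), seed=int(child_seed))
        crng = np.random.default_rng(spec.seed)
        loci, contig_logs = [], []
        for name, anc in zip(names, ancestor):
            codes, log = _mutate_codes(anc, spec, crng)
            loci.append((name, _codes_to_str(codes)))
            contig_logs.append(log)
        profiles.append(ConcatProfile(taxon_id=tid, loci=loci))
        logs[tid] = MutationLog(spec=spec, contigs=contig_logs)
    return profiles, logs


def generate_joint_panel(
    n_taxa: int,
    divergence_gradient: Sequence[float],
    genome_length: int = 100_000,
    locus_lengths: Sequence[int] = DEFAULT_LOCUS_LENGTHS,
    gc: float = 0.45,
    seed: int = 0,
    taxon_ids: Sequence[str] | None = None,
) -> tuple[list[GenomeRecord], list[ConcatProfile], dict[str, dict]]:
    """Generate matched genomes and locus panels from one shared ancestor.

    The same per-taxon substitution rate drives both the whole genome and
    the locus panel, so multilocus similarity and genome-wide identity are
    coupled across taxon pairs — the structure the similarity→ANI
    calibration exploits. Returns (genomes, profiles, truth) where truth
    maps taxon id to its rate and expected pairwise identity components.
    """
    if len(divergence_gradient) != n_taxa:
        raise ValueError("divergence_gradient length must equal n_taxa")
    ids = list(taxon_ids) if taxon_ids is not None else [f"taxon{i+1}" for i in range(n_taxa)]
    rng = np.random.default_rng(seed)
    ancestor = generate_genome(genome_length, gc=gc, seed=int(rng.integers(2**31 - 1)),
                               genome_id="ancestor")
    panel_seed = int(rng.integers(2**31 - 1))
    profiles, panel_logs = generate_mlsa_panel(
        n_taxa, locus_lengths=locus_lengths,
        divergence_gradient=divergence_gradient,
        seed=panel_seed, gc=gc, taxon_ids=ids,
    )
    genomes, truth = [], {}
    for tid, rate in zip(ids, divergence_gradient):
        spec = DivergenceSpec(substitution_rate=float(rate),
                              seed=int(rng.integers(2**31 - 1)))
        g, glog = mutate_genome(ancestor, spec, mutated_id=tid)
        genomes.append(g)
        truth[tid] = {
            "rate": float(rate),
            "genome_identity_vs_ancestor": glog.true_identity(),
            "panel_identity_vs_ancestor": panel_logs[tid].true_identity(),
        }
    return genomes, profiles, truth
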