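"""Shared fixtures: tiny genomes, panels and alignments generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from anitax.mlsa import ConcatProfile
from anitax.seqio import GenomeRecord
from anitax.synthetic import generate_genome


@pytest.fixture
def small_genome() -> GenomeRecord:
    """10 kbp single-contig genome at 45 % G+C."""
    return generate_genome(10_000, gc=0.45, seed=101, genome_id="g10k")


@pytest.fixture
def mk_fasta(tmp_path):
    """Write (id, sequence) pairs to a FASTA file and return its path."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def mutate_at(seq: str, positions, rng=None) -> str:
    """Substitute a different base at each given position (deterministic)."""
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = alt[out[p]]
    return "".join(out)


@pytest.fixture
def profile_pair_6087():
    """Two aligned 6087-bp single-locus-panel profiles and a mutator.

    Returns (ancestor_profile, make_diverged) where make_diverged(k) is a
    profile differing from the ancestor at exactly k sites.
    """
    rng = np.random.default_rng(77)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=6087))
    anc = ConcatProfile(taxon_id="anc", loci=[("locusA", seq)])

    def make(k: int, taxon_id: str = "div") -> ConcatProfile:
        pos = rng.choice(6087, size=k, replace=False)
        return ConcatProfile(taxon_id=taxon_id, loci=[("locusA", mutate_at(seq, pos))])

    return anc, make


def perfect_alignment(tree, per_edge=60, per_leaf=5):
    """Homoplasy-free alignment for a tree: one column block per internal
    edge (binary split states) plus a few private columns per leaf."""
    from anitax.phylo import bipartitions

    leaves = sorted(t.name for t in tree.tips())
    cols = {l: [] for l in leaves}
    for part in bipartitions(tree):
        for l in leaves:
            cols[l].extend(("A" if l in part else "C") * per_edge)
    for i, l in enumerate(leaves):
        for j, other in enumerate(leaves):
            cols[other].extend(("G" if i == j else "T") * per_leaf)
    return {l: "".join(v) for l, v in cols.items()}
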