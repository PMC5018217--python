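"""Species demarcation from ANI values.

Prokaryotic genomes with ANI below the conventional 95–96 % band are
treated as different species. The partitioner applies a hard threshold
(default 95.0, the conservative end of the band) by single-linkage
connectivity: taxa land in one species cluster when a chain of pairs at or
above the threshold connects them. Pairs inside the [95, 96) band are
always flagged as ambiguous, whatever threshold is chosen, and chains that
merge taxa whose direct ANI is below the threshold raise a chaining
warning rather than being silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import numpy as np

from .calibrate import AniPrediction
from .seqio import SymMatrix

__all__ = ["SpeciesPartition", "partition_species", "classify_against_type", "Verdict"]

AMBIGUOUS_BAND = (95.0, 96.0)

Verdict = Literal["same_species", "new_species", "ambiguous"]


@dataclass
class SpeciesPartition:
    """Clusters induced by thresholding an ANI matrix."""

    clusters: list[frozenset[str]]
    threshold_used: float
    ambiguous_pairs: list[tuple[str, str, float]]
    method: str = "single-linkage"
    chained_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.clusters)

    def cluster_of(self, taxon: str) -> frozenset[str]:
        for cluster in self.clusters:
            if taxon in cluster:
                return cluster
        raise KeyError(f"taxon {taxon!r} not in partition")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold_used,
            "n_species": self.n_species,
            "clusters": [sorted(c) for c in self.clusters],
            "ambiguous_pairs": [list(p) for p in self.ambiguous_pairs],
            "chained_pairs": [list(p) for p in self.chained_pairs],
        }


def partition_species(ani: SymMatrix, threshold: float = 95.0) -> SpeciesPartition:
    """Single-linkage species clusters over edges with ANI >= threshold.

    Missing cells are treated as below-threshold with a warning. Clusters
    are reported sorted by their smallest member, so taxon order never
    affects the result.
    """
    if ani.kind != "ani":
        raise ValueError(f"expected an ani matrix, got kind={ani.kind!r}")
    g = nx.Graph()
    g.add_nodes_from(ani.labels)
    ambiguous, missing = [], []
    for a, b, v in ani.offdiagonal():
        if np.isnan(v):
            missing.append((a, b))
            continue
        if AMBIGUOUS_BAND[0] <= v < AMBIGUOUS_BAND[1]:
            ambiguous.append((a, b, v))
        if v >= threshold:
            g.add_edge(a, b, ani=v)
    if missing:
        warnings.warn(
            f"{len(missing)} missing ANI cells treated as below threshold: {missing}",
            stacklevel=2,
        )
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: min(c),
    )
    chained = []
    for cluster in clusters:
        members = sorted(cluster)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                v = ani.value(members[i], members[j])
                if np.isnan(v) or v < threshold:
                    chained.append((members[i], members[j], v))
    if chained:
        warnings.warn(
            f"single-linkage chaining merged {len(chained)} below-threshold pair(s)",
            stacklevel=2,
        )
    return SpeciesPartition(
        clusters=clusters,
        threshold_used=float(threshold),
        ambiguous_pairs=sorted(ambiguous),
        chained_pairs=chained,
    )


def classify_against_type(
    values: Mapping[str, float | AniPrediction],
    type_strain: str = "type",
    threshold: float = 95.0,
) -> dict[str, Verdict]:
    """Per-taxon verdict against a named type strain.

    ``values`` maps taxon id to either a measured ANI or an
    :class:`AniPrediction`; for predictions the interval's upper bound is
    the decisive quantity (a taxon is only called a new species when even
    the optimistic end of its predicted ANI stays below 95 %).
    Verdicts: < 95 new_species, [95, 96) ambiguous, >= 96 same_species.
    """
    upper_band = max(AMBIGUOUS_BAND[1], threshold)
    verdicts: dict[str, Verdict] = {}
    for taxon, value in values.items():
        v = value.upper if isinstance(value, AniPrediction) else float(value)
        if v < threshold:
            verdicts[taxon] = "new_species"
        elif v < upper_band:
            verdicts[taxon] = "ambiguous"
        else:
            verdicts[taxon] = "same_species"
    return verdicts
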