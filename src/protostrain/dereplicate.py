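"""Species gating, quality filtering, and de-replication into lineages.

The chain mirrors standard practice for building a non-redundant strain set:
first drop genomes below the species boundary (ANI to the species type/
reference below 94%), then drop low-quality assemblies (completeness /
contamination), then collapse genomes sharing >99.8% identity into a single
lineage (clade) with one representative each.

Default linkage is single (connected components of the >threshold graph),
which is order-independent and matches greedy secondary clustering closely;
complete linkage is available via scipy's hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .ani import ANIMatrix

SPECIES_GATE_DEFAULT = 94.0
DEREP_THRESHOLD_DEFAULT = 99.8
MIN_COMPLETENESS_DEFAULT = 90.0
MAX_CONTAMINATION_DEFAULT = 5.0

Linkage = Literal["single", "complete"]


@dataclass
class GenomeQuality:
    """Assembly completeness/contamination estimates (CheckM-style inputs)."""

    genome_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.completeness) or not np.isfinite(self.contamination):
            raise ValueError(f"{self.genome_id}: quality values must be finite")
        if self.completeness > 100 or self.completeness < 0:
            raise ValueError(f"{self.genome_id}: completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.genome_id}: contamination must be >= 0")

    @property
    def score(self) -> float:
        """dRep-style genome score used for representative selection."""
        return self.completeness - 5.0 * self.contamination


@dataclass
class Clade:
    """A de-replicated lineage: representative, members, mean intra-clade ANI."""

    representative_id: str
    member_ids: list[str]
    mean_intra_ani: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a clade member")
        if not (0.0 <= self.mean_intra_ani <= 100.0):
            raise ValueError("mean intra-clade ANI must be in [0, 100]")


def filter_genomes(
    genome_ids: Sequence[str],
    quality: Sequence[GenomeQuality],
    ani_to_type: Mapping[str, float],
    species_gate: float = SPECIES_GATE_DEFAULT,
    min_completeness: float = MIN_COMPLETENESS_DEFAULT,
    max_contamination: float = MAX_CONTAMINATION_DEFAULT,
) -> tuple[list[str], dict[str, str]]:
    """Apply the species and quality gates.

    A genome is retained iff its ANI to the species type/reference genome is
    >= ``species_gate`` AND completeness >= ``min_completeness`` AND
    contamination <= ``max_contamination``.  Returns retained ids (input
    order) and a rejection-reason map for the rest.
    """
    qmap = {q.genome_id: q for q in quality}
    retained: list[str] = []
    rejected: dict[str, str] = {}
    for gid in genome_ids:
        if gid not in qmap:
            raise KeyError(f"no quality record for genome {gid!r}")
        if gid not in ani_to_type:
            raise KeyError(f"no ANI-to-reference value for genome {gid!r}")
        if ani_to_type[gid] < species_gate:
            rejected[gid] = "species_gate"
            continue
        q = qmap[gid]
        if q.completeness < min_completeness or q.contamination > max_contamination:
            rejected[gid] = "quality"
            continue
        retained.append(gid)
    return retained, rejected


def cluster_lineages(
    matrix: ANIMatrix,
    threshold: float = DEREP_THRESHOLD_DEFAULT,
    linkage: Linkage = "single",
) -> list[list[str]]:
    """Partition genomes into lineages at strictly-greater-than ``threshold`` ANI.

    Returns member-id groups, each sorted lexicographically, groups ordered by
    their first member — a deterministic, input-order-invariant labelling.
    """
    ids = matrix.ids
    n = len(ids)
    if n == 1:
        return [[ids[0]]]
    if linkage == "single":
        adj = matrix.values > threshold
        np.fill_diagonal(adj, True)
        n_comp, labels = connected_components(adj, directed=False)
        groups = [[] for _ in range(n_comp)]
        for gid, lab in zip(ids, labels):
            groups[lab].append(gid)
    elif linkage == "complete":
        dist = 100.0 - matrix.values
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        z = scipy_linkage(condensed, method="complete")
        # fcluster merges at distance <= t; the lineage rule is strict (> threshold
        # identity, i.e. distance < 100-threshold), hence the nextafter nudge
        t = np.nextafter(100.0 - threshold, -np.inf)
        labels = fcluster(z, t=t, criterion="distance")
        groups_map: dict[int, list[str]] = {}
        for gid, lab in zip(ids, labels):
            groups_map.setdefault(int(lab), []).append(gid)
        groups = list(groups_map.values())
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    groups = [sorted(g) for g in groups]
    groups.sort(key=lambda g: g[0])
    return groups


def summarize_clades(
    groups: Sequence[Sequence[str]],
    matrix: ANIMatrix,
    quality: Sequence[GenomeQuality],
    genome_lengths: Mapping[str, int] | None = None,
    singleton_ani: float = 100.0,
) -> list[Clade]:
    """Attach the mean intra-clade ANI and pick a representative per lineage.

    The mean is over unordered member pairs; a singleton clade defaults to
    ``singleton_ani`` (self-identity convention, 100.0).  The representative
    maximises completeness − 5·contamination, ties broken by genome length
    (longest first) then lexicographic id.
    """
    qmap = {q.genome_id: q for q in quality}
    lengths = genome_lengths or {}
    idx = {gid: i for i, gid in enumerate(matrix.ids)}
    clades: list[Clade] = []
    for group in groups:
        for gid in group:
            if gid not in idx:
                raise KeyError(f"clade member {gid!r} missing from the ANI matrix")
            if gid not in qmap:
                raise KeyError(f"clade member {gid!r} missing from quality records")
        members = sorted(group)
        if len(members) == 1:
            mean_ani = singleton_ani
        else:
            pairs = [
                matrix.values[idx[a], idx[b]]
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            ]
            mean_ani = float(np.mean(pairs))
        rep = min(
            members,
            key=lambda g: (-qmap[g].score, -lengths.get(g, 0), g),
        )
        clades.append(Clade(representative_id=rep, member_ids=members, mean_intra_ani=mean_ani))
    return clades


def dereplicate(
    matrix: ANIMatrix,
    quality: Sequence[GenomeQuality],
    threshold: float = DEREP_THRESHOLD_DEFAULT,
    linkage: Linkage = "single",
    genome_lengths: Mapping[str, int] | None = None,
) -> list[Clade]:
    """cluster_lineages + summarize_clades in one call."""
    groups = cluster_lineages(matrix, threshold=threshold, linkage=linkage)
    return summarize_clades(groups, matrix, quality, genome_lengths=genome_lengths)
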