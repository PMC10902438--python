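"""Gene-family (COG) clustering and core / dispensable / unique partitioning.

Proteins from N genomes are compared all-vs-all with local affine-gap
alignments; a similarity edge is kept when it clears three cut-offs at once:
E-value < 1e-5, >= 50% identity, and alignment coverage >= 80% of BOTH
protein sequences.  Gene families are the clusters of the kept-edge graph —
connected components by default, with an MCL-style Markov clustering option.

Families are then partitioned by genome span: a family present in all N
genomes is core, in exactly one genome unique (its members are that
genome's truly unique genes, TUGs), otherwise dispensable.  With a single
input genome every family is classified unique (TUG semantics dominate).

E-values are computed from alignment scores via the Karlin-Altschul
relation E = K * m * n' * exp(-lambda * S) with the gapped BLOSUM62-11-1
constants (lambda = 0.267, K = 0.041) and search space = query length x
total database residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ppos import ScoringScheme, align_proteins, percent_identity, shared_word_pairs
from .seqio import SequenceRecord

KA_LAMBDA = 0.267
KA_K = 0.041

E_MAX_DEFAULT = 1e-5
MIN_IDENTITY_DEFAULT = 50.0
MIN_COVERAGE_DEFAULT = 0.8

FamilyClass = Literal["core", "dispensable", "unique"]


@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    identity: float
    coverage_query: float
    coverage_subject: float
    e_value: float

    def passes(self, e_max: float, min_identity: float, min_coverage: float) -> bool:
        return (
            self.e_value < e_max
            and self.identity >= min_identity
            and self.coverage_query >= min_coverage
            and self.coverage_subject >= min_coverage
        )


@dataclass
class GeneFamily:
    family_id: str
    members: set[tuple[str, str]]  # (genome_id, gene_id)
    family_class: FamilyClass | None = None

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


def karlin_altschul_evalue(
    score: float, query_len: int, db_len: int, lam: float = KA_LAMBDA, k: float = KA_K
) -> float:
    """Expected number of chance local alignments scoring >= score."""
    return k * query_len * db_len * math.exp(-lam * score)


def cluster_gene_families(
    proteomes: Mapping[str, Sequence[SequenceRecord]],
    scheme: ScoringScheme | None = None,
    e_max: float = E_MAX_DEFAULT,
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_coverage: float = MIN_COVERAGE_DEFAULT,
    method: Literal["components", "mcl"] = "components",
    inflation: float = 1.5,
    word: int = 4,
    min_shared_words: int = 2,
) -> list[GeneFamily]:
    """Cluster all genes of all genomes into families under the three cut-offs.

    Every gene belongs to exactly one family; genes with no qualifying edge
    form singleton families.  Candidate pairs are pre-seeded by shared exact
    words (see :func:`protostrain.ppos.shared_word_pairs`) so unrelated
    proteins are never aligned.
    """
    scheme = scheme or ScoringScheme()
    genes: list[tuple[str, str]] = []  # (genome_id, gene_id)
    records: list[SequenceRecord] = []
    seen: set[tuple[str, str]] = set()
    for genome_id, proteome in proteomes.items():
        for rec in proteome:
            key = (genome_id, rec.id)
            if key in seen:
                raise ValueError(f"duplicate gene id {rec.id!r} in genome {genome_id!r}")
            seen.add(key)
            genes.append(key)
            records.append(rec)
    db_len = sum(len(r.seq) for r in records)

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    cand = shared_word_pairs([r.seq for r in records], word=word, min_shared=min_shared_words)
    weights: dict[tuple[int, int], float] = {}
    for i, j in sorted(cand):
        if i >= j:  # symmetric seeding; align each unordered pair once
            continue
        pair = align_proteins(records[i], records[j], scheme, mode="local")
        if pair.aligned_columns == 0:
            continue
        hit = SimilarityHit(
            query_id=records[i].id,
            subject_id=records[j].id,
            identity=percent_identity(pair),
            coverage_query=pair.coverage_query,
            coverage_subject=pair.coverage_target,
            e_value=karlin_altschul_evalue(pair.score, len(records[i].seq), db_len),
        )
        if hit.passes(e_max, min_identity, min_coverage):
            graph.add_edge(genes[i], genes[j])
            weights[(i, j)] = pair.score

    if method == "components":
        clusters = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "mcl":
        clusters = []
        for comp in nx.connected_components(graph):
            comp = sorted(comp)
            if len(comp) <= 2:
                clusters.append(comp)
                continue
            sub = _mcl(graph.subgraph(comp), comp, inflation)
            clusters.extend(sub)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    clusters.sort(key=lambda c: c[0])
    return [
        GeneFamily(family_id=f"F{i + 1:06d}", members=set(c))
        for i, c in enumerate(clusters)
    ]


def _mcl(subgraph: nx.Graph, nodes: list, inflation: float, max_iter: int = 100) -> list[list]:
    """Dense Markov clustering on one connected component (small by construction)."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.eye(n)  # self-loops, standard MCL regularisation
    for u, v in subgraph.edges():
        m[index[u], index[v]] = m[index[v], index[u]] = 1.0
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.allclose(inflated, m, atol=1e-8):
            m = inflated
            break
        m = inflated
    attractors = np.where(np.diag(m) > 1e-6)[0]
    clusters: list[list] = []
    assigned: set[int] = set()
    for a in attractors:
        members = sorted(set(np.where(m[a] > 1e-6)[0]) | {a})
        members = [i for i in members if i not in assigned]
        if members:
            assigned.update(members)
            clusters.append([nodes[i] for i in members])
    for i in range(n):  # safety: never drop a gene
        if i not in assigned:
            clusters.append([nodes[i]])
    return [sorted(c) for c in clusters]


@dataclass
class PangenomeSummary:
    n_genomes: int
    pangenome: int
    core: int
    dispensable: int
    unique: int
    tugs_per_genome: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_genomes": self.n_genomes,
                    "pangenome": self.pangenome,
                    "core": self.core,
                    "dispensable": self.dispensable,
                    "unique": self.unique,
                }
            ]
        )


def classify_families(
    families: Sequence[GeneFamily], genome_ids: Sequence[str]
) -> PangenomeSummary:
    """Partition families into core / dispensable / unique and count TUGs.

    Mutates each family's ``family_class``.  A family spanning a genome not
    in ``genome_ids`` is an error.
    """
    genome_set = set(genome_ids)
    n = len(genome_set)
    core = dispensable = unique = 0
    tugs = {g: 0 for g in genome_ids}
    for fam in families:
        span = fam.genomes()
        stray = span - genome_set
        if stray:
            raise ValueError(f"family {fam.family_id} spans undeclared genomes {sorted(stray)}")
        if len(span) == 1:  # unique takes precedence when n == 1
            fam.family_class = "unique"
            unique += 1
            tugs[next(iter(span))] += 1
        elif len(span) == n:
            fam.family_class = "core"
            core += 1
        else:
            fam.family_class = "dispensable"
            dispensable += 1
    return PangenomeSummary(
        n_genomes=n,
        pangenome=len(families),
        core=core,
        dispensable=dispensable,
        unique=unique,
        tugs_per_genome=tugs,
    )


def membership_table(families: Sequence[GeneFamily]) -> pd.DataFrame:
    rows = [
        {
            "family_id": fam.family_id,
            "genome_id": genome,
            "gene_id": gene,
            "class": fam.family_class,
        }
        for fam in families
        for genome, gene in sorted(fam.members)
    ]
    return pd.DataFrame(rows)


def presence_absence_matrix(
    families: Sequence[GeneFamily], genome_ids: Sequence[str]
) -> pd.DataFrame:
    data = {
        fam.family_id: [int(g in fam.genomes()) for g in genome_ids] for fam in families
    }
    return pd.DataFrame(data, index=list(genome_ids)).T
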