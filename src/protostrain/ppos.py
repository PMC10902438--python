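"""Proteome-vs-proteome matching by PPOS (percentage of positive-scoring matches).

Given a prototype strain and a set of local candidate strains, each
candidate's proteome is aligned to the prototype's, ortholog pairs are
formed by reciprocal best hits, and each pair's PPOS — the fraction of
alignment columns whose substitution-matrix score is positive — is averaged
into the candidate's avg PPOS.  Candidates are ranked by the selection score

    score = ANI x avg PPOS

so the top-ranked candidate is the local strain most representative of the
prototype, genomically (ANI) and proteome-wide (PPOS).

Alignment uses affine-gap dynamic programming (Biopython's PairwiseAligner)
with BLOSUM62 and gap penalties 11 (open) / 1 (extend), mirroring BLASTP
defaults; the default mode for ortholog pairing is global with free end
gaps, the usual convention for comparing full-length protein sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

AlignMode = Literal["global", "local"]
Aggregation = Literal["mean", "length_weighted"]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap penalties (BLAST convention: a gap of
    length L costs gap_open + L * gap_extend)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


def make_aligner(scheme: ScoringScheme, mode: AlignMode = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix
    # BLAST charges open+extend for the first gap position
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    if mode == "local":
        aligner.mode = "local"
    elif mode == "global":
        aligner.mode = "global"
        try:  # free end gaps (attribute names changed across Biopython releases)
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # pragma: no cover
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return aligner


@dataclass
class OrthologPair:
    """Column statistics of one query-target protein alignment."""

    query_id: str
    target_id: str
    aligned_columns: int
    identical: int
    positives: int
    coverage_query: float
    coverage_target: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.identical <= self.positives <= self.aligned_columns):
            raise ValueError(
                f"{self.query_id}/{self.target_id}: need identical <= positives <= columns"
            )


def _column_stats(row_a: str, row_b: str, matrix) -> tuple[int, int, int]:
    """(columns, identical, positives) over an already-trimmed alignment."""
    columns = len(row_a)
    identical = positives = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            identical += 1
        if matrix[ca, cb] > 0:
            positives += 1
    return columns, identical, positives


def align_proteins(
    a: SequenceRecord,
    b: SequenceRecord,
    scheme: ScoringScheme | None = None,
    mode: AlignMode = "global",
) -> OrthologPair:
    """Optimal affine-gap alignment of two proteins with column statistics.

    Statistics are computed over the aligned region: terminal free-end gap
    columns are excluded in global mode; local alignments cover only the
    optimal local region by construction.
    """
    if a.moltype != "protein" or b.moltype != "protein":
        raise ValueError("align_proteins requires protein records")
    scheme = scheme or ScoringScheme()
    aligner = make_aligner(scheme, mode)
    best = aligner.align(a.seq, b.seq)[0]
    row_a, row_b = best[0], best[1]
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    row_a, row_b = row_a[start:end], row_b[start:end]
    columns, identical, positives = _column_stats(row_a, row_b, scheme.matrix)
    cov_q = (len(row_a) - row_a.count("-")) / len(a.seq)
    cov_t = (len(row_b) - row_b.count("-")) / len(b.seq)
    return OrthologPair(
        query_id=a.id,
        target_id=b.id,
        aligned_columns=columns,
        identical=identical,
        positives=positives,
        coverage_query=cov_q,
        coverage_target=cov_t,
        score=float(best.score),
    )


def compute_ppos(pair: OrthologPair) -> float:
    """PPOS% = 100 x positives / aligned columns."""
    if pair.aligned_columns == 0:
        raise ValueError(f"{pair.query_id}/{pair.target_id}: zero aligned columns")
    return 100.0 * pair.positives / pair.aligned_columns


def percent_identity(pair: OrthologPair) -> float:
    if pair.aligned_columns == 0:
        raise ValueError(f"{pair.query_id}/{pair.target_id}: zero aligned columns")
    return 100.0 * pair.identical / pair.aligned_columns


def shared_word_pairs(
    seqs_a: Sequence[str],
    seqs_b: Sequence[str] | None = None,
    word: int = 4,
    min_shared: int = 2,
) -> set[tuple[int, int]]:
    """Index pairs sharing >= min_shared exact length-`word` substrings.

    A BLAST-like seeding heuristic: unrelated random proteins almost never
    share multiple exact words, while homologs at the identity levels this
    pipeline clusters share many.  Sequences shorter than ``word + min_shared``
    are paired with everything (alignment decides).
    """
    from collections import Counter, defaultdict

    symmetric = seqs_b is None
    seqs_b = seqs_a if symmetric else seqs_b

    def words(seq: str) -> set[str]:
        return {seq[i : i + word] for i in range(len(seq) - word + 1)}

    index: dict[str, list[int]] = defaultdict(list)
    for j, seq in enumerate(seqs_b):
        for w in words(seq):
            index[w].append(j)

    pairs: set[tuple[int, int]] = set()
    short_b = [j for j, s in enumerate(seqs_b) if len(s) < word + min_shared]
    for i, seq in enumerate(seqs_a):
        if len(seq) < word + min_shared:
            pairs.update((i, j) for j in range(len(seqs_b)) if not (symmetric and i == j))
            continue
        counts: Counter[int] = Counter()
        for w in words(seq):
            counts.update(index[w])
        for j, c in counts.items():
            if symmetric and i == j:
                continue
            if c >= min_shared:
                pairs.add((i, j))
        pairs.update((i, j) for j in short_b if not (symmetric and i == j))
    return pairs


def reciprocal_best_hits(
    proteome_q: Sequence[SequenceRecord],
    proteome_t: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    mode: AlignMode = "global",
    prefilter: bool = True,
) -> list[OrthologPair]:
    """Ortholog pairs (q, t) where each is the other's best-scoring hit.

    Ties on score are broken by higher PPOS, then lexicographic partner id.
    Each protein appears in at most one pair.
    """
    if not proteome_q or not proteome_t:
        raise ValueError("both proteomes must be non-empty")
    scheme = scheme or ScoringScheme()
    if prefilter:
        cand = shared_word_pairs([r.seq for r in proteome_q], [r.seq for r in proteome_t])
    else:
        cand = {(i, j) for i in range(len(proteome_q)) for j in range(len(proteome_t))}
    aligned: dict[tuple[int, int], OrthologPair] = {}
    for i, j in sorted(cand):
        aligned[(i, j)] = align_proteins(proteome_q[i], proteome_t[j], scheme, mode)

    def best_partner(this: int, axis: int) -> int | None:
        hits = [
            (pair, ij[1 - axis])
            for ij, pair in aligned.items()
            if ij[axis] == this and pair.aligned_columns > 0
        ]
        if not hits:
            return None
        ids = [r.id for r in (proteome_t if axis == 0 else proteome_q)]
        hits.sort(key=lambda h: (-h[0].score, -compute_ppos(h[0]), ids[h[1]]))
        return hits[0][1]

    pairs: list[OrthologPair] = []
    for i in range(len(proteome_q)):
        j = best_partner(i, axis=0)
        if j is None:
            continue
        if best_partner(j, axis=1) == i:
            pairs.append(aligned[(i, j)])
    return pairs


@dataclass
class PPOSReport:
    """One candidate's aggregate comparison to the prototype."""

    candidate_id: str
    prototype_id: str
    n_pairs: int
    avg_ppos: float | None
    ani: float
    score: float | None = None
    pairs: list[OrthologPair] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.avg_ppos is not None and self.score is None:
            self.score = selection_score(self.ani, self.avg_ppos)


def selection_score(ani: float, avg_ppos: float) -> float:
    """ANI x avg PPOS, the prototype-matching selection score."""
    if not (0.0 <= ani <= 100.0) or not (0.0 <= avg_ppos <= 100.0):
        raise ValueError("ani and avg_ppos must be percentages in [0, 100]")
    return ani * avg_ppos


def score_candidates(
    candidates: Sequence[tuple[str, Sequence[SequenceRecord], float]],
    prototype_id: str,
    prototype_proteome: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    aggregation: Aggregation = "mean",
    prefilter: bool = True,
) -> list[PPOSReport]:
    """Score (candidate_id, proteome, ani) triples against the prototype.

    avg PPOS aggregates reciprocal-best-hit pair PPOS values, unweighted by
    default or weighted by alignment length.  Candidates without any
    ortholog pair are reported with avg_ppos None and rank last.
    """
    if not candidates:
        raise ValueError("at least one candidate is required")
    scheme = scheme or ScoringScheme()
    reports: list[PPOSReport] = []
    for cand_id, proteome, ani in candidates:
        pairs = reciprocal_best_hits(
            proteome, prototype_proteome, scheme=scheme, prefilter=prefilter
        )
        if not pairs:
            warnings.warn(f"candidate {cand_id!r}: no ortholog pairs; excluded from ranking")
            reports.append(
                PPOSReport(
                    candidate_id=cand_id,
                    prototype_id=prototype_id,
                    n_pairs=0,
                    avg_ppos=None,
                    ani=ani,
                )
            )
            continue
        ppos_vals = np.array([compute_ppos(p) for p in pairs])
        if aggregation == "mean":
            avg = float(ppos_vals.mean())
        elif aggregation == "length_weighted":
            w = np.array([p.aligned_columns for p in pairs], dtype=float)
            avg = float(np.average(ppos_vals, weights=w))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        reports.append(
            PPOSReport(
                candidate_id=cand_id,
                prototype_id=prototype_id,
                n_pairs=len(pairs),
                avg_ppos=avg,
                ani=ani,
                pairs=list(pairs),
            )
        )
    ranked = [r for r in reports if r.avg_ppos is not None]
    ranked.sort(key=lambda r: (-r.score, r.candidate_id))
    return ranked + [r for r in reports if r.avg_ppos is None]


def report_table(reports: Iterable[PPOSReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate": r.candidate_id,
                "prototype": r.prototype_id,
                "n_pairs": r.n_pairs,
                "ani": r.ani,
                "avg_ppos": None if r.avg_ppos is None else round(r.avg_ppos, 2),
                "score": None if r.score is None else round(r.score, 1),
            }
            for r in reports
        ]
    )
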