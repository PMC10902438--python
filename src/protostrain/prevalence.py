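"""Lineage detection in metagenome samples via discriminative k-mers.

Each de-replicated lineage is represented by its marker set: the canonical
k-mers present in its representative genome and absent from every other
representative.  Marker sets of distinct lineages are therefore disjoint by
construction, so a sample containing only a sibling lineage scores zero
breadth on this lineage's markers even at >99% whole-genome identity.

Detection is a breadth rule: the fraction of a lineage's markers observed in
the sample's k-mer content must reach a threshold (default 0.5).  Prevalence
of a lineage in a cohort is the exact fraction of samples in which it is
detected, with ALL cohort samples in the denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import KmerSet, sorted_unique

BREADTH_THRESHOLD_DEFAULT = 0.5


@dataclass
class MarkerSet:
    """Canonical k-mers unique to one lineage representative."""

    lineage_id: str
    k: int
    markers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=np.uint64)

    def __len__(self) -> int:
        return int(self.markers.size)


@dataclass
class Detection:
    lineage_id: str
    detected: bool
    breadth: float  # NaN when the lineage has an empty marker set


@dataclass
class CohortProfile:
    """Per-cohort detection counts and exact prevalence fractions."""

    cohort_name: str
    n_samples: int
    detections: dict[str, int]
    prevalence: dict[str, float]

    def __post_init__(self) -> None:
        for lid, count in self.detections.items():
            if not (0 <= count <= self.n_samples):
                raise ValueError(f"{lid}: detection count outside [0, n_samples]")
            expected = count / self.n_samples if self.n_samples else 0.0
            if not math.isclose(self.prevalence[lid], expected, rel_tol=0, abs_tol=1e-15):
                raise ValueError(f"{lid}: prevalence is not count/n_samples")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cohort": self.cohort_name,
                "lineage": lid,
                "detections": self.detections[lid],
                "n_samples": self.n_samples,
                "prevalence": self.prevalence[lid],
                "prevalence_pct": f"{100.0 * self.prevalence[lid]:.2f}%",
            }
            for lid in sorted(self.detections)
        ]
        return pd.DataFrame(rows)


def build_markers(representatives: Sequence[KmerSet]) -> list[MarkerSet]:
    """Discriminative k-mers per lineage: own k-mers minus the union of all others."""
    if not representatives:
        raise ValueError("at least one representative k-mer set is required")
    ks = {r.k for r in representatives}
    if len(ks) > 1:
        raise ValueError(f"representatives mix k values: {sorted(ks)}")
    out: list[MarkerSet] = []
    for i, rep in enumerate(representatives):
        others = [r.kmers for j, r in enumerate(representatives) if j != i]
        if others:
            pool = sorted_unique(np.concatenate(others))
            markers = np.setdiff1d(rep.kmers, pool, assume_unique=True)
        else:
            markers = rep.kmers.copy()
        if markers.size == 0:
            warnings.warn(
                f"lineage {rep.source_id!r} has an empty marker set "
                "(k-mer content indistinguishable from another lineage)"
            )
        out.append(MarkerSet(lineage_id=rep.source_id, k=rep.k, markers=markers))
    return out


def marker_breadth(sample: KmerSet, markers: MarkerSet) -> float:
    """Fraction of a lineage's markers present in the sample (NaN if no markers)."""
    if sample.k != markers.k:
        raise ValueError(f"k mismatch: sample k={sample.k}, markers k={markers.k}")
    if len(markers) == 0:
        return float("nan")
    if sample.kmers.size == 0:
        return 0.0
    # both arrays are sorted uint64: membership via searchsorted
    pos = np.searchsorted(sample.kmers, markers.markers)
    pos[pos >= sample.kmers.size] = 0
    hits = sample.kmers[pos] == markers.markers
    return float(np.count_nonzero(hits)) / len(markers)


def detect_lineage(
    sample: KmerSet,
    markers: MarkerSet,
    breadth_threshold: float = BREADTH_THRESHOLD_DEFAULT,
) -> Detection:
    breadth = marker_breadth(sample, markers)
    detected = bool(not math.isnan(breadth) and breadth >= breadth_threshold)
    return Detection(lineage_id=markers.lineage_id, detected=detected, breadth=breadth)


def detection_matrix(
    samples: Sequence[KmerSet],
    markers: Sequence[MarkerSet],
    breadth_threshold: float = BREADTH_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Samples × lineages breadth table (values in [0,1], NaN for empty marker sets)."""
    data = {
        ms.lineage_id: [marker_breadth(sample, ms) for sample in samples] for ms in markers
    }
    return pd.DataFrame(data, index=[s.source_id for s in samples])


def cohort_prevalence(
    samples: Sequence[KmerSet],
    markers: Sequence[MarkerSet],
    cohort_name: str,
    breadth_threshold: float = BREADTH_THRESHOLD_DEFAULT,
) -> CohortProfile:
    """Detection counts and exact prevalence fractions over ALL cohort samples."""
    if not samples:
        raise ValueError("a cohort requires at least one sample")
    n = len(samples)
    detections: dict[str, int] = {}
    for ms in markers:
        count = sum(
            detect_lineage(sample, ms, breadth_threshold).detected for sample in samples
        )
        detections[ms.lineage_id] = count
    prevalence = {lid: c / n for lid, c in detections.items()}
    return CohortProfile(
        cohort_name=cohort_name, n_samples=n, detections=detections, prevalence=prevalence
    )
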