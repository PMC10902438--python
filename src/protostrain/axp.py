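"""AxP prototype ranking.

The AxP index couples a phylogenomic term with an ecological one:

    AxP = (ANI term) x (prevalence) x 100

where the ANI term is, by default, the mean pairwise ANI among the genomes
of the lineage (its clade), and prevalence is the exact fraction of cohort
samples in which the lineage is detected.  The lineage with the highest AxP
in a cohort is that cohort's prototype.

Prevalence is kept as the exact fraction count/n — the percentage printed in
reports is rounded too coarsely to regenerate AxP values from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd


def compute_axp(ani_term: float, prevalence: float) -> float:
    """AxP = ani_term x prevalence x 100, at full precision."""
    if not (0.0 <= ani_term <= 100.0):
        raise ValueError(f"ani_term must be in [0, 100], got {ani_term}")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    return ani_term * prevalence * 100.0


@dataclass
class AxPRecord:
    """One lineage x cohort ranking unit."""

    lineage_id: str
    cohort: str
    ani_term: float
    prevalence: float
    axp: float | None = None

    def __post_init__(self) -> None:
        expected = compute_axp(self.ani_term, self.prevalence)
        if self.axp is None:
            self.axp = expected

    @property
    def axp_rounded(self) -> float:
        """The 2-decimal rendering used in reports."""
        return round(self.axp, 2)


def rank_prototypes(records: Sequence[AxPRecord], cohort: str) -> list[AxPRecord]:
    """Rank a cohort's lineages by AxP descending; the head is the prototype.

    Ties broken by higher ANI term, then lexicographic lineage id.
    """
    pool = [r for r in records if r.cohort == cohort]
    if not pool:
        raise ValueError(f"no AxP records for cohort {cohort!r}")
    return sorted(pool, key=lambda r: (-r.axp, -r.ani_term, r.lineage_id))


def axp_table(records: Sequence[AxPRecord]) -> pd.DataFrame:
    """Report-style table: one row per lineage, AxP columns per cohort."""
    cohorts = sorted({r.cohort for r in records})
    rows: dict[str, dict] = {}
    for r in records:
        row = rows.setdefault(r.lineage_id, {"lineage": r.lineage_id, "ani_term": r.ani_term})
        row[f"{r.cohort}_prevalence_pct"] = round(100.0 * r.prevalence, 2)
        row[f"{r.cohort}_axp"] = r.axp_rounded
    df = pd.DataFrame(list(rows.values()))
    first = cohorts[0]
    return df.sort_values(f"{first}_axp", ascending=False, ignore_index=True)
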