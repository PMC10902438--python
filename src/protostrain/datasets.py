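"""Bundled worked-example data for *Bifidobacterium breve* prototype selection.

Two small published summary tables ship with the package so the AxP and
selection-score arithmetic can be exercised and demonstrated without any
genome or metagenome downloads:

* ``load_bbreve_lineage_table`` — 37 de-replicated *B. breve* lineages with
  their clade ANI term and their prevalence/AxP in an adult cohort
  (n = 4,019 gut metagenomes) and an infant cohort (n = 9,505).
* ``load_bbreve_candidate_table`` — 11 local *B. breve* isolates scored
  against the adult-cohort prototype (ANI, average PPOS, ANI x avg PPOS).

``ADULT_DETECTIONS`` gives integer adult-cohort detection counts for the
lineages whose printed AxP values back-solve unambiguously to counts over
the 4,019-sample denominator; these are the inputs for the worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

ADULT_COHORT_SIZE = 4019
INFANT_COHORT_SIZE = 9505

# adult-cohort detection counts consistent with the published prevalence/AxP
ADULT_DETECTIONS: dict[str, int] = {
    "NRBB09": 18,
    "MC1": 14,
    "NRBB50": 6,
    "PRL2012": 5,
    "215W447a": 1,
    "017W439": 0,
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("protostrain.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_bbreve_lineage_table() -> pd.DataFrame:
    """Published lineage table: ANI term + adult/infant prevalence and AxP."""
    return _load("bbreve_lineages.tsv")


def load_bbreve_candidate_table() -> pd.DataFrame:
    """Published candidate table: ANI, average PPOS and selection score."""
    return _load("bbreve_candidates.tsv")
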