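"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of (parameters, seed) and returns, next
to the data, a :class:`SyntheticTruth` record sufficient to compute the
expected downstream result without re-running generation:

* ``evolve_genomes`` — a species' genome set: a random ancestor plus
  lineages diverged by i.i.d. substitutions to target ANI values.
* ``simulate_cohort`` — metagenome samples as k-mer sets: shared background
  genomes plus per-lineage Bernoulli(prevalence) presence of the full
  lineage genome.
* ``simulate_proteomes`` — proteomes with planted core / dispensable /
  unique (TUG) family structure.
* ``simulate_abundances`` — log-normal relative-abundance tables with
  species tied to a focal species at target Spearman correlations via a
  Gaussian copula (Pearson r = 2 sin(pi * rho_S / 6) on the latent normals).

Evolution is substitution-only (no indels), which keeps the ANI / k-mer
arithmetic analytically checkable; see the methods note for what this does
and does not emulate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import KmerSet, SequenceRecord, canonical_kmers, sorted_unique

_NUCS = np.frombuffer(b"ACGT", dtype=np.uint8)
_AAS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    seed: int
    lineage_divergences: dict[str, float] = field(default_factory=dict)
    realized_substitutions: dict[str, float] = field(default_factory=dict)
    planted_presence: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    planted_prototype: dict[str, str] = field(default_factory=dict)
    family_structure: dict[str, int] = field(default_factory=dict)
    family_members: dict[str, list[str]] = field(default_factory=dict)
    planted_correlations: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_nucleotides(rng: np.random.Generator, length: int) -> np.ndarray:
    return _NUCS[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """i.i.d. substitutions at `rate`; each hit site becomes one of the 3 others."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        cur = out[hits]
        # map current base to a uniformly random different base
        offsets = rng.integers(1, 4, size=hits.size)
        cur_idx = np.searchsorted(_NUCS, cur)
        out[hits] = _NUCS[(cur_idx + offsets) % 4]
    return out, hits.size / seq.size


def evolve_genomes(
    ancestor_length: int,
    lineage_specs: Sequence[tuple[str, float]],
    seed: int,
) -> tuple[dict[str, SequenceRecord], SyntheticTruth]:
    """Derive lineage genomes from a random ancestor at target ANI values.

    Substitution rate per lineage is 1 - ANI/100.  Target ANI must exceed
    80 (the validity range of sketch-based ANI estimation).
    """
    rng = np.random.default_rng(seed)
    ancestor = _random_nucleotides(rng, ancestor_length)
    truth = SyntheticTruth(seed=seed)
    genomes: dict[str, SequenceRecord] = {}
    for lineage_id, target_ani in lineage_specs:
        if not (80.0 < target_ani <= 100.0):
            raise ValueError(f"{lineage_id}: target ANI must be in (80, 100], got {target_ani}")
        rate = 1.0 - target_ani / 100.0
        mutated, realized = _mutate(ancestor, rate, rng)
        genomes[lineage_id] = SequenceRecord(
            id=lineage_id, seq=mutated.tobytes().decode("ascii"), moltype="nucleotide"
        )
        truth.lineage_divergences[lineage_id] = target_ani
        truth.realized_substitutions[lineage_id] = realized
    return genomes, truth


def simulate_cohort(
    lineage_genomes: Mapping[str, SequenceRecord],
    prevalences: Mapping[str, float],
    n_samples: int,
    background: tuple[int, int] = (3, 20_000),
    seed: int = 0,
    k: int = 23,
    cohort_name: str = "cohort",
) -> tuple[list[KmerSet], SyntheticTruth]:
    """Metagenome cohort as per-sample canonical k-mer sets.

    Every sample carries the k-mers of `background` random genomes (shared
    across the cohort); each lineage's full genome k-mers are added with
    independent Bernoulli(prevalence) draws.  Presence flags are recorded
    in the truth object, keyed cohort -> sample -> present lineages.
    """
    for lid, p in prevalences.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{lid}: prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bg, bg_len = background
    bg_arrays = [
        canonical_kmers(
            SequenceRecord(id=f"bg{i}", seq=_random_nucleotides(rng, bg_len).tobytes().decode()),
            k,
        ).kmers
        for i in range(n_bg)
    ]
    bg_union = (
        sorted_unique(np.concatenate(bg_arrays))
        if bg_arrays
        else np.empty(0, dtype=np.uint64)
    )
    lineage_kmers = {lid: canonical_kmers(rec, k).kmers for lid, rec in lineage_genomes.items()}

    truth = SyntheticTruth(seed=seed)
    truth.planted_presence[cohort_name] = {}
    if prevalences:
        best = max(
            prevalences, key=lambda lid: (prevalences[lid], lid)
        )
        truth.planted_prototype[cohort_name] = best
    samples: list[KmerSet] = []
    lineage_ids = sorted(prevalences)
    for i in range(n_samples):
        sample_id = f"{cohort_name}_s{i:04d}"
        present = [lid for lid in lineage_ids if rng.random() < prevalences[lid]]
        parts = [bg_union] + [lineage_kmers[lid] for lid in present]
        kmers = sorted_unique(np.concatenate(parts))
        samples.append(KmerSet(source_id=sample_id, k=k, kmers=kmers))
        truth.planted_presence[cohort_name][sample_id] = present
    return samples, truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return _AAS[rng.integers(0, 20, size=length)].tobytes().decode("ascii")


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        cur_idx = np.searchsorted(_AAS, arr[hits])
        offsets = rng.integers(1, 20, size=hits.size)
        arr[hits] = _AAS[(cur_idx + offsets) % 20]
    return arr.tobytes().decode("ascii")


def simulate_proteomes(
    n_genomes: int,
    core: int,
    dispensable_rate: float = 0.2,
    tugs_per_genome: int = 30,
    divergence: float = 0.05,
    seed: int = 0,
    length_range: tuple[int, int] = (120, 260),
) -> tuple[dict[str, list[SequenceRecord]], SyntheticTruth]:
    """Proteomes with planted core / dispensable / unique family structure.

    * ``core`` families appear in every genome (one member each), members
      diverged from a family ancestor by i.i.d. substitutions at
      ``divergence``.
    * ``round(dispensable_rate * core)`` dispensable families appear in a
      random proper subset (>= 2, < n) of genomes.
    * ``tugs_per_genome`` unique proteins are drawn independently per genome
      with no homolog anywhere else.

    ``divergence`` must keep within-family identity far above the 50%
    clustering cut-off; values <= 0.2 are accepted.
    """
    if not (0.0 <= divergence <= 0.2):
        raise ValueError("divergence must be in [0, 0.2] to respect clustering cut-offs")
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    rng = np.random.default_rng(seed)
    genome_ids = [f"G{i + 1:02d}" for i in range(n_genomes)]
    proteomes: dict[str, list[SequenceRecord]] = {g: [] for g in genome_ids}
    truth = SyntheticTruth(seed=seed)
    n_disp = int(round(dispensable_rate * core)) if n_genomes > 2 else 0

    seen_seqs: set[str] = set()

    def fresh_protein(length: int) -> str:
        for _ in range(100):
            seq = _random_protein(rng, length)
            if seq not in seen_seqs:
                seen_seqs.add(seq)
                return seq
        warnings.warn("regenerating colliding random protein")  # pragma: no cover
        raise RuntimeError("could not draw a fresh random protein")  # pragma: no cover

    def plant_family(fam_id: str, member_genomes: Sequence[str]) -> None:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = fresh_protein(length)
        members = []
        for g in member_genomes:
            gene_id = f"{g}_{fam_id}"
            seq = _mutate_protein(ancestor, divergence, rng)
            proteomes[g].append(SequenceRecord(id=gene_id, seq=seq, moltype="protein"))
            members.append(f"{g}:{gene_id}")
        truth.family_members[fam_id] = members

    for c in range(core):
        plant_family(f"core{c + 1:05d}", genome_ids)
    for d in range(n_disp):
        size = int(rng.integers(2, n_genomes))  # proper subset, never unique
        subset = sorted(rng.choice(genome_ids, size=size, replace=False))
        plant_family(f"disp{d + 1:05d}", subset)
    for g in genome_ids:
        for t in range(tugs_per_genome):
            plant_family(f"tug_{g}_{t + 1:04d}", [g])

    truth.family_structure = {
        "core": core,
        "dispensable": n_disp,
        "unique": tugs_per_genome * n_genomes,
        "tugs_per_genome": tugs_per_genome,
        "n_genomes": n_genomes,
    }
    return proteomes, truth


def spearman_to_pearson(rho_s: float) -> float:
    """Latent-normal Pearson correlation achieving a target Spearman rho."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_abundances(
    n_samples: int,
    n_species: int,
    focal_correlations: Mapping[str, float],
    seed: int = 0,
    focal_id: str = "focal",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Log-normal relative-abundance table with planted focal correlations.

    Species named ``sp001`` .. ``spNNN`` plus the focal species.  Keys of
    ``focal_correlations`` must be species names; each named species is
    coupled to the focal species through a Gaussian copula at the requested
    Spearman correlation; all other species are independent.
    """
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    unknown = set(focal_correlations) - set(species)
    if unknown:
        raise KeyError(f"unknown species in focal_correlations: {sorted(unknown)}")
    for sp, rho in focal_correlations.items():
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"{sp}: target rank correlation must be in (-1, 1)")
    r = {sp: spearman_to_pearson(rho) for sp, rho in focal_correlations.items()}
    if sum(v * v for v in r.values()) > 1.0:
        raise ValueError("requested correlations are jointly infeasible (not PSD)")

    rng = np.random.default_rng(seed)
    z_focal = rng.standard_normal(n_samples)
    cols = {}
    for sp in species:
        if sp in r:
            ri = r[sp]
            z = ri * z_focal + np.sqrt(1.0 - ri * ri) * rng.standard_normal(n_samples)
        else:
            z = rng.standard_normal(n_samples)
        cols[sp] = z
    cols[focal_id] = z_focal
    mu = {sp: rng.normal(0.0, 1.0) for sp in cols}
    table = pd.DataFrame(
        {sp: np.exp(mu[sp] + z) for sp, z in cols.items()},
        index=[f"sample{i + 1:04d}" for i in range(n_samples)],
    )
    table = table.div(table.sum(axis=1), axis=0)
    truth = SyntheticTruth(seed=seed, planted_correlations=dict(focal_correlations))
    return table, truth
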