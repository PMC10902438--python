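"""Co-occurrence statistics for the focal-species partner screen.

Two complementary filters identify species ecologically linked to a focal
taxon across a cohort of relative-abundance profiles:

1. a Spearman rank-correlation screen of every species against the focal
   species, Benjamini-Hochberg adjusted, keeping positive correlations at
   FDR < 0.05; and
2. an ordination-impact screen: samples are embedded by PCoA of the
   Bray-Curtis dissimilarity matrix, each species-abundance vector is
   fitted onto the ordination axes (envfit), and its squared multiple
   correlation R^2 is tested by permutation (999 permutations), keeping
   species with R^2 > 0.2 at FDR < 0.01.

The partner set is the intersection of both filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

RHO_FDR_DEFAULT = 0.05
R2_MIN_DEFAULT = 0.2
R2_FDR_DEFAULT = 0.01
N_PERMUTATIONS_DEFAULT = 999


@dataclass
class CorrelationResult:
    species_id: str
    rho: float
    p: float
    q: float


@dataclass
class EnvfitResult:
    species_id: str
    r2: float
    p_perm: float
    q: float = float("nan")


def validate_abundance_table(table: pd.DataFrame) -> None:
    """Samples x species relative-abundance table: non-negative, no empty samples."""
    if (table.to_numpy() < 0).any():
        raise ValueError("abundance table contains negative entries")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("abundance table contains all-zero samples")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def focal_correlations(table: pd.DataFrame, focal: str) -> list[CorrelationResult]:
    """Spearman rho of every other species against the focal one, BH-adjusted.

    p-values use the t-distribution approximation with average-rank ties
    (scipy's default).  A constant focal vector is an error.
    """
    validate_abundance_table(table)
    if focal not in table.columns:
        raise KeyError(f"focal species {focal!r} not in table")
    if len(table) < 5:
        raise ValueError("at least 5 samples are required")
    x = table[focal].to_numpy()
    if np.all(x == x[0]):
        raise ValueError("focal species abundance is constant; rho undefined")
    others = [c for c in table.columns if c != focal]
    rhos, ps = [], []
    for sp in others:
        y = table[sp].to_numpy()
        if np.all(y == y[0]):
            rhos.append(0.0)
            ps.append(1.0)
            continue
        rho, p = stats.spearmanr(x, y)
        rhos.append(float(rho))
        ps.append(float(p))
    qs = bh_fdr(ps)
    return [
        CorrelationResult(species_id=sp, rho=r, p=p, q=float(q))
        for sp, r, p, q in zip(others, rhos, ps, qs)
    ]


def bray_curtis_matrix(table: pd.DataFrame) -> np.ndarray:
    validate_abundance_table(table)
    return squareform(pdist(table.to_numpy(), metric="braycurtis"))


def pcoa(distances: np.ndarray, n_axes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinate analysis by Gower centering + eigendecomposition.

    Returns (coordinates over the leading positive-eigenvalue axes, the full
    eigenvalue spectrum in descending order — negative eigenvalues included,
    as Bray-Curtis is not Euclidean).
    """
    d2 = np.asarray(distances, dtype=float) ** 2
    n = d2.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int(np.sum(eigvals > 1e-10))
    use = min(n_axes, n_pos)
    coords = eigvecs[:, :use] * np.sqrt(eigvals[:use])
    return coords, eigvals


def bray_curtis_pcoa(
    table: pd.DataFrame, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCoA of the Bray-Curtis matrix; coordinates indexed by sample id."""
    coords, eigvals = pcoa(bray_curtis_matrix(table), n_axes=n_axes)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=table.index, columns=cols), eigvals


def _r2(coords_c: np.ndarray, y: np.ndarray) -> float:
    """Squared multiple correlation of y regressed on centred coordinates."""
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(coords_c, yc, rcond=None)
    fitted = coords_c @ beta
    return float(fitted @ fitted) / sst


def envfit_r2(
    coordinates: np.ndarray | pd.DataFrame,
    species_vector: np.ndarray | pd.Series,
    species_id: str = "",
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int = 0,
) -> EnvfitResult:
    """envfit-style vector fitting: R^2 of the species on the ordination axes,
    with a permutation p-value (floor 1/(n_permutations+1))."""
    coords = np.asarray(coordinates, dtype=float)
    y = np.asarray(species_vector, dtype=float)
    if coords.shape[0] != y.shape[0]:
        raise ValueError("coordinates and species vector disagree on sample count")
    if np.all(y == y[0]):
        return EnvfitResult(species_id=species_id, r2=0.0, p_perm=1.0)
    coords_c = coords - coords.mean(axis=0)
    observed = _r2(coords_c, y)
    rng = np.random.default_rng(seed)
    # vectorised permutation null: R^2 = ||Q^T y_c||^2 / ||y_c||^2 per column
    q, _ = np.linalg.qr(coords_c)
    perms = np.empty((y.size, n_permutations))
    for i in range(n_permutations):
        perms[:, i] = rng.permutation(y)
    perms_c = perms - perms.mean(axis=0, keepdims=True)
    num = np.sum((q.T @ perms_c) ** 2, axis=0)
    den = np.sum(perms_c**2, axis=0)
    null_r2 = num / den
    exceed = int(np.sum(null_r2 >= observed))
    p_perm = (1 + exceed) / (n_permutations + 1)
    return EnvfitResult(species_id=species_id, r2=observed, p_perm=p_perm)


def envfit_screen(
    table: pd.DataFrame,
    n_axes: int = 2,
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int = 0,
    species: Sequence[str] | None = None,
) -> list[EnvfitResult]:
    """envfit every species (or a subset) on the table's PCoA, BH-adjusted."""
    coords, _ = bray_curtis_pcoa(table, n_axes=n_axes)
    species = list(species) if species is not None else list(table.columns)
    results = [
        envfit_r2(coords, table[sp], species_id=sp, n_permutations=n_permutations,
                  seed=seed + i)
        for i, sp in enumerate(species)
    ]
    qs = bh_fdr([r.p_perm for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def select_partners(
    correlations: Sequence[CorrelationResult],
    envfits: Sequence[EnvfitResult],
    rho_fdr: float = RHO_FDR_DEFAULT,
    r2_min: float = R2_MIN_DEFAULT,
    r2_fdr: float = R2_FDR_DEFAULT,
) -> list[str]:
    """Species passing both filters, sorted by rho descending."""
    corr_map = {c.species_id: c for c in correlations}
    env_map = {e.species_id: e for e in envfits}
    only = set(corr_map) ^ set(env_map)
    if only:
        warnings.warn(f"species present in one result list only are excluded: {sorted(only)}")
    selected = [
        c
        for sp, c in corr_map.items()
        if sp in env_map
        and c.rho > 0
        and c.q < rho_fdr
        and env_map[sp].r2 > r2_min
        and env_map[sp].q < r2_fdr
    ]
    selected.sort(key=lambda c: -c.rho)
    return [c.species_id for c in selected]


def permanova_bc(
    table: pd.DataFrame,
    grouping: Sequence[str],
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    seed: int = 0,
) -> dict:
    """Optional PERMANOVA (pseudo-F permutation test) on the Bray-Curtis matrix.

    Reported for population-difference questions; not part of partner selection.
    """
    from skbio.stats.distance import DistanceMatrix, permanova

    dm = DistanceMatrix(bray_curtis_matrix(table), ids=[str(i) for i in table.index])
    np.random.seed(seed)  # skbio's permanova draws from the global RNG
    res = permanova(dm, grouping=list(grouping), permutations=n_permutations)
    return {
        "test_statistic": float(res["test statistic"]),
        "p_value": float(res["p-value"]),
        "permutations": int(res["number of permutations"]),
    }
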