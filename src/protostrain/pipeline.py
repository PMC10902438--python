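"""End-to-end orchestration: filter → derep → prevalence → AxP → PPOS →
pangenome → co-occurrence, driven by a validated config.

Every stage is skippable simply by omitting its inputs; each stage that
runs writes a TSV report into the run directory, and a machine-readable
``summary.json`` names the cohort prototype(s) and the top local candidate.
Stage outputs are pure functions of (inputs, config): no timestamps or
environment state enter any report, so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .ani import ani_matrix, build_sketch
from .axp import AxPRecord, axp_table, rank_prototypes
from .cooccurrence import envfit_screen, focal_correlations, select_partners
from .dereplicate import GenomeQuality, dereplicate, filter_genomes
from .pangenome import classify_families, cluster_gene_families, membership_table
from .ppos import ScoringScheme, report_table, score_candidates
from .prevalence import build_markers, cohort_prevalence
from .seqio import KmerSet, canonical_kmers, read_fasta

import numpy as np


class ConfigError(ValueError):
    """Configuration failed validation; message names the offending field."""


_PARAM_DEFAULTS: dict[str, Any] = {
    "k": 23,
    "sketch_size": 5000,
    "hash_seed": 42,
    "species_gate": 94.0,
    "min_completeness": 90.0,
    "max_contamination": 5.0,
    "derep_threshold": 99.8,
    "linkage": "single",
    "breadth_threshold": 0.5,
    "ani_term": "mean_intra_clade",
    "gap_open": 11.0,
    "gap_extend": 1.0,
    "matrix": "BLOSUM62",
    "e_max": 1e-5,
    "min_identity": 50.0,
    "min_coverage": 0.8,
    "cluster_method": "components",
    "inflation": 1.5,
    "rho_fdr": 0.05,
    "r2_min": 0.2,
    "r2_fdr": 0.01,
    "n_permutations": 999,
    "n_axes": 2,
}

_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "species_gate": (0, 100),
    "min_completeness": (0, 100),
    "max_contamination": (0, 100),
    "derep_threshold": (0, 100),
    "breadth_threshold": (0, 1),
    "min_identity": (0, 100),
    "min_coverage": (0, 1),
    "rho_fdr": (0, 1),
    "r2_min": (0, 1),
    "r2_fdr": (0, 1),
}

_INPUT_KEYS = {
    "genomes",
    "quality",
    "reference_genome",
    "cohorts",
    "proteomes",
    "prototype_id",
    "candidate_ani",
    "abundance_table",
    "focal_species",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :func:`validate_config`)."""

    run_dir: Path
    seed: int = 0
    parameters: dict[str, Any] = dc_field(default_factory=dict)
    inputs: dict[str, Any] = dc_field(default_factory=dict)

    def param(self, name: str) -> Any:
        return self.parameters[name]


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a raw config mapping; unknown keys are rejected by name."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed_top = {"run_dir", "seed", "parameters", "inputs"}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    if "run_dir" not in raw:
        raise ConfigError("missing required field: run_dir")
    params = dict(_PARAM_DEFAULTS)
    for key, value in (raw.get("parameters") or {}).items():
        if key not in _PARAM_DEFAULTS:
            raise ConfigError(f"unknown parameter: {key}")
        params[key] = value
    for key, (lo, hi) in _PARAM_RANGES.items():
        if not (lo <= float(params[key]) <= hi):
            raise ConfigError(f"parameter {key}={params[key]} outside [{lo}, {hi}]")
    if params["linkage"] not in ("single", "complete"):
        raise ConfigError(f"parameter linkage must be single|complete, got {params['linkage']}")
    if params["ani_term"] not in ("mean_intra_clade", "ani_to_reference", "user_supplied"):
        raise ConfigError(f"parameter ani_term has unknown mode {params['ani_term']!r}")
    inputs = dict(raw.get("inputs") or {})
    unknown = set(inputs) - _INPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown input keys: {sorted(unknown)}")
    if inputs.get("cohorts") is not None and not isinstance(inputs["cohorts"], dict):
        raise ConfigError("inputs.cohorts must map cohort name -> sample directory")
    if inputs.get("abundance_table") and not inputs.get("focal_species"):
        raise ConfigError("inputs.focal_species is required with inputs.abundance_table")
    for path_key in ("genomes", "quality", "abundance_table"):
        p = inputs.get(path_key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"inputs.{path_key}: path does not exist: {p}")
    for name, d in (inputs.get("cohorts") or {}).items():
        if not Path(d).is_dir():
            raise ConfigError(f"inputs.cohorts[{name}]: not a directory: {d}")
    for strain, p in (inputs.get("proteomes") or {}).items():
        if not Path(p).exists():
            raise ConfigError(f"inputs.proteomes[{strain}]: path does not exist: {p}")
    return PipelineConfig(
        run_dir=Path(raw["run_dir"]),
        seed=int(raw.get("seed", 0)),
        parameters=params,
        inputs=inputs,
    )


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _load_quality(path: str | Path | None, genome_ids: list[str]) -> list[GenomeQuality]:
    if path is None:
        return [GenomeQuality(g, 100.0, 0.0) for g in genome_ids]
    df = pd.read_csv(path, sep="\t")
    return [
        GenomeQuality(str(r.genome_id), float(r.completeness), float(r.contamination))
        for r in df.itertuples()
    ]


def _load_cohort_samples(directory: Path, k: int) -> list[KmerSet]:
    samples: list[KmerSet] = []
    for path in sorted(directory.iterdir()):
        if path.suffix == ".json":
            with open(path) as fh:
                d = json.load(fh)
            samples.append(
                KmerSet(
                    source_id=d["source_id"],
                    k=int(d["k"]),
                    kmers=np.asarray(d["kmers"], dtype=np.uint64),
                )
            )
        elif path.suffix in (".fa", ".fasta", ".fna") or path.name.endswith(
            (".fa.gz", ".fasta.gz", ".fna.gz")
        ):
            recs = read_fasta(path, "nucleotide")
            arrays = [canonical_kmers(r, k).kmers for r in recs]
            from .seqio import sorted_unique

            kmers = (
                sorted_unique(np.concatenate(arrays)) if arrays else np.empty(0, np.uint64)
            )
            samples.append(KmerSet(source_id=path.stem, k=k, kmers=kmers))
    return samples


def save_kmerset(ks: KmerSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"source_id": ks.source_id, "k": ks.k, "kmers": [int(x) for x in ks.kmers]}, fh
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the summary dict (also written
    to ``<run_dir>/summary.json``)."""
    run_dir = config.run_dir
    run_dir.mkdir(parents=True, exist_ok=True)
    p = config.param
    summary: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": []}
    log_lines = [f"protostrain {__version__}", f"seed={config.seed}"] + [
        f"param {k}={v}" for k, v in sorted(config.parameters.items())
    ]

    clades = None
    genomes = None
    if config.inputs.get("genomes"):
        genomes = read_fasta(config.inputs["genomes"], "nucleotide")
        genome_ids = [g.id for g in genomes]
        quality = _load_quality(config.inputs.get("quality"), genome_ids)
        sketches = {
            g.id: build_sketch(g, k=p("k"), s=p("sketch_size"), hash_seed=p("hash_seed"))
            for g in genomes
        }
        ref = config.inputs.get("reference_genome")
        if ref is not None:
            if ref not in sketches:
                raise ConfigError(f"inputs.reference_genome {ref!r} not among genomes")
            from .ani import estimate_ani

            ani_to_ref = {g: (100.0 if g == ref else estimate_ani(sketches[g], sketches[ref]))
                          for g in genome_ids}
            retained, rejected = filter_genomes(
                genome_ids,
                quality,
                ani_to_ref,
                species_gate=p("species_gate"),
                min_completeness=p("min_completeness"),
                max_contamination=p("max_contamination"),
            )
            pd.DataFrame(
                [{"genome_id": g, "reason": r} for g, r in sorted(rejected.items())]
            ).to_csv(run_dir / "rejections.tsv", sep="\t", index=False)
            summary["stages"].append("filter")
        else:
            retained = genome_ids
        matrix = ani_matrix([sketches[g] for g in retained])
        matrix.to_tsv(run_dir / "ani_matrix.tsv")
        lengths = {g.id: len(g.seq) for g in genomes}
        clades = dereplicate(
            matrix,
            quality,
            threshold=p("derep_threshold"),
            linkage=p("linkage"),
            genome_lengths=lengths,
        )
        pd.DataFrame(
            [
                {
                    "clade_id": f"L{i + 1:03d}",
                    "representative": c.representative_id,
                    "members": ",".join(c.member_ids),
                    "mean_intra_ani": round(c.mean_intra_ani, 4),
                }
                for i, c in enumerate(clades)
            ]
        ).to_csv(run_dir / "clades.tsv", sep="\t", index=False)
        summary["stages"] += ["ani", "dereplicate"]
        summary["n_lineages"] = len(clades)

    axp_records: list[AxPRecord] = []
    if config.inputs.get("cohorts") and clades is not None and genomes is not None:
        rep_ids = [c.representative_id for c in clades]
        rep_records = {g.id: g for g in genomes if g.id in rep_ids}
        rep_kmers = [canonical_kmers(rep_records[r], p("k")) for r in rep_ids]
        markers = build_markers(rep_kmers)
        ani_terms = {c.representative_id: c.mean_intra_ani for c in clades}
        prototypes: dict[str, str] = {}
        for cohort_name, directory in sorted(config.inputs["cohorts"].items()):
            samples = _load_cohort_samples(Path(directory), p("k"))
            profile = cohort_prevalence(
                samples, markers, cohort_name, breadth_threshold=p("breadth_threshold")
            )
            profile.to_frame().to_csv(
                run_dir / f"prevalence_{cohort_name}.tsv", sep="\t", index=False
            )
            for lid in sorted(profile.prevalence):
                axp_records.append(
                    AxPRecord(
                        lineage_id=lid,
                        cohort=cohort_name,
                        ani_term=ani_terms[lid],
                        prevalence=profile.prevalence[lid],
                    )
                )
            ranked = rank_prototypes(axp_records, cohort_name)
            prototypes[cohort_name] = ranked[0].lineage_id
        axp_table(axp_records).to_csv(run_dir / "axp_ranking.tsv", sep="\t", index=False)
        summary["stages"] += ["prevalence", "axp"]
        summary["prototypes"] = prototypes

    scheme = ScoringScheme(
        matrix_name=p("matrix"), gap_open=p("gap_open"), gap_extend=p("gap_extend")
    )
    if config.inputs.get("proteomes"):
        proteomes = {
            strain: read_fasta(path, "protein")
            for strain, path in sorted(config.inputs["proteomes"].items())
        }
        prototype_id = config.inputs.get("prototype_id")
        if prototype_id is None and summary.get("prototypes"):
            prototype_id = sorted(summary["prototypes"].values())[0]
        if prototype_id is not None and prototype_id in proteomes:
            candidate_ani = config.inputs.get("candidate_ani") or {}
            candidates = [
                (strain, prot, float(candidate_ani.get(strain, 100.0)))
                for strain, prot in proteomes.items()
                if strain != prototype_id
            ]
            if candidates:
                reports = score_candidates(
                    candidates, prototype_id, proteomes[prototype_id], scheme=scheme
                )
                report_table(reports).to_csv(
                    run_dir / "candidate_scores.tsv", sep="\t", index=False
                )
                summary["stages"].append("ppos")
                top = next((r for r in reports if r.avg_ppos is not None), None)
                if top is not None:
                    summary["top_candidate"] = top.candidate_id
        families = cluster_gene_families(
            proteomes,
            scheme=scheme,
            e_max=p("e_max"),
            min_identity=p("min_identity"),
            min_coverage=p("min_coverage"),
            method=p("cluster_method"),
            inflation=p("inflation"),
        )
        pg = classify_families(families, list(proteomes))
        membership_table(families).to_csv(run_dir / "gene_families.tsv", sep="\t", index=False)
        pg.to_frame().assign(
            **{f"tugs_{g}": n for g, n in sorted(pg.tugs_per_genome.items())}
        ).to_csv(run_dir / "pangenome_summary.tsv", sep="\t", index=False)
        summary["stages"].append("pangenome")
        summary["pangenome"] = {
            "pangenome": pg.pangenome,
            "core": pg.core,
            "dispensable": pg.dispensable,
            "unique": pg.unique,
        }

    if config.inputs.get("abundance_table"):
        table = pd.read_csv(config.inputs["abundance_table"], sep="\t", index_col=0)
        focal = config.inputs["focal_species"]
        corrs = focal_correlations(table, focal)
        pd.DataFrame(
            [{"species": c.species_id, "rho": c.rho, "p": c.p, "q": c.q} for c in corrs]
        ).to_csv(run_dir / "correlations.tsv", sep="\t", index=False)
        envs = envfit_screen(
            table.drop(columns=[focal]).join(table[focal]),
            n_axes=p("n_axes"),
            n_permutations=p("n_permutations"),
            seed=config.seed,
            species=[c.species_id for c in corrs],
        )
        pd.DataFrame(
            [{"species": e.species_id, "r2": e.r2, "p_perm": e.p_perm, "q": e.q} for e in envs]
        ).to_csv(run_dir / "envfit.tsv", sep="\t", index=False)
        partners = select_partners(
            corrs, envs, rho_fdr=p("rho_fdr"), r2_min=p("r2_min"), r2_fdr=p("r2_fdr")
        )
        pd.DataFrame({"species": partners}).to_csv(
            run_dir / "partners.tsv", sep="\t", index=False
        )
        summary["stages"].append("cooccurrence")
        summary["n_correlated"] = sum(1 for c in corrs if c.rho > 0 and c.q < p("rho_fdr"))
        summary["partners"] = partners

    with open(run_dir / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines + [f"stage {s}" for s in summary["stages"]]) + "\n")
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
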