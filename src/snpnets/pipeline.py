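"""End-to-end orchestration: associate -> normalize -> networks -> select K
-> cluster -> annotate, with deterministic seeding and per-stage artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as annotate_mod
from . import io as io_mod
from .association import AssociationMap, build_association_map, normalize_rows
from .io import CohortSpec
from .networks import MEASURES, SimilarityNetwork, build_all_networks
from .selection import SilhouetteReport, sweep_and_select

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_cohorts"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def default_cohorts() -> list[CohortSpec]:
    """The five standard case-control comparison groups for an AD cohort."""
    hc = frozenset({"HC"})
    return [
        CohortSpec("EMCI_vs_HC", frozenset({"EMCI"}), hc),
        CohortSpec("LMCI_vs_HC", frozenset({"LMCI"}), hc),
        CohortSpec("AD_vs_HC", frozenset({"AD"}), hc),
        CohortSpec("MCI_vs_HC", frozenset({"EMCI", "LMCI"}), hc),
        CohortSpec("ALL_vs_HC", frozenset({"EMCI", "LMCI", "AD"}), hc),
    ]


@dataclass
class PipelineConfig:
    genotypes_path: str | Path = ""
    phenotypes_path: str | Path = ""
    snp_gene_map_path: str | Path | None = None
    genotype_dialect: str = "csv"
    cohorts: list[CohortSpec] = field(default_factory=default_cohorts)
    measures: tuple[str, ...] = MEASURES
    k_min: int = 2
    k_max: int = 9
    tolerance: float = 0.01
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-6
    output_dir: str | Path = "snpnets_run"

    def validate(self) -> None:
        if not self.genotypes_path:
            raise ConfigError("genotypes_path is required")
        if not self.phenotypes_path:
            raise ConfigError("phenotypes_path is required")
        if not Path(self.genotypes_path).exists():
            raise ConfigError(f"genotype file not found: {self.genotypes_path}")
        if not Path(self.phenotypes_path).exists():
            raise ConfigError(f"phenotype file not found: {self.phenotypes_path}")
        if not self.cohorts:
            raise ConfigError("at least one cohort is required")
        if not self.measures:
            raise ConfigError("at least one measure is required")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ConfigError(f"unknown measures: {sorted(unknown)}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat-key YAML/JSON config file."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohorts = raw.pop("cohorts", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if cohorts is not None:
            cfg.cohorts = [
                CohortSpec(c["name"], frozenset(c["case_labels"]), frozenset(c["control_labels"]))
                for c in cohorts
            ]
        if "measures" in raw:
            cfg.measures = tuple(raw["measures"])
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    maps: dict[str, AssociationMap]  # cohort -> normalized map
    networks: dict[tuple[str, str], SimilarityNetwork]
    report: SilhouetteReport
    assignments: dict[str, dict[str, int]]  # cohort -> {snp: cluster}
    summary: dict

    @property
    def selected_K(self) -> int:
        return self.report.selected_K


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all intermediate artifacts.

    Identical config and seed produce identical outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage associate: reading inputs")
    genotypes = io_mod.read_genotypes(config.genotypes_path, dialect=config.genotype_dialect)
    phenotypes = io_mod.read_phenotypes(config.phenotypes_path)
    gene_map = (
        io_mod.read_snp_gene_map(config.snp_gene_map_path)
        if config.snp_gene_map_path
        else {}
    )

    maps: dict[str, AssociationMap] = {}
    networks: dict[tuple[str, str], SimilarityNetwork] = {}
    for cohort in config.cohorts:
        logger.info("stage associate: cohort %s", cohort.name)
        assoc = build_association_map(genotypes, phenotypes, cohort)
        io_mod.write_matrix(assoc.to_frame(), out / f"map_raw_{cohort.name}.tsv")
        norm = normalize_rows(assoc)
        io_mod.write_matrix(norm.to_frame(), out / f"map_normalized_{cohort.name}.tsv")
        maps[cohort.name] = norm
        logger.info("stage networks: cohort %s", cohort.name)
        for net in build_all_networks(norm):
            if net.measure in config.measures:
                networks[(net.measure, cohort.name)] = net
                io_mod.write_matrix(
                    net.to_frame(), out / f"network_{net.measure}_{cohort.name}.tsv", kind="network"
                )

    logger.info("stage select-k: sweeping K=%d..%d", config.k_min, config.k_max)
    report = sweep_and_select(
        networks,
        k_range=range(config.k_min, config.k_max + 1),
        tolerance=config.tolerance,
        seed=config.seed,
        max_iter=config.max_iter,
        tol=config.tol,
    )
    report.to_json(out / "silhouette_report.json")
    report.curve_to_csv(out / "silhouette_curve.csv")
    K = report.selected_K

    logger.info("stage cluster: K=%d", K)
    assignments: dict[str, dict[str, int]] = {}
    objectives: dict[str, float] = {}
    for cohort in config.cohorts:
        res = report.fits[(cohort.name, K)]
        assignments[cohort.name] = res.assignment
        objectives[cohort.name] = res.hard_objective_
        io_mod.write_assignment(res.assignment, out / f"assignment_{cohort.name}.json")

    logger.info("stage annotate")
    for cohort in config.cohorts:
        annotations = annotate_mod.annotate_clusters(
            maps[cohort.name], assignments[cohort.name], gene_map
        )
        annotate_mod.export_annotation(annotations, out / f"annotation_{cohort.name}")

    summary = {
        "selected_K": K,
        "tolerance": config.tolerance,
        "seed": config.seed,
        "silhouette_curve": {str(k): v for k, v in sorted(report.averaged_score.items())},
        "cohorts": {
            c.name: {
                "cluster_sizes": _sizes(assignments[c.name], K),
                "hard_objective": objectives[c.name],
            }
            for c in config.cohorts
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return PipelineResult(config, maps, networks, report, assignments, summary)


def _sizes(assignment: dict[str, int], K: int) -> list[int]:
    sizes = [0] * K
    for v in assignment.values():
        sizes[v] += 1
    return sizes
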