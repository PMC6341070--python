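"""End-to-end orchestration: associate -> screen -> validate -> survive.

A :class:`RunConfig` (usually parsed from a YAML file) names the cohort
expression files, the seed feature, the filter tiers and the optional
validation/survival inputs.  :func:`run_pipeline` executes the stages in
order, writes every stage output under the configured directory and returns
a machine-readable manifest (paths, candidate-set sizes, sha256 checksums).
Re-running with identical inputs and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import screening, validation
from .association import AssociationTable, associate_all
from .errors import ConfigurationError
from .io import (
    ExpressionCohort,
    ProbeMap,
    read_expression_matrix,
    read_probe_map,
    read_sample_metadata,
    read_survival,
    write_association_table,
)
from .screening import FilterTier, default_tiers, run_tiered_screen
from .survival import survival_screen

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Paths and parameters of one full screening run."""

    seed_feature: str
    cohorts: list[dict]  # each: {id, expression, metadata?}
    output_dir: str
    probe_map: str | None = None
    tiers: list[FilterTier] = field(default_factory=default_tiers)
    alpha: float = 0.05
    validation_groups: list[dict] = field(default_factory=list)  # {id, expression}
    survival: dict | None = None  # {expression, table, features}
    rng_seed: int = 0

    def __post_init__(self) -> None:
        names = [t.name for t in self.tiers]
        if len(set(names)) != len(names):
            raise ConfigurationError("tier names must be unique")
        if not self.cohorts:
            raise ConfigurationError("at least one cohort is required")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tiers = default_tiers()
    if "tiers" in raw:
        tiers = [FilterTier(**t) for t in raw["tiers"]]
    return RunConfig(
        seed_feature=raw["seed_feature"],
        cohorts=raw["cohorts"],
        output_dir=raw["output_dir"],
        probe_map=raw.get("probe_map"),
        tiers=tiers,
        alpha=float(raw.get("alpha", 0.05)),
        validation_groups=raw.get("validation_groups", []),
        survival=raw.get("survival"),
        rng_seed=int(raw.get("rng_seed", 0)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(entry: dict) -> ExpressionCohort:
    path = Path(entry["expression"])
    if not path.exists():
        raise ConfigurationError(f"cohort expression file not found: {path}")
    cohort = read_expression_matrix(path, cohort_id=entry.get("id"))
    if entry.get("metadata"):
        cohort.sample_annotations = read_sample_metadata(entry["metadata"]).reindex(
            cohort.values.columns
        )
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; return (and write) the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed_feature": config.seed_feature,
        "rng_seed": config.rng_seed,
        "outputs": {},
        "set_sizes": {},
        "checksums": {},
        "funnel": [],
    }
    failed_marker = out_dir / "FAILED"

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)
        manifest["checksums"][name] = _sha256(path)

    try:
        pm = read_probe_map(config.probe_map) if config.probe_map else ProbeMap()

        # stage 1: per-cohort association
        tables: list[AssociationTable] = []
        for entry in config.cohorts:
            cohort = _load_cohort(entry)
            table = associate_all(cohort, config.seed_feature)
            tables.append(table)
            path = out_dir / f"assoc_{cohort.cohort_id}.tsv"
            write_association_table(table, path, pm)
            record(f"assoc_{cohort.cohort_id}", path)
        manifest["funnel"].append(
            {"stage": "association", "n_features": len({f for t in tables for f in t.feature_ids})}
        )

        # stage 2: tiered screen
        candidate_sets = run_tiered_screen(tables, pm, tiers=config.tiers)
        for name, cs in candidate_sets.items():
            path = out_dir / f"candidates_{name}.tsv"
            with open(path, "w") as fh:
                cohorts = sorted({c for t in tables for c in t.cohorts})
                fh.write("feature_id\tgene\t" + "\t".join(cohorts) + "\n")
                for fid in sorted(cs.features):
                    flags = dict(cs.per_feature_evidence.get(fid, []))
                    fh.write(
                        fid + "\t" + pm.gene(fid) + "\t"
                        + "\t".join(str(int(flags.get(c, False))) for c in cohorts) + "\n"
                    )
            record(f"candidates_{name}", path)
            manifest["set_sizes"][name] = {"probes": len(cs.features), "genes": len(cs.genes)}
            manifest["funnel"].append({"stage": f"tier:{name}", "n_features": len(cs.features)})

        # stage 3: replication in validation groups
        relaxed_name = config.tiers[0].name
        relaxed = candidate_sets[relaxed_name]
        if config.validation_groups and relaxed.features:
            ref_dir = validation.reference_directions(relaxed, tables)
            report_path = out_dir / "replication.tsv"
            with open(report_path, "w") as fh:
                fh.write(
                    "group_id\tn_candidates\tn_significant_same_direction\t"
                    "n_significant_total\tn_opposite_among_significant\t"
                    "consistent_rate\topposite_rate\n"
                )
                for entry in config.validation_groups:
                    gcohort = _load_cohort(entry)
                    gtable = associate_all(gcohort, config.seed_feature)
                    rep = validation.replication_report(
                        relaxed, ref_dir, gtable, alpha=config.alpha, group_id=gcohort.cohort_id
                    )
                    fh.write(
                        f"{rep.group_id}\t{rep.n_candidates}\t"
                        f"{rep.n_significant_same_direction}\t{rep.n_significant_total}\t"
                        f"{rep.n_opposite_among_significant}\t"
                        f"{rep.consistent_rate_text}\t{rep.opposite_rate_text}\n"
                    )
            record("replication", report_path)

        # stage 4: survival screen
        if config.survival:
            scohort = _load_cohort(
                {"id": "survival", "expression": config.survival["expression"]}
            )
            records = read_survival(config.survival["table"])
            feats = config.survival.get("features") or scohort.features
            frame = survival_screen(scohort, records, feats)
            path = out_dir / "survival_screen.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
            record("survival_screen", path)
            manifest["set_sizes"]["survival_significant"] = int(
                (frame["p_value"] <= config.alpha).sum()
            )
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    else:
        if failed_marker.exists():
            failed_marker.unlink()

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
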