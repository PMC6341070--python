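"""Tiered, direction-consistent multi-cohort candidate filters.

The screen narrows genome-wide association results in nested steps:

* **relaxed** -- p <= 0.05 in *every* cohort, same slope direction in every
  cohort (a feature must be measured in all cohorts to qualify);
* **strict** -- among relaxed survivors, p <= 2e-6 *and* adjusted r^2 >= 0.1
  in at least five cohorts;
* **heatmap** -- among strict survivors, adjusted r^2 >= 0.3 in at least one
  cohort.

Thresholds live in :class:`FilterTier` so alternative screens are a config
change, not a code change.  All tier decisions consult the adjusted
r-squared, the statistic the candidate tables report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .association import AssociationTable
from .errors import ConfigurationError
from .io import ProbeMap

__all__ = [
    "FilterTier",
    "CandidateSet",
    "relaxed_tier",
    "strict_tier",
    "heatmap_tier",
    "default_tiers",
    "apply_tier",
    "run_tiered_screen",
    "collapse_to_genes",
]


@dataclass(frozen=True)
class FilterTier:
    """A named bundle of screening thresholds.

    ``min_cohorts`` counts cohorts that individually satisfy both ``p_max``
    and ``r2_min`` (0 disables the r^2 floor).  ``r2_min_any`` requires at
    least one cohort to reach that adjusted r^2.
    """

    name: str
    p_max: float = 0.05
    r2_min: float = 0.0
    min_cohorts: int = 1
    require_all_cohorts_significant: bool = False
    require_same_direction: bool = False
    r2_min_any: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ConfigurationError(f"p_max must be in (0,1], got {self.p_max}")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ConfigurationError(f"r2_min must be in [0,1], got {self.r2_min}")
        if self.min_cohorts < 1:
            raise ConfigurationError("min_cohorts must be >= 1")


def relaxed_tier() -> FilterTier:
    """Significant (p <= 0.05) everywhere, direction-consistent everywhere."""
    return FilterTier(
        name="relaxed",
        p_max=0.05,
        min_cohorts=1,
        require_all_cohorts_significant=True,
        require_same_direction=True,
    )


def strict_tier() -> FilterTier:
    """p <= 2e-6 and adjusted r^2 >= 0.1 in at least five cohorts."""
    return FilterTier(name="strict", p_max=2e-6, r2_min=0.1, min_cohorts=5)


def heatmap_tier() -> FilterTier:
    """Additionally adjusted r^2 >= 0.3 in at least one cohort."""
    return FilterTier(name="heatmap", p_max=1.0, min_cohorts=1, r2_min_any=0.3)


def default_tiers() -> list[FilterTier]:
    return [relaxed_tier(), strict_tier(), heatmap_tier()]


@dataclass
class CandidateSet:
    """Features surviving one tier, with per-cohort pass provenance."""

    tier_name: str
    features: frozenset[str]
    genes: frozenset[str]
    per_feature_evidence: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.features


def _merge_tables(tables: list[AssociationTable]) -> AssociationTable:
    seeds = {t.seed_id for t in tables if t.seed_id}
    if len(seeds) > 1:
        raise ConfigurationError(f"association tables disagree on the seed: {sorted(seeds)}")
    merged = AssociationTable(seed_id=next(iter(seeds)) if seeds else "")
    for t in tables:
        merged = merged.merged(t)
    return merged


def apply_tier(
    tables: list[AssociationTable],
    tier: FilterTier,
    probe_map: ProbeMap | None = None,
    candidates: frozenset[str] | None = None,
) -> CandidateSet:
    """Evaluate one tier over per-cohort association tables.

    A feature is evaluated only in cohorts where it has a result.  When
    ``candidates`` is given, only those features are considered (sequential
    narrowing).  Deterministic and independent of cohort/feature ordering.
    """
    pm = probe_map or ProbeMap()
    merged = _merge_tables(tables)
    cohorts = sorted(merged.cohorts)
    if tier.min_cohorts > max(len(cohorts), 1):
        raise ConfigurationError(
            f"tier {tier.name!r} needs {tier.min_cohorts} cohorts, only {len(cohorts)} given"
        )

    features = sorted(set(merged.feature_ids) if candidates is None else candidates)
    passing: list[str] = []
    evidence: dict[str, list[tuple[str, bool]]] = {}
    for fid in features:
        results = {c: merged.get(fid, c) for c in cohorts}
        measured = {c: r for c, r in results.items() if r is not None}
        if not measured:
            continue
        cohort_pass = {
            c: (r.p_value <= tier.p_max and r.adjusted_r2 >= tier.r2_min)
            for c, r in measured.items()
        }
        ok = True
        if tier.require_all_cohorts_significant:
            ok = len(measured) == len(cohorts) and all(
                r.p_value <= tier.p_max for r in measured.values()
            )
        if ok and sum(cohort_pass.values()) < tier.min_cohorts:
            ok = False
        if ok and tier.require_same_direction:
            directions = {r.direction for r in measured.values()}
            ok = len(directions) == 1 and 0 not in directions
        if ok and tier.r2_min_any > 0:
            ok = max(r.adjusted_r2 for r in measured.values()) >= tier.r2_min_any
        if ok:
            passing.append(fid)
            evidence[fid] = [(c, bool(cohort_pass.get(c, False))) for c in cohorts]
    feats = frozenset(passing)
    return CandidateSet(
        tier_name=tier.name,
        features=feats,
        genes=frozenset(pm.genes_of(feats)),
        per_feature_evidence=evidence,
    )


def run_tiered_screen(
    tables: list[AssociationTable],
    probe_map: ProbeMap | None = None,
    tiers: list[FilterTier] | None = None,
    sequential: bool = True,
) -> dict[str, CandidateSet]:
    """Run the tier cascade; by default each tier filters the previous one.

    With ``sequential=True`` (the default) the candidate sets are nested:
    heatmap is a subset of strict is a subset of relaxed.  ``sequential=False``
    evaluates every tier independently on the full table.
    """
    if len({t for tab in tables for t in tab.cohorts}) < 2:
        raise ConfigurationError("tiered screening needs at least 2 cohorts")
    tiers = list(default_tiers() if tiers is None else tiers)
    if len({t.name for t in tiers}) != len(tiers):
        raise ConfigurationError("tier names must be unique")
    out: dict[str, CandidateSet] = {}
    surviving: frozenset[str] | None = None
    for tier in tiers:
        cs = apply_tier(tables, tier, probe_map, candidates=surviving)
        out[tier.name] = cs
        if sequential:
            surviving = cs.features
    return out


def collapse_to_genes(candidates: CandidateSet, probe_map: ProbeMap | None = None) -> set[str]:
    """Distinct gene symbols of a candidate set (unmapped probes keep their id)."""
    pm = probe_map or ProbeMap()
    return set(pm.genes_of(candidates.features))
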