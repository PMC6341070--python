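"""Replication of a candidate set in new patient groups.

Two questions are answered here.  First, do discovery candidates stay
significantly associated with the seed — in the discovery direction — in an
independent group (another leukemia type, a molecular subtype, healthy
marrow)?  That is the consistency (replication) rate; among the significant
replications the opposite-direction rate counts sign flips.  Second, in
paired tumor/normal designs, is the seed-feature association tissue
specific?  :func:`classify_specificity` partitions each (feature, cancer
type) into consistent / tumor_specific / normal_specific / opposite /
neither.

Candidates unmeasured in a validation group count toward the candidate
denominator but can never replicate, which makes the rates conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import AssociationResult, AssociationTable
from .errors import ConfigurationError, DomainError
from .io import ExpressionCohort
from .screening import CandidateSet

__all__ = [
    "ConsistencyReport",
    "SpecificityCall",
    "format_percent",
    "reference_directions",
    "replication_report",
    "subtype_screen",
    "classify_specificity",
    "paired_regulation_frequency",
]


def format_percent(numerator: int, denominator: int) -> str:
    """Render a count ratio as a percentage at two decimals, e.g. ``"99.07%"``."""
    if denominator == 0:
        return "0.00%"
    return f"{100.0 * numerator / denominator:.2f}%"


@dataclass(frozen=True)
class ConsistencyReport:
    """Replication counts and rates for one validation group."""

    group_id: str
    n_candidates: int
    n_significant_same_direction: int
    n_significant_total: int
    n_opposite_among_significant: int

    @property
    def consistent_rate(self) -> float:
        return self.n_significant_same_direction / self.n_candidates

    @property
    def opposite_rate(self) -> float:
        if self.n_significant_total == 0:
            return 0.0
        return self.n_opposite_among_significant / self.n_significant_total

    @property
    def consistent_rate_text(self) -> str:
        return format_percent(self.n_significant_same_direction, self.n_candidates)

    @property
    def opposite_rate_text(self) -> str:
        if self.n_significant_total == 0:
            return "0.00%"
        return format_percent(self.n_opposite_among_significant, self.n_significant_total)

    def __str__(self) -> str:
        return (
            f"{self.group_id}: {self.n_significant_same_direction}/{self.n_candidates} "
            f"consistent ({self.consistent_rate_text}), "
            f"{self.n_opposite_among_significant}/{self.n_significant_total} "
            f"opposite among significant ({self.opposite_rate_text})"
        )


@dataclass(frozen=True)
class SpecificityCall:
    """Tissue-specificity of a seed-feature association in one cancer type."""

    feature_id: str
    cancer_type: str
    call: str  # consistent | tumor_specific | normal_specific | opposite | neither
    tumor_result: AssociationResult | None = None
    normal_result: AssociationResult | None = None


def reference_directions(candidates: CandidateSet, tables: list[AssociationTable]) -> dict[str, int]:
    """Discovery direction per candidate (unanimous across discovery cohorts).

    The relaxed tier enforces direction consistency, so the direction in any
    discovery cohort where the feature is measured is the reference.
    """
    directions: dict[str, int] = {}
    for table in tables:
        for (fid, _), res in table.results.items():
            if fid in candidates.features and fid not in directions:
                directions[fid] = res.direction
    missing = candidates.features - directions.keys()
    if missing:
        raise DomainError(f"no discovery direction for candidates: {sorted(missing)[:5]}")
    return directions


def replication_report(
    candidates: CandidateSet,
    reference_direction: dict[str, int],
    group_table: AssociationTable,
    alpha: float = 0.05,
    group_id: str | None = None,
) -> ConsistencyReport:
    """Count candidate replications in one validation group.

    A candidate replicates when its p-value in the group is <= alpha and the
    slope sign matches the discovery direction; significant candidates with
    the flipped sign are 'opposite'.
    """
    if not candidates.features:
        raise DomainError("empty candidate set")
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    missing_ref = [f for f in candidates.features if f not in reference_direction]
    if missing_ref:
        raise DomainError(f"reference direction missing for {sorted(missing_ref)[:5]}")
    gid = group_id or (group_table.cohorts[0] if group_table.cohorts else "group")
    n_sig = n_same = n_opp = 0
    for fid in candidates.features:
        res = None
        for cohort in group_table.cohorts or [gid]:
            res = group_table.get(fid, cohort)
            if res is not None:
                break
        if res is None or res.p_value > alpha:
            continue
        n_sig += 1
        if res.direction == reference_direction[fid]:
            n_same += 1
        elif res.direction == -reference_direction[fid]:
            n_opp += 1
    return ConsistencyReport(
        group_id=gid,
        n_candidates=len(candidates.features),
        n_significant_same_direction=n_same,
        n_significant_total=n_sig,
        n_opposite_among_significant=n_opp,
    )


def subtype_screen(
    candidates: CandidateSet,
    subtype_tables: dict[str, AssociationTable],
    alpha: float = 0.05,
    reference_direction: dict[str, int] | None = None,
) -> tuple[set[str], dict[str, ConsistencyReport]]:
    """Candidates significant with one shared direction in every subtype.

    Returns the surviving feature set and a per-subtype
    :class:`ConsistencyReport` side table.  Subtypes must overlap the
    candidate features.
    """
    if len(subtype_tables) < 2:
        raise ConfigurationError("subtype screen needs >= 2 subtypes")
    for name, table in subtype_tables.items():
        if not (set(table.feature_ids) & candidates.features):
            raise ConfigurationError(f"subtype {name!r} shares no features with the candidates")

    if reference_direction is None:
        # fall back to the direction observed in the first subtype listed
        first = next(iter(subtype_tables.values()))
        reference_direction = {}
        for (fid, _), res in first.results.items():
            if fid in candidates.features:
                reference_direction.setdefault(fid, res.direction)

    survivors: set[str] = set()
    for fid in candidates.features:
        directions = []
        ok = True
        for table in subtype_tables.values():
            res = None
            for cohort in table.cohorts:
                res = table.get(fid, cohort)
                if res is not None:
                    break
            if res is None or res.p_value > alpha or res.direction == 0:
                ok = False
                break
            directions.append(res.direction)
        if ok and len(set(directions)) == 1:
            survivors.add(fid)

    reports = {
        name: replication_report(
            candidates,
            {f: reference_direction.get(f, 0) for f in candidates.features},
            table,
            alpha=alpha,
            group_id=name,
        )
        for name, table in subtype_tables.items()
    }
    return survivors, reports


def classify_specificity(
    tumor: AssociationResult, normal: AssociationResult, alpha: float = 0.05
) -> SpecificityCall:
    """Partition a tumor/normal association pair into one specificity class."""
    if tumor.feature_id != normal.feature_id:
        raise DomainError(
            f"feature mismatch: tumor={tumor.feature_id!r} normal={normal.feature_id!r}"
        )
    sig_t = tumor.p_value <= alpha
    sig_n = normal.p_value <= alpha
    if sig_t and sig_n:
        call = "consistent" if tumor.direction == normal.direction else "opposite"
    elif sig_t:
        call = "tumor_specific"
    elif sig_n:
        call = "normal_specific"
    else:
        call = "neither"
    return SpecificityCall(
        feature_id=tumor.feature_id,
        cancer_type=tumor.cohort_id,
        call=call,
        tumor_result=tumor,
        normal_result=normal,
    )


def paired_regulation_frequency(
    cohort: ExpressionCohort,
    feature_id: str,
    log_fc_threshold: float = 1.0,
) -> tuple[float, float]:
    """Fraction of tumor/normal pairs with the feature up- or down-regulated.

    Pairs are linked by the ``pair_id`` annotation; values are log-scale, so
    the default threshold of 1.0 is a two-fold change.  Returns
    ``(up_fraction, down_fraction)`` over complete pairs.
    """
    ann = cohort.sample_annotations
    if ann is None or "tissue" not in ann.columns or "pair_id" not in ann.columns:
        raise DomainError("cohort lacks tissue/pair_id annotations for paired analysis")
    expr = cohort.values.loc[feature_id] if feature_id in cohort.values.index else None
    if expr is None:
        raise DomainError(f"feature {feature_id!r} not in cohort {cohort.cohort_id}")
    tumors: dict[str, float] = {}
    normals: dict[str, float] = {}
    for sid in cohort.samples:
        if sid not in ann.index:
            continue
        pid = ann.loc[sid, "pair_id"]
        tissue = ann.loc[sid, "tissue"]
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            continue
        if tissue == "tumor":
            tumors[str(pid)] = float(expr[sid])
        elif tissue == "normal":
            normals[str(pid)] = float(expr[sid])
    complete = sorted(set(tumors) & set(normals))
    if not complete:
        raise DomainError("no complete tumor/normal pairs")
    diffs = np.array([tumors[p] - normals[p] for p in complete])
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size == 0:
        raise DomainError("no complete tumor/normal pairs with finite values")
    up = float((diffs >= log_fc_threshold).mean())
    down = float((diffs <= -log_fc_threshold).mean())
    return up, down
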