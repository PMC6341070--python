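"""Seed-gene association: per-feature simple linear regression.

Every downstream filter consumes the statistics produced here.  For each
non-seed feature the model regresses that feature's expression on the seed
gene's expression (ordinary least squares with intercept) within one cohort
and records the slope, its standard error, the two-sided t-test p-value
(n - 2 degrees of freedom), r-squared (the squared Pearson correlation) and
the one-predictor adjusted r-squared

    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2).

The orientation (target on seed) affects only the coefficient; p, t and
r-squared are symmetric in the two variables for a single predictor, so
screening decisions do not depend on it.

Missing cells are handled pairwise: each feature's regression uses the
samples where both that feature and the seed are observed.

The module exposes both a functional surface (:func:`fit_seed_association`,
:func:`associate_all`, :func:`permutation_p`) and a model/results pair
(:class:`SeedAssociation` / :class:`SeedAssociationResults`) in the style of
statsmodels: build the model from a cohort, call ``fit()``, inspect
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    ConstantFeatureError,
    InsufficientSamplesError,
    KeyNotFoundError,
)
from .io import ExpressionCohort

__all__ = [
    "AssociationResult",
    "AssociationTable",
    "SeedAssociation",
    "SeedAssociationResults",
    "fit_seed_association",
    "associate_all",
    "permutation_p",
]

MIN_SAMPLES = 4


@dataclass(frozen=True)
class AssociationResult:
    """OLS statistics for one (feature, cohort) pair.

    ``direction`` is the sign of the slope; under exact collinearity
    ``p_value`` is 0, ``r2`` is 1 and ``se`` degenerates to 0.
    """

    feature_id: str
    cohort_id: str
    n: int
    coefficient: float
    se: float
    t: float
    p_value: float
    r2: float
    adjusted_r2: float
    direction: int

    def significant(self, alpha: float) -> bool:
        return self.p_value <= alpha


@dataclass
class AssociationTable:
    """Collection of :class:`AssociationResult` keyed by (feature, cohort).

    The seed feature itself never appears among the results.  ``skipped``
    records features that failed regression preconditions, with the reason.
    """

    results: dict[tuple[str, str], AssociationResult] = field(default_factory=dict)
    seed_id: str = ""
    cohorts: list[str] = field(default_factory=list)
    skipped: dict[tuple[str, str], str] = field(default_factory=dict)

    def get(self, feature_id: str, cohort_id: str) -> AssociationResult | None:
        return self.results.get((feature_id, cohort_id))

    @property
    def feature_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f, _ in self.results:
            seen.setdefault(f, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": r.feature_id,
                "cohort_id": r.cohort_id,
                "n": r.n,
                "coefficient": r.coefficient,
                "se": r.se,
                "t": r.t,
                "p_value": r.p_value,
                "r2": r.r2,
                "adjusted_r2": r.adjusted_r2,
                "direction": r.direction,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows, columns=[
            "feature_id", "cohort_id", "n", "coefficient", "se", "t",
            "p_value", "r2", "adjusted_r2", "direction",
        ])

    def merged(self, other: "AssociationTable") -> "AssociationTable":
        if self.seed_id and other.seed_id and self.seed_id != other.seed_id:
            raise ConfigurationError(
                f"cannot merge tables with different seeds: {self.seed_id!r} vs {other.seed_id!r}"
            )
        results = dict(self.results)
        results.update(other.results)
        skipped = dict(self.skipped)
        skipped.update(other.skipped)
        cohorts = list(dict.fromkeys(self.cohorts + other.cohorts))
        return AssociationTable(results=results, seed_id=self.seed_id or other.seed_id,
                                cohorts=cohorts, skipped=skipped)


# ---------------------------------------------------------------------------
# numerical kernel


def _assoc_kernel(seed: np.ndarray, targets: np.ndarray):
    """Vectorised pairwise-complete OLS of each target row on the seed.

    Returns per-row arrays (n, beta, se, t, p, r2) plus a status array:
    0 = ok, 1 = too few complete pairs, 2 = constant feature/seed.
    Both the single-feature and the all-features paths run through this
    function, so they are bitwise identical by construction.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    seed = np.asarray(seed, dtype=float)
    mask = np.isfinite(targets) & np.isfinite(seed)[None, :]
    n = mask.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        sum_x = np.where(mask, seed, 0.0).sum(axis=1)
        sum_y = np.where(mask, targets, 0.0).sum(axis=1)
        mean_x = sum_x / n
        mean_y = sum_y / n
        xc = np.where(mask, seed[None, :] - mean_x[:, None], 0.0)
        yc = np.where(mask, targets - mean_y[:, None], 0.0)
        sxx = (xc * xc).sum(axis=1)
        syy = (yc * yc).sum(axis=1)
        sxy = (xc * yc).sum(axis=1)

        status = np.zeros(targets.shape[0], dtype=int)
        status[n < MIN_SAMPLES] = 1
        status[(status == 0) & ((sxx <= 0.0) | (syy <= 0.0))] = 2
        ok = status == 0

        beta = np.where(ok, sxy / sxx, np.nan)
        rss = np.maximum(syy - sxy * sxy / np.where(sxx > 0, sxx, np.nan), 0.0)
        # exact collinearity leaves only rounding residue; snap it to zero so
        # the degenerate case reports se = 0, p = 0, r2 = 1 exactly
        rss = np.where(rss <= 1e-12 * syy, 0.0, rss)
        s2 = rss / (n - 2)
        se = np.where(ok, np.sqrt(s2 / sxx), np.nan)
        r2 = np.where(ok, np.where(rss == 0.0, 1.0, (sxy * sxy) / (sxx * syy)), np.nan)
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = np.empty_like(beta)
        p.fill(np.nan)
        finite_t = ok & np.isfinite(t)
        p[finite_t] = 2.0 * stats.t.sf(np.abs(t[finite_t]), n[finite_t] - 2)
        p[ok & ~np.isfinite(t)] = 0.0  # exact collinearity
    return n.astype(int), beta, se, t, p, r2, status


def _result_from_row(feature_id, cohort_id, n, beta, se, t, p, r2) -> AssociationResult:
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AssociationResult(
        feature_id=feature_id,
        cohort_id=cohort_id,
        n=int(n),
        coefficient=float(beta),
        se=float(se),
        t=float(t),
        p_value=float(p),
        r2=float(r2),
        adjusted_r2=float(adj),
        direction=int(np.sign(beta)),
    )


def fit_seed_association(
    cohort: ExpressionCohort, seed_id: str, target_id: str
) -> AssociationResult:
    """OLS of one target feature on the seed feature within a cohort.

    Requires at least 4 complete sample pairs and nonzero variance in both
    features on that subset.
    """
    seed = cohort.feature_values(seed_id)
    target = cohort.feature_values(target_id)
    n, beta, se, t, p, r2, status = _assoc_kernel(seed, target[None, :])
    if status[0] == 1:
        raise InsufficientSamplesError(
            f"{target_id}: {n[0]} complete pairs, need >= {MIN_SAMPLES}"
        )
    if status[0] == 2:
        raise ConstantFeatureError(f"{target_id} or seed constant on complete pairs")
    return _result_from_row(target_id, cohort.cohort_id, n[0], beta[0], se[0], t[0], p[0], r2[0])


def associate_all(cohort: ExpressionCohort, seed_id: str) -> AssociationTable:
    """Regress every non-seed feature on the seed; one vectorised pass.

    Features failing preconditions (too few complete pairs, zero variance)
    are listed in ``table.skipped`` with a reason instead of a result.
    """
    if seed_id not in cohort.values.index:
        raise KeyNotFoundError(f"seed {seed_id!r} not in cohort {cohort.cohort_id}")
    features = [f for f in cohort.features if f != seed_id]
    seed = cohort.feature_values(seed_id)
    targets = cohort.values.loc[features].to_numpy(dtype=float)
    n, beta, se, t, p, r2, status = _assoc_kernel(seed, targets)
    table = AssociationTable(seed_id=seed_id, cohorts=[cohort.cohort_id])
    reasons = {1: "insufficient complete pairs", 2: "constant feature"}
    for i, fid in enumerate(features):
        if status[i]:
            table.skipped[(fid, cohort.cohort_id)] = reasons[status[i]]
            continue
        table.results[(fid, cohort.cohort_id)] = _result_from_row(
            fid, cohort.cohort_id, n[i], beta[i], se[i], t[i], p[i], r2[i]
        )
    return table


def permutation_p(
    cohort: ExpressionCohort,
    seed_id: str,
    target_id: str,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the seed-target slope.

    The seed vector is permuted ``n_perm`` times; because the permuted seed
    keeps its marginal values, ranking by absolute slope equals ranking by
    absolute correlation.  The add-one correction (count+1)/(n_perm+1) makes
    the smallest attainable value 1/(n_perm+1).
    """
    if n_perm < 1000:
        raise ConfigurationError("n_perm must be >= 1000")
    obs = fit_seed_association(cohort, seed_id, target_id)
    seed = cohort.feature_values(seed_id)
    target = cohort.feature_values(target_id)
    keep = np.isfinite(seed) & np.isfinite(target)
    x = seed[keep]
    y = target[keep]
    rng = np.random.default_rng(rng_seed)
    yc = y - y.mean()
    count = 0
    # permute in blocks to bound memory at ~block * n floats
    block = max(1, min(n_perm, 2_000_000 // max(len(x), 1)))
    done = 0
    abs_obs = abs(obs.coefficient)
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.empty((b, len(x)))
        for i in range(b):
            perms[i] = rng.permutation(x)
        mx = perms.mean(axis=1, keepdims=True)
        xc = perms - mx
        sxx = (xc * xc).sum(axis=1)
        sxy = xc @ yc
        slopes = sxy / sxx
        count += int((np.abs(slopes) >= abs_obs - 1e-15).sum())
        done += b
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# model / results surface


class SeedAssociation:
    """Genome-wide seed-gene association model for one cohort.

    Examples
    --------
    >>> model = SeedAssociation(cohort, seed_id="SEED")
    >>> res = model.fit()
    >>> res.table.get("P0001", cohort.cohort_id).p_value  # doctest: +SKIP
    """

    def __init__(self, cohort: ExpressionCohort, seed_id: str):
        if seed_id not in cohort.values.index:
            raise KeyNotFoundError(f"seed {seed_id!r} not in cohort {cohort.cohort_id}")
        self.cohort = cohort
        self.seed_id = seed_id

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, seed_id: str, cohort_id: str = "cohort"
    ) -> "SeedAssociation":
        """Build the model from a features x samples DataFrame."""
        return cls(ExpressionCohort(cohort_id=cohort_id, values=values), seed_id)

    def fit(self) -> "SeedAssociationResults":
        return SeedAssociationResults(self, associate_all(self.cohort, self.seed_id))


class SeedAssociationResults:
    """Fit results: the association table plus summary/report helpers."""

    def __init__(self, model: SeedAssociation, table: AssociationTable):
        self.model = model
        self.table = table

    @property
    def n_features(self) -> int:
        return len(self.table.results)

    @property
    def n_skipped(self) -> int:
        return len(self.table.skipped)

    def to_frame(self) -> pd.DataFrame:
        return self.table.to_frame()

    def with_fdr(self) -> pd.DataFrame:
        """Result frame plus a Benjamini-Hochberg q-value column.

        Informational only: the screening tiers consult raw p-values.
        """
        frame = self.to_frame().sort_values("p_value").reset_index(drop=True)
        m = len(frame)
        rank = np.arange(1, m + 1)
        q = frame["p_value"].to_numpy() * m / rank
        frame["q_value"] = np.minimum.accumulate(q[::-1])[::-1]
        return frame

    def summary(self, top: int = 10) -> str:
        frame = self.to_frame().sort_values("p_value")
        lines = [
            "Seed association results",
            "========================",
            f"cohort:      {self.model.cohort.cohort_id}",
            f"seed:        {self.model.seed_id}",
            f"features:    {self.n_features} fitted, {self.n_skipped} skipped",
            f"samples:     {self.model.cohort.n_samples}",
            "",
            f"top {min(top, len(frame))} features by p-value:",
            frame.head(top).to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                columns=["feature_id", "n", "coefficient", "se", "t", "p_value", "adjusted_r2"],
            ),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SeedAssociationResults cohort={self.model.cohort.cohort_id!r} "
            f"seed={self.model.seed_id!r} n={self.n_features}>"
        )
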