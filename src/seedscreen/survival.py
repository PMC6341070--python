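"""Expression-dichotomized overall-survival screening.

Patients are split into high- and low-expression groups at the antimode of
the expression distribution — the "significant low point" of its histogram,
operationalised as the minimum of a Gaussian kernel density estimate
(Silverman bandwidth) between the two dominant modes.  Unimodal features
fall back to the sample median.  The two groups are then compared with the
standard two-group log-rank test; the direction of benefit (which group
lives longer) comes from the restricted mean survival of the two
Kaplan-Meier curves.

The Kaplan-Meier estimate itself is delegated to lifelines; the log-rank
statistic is accumulated here because the result object exposes the
per-group observed and expected event counts, which the screen reports.
Ties between an event and a censoring at the same time follow the standard
convention: the censored subject is still at risk at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import DomainError
from .io import ExpressionCohort, SurvivalRecord

__all__ = [
    "DichotomyResult",
    "LogRankResult",
    "KMCurve",
    "antimode_threshold",
    "km_curve",
    "logrank_test",
    "survival_screen",
    "SurvivalScreen",
    "SurvivalScreenResults",
]

#: Smallest allowed fraction of samples in either expression group.
MIN_GROUP_FRAC = 0.1

#: Grid resolution for the density scan.
KDE_GRID_SIZE = 512


@dataclass
class DichotomyResult:
    """An expression cut-point and the resulting high/low group assignment."""

    feature_id: str
    threshold: float
    method: str  # "antimode" | "median_fallback"
    group_of: dict[str, str]
    group_sizes: tuple[int, int]  # (n_low, n_high)


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank test outcome (chi-squared, 1 df)."""

    statistic: float
    p_value: float
    n_low: int
    n_high: int
    observed_events: tuple[float, float]
    expected_events: tuple[float, float]


class KMCurve:
    """Right-continuous Kaplan-Meier survival curve, S(0) = 1."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = times
        self.survival = survival

    @classmethod
    def from_records(cls, records: list[SurvivalRecord]) -> "KMCurve":
        if not records:
            raise DomainError("cannot estimate a survival curve from no records")
        kmf = KaplanMeierFitter()
        kmf.fit(
            durations=[r.time for r in records],
            event_observed=[r.event for r in records],
        )
        sf = kmf.survival_function_
        return cls(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def restricted_mean(self, tau: float | None = None) -> float:
        """Area under the curve up to ``tau`` (default: last observed time)."""
        tau = float(self.times[-1]) if tau is None else tau
        knots = self.times[self.times <= tau]
        if knots.size == 0 or knots[0] > 0:
            knots = np.concatenate([[0.0], knots])
        vals = np.array([self(t) for t in knots])
        widths = np.diff(np.concatenate([knots, [tau]]))
        return float((vals * widths).sum())


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate as a step function."""
    return KMCurve.from_records(records)


def antimode_threshold(
    values: np.ndarray | list[float],
    sample_ids: list[str] | None = None,
    feature_id: str = "",
    min_group_frac: float = MIN_GROUP_FRAC,
    bw_method: str | float = "silverman",
    grid_size: int = KDE_GRID_SIZE,
) -> DichotomyResult:
    """Split expression values at the density antimode between the two modes.

    A Gaussian KDE (Silverman bandwidth) is scanned on a regular grid.  If
    it has at least two local maxima, the threshold is the location of the
    minimum density between the two highest maxima and the method is
    ``"antimode"``; otherwise — or when the antimode split would leave
    either group below ``min_group_frac`` of the samples — the threshold is
    the sample median (``"median_fallback"``).  Deterministic given values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 20:
        raise DomainError(f"antimode split needs >= 20 values, got {arr.size}")
    if np.ptp(arr) == 0:
        raise DomainError("constant expression values")
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(arr))]
    if len(ids) != arr.size:
        raise DomainError("sample_ids length does not match finite values")

    kde = stats.gaussian_kde(arr, bw_method=bw_method)
    lo, hi = arr.min(), arr.max()
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    maxima = interior[is_max]

    threshold = float(np.median(arr))
    method = "median_fallback"
    if maxima.size >= 2:
        top_two = maxima[np.argsort(dens[maxima])][-2:]
        left, right = int(top_two.min()), int(top_two.max())
        between = np.arange(left, right + 1)
        cut = float(grid[between[np.argmin(dens[between])]])
        n_low = int((arr <= cut).sum())
        n_high = arr.size - n_low
        if min(n_low, n_high) >= min_group_frac * arr.size:
            threshold, method = cut, "antimode"

    # keep the cut strictly inside the observed range
    if not (lo < threshold < hi):
        threshold = float(np.median(arr))
        method = "median_fallback"
        if not (lo < threshold < hi):
            inner = arr[(arr > lo) & (arr < hi)]
            if inner.size == 0:
                raise DomainError("cannot place a threshold strictly inside the value range")
            threshold = float(inner[0])

    group_of = {sid: ("low" if v <= threshold else "high") for sid, v in zip(ids, arr)}
    n_low = sum(1 for g in group_of.values() if g == "low")
    return DichotomyResult(
        feature_id=feature_id,
        threshold=threshold,
        method=method,
        group_of=group_of,
        group_sizes=(n_low, arr.size - n_low),
    )


def logrank_test(
    records: list[SurvivalRecord], group_of: dict[str, str]
) -> LogRankResult:
    """Standard two-group log-rank test.

    At each distinct event time the expected events per group follow the
    hypergeometric model; the statistic is (O1 - E1)^2 / V with the summed
    hypergeometric variance, referred to chi-squared with 1 df.
    """
    unassigned = [r.sample_id for r in records if r.sample_id not in group_of]
    if unassigned:
        raise DomainError(f"records without group assignment: {unassigned[:5]}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    in_low = np.array([group_of[r.sample_id] == "low" for r in records])
    n_low_total = int(in_low.sum())
    n_high_total = len(records) - n_low_total
    if n_low_total == 0 or n_high_total == 0:
        raise DomainError("both groups must be non-empty")

    obs_low = exp_low = var = 0.0
    total_events = float(events.sum())
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & in_low).sum())
        d = float((events & (times == t)).sum())
        d1 = float((events & (times == t) & in_low).sum())
        obs_low += d1
        exp_low += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    o_high = total_events - obs_low
    e_high = total_events - exp_low
    if var <= 0:
        statistic = 0.0
        p = 1.0
    else:
        statistic = (obs_low - exp_low) ** 2 / var
        p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(
        statistic=float(statistic),
        p_value=max(p, np.finfo(float).tiny) if statistic > 0 else 1.0,
        n_low=n_low_total,
        n_high=n_high_total,
        observed_events=(float(obs_low), float(o_high)),
        expected_events=(float(exp_low), float(e_high)),
    )


def survival_screen(
    cohort: ExpressionCohort,
    survival: list[SurvivalRecord],
    features: list[str],
    min_group_frac: float = MIN_GROUP_FRAC,
    min_samples: int = 20,
) -> pd.DataFrame:
    """Antimode-dichotomized log-rank screen over a list of features.

    For each feature: split samples at the antimode (median fallback), run
    the log-rank test between the low and high groups, and call the
    direction of benefit from the restricted mean survival of the two
    Kaplan-Meier curves.  Returns one row per feature.
    """
    surv_by_id = {r.sample_id: r for r in survival}
    linked = [s for s in cohort.samples if s in surv_by_id]
    if len(linked) < min_samples:
        raise DomainError(
            f"only {len(linked)} samples have both expression and survival, need >= {min_samples}"
        )
    rows = []
    for fid in features:
        expr = cohort.values.loc[fid, linked]
        usable = expr.index[np.isfinite(expr.to_numpy(dtype=float))].tolist()
        if len(usable) < min_samples:
            raise DomainError(f"feature {fid!r}: only {len(usable)} usable samples")
        vals = cohort.values.loc[fid, usable].to_numpy(dtype=float)
        dich = antimode_threshold(
            vals, sample_ids=usable, feature_id=fid, min_group_frac=min_group_frac
        )
        recs = [surv_by_id[s] for s in usable]
        lr = logrank_test(recs, dich.group_of)
        low = km_curve([r for r in recs if dich.group_of[r.sample_id] == "low"])
        high = km_curve([r for r in recs if dich.group_of[r.sample_id] == "high"])
        tau = min(low.times[-1], high.times[-1])
        benefit = "low" if low.restricted_mean(tau) >= high.restricted_mean(tau) else "high"
        rows.append(
            {
                "feature_id": fid,
                "threshold": dich.threshold,
                "method": dich.method,
                "n_low": lr.n_low,
                "n_high": lr.n_high,
                "statistic": lr.statistic,
                "p_value": lr.p_value,
                "direction_of_benefit": benefit,
            }
        )
    return pd.DataFrame(rows)


class SurvivalScreen:
    """Model-style wrapper: screen features for survival effects in a cohort."""

    def __init__(
        self,
        cohort: ExpressionCohort,
        survival: list[SurvivalRecord],
        features: list[str] | None = None,
        min_group_frac: float = MIN_GROUP_FRAC,
    ):
        self.cohort = cohort
        self.survival = survival
        self.features = list(features) if features is not None else cohort.features
        self.min_group_frac = min_group_frac

    def fit(self) -> "SurvivalScreenResults":
        frame = survival_screen(
            self.cohort, self.survival, self.features, min_group_frac=self.min_group_frac
        )
        return SurvivalScreenResults(self, frame)


class SurvivalScreenResults:
    def __init__(self, model: SurvivalScreen, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["p_value"] <= alpha]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Survival screen results",
            "=======================",
            f"cohort:   {self.model.cohort.cohort_id}",
            f"features: {len(self.frame)} screened, {len(sig)} significant at 0.05",
            "",
            self.frame.sort_values("p_value").to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)
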