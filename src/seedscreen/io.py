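"""Domain containers and tab-delimited readers/writers.

Expression matrices are features x samples TSV files (first column feature
id, header row of sample ids), optionally gzip-compressed.  Values are
assumed to be on a log scale already; ``transform="log2_offset"`` applies
``log2(x + 0.001)`` for raw TPM-style inputs.  Missing cells are tolerated:
a feature missing in more than ``max_missing_frac`` of samples is dropped at
read time, remaining missing cells are excluded pairwise from downstream
regressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "ExpressionCohort",
    "ProbeMap",
    "SurvivalRecord",
    "read_expression_matrix",
    "read_sample_metadata",
    "read_probe_map",
    "read_survival",
    "write_association_table",
    "read_association_table",
]

#: Offset used by the log2 transform for raw TPM-like values.
LOG2_OFFSET = 0.001

#: A feature is dropped when more than this fraction of its samples is missing.
MAX_MISSING_FRAC = 0.2


@dataclass
class ExpressionCohort:
    """One cohort's expression matrix plus per-sample annotations.

    Parameters
    ----------
    cohort_id : str
        Identifier for the cohort (e.g. a GEO accession).
    values : pandas.DataFrame
        Log-scale expression, features in rows, samples in columns.  NaN
        marks a missing cell; infinities are rejected.
    sample_annotations : pandas.DataFrame
        Indexed by sample id; recognised columns are ``group``, ``subtype``,
        ``tissue`` (``tumor``/``normal``) and ``pair_id``; extra columns are
        carried through untouched.
    """

    cohort_id: str
    values: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids in {self.cohort_id}: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in {self.cohort_id}: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise DomainError(f"non-finite expression values in {self.cohort_id}")
        if self.sample_annotations is None:
            self.sample_annotations = pd.DataFrame(index=cols.copy())

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature_values(self, feature_id: str) -> np.ndarray:
        from .errors import KeyNotFoundError

        if feature_id not in self.values.index:
            raise KeyNotFoundError(f"feature {feature_id!r} not in cohort {self.cohort_id}")
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionCohort":
        ids = [s for s in sample_ids if s in self.values.columns]
        return ExpressionCohort(
            cohort_id=self.cohort_id,
            values=self.values.loc[:, ids],
            sample_annotations=self.sample_annotations.loc[ids]
            if self.sample_annotations is not None
            else None,
        )


@dataclass
class ProbeMap:
    """Feature id -> gene symbol map, with optional transcription-factor flags.

    Several feature ids (array probes) may share one gene symbol; each
    feature maps to exactly one symbol.  Features absent from the map
    collapse to their own id.
    """

    entries: dict[str, str] = field(default_factory=dict)
    tf_flag: dict[str, bool] = field(default_factory=dict)

    def gene(self, feature_id: str) -> str:
        return self.entries.get(feature_id, feature_id)

    def genes_of(self, feature_ids: Iterable[str]) -> set[str]:
        return {self.gene(f) for f in feature_ids}

    def is_tf(self, feature_id: str) -> bool:
        return bool(self.tf_flag.get(feature_id, False))


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored time-to-event observation for one sample.

    ``event=True`` means the event (death) was observed at ``time`` (days);
    ``event=False`` means follow-up was censored at ``time``.
    """

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise DomainError(f"survival time must be finite and >= 0, got {self.time}")


# ---------------------------------------------------------------------------
# readers


def read_expression_matrix(
    path: str | Path,
    transform: str = "none",
    cohort_id: str | None = None,
    max_missing_frac: float = MAX_MISSING_FRAC,
) -> ExpressionCohort:
    """Read a features x samples TSV into an :class:`ExpressionCohort`.

    ``transform="log2_offset"`` applies ``log2(x + 0.001)`` to non-negative
    raw values; ``"none"`` ingests the values as printed.  Row and column
    order is preserved.  Features with more than ``max_missing_frac``
    missing cells are dropped.
    """
    if transform not in ("none", "log2_offset"):
        raise ValueError(f"unknown transform {transform!r}")
    path = Path(path)
    # pandas silently renames duplicate column headers, so check the raw header
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError(f"duplicate sample ids in {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.index.duplicated().any():
        raise FormatError(f"duplicate feature ids in {path}")
    values = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # locate unparseable cells explicitly so the error names row and column
    mask_bad = numeric.isna() & df.notna()
    if mask_bad.to_numpy().any():
        r, c = np.argwhere(mask_bad.to_numpy())[0]
        raise FormatError(
            f"unparseable expression value at feature {df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    values.iloc[:, :] = numeric.to_numpy(dtype=float)
    if transform == "log2_offset":
        arr = values.to_numpy(dtype=float)
        if np.isfinite(arr).any() and np.nanmin(arr) < 0:
            raise DomainError(f"negative raw values with log2_offset transform in {path}")
        values = np.log2(values + LOG2_OFFSET)
    # drop features with excessive missingness, keep pairwise-complete rest
    frac_missing = values.isna().mean(axis=1)
    values = values.loc[frac_missing <= max_missing_frac]
    return ExpressionCohort(cohort_id=cohort_id or path.stem, values=values)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample annotation TSV keyed by ``sample_id``.

    Returns a DataFrame indexed by sample id.  Optional columns (``group``,
    ``subtype``, ``tissue``, ``pair_id``) and any unknown columns are carried
    through; empty cells become missing values, not empty strings.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"metadata file {path} lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"duplicated sample_id in metadata file {path}")
    df = df.set_index("sample_id")
    return df


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a probe-to-gene TSV (columns: feature_id, gene, optional is_tf)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "feature_id" not in df.columns or "gene" not in df.columns:
        raise FormatError(f"probe map {path} needs feature_id and gene columns")
    if df["feature_id"].duplicated().any():
        raise FormatError(f"feature id mapped more than once in {path}")
    entries = dict(zip(df["feature_id"], df["gene"]))
    tf_flag: dict[str, bool] = {}
    if "is_tf" in df.columns:
        truthy = {"1", "true", "yes", "y"}
        tf_flag = {f: str(v).strip().lower() in truthy for f, v in zip(df["feature_id"], df["is_tf"])}
    return ProbeMap(entries=entries, tf_flag=tf_flag)


_EVENT_VALUES = {"0": False, "1": True, "false": False, "true": True}


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival TSV with sample_id, time (days) and event columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"survival file {path} lacks column {col!r}")
    records = []
    for _, row in df.iterrows():
        try:
            t = float(row["time"])
        except ValueError as exc:
            raise FormatError(f"unparseable time {row['time']!r} in {path}") from exc
        ev_raw = str(row["event"]).strip().lower()
        if ev_raw not in _EVENT_VALUES:
            raise FormatError(f"event must be 0/1/true/false, got {row['event']!r} in {path}")
        records.append(SurvivalRecord(sample_id=str(row["sample_id"]), time=t, event=_EVENT_VALUES[ev_raw]))
    return records


# ---------------------------------------------------------------------------
# association table round trip

_ASSOC_COLUMNS = [
    "feature_id",
    "gene",
    "cohort_id",
    "n",
    "coefficient",
    "se",
    "p_value",
    "adjusted_r2",
    "direction",
]


def write_association_table(table, path: str | Path, probe_map: ProbeMap | None = None) -> None:
    """Write an association table as TSV, 12 significant digits per statistic.

    One row per (feature, cohort); round-trips through
    :func:`read_association_table` to 1e-9 relative.
    """
    frame = table.to_frame()
    if frame.empty:
        raise DomainError("refusing to write an empty association table")
    frame = frame.copy()
    pm = probe_map or ProbeMap()
    frame.insert(1, "gene", [pm.gene(f) for f in frame["feature_id"]])
    frame = frame[_ASSOC_COLUMNS + [c for c in frame.columns if c not in _ASSOC_COLUMNS]]
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_association_table(path: str | Path):
    """Read a TSV written by :func:`write_association_table`."""
    from .association import AssociationResult, AssociationTable

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ASSOC_COLUMNS if c not in df.columns and c != "gene"]
    if missing:
        raise FormatError(f"association table {path} lacks columns {missing}")
    results = {}
    for _, row in df.iterrows():
        n = int(row["n"])
        coef = float(row["coefficient"])
        se = float(row["se"])
        p = float(row["p_value"])
        adj = float(row["adjusted_r2"])
        # invert the one-predictor adjustment to recover r2
        r2 = 1.0 - (1.0 - adj) * (n - 2) / (n - 1)
        res = AssociationResult(
            feature_id=str(row["feature_id"]),
            cohort_id=str(row["cohort_id"]),
            n=n,
            coefficient=coef,
            se=se,
            t=coef / se if se > 0 else math.inf * np.sign(coef),
            p_value=p,
            r2=min(max(r2, 0.0), 1.0),
            adjusted_r2=adj,
            direction=int(row["direction"]),
        )
        results[(res.feature_id, res.cohort_id)] = res
    seed_id = ""
    cohorts = sorted(df["cohort_id"].astype(str).unique())
    return AssociationTable(results=results, seed_id=seed_id, cohorts=cohorts)
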