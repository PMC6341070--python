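"""Reference seed-association statistics for a worked example.

Published association statistics of a seed gene with 11 candidate probes
(10 transcription-factor genes; NCOA1 is represented by two probes) across
eight independent pediatric B-ALL microarray cohorts.  The values — p-value,
slope, its standard error and adjusted r-squared per (probe, cohort) — are
transcribed as printed, so they serve as a fixed regression fixture for the
screening tiers: all 11 probes pass the relaxed tier, and exactly the PRMT2
and RBL2 probes pass the strict tier.
"""

from __future__ import annotations

import math

from .association import AssociationResult, AssociationTable
from .io import ProbeMap

__all__ = ["ball_candidate_tables", "ball_probe_map", "BALL_COHORT_SIZES", "BALL_PROBES"]

BALL_PROBES = [
    ("202098_s_at", "PRMT2"),
    ("202449_s_at", "RXRA"),
    ("204529_s_at", "TOX"),
    ("205038_at", "IKZF1"),
    ("209107_x_at", "NCOA1"),
    ("209930_s_at", "NFE2"),
    ("210249_s_at", "NCOA1"),
    ("212330_at", "TFDP1"),
    ("212331_at", "RBL2"),
    ("216241_s_at", "TCEA1"),
    ("43544_at", "MED16"),
]

BALL_COHORT_SIZES = {
    "GSE7440": 99,
    "GSE10255": 161,
    "GSE10792": 160,
    "GSE11877": 207,
    "GSE13351": 107,
    "GSE13425": 190,
    "GSE33315": 575,
    "GSE635": 173,
}

# per cohort: (p_values, coefficients, standard errors, adjusted r2),
# one entry per probe in BALL_PROBES order
_TABLE: dict[str, tuple[list[float], list[float], list[float], list[float]]] = {
    "GSE7440": (
        [7.49e-10, 7.10e-13, 8.58e-7, 4.89e-5, 1.69e-10, 2.64e-9, 2.93e-13, 2.94e-12, 8.99e-10, 8.56e-8, 3.64e-11],
        [0.64, 0.61, 0.33, 0.38, 0.84, 0.38, 0.92, 0.51, 0.58, 0.65, 0.74],
        [0.09, 0.07, 0.06, 0.09, 0.12, 0.06, 0.11, 0.06, 0.09, 0.11, 0.10],
        [0.32, 0.41, 0.21, 0.15, 0.34, 0.30, 0.42, 0.39, 0.32, 0.25, 0.36],
    ),
    "GSE10255": (
        [0.01, 0.01, 7.56e-4, 0.03, 4.10e-3, 4.80e-15, 1.84e-3, 1.35e-3, 4.50e-3, 3.65e-3, 9.86e-9],
        [0.40, 0.20, 0.16, 0.26, 0.57, 0.26, 0.51, 0.15, 0.37, 0.49, 0.72],
        [0.15, 0.08, 0.05, 0.12, 0.20, 0.03, 0.16, 0.05, 0.13, 0.17, 0.12],
        [0.04, 0.03, 0.06, 0.02, 0.04, 0.32, 0.05, 0.06, 0.04, 0.05, 0.18],
    ),
    "GSE10792": (
        [5.74e-7, 0.01, 0.02, 0.03, 0.02, 1.67e-3, 0.04, 8.94e-7, 6.12e-4, 2.96e-3, 5.79e-4],
        [0.53, 0.22, 0.16, 0.33, 0.48, 0.24, 0.44, 0.29, 0.64, 0.84, 0.51],
        [0.10, 0.08, 0.07, 0.14, 0.21, 0.07, 0.21, 0.06, 0.18, 0.28, 0.14],
        [0.26, 0.07, 0.05, 0.05, 0.05, 0.11, 0.04, 0.26, 0.13, 0.10, 0.13],
    ),
    "GSE11877": (
        [4.93e-9, 1.65e-3, 2.19e-3, 1.03e-6, 1.02e-4, 1.60e-5, 1.21e-4, 2.24e-3, 8.65e-13, 1.96e-4, 2.71e-7],
        [0.39, 0.17, 0.17, 0.33, 0.49, 0.15, 0.46, 0.20, 0.59, 0.43, 0.34],
        [0.06, 0.05, 0.05, 0.07, 0.12, 0.03, 0.12, 0.06, 0.08, 0.11, 0.06],
        [0.15, 0.04, 0.04, 0.11, 0.07, 0.08, 0.07, 0.04, 0.22, 0.06, 0.12],
    ),
    "GSE13351": (
        [4.53e-9, 3.81e-4, 3.94e-3, 1.02e-3, 1.80e-5, 1.89e-6, 3.54e-5, 1.72e-3, 3.46e-12, 4.43e-5, 9.53e-6],
        [0.58, 0.24, 0.19, 0.31, 0.91, 0.28, 0.82, 0.20, 0.67, 0.58, 0.45],
        [0.09, 0.07, 0.07, 0.09, 0.20, 0.06, 0.19, 0.06, 0.08, 0.14, 0.10],
        [0.31, 0.12, 0.08, 0.10, 0.18, 0.22, 0.16, 0.09, 0.41, 0.16, 0.19],
    ),
    "GSE13425": (
        [9.14e-5, 1.01e-6, 5.30e-3, 1.18e-3, 2.07e-4, 2.99e-3, 3.79e-3, 5.78e-3, 1.32e-6, 3.31e-4, 1.47e-3],
        [0.36, 0.39, 0.25, 0.31, 0.66, 0.18, 0.52, 0.20, 0.54, 0.54, 0.33],
        [0.09, 0.08, 0.09, 0.09, 0.17, 0.06, 0.18, 0.07, 0.11, 0.15, 0.10],
        [0.09, 0.14, 0.04, 0.06, 0.08, 0.05, 0.05, 0.04, 0.14, 0.08, 0.06],
    ),
    "GSE33315": (
        [4.32e-17, 9.08e-5, 3.21e-3, 1.88e-9, 1.38e-12, 1.32e-26, 8.79e-14, 3.64e-16, 1.81e-23, 8.81e-11, 5.83e-21],
        [0.56, 0.16, 0.11, 0.34, 0.75, 0.22, 0.67, 0.24, 0.68, 0.57, 0.60],
        [0.06, 0.04, 0.04, 0.05, 0.10, 0.02, 0.09, 0.03, 0.06, 0.09, 0.06],
        [0.13, 0.03, 0.02, 0.07, 0.10, 0.21, 0.11, 0.13, 0.19, 0.08, 0.17],
    ),
    "GSE635": (
        [2.01e-6, 1.38e-4, 5.41e-7, 0.02, 3.65e-3, 1.23e-3, 2.97e-3, 2.86e-3, 3.44e-5, 6.07e-5, 1.01e-3],
        [0.41, 0.28, 0.29, 0.20, 0.51, 0.14, 0.49, 0.18, 0.44, 0.64, 0.30],
        [0.08, 0.07, 0.05, 0.09, 0.17, 0.04, 0.16, 0.06, 0.10, 0.16, 0.09],
        [0.12, 0.08, 0.13, 0.02, 0.04, 0.05, 0.04, 0.05, 0.09, 0.08, 0.06],
    ),
}

SEED_GENE = "PIP4K2A"


def ball_probe_map() -> ProbeMap:
    """Probe -> gene map of the reference candidates (all transcription factors)."""
    return ProbeMap(
        entries={probe: gene for probe, gene in BALL_PROBES},
        tf_flag={probe: True for probe, _ in BALL_PROBES},
    )


def ball_candidate_tables() -> list[AssociationTable]:
    """The reference statistics as one association table per cohort."""
    tables = []
    for cohort, (pvals, coefs, ses, adjs) in _TABLE.items():
        n = BALL_COHORT_SIZES[cohort]
        table = AssociationTable(seed_id=SEED_GENE, cohorts=[cohort])
        for (probe, _), p, b, se, adj in zip(BALL_PROBES, pvals, coefs, ses, adjs):
            r2 = 1.0 - (1.0 - adj) * (n - 2) / (n - 1)
            table.results[(probe, cohort)] = AssociationResult(
                feature_id=probe,
                cohort_id=cohort,
                n=n,
                coefficient=b,
                se=se,
                t=b / se,
                p_value=p,
                r2=r2,
                adjusted_r2=adj,
                direction=int(math.copysign(1, b)),
            )
        tables.append(table)
    return tables
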