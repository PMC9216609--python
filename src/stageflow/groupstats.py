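"""Nonparametric group comparison and intercoder reliability.

The per-stage stationary-distribution entries of the two groups are
compared with the Mann-Whitney U test (rank-sum form, midranks for ties,
tie-corrected normal approximation, no continuity correction).  Intercoder
agreement on stage codes is summarised by Cohen's kappa.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .markov import StationaryTable
from .protocol import STAGE_LABELS

__all__ = [
    "RankTestResult",
    "KappaResult",
    "mann_whitney_u",
    "compare_stationary_distributions",
    "cohens_kappa",
    "stationary_summary_report",
    "REPORT_STAGE_ORDER",
]

#: Display row order of the stage reports (differs from matrix order).
REPORT_STAGE_ORDER = (
    "Preparation",
    "Block",
    "Ideation",
    "Evaluation",
    "Refinement",
    "Production",
    "Other",
    "Illumination",
)


#: Pooled-size bound below which the two-sided p is computed by exact
#: enumeration of rank-sum assignments instead of the normal approximation.
EXACT_P_MAX_POOLED = 12


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U result for two independent samples.

    ``U`` is the statistic of the first sample (``U + U' = n1 * n2``);
    ``z`` is the tie-corrected standardised statistic with the sign of
    (rank sum of the first sample minus its null expectation).  ``p`` is
    two-sided: exact (enumeration of all rank assignments, ties included)
    for pooled samples of at most ``EXACT_P_MAX_POOLED`` values, else
    from the tie-corrected normal approximation without continuity
    correction.
    """

    U: float
    z: float
    p: float
    n1: int
    n2: int
    p_method: str = "normal_approximation"


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa between two coders of the same items."""

    kappa: float
    observed_agreement: float
    n_items: int
    degenerate: bool = False


def mann_whitney_u(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> RankTestResult:
    """Mann-Whitney U from rank sums with midranks for ties.

    ``z`` always carries the tie-corrected normal standardisation (no
    continuity correction).  The two-sided ``p`` is exact for small
    pooled samples — the proportion of the ``C(n, n1)`` rank assignments
    whose rank sum is at least as far from its null expectation as the
    observed one — and the normal tail otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValidationError("all pooled values identical: rank variance is zero")
    ranks = scipy.stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    n = n1 + n2
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        raise ValidationError("tie-corrected variance is zero")
    z = (u1 - mean_u) / np.sqrt(var_u)
    if n <= EXACT_P_MAX_POOLED:
        expectation = n1 * (n + 1) / 2.0
        observed_dev = abs(r1 - expectation)
        hits = total = 0
        for comb in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(comb)].sum() - expectation) >= observed_dev - 1e-12:
                hits += 1
        p = hits / total
        p_method = "exact_permutation"
    else:
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
        p_method = "normal_approximation"
    return RankTestResult(U=float(u1), z=float(z), p=min(p, 1.0), n1=n1, n2=n2,
                          p_method=p_method)


def compare_stationary_distributions(
    table_a: StationaryTable | pd.DataFrame, table_b: StationaryTable | pd.DataFrame
) -> pd.DataFrame:
    """Per-stage Mann-Whitney comparison of two groups' stationary tables.

    Returns a frame in report stage order with columns ``U, z, p,
    p_holm, testable``; a stage whose pooled values are all identical is
    flagged untestable (NaN statistics) rather than fabricated.  The
    Holm-adjusted column is an extension beyond the unadjusted per-stage
    tests and is clearly separate.
    """
    a = table_a.pi if isinstance(table_a, StationaryTable) else table_a
    b = table_b.pi if isinstance(table_b, StationaryTable) else table_b
    for t in (a, b):
        missing = [s for s in STAGE_LABELS if s not in t.columns]
        if missing:
            raise ValidationError(f"stationary table lacks stage column(s) {missing}")
    rows = []
    for stage in REPORT_STAGE_ORDER:
        try:
            res = mann_whitney_u(a[stage].to_numpy(), b[stage].to_numpy())
            rows.append(
                {"stage": stage, "U": res.U, "z": res.z, "p": res.p, "testable": True}
            )
        except ValidationError:
            rows.append(
                {"stage": stage, "U": np.nan, "z": np.nan, "p": np.nan,
                 "testable": False}
            )
    out = pd.DataFrame(rows).set_index("stage")
    # Holm step-down adjustment over the testable stages (extension column)
    testable = out.index[out["testable"]]
    pvals = out.loc[testable, "p"].to_numpy()
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * pvals[k])
        adj[k] = min(1.0, running)
    out["p_holm"] = np.nan
    out.loc[testable, "p_holm"] = adj
    return out


def cohens_kappa(
    labels_a: Sequence, labels_b: Sequence
) -> KappaResult:
    """Chance-corrected agreement between two coders.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement ``p_e``
    from each coder's marginal label frequencies.  If both coders are
    constant and identical (``p_e = 1``) kappa is reported as 1 with a
    degeneracy flag.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"label sequences must be equal-length 1-D, got {a.shape} vs {b.shape}"
        )
    n = len(a)
    if n < 1:
        raise ValidationError("label sequences are empty")
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        return KappaResult(kappa=1.0, observed_agreement=p_o, n_items=n,
                           degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), observed_agreement=p_o, n_items=n)


def stationary_summary_report(
    table_a: StationaryTable, table_b: StationaryTable
) -> pd.DataFrame:
    """Group mean (SD) of the stationary entries per stage, report order."""
    out = pd.DataFrame(index=list(REPORT_STAGE_ORDER))
    for t in (table_a, table_b):
        out[f"{t.group}_mean"] = t.mean.reindex(out.index)
        out[f"{t.group}_sd"] = t.sd.reindex(out.index)
    out.index.name = "stage"
    return out
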