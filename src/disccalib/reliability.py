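"""Interobserver reliability statistics.

Measurement studies that rely on human readers need two homogeneity checks
before their numbers are pooled: agreement on the *categorical* degeneration
grade (Cohen's kappa, computed for every observer pair) and consistency of
the *continuous* measurements (Cronbach's alpha across observers treated as
items).  Both statistics are computed here from complete observer-by-subject
tables.

Conventions: sample variances use the n-1 denominator throughout; kappa is
unweighted (grades treated nominally); multi-observer agreement is reported
as all pairwise kappas rather than a pooled statistic.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError

__all__ = [
    "cohen_kappa",
    "pairwise_kappa",
    "cronbach_alpha",
    "alpha_by_indicator",
]


def cohen_kappa(a: Sequence, b: Sequence) -> float:
    """Unweighted Cohen's kappa between two raters' categorical vectors.

    kappa = (p_o - p_e) / (1 - p_e) where p_o is the observed agreement rate
    and p_e the chance agreement from the marginal label frequencies.

    Raises
    ------
    UndefinedStatisticError
        If chance agreement p_e equals 1 (both raters constant with
        identical marginals), which leaves kappa undefined.
    ValueError
        If the vectors differ in length or have fewer than 2 entries.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 rated subjects")
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedStatisticError(
            "kappa undefined: chance agreement is 1 (both raters constant)"
        )
    return (p_o - p_e) / (1.0 - p_e)


def pairwise_kappa(ratings: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Cohen's kappa for every observer pair of a subjects-by-observers table.

    ``ratings`` has one row per subject and one column per observer, holding
    categorical grades; every cell must be filled.
    """
    if ratings.isna().any().any():
        raise ValueError("ratings table must be complete (no missing cells)")
    if ratings.shape[1] < 2:
        raise ValueError("need at least 2 observers")
    return {
        (str(u), str(v)): cohen_kappa(ratings[u].to_numpy(), ratings[v].to_numpy())
        for u, v in combinations(ratings.columns, 2)
    }


def cronbach_alpha(matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha for an observers-by-subjects measurement matrix.

    Observers play the role of items:

        alpha = k/(k-1) * (1 - sum of item variances / variance of item sums)

    with k observers and sample (n-1) variances taken across subjects.

    Raises
    ------
    UndefinedStatisticError
        If the variance of the summed scores is zero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurement matrix must be 2-D (observers x subjects)")
    k, n = m.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 observers and 2 subjects")
    if np.isnan(m).any():
        raise ValueError("measurement matrix must be complete (no missing cells)")
    item_var = m.var(axis=1, ddof=1).sum()
    total_var = m.sum(axis=0).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("alpha undefined: zero total-score variance")
    return k / (k - 1.0) * (1.0 - item_var / total_var)


def alpha_by_indicator(
    records: pd.DataFrame,
    indicators: Sequence[str] = ("d1_mm", "d2_mm", "disc_area_mm2", "nucleus_area_mm2"),
) -> dict[str, float]:
    """Cronbach's alpha per measured indicator from a long record table.

    ``records`` is the long measurement table (one row per subject-observer
    pair); each indicator column is pivoted to observers-by-subjects first.
    """
    out: dict[str, float] = {}
    for col in indicators:
        wide = records.pivot(index="observer_id", columns="subject_id", values=col)
        out[col] = cronbach_alpha(wide)
    return out
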