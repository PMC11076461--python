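"""Two-group comparison of subject-level network features.

Welch (unequal-variance) t-tests with Welch–Satterthwaite degrees of
freedom, Cohen's d effect sizes with large-sample confidence intervals, and
Benjamini–Hochberg FDR control applied simultaneously over the whole family
of global measures x frequency bands (36 tests by default). Regional
betweenness comparisons are exploratory and reported uncorrected.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Columns of a feature table (one row per subject x band x measure).
FEATURE_COLUMNS = ("subject_id", "group", "band", "measure", "value")

#: Columns of a comparison table (one row per measure x band).
COMPARISON_COLUMNS = (
    "measure", "band", "t", "df", "direction", "p", "p_adj",
    "d", "d_ci_low", "d_ci_high",
)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t-test from group means, standard deviations and sizes."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both zero")
    t, p = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(p)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Cohen's d with pooled SD and a 95% large-sample confidence interval.

    Var(d) ≈ (n_a + n_b)/(n_a n_b) + d² / (2 (n_a + n_b)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    s_pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pooled == 0.0:
        raise ValueError("zero pooled variance")
    d = float((a.mean() - b.mean()) / s_pooled)
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
    z = sps.norm.ppf(0.975)
    return d, d - z * se, d + z * se


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_values(
    features: pd.DataFrame, group: str, band: str, measure: str
) -> np.ndarray:
    sel = features[
        (features["group"] == group)
        & (features["band"] == band)
        & (features["measure"] == measure)
    ]
    return sel["value"].to_numpy(dtype=float)


def compare_groups(
    features: pd.DataFrame,
    family: Iterable[tuple[str, str]],
    exploratory: Iterable[tuple[str, str]] = (),
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-(measure, band) Welch comparisons with BH-FDR over ``family``.

    ``features`` is a tidy table with FEATURE_COLUMNS. The BH adjustment is
    computed over exactly the (measure, band) pairs in ``family``;
    ``exploratory`` pairs get uncorrected p only (p_adj = NaN). ``direction``
    flags which group mean is larger, in ``group_order`` terms.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    groups = sorted(features["group"].unique()) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    ga, gb = groups
    family = list(family)
    exploratory = list(exploratory)

    rows = []
    for measure, band in family + exploratory:
        va = _group_values(features, ga, band, measure)
        vb = _group_values(features, gb, band, measure)
        if va.size < 2 or vb.size < 2:
            raise ValueError(
                f"missing data for measure={measure!r} band={band!r} "
                f"(n_{ga}={va.size}, n_{gb}={vb.size})"
            )
        # NaN-valued subjects (e.g. undefined assortativity) are dropped per cell
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        t, df, p = welch_t(va, vb)
        d, lo, hi = cohens_d(va, vb)
        if t > 0:
            direction = f"{ga} > {gb}"
        elif t < 0:
            direction = f"{ga} < {gb}"
        else:
            direction = "="
        rows.append({
            "measure": measure, "band": band, "t": t, "df": df,
            "direction": direction, "p": p, "p_adj": np.nan,
            "d": d, "d_ci_low": lo, "d_ci_high": hi,
        })
    out = pd.DataFrame(rows, columns=list(COMPARISON_COLUMNS))
    n_fam = len(family)
    if n_fam:
        out.loc[: n_fam - 1, "p_adj"] = bh_adjust(out.loc[: n_fam - 1, "p"].to_numpy())
    return out
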