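"""Post-hoc rank tests: Mann-Whitney U with Holm-Bonferroni correction.

Pairwise comparisons are organised in families per measure and period:

(i)   all pairs of eligible deprivation classes (always run);
(ii)  female vs male, when sex was retained in the best model;
(iii) class pairs within each sex, when the sex x class interaction was
      retained.

Holm's step-down correction is applied within each family.  Classes whose
sample size (on the non-missing response) falls below ``min_class_n`` are
excluded from every family, mirroring the usual exclusion of tiny classes.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["mann_whitney_u", "holm_adjust", "posthoc_pairwise"]

EXACT_MAX_PRODUCT = 400

POSTHOC_COLUMNS = [
    "family", "factor", "level_a", "level_b", "n_a", "n_b",
    "U", "p_raw", "p_holm", "significant",
]


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_a, U_b).

    The p-value is exact (full null enumeration) when there are no ties and
    n_a * n_b <= 400, otherwise the normal approximation with tie and
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and a.size * b.size <= EXACT_MAX_PRODUCT
    res = mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u = min(float(res.statistic), a.size * b.size - float(res.statistic))
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance degenerate case (all values tied)
        p = 1.0
    return u, p


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _eligible(levels: pd.Series, min_n: int) -> list[str]:
    counts = levels.value_counts()
    return sorted(counts.index[counts >= min_n])


def _family_rows(
    df: pd.DataFrame,
    response: str,
    factor: str,
    levels: list[str],
    family: str,
    subset_label: str = "",
) -> list[dict]:
    rows = []
    for la, lb in combinations(levels, 2):
        a = df.loc[df[factor] == la, response].to_numpy()
        b = df.loc[df[factor] == lb, response].to_numpy()
        u, p = mann_whitney_u(a, b)
        rows.append(
            {
                "family": family,
                "factor": f"{subset_label}{factor}",
                "level_a": la,
                "level_b": lb,
                "n_a": len(a),
                "n_b": len(b),
                "U": u,
                "p_raw": p,
            }
        )
    return rows


def posthoc_pairwise(
    table: pd.DataFrame,
    response: str,
    retained_terms: Sequence[str] = (),
    alpha: float = 0.05,
    min_class_n: int = 3,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons for one measure-period subset.

    ``table`` must carry ``deprivation_class``, ``sex`` and the response
    column; rows with a missing response are dropped (undefined disparity).
    ``retained_terms`` are the fixed terms kept by model selection and gate
    families (ii) and (iii).  Holm correction is applied within each family;
    ``significant`` flags p_holm <= alpha.
    """
    df = table.dropna(subset=[response])
    families: list[list[dict]] = []

    classes = _eligible(df["deprivation_class"], min_class_n)
    if len(classes) >= 2:
        families.append(
            _family_rows(df, response, "deprivation_class", classes, "class")
        )

    if "sex" in retained_terms:
        sexes = [s for s in ("female", "male") if (df["sex"] == s).any()]
        if len(sexes) == 2:
            families.append(_family_rows(df, response, "sex", sexes, "sex"))

    if "sex:deprivation_class" in retained_terms:
        rows: list[dict] = []
        for sex in ("female", "male"):
            sub = df[df["sex"] == sex]
            levels = _eligible(sub["deprivation_class"], min_class_n)
            if len(levels) >= 2:
                rows.extend(
                    _family_rows(
                        sub, response, "deprivation_class", levels,
                        "sex_by_class", subset_label=f"{sex}:",
                    )
                )
        if rows:
            families.append(rows)

    all_rows: list[dict] = []
    for fam in families:
        adj = holm_adjust([r["p_raw"] for r in fam])
        for r, ph in zip(fam, adj):
            r["p_holm"] = float(ph)
            r["significant"] = bool(ph <= alpha)
        all_rows.extend(fam)
    return pd.DataFrame(all_rows, columns=POSTHOC_COLUMNS)
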