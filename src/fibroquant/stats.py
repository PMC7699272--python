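"""Group comparisons and the three-family significance-symbol policy.

Longitudinal readouts are annotated with one of three glyph families:

* ``*``  — bleomycin vs. same-day saline control,
* ``#``  — between-day comparisons within the bleomycin group,
* ``§``  — any day vs. its own group's day-0 baseline,

with 1–4 repeats of the glyph at the p < 0.05 / 0.01 / 0.001 / 0.0001 tiers
and an empty string when p >= 0.05.  P values come from standard routines
(one-way ANOVA with Bonferroni-adjusted pairwise t-tests, or Mann–Whitney);
only the orchestration and the symbol policy are local.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FAMILIES",
    "assign_symbol",
    "bonferroni",
    "compare_groups",
    "type_one_error_rate",
]

FAMILIES = {
    "vs_control_same_day": "*",
    "between_days_bleomycin": "#",
    "vs_baseline_within_group": "§",
}

_TIERS = (0.05, 0.01, 0.001, 0.0001)


def assign_symbol(family: str, p: float) -> str:
    """Glyph string for a p value under the family's symbol convention."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {list(FAMILIES)}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value {p} outside [0, 1]")
    glyph = FAMILIES[family]
    n = sum(p < t for t in _TIERS)
    return glyph * n


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def _pairs(table: pd.DataFrame, family: str,
           treated: str, control: str) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(label, sample_a, sample_b) for every comparison the family implies."""
    out = []
    if family == "vs_control_same_day":
        for day in sorted(table["day"].unique()):
            sub = table[table["day"] == day]
            a = sub.loc[sub["group"] == treated, "value"].to_numpy()
            b = sub.loc[sub["group"] == control, "value"].to_numpy()
            out.append((f"day{day}:{treated}-vs-{control}", a, b))
    elif family == "between_days_bleomycin":
        sub = table[table["group"] == treated]
        for d1, d2 in itertools.combinations(sorted(sub["day"].unique()), 2):
            a = sub.loc[sub["day"] == d1, "value"].to_numpy()
            b = sub.loc[sub["day"] == d2, "value"].to_numpy()
            out.append((f"{treated}:day{d1}-vs-day{d2}", a, b))
    elif family == "vs_baseline_within_group":
        for group in sorted(table["group"].unique()):
            sub = table[table["group"] == group]
            base = sub.loc[sub["day"] == 0, "value"].to_numpy()
            for day in sorted(d for d in sub["day"].unique() if d != 0):
                a = sub.loc[sub["day"] == day, "value"].to_numpy()
                out.append((f"{group}:day{day}-vs-baseline", a, base))
    else:
        raise ValueError(f"unknown family {family!r}")
    return out


def compare_groups(
    table: pd.DataFrame,
    family: str,
    method: str = "anova_bonferroni",
    treated_group: str = "bleomycin",
    control_group: str = "control",
) -> pd.DataFrame:
    """All comparisons of a symbol family over a long-format table.

    ``table`` needs columns ``value``, ``group`` and ``day``.  With
    ``anova_bonferroni`` each comparison is a two-sample t-test whose p is
    Bonferroni-adjusted for the number of comparisons in the family (the
    post-hoc convention); with ``mann_whitney`` raw exact/asymptotic rank-sum
    p values are reported.  Every row carries the symbol assigned from the
    reported p.
    """
    for col in ("value", "group", "day"):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    if method not in ("anova_bonferroni", "mann_whitney"):
        raise ValueError(f"unknown method {method!r}")

    pairs = _pairs(table, family, treated_group, control_group)
    pairs = [(lbl, a, b) for lbl, a, b in pairs if len(a) and len(b)]
    if not pairs:
        raise ValueError("no comparisons possible for this family/table")
    for lbl, a, b in pairs:
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"comparison {lbl}: need n >= 2 per group")
    m = len(pairs)

    rows = []
    for lbl, a, b in pairs:
        if method == "anova_bonferroni":
            if np.ptp(np.concatenate([a, b])) == 0:
                p_raw = 1.0
            else:
                p_raw = float(sps.ttest_ind(a, b).pvalue)
                if np.isnan(p_raw):
                    p_raw = 1.0
            p = bonferroni(p_raw, m)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            p_raw = p = float(res.pvalue)
        rows.append(
            {
                "comparison": lbl,
                "family": family,
                "method": method,
                "n_a": len(a),
                "n_b": len(b),
                "p_raw": p_raw,
                "p": p,
                "m_comparisons": m,
                "symbol": assign_symbol(family, p),
            }
        )
    return pd.DataFrame(rows)


def type_one_error_rate(
    n_reps: int = 10_000,
    n_per_group: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical false-positive rate of the vs-control comparison under the null.

    Draws ``n_reps`` pairs of same-distribution normal samples and reports
    the fraction of two-sample t-tests with p < alpha (vectorised across
    repetitions).  Should sit near alpha up to Monte-Carlo error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 61]))
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    p = sps.ttest_ind(a, b, axis=1).pvalue
    return float(np.mean(p < alpha))
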