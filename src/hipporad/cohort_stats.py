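"""Group-comparison statistics for cohort demographics.

Continuous variables (age, education, MMSE) are compared by two-sample
t-tests computable either from raw data or from printed group
summaries (mean, SD, n); sex by a Pearson chi-square on the 2x2 table
without continuity correction.  The pooled-variance (Student) t is the
default for the demographics table — it reproduces the conventional
SPSS two-sample output — with Welch available for unequal variances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch unequal-variance t from group summaries.

    Returns (t, df, p) with Welch-Satterthwaite degrees of freedom.
    """
    _check(sd1, n1, sd2, n2)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def student_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance (Student) two-sample t from group summaries."""
    _check(sd1, n1, sd2, n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        return 0.0, float(df), 1.0
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _check(sd1, n1, sd2, n2):
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square for a 2x2 table, no continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all margins must be positive")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


CONTINUOUS_VARS = ["age", "education", "mmse"]


def demographics_table(manifest: pd.DataFrame,
                       label_column: str = "label",
                       variant: str = "student") -> pd.DataFrame:
    """Per-variable group comparison from a raw cohort manifest.

    One row per available variable: group means +/- SD (or sex
    counts), the test statistic and its p-value.  ``variant`` selects
    pooled ('student') or Welch t for the continuous rows.
    """
    groups = sorted(manifest[label_column].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    g1 = manifest[manifest[label_column] == groups[0]]
    g2 = manifest[manifest[label_column] == groups[1]]
    tfun = student_t_from_summary if variant == "student" else welch_t_from_summary
    rows = []
    for var in CONTINUOUS_VARS:
        if var not in manifest.columns:
            continue
        x, y = g1[var].dropna(), g2[var].dropna()
        t, df, p = tfun(x.mean(), x.std(ddof=1), len(x),
                        y.mean(), y.std(ddof=1), len(y))
        rows.append({
            "variable": var,
            groups[0]: f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
            groups[1]: f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
            "statistic": t, "p_value": p,
        })
    if "sex" in manifest.columns:
        def mf(g):
            return (int((g["sex"] == "M").sum()), int((g["sex"] == "F").sum()))
        (a, b), (c, d) = mf(g1), mf(g2)
        chi2, _, p = chi_square_2x2(a, b, c, d)
        rows.append({
            "variable": "sex",
            groups[0]: f"{a}:{b}", groups[1]: f"{c}:{d}",
            "statistic": chi2, "p_value": p,
        })
    return pd.DataFrame(rows)


def demographics_from_summaries(summaries: pd.DataFrame,
                                variant: str = "student") -> pd.DataFrame:
    """Group comparison from printed summary rows.

    ``summaries`` needs columns variable, mean1, sd1, n1, mean2, sd2,
    n2 (continuous) and may include a sex row given as counts a,b,c,d.
    """
    tfun = student_t_from_summary if variant == "student" else welch_t_from_summary
    rows = []
    for _, r in summaries.iterrows():
        if r["variable"] == "sex":
            chi2, _, p = chi_square_2x2(int(r["a"]), int(r["b"]),
                                        int(r["c"]), int(r["d"]))
            rows.append({"variable": "sex", "statistic": chi2, "p_value": p})
        else:
            t, df, p = tfun(r["mean1"], r["sd1"], int(r["n1"]),
                            r["mean2"], r["sd2"], int(r["n2"]))
            rows.append({"variable": r["variable"], "statistic": t,
                         "p_value": p})
    return pd.DataFrame(rows)
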