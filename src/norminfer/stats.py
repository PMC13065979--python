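"""Frequentist layer: repeated-measures ANOVA and corrected t tests.

This mirrors the descriptive statistics of the experiments: a one-way
repeated-measures ANOVA over conditions with Greenhouse–Geisser correction
(applied when Mauchly's test rejects sphericity at p < 0.05) and partial
eta-squared, Bonferroni-corrected paired t tests between adjacent conditions,
and one-sample t tests against reference points (0.5 for probabilities, 0
for KL divergences).  The ANOVA decomposition, epsilon and Mauchly test are
delegated to pingouin; the effect sizes and the Bonferroni rule (multiply the
raw p by the number of comparisons, cap at 1.00) are computed here.

Paired Cohen's d uses the average of the two condition standard deviations as
denominator, not the standard deviation of the difference scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "rm_anova",
    "paired_posthoc",
    "one_sample_t",
    "partial_eta_sq_from_f",
    "to_wide",
]


@dataclass(frozen=True)
class AnovaResult:
    f_value: float
    df_effect: float
    df_error: float
    p_value: float
    p_uncorrected: float
    partial_eta_sq: float
    gg_epsilon: float
    sphericity_violated: bool
    mauchly_w: float
    mauchly_p: float


@dataclass(frozen=True)
class TTestResult:
    comparison: str
    t_value: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohen_d: float


def bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


def partial_eta_sq_from_f(f_value: float, df_effect: float, df_error: float) -> float:
    """Partial eta-squared implied by an F statistic and its (possibly
    sphericity-corrected, fractional) degrees of freedom."""
    return f_value * df_effect / (f_value * df_effect + df_error)


def to_wide(agg: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Participants × conditions table of one measure from the aggregated frame."""
    sub = agg[agg["measure"] == measure]
    if sub.empty:
        raise KeyError(f"measure {measure!r} not present")
    return sub.pivot(index="participant", columns="condition", values="mean_value")


def rm_anova(wide: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participants × conditions table.

    Greenhouse–Geisser-corrected degrees of freedom and p value are reported
    whenever Mauchly's test rejects sphericity (p < 0.05); with two conditions
    sphericity holds trivially (epsilon = 1) and the ANOVA reduces to the
    paired t test (F = t^2).
    """
    import pingouin as pg

    wide = pd.DataFrame(wide)
    if wide.isna().any().any():
        raise ValueError("missing cells in the repeated-measures table")
    n, k = wide.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 3:
        raise ValueError("need at least 3 participants")

    long = wide.reset_index(names="participant").melt(
        id_vars="participant", var_name="condition", value_name="value"
    )
    res = pg.rm_anova(
        data=long,
        dv="value",
        within="condition",
        subject="participant",
        correction=True,
        detailed=True,
    )
    effect = res.iloc[0]
    error = res.iloc[1]
    f_value = float(effect["F"])
    eta_p2 = float(effect["SS"] / (effect["SS"] + error["SS"]))

    if k == 2:
        eps, violated, w, p_sph = 1.0, False, 1.0, 1.0
    else:
        eps = float(effect["eps"])
        sph = pg.sphericity(data=long, dv="value", within="condition", subject="participant")
        w, p_sph = float(sph.W), float(sph.pval)
        violated = p_sph < 0.05

    df1, df2 = float(effect["DF"]), float(error["DF"])
    p_unc = float(effect["p_unc"])
    if violated:
        df1, df2 = eps * df1, eps * df2
        p_corr = float(effect["p_GG_corr"])
    else:
        p_corr = p_unc
    return AnovaResult(
        f_value=f_value,
        df_effect=df1,
        df_error=df2,
        p_value=p_corr,
        p_uncorrected=p_unc,
        partial_eta_sq=eta_p2,
        gg_epsilon=eps,
        sphericity_violated=violated,
        mauchly_w=w,
        mauchly_p=p_sph,
    )


def paired_posthoc(
    wide: pd.DataFrame, comparisons: list[tuple] | None = None
) -> list[TTestResult]:
    """Bonferroni-corrected paired t tests, by default between adjacent conditions.

    Cohen's d divides the mean difference by the average of the two condition
    standard deviations.  A constant difference score (zero variance) is an
    error rather than an infinite t.
    """
    wide = pd.DataFrame(wide)
    cols = list(wide.columns)
    if comparisons is None:
        comparisons = list(zip(cols[:-1], cols[1:]))
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        da, db = wide[a].to_numpy(float), wide[b].to_numpy(float)
        diff = da - db
        if np.allclose(diff, 0.0, atol=1e-12):
            t, p, d = 0.0, 1.0, 0.0
        elif np.std(diff, ddof=1) <= 1e-12 * max(1.0, float(np.abs(diff).max())):
            # a constant non-zero shift: t would be infinite
            raise ZeroDivisionError(
                f"difference scores for {a!r} vs {b!r} have zero variance"
            )
        else:
            t, p = sps.ttest_rel(da, db)
            d = float(np.mean(diff) / ((np.std(da, ddof=1) + np.std(db, ddof=1)) / 2.0))
        out.append(
            TTestResult(
                comparison=f"{a} vs {b}",
                t_value=float(t),
                df=len(diff) - 1,
                p_raw=float(p),
                p_bonferroni=bonferroni(float(p), m),
                cohen_d=d,
            )
        )
    return out


def one_sample_t(values, mu: float = 0.5, m: int = 1, label: str = "") -> TTestResult:
    """One-sample t test against ``mu`` with Bonferroni correction over ``m``.

    Cohen's d is ``(mean - mu) / sd``, which equals ``t / sqrt(n)`` exactly.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ZeroDivisionError("values have zero variance")
    t, p = sps.ttest_1samp(v, mu)
    return TTestResult(
        comparison=label or f"vs {mu}",
        t_value=float(t),
        df=len(v) - 1,
        p_raw=float(p),
        p_bonferroni=bonferroni(float(p), m),
        cohen_d=float((v.mean() - mu) / sd),
    )
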