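"""Group-level statistical battery for the two-group MRE design.

The design is age group (young / older) crossed with sex (F / M),
n = 12 per age group by default.  Implemented:

* two-way ANOVA per univariate outcome (Type III sums of squares with sum
  contrasts; identical to the classical decomposition in the balanced case),
* two-way MANOVA with Pillai's trace over the six subcortical ROIs,
* ANCOVA with structure volume as covariate and age and sex as factors,
* noncentral-F power for the ANOVA age effect,
* exclusion accounting with the study's gate rules (OSS-SNR, cognitive
  screen applied to the older group, radiological flag).

Linear-model fitting is delegated to statsmodels; this module owns the
protocol, the df conventions and the reporting shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.multivariate.manova import MANOVA

from .containers import StatResult

_MODEL = "C({age}, Sum) * C({sex}, Sum)"


def _check_design(df: pd.DataFrame, age: str, sex: str):
    counts = df.groupby([age, sex]).size()
    if len(counts) < 4 or (counts < 1).any():
        raise ValueError("design has empty age-by-sex cells")


def two_way_anova(
    df: pd.DataFrame, value: str = "value", age: str = "group",
    sex: str = "sex",
) -> dict[str, StatResult]:
    """Age x sex ANOVA; returns StatResults keyed 'age', 'sex', 'age:sex'.

    Uses Type III sums of squares with sum-to-zero contrasts, the
    convention under which main effects are interpretable alongside the
    interaction; with balanced cells it equals the classical decomposition.
    """
    _check_design(df, age, sex)
    model = ols(f"{value} ~ " + _MODEL.format(age=age, sex=sex), data=df).fit()
    if model.ssr <= 1e-12 * max(model.centered_tss, 1e-300):
        raise ValueError("zero within-cell variance: F undefined")
    table = sm.stats.anova_lm(model, typ=3)
    keys = {
        f"C({age}, Sum)": "age",
        f"C({sex}, Sum)": "sex",
        f"C({age}, Sum):C({sex}, Sum)": "age:sex",
    }
    df_den = int(table.loc["Residual", "df"])
    out = {}
    for row, name in keys.items():
        out[name] = StatResult(
            effect=name, F=float(table.loc[row, "F"]),
            df_num=int(table.loc[row, "df"]), df_den=df_den,
            p=float(table.loc[row, "PR(>F)"]),
        )
    return out


def one_way_anova(values, groups) -> StatResult:
    """Single-factor ANOVA; for two balanced groups F equals the squared
    pooled two-sample t statistic."""
    df = pd.DataFrame(dict(value=np.asarray(values, float),
                           g=np.asarray(groups)))
    if df.g.nunique() < 2:
        raise ValueError("need at least two groups")
    model = ols("value ~ C(g)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    return StatResult(
        effect="group", F=float(table.loc["C(g)", "F"]),
        df_num=int(table.loc["C(g)", "df"]),
        df_den=int(table.loc["Residual", "df"]),
        p=float(table.loc["C(g)", "PR(>F)"]),
    )


def ancova_volume(
    df: pd.DataFrame, value: str = "value", age: str = "group",
    sex: str = "sex", volume: str = "vol_cm3",
) -> dict[str, StatResult]:
    """Volume-covaried ANCOVA: age and sex fixed factors plus the covariate.

    With the interaction retained the model has 5 parameters, so the age
    effect is reported on (1, N - 5) df.  A covariate perfectly confounded
    with the age factor is rejected with a diagnostic.
    """
    _check_design(df, age, sex)
    groups = df[age].astype("category").cat.codes
    v = df[volume].to_numpy(dtype=float)
    within = np.concatenate([v[groups == g] - v[groups == g].mean()
                             for g in np.unique(groups)])
    if np.allclose(within, 0.0):
        raise ValueError(
            "volume covariate is constant within age groups: "
            "perfectly collinear with the age factor")
    formula = f"{value} ~ " + _MODEL.format(age=age, sex=sex) + f" + {volume}"
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    df_den = int(table.loc["Residual", "df"])
    keys = {
        f"C({age}, Sum)": "age",
        f"C({sex}, Sum)": "sex",
        f"C({age}, Sum):C({sex}, Sum)": "age:sex",
        volume: "volume",
    }
    return {
        name: StatResult(
            effect=name, F=float(table.loc[row, "F"]),
            df_num=int(table.loc[row, "df"]), df_den=df_den,
            p=float(table.loc[row, "PR(>F)"]))
        for row, name in keys.items()
    }


def manova_pillai(
    df: pd.DataFrame, outcomes: list[str], age: str = "group",
    sex: str = "sex",
) -> dict[str, StatResult]:
    """Two-way MANOVA, Pillai's trace, over the given outcome columns.

    For the default six-ROI outcome set with two two-level factors and
    N = 24, each effect is reported as F(6, 15) — tr[H (H + E)^-1]
    transformed through the standard Pillai F approximation.
    """
    _check_design(df, age, sex)
    if len(outcomes) == 1:
        # univariate reduction: V = SSH/(SSH + SSE) and the Pillai F
        # approximation collapses to the ANOVA F on the same df
        uni = two_way_anova(df, value=outcomes[0], age=age, sex=sex)
        out = {}
        for name, r in uni.items():
            v = r.F * r.df_num / (r.F * r.df_num + r.df_den)
            out[name] = StatResult(effect=name, F=r.F, df_num=r.df_num,
                                   df_den=r.df_den, p=r.p, pillai=v)
        return out
    lhs = " + ".join(outcomes)
    mv = MANOVA.from_formula(
        f"{lhs} ~ " + _MODEL.format(age=age, sex=sex), data=df)
    try:
        results = mv.mv_test()
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular error cross-product matrix: {err}") from err
    keys = {
        f"C({age}, Sum)": "age",
        f"C({sex}, Sum)": "sex",
        f"C({age}, Sum):C({sex}, Sum)": "age:sex",
    }
    out = {}
    for row, name in keys.items():
        tab = results.results[row]["stat"]
        pill = tab.loc["Pillai's trace"]
        out[name] = StatResult(
            effect=name, F=float(pill["F Value"]),
            df_num=int(round(pill["Num DF"])),
            df_den=int(round(pill["Den DF"])),
            p=float(pill["Pr > F"]), pillai=float(pill["Value"]),
        )
    return out


@dataclass(frozen=True)
class PowerSpec:
    """Noncentral-F power specification for the ANOVA age effect.

    Defaults follow the study design: Cohen's f = 0.40 ("large"), total
    N = 24, effect on (1, 20) df, alpha = 0.05, noncentrality
    lambda = f^2 N.
    """

    effect_size_f: float = 0.40
    total_n: int = 24
    df_num: int = 1
    df_den: int = 20
    alpha: float = 0.05

    def __post_init__(self):
        if self.effect_size_f < 0:
            raise ValueError("effect size must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.total_n <= self.df_den:
            raise ValueError("total N must exceed the denominator df")


def anova_power(spec: PowerSpec) -> float:
    """P(F' > F_crit) under the noncentral F with lambda = f^2 N.

    At f = 0 this is exactly alpha (central case).
    """
    fcrit = sps.f.ppf(1.0 - spec.alpha, spec.df_num, spec.df_den)
    lam = spec.effect_size_f**2 * spec.total_n
    if lam == 0:
        return float(spec.alpha)
    return float(sps.ncf.sf(fcrit, spec.df_num, spec.df_den, lam))


def apply_exclusions(
    roster: pd.DataFrame,
    oss_snr_threshold: float = 3.0,
    cognitive_threshold: float = 26.0,
    cognitive_group: str = "older",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a recruitment roster by the study gates.

    Expected columns: subject, group, oss_snr, cognitive_score,
    wm_abnormality (bool).  A subject failing several gates is counted
    once, under the first failing reason in the order OSS-SNR, cognitive
    screen, radiological flag.  The cognitive screen applies only to
    ``cognitive_group`` (set to None to screen everyone).
    """
    required = {"subject", "group", "oss_snr", "cognitive_score",
                "wm_abnormality"}
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"roster missing columns: {sorted(missing)}")
    low_oss = roster.oss_snr < oss_snr_threshold
    cog_applies = (roster.group == cognitive_group) if cognitive_group \
        else pd.Series(True, index=roster.index)
    low_cog = cog_applies & (roster.cognitive_score < cognitive_threshold)
    flagged = roster.wm_abnormality.astype(bool)
    reason = np.select(
        [low_oss, ~low_oss & low_cog, ~low_oss & ~low_cog & flagged],
        ["oss_snr", "cognitive", "wm_abnormality"], default="")
    kept = roster[reason == ""].reset_index(drop=True)
    counts = {
        "oss_snr": int((reason == "oss_snr").sum()),
        "cognitive": int((reason == "cognitive").sum()),
        "wm_abnormality": int((reason == "wm_abnormality").sum()),
        "kept": len(kept),
    }
    return kept, counts


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p-values (reported alongside, never in place
    of, the unadjusted post-hoc values)."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, (m - i) * p)
        adj[k] = min(1.0, running)
    return {k: adj[k] for k in pvalues}
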