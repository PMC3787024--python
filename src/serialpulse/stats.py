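"""Ancestor-vs-evolved contrasts, family-wise error control, clonal
variation, and trait correlations.

Populations (microcosms) are summarized by the mean and the sample SD of
their clones; the SD across clones is the estimate of clonal variation.
Ancestor-vs-evolved contrasts use a two-tailed Welch-type t statistic with
Satterthwaite degrees of freedom, in two modes: a summary mode comparing
the ancestral clone mean to an evolved group mean +- SE (the shape of the
original mean-vs-estimated-marginal-mean comparison, consistent with the
fractional dfs it reports), and a plain two-sample mode on clone lists.
Families of k contrasts are Bonferroni-controlled at alpha/k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "GROUP_KEYS",
    "DEFAULT_TRAITS",
    "ComparisonResult",
    "BonferroniResult",
    "CorrelationResult",
    "summarize_populations",
    "ancestor_vs_evolved",
    "welch_from_summary",
    "bonferroni",
    "trait_correlation",
    "variation_trend",
    "fit_repeated_model",
    "RepeatedModelReport",
]

GROUP_KEYS = ["species", "pulse", "diversity", "week", "replicate"]
DEFAULT_TRAITS = ["max_growth_rate", "yield_od", "proportional_mortality", "biofilm"]


@dataclass
class ComparisonResult:
    """One two-tailed contrast with its multiplicity-adjusted decision."""

    label: str
    t: float
    df: float
    p: float
    alpha_adjusted: float
    significant: bool
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p must be in [0, 1], got {self.p}")


def summarize_populations(
    traits_table: pd.DataFrame,
    traits: Sequence[str] = DEFAULT_TRAITS,
    group_keys: Sequence[str] = GROUP_KEYS,
) -> pd.DataFrame:
    """Per-population clone mean, sample SD (n-1 denominator) and n.

    Output columns: the group keys, ``n_clones``, then ``mean_<trait>`` and
    ``sd_<trait>``.  Groups with a single clone get SD = NaN (flagged by
    absence, not by error).
    """
    missing = [k for k in list(group_keys) + list(traits) if k not in traits_table]
    if missing:
        raise ValidationError(f"traits table lacks columns {missing}")
    grouped = traits_table.groupby(list(group_keys), dropna=False, sort=True)
    out = grouped.size().rename("n_clones").reset_index()
    for trait in traits:
        agg = grouped[trait].agg(["mean", "std"]).reset_index(drop=True)
        out[f"mean_{trait}"] = agg["mean"]
        out[f"sd_{trait}"] = agg["std"]
    return out


def welch_from_summary(
    mean_a: float,
    se_a: float,
    n_a: float,
    mean_b: float,
    se_b: float,
    n_b: float,
    label: str = "",
    alpha_adjusted: float = 0.05,
) -> ComparisonResult:
    """Welch-type t on two summarized groups with Satterthwaite df.

    t = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2);
    df = (se_a^2 + se_b^2)^2 / (se_a^4/(n_a-1) + se_b^4/(n_b-1)).
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError(f"need n >= 2 per group, got {n_a}, {n_b}")
    va, vb = se_a**2, se_b**2
    pooled = va + vb
    if pooled == 0.0:
        if mean_a == mean_b:
            return ComparisonResult(label, float("nan"), float("nan"), float("nan"),
                                    alpha_adjusted, False, mean_a, mean_b,
                                    note="degenerate: zero variance, equal means")
        return ComparisonResult(label, float(np.sign(mean_a - mean_b)) * float("inf"),
                                float("nan"), 0.0, alpha_adjusted, True, mean_a, mean_b,
                                note="degenerate: zero variance, unequal means")
    t = (mean_a - mean_b) / np.sqrt(pooled)
    df = pooled**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(label, float(t), float(df), p, alpha_adjusted,
                            bool(p < alpha_adjusted), float(mean_a), float(mean_b))


def ancestor_vs_evolved(
    ancestor_values: Sequence[float],
    evolved_mean: float | None = None,
    evolved_se: float | None = None,
    evolved_n_effective: float | None = None,
    evolved_values: Sequence[float] | None = None,
    alpha_adjusted: float = 0.05,
    label: str = "",
    pooled_variance: bool = False,
) -> ComparisonResult:
    """Two-tailed comparison of ancestral clones to an evolved group.

    Summary mode (``evolved_mean``/``evolved_se``/``evolved_n_effective``)
    compares the ancestor clone mean to a model-estimated group mean with
    its SE.  Two-sample mode (``evolved_values``) is a plain Welch test on
    the two clone lists; ``pooled_variance=True`` switches it to the
    classical equal-variance Student t for sensitivity analysis.
    """
    anc = np.asarray(ancestor_values, dtype=float)
    if anc.size < 2:
        raise ValidationError(f"need >= 2 ancestor clones, got {anc.size}")
    mean_a = float(anc.mean())
    sd_a = float(anc.std(ddof=1))
    se_a = sd_a / np.sqrt(anc.size)

    if evolved_values is not None:
        evo = np.asarray(evolved_values, dtype=float)
        if evo.size < 2:
            raise ValidationError(f"need >= 2 evolved clones, got {evo.size}")
        if pooled_variance:
            n1, n2 = anc.size, evo.size
            sp2 = ((n1 - 1) * anc.var(ddof=1) + (n2 - 1) * evo.var(ddof=1)) / (n1 + n2 - 2)
            if sp2 == 0.0:
                return welch_from_summary(mean_a, 0.0, n1, float(evo.mean()), 0.0, n2,
                                          label, alpha_adjusted)
            t = (mean_a - evo.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
            p = float(2.0 * sps.t.sf(abs(t), df))
            return ComparisonResult(label, float(t), float(df), p, alpha_adjusted,
                                    bool(p < alpha_adjusted), mean_a, float(evo.mean()),
                                    note="pooled-variance mode")
        se_e = float(evo.std(ddof=1)) / np.sqrt(evo.size)
        return welch_from_summary(mean_a, se_a, anc.size, float(evo.mean()), se_e,
                                  evo.size, label, alpha_adjusted)

    if evolved_mean is None or evolved_se is None or evolved_n_effective is None:
        raise ValidationError(
            "provide either evolved_values or (evolved_mean, evolved_se, "
            "evolved_n_effective)"
        )
    if evolved_se < 0:
        raise ValidationError(f"evolved_se must be >= 0, got {evolved_se}")
    return welch_from_summary(mean_a, se_a, anc.size, evolved_mean, evolved_se,
                              evolved_n_effective, label, alpha_adjusted)


class BonferroniResult(NamedTuple):
    alpha_adjusted: float
    fwe_uncorrected: float
    fwe_corrected: float


def bonferroni(alpha: float, k: int) -> BonferroniResult:
    """Bonferroni control of a family of k independent tests.

    Returns the per-test threshold alpha/k, the family-wise error without
    correction 1 - (1-alpha)^k, and with correction 1 - (1-alpha/k)^k.
    For alpha = 0.05 and k = 4: 0.0125, 18.55% and 4.91%.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    adjusted = alpha / k
    return BonferroniResult(
        alpha_adjusted=adjusted,
        fwe_uncorrected=1.0 - (1.0 - alpha) ** k,
        fwe_corrected=1.0 - (1.0 - adjusted) ** k,
    )


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    undefined: bool = False


def trait_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-tailed p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need >= 3 pairs, got {x.size}")
    if np.allclose(x.var(), 0.0) or np.allclose(y.var(), 0.0):
        return CorrelationResult(float("nan"), float("nan"), int(x.size), undefined=True)
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


@dataclass
class VariationTrend:
    """Change in clonal variation (population SDs) between two weeks."""

    comparison: ComparisonResult
    mean_sd_early: float
    se_sd_early: float
    mean_sd_late: float
    se_sd_late: float
    n_early: int
    n_late: int


def variation_trend(
    summaries: pd.DataFrame,
    trait: str,
    weeks: tuple[int, int] = (1, 13),
    alpha: float = 0.05,
) -> VariationTrend:
    """Compare population SDs of one trait between two sampling weeks.

    A two-sample Welch comparison of the per-population clonal SDs (late
    minus early), reporting mean +- SE of the SDs per week.
    """
    col = f"sd_{trait}"
    if col not in summaries:
        raise ValidationError(f"summaries lack the clonal-SD column for trait {trait!r}")
    early_wk, late_wk = weeks
    for wk in weeks:
        if not (summaries["week"] == wk).any():
            raise ValidationError(f"no populations sampled at week {wk}")
    early = summaries.loc[summaries["week"] == early_wk, col].dropna().to_numpy()
    late = summaries.loc[summaries["week"] == late_wk, col].dropna().to_numpy()
    if early.size < 2 or late.size < 2:
        raise ValidationError(
            f"need >= 2 populations per week, got {early.size} and {late.size}"
        )
    comp = ancestor_vs_evolved(
        late, evolved_values=early, alpha_adjusted=alpha,
        label=f"clonal SD of {trait}: week {late_wk} vs week {early_wk}",
    )
    return VariationTrend(
        comparison=comp,
        mean_sd_early=float(early.mean()),
        se_sd_early=float(early.std(ddof=1) / np.sqrt(early.size)),
        mean_sd_late=float(late.mean()),
        se_sd_late=float(late.std(ddof=1) / np.sqrt(late.size)),
        n_early=int(early.size),
        n_late=int(late.size),
    )


@dataclass
class RepeatedModelReport:
    """Mixed-model fit of treatment effects on a per-population response.

    An approximation of the original repeated-measures analysis: a linear
    mixed model with a random intercept per microcosm instead of a fully
    unstructured within-subject covariance.
    """

    table: pd.DataFrame          # term, estimate, se, t, df, p
    converged: bool
    n_obs: int
    dropped_microcosms: list
    formula: str
    note: str = (
        "random-intercept approximation of the repeated-measures model; "
        "p-values from t with residual df"
    )


def fit_repeated_model(
    summaries: pd.DataFrame,
    trait: str,
    response: str = "mean",
    formula: str | None = None,
) -> RepeatedModelReport:
    """Fit treatment effects on per-population summaries of one trait.

    ``response`` selects the per-population mean (``"mean"``) or the clonal
    SD (``"sd"``).  The model has week as the within-subject factor and
    pulse and diversity as between-subject factors, with a random intercept
    for each microcosm; microcosms missing either week are dropped
    (listwise) and reported.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    col = f"{response}_{trait}"
    if col not in summaries:
        raise ValidationError(f"summaries lack column {col!r}")
    data = summaries.loc[summaries["week"] != 0].copy()
    data["microcosm"] = (
        data["species"].astype(str) + "/" + data["pulse"].astype(str) + "/"
        + data["diversity"].astype(str) + "/" + data["replicate"].astype(str)
    )
    data = data.rename(columns={col: "response"}).dropna(subset=["response"])
    weeks = sorted(data["week"].unique())
    counts = data.groupby("microcosm")["week"].nunique()
    dropped = sorted(counts.index[counts < len(weeks)])
    data = data[~data["microcosm"].isin(dropped)]
    if data["microcosm"].nunique() < 3:
        raise ValidationError("fewer than 3 complete microcosms; cannot fit")

    if formula is None:
        formula = "response ~ C(week) * C(pulse) * C(diversity)"
    model = smf.mixedlm(formula, data=data, groups=data["microcosm"])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=True, method="powell")
            converged = bool(fit.converged)

    fe = fit.fe_params
    se = fit.bse_fe
    resid_df = max(int(len(data) - len(fe)), 1)
    tvals = fe / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), resid_df)
    table = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.to_numpy(),
            "se": se.to_numpy(),
            "t": tvals.to_numpy(),
            "df": resid_df,
            "p": pvals,
        }
    ).reset_index(drop=True)
    return RepeatedModelReport(
        table=table,
        converged=converged,
        n_obs=int(len(data)),
        dropped_microcosms=list(dropped),
        formula=formula,
    )
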