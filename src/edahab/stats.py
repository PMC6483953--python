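"""Group statistics: distribution screening, the 3-IQR winsorization
variant, effect sizes, one-way and mixed-design ANOVA, correlations,
Bonferroni correction, and the full cohort analysis report.

Sign convention: Cohen's d is (mean of group 2 − mean of group 1) divided
by the pooled SD, with group 1 the clinical group and group 2 the
comparison group, so a higher clinical-group mean yields a negative d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "VariableScreen",
    "GroupComparison",
    "shape_zscores",
    "screen_variable",
    "winsorize_outliers",
    "cohens_d_from_summary",
    "cohens_d",
    "oneway_anova",
    "rm_anova_blocks",
    "correlations",
    "bonferroni_alpha",
    "round_alpha",
    "AnalysisConfig",
    "analyze_cohort",
]


@dataclass(frozen=True)
class VariableScreen:
    """Normality screen for one variable: standardized shape statistics and
    the transform applied when the screen fails."""

    variable: str
    z_skewness: float
    z_kurtosis: float
    normal_flag: bool
    applied_transform: str = "none"  # none | log | sqrt


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison summary in descriptive-table layout."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    F_statistic: float
    p_value: float
    cohens_d: float


def _shape_standard_errors(n: int) -> tuple[float, float]:
    se_skew = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    se_kurt = 2.0 * se_skew * math.sqrt((n * n - 1) / ((n - 3.0) * (n + 5.0)))
    return se_skew, se_kurt


def shape_zscores(x) -> tuple[float, float]:
    """Standardized sample skewness and excess kurtosis.

    Each z is the bias-corrected shape statistic (G1, G2) divided by its
    exact small-sample standard error, the screening form common in applied
    statistics texts.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ParameterError("need n >= 4 for shape z-scores")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance: shape undefined")
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, fisher=True, bias=False)
    se_skew, se_kurt = _shape_standard_errors(n)
    return float(g1 / se_skew), float(g2 / se_kurt)


def screen_variable(
    x, name: str = "", z_cutoff: float = 1.96, allow_transforms: bool = True
) -> tuple[np.ndarray, VariableScreen]:
    """Screen a variable for normality and transform it if the screen fails.

    When |z_skew| or |z_kurt| exceeds ``z_cutoff``, a log transform (for
    strictly positive data) or a square-root transform (for non-negative
    data) is tried; the transform is kept only if it passes the re-screen or
    at least shrinks the worst |z|.  Returns the (possibly transformed)
    values and the screen record.
    """
    x = np.asarray(x, dtype=float)
    z_s, z_k = shape_zscores(x)
    ok = abs(z_s) <= z_cutoff and abs(z_k) <= z_cutoff
    if ok or not allow_transforms:
        return x, VariableScreen(name, z_s, z_k, ok, "none")
    candidates = []
    if np.all(x > 0):
        candidates.append(("log", np.log(x)))
    if np.all(x >= 0):
        candidates.append(("sqrt", np.sqrt(x)))
    best = ("none", x, max(abs(z_s), abs(z_k)), z_s, z_k)
    for label, tx in candidates:
        if np.ptp(tx) == 0:
            continue
        tz_s, tz_k = shape_zscores(tx)
        worst = max(abs(tz_s), abs(tz_k))
        if worst < best[2]:
            best = (label, tx, worst, tz_s, tz_k)
        if worst <= z_cutoff:
            break
    label, tx, _, tz_s, tz_k = best
    ok_after = abs(tz_s) <= z_cutoff and abs(tz_k) <= z_cutoff
    return tx, VariableScreen(name, tz_s, tz_k, ok_after, label)


def winsorize_outliers(
    x, unit: float, anchor: str = "q3"
) -> tuple[np.ndarray, list[int]]:
    """Replace 3-IQR outliers with the nearest non-outlier value ± one unit.

    Fences sit at Q1 − 3·IQR and, with the default ``anchor="q3"``, at
    Q3 + 3·IQR (``anchor="q1"`` puts the upper fence at Q1 + 3·IQR for a
    strictly literal reading of the rule this implements).  Quartiles use
    linear interpolation (type 7).  Each high outlier becomes
    max(non-outliers) + unit; each low outlier min(non-outliers) − unit.
    Returns the adjusted sample and the outlier indices.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ParameterError("need n >= 4 to winsorize")
    if unit <= 0:
        raise ParameterError("unit must be positive")
    if anchor not in ("q3", "q1"):
        raise ParameterError("anchor must be 'q3' or 'q1'")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    hi_anchor = q3 if anchor == "q3" else q1
    lower, upper = q1 - 3.0 * iqr, hi_anchor + 3.0 * iqr
    is_out = (x < lower) | (x > upper)
    if is_out.all():
        raise DegenerateInputError("every point is an outlier")
    keep = x[~is_out]
    adjusted = x.copy()
    adjusted[x > upper] = keep.max() + unit
    adjusted[x < lower] = keep.min() - unit
    return adjusted, list(np.flatnonzero(is_out))


def cohens_d_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Pooled-SD standardized mean difference d = (m2 − m1) / s_pooled."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ParameterError("SDs must be non-negative")
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise DegenerateInputError("zero pooled spread: d undefined")
    return (m2 - m1) / math.sqrt(pooled_var)


def cohens_d(x1, x2) -> float:
    """Cohen's d from raw samples (group 2 mean minus group 1 mean)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohens_d_from_summary(
        x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
    )


def oneway_anova(x1, x2) -> GroupComparison:
    """Two-group one-way ANOVA with descriptives and Cohen's d.

    With two groups F equals the squared pooled-variance t statistic.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ParameterError("need n >= 2 per group")
    if np.ptp(x1) == 0 and np.ptp(x2) == 0:
        raise DegenerateInputError("zero within-group variance in both groups")
    res = sps.f_oneway(x1, x2)
    return GroupComparison(
        mean1=float(x1.mean()),
        sd1=float(x1.std(ddof=1)),
        n1=int(x1.size),
        mean2=float(x2.mean()),
        sd2=float(x2.std(ddof=1)),
        n2=int(x2.size),
        F_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=cohens_d(x1, x2),
    )


def rm_anova_blocks(block_values, group_labels) -> dict[str, dict[str, float]]:
    """Mixed-design ANOVA: repeated blocks (within) × group (between).

    ``block_values`` is an (n_participants, n_blocks) array of per-block
    mean SCR magnitudes; ``group_labels`` the between-subject factor.
    Returns F, p and degrees of freedom for the between-group effect, the
    within-subject block effect, and their interaction.
    """
    vals = np.asarray(block_values, dtype=float)
    if vals.ndim != 2:
        raise ParameterError("block_values must be 2-D (participants × blocks)")
    if np.isnan(vals).any():
        raise ParameterError("missing block values")
    labels = np.asarray(group_labels)
    if labels.size != vals.shape[0]:
        raise ParameterError("one group label per participant required")
    n, k = vals.shape
    if np.ptp(vals) == 0:  # constant data: every sum of squares is zero
        df_groups = len(np.unique(labels)) - 1
        return {
            "group": {"F": 0.0, "p": 1.0, "df1": float(df_groups), "df2": float(n - df_groups - 1)},
            "block": {"F": 0.0, "p": 1.0, "df1": float(k - 1), "df2": float((n - df_groups - 1) * (k - 1))},
            "interaction": {"F": 0.0, "p": 1.0, "df1": float(df_groups * (k - 1)), "df2": float((n - df_groups - 1) * (k - 1))},
        }
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "group": np.repeat(labels, k),
            "block": np.tile(np.arange(1, k + 1), n),
            "value": vals.ravel(),
        }
    )
    aov = pg.mixed_anova(
        data=long, dv="value", within="block", subject="subject", between="group"
    ).set_index("Source")
    out = {}
    for key, source in (("group", "group"), ("block", "block"), ("interaction", "Interaction")):
        row = aov.loc[source]
        out[key] = {
            "F": float(row["F"]),
            "p": float(row["p_unc"]),
            "df1": float(row["DF1"]),
            "df2": float(row["DF2"]),
        }
    return out


def correlations(x, y, kind: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    if kind == "pearson":
        r, p = sps.pearsonr(x, y)
    elif kind == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ParameterError("kind must be 'pearson' or 'spearman'")
    return float(r), float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison significance level alpha / m."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must lie in (0, 1]")
    return alpha / m


def round_alpha(alpha: float, sig_figs: int = 2) -> float:
    """Report a corrected level at 2 significant figures, half-up
    (0.05/11 → 0.0045, 0.05/4 → 0.013)."""
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    exponent = math.floor(math.log10(alpha))
    quantum = Decimal(1).scaleb(exponent - sig_figs + 1)
    return float(Decimal(repr(alpha)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# full cohort analysis


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the end-to-end cohort analysis.

    ``ordinal_variables`` are rating scales that are screened but never
    transformed and compared non-parametrically (Spearman in the
    correlation panel).  ``winsorize_units`` gives each variable's
    measurement resolution for outlier replacement (default 1.0 for
    questionnaire sums, 0.1 for physiological/derived means).
    """

    z_cutoff: float = 1.96
    winsorize_units: dict[str, float] = field(default_factory=dict)
    default_unit: float = 1.0
    ordinal_variables: tuple[str, ...] = (
        "arousal_tone",
        "arousal_siren",
        "valence_tone",
        "valence_siren",
    )
    responder_rule: str = "both_absent"
    group_order: tuple[str, str] = ("ASD", "TD")


def _comparison_dict(comp: GroupComparison) -> dict[str, float]:
    return {
        "mean1": comp.mean1,
        "sd1": comp.sd1,
        "n1": comp.n1,
        "mean2": comp.mean2,
        "sd2": comp.sd2,
        "n2": comp.n2,
        "F": comp.F_statistic,
        "p": comp.p_value,
        "d": comp.cohens_d,
    }


def analyze_cohort(
    data: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict:
    """Run the full statistical stage on a scored per-participant table.

    ``data`` holds one row per participant with a ``group`` column, outcome
    scores (questionnaire, ratings), and — where the scoring pipeline ran —
    ``threshold_db``, ``habituation_tone``/``habituation_siren``,
    ``responder`` and block-mean columns ``block1_tone`` ... ``block3_tone``
    (likewise ``_siren``).

    The report dict contains screening records, descriptive comparisons
    with F/p/d per variable, the correlation panel, the block-slope
    mixed-design ANOVA per condition (responders only), Bonferroni levels,
    and a log of every screening/transform/outlier decision.
    """
    if config is None:
        config = AnalysisConfig()
    g1, g2 = config.group_order
    for g in (g1, g2):
        if (data["group"] == g).sum() == 0:
            raise ParameterError(f"empty group {g!r}")
    log: list[str] = []
    report: dict = {"screening": [], "comparisons": {}, "correlations": {},
                    "block_anova": {}, "bonferroni": {}, "decisions": log,
                    "bayes_factors": "not computed"}

    responders = data["responder"].astype(bool) if "responder" in data else pd.Series(True, index=data.index)
    comparison_vars = [
        c for c in (
            "aasp_auditory", "threshold_db",
            "habituation_tone", "habituation_siren",
            "arousal_tone", "arousal_siren", "valence_tone", "valence_siren",
            "baseline_scl_uS",
        ) if c in data.columns
    ]

    work = data.copy()
    for var in comparison_vars:
        subset = work if not var.startswith("habituation") else work[responders]
        x = subset[var].to_numpy(dtype=float)
        unit = config.winsorize_units.get(var, config.default_unit)
        adjusted, out_idx = winsorize_outliers(x, unit)
        if out_idx:
            log.append(f"{var}: replaced {len(out_idx)} outlier(s) beyond 3*IQR fences")
        ordinal = var in config.ordinal_variables
        transformed, screen = screen_variable(
            adjusted, name=var, z_cutoff=config.z_cutoff, allow_transforms=not ordinal
        )
        if ordinal and not screen.normal_flag:
            log.append(f"{var}: ordinal scale, no transform; non-parametric tests used")
        elif screen.applied_transform != "none":
            log.append(f"{var}: {screen.applied_transform} transform applied "
                       f"(|z| screen at {config.z_cutoff})")
        report["screening"].append(screen.__dict__.copy())

        mask1 = (subset["group"] == g1).to_numpy()
        mask2 = (subset["group"] == g2).to_numpy()
        comp = oneway_anova(transformed[mask1], transformed[mask2])
        # descriptives reported on the original (winsorized) scale
        raw = _comparison_dict(comp)
        raw["mean1"], raw["sd1"] = float(adjusted[mask1].mean()), float(adjusted[mask1].std(ddof=1))
        raw["mean2"], raw["sd2"] = float(adjusted[mask2].mean()), float(adjusted[mask2].std(ddof=1))
        report["comparisons"][var] = raw

    # correlation panel
    corr_panel = {}
    if {"habituation_tone", "aasp_auditory"} <= set(data.columns):
        sub = data[responders]
        corr_panel["habituation_tone~aasp"] = correlations(
            sub["habituation_tone"], sub["aasp_auditory"], "pearson"
        )
    if {"threshold_db", "aasp_auditory"} <= set(data.columns):
        corr_panel["threshold~aasp"] = correlations(
            data["threshold_db"], data["aasp_auditory"], "pearson"
        )
    for rating in config.ordinal_variables:
        if {rating, "aasp_auditory"} <= set(data.columns):
            corr_panel[f"{rating}~aasp"] = correlations(
                data[rating], data["aasp_auditory"], "spearman"
            )
    report["correlations"] = {k: {"r": v[0], "p": v[1]} for k, v in corr_panel.items()}

    # block-slope mixed ANOVA per condition, responders only
    for cond in ("tone", "siren"):
        cols = [f"block{i}_{cond}" for i in (1, 2, 3)]
        if set(cols) <= set(data.columns):
            sub = data[responders]
            report["block_anova"][cond] = rm_anova_blocks(
                sub[cols].to_numpy(), sub["group"].to_numpy()
            )

    report["bonferroni"] = {
        "descriptives": round_alpha(bonferroni_alpha(0.05, 5)),
        "ratings": round_alpha(bonferroni_alpha(0.05, 4)),
    }
    n_non = int((~responders).sum())
    report["non_responders"] = {
        "n": n_non,
        "percent_by_group": {
            g: round(
                100.0 * float((~responders & (data["group"] == g)).sum())
                / float((data["group"] == g).sum()),
                1,
            )
            for g in (g1, g2)
        },
    }
    return report
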