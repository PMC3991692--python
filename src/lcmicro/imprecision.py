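"""Repeat-scan imprecision statistics with a nested measurement error model.

Each eye is scanned twice with the same device and analysis method, so the
measurement model is

    value[subject, eye, replicate] = grand_mean + scan_occasion_effect
                                   + subject_effect + eye_within_subject_effect
                                   + replicate_error,

with random subject and eye-within-subject effects (some subjects contribute
both eyes, which are correlated) and method bias fixed at 1 — the same
algorithm analyses both scans, so there is no slope between replicates.

With exactly two replicates per eye the model factorizes exactly: the
per-eye replicate differences ``d_e = value2 - value1`` are free of the
subject and eye effects, so the REML estimate of the residual (imprecision)
variance is ``Var(d)/2`` with the usual n-1 denominator — the classic
``SD(paired differences)/sqrt(2)`` repeatability estimator.  The subject and
eye variance components are then estimated from the per-eye means with a
linear mixed model (REML; method-of-moments fallback on non-convergence).

Relative imprecision is ``100 * imprecision_sd / mean_value`` (percent),
where the mean is the grand mean over all scans of all eyes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "ImprecisionEstimate",
    "GroupComparison",
    "validate_repeated_table",
    "fit_measurement_error_model",
    "relative_imprecision",
    "imprecision_by_group",
    "compare_group_imprecision",
]

REQUIRED_COLUMNS = ("subject_id", "eye_id", "group", "replicate", "parameter", "value")

MIN_EYES = 3  # minimum eyes for a meaningful fit


@dataclass(frozen=True)
class ImprecisionEstimate:
    """Fitted imprecision of one parameter over a cohort of repeat-scanned eyes."""

    parameter: str
    mean_value: float
    imprecision_sd: float
    relative_imprecision: float  # percent
    subject_var: float
    eye_within_subject_var: float
    residual_var: float
    n_eyes: int
    n_subjects: int
    components_method: str = "reml"  # 'reml' or 'mom' (fallback)
    flags: tuple[str, ...] = ()
    #: per-eye replicate differences, kept for bootstrap comparisons
    eye_diffs: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class GroupComparison:
    """Bootstrap comparison of residual (imprecision) variance between groups."""

    variance_ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def validate_repeated_table(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Check the long-format table and return the rows for one parameter.

    Every (subject, eye) must have exactly replicates 1 and 2; violations
    are reported naming the offending eyes.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    sub = table[table["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    bad = []
    for (s, e), g in sub.groupby(["subject_id", "eye_id"], sort=True):
        if sorted(g["replicate"].tolist()) != [1, 2]:
            bad.append(f"{s}/{e}")
    if bad:
        raise ValueError(
            "each eye needs exactly replicates 1 and 2; offending eyes: "
            + ", ".join(bad)
        )
    return sub


def _eye_summaries(sub: pd.DataFrame) -> pd.DataFrame:
    wide = sub.pivot_table(
        index=["subject_id", "eye_id"], columns="replicate", values="value"
    )
    out = pd.DataFrame(
        {
            "mean": (wide[1] + wide[2]) / 2.0,
            "diff": wide[2] - wide[1],
        }
    ).reset_index()
    return out


def _components_from_means(
    eyes: pd.DataFrame, resid_var: float
) -> tuple[float, float, str, list[str]]:
    """Subject and eye-within-subject variances from the per-eye means.

    Var(eye mean) = subject_var + eye_var + resid_var/2.  When some subjects
    contribute both eyes a random-intercept mixed model (REML) separates the
    subject level; with one eye per subject the two levels are confounded
    and the whole between-eye excess is attributed to subjects.
    """
    flags: list[str] = []
    n_per_subject = eyes.groupby("subject_id")["eye_id"].count()
    if (n_per_subject < 2).all():
        total = float(eyes["mean"].var(ddof=1)) if len(eyes) > 1 else 0.0
        subject_var = max(0.0, total - resid_var / 2.0)
        flags.append("eye level not identifiable (one eye per subject)")
        return subject_var, 0.0, "confounded", flags

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula("mean ~ 1", groups="subject_id", data=eyes)
            fit = md.fit(reml=True)
        if not fit.converged:
            raise RuntimeError("MixedLM did not converge")
        subject_var = float(fit.cov_re.iloc[0, 0])
        between_eye_resid = float(fit.scale)
        method = "reml"
    except Exception as exc:  # pragma: no cover - exercised via fallback tests
        flags.append(f"REML failed ({exc}); method-of-moments fallback")
        grand = eyes["mean"].mean()
        grp = eyes.groupby("subject_id")["mean"]
        k = len(grp)
        n = len(eyes)
        ss_between = float(((grp.mean() - grand) ** 2 * grp.count()).sum())
        ss_within = float(((eyes["mean"] - grp.transform("mean")) ** 2).sum())
        ms_within = ss_within / max(1, n - k)
        ms_between = ss_between / max(1, k - 1)
        n0 = (n - (grp.count() ** 2).sum() / n) / max(1, k - 1)
        subject_var = max(0.0, (ms_between - ms_within) / max(n0, 1e-12))
        between_eye_resid = ms_within
        method = "mom"
    eye_var = max(0.0, between_eye_resid - resid_var / 2.0)
    return float(subject_var), float(eye_var), method, flags


def fit_measurement_error_model(
    table: pd.DataFrame, parameter: str
) -> ImprecisionEstimate:
    """Fit the nested measurement error model for one parameter.

    Requires at least three eyes with two replicates each.  The imprecision
    SD (residual) comes from the exact difference-stratum REML solution;
    subject/eye variance components from the per-eye means.
    """
    sub = validate_repeated_table(table, parameter)
    eyes = _eye_summaries(sub)
    n_eyes = len(eyes)
    n_subjects = eyes["subject_id"].nunique()
    if n_eyes < MIN_EYES:
        raise ValueError(f"need >= {MIN_EYES} eyes with 2 replicates, got {n_eyes}")

    diffs = eyes["diff"].to_numpy(dtype=float)
    resid_var = float(np.var(diffs, ddof=1)) / 2.0
    imprecision_sd = float(np.sqrt(resid_var))
    mean_value = float(sub["value"].mean())

    subject_var, eye_var, method, flags = _components_from_means(eyes, resid_var)

    rel = _relative(imprecision_sd, mean_value)
    return ImprecisionEstimate(
        parameter=parameter,
        mean_value=mean_value,
        imprecision_sd=imprecision_sd,
        relative_imprecision=rel,
        subject_var=subject_var,
        eye_within_subject_var=eye_var,
        residual_var=resid_var,
        n_eyes=n_eyes,
        n_subjects=n_subjects,
        components_method=method,
        flags=tuple(flags),
        eye_diffs=tuple(float(d) for d in diffs),
    )


def _relative(imprecision_sd: float, mean_value: float) -> float:
    if mean_value == 0:
        raise ValueError("relative imprecision undefined for zero mean")
    return 100.0 * imprecision_sd / abs(mean_value)


def relative_imprecision(est: ImprecisionEstimate) -> float:
    """Imprecision SD as a percentage of the measurement's average."""
    return _relative(est.imprecision_sd, est.mean_value)


def imprecision_by_group(
    table: pd.DataFrame, parameter: str | None = None
) -> dict[str, dict[str, ImprecisionEstimate]]:
    """Independent model fits within each diagnostic group.

    Returns ``{group: {parameter: estimate}}``.  Groups too small to fit are
    skipped with a warning rather than aborting the whole report.
    """
    out: dict[str, dict[str, ImprecisionEstimate]] = {}
    params = (
        [parameter] if parameter is not None else sorted(table["parameter"].unique())
    )
    for group, gtab in table.groupby("group", sort=True):
        out[str(group)] = {}
        for p in params:
            try:
                out[str(group)][p] = fit_measurement_error_model(gtab, p)
            except ValueError as exc:
                warnings.warn(f"group {group!r}, parameter {p!r} skipped: {exc}")
    return out


def compare_group_imprecision(
    est_a: ImprecisionEstimate,
    est_b: ImprecisionEstimate,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> GroupComparison:
    """Ratio of residual variances (A / B) with a bootstrap CI.

    Eyes (their replicate differences) are resampled with replacement within
    each group; the percentile interval of the resampled variance ratios is
    returned.  The point ratio uses the fitted variances.
    """
    if est_b.residual_var == 0:
        raise ValueError("denominator group has zero residual variance")
    da = np.asarray(est_a.eye_diffs, dtype=float)
    db = np.asarray(est_b.eye_diffs, dtype=float)
    if da.size < 2 or db.size < 2:
        raise ValueError("both groups need >= 2 eyes for a bootstrap comparison")
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        ra = rng.choice(da, size=da.size, replace=True)
        rb = rng.choice(db, size=db.size, replace=True)
        va = np.var(ra, ddof=1) / 2.0
        vb = np.var(rb, ddof=1) / 2.0
        ratios[b] = va / vb if vb > 0 else np.inf
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(ratios, [alpha, 1 - alpha])
    return GroupComparison(
        variance_ratio=est_a.residual_var / est_b.residual_var,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )
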