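"""Shared-control effect sizes with BCa bootstrap confidence intervals.

Every behavioural comparison in the assay uses a three-group design: one
test genotype and two genetic controls (driver and responder).  The effect
size is the unstandardised mean difference

    delta = mean(test) - (mean(control_1) + mean(control_2)) / 2

i.e. the test mean minus the *average of the two control means* (not the
pooled-observation mean).  Uncertainty comes from a nonparametric
bootstrap: each group is resampled independently with replacement (the
resampling unit is the fly), delta is recomputed per draw, and the 95%
confidence interval is taken by the bias-corrected and accelerated (BCa)
method.  Hedges' g (small-sample-corrected standardised difference,
test vs the two controls concatenated) and a two-sided Mann-Whitney
p-value are attached pro forma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_RESAMPLES = 3000


@dataclass
class EffectSize:
    delta: float
    ci_low: float
    ci_high: float
    bootstrap_draws: np.ndarray
    n_test: int
    n_control_1: int
    n_control_2: int
    hedges_g: float
    p_mannwhitney: float
    resamples: int
    seed: object = None
    ci_method: str = "bca"
    metric: str = ""


def control_reference(ctrl1: np.ndarray, ctrl2: np.ndarray) -> float:
    """Average of the two control-group means (size-unweighted)."""
    c1 = np.asarray(ctrl1, float)
    c2 = np.asarray(ctrl2, float)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("both control groups must be non-empty")
    return 0.5 * (float(np.mean(c1)) + float(np.mean(c2)))


def bca_interval(
    draws: np.ndarray,
    theta_hat: float,
    jackknife_thetas: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """BCa interval endpoints from a bootstrap distribution.

    Bias correction z0 comes from the fraction of draws below the point
    estimate; acceleration from the jackknife skewness of the leave-one-out
    estimates.  Degenerate cases (constant draws, draws all on one side of
    the point estimate, zero acceleration denominator) fall back to the
    percentile interval with a logged warning.
    """
    draws = np.asarray(draws, float)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        raise ValueError("no finite bootstrap draws")
    lo_pct, hi_pct = 100 * (alpha / 2), 100 * (1 - alpha / 2)
    frac_below = np.mean(draws < theta_hat)
    jk = np.asarray(jackknife_thetas, float)
    jk_dev = jk.mean() - jk
    denom = np.sum(jk_dev**2) ** 1.5
    if frac_below <= 0.0 or frac_below >= 1.0 or denom == 0.0 or np.ptp(draws) == 0.0:
        log.warning("degenerate BCa inputs; falling back to percentile interval")
        return (
            float(np.percentile(draws, lo_pct)),
            float(np.percentile(draws, hi_pct)),
            "percentile",
        )
    z0 = stats.norm.ppf(frac_below)
    a = np.sum(jk_dev**3) / (6.0 * denom)
    z_alpha = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha)))
    lo, hi = np.percentile(draws, 100 * adj)
    return float(lo), float(hi), "bca"


def hedges_g(test: np.ndarray, control: np.ndarray) -> float:
    """Standardised mean difference with the small-sample correction."""
    t = np.asarray(test, float)
    c = np.asarray(control, float)
    nt, nc = t.size, c.size
    df = nt + nc - 2
    if df <= 0:
        return np.nan
    s_pooled = np.sqrt(
        ((nt - 1) * np.var(t, ddof=1) + (nc - 1) * np.var(c, ddof=1)) / df
    )
    if s_pooled == 0:
        return np.nan
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float((t.mean() - c.mean()) / s_pooled * correction)


def _clean(values, name: str, metric: str) -> np.ndarray:
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(
            f"group {name!r} has {v.size} non-censored value(s) for metric "
            f"{metric or 'value'!r}; need >= 2"
        )
    return v


def mean_difference(
    test,
    ctrl1,
    ctrl2,
    resamples: int = DEFAULT_RESAMPLES,
    seed=None,
    alpha: float = 0.05,
    metric: str = "",
) -> EffectSize:
    """Shared-control mean difference with a BCa bootstrap 95% CI.

    Censored (non-finite) values are dropped per group before anything
    else; an effectively empty group raises with the metric and group
    named.  The control-reference convention is applied inside every
    bootstrap draw.
    """
    t = _clean(test, "test", metric)
    c1 = _clean(ctrl1, "control_1", metric)
    c2 = _clean(ctrl2, "control_2", metric)
    delta = float(t.mean()) - control_reference(c1, c2)

    rng = np.random.default_rng(seed)
    draws = np.empty(resamples)
    means = []
    for g in (t, c1, c2):
        idx = rng.integers(0, g.size, size=(resamples, g.size))
        means.append(g[idx].mean(axis=1))
    draws = means[0] - 0.5 * (means[1] + means[2])

    # jackknife: leave one observation out of whichever group it belongs to
    def loo_means(g: np.ndarray) -> np.ndarray:
        return (g.sum() - g) / (g.size - 1)

    jk = np.concatenate(
        [
            loo_means(t) - 0.5 * (c1.mean() + c2.mean()),
            t.mean() - 0.5 * (loo_means(c1) + c2.mean()),
            t.mean() - 0.5 * (c1.mean() + loo_means(c2)),
        ]
    )
    lo, hi, method = bca_interval(draws, delta, jk, alpha)

    pooled_controls = np.concatenate([c1, c2])
    if (t.size + pooled_controls.size) < 20:
        mw_method = "exact"
    else:
        mw_method = "asymptotic"
    try:
        p = float(
            stats.mannwhitneyu(
                t, pooled_controls, alternative="two-sided", method=mw_method
            ).pvalue
        )
    except ValueError:  # exact method refuses ties
        p = float(
            stats.mannwhitneyu(
                t, pooled_controls, alternative="two-sided", method="asymptotic"
            ).pvalue
        )

    return EffectSize(
        delta=delta,
        ci_low=lo,
        ci_high=hi,
        bootstrap_draws=draws,
        n_test=t.size,
        n_control_1=c1.size,
        n_control_2=c2.size,
        hedges_g=hedges_g(t, pooled_controls),
        p_mannwhitney=p,
        resamples=resamples,
        seed=seed,
        ci_method=method,
        metric=metric,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney power simulation
# ---------------------------------------------------------------------------


@dataclass
class PowerResult:
    power: float
    alpha: float
    effect_g: float
    n_test: int
    n_control: int
    reps: int
    seed: object
    test: str = "mannwhitney"


def mannwhitney_p_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p-values, normal approximation.

    ``x`` is (reps, n1), ``y`` is (reps, n2).  Uses the tie-corrected
    variance and a continuity correction, matching scipy's asymptotic
    method; rows containing ties are delegated to scipy (rare for
    continuous draws).
    """
    reps, n1 = x.shape
    n2 = y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var0 = n1 * n2 * (n + 1) / 12.0
    z = (np.abs(u1 - mu) - 0.5) / np.sqrt(var0)
    p = 2.0 * stats.norm.sf(z)
    tied_rows = np.flatnonzero((np.diff(np.sort(combined, axis=1), axis=1) == 0).any(axis=1))
    for i in tied_rows:
        p[i] = stats.mannwhitneyu(
            x[i], y[i], alternative="two-sided", method="asymptotic"
        ).pvalue
    return np.minimum(p, 1.0)


def power_simulation(
    n_test: int,
    n_control: int,
    effect_g: float = 0.6,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed=None,
    test: str = "mannwhitney",
) -> PowerResult:
    """Monte-Carlo power of the two-group comparison.

    Draws standard-normal groups with the test group shifted by
    ``effect_g`` SD and counts two-sided rejections at ``alpha``.  The
    Mann-Whitney variant matches the study's analysis test; a Welch t-test
    variant is available for comparison.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable power estimate")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n_test)) + effect_g
    y = rng.standard_normal((reps, n_control))
    if test == "mannwhitney":
        p = mannwhitney_p_matrix(x, y)
    elif test == "t":
        p = stats.ttest_ind(x, y, axis=1).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return PowerResult(
        power=float(np.mean(p < alpha)),
        alpha=alpha,
        effect_g=effect_g,
        n_test=n_test,
        n_control=n_control,
        reps=reps,
        seed=seed,
        test=test,
    )
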