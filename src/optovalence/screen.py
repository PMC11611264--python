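"""Cross-replicate and cross-line aggregation.

Four layers sit above the per-fly metrics:

* fixed-effects inverse-variance meta-analysis of replicate effect sizes,
  theta_w = sum(theta_i * w_i) / sum(w_i) with w_i = 1 / s_i^2;
* percent-of-control summaries for loss-of-function interventions,
  %dPI = 100 * intervention dPI / mean control dPI at the same intensity;
* screen-wide least-squares regressions of locomotor effect sizes (dLSR,
  dChI, dPEDL, dPELD) against the valence effect size (dPI), with BCa
  bootstrap CIs on R^2 obtained by resampling lines;
* co-zonal pairing of driver lines by shared major anatomical staining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import DEFAULT_RESAMPLES, EffectSize, bca_interval, mean_difference
from .metrics import summarize_group

log = logging.getLogger(__name__)

DELTA_METRICS = ("pi", "lsr", "chi", "pedl", "peld")


@dataclass
class MetaResult:
    theta_weighted: float
    se_weighted: float
    theta_i: np.ndarray
    s2_i: np.ndarray
    weights: np.ndarray

    @property
    def k(self) -> int:
        return len(self.theta_i)

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se_weighted
        return (self.theta_weighted - half, self.theta_weighted + half)


def fixed_effects_meta(replicates) -> MetaResult:
    """Inverse-variance fixed-effects pooling of (theta_i, s_i^2) pairs."""
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate")
    theta = np.array([r[0] for r in reps], float)
    s2 = np.array([r[1] for r in reps], float)
    if np.any(s2 <= 0) or not np.all(np.isfinite(s2)):
        raise ValueError("all replicate variances must be positive and finite")
    w = 1.0 / s2
    return MetaResult(
        theta_weighted=float(np.sum(theta * w) / np.sum(w)),
        se_weighted=float(np.sqrt(1.0 / np.sum(w))),
        theta_i=theta,
        s2_i=s2,
        weights=w,
    )


def replicate_variance(effect: EffectSize) -> float:
    """Pooled control+test variance of one replicate's effect size.

    Operationalised as the variance of the replicate's bootstrap delta
    distribution, which estimates var(test mean) + var(control reference)
    — the variance of a difference of independent means.
    """
    return float(np.var(effect.bootstrap_draws, ddof=1))


@dataclass
class PercentOfControl:
    percent: float
    intervention_delta: float
    control_mean_delta: float
    intensity: float
    defined: bool = True


def percent_of_control(
    intervention_delta: float,
    replicate_control_deltas,
    intensity: float,
) -> PercentOfControl:
    """Intervention dPI as a percentage of the mean control dPI.

    The control reference is the simple average of the replicate control
    deltas measured at the same light intensity; a zero control mean makes
    the percentage undefined (flagged, not raised).
    """
    controls = np.asarray(list(replicate_control_deltas), float)
    if controls.size == 0:
        raise ValueError("need at least one control replicate at this intensity")
    control_mean = float(controls.mean())
    if control_mean == 0.0:
        log.warning("control mean delta is 0 at %s uW/mm2; percent undefined", intensity)
        return PercentOfControl(np.nan, intervention_delta, control_mean, intensity, False)
    return PercentOfControl(
        percent=100.0 * intervention_delta / control_mean,
        intervention_delta=intervention_delta,
        control_mean_delta=control_mean,
        intensity=intensity,
    )


def summarize_percents(percents, weights=None) -> float:
    """Cross-intervention summary: unweighted mean of the defined percents.

    ``weights`` switches on precision weighting for sensitivity analyses;
    the headline summary is the simple mean.
    """
    vals = np.array([p.percent for p in percents if p.defined], float)
    if vals.size == 0:
        return np.nan
    if weights is None:
        return float(vals.mean())
    w = np.asarray(weights, float)[: vals.size]
    return float(np.sum(vals * w) / np.sum(w))


# ---------------------------------------------------------------------------
# Screen-wide delta metrics and effect-size regression
# ---------------------------------------------------------------------------


def line_effects_from_tables(
    tables: dict[str, pd.DataFrame],
    metrics=DELTA_METRICS,
    resamples: int = DEFAULT_RESAMPLES,
    seed=None,
    line: str = "",
) -> pd.DataFrame:
    """Delta metrics for one line from per-group tidy metric tables.

    ``tables`` maps 'test', 'driver-control', 'responder-control' to the
    output of :func:`optovalence.metrics.summarize_group` filtered to one
    epoch.  Metrics whose censoring empties a group are omitted with a
    logged notice; censoring otherwise just shrinks the group.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for metric in metrics:
        cols = {g: tables[g][metric].to_numpy(float) for g in tables}
        try:
            es = mean_difference(
                cols["test"],
                cols["driver-control"],
                cols["responder-control"],
                resamples=resamples,
                seed=rng.integers(0, 2**31 - 1),
                metric=metric,
            )
        except ValueError as err:
            log.warning("line %s: metric %s omitted (%s)", line or "?", metric, err)
            continue
        rows.append(
            {
                "line": line,
                "metric": metric,
                "delta": es.delta,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "hedges_g": es.hedges_g,
                "p_mannwhitney": es.p_mannwhitney,
                "n_test": es.n_test,
                "n_control": es.n_control_1 + es.n_control_2,
                "bootstrap_var": replicate_variance(es),
            }
        )
    return pd.DataFrame(rows)


def line_delta_metrics(
    records_by_line: dict[str, dict],
    intensities=(22.0, 70.0),
    metrics=DELTA_METRICS,
    resamples: int = DEFAULT_RESAMPLES,
    seed=None,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Per-line delta metrics at the requested light intensities.

    ``records_by_line`` maps line name -> {'test', 'driver-control',
    'responder-control'} ExperimentRecords.  Epochs are matched by
    intensity; each delta goes through the shared-control bootstrap
    machinery, and per-fly censoring propagates into the group vectors.
    """
    rng = np.random.default_rng(seed)
    out = []
    for line, groups in records_by_line.items():
        schedule = groups["test"].schedule
        epochs = [ep for ep in schedule if not ep.is_dark and ep.intensity in intensities]
        tables = {
            g: summarize_group(rec, epochs=epochs, window_s=window_s)
            for g, rec in groups.items()
        }
        for ep in epochs:
            per_epoch = {
                g: df[df["intensity_uW_mm2"] == ep.intensity] for g, df in tables.items()
            }
            eff = line_effects_from_tables(
                per_epoch,
                metrics=metrics,
                resamples=resamples,
                seed=rng.integers(0, 2**31 - 1),
                line=line,
            )
            if len(eff):
                eff["intensity_uW_mm2"] = ep.intensity
                out.append(eff)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    r_squared_adj: float
    r2_ci_low: float
    r2_ci_high: float
    p_value: float
    n: int


def regress_effects(
    x,
    y,
    resamples: int = DEFAULT_RESAMPLES,
    seed=None,
    alpha: float = 0.05,
) -> RegressionResult:
    """Least-squares regression of y on x with a BCa bootstrap CI on R^2.

    Observations (lines) are resampled in pairs with replacement; draws in
    which the resampled x collapses to zero variance are discarded.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points to regress")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    def r2_of(xi: np.ndarray, yi: np.ndarray) -> float:
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            return np.nan
        r = np.corrcoef(xi, yi)[0, 1]
        return r * r

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(resamples, n))
    draws = np.array([r2_of(x[i], y[i]) for i in idx])
    jk = np.array(
        [r2_of(np.delete(x, i), np.delete(y, i)) for i in range(n)]
    )
    lo, hi, _ = bca_interval(draws, r2, jk[np.isfinite(jk)], alpha)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        r_squared_adj=float(r2_adj),
        r2_ci_low=max(0.0, lo),
        r2_ci_high=min(1.0, hi),
        p_value=float(fit.pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# Co-zonal pairing of driver lines by shared mushroom-body zones
# ---------------------------------------------------------------------------


def major_zones(row: pd.Series, zone_columns, threshold: float) -> frozenset[str]:
    """Zones where a line's staining intensity reaches the threshold."""
    return frozenset(z for z in zone_columns if row[z] >= threshold)


def pair_cozonal(
    pam_table: pd.DataFrame,
    mbon_table: pd.DataFrame,
    staining_threshold: float = 3.0,
    resamples: int = DEFAULT_RESAMPLES,
    seed=None,
) -> tuple[pd.DataFrame, RegressionResult | None]:
    """Pair dopaminergic and output-neuron lines by shared major zones.

    Each table has columns ``line``, ``delta_pi`` and one column per
    mushroom-body zone holding a staining intensity; major staining is an
    intensity >= ``staining_threshold``.  A pair is emitted for every
    PAM x MBON combination sharing at least one major zone, and the paired
    delta-PIs are regressed (MBON on PAM) when >= 3 pairs exist.
    """
    zone_cols_p = [c for c in pam_table.columns if c not in ("line", "delta_pi")]
    zone_cols_m = [c for c in mbon_table.columns if c not in ("line", "delta_pi")]
    if set(zone_cols_p) != set(zone_cols_m):
        raise ValueError("PAM and MBON tables must share the same zone vocabulary")
    rows = []
    for _, p in pam_table.iterrows():
        pz = major_zones(p, zone_cols_p, staining_threshold)
        if not pz:
            continue
        for _, m in mbon_table.iterrows():
            shared = pz & major_zones(m, zone_cols_m, staining_threshold)
            if shared:
                rows.append(
                    {
                        "pam_line": p["line"],
                        "mbon_line": m["line"],
                        "shared_zones": ";".join(sorted(shared)),
                        "pam_delta_pi": p["delta_pi"],
                        "mbon_delta_pi": m["delta_pi"],
                    }
                )
    pairs = pd.DataFrame(
        rows,
        columns=["pam_line", "mbon_line", "shared_zones", "pam_delta_pi", "mbon_delta_pi"],
    )
    result = None
    if len(pairs) >= 3 and np.ptp(pairs["pam_delta_pi"].to_numpy(float)) > 0:
        result = regress_effects(
            pairs["pam_delta_pi"], pairs["mbon_delta_pi"], resamples=resamples, seed=seed
        )
    return pairs, result
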