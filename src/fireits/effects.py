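"""Stage 2: excess visits, percent changes, and Monte Carlo empirical CIs.

Observed and counterfactual post-event series are contrasted into daily and
window excess counts (observed minus expected) and percent changes
(100 * excess / expected). Uncertainty is propagated by a Monte Carlo
scheme: each iteration forms a perturbed counterfactual by block-resampling
pre-event residuals (circular block bootstrap, preserving weekly
autocorrelation) and re-computes every contrast; the 2.5th and 97.5th
percentiles over iterations are the 95% empirical confidence interval (eCI).

Residual perturbation defaults to the *relative* scale — the perturbed
counterfactual is ``prediction * (1 + r*)`` with ``r*`` bootstrapped relative
residuals — because count noise grows with the mean, so additive pre-period
residuals understate post-event uncertainty whenever the event lifts the
level. ``residual_scale="absolute"`` gives the plain additive scheme.

Strata are pooled by summing counts (and per-iteration draws), matching the
count-additive totals the design reports; a coverage-fraction division scales
member-population excess to a county total; and a deliberately naive
log-scale difference-in-differences comparator is provided as a sensitivity
contrast.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, t as student_t

from .counterfactual import CounterfactualFit, PredictionResult

__all__ = [
    "EffectEstimate",
    "PooledEstimate",
    "DiDResult",
    "daily_excess",
    "window_excess",
    "monte_carlo_eci",
    "pool_strata",
    "scale_to_population",
    "did_estimate",
]


@dataclass
class EffectEstimate:
    """Excess-visit estimate for one scope (cell x window) with its eCI.

    ``excess_draws`` and ``predicted_draws`` retain the per-iteration window
    sums so pooled estimates can be formed from the same Monte Carlo run.
    """

    scope: tuple
    window: tuple[int, int]
    observed: float
    predicted: float
    excess_count: float
    pct_change: float | None
    eci_low: float | None = None
    eci_high: float | None = None
    eci_low_count: float | None = None
    eci_high_count: float | None = None
    n_iterations: int = 0
    excess_draws: np.ndarray | None = field(default=None, repr=False)
    predicted_draws: np.ndarray | None = field(default=None, repr=False)


@dataclass
class PooledEstimate:
    """Count-additive pooling of stratum-level estimates."""

    members: tuple
    window: tuple[int, int]
    observed: float
    predicted: float
    excess_count: float
    pct_change: float | None
    eci_low: float | None
    eci_high: float | None
    eci_low_count: float | None
    eci_high_count: float | None
    n_iterations: int


# ---------------------------------------------------------------------------
# point contrasts
# ---------------------------------------------------------------------------


def daily_excess(observed: np.ndarray, predicted: np.ndarray):
    """Per-day excess and percent change.

    Returns ``(excess, pct, undefined)`` arrays; days with a zero prediction
    have undefined percent change (NaN, flagged) but still report the excess.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must be aligned, equal-length series")
    excess = observed - predicted
    undefined = predicted == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(undefined, np.nan, 100.0 * excess / predicted)
    return excess, pct, undefined


def window_excess(
    observed: np.ndarray,
    predicted: np.ndarray,
    window: tuple[int, int],
    scope: tuple = (),
) -> EffectEstimate:
    """Sum the daily contrasts over ``window`` = (start_offset, end_offset).

    Offsets are day indices into the post-period, end-exclusive; the window
    percent change is the predicted-weighted aggregate
    100 * sum(excess) / sum(predicted), not a mean of daily percents.
    """
    start, end = window
    if not (0 <= start < end <= len(observed)):
        raise ValueError(f"window {window} is empty or outside the post-period")
    obs_w = np.asarray(observed, dtype=float)[start:end]
    pred_w = np.asarray(predicted, dtype=float)[start:end]
    obs = float(np.sum(obs_w))
    pred = float(np.sum(pred_w))
    # summed daily differences, so window excess is *exactly* additive in
    # the daily excesses (obs_sum - pred_sum differs in the last few ulps)
    excess = float(np.sum(obs_w - pred_w))
    pct = 100.0 * excess / pred if pred > 0 else None
    return EffectEstimate(
        scope=scope,
        window=window,
        observed=obs,
        predicted=pred,
        excess_count=excess,
        pct_change=pct,
    )


# ---------------------------------------------------------------------------
# Monte Carlo empirical confidence intervals
# ---------------------------------------------------------------------------


def _circular_block_indices(
    rng: np.random.Generator, n_resid: int, n_out: int, block_days: int, n_iter: int
) -> np.ndarray:
    """(n_iter, n_out) index matrix of circular blocks into the residual pool."""
    n_blocks = int(np.ceil(n_out / block_days))
    starts = rng.integers(0, n_resid, size=(n_iter, n_blocks))
    offsets = np.arange(block_days)
    idx = (starts[:, :, None] + offsets[None, None, :]) % n_resid
    return idx.reshape(n_iter, n_blocks * block_days)[:, :n_out]


def monte_carlo_eci(
    fit: CounterfactualFit,
    prediction: PredictionResult | np.ndarray,
    observed: np.ndarray,
    windows: Sequence[tuple[int, int]] = ((0, 7), (0, 14)),
    n_iter: int = 1000,
    block_days: int = 7,
    seed: int = 0,
    residual_scale: str = "relative",
    residual_source: str = "oof",
    finite_pool_correction: bool = True,
    smooth: bool = True,
    scope: tuple = (),
) -> list[EffectEstimate]:
    """Empirical 95% CIs for window excess and percent change.

    Each of ``n_iter`` iterations builds a perturbed counterfactual from
    circular-block-bootstrapped pre-period residuals (out-of-fold by default)
    and recomputes every window contrast; bounds are the 2.5th/97.5th
    percentiles. All pre-period residuals exactly zero collapses the interval
    onto the point estimate. Seeded and reproducible.
    """
    pred = prediction.values if isinstance(prediction, PredictionResult) else np.asarray(prediction, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if pred.shape != observed.shape:
        raise ValueError("prediction and observed post-period series must align")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if residual_scale not in ("relative", "absolute"):
        raise ValueError(f"unknown residual_scale {residual_scale!r}")
    if residual_source == "oof":
        residuals = fit.oof_relative_residuals if residual_scale == "relative" else fit.oof_residuals
    elif residual_source == "insample":
        residuals = fit.relative_residuals if residual_scale == "relative" else fit.residuals
    else:
        raise ValueError(f"unknown residual_source {residual_source!r}")
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) < block_days:
        raise ValueError(
            f"{len(residuals)} residuals cannot supply blocks of {block_days} days"
        )

    rng = np.random.default_rng(seed)
    idx = _circular_block_indices(rng, len(residuals), len(pred), block_days, n_iter)
    r_star = residuals[idx]  # (n_iter, n_post)
    pool_sd = float(np.std(residuals))
    if smooth and pool_sd > 0:
        # variance-corrected smoothed bootstrap (Silverman bandwidth): the
        # pool holds few exchangeable blocks, so raw draw quantiles are
        # near-order-statistics and noisy; kernel noise continuizes the
        # tails while the correction keeps the marginal spread unchanged
        bw = 1.06 * pool_sd * len(residuals) ** (-0.2)
        eps = rng.normal(0.0, bw, size=r_star.shape)
        r_star = (r_star + eps) / np.sqrt(1.0 + (bw / pool_sd) ** 2)
    if finite_pool_correction:
        # the residual pool holds only ~n/block_days exchangeable blocks, so
        # its empirical spread understates the true scale in any one run;
        # inflate by the Student-t/normal quantile ratio at that many degrees
        # of freedom (the bootstrap analogue of using t instead of z)
        df = max(len(residuals) / block_days - 1.0, 2.0)
        r_star = r_star * (student_t.ppf(0.975, df) / norm.ppf(0.975))
    if residual_scale == "relative":
        pred_star = np.clip(pred[None, :] * (1.0 + r_star), 0.0, None)
    else:
        pred_star = np.clip(pred[None, :] + r_star, 0.0, None)

    out: list[EffectEstimate] = []
    for window in windows:
        est = window_excess(observed, pred, window, scope=scope)
        start, end = window
        obs_sum = est.observed
        pred_draws = pred_star[:, start:end].sum(axis=1)
        excess_draws = obs_sum - pred_draws
        lo_c, hi_c = np.percentile(excess_draws, [2.5, 97.5])
        # percent bounds recompute the percent change within each iteration
        # ((obs - pred*)/pred*): the 1/pred* convexity stretches the upper
        # side, matching the right skew of the count-noise-driven estimator
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_draws = np.where(pred_draws > 0, 100.0 * excess_draws / pred_draws, np.nan)
        finite = pct_draws[np.isfinite(pct_draws)]
        if len(finite):
            lo_p, hi_p = np.percentile(finite, [2.5, 97.5])
        else:
            lo_p = hi_p = np.nan
        est.eci_low = float(lo_p)
        est.eci_high = float(hi_p)
        est.eci_low_count = float(lo_c)
        est.eci_high_count = float(hi_c)
        est.n_iterations = int(n_iter)
        est.excess_draws = excess_draws
        est.predicted_draws = pred_draws
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# pooling and scaling
# ---------------------------------------------------------------------------


def pool_strata(estimates: Sequence[EffectEstimate]) -> PooledEstimate:
    """Pool stratum estimates by summing counts and per-iteration draws.

    All members must share the same window. The pooled percent change is
    predicted-weighted (100 * total excess / total predicted); the pooled eCI
    comes from the per-iteration sums of the members' Monte Carlo draws, so
    cross-stratum draws pair by iteration.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    window = estimates[0].window
    if any(e.window != window for e in estimates):
        raise ValueError("cannot pool estimates with mismatched windows")
    observed = sum(e.observed for e in estimates)
    predicted = sum(e.predicted for e in estimates)
    excess = sum(e.excess_count for e in estimates)
    pct = 100.0 * excess / predicted if predicted > 0 else None

    lo_p = hi_p = lo_c = hi_c = None
    n_iter = 0
    if all(e.excess_draws is not None for e in estimates):
        n_iters = {len(e.excess_draws) for e in estimates}
        if len(n_iters) != 1:
            raise ValueError("members were run with different n_iter; cannot pool draws")
        n_iter = n_iters.pop()
        excess_draws = np.sum([e.excess_draws for e in estimates], axis=0)
        pred_draws = np.sum([e.predicted_draws for e in estimates], axis=0)
        lo_c, hi_c = (float(v) for v in np.percentile(excess_draws, [2.5, 97.5]))
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_draws = np.where(pred_draws > 0, 100.0 * excess_draws / pred_draws, np.nan)
        finite = pct_draws[np.isfinite(pct_draws)]
        if len(finite):
            lo_p, hi_p = (float(v) for v in np.percentile(finite, [2.5, 97.5]))
    return PooledEstimate(
        members=tuple(e.scope for e in estimates),
        window=window,
        observed=observed,
        predicted=predicted,
        excess_count=excess,
        pct_change=pct,
        eci_low=lo_p,
        eci_high=hi_p,
        eci_low_count=lo_c,
        eci_high_count=hi_c,
        n_iterations=n_iter,
    )


def scale_to_population(excess: float, coverage_fraction: float) -> float:
    """Scale member-population excess to the full population.

    ``coverage_fraction`` is the share of the target population enrolled in
    the health system whose records produced ``excess``; dividing by it
    extrapolates to everyone (e.g. all county residents).
    """
    if not (0.0 < coverage_fraction <= 1.0):
        raise ValueError("coverage_fraction must be in (0, 1]")
    return excess / coverage_fraction


# ---------------------------------------------------------------------------
# difference-in-differences comparator
# ---------------------------------------------------------------------------


@dataclass
class DiDResult:
    """Naive log-scale difference-in-differences contrast with jackknife SE."""

    effect_log: float
    pct: float
    se_log: float
    pct_low: float
    pct_high: float


def did_estimate(
    treated_pre: np.ndarray,
    treated_post: np.ndarray,
    control_pre: np.ndarray,
    control_post: np.ndarray,
) -> DiDResult:
    """Simplified difference-in-differences on log total counts.

    effect = (log T_post - log T_pre) - (log C_post - log C_pre) on totals,
    reported as a percent (100 * (exp(effect) - 1)). Deliberately ignores
    seasonality and covariates — it is the naive comparator whose bias the
    counterfactual ITS avoids. The standard error is a leave-one-day-out
    jackknife over the shared pre- and post-period calendars (treated and
    control must be day-aligned within each period). All four totals must be
    positive.
    """
    tp = np.asarray(treated_pre, dtype=float)
    ta = np.asarray(treated_post, dtype=float)
    cp = np.asarray(control_pre, dtype=float)
    ca = np.asarray(control_post, dtype=float)
    if tp.shape != cp.shape or ta.shape != ca.shape:
        raise ValueError("treated and control series must be day-aligned per period")

    def _effect(tp_, ta_, cp_, ca_):
        totals = [tp_.sum(), ta_.sum(), cp_.sum(), ca_.sum()]
        if any(t <= 0 for t in totals):
            raise ValueError("difference-in-differences requires positive totals in all four cells")
        return (np.log(totals[1]) - np.log(totals[0])) - (np.log(totals[3]) - np.log(totals[2]))

    effect = _effect(tp, ta, cp, ca)
    # delete-one-day jackknife across both periods
    thetas = []
    for i in range(len(tp)):
        keep = np.arange(len(tp)) != i
        thetas.append(_effect(tp[keep], ta, cp[keep], ca))
    for i in range(len(ta)):
        keep = np.arange(len(ta)) != i
        thetas.append(_effect(tp, ta[keep], cp, ca[keep]))
    thetas = np.asarray(thetas)
    n = len(thetas)
    se = float(np.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)))
    lo = effect - 1.96 * se
    hi = effect + 1.96 * se
    return DiDResult(
        effect_log=float(effect),
        pct=float(100.0 * (np.exp(effect) - 1.0)),
        se_log=se,
        pct_low=float(100.0 * (np.exp(lo) - 1.0)),
        pct_high=float(100.0 * (np.exp(hi) - 1.0)),
    )
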