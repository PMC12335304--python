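"""Flux estimation and regression analysis of diffusion-cell time series.

Flux is the slope of the acceptor *amount* curve (concentration times
live volume, so sampling withdrawals do not bias the estimate) divided
by the membrane area, taken over an initial window where the donor side
is stable: high linearity, limited donor depletion, and no precipitation.

Flux-vs-donor-concentration lines estimate the apparent permeability;
flux-vs-dSSR lines estimate the effective SSR coefficient B_e. Whether
two experimental arms (e.g. with and without cyclodextrin in the donor)
share a slope is tested with the classical ANCOVA homogeneity-of-slopes
F-test on the group-by-x interaction, with an optional permutation
variant for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .transport_sim import CellSimulationResult, DiffusionCellConfig


@dataclass(frozen=True)
class FluxEstimate:
    """Initial flux from a linear window of the acceptor curve."""

    J: float  # ug cm^-2 min^-1
    window: tuple[float, float]  # minutes
    r_squared: float
    mean_donor_concentration: float  # ug/mL
    mean_delta_ssr: float | None = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed window start")


@dataclass(frozen=True)
class SlopeComparison:
    """ANCOVA homogeneity-of-slopes comparison of two regression lines."""

    slope_group1: float
    slope_group2: float
    F_statistic: float
    p_value: float
    df: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class WindowRule:
    """Selection rule for the initial linear flux window.

    The window is the longest prefix of samples starting after
    ``mixing_offset_min`` whose acceptor-amount regression has
    r^2 >= ``min_r_squared`` and whose donor concentration declines by at
    most ``max_donor_decline`` (fractional), truncated at any detected
    precipitation onset.
    """

    mixing_offset_min: float = 1.0
    min_r_squared: float = 0.98
    max_donor_decline: float = 0.10
    min_points: int = 4


def average_flux_from_endpoint(endpoint_concentration: float, elapsed: float) -> float:
    """Endpoint-concentration-over-time flux figure, c / t.

    This reproduces the per-volume convention used for reporting
    size-exclusion ligand transport (endpoint ug/mL divided by elapsed
    minutes); note it is not a mass flux per membrane area, which for an
    18-20 mL cell and 1.54 cm^2 membrane would be roughly 13x larger.
    """
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    return endpoint_concentration / elapsed


def detect_precipitation_onset(
    times: np.ndarray,
    donor_concentration: np.ndarray,
    solubility: float | np.ndarray,
    slope_threshold: float = -0.02,
) -> int | None:
    """Index of the first sample where precipitation is apparent.

    Flags the first point whose centered moving slope of donor
    concentration, relative to the local concentration (fraction per
    minute), falls below ``slope_threshold`` while the donor is
    supersaturated (SSR > 1). Transport alone drains a stirred 18-20 mL
    donor at well under 0.1 %/min, and probe noise stays an order of
    magnitude below the default 2 %/min threshold, while a solubility
    clamp collapses the donor toward its solubility within a couple of
    sampling intervals. Returns None if no such point exists.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(donor_concentration, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    s = np.broadcast_to(np.asarray(solubility, dtype=float), c.shape)
    if slope_threshold >= 0:
        raise ValueError("slope_threshold must be negative")
    for i in range(1, len(t) - 1):
        if c[i] <= 0:
            continue
        slope = (c[i + 1] - c[i - 1]) / (t[i + 1] - t[i - 1]) / c[i]
        if slope < slope_threshold and c[i] / s[i] > 1.0:
            return i
    return None


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def estimate_initial_flux(
    result: CellSimulationResult,
    cell: DiffusionCellConfig | None = None,
    window_rule: WindowRule | None = None,
) -> FluxEstimate:
    """Initial flux from the linear phase of a simulated/measured run.

    Operates on acceptor amount n(t) = c_A(t) * V_A(t); J is the fitted
    slope divided by the membrane area. The window follows
    :class:`WindowRule`; a run with no admissible window raises with
    diagnostics.
    """
    rule = window_rule or WindowRule()
    area = cell.membrane.area if cell is not None else result.metadata.get("area", None)
    if area is None:
        area = 1.54
    t = result.times
    amount = result.acceptor_total * result.V_acceptor
    donor = result.donor_total

    start = int(np.searchsorted(t, rule.mixing_offset_min, side="left"))
    stop = len(t)
    solub = result.solubility_donor_eff
    if len(t) >= 5:
        onset = detect_precipitation_onset(t, donor, solub)
        if onset is not None and onset > start:
            stop = onset
    best = None
    for end in range(stop, start + rule.min_points - 1, -1):
        xs, ys = t[start:end], amount[start:end]
        if np.ptp(xs) == 0:
            continue
        slope, _, r2 = _ols_line(xs, ys)
        decline = (donor[start] - donor[end - 1]) / donor[start] if donor[start] > 0 else 0.0
        if r2 >= rule.min_r_squared and decline <= rule.max_donor_decline:
            dssr = result.SSR_donor[start:end] - result.SSR_acceptor[start:end]
            best = FluxEstimate(
                J=slope / area,
                window=(float(xs[0]), float(xs[-1])),
                r_squared=r2,
                mean_donor_concentration=float(np.mean(donor[start:end])),
                mean_delta_ssr=float(np.mean(dssr)),
                n_points=end - start,
            )
            break
    if best is None:
        raise ValueError(
            "no window satisfied the rule "
            f"(start index {start}, stop {stop}, min_r2 {rule.min_r_squared}, "
            f"max donor decline {rule.max_donor_decline})"
        )
    return best


def flux_vs_x_regression(
    points: np.ndarray | list[tuple[float, float]],
    x_kind: str = "donor_concentration",
) -> tuple[float, float, float]:
    """OLS line through (x, J) points: (slope, intercept, slope SE).

    For ``x_kind="donor_concentration"`` the slope estimates the apparent
    permeability (in the per-volume units of J over x); for
    ``x_kind="delta_SSR"`` it estimates the effective coefficient B_e.
    """
    if x_kind not in ("donor_concentration", "delta_SSR"):
        raise ValueError("x_kind must be donor_concentration or delta_SSR")
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (x, J) points")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    return float(res.slope), float(res.intercept), float(res.stderr)


def homogeneity_of_slopes(
    group1: np.ndarray | list[tuple[float, float]],
    group2: np.ndarray | list[tuple[float, float]],
    method: str = "f",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> SlopeComparison:
    """ANCOVA homogeneity-of-slopes test between two (x, J) groups.

    Tests the group-by-x interaction in the two-group linear model
    y = a_g + b_g * x: the F statistic compares the residual sum of
    squares of the parallel-slopes model against the separate-slopes
    model, F ~ F(1, n1 + n2 - 4) under the null of equal slopes.
    ``method="permutation"`` instead permutes residuals from the
    parallel-slopes fit and reports the permutation p-value of the same
    F statistic (exact-level alternative for small groups).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    for g in (g1, g2):
        if g.ndim != 2 or g.shape[1] != 2 or g.shape[0] < 3:
            raise ValueError("each group needs at least 3 (x, J) points")
        if np.ptp(g[:, 0]) == 0:
            raise ValueError("degenerate design: no x variance in a group")

    f_obs, slopes, df = _interaction_f(g1, g2)
    if method == "f":
        p = float(stats.f.sf(f_obs, *df))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        x = np.concatenate([g1[:, 0], g2[:, 0]])
        y = np.concatenate([g1[:, 1], g2[:, 1]])
        group = np.concatenate([np.zeros(len(g1)), np.ones(len(g2))])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(group))
            pg = group[perm]
            p1 = np.column_stack([x[pg == 0], y[pg == 0]])
            p2 = np.column_stack([x[pg == 1], y[pg == 1]])
            if np.ptp(p1[:, 0]) == 0 or np.ptp(p2[:, 0]) == 0:
                continue
            f_perm, _, _ = _interaction_f(p1, p2)
            if f_perm >= f_obs:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError("method must be 'f' or 'permutation'")
    return SlopeComparison(
        slope_group1=slopes[0],
        slope_group2=slopes[1],
        F_statistic=f_obs,
        p_value=p,
        df=df,
    )


def _interaction_f(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[float, tuple[float, float], tuple[int, int]]:
    """F statistic of the group-by-x interaction (separate intercepts)."""

    def rss_separate(g: np.ndarray) -> tuple[float, float]:
        slope, intercept, _ = _ols_line(g[:, 0], g[:, 1])
        resid = g[:, 1] - (intercept + slope * g[:, 0])
        return float(np.dot(resid, resid)), slope

    rss1, b1 = rss_separate(g1)
    rss2, b2 = rss_separate(g2)
    rss_full = rss1 + rss2

    # parallel-slopes (common b, separate intercepts) via centered fit
    x1, y1 = g1[:, 0], g1[:, 1]
    x2, y2 = g2[:, 0], g2[:, 1]
    x1c, y1c = x1 - x1.mean(), y1 - y1.mean()
    x2c, y2c = x2 - x2.mean(), y2 - y2.mean()
    sxx = np.dot(x1c, x1c) + np.dot(x2c, x2c)
    sxy = np.dot(x1c, y1c) + np.dot(x2c, y2c)
    b_common = sxy / sxx
    resid = np.concatenate([y1c - b_common * x1c, y2c - b_common * x2c])
    rss_reduced = float(np.dot(resid, resid))

    n = len(x1) + len(x2)
    df = (1, n - 4)
    if rss_full <= 0.0:
        f = 0.0 if rss_reduced <= 1e-300 else np.inf
    else:
        f = (rss_reduced - rss_full) / 1.0 / (rss_full / df[1])
    return float(max(f, 0.0)), (b1, b2), df
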