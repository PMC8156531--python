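"""Regression-based and windowed complements to the recurrence pipeline.

* Time-varying VAR(1): kernel-weighted least squares re-estimated along a
  time grid, showing how lag-1 relationships between variables drift or
  even flip sign over a study — structure a single stationary VAR would
  average away.
* Assumption battery: per-variable checks of level stationarity, trend
  stationarity and linearity (the latter via the surrogate determinism
  test), each returning a statistic, p-value and verdict.
* Early-warning indicators: rolling lag-1 autocorrelation and variance
  (critical slowing down) and dynamic complexity (turbulence on a bounded
  scale).
* Generalized logistic change curve: floor, ceiling, growth rate and timing
  of a sigmoid change process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .core_io import LongitudinalSeries
from .surrogates import determinism_statistic, surrogate_test

logger = logging.getLogger("idiodyn")

__all__ = [
    "TVARFit",
    "EWSeries",
    "LogisticFit",
    "CheckResult",
    "fit_tv_var",
    "snapshot_network",
    "assumption_battery",
    "rolling_ews",
    "fit_generalized_logistic",
]


# ---------------------------------------------------------------------------
# Time-varying VAR(1)
# ---------------------------------------------------------------------------


@dataclass
class TVARFit:
    times: np.ndarray            # (G,) grid of evaluation times
    coefficients: np.ndarray     # (G, V, V): [g, i, j] = effect of var j(t-1) on var i(t)
    intercepts: np.ndarray       # (G, V)
    bandwidth: float
    variables: list[str]


def _require_complete(series: LongitudinalSeries) -> np.ndarray:
    if series.missing_mask.any():
        raise ValueError("this analysis requires a complete series "
                         "(missing values found)")
    return series.values


def fit_tv_var(
    series: LongitudinalSeries,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
) -> TVARFit:
    """Gaussian-kernel weighted lag-1 VAR estimates along a time grid.

    At each grid time ``g`` every variable is regressed on all variables at
    the previous occasion, with observation weights
    ``exp(-0.5 ((t - g)/h)^2)``.  The default bandwidth is 10% of the
    observed time range; as ``h -> inf`` the fit converges to the global
    VAR(1) least-squares solution.
    """
    X = _require_complete(series)
    T, V = X.shape
    if T < 20:
        raise ValueError("fit_tv_var needs T >= 20")
    ts = series.timestamps
    t_range = ts[-1] - ts[0]
    h = bandwidth if bandwidth is not None else 0.10 * t_range
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(ts[0], ts[-1], n_grid)
    grid = np.asarray(grid, dtype=float)

    Y = X[1:]                      # (T-1, V) responses
    Z = np.column_stack([np.ones(T - 1), X[:-1]])   # intercept + lagged values
    t_resp = ts[1:]
    coeffs = np.empty((grid.size, V, V))
    inters = np.empty((grid.size, V))
    for gi, g in enumerate(grid):
        w = np.exp(-0.5 * ((t_resp - g) / h) ** 2)
        wsq = np.sum(w ** 2)
        ess = w.sum() ** 2 / wsq if wsq > 0 else 0.0
        if ess < V + 2:
            raise ValueError(
                f"weighted design near-singular at t={g:.3g} "
                f"(effective n {ess:.1f} < {V + 2}); increase the bandwidth"
            )
        sw = np.sqrt(w)
        beta, _, rank, _ = np.linalg.lstsq(Z * sw[:, None], Y * sw[:, None],
                                           rcond=None)
        if rank < V + 1:
            raise ValueError(
                f"weighted design rank-deficient at t={g:.3g}; "
                "increase the bandwidth"
            )
        inters[gi] = beta[0]
        coeffs[gi] = beta[1:].T     # [i, j]: var j at t-1 -> var i at t
    return TVARFit(times=grid, coefficients=coeffs, intercepts=inters,
                   bandwidth=float(h), variables=list(series.variables))


def snapshot_network(
    fit: TVARFit,
    fraction: float,
    threshold: float = 0.1,
) -> nx.DiGraph:
    """Signed directed lag-1 network at a study-completion fraction.

    An edge j -> i means variable j predicts variable i at the next
    occasion; the ``sign`` attribute is '+' or '-'.  Edges with
    ``|beta| < threshold`` are omitted; self-loops are kept (they are the
    autoregressive terms).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    target = fit.times[0] + fraction * (fit.times[-1] - fit.times[0])
    gi = int(np.argmin(np.abs(fit.times - target)))
    B = fit.coefficients[gi]
    G = nx.DiGraph(time=float(fit.times[gi]), fraction=float(fraction))
    G.add_nodes_from(fit.variables)
    V = len(fit.variables)
    for i in range(V):
        for j in range(V):
            b = float(B[i, j])
            if abs(b) >= threshold:
                G.add_edge(fit.variables[j], fit.variables[i],
                           weight=b, sign="+" if b >= 0 else "-")
    return G


# ---------------------------------------------------------------------------
# Assumption battery
# ---------------------------------------------------------------------------


@dataclass
class CheckResult:
    statistic: float
    p_value: float
    reject: bool


def _level_check(x: np.ndarray, alpha: float) -> CheckResult:
    """Split-half comparison of mean (Welch t) and variance (Levene).

    The two sub-tests each run at alpha/2 (Bonferroni), so the check as a
    whole holds its nominal level on stationary data.
    """
    half = x.size // 2
    a, b = x[:half], x[half:]
    t_stat, p_mean = stats.ttest_ind(a, b, equal_var=False)
    l_stat, p_var = stats.levene(a, b)
    p = min(1.0, 2.0 * min(p_mean, p_var))
    return CheckResult(statistic=float(t_stat if p_mean <= p_var else l_stat),
                       p_value=float(p), reject=bool(p <= alpha))


def _trend_check(x: np.ndarray, t: np.ndarray, alpha: float) -> CheckResult:
    """Deterministic-trend check: overall slope != 0, or half-slopes differ.

    A single global trend leaves the half-slopes equal, and a sign-flipping
    trend can leave the overall slope near zero, so the union of the two
    sub-tests (Bonferroni at alpha/2 each) catches both shapes.
    """
    full = stats.linregress(t, x)
    half = x.size // 2
    r1 = stats.linregress(t[:half], x[:half])
    r2 = stats.linregress(t[half:], x[half:])
    se = np.hypot(r1.stderr, r2.stderr)
    z = (r1.slope - r2.slope) / se if se > 0 else 0.0
    p_diff = 2.0 * stats.norm.sf(abs(z))
    p = min(1.0, 2.0 * min(full.pvalue, p_diff))
    return CheckResult(statistic=float(full.slope), p_value=float(p),
                       reject=bool(p <= alpha))


def assumption_battery(
    series: LongitudinalSeries,
    alpha: float = 0.05,
    checks: tuple[str, ...] = ("level", "trend", "linearity"),
    n_surrogates: int = 99,
    surrogate_method: str = "iaaft",
    target_rr: float = 0.05,
    seed: int = 0,
) -> dict[str, dict[str, CheckResult]]:
    """Per-variable stationarity and linearity checks.

    Returns ``{variable: {check_name: CheckResult}}``.  The linearity check
    delegates to the surrogate determinism test; longer series reject more
    of the assumptions under fixed violations, simply through power.
    """
    X = _require_complete(series)
    T = X.shape[0]
    if T < 30:
        raise ValueError(f"assumption_battery needs T >= 30 (got {T})")
    ts = series.timestamps
    report: dict[str, dict[str, CheckResult]] = {}
    for j, name in enumerate(series.variables):
        x = X[:, j]
        res: dict[str, CheckResult] = {}
        if "level" in checks:
            res["level"] = _level_check(x, alpha)
        if "trend" in checks:
            res["trend"] = _trend_check(x, ts, alpha)
        if "linearity" in checks:
            ens = surrogate_test(
                x, determinism_statistic(target_rr=target_rr),
                method=surrogate_method, n=n_surrogates,
                seed=seed + j, side="greater",
            )
            # rank p-values are exact: p <= alpha rejects at level alpha,
            # and the floor 1/(n+1) can attain it
            res["linearity"] = CheckResult(
                statistic=float(ens.observed_stat),
                p_value=float(ens.p_value),
                reject=bool(ens.p_value <= alpha),
            )
        report[name] = res
    return report


# ---------------------------------------------------------------------------
# Early-warning indicators
# ---------------------------------------------------------------------------


@dataclass
class EWSeries:
    window: int
    centres: np.ndarray              # (W,) window-centre times
    autocorr: np.ndarray             # (W, V); NaN where the window is constant
    variance: np.ndarray             # (W, V)
    dynamic_complexity: np.ndarray   # (W, V), in [0, 1] for bounded scales


def _dynamic_complexity(win: np.ndarray, lo: float, hi: float,
                        n_bins: int = 10) -> float:
    """C = F * D on one window of a bounded scale.

    F — fluctuation: mean absolute successive difference scaled by the
    scale range (1 under maximal min/max alternation).  D — distribution:
    one minus the total-variation distance between the windowed value
    histogram (over ``n_bins`` equal bins spanning the scale) and the
    uniform distribution, normalised so a constant window gives 0 and a
    uniform spread gives 1.  High C flags turbulence: large, scale-filling
    fluctuations that often precede state transitions.
    """
    rng_ = hi - lo
    F = float(np.mean(np.abs(np.diff(win)))) / rng_
    hist, _ = np.histogram(win, bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    tv = 0.5 * np.abs(p - 1.0 / n_bins).sum()
    D = 1.0 - tv / (1.0 - 1.0 / n_bins)
    return F * D


def rolling_ews(
    series: LongitudinalSeries,
    window: int = 14,
    n_bins: int = 10,
) -> EWSeries:
    """Sliding-window early-warning indicators, one value per full window.

    Critical slowing down shows up as rising lag-1 autocorrelation and
    variance ahead of a transition; dynamic complexity rises with erratic
    scale-filling fluctuation.  Bounded variables use their scale bounds
    for the complexity normalisation; unbounded ones fall back to their
    observed range.
    """
    X = _require_complete(series)
    T, V = X.shape
    if window < 5:
        raise ValueError("window must be at least 5")
    if window > T:
        raise ValueError(f"window ({window}) exceeds series length ({T})")
    W = T - window + 1
    autoc = np.full((W, V), np.nan)
    var = np.empty((W, V))
    comp = np.empty((W, V))
    bounds = series.scale_bounds or [None] * V
    for j in range(V):
        b = bounds[j]
        lo, hi = b if b is not None else (X[:, j].min(), X[:, j].max())
        if hi <= lo:                      # constant unbounded variable
            lo, hi = lo, lo + 1.0
        for w in range(W):
            win = X[w:w + window, j]
            var[w, j] = win.var(ddof=1)
            a, bb = win[:-1], win[1:]
            if a.std() > 0 and bb.std() > 0:
                autoc[w, j] = np.corrcoef(a, bb)[0, 1]
            comp[w, j] = _dynamic_complexity(win, lo, hi, n_bins=n_bins)
    centres = np.array([
        series.timestamps[w:w + window].mean() for w in range(W)
    ])
    return EWSeries(window=window, centres=centres, autocorr=autoc,
                    variance=var, dynamic_complexity=comp)


# ---------------------------------------------------------------------------
# Generalized logistic change curve
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    floor: float
    ceiling: float
    growth_rate: float       # per time unit; NaN when unidentifiable
    midpoint: float          # time of fastest change; NaN when unidentifiable
    rss: float
    degenerate: bool = False


def _logistic(t, f, c, g, m):
    return f + (c - f) / (1.0 + np.exp(-g * (t - m)))


def fit_generalized_logistic(
    values,
    times=None,
    n_bins_unused=None,
) -> LogisticFit:
    """Bounded nonlinear least squares fit of a four-parameter logistic.

    ``y(t) = floor + (ceiling - floor) / (1 + exp(-growth (t - midpoint)))``

    Floor and ceiling are bounded to the observed range +/- 20%; eight
    deterministic multi-starts (two growth magnitudes x two signs x two
    midpoints) guard against local minima and the best residual sum of
    squares wins.  The parameterisation is symmetric under
    ``(floor, ceiling, growth) -> (ceiling, floor, -growth)``; results are
    normalised to ``floor <= ceiling``, so a decreasing curve has negative
    growth.  A constant series yields a degenerate fit with NaN growth.
    """
    y = np.asarray(values, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValueError("fit_generalized_logistic requires complete data")
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    t = (np.arange(y.size, dtype=float) if times is None
         else np.asarray(times, dtype=float))
    y_lo, y_hi = float(y.min()), float(y.max())
    y_rng = y_hi - y_lo
    if y_rng < 1e-12:
        return LogisticFit(floor=y_lo, ceiling=y_hi, growth_rate=np.nan,
                           midpoint=np.nan, rss=0.0, degenerate=True)
    t_rng = float(t[-1] - t[0])
    pad = 0.2 * y_rng
    lo = [y_lo - pad, y_lo - pad, -50.0 / t_rng * 10, t[0] - t_rng]
    hi = [y_hi + pad, y_hi + pad, 50.0 / t_rng * 10, t[-1] + t_rng]
    g0 = 8.0 / t_rng

    def residuals(p):
        return _logistic(t, *p) - y

    best = None
    failures = []
    for g in (g0, -g0, 4 * g0, -4 * g0):
        for mfrac in (0.3, 0.7):
            p0 = [y_lo, y_hi, g, t[0] + mfrac * t_rng]
            try:
                sol = optimize.least_squares(residuals, p0, bounds=(lo, hi),
                                             method="trf")
            except Exception as exc:   # pragma: no cover - scipy internal
                failures.append(str(exc))
                continue
            if not sol.success:
                failures.append(sol.message)
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError(
            "generalized logistic fit failed from every start: "
            + "; ".join(dict.fromkeys(failures))
        )
    rss, (f, c, g, m) = best
    if f > c:                     # normalise the symmetric parameterisation
        f, c, g = c, f, -g
    degenerate = (c - f) < 1e-6 * max(1.0, y_rng)
    if degenerate:
        g, m = np.nan, np.nan
    return LogisticFit(floor=float(f), ceiling=float(c),
                       growth_rate=float(g), midpoint=float(m),
                       rss=rss, degenerate=degenerate)
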