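"""Ground-truth-labelled synthetic EMA data.

Real behaviour-change EMA series show recurrent multivariate "profiles"
(attractor-like configurations the person keeps returning to), regime
switching between them, nonstationary trend and level, bounded scales and
occasionally heavy-tailed noise.  The generators here plant exactly those
features with known labels, so the recurrence/transition pipeline can be
verified quantitatively at desk scale.

All generators draw from one explicitly seeded ``numpy`` Generator per call;
there is no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import hadamard

from .core_io import LongitudinalSeries

logger = logging.getLogger("idiodyn")

__all__ = [
    "RegimeSpec",
    "generate_regime_switching",
    "generate_linear_var",
    "generate_nonstationary",
    "subsample",
    "make_profiles",
    "demo_spec",
    "logistic_map",
]


@dataclass
class RegimeSpec:
    """Hidden-Markov regime specification.

    ``profiles`` is a ``(K, V)`` matrix of state-mean vectors;
    ``transition_probs`` is ``(K, K)`` *column*-stochastic — entry
    ``[next, current]`` is ``P(next | current)``.  ``noise_sd`` broadcasts
    over ``(K, V)`` so a "background" state may be noisier than the
    attractor profiles.
    """

    profiles: np.ndarray
    transition_probs: np.ndarray
    noise_sd: float | np.ndarray = 1.0
    noise_family: str = "gaussian"        # gaussian | lognormal
    initial_state: int | None = None      # None -> stationary draw

    def __post_init__(self) -> None:
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        K = self.profiles.shape[0]
        if self.transition_probs.shape != (K, K):
            raise ValueError("transition_probs must be K x K")
        cols = self.transition_probs.sum(axis=0)
        if np.any(self.transition_probs < 0) or not np.allclose(cols, 1.0, atol=1e-12):
            raise ValueError("transition_probs columns must be stochastic (sum to 1)")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), self.profiles.shape
        ).copy()
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if self.noise_family not in ("gaussian", "lognormal"):
            raise ValueError("noise_family must be 'gaussian' or 'lognormal'")
        if self.initial_state is not None and not (0 <= self.initial_state < K):
            raise ValueError("initial_state out of range")

    @property
    def n_states(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_variables(self) -> int:
        return self.profiles.shape[1]

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition_probs)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


def _centered_lognormal(rng: np.random.Generator, sd: np.ndarray, shape) -> np.ndarray:
    """Right-skewed zero-mean noise with the requested standard deviation.

    Fixed log-scale shape 0.75 gives pronounced positive skew; the draw is
    rescaled and mean-shifted so sd matches the Gaussian option.
    """
    s = 0.75
    raw = rng.lognormal(mean=0.0, sigma=s, size=shape)
    raw_mean = np.exp(s * s / 2.0)
    raw_sd = raw_mean * np.sqrt(np.exp(s * s) - 1.0)
    return (raw - raw_mean) * (sd / raw_sd)


def generate_regime_switching(
    spec: RegimeSpec,
    T: int,
    seed: int,
    bounds: tuple[float, float] | None = (0.0, 100.0),
    variables: list[str] | None = None,
    subject_id: str = "synthetic",
) -> tuple[LongitudinalSeries, np.ndarray]:
    """Draw a hidden-Markov regime sequence and noisy bounded observations.

    Observation = profile mean + noise, clipped to the scale bounds (the
    questionnaire scale itself is bounded, so out-of-scale draws are clipped
    rather than resampled; the clip count is logged).  Returns the series
    and the true state labels.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = np.random.default_rng(seed)
    K, V = spec.n_states, spec.n_variables
    states = np.empty(T, dtype=int)
    if spec.initial_state is None:
        states[0] = rng.choice(K, p=spec.stationary_distribution())
    else:
        states[0] = spec.initial_state
    for t in range(1, T):
        states[t] = rng.choice(K, p=spec.transition_probs[:, states[t - 1]])

    sd = spec.noise_sd[states]            # (T, V)
    if spec.noise_family == "gaussian":
        noise = rng.standard_normal((T, V)) * sd
    else:
        noise = _centered_lognormal(rng, sd, (T, V))
    values = spec.profiles[states] + noise
    if bounds is not None:
        lo, hi = bounds
        n_clip = int(np.sum((values < lo) | (values > hi)))
        if n_clip:
            logger.info("regime generator clipped %d values to bounds", n_clip)
        values = np.clip(values, lo, hi)
    series = LongitudinalSeries(
        subject_id=subject_id,
        timestamps=np.arange(T, dtype=float),
        variables=variables or [f"v{j + 1}" for j in range(V)],
        values=values,
        scale_bounds=bounds,
    )
    return series, states


def generate_linear_var(
    phi: np.ndarray,
    noise_sd: float = 1.0,
    T: int = 100,
    seed: int = 0,
    burn_in: int = 100,
    subject_id: str = "var1",
) -> LongitudinalSeries:
    """Stationary Gaussian VAR(1) realisation — the linear negative control.

    This is exactly the class of process the surrogate null represents, so
    nonlinearity tests run on its output calibrate the type-I error.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    V = phi.shape[0]
    if phi.shape != (V, V):
        raise ValueError("phi must be square")
    rho = np.max(np.abs(np.linalg.eigvals(phi)))
    if rho >= 1.0:
        raise ValueError(f"unstable VAR: spectral radius {rho:.3f} >= 1")
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = np.random.default_rng(seed)
    x = np.zeros(V)
    out = np.empty((T, V))
    for t in range(-burn_in, T):
        x = phi @ x + rng.standard_normal(V) * noise_sd
        if t >= 0:
            out[t] = x
    return LongitudinalSeries(
        subject_id=subject_id,
        timestamps=np.arange(T, dtype=float),
        variables=[f"v{j + 1}" for j in range(V)],
        values=out,
        scale_bounds=None,
    )


def generate_nonstationary(
    base: LongitudinalSeries,
    trend_pieces: list[tuple[int, float]] | None = None,
    level_shifts: list[tuple[int, float]] | None = None,
) -> LongitudinalSeries:
    """Add a continuous piecewise-linear trend and step level shifts.

    ``trend_pieces`` is a list of ``(start_occasion, slope_per_occasion)``;
    pieces must start at occasion 0, be strictly ordered and non-overlapping,
    and jointly cover ``[0, T)``.  The trend is integrated continuously, so
    e.g. slopes (+1, -1) produce a tent-shaped mean path.  ``level_shifts``
    is a list of ``(start_occasion, delta)`` step offsets.  Both apply to
    every variable.  Scale bounds are dropped from the result, since trends
    may exit the original scale.
    """
    T = base.n_occasions
    drift = np.zeros(T)
    if trend_pieces:
        starts = [int(s) for s, _ in trend_pieces]
        if starts[0] != 0:
            raise ValueError("first trend piece must start at occasion 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("trend pieces overlap or are out of order")
        if any(s >= T or s < 0 for s in starts):
            raise ValueError("trend piece start outside [0, T)")
        slope = np.zeros(T)
        bounds = starts + [T]
        for (s, sl), e in zip(trend_pieces, bounds[1:]):
            slope[s:e] = sl
        drift += np.concatenate([[0.0], np.cumsum(slope[:-1])])
    if level_shifts:
        for s, delta in level_shifts:
            if not (0 <= s < T):
                raise ValueError("level shift outside [0, T)")
            drift[int(s):] += delta
    values = base.values + drift[:, None]
    return LongitudinalSeries(
        subject_id=base.subject_id,
        timestamps=base.timestamps.copy(),
        variables=list(base.variables),
        values=values,
        scale_bounds=None,
        missing_mask=base.missing_mask.copy(),
    )


def subsample(series: LongitudinalSeries, indices) -> LongitudinalSeries:
    """Restrict a series to the given occasions, keeping their timestamps.

    Mirrors sparse evaluation designs (baseline / post / follow-up): the
    fitted trend through 3 such points can have either sign depending on
    which days happen to be sampled.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size < 2:
        raise ValueError("subsample needs at least 2 occasions")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("indices must be strictly increasing")
    if idx.min() < 0 or idx.max() >= series.n_occasions:
        raise ValueError("subsample index out of range")
    return LongitudinalSeries(
        subject_id=series.subject_id,
        timestamps=series.timestamps[idx],
        variables=list(series.variables),
        values=series.values[idx],
        scale_bounds=series.scale_bounds,
        missing_mask=series.missing_mask[idx],
    )


# ---------------------------------------------------------------------------
# Scenario helpers
# ---------------------------------------------------------------------------


def make_profiles(
    K: int,
    V: int,
    min_distance: float,
    center: float = 50.0,
) -> np.ndarray:
    """K well-separated state-mean vectors in V dimensions.

    Rows of a Hadamard matrix (truncated to V columns) give near-orthogonal
    +/-1 patterns; they are rescaled so the *minimum* pairwise Euclidean
    distance equals ``min_distance``, then shifted to ``center``.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    n = 1
    while n < max(K, 2):
        n *= 2
    H = hadamard(n).astype(float)
    pat = np.tile(H[:K], (1, (V + n - 1) // n))[:, :V]
    if K == 1:
        return np.full((1, V), center)
    d = np.inf
    for a in range(K):
        for b in range(a + 1, K):
            d = min(d, float(np.linalg.norm(pat[a] - pat[b])))
    if d == 0:
        raise ValueError("profiles not distinct after truncation; increase V")
    return center + pat * (min_distance / d)


def demo_spec(
    K: int = 4,
    V: int = 6,
    noise_sd: float = 10.0,
    separation: float = 2.0,
    stay_prob: float = 0.6,
    background: bool = True,
) -> RegimeSpec:
    """Default demo scenario: K attractor profiles plus a background state.

    Shapes mirror a single-participant EMA study with six 0–100 items over
    ~122 occasions.  Profile separation defaults to ``separation`` x
    ``noise_sd`` per variable (min pairwise distance ``separation * noise_sd
    * sqrt(V)``), chosen so recovery is neither trivial nor impossible.  The
    background state sits at mid-scale with doubled noise and never repeats
    a tight configuration.
    """
    profiles = make_profiles(K, V, min_distance=separation * noise_sd * np.sqrt(V))
    n_states = K + 1 if background else K
    if background:
        profiles = np.vstack([profiles, np.full(V, 50.0)])
        sd = np.full((n_states, V), noise_sd)
        sd[-1] = 2.5 * noise_sd
    else:
        sd = np.full((n_states, V), noise_sd)
    P = np.full((n_states, n_states), (1.0 - stay_prob) / (n_states - 1))
    np.fill_diagonal(P, stay_prob)
    return RegimeSpec(profiles=profiles, transition_probs=P, noise_sd=sd)


def logistic_map(T: int, r: float = 4.0, x0: float = 0.2) -> LongitudinalSeries:
    """Deterministic chaotic series x[t+1] = r x (1 - x): nonlinearity testbed."""
    if T < 2:
        raise ValueError("T must be at least 2")
    x = np.empty(T)
    x[0] = x0
    for t in range(1, T):
        x[t] = r * x[t - 1] * (1.0 - x[t - 1])
    return LongitudinalSeries(
        subject_id="logistic_map",
        timestamps=np.arange(T, dtype=float),
        variables=["x"],
        values=x[:, None],
        scale_bounds=(0.0, 1.0),
    )
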