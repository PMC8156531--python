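"""Surrogate-data hypothesis tests for nonlinear structure.

Surrogates are temporally disordered versions of the data embodying the
null hypothesis of a rescaled Gaussian linear process.  A nonlinear
statistic (by default determinism from the recurrence module) computed on
the observed series is ranked within the statistic's distribution over an
ensemble of surrogates; the rank p-value ``(1 + #{surrogate >= observed}) /
(n + 1)`` can never reach zero, so at least 19 surrogates are needed for a
one-sided test at alpha = 0.05.

Methods: ``shuffle`` (random permutation — destroys all temporal order),
``phase`` (Fourier phase randomisation — preserves the periodogram),
``iaaft`` (iterative amplitude-adjusted Fourier transform — preserves the
value distribution exactly and the spectrum approximately).  Multivariate
series use a shared random phase sequence per surrogate so cross-variable
correlations survive under the Fourier methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .recurrence import (
    distance_matrix,
    radius_for_rate,
    recurrence_structure,
    rqa_measures,
)

__all__ = [
    "SurrogateEnsemble",
    "make_surrogate",
    "surrogate_test",
    "determinism_statistic",
]

_METHODS = ("shuffle", "phase", "iaaft")


@dataclass
class SurrogateEnsemble:
    method: str
    n: int
    observed_stat: float
    surrogate_stats: np.ndarray
    p_value: float
    side: str
    seed: int

    def summary(self) -> dict:
        s = self.surrogate_stats
        return {
            "method": self.method,
            "n_surrogates": self.n,
            "seed": self.seed,
            "side": self.side,
            "observed": float(self.observed_stat),
            "surrogate_mean": float(np.mean(s)),
            "surrogate_sd": float(np.std(s, ddof=1)) if self.n > 1 else float("nan"),
            "surrogate_q05": float(np.quantile(s, 0.05)),
            "surrogate_q95": float(np.quantile(s, 0.95)),
            "p_value": float(self.p_value),
        }


def _as_matrix(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("series must be 1-D or T x V")
    return x


def _random_phases(rng: np.random.Generator, T: int) -> np.ndarray:
    """Random phase rotations for an rfft spectrum, DC (and Nyquist) fixed."""
    n_freq = T // 2 + 1
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_freq)
    phases[0] = 0.0
    if T % 2 == 0:
        phases[-1] = 0.0
    return phases


def _phase_randomise(x: np.ndarray, phases: np.ndarray) -> np.ndarray:
    spec = np.fft.rfft(x)
    return np.fft.irfft(np.abs(spec) * np.exp(1j * (np.angle(spec) + phases)),
                        n=x.size)


def _iaaft_column(
    x: np.ndarray,
    phases: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """IAAFT for one variable given an initial shared phase draw.

    Alternates spectrum adjustment (impose the original Fourier amplitudes)
    and amplitude adjustment (impose the original sorted values) until the
    spectrum change falls below ``tol`` or ``max_iter`` is hit; the final
    step is an amplitude adjustment, so the value multiset is exact.
    """
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    s = _phase_randomise(x, phases)
    # start from the correct value distribution
    s = sorted_x[np.argsort(np.argsort(s))]
    prev_err = np.inf
    for _ in range(max_iter):
        spec = np.fft.rfft(s)
        mag = np.abs(spec)
        mag[mag == 0] = 1.0
        s = np.fft.irfft(spec * (target_amp / mag), n=x.size)
        err = float(np.sqrt(np.mean((np.abs(np.fft.rfft(s)) - target_amp) ** 2)))
        s = sorted_x[np.argsort(np.argsort(s))]
        if abs(prev_err - err) < tol:
            break
        prev_err = err
    return s


def make_surrogate(values, method: str = "iaaft", seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """One surrogate series with the same shape as the input."""
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    x = _as_matrix(values)
    T, V = x.shape
    if rng is None:
        rng = np.random.default_rng(seed)
    if np.isnan(x).any():
        raise ValueError(
            "surrogate methods require a complete series (missing values found)"
        )
    if method == "shuffle":
        out = x[rng.permutation(T)]
    else:
        if T < 8:
            raise ValueError("spectral surrogate methods need T >= 8")
        phases = _random_phases(rng, T)   # shared across variables
        cols = []
        for j in range(V):
            if method == "phase":
                cols.append(_phase_randomise(x[:, j], phases))
            else:
                cols.append(_iaaft_column(x[:, j], phases))
        out = np.column_stack(cols)
    return out[:, 0] if np.asarray(values).ndim == 1 else out


def surrogate_test(
    values,
    statistic: Callable[[np.ndarray], float],
    method: str = "iaaft",
    n: int = 99,
    seed: int = 0,
    side: str = "greater",
) -> SurrogateEnsemble:
    """Rank the observed statistic within an ensemble of surrogates.

    The statistic is applied to observed and surrogate series with
    identical settings (e.g. a determinism statistic recalibrates its
    fixed-recurrence-rate radius on each series it sees).  ``side='greater'``
    is the default: nonlinear temporal structure inflates determinism.
    """
    if n < 19:
        raise ValueError(
            "n must be at least 19 so the rank p-value floor 1/(n+1) can "
            "reach alpha = 0.05 one-sided"
        )
    if side not in ("greater", "less", "two-sided"):
        raise ValueError("side must be 'greater', 'less' or 'two-sided'")
    rng = np.random.default_rng(seed)
    observed = float(statistic(np.asarray(values, dtype=float)))
    stats = np.empty(n)
    for b in range(n):
        stats[b] = statistic(make_surrogate(values, method=method, rng=rng))
    p_greater = (1.0 + np.sum(stats >= observed)) / (n + 1.0)
    p_less = (1.0 + np.sum(stats <= observed)) / (n + 1.0)
    if side == "greater":
        p = p_greater
    elif side == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return SurrogateEnsemble(method=method, n=n, observed_stat=observed,
                             surrogate_stats=stats, p_value=float(p),
                             side=side, seed=seed)


def determinism_statistic(
    target_rr: float = 0.05,
    theiler: int = 1,
    l_min: int = 2,
    metric: str = "euclidean",
) -> Callable[[np.ndarray], float]:
    """DET at a fixed recurrence rate, recalibrated per series.

    Fixing RR (rather than the radius) makes the statistic comparable
    between the observed series and each surrogate: every series gets the
    same density of recurrences, and only their *organisation* into
    diagonal lines differs.
    """

    def det(values: np.ndarray) -> float:
        X = _as_matrix(values)
        D = distance_matrix(X, metric=metric)
        eps = radius_for_rate(D, target_rr, theiler=theiler).epsilon
        rs = recurrence_structure(D, eps, theiler=theiler)
        m = rqa_measures(rs, l_min=l_min)
        return 0.0 if np.isnan(m.determinism) else m.determinism

    det.__name__ = f"determinism_rr{target_rr:g}"
    return det
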