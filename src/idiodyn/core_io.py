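"""Domain types, CSV I/O and run configuration.

The central container is :class:`LongitudinalSeries`: one person's
multivariate, time-indexed observations (e.g. six motivation items answered
once or twice a day), with an explicit missing-data mask.  Every analysis
module consumes this type; nothing downstream ever imputes.

Missing-data policy: readers flag empty cells in the mask and store NaN in
the value matrix.  Occasions with any masked variable are excluded from
multivariate distance computation downstream, and the exclusion count is
logged — silent imputation would fabricate recurrences.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("idiodyn")

__all__ = [
    "LongitudinalSeries",
    "RunConfig",
    "read_series",
    "write_series",
    "validate_config",
]


@dataclass(eq=False)
class LongitudinalSeries:
    """One individual's multivariate time series.

    Parameters
    ----------
    subject_id:
        Identifier of the person the series belongs to.
    timestamps:
        Strictly increasing time points, arbitrary units (occasion index,
        hours, days).  Equidistance is *checked and reported*, never
        enforced: recurrence methods tolerate mild irregularity.
    variables:
        Ordered variable names (columns of ``values``).
    values:
        ``(T, V)`` float matrix of scores; NaN at masked cells.
    scale_bounds:
        Per-variable ``(min, max)`` tuple, or ``None`` for an unbounded
        variable.  A single tuple is broadcast to all variables.  Bounded
        questionnaire scales (e.g. 0–100 visual-analog) matter for clipping
        in the generator and for dynamic-complexity normalisation.
    missing_mask:
        ``(T, V)`` booleans, True where the observation is missing.
    """

    subject_id: str
    timestamps: np.ndarray
    variables: list[str]
    values: np.ndarray
    scale_bounds: list[tuple[float, float] | None] | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.variables = list(self.variables)
        T, V = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x V matrix")
        if T < 2:
            raise ValueError(f"need at least 2 occasions, got T={T}")
        if V < 1 or len(self.variables) != V:
            raise ValueError(
                f"variables ({len(self.variables)}) must match value columns ({V})"
            )
        if self.timestamps.shape != (T,):
            raise ValueError("timestamps must have one entry per occasion")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (T, V):
            raise ValueError("missing_mask must match values in shape")
        # NaN values must be masked; masked cells are normalised to NaN.
        if np.any(np.isnan(self.values) & ~self.missing_mask):
            raise ValueError("NaN value present at an unmasked cell")
        self.values = np.where(self.missing_mask, np.nan, self.values)
        if self.scale_bounds is not None:
            if isinstance(self.scale_bounds, tuple):
                self.scale_bounds = [self.scale_bounds] * V
            self.scale_bounds = list(self.scale_bounds)
            if len(self.scale_bounds) != V:
                raise ValueError("scale_bounds must have one entry per variable")
            for j, b in enumerate(self.scale_bounds):
                if b is None:
                    continue
                lo, hi = b
                if lo >= hi:
                    raise ValueError(f"degenerate bounds for {self.variables[j]}")
                col = self.values[:, j]
                obs = col[~self.missing_mask[:, j]]
                if obs.size and (obs.min() < lo or obs.max() > hi):
                    raise ValueError(
                        f"observed values of {self.variables[j]} outside "
                        f"bounds ({lo}, {hi})"
                    )

    # -- convenience ---------------------------------------------------

    @property
    def n_occasions(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def complete_occasions(self) -> np.ndarray:
        """Boolean vector: True where every variable is observed."""
        return ~self.missing_mask.any(axis=1)

    def is_equidistant(self, rtol: float = 1e-9) -> bool:
        steps = np.diff(self.timestamps)
        return bool(np.allclose(steps, steps[0], rtol=rtol, atol=0.0))

    def equals(self, other: "LongitudinalSeries") -> bool:
        """Exact equality on identity, timestamps, values and mask."""
        return (
            self.subject_id == other.subject_id
            and self.variables == other.variables
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values, equal_nan=True)
            and np.array_equal(self.missing_mask, other.missing_mask)
        )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration with field-level invariants.

    Rank-based surrogate p-values are floored at ``1/(n_surrogates + 1)``,
    so at least 19 surrogates are required before a one-sided test can reach
    alpha = 0.05; :func:`validate_config` enforces this.
    """

    # recurrence
    radius_mode: str = "fixed_rate"       # fixed_rate | manual
    target_rr: float = 0.05               # target recurrence rate in (0, 1)
    radius: float | None = None           # manual epsilon, distance units
    metric: str = "euclidean"             # euclidean | manhattan | chebyshev
    profile_mode: str = "raw"             # raw | first_difference
    standardise: str = "none"             # none | per_variable
    theiler: int = 1                      # excluded diagonal band half-width
    l_min: int = 2                        # minimum RQA line length
    weight_kind: str = "linear"           # linear | exponential similarity
    # categorisation
    k_classes: int = 4                    # hub classes, as in the 4-colour demo
    # surrogates
    surrogate_method: str = "iaaft"       # shuffle | phase | iaaft
    n_surrogates: int = 99
    surrogate_statistic: str = "determinism"
    alpha: float = 0.05
    side: str = "greater"
    # time-varying VAR
    tv_bandwidth_frac: float = 0.10       # kernel width as fraction of time range
    tv_grid_points: int = 50
    snapshot_fractions: tuple[float, ...] = (0.1, 0.5, 0.9)
    edge_threshold: float = 0.1
    # early-warning windows
    ews_window: int = 14                  # occasions (~a week at 2/day)
    seed: int = 0

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


_CHOICES = {
    "radius_mode": {"fixed_rate", "manual"},
    "metric": {"euclidean", "manhattan", "chebyshev"},
    "profile_mode": {"raw", "first_difference"},
    "standardise": {"none", "per_variable"},
    "weight_kind": {"linear", "exponential"},
    "surrogate_method": {"shuffle", "phase", "iaaft"},
    "side": {"greater", "less", "two-sided"},
}


def validate_config(raw: Mapping | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed JSON mapping.

    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offending parameter; an empty mapping yields the full default
    configuration.  The effective configuration is echoed to the log.
    """
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown configuration key: {key!r}")
    if "snapshot_fractions" in raw:
        raw["snapshot_fractions"] = tuple(raw["snapshot_fractions"])
    cfg = RunConfig(**raw)

    def _in_open_unit(name: str, value: float) -> None:
        if not (0.0 < value < 1.0):
            raise ValueError(f"{name} must lie strictly between 0 and 1, got {value}")

    _in_open_unit("target_rr", cfg.target_rr)
    _in_open_unit("alpha", cfg.alpha)
    _in_open_unit("tv_bandwidth_frac", cfg.tv_bandwidth_frac)
    for name, value in _CHOICES.items():
        if getattr(cfg, name) not in value:
            raise ValueError(f"{name} must be one of {sorted(value)}")
    if cfg.radius_mode == "manual" and (cfg.radius is None or cfg.radius <= 0):
        raise ValueError("radius must be a positive number in manual radius_mode")
    if cfg.n_surrogates < 19:
        raise ValueError(
            "n_surrogates must be at least 19: the rank p-value floor "
            f"1/(n+1) = {1.0 / (cfg.n_surrogates + 1):.3f} cannot reach "
            "alpha = 0.05 one-sided otherwise"
        )
    if cfg.k_classes < 1:
        raise ValueError("k_classes must be at least 1")
    if cfg.theiler < 0:
        raise ValueError("theiler must be non-negative")
    if cfg.l_min < 2:
        raise ValueError("l_min must be at least 2")
    if cfg.tv_grid_points < 2:
        raise ValueError("tv_grid_points must be at least 2")
    if any(not (0.0 <= f <= 1.0) for f in cfg.snapshot_fractions):
        raise ValueError("snapshot_fractions must lie in [0, 1]")
    if cfg.ews_window < 5:
        raise ValueError("ews_window must be at least 5")
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {"subject": "subject", "time": "time",
                   "variable": "variable", "value": "value"}


def read_series(
    path,
    layout: str = "wide",
    schema: Mapping[str, str] | None = None,
    scale_bounds=None,
) -> LongitudinalSeries:
    """Read one person's series from CSV.

    ``layout='wide'`` expects columns ``subject,time,<var1..varV>``;
    ``layout='long'`` expects ``subject,time,variable,value``.  Empty cells
    become masked entries — the reader never imputes.
    """
    sch = dict(_DEFAULT_SCHEMA)
    sch.update(schema or {})
    df = pd.read_csv(path, dtype={sch["subject"]: str})
    for role in ("subject", "time"):
        if sch[role] not in df.columns:
            raise ValueError(f"missing required column {sch[role]!r}")
    subjects = df[sch["subject"]].unique()
    if len(subjects) != 1:
        raise ValueError(f"expected a single subject per file, found {len(subjects)}")

    if layout == "wide":
        variables = [c for c in df.columns if c not in (sch["subject"], sch["time"])]
        if not variables:
            raise ValueError("wide layout requires at least one variable column")
        df = df.sort_values(sch["time"], kind="stable")
        timestamps = df[sch["time"]].to_numpy(dtype=float)
        values = df[variables].to_numpy(dtype=float)
    elif layout == "long":
        for role in ("variable", "value"):
            if sch[role] not in df.columns:
                raise ValueError(f"missing required column {sch[role]!r}")
        expected = {sch[k] for k in ("subject", "time", "variable", "value")}
        extra = [c for c in df.columns if c not in expected]
        if extra:
            raise ValueError(f"unknown column in long layout: {extra[0]!r}")
        wide = df.pivot_table(
            index=sch["time"], columns=sch["variable"], values=sch["value"],
            aggfunc="first", dropna=False, sort=True,
        )
        # preserve first-appearance variable order rather than alphabetical
        order = list(dict.fromkeys(df[sch["variable"]]))
        wide = wide[order]
        timestamps = wide.index.to_numpy(dtype=float)
        variables = [str(v) for v in wide.columns]
        values = wide.to_numpy(dtype=float)
    else:
        raise ValueError("layout must be 'wide' or 'long'")

    if not np.all(np.diff(timestamps) > 0):
        raise ValueError("timestamps are not strictly increasing (duplicates?)")
    series = LongitudinalSeries(
        subject_id=str(subjects[0]),
        timestamps=timestamps,
        variables=variables,
        values=values,
        scale_bounds=scale_bounds,
    )
    n_masked = int(series.missing_mask.sum())
    if n_masked:
        logger.info("read %s: %d missing cells flagged", path, n_masked)
    if not series.is_equidistant():
        logger.info("read %s: timestamps are not equidistant", path)
    return series


def write_series(series: LongitudinalSeries, path, layout: str = "wide") -> None:
    """Write a series to CSV; ``read_series(write_series(s)) == s``.

    Masked cells are emitted as blanks (never zeros), so the missingness
    contract survives the round trip.
    """
    if layout == "wide":
        df = pd.DataFrame(series.values, columns=series.variables)
        df.insert(0, "time", series.timestamps)
        df.insert(0, "subject", series.subject_id)
        df.to_csv(path, index=False)
    elif layout == "long":
        recs = []
        for i, t in enumerate(series.timestamps):
            for j, v in enumerate(series.variables):
                recs.append(
                    (series.subject_id, t, v,
                     np.nan if series.missing_mask[i, j] else series.values[i, j])
                )
        pd.DataFrame(recs, columns=["subject", "time", "variable", "value"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError("layout must be 'wide' or 'long'")
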