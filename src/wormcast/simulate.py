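"""Weibull lifespan-assay simulator.

Generates the synthetic training world for the lifespan forecaster: per-plate
survival curves drawn from a 2-parameter Weibull model, "no capture day" step
distortions mimicking weekend gaps in real assays, and per-worm daily
trajectories in which dead worms stay frozen in place.

Conventions
-----------
* Days are 0-based integers; day 0 is the first capture day with all worms
  alive.
* A plate holds ``n_worms`` age-synchronized worms; the live count is observed
  once per day until it reaches zero.
* The survival model is ``S(t) = exp(-(t/b)**a)`` with shape ``a``
  (steepness of the mortality drop) and scale ``b`` in days. For the steep
  shapes typical of synchronized populations the Weibull mean ``b*Γ(1+1/a)``
  is close to ``b``, so ``b`` is read as the mean lifespan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GapSpec",
    "ArenaSpec",
    "SimulatorParams",
    "LifespanCurve",
    "WormTrajectory",
    "HorizonError",
    "weibull_survival",
    "generate_curve",
    "apply_capture_gaps",
    "sample_trajectories",
]

# Ranges the model is meant to cover (matching the assays the method targets):
# plates of 10-15 worms, mean lifespans from short-lived mutants (~10 d) to
# long-lived daf-2-like strains (~57 d).
WORMS_RANGE = (10, 16)
SCALE_RANGE = (10.0, 57.0)


class HorizonError(ValueError):
    """The simulation horizon is too short for the curve to reach zero."""


@dataclass(frozen=True)
class GapSpec:
    """Capture-gap distortion: weekend-style runs of missed capture days.

    Every ``period`` days, ``gap_days`` consecutive days are skipped, with a
    random phase per curve; a curve is distorted at all only with probability
    ``prob``. On a skipped day the count of the last captured day is held,
    producing the step artifacts seen in manually captured assays.
    """

    gap_days: int = 2
    period: int = 7
    prob: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_days < 0 or self.period < 1:
            raise ValueError("gap_days must be >= 0 and period >= 1")
        if self.gap_days >= self.period:
            raise ValueError("gap_days must be shorter than the period")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must be in [0, 1]")


@dataclass(frozen=True)
class ArenaSpec:
    """Where worms can sit: a centred food-lawn disc inside a square arena.

    ``side`` is the arena side in pixels of the target image; positions are
    drawn uniformly in a disc of radius ``lawn_fraction * side / 2`` centred
    in the arena, mirroring a bacterial lawn placed at the plate centre.
    """

    side: int = 64
    lawn_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.side < 4:
            raise ValueError("arena side must be at least 4 pixels")
        if not 0.0 < self.lawn_fraction <= 1.0:
            raise ValueError("lawn_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimulatorParams:
    """Parameters of one simulated plate."""

    n_worms: int
    a: float
    b: float
    max_days: int = 120
    gap_spec: GapSpec = field(default_factory=GapSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Weibull parameters a and b must be positive")
        if self.n_worms < 1:
            raise ValueError("n_worms must be positive")
        if self.max_days < int(np.ceil(self.b)):
            raise HorizonError(
                f"max_days={self.max_days} < ceil(b)={int(np.ceil(self.b))}: "
                "curve cannot reach zero within the horizon"
            )

    @property
    def in_reference_range(self) -> bool:
        """Whether (n_worms, b) lie in the ranges the method was designed for."""
        lo, hi = WORMS_RANGE
        blo, bhi = SCALE_RANGE
        return lo <= self.n_worms < hi and blo <= self.b <= bhi


@dataclass(frozen=True)
class LifespanCurve:
    """Daily live counts of one plate, day 0 through extinction."""

    days: np.ndarray
    live_counts: np.ndarray
    initial_count: int

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        counts = np.asarray(self.live_counts, dtype=int)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "live_counts", counts)
        if len(days) != len(counts):
            raise ValueError("days and live_counts must have equal length")
        if len(days) == 0:
            raise ValueError("curve must have at least one day")
        if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
            raise ValueError("days must increase in steps of 1")
        if counts[0] != self.initial_count:
            raise ValueError("live_counts[0] must equal initial_count")
        if np.any(np.diff(counts) > 0):
            raise ValueError("live_counts must be non-increasing")

    @property
    def last_day(self) -> int:
        return int(self.days[-1])

    @property
    def extinct(self) -> bool:
        return int(self.live_counts[-1]) == 0


@dataclass(frozen=True)
class WormTrajectory:
    """One worm's daily (x, y) position and alive flag.

    ``death_day`` is the first day the worm is counted dead; from that day on
    its position is frozen. ``death_day`` of ``None`` means the worm survived
    to the end of the observed window.
    """

    positions: np.ndarray  # (n_days, 2) float, arena pixels
    death_day: int | None
    alive_mask: np.ndarray  # (n_days,) bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        mask = np.asarray(self.alive_mask, dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "alive_mask", mask)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] != mask.shape[0]:
            raise ValueError("positions must be (n_days, 2) aligned with alive_mask")
        if self.death_day is not None:
            d = self.death_day
            if mask[:d].sum() != d or mask[d:].any():
                raise ValueError("alive_mask inconsistent with death_day")
            if not np.all(pos[d:] == pos[d]):
                raise ValueError("dead worm moved: positions after death differ")
        elif not mask.all():
            raise ValueError("surviving worm must be alive on every day")


def weibull_survival(t, a: float, b: float):
    """Fraction of the population expected alive at day ``t``.

    ``S(t) = exp(-(t/b)**a)``: 1 at t=0, e**-1 at t=b regardless of shape,
    strictly decreasing for t>0. Accepts scalars or arrays of day values.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Weibull parameters a and b must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be non-negative")
    out = np.exp(-((t_arr / b) ** a))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _death_days_stochastic(params: SimulatorParams, rng: np.random.Generator) -> np.ndarray:
    """Per-worm death days: a continuous Weibull lifetime, rounded up.

    A worm with lifetime L in (d-1, d] is first observed dead on day d, hence
    death_day = ceil(L); a zero-length lifetime (probability 0) maps to day 1.
    """
    lifetimes = params.b * rng.weibull(params.a, size=params.n_worms)
    return np.maximum(np.ceil(lifetimes).astype(int), 1)


def _death_days_deterministic(params: SimulatorParams) -> np.ndarray:
    """Deterministic alternative: threshold the expected survival curve.

    The live count at day d is round(n * S(d)); deaths are its decrements.
    """
    t = np.arange(params.max_days + 1)
    expected = np.rint(params.n_worms * weibull_survival(t, params.a, params.b)).astype(int)
    expected = np.minimum.accumulate(expected)
    deaths_per_day = -np.diff(expected)
    death_days = np.repeat(np.arange(1, params.max_days + 1), deaths_per_day)
    if len(death_days) < params.n_worms:  # survivors past the horizon
        death_days = np.concatenate(
            [death_days, np.full(params.n_worms - len(death_days), params.max_days + 1)]
        )
    return death_days


def generate_curve(
    params: SimulatorParams,
    *,
    method: str = "stochastic",
    on_horizon: str = "error",
) -> LifespanCurve:
    """Simulate one plate's lifespan curve.

    Parameters
    ----------
    params:
        Plate configuration; ``params.seed`` makes the draw reproducible.
    method:
        ``"stochastic"`` draws an independent Weibull lifetime per worm
        (default); ``"deterministic"`` thresholds the expected survival curve.
    on_horizon:
        What to do when a lifetime exceeds ``max_days``: ``"error"`` raises
        :class:`HorizonError`, ``"truncate"`` forces death on the last day.
    """
    if method not in ("stochastic", "deterministic"):
        raise ValueError(f"unknown method {method!r}")
    if on_horizon not in ("error", "truncate"):
        raise ValueError(f"unknown on_horizon {on_horizon!r}")

    rng = np.random.default_rng(params.seed)
    if method == "stochastic":
        death_days = _death_days_stochastic(params, rng)
    else:
        death_days = _death_days_deterministic(params)

    if death_days.max() > params.max_days:
        if on_horizon == "error":
            raise HorizonError(
                f"a simulated lifetime reached day {int(death_days.max())} "
                f"beyond max_days={params.max_days}; enlarge the horizon or "
                "pass on_horizon='truncate'"
            )
        death_days = np.minimum(death_days, params.max_days)

    last_day = int(death_days.max())
    days = np.arange(last_day + 1)
    # alive at day d  <=>  death_day > d
    live = (death_days[None, :] > days[:, None]).sum(axis=1)
    return LifespanCurve(days=days, live_counts=live, initial_count=params.n_worms)


def apply_capture_gaps(
    curve: LifespanCurve,
    gap_spec: GapSpec | None,
    rng: np.random.Generator | int | None = None,
) -> LifespanCurve:
    """Distort a curve with no-capture days.

    On each gap day the count of the last captured day is held, creating steps;
    the first and last day are never gapped, so the initial count and the
    extinction endpoint are preserved and total deaths are unchanged.
    """
    if gap_spec is None or gap_spec.gap_days == 0:
        return curve
    n_days = len(curve.days)
    if gap_spec.gap_days >= n_days:
        raise ValueError("gap length must be shorter than the curve")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if rng.random() >= gap_spec.prob:
        return curve

    phase = int(rng.integers(gap_spec.period))
    offsets = np.arange(n_days)
    gap = ((offsets - phase) % gap_spec.period) < gap_spec.gap_days
    gap[0] = False
    gap[-1] = False

    counts = curve.live_counts.copy()
    for i in range(1, n_days):
        if gap[i]:
            counts[i] = counts[i - 1]
    return LifespanCurve(days=curve.days, live_counts=counts, initial_count=curve.initial_count)


def _uniform_disc(rng: np.random.Generator, n: int, arena: ArenaSpec) -> np.ndarray:
    """n points uniform in the food-lawn disc, in arena pixel coordinates."""
    radius = arena.lawn_fraction * arena.side / 2.0
    centre = arena.side / 2.0
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    return np.column_stack([centre + r * np.cos(theta), centre + r * np.sin(theta)])


def sample_trajectories(
    curve: LifespanCurve,
    arena: ArenaSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[WormTrajectory]:
    """Sample per-worm daily positions consistent with a lifespan curve.

    Worms are exchangeable: death days are assigned to worm indices in a
    random order. Alive worms get a fresh uniform position in the food lawn
    each day (the day-to-day displacement is the movement signal the image
    branch of the model exploits); dead worms keep the position they died at.
    """
    arena = arena or ArenaSpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    counts = curve.live_counts
    n = curve.initial_count
    n_days = len(curve.days)
    deaths_per_day = -np.diff(counts)  # deaths surfacing at day d+1

    # death day per worm slot, None-like sentinel for survivors
    death_days = np.full(n, np.iinfo(np.int64).max)
    cursor = 0
    order = rng.permutation(n)
    for d, k in zip(curve.days[1:], deaths_per_day):
        for _ in range(int(k)):
            death_days[order[cursor]] = d
            cursor += 1

    # A worm counted dead on day d is one that stopped moving: frame d shows it
    # at its day d-1 position, and it stays there ever after.
    positions = np.empty((n, n_days, 2))
    positions[:, 0, :] = _uniform_disc(rng, n, arena)
    for d in range(1, n_days):
        alive = death_days > d  # still alive at day d -> moved since yesterday
        fresh = _uniform_disc(rng, int(alive.sum()), arena)
        positions[:, d, :] = positions[:, d - 1, :]
        positions[alive, d, :] = fresh
    trajectories = []
    for w in range(n):
        dd = int(death_days[w])
        survived = dd > curve.last_day
        mask = np.arange(n_days) < (n_days if survived else dd)
        trajectories.append(
            WormTrajectory(
                positions=positions[w],
                death_day=None if survived else dd,
                alive_mask=mask,
            )
        )
    return trajectories


def curves_to_frame(curves: Sequence[LifespanCurve], plate_ids: Sequence[int] | None = None):
    """Long-format DataFrame (plate_id, day, live_count, initial_count)."""
    import pandas as pd

    if plate_ids is None:
        plate_ids = range(len(curves))
    rows = []
    for pid, c in zip(plate_ids, curves):
        for d, v in zip(c.days, c.live_counts):
            rows.append((pid, int(d), int(v), c.initial_count))
    return pd.DataFrame(rows, columns=["plate_id", "day", "live_count", "initial_count"])


def trajectories_to_frame(trajectories: Sequence[WormTrajectory], plate_id: int = 0):
    """Long-format DataFrame (plate_id, worm_id, day, x, y, alive)."""
    import pandas as pd

    rows = []
    for w, tr in enumerate(trajectories):
        for d in range(tr.positions.shape[0]):
            rows.append(
                (plate_id, w, d, float(tr.positions[d, 0]), float(tr.positions[d, 1]),
                 bool(tr.alive_mask[d]))
            )
    return pd.DataFrame(rows, columns=["plate_id", "worm_id", "day", "x", "y", "alive"])
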