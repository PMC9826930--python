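"""Log-rank halting criterion.

The assay can be halted once the prediction is reliable: reliability is
declared when the survival curves built from the lower and upper bounds of
the condition-level confidence band are NOT significantly different under a
log-rank (Mantel-Cox) test at significance level alpha (default 5%). Early
in an assay the band is wide and its bounds differ significantly; as days
accumulate the band tightens and the test stops rejecting — that first
non-significant day is the proposed halting day.

The log-rank test is implemented here from first principles (hypergeometric
observed-minus-expected deaths at each distinct death day, chi-square with
1 df); an established survival-analysis library serves only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .uncertainty import ConditionBand, NoiseSpec, estimate_plate, propagate_condition

__all__ = [
    "UndefinedTestError",
    "HaltReport",
    "curve_to_events",
    "logrank_test",
    "halt_decision",
    "find_halt_day",
    "round_half_up",
]


class UndefinedTestError(ValueError):
    """Neither curve contains a death event; the log-rank test is undefined."""


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 going up (not banker's rounding)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def curve_to_events(curve: np.ndarray) -> dict[int, int]:
    """Death events implied by a non-increasing live-count curve.

    Deaths on day d are the count drop from day d-1 to day d; worms alive on
    the last day are right-censored there (they contribute at-risk time but
    no event).
    """
    counts = np.asarray(curve, dtype=int)
    if counts.ndim != 1 or len(counts) < 1:
        raise ValueError("curve must be a 1-D count series")
    if np.any(np.diff(counts) > 0):
        raise ValueError("live counts must be non-increasing")
    drops = -np.diff(counts)
    return {int(d): int(drop) for d, drop in enumerate(drops, start=1) if drop > 0}


def logrank_test(curve_a: np.ndarray, curve_b: np.ndarray) -> tuple[float, float]:
    """Unweighted (Mantel-Cox) log-rank test between two count curves.

    At each distinct death day j, with n1j/n2j worms at risk and d1j/d2j
    observed deaths, group 1's expected deaths under the null are
    e1j = dj * n1j / nj and the hypergeometric variance is
    vj = dj * (n1j/nj) * (n2j/nj) * (nj-dj) / (nj-1). The statistic
    (sum(d1j-e1j))^2 / sum(vj) is chi-square with 1 df under the null.

    Returns (statistic, p_value). Symmetric in its arguments. Raises
    :class:`UndefinedTestError` when neither curve has any death.
    """
    a = np.asarray(curve_a, dtype=int)
    b = np.asarray(curve_b, dtype=int)
    events_a = curve_to_events(a)
    events_b = curve_to_events(b)
    if not events_a and not events_b:
        raise UndefinedTestError("no death events in either curve")

    o_minus_e = 0.0
    variance = 0.0
    for day in sorted(set(events_a) | set(events_b)):
        # at risk just before day j = live count on day j-1; a group whose
        # series ended earlier has everyone censored, i.e. zero at risk
        n1 = int(a[day - 1]) if day - 1 < len(a) else 0
        n2 = int(b[day - 1]) if day - 1 < len(b) else 0
        d1 = events_a.get(day, 0)
        d2 = events_b.get(day, 0)
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)

    if variance == 0.0:
        # deaths only where one group had the whole risk set: O-E is exactly 0
        return 0.0, 1.0
    statistic = o_minus_e**2 / variance
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


@dataclass
class HaltReport:
    """Outcome of the day-by-day halting search."""

    halt_day: int | None
    evaluated_days: list[int] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    alpha: float = 0.05

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": self.evaluated_days, "p_value": self.p_values,
             "halt": [p > self.alpha for p in self.p_values]}
        )


def halt_decision(band: ConditionBand, alpha: float | None = None) -> tuple[bool, float]:
    """Should the assay stop, given the current confidence band?

    The CI bound curves are rounded half-up to integers and re-monotonized,
    then compared with the log-rank test; the verdict is halt when
    p > alpha (no significant difference between the bounds). A fully
    degenerate band (identical bounds) halts with p = 1.
    """
    alpha = band.alpha if alpha is None else alpha
    lower = np.minimum.accumulate(round_half_up(band.ci_lower))
    upper = np.minimum.accumulate(round_half_up(band.ci_upper))
    if np.array_equal(lower, upper) and len(curve_to_events(lower)) == 0:
        return True, 1.0
    _, p = logrank_test(lower, upper)
    return bool(p > alpha), float(p)


def find_halt_day(
    predictor,
    plate_curves: list[np.ndarray],
    plate_frames: list | None = None,
    noise: NoiseSpec | None = None,
    alpha: float = 0.05,
    *,
    sqrt_n_divisor: bool = True,
    start_day: int | None = None,
) -> HaltReport:
    """Scan the assay day by day for the first reliable prediction.

    ``plate_curves`` are the full observed count series of every plate in the
    condition (``plate_frames`` the matching frame sequences for image
    modes). For each current day k — starting from the first day the curve
    has fallen on *every* plate, the earliest day uncertainty propagation is
    well-founded — the day-0..k prefixes are pushed through the
    perturbation/propagation/log-rank chain; the first k whose band bounds do
    not differ significantly is the proposed halting day.
    """
    from .dataset import NoDropError

    noise = noise or NoiseSpec()
    curves = [np.asarray(c, dtype=float) for c in plate_curves]
    if start_day is None:
        drop_days = []
        for c in curves:
            below = np.nonzero(c < c[0])[0]
            if below.size == 0:
                raise NoDropError(
                    "a plate never drops within the observed window; the "
                    "halting search cannot start"
                )
            drop_days.append(int(below[0]))
        start_day = max(drop_days)

    last_common = min(len(c) for c in curves) - 1
    if start_day > last_common:
        raise ValueError("no qualifying start day within the common day range")

    report = HaltReport(halt_day=None, alpha=alpha)
    for k in range(start_day, last_common + 1):
        plates = []
        for i, c in enumerate(curves):
            frames = None
            if plate_frames is not None:
                seq = plate_frames[i]
                from .render import FrameSequence

                frames = FrameSequence(frames=seq.frames[: k + 1],
                                       day_index=seq.day_index[: k + 1])
            plates.append(
                estimate_plate(predictor, c[: k + 1], frames, noise)
            )
        band = propagate_condition(plates, alpha, sqrt_n_divisor=sqrt_n_divisor)
        halt, p = halt_decision(band)
        report.evaluated_days.append(k)
        report.p_values.append(p)
        if halt and report.halt_day is None:
            report.halt_day = k
            break
    return report
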