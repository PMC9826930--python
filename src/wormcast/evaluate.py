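"""Scoring a forecast against the reference assay.

Metrics follow the reference evaluation protocol:

* survival percentage  %live(d) = count(d) * 100 / initial;
* MAE (%) — mean absolute difference of survival percentages over the
  *future* period only (from the day the assay stops to the end; the earlier
  period is observed, so it carries no prediction error);
* mean lifespan — the average reconstructed death day of the population
  (deaths on day d contribute d), the reference point the halting day is
  compared against;
* a log-rank p-value between the reference condition curve and the
  observed-prefix-plus-predicted-suffix curve;
* a curve-fitting baseline: nonlinear least squares of a scaled Weibull
  survival model to the observed prefix, extrapolated over the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .halting import curve_to_events, find_halt_day, logrank_test, round_half_up
from .model import LifespanPredictor, predict_plate
from .simulate import LifespanCurve, weibull_survival
from .uncertainty import NoiseSpec

__all__ = [
    "EvaluationReport",
    "percent_live",
    "mae_percent",
    "mean_lifespan",
    "weibull_fit_baseline",
    "evaluate_assay",
    "plot_condition",
]


@dataclass
class EvaluationReport:
    """One condition's scorecard (mirrors the reference result tables)."""

    mean_lifespan_ref: float
    mean_lifespan_pred: float
    halt_day: int | None
    mae_percent: float
    p_value_ref_vs_pred: float
    baseline_mae_percent: float

    def to_row(self) -> dict:
        return {
            "mean_lifespan": self.mean_lifespan_ref,
            "mean_lifespan_nn": self.mean_lifespan_pred,
            "day_halted": self.halt_day,
            "mae_percent": self.mae_percent,
            "p_value": self.p_value_ref_vs_pred,
            "mae_percent_opt": self.baseline_mae_percent,
        }


def percent_live(count: float, initial: float) -> float:
    """Survival percentage: count * 100 / initial."""
    if initial <= 0:
        raise ValueError("initial count must be positive")
    return float(count) * 100.0 / float(initial)


def mae_percent(
    reference: np.ndarray,
    predicted: np.ndarray,
    day_range: tuple[int, int],
    initial: float | None = None,
) -> float:
    """Mean absolute error of survival percentages over ``day_range``.

    ``day_range`` is inclusive on both ends and must lie inside both curves.
    ``initial`` defaults to the reference count at day 0.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    lo, hi = day_range
    if lo > hi:
        raise ValueError("empty day range")
    if lo < 0 or hi >= min(len(ref), len(pred)):
        raise ValueError("day range outside the curves")
    initial = ref[0] if initial is None else float(initial)
    if initial <= 0:
        raise ValueError("initial count must be positive")
    diff = np.abs(ref[lo : hi + 1] - pred[lo : hi + 1]) * 100.0 / initial
    return float(diff.mean())


def mean_lifespan(curve: LifespanCurve | np.ndarray) -> float:
    """Average death day of the population.

    Death events are reconstructed from the count decrements; deaths on day d
    contribute d to the average. For a curve that has not reached zero the
    survivors are excluded and a restricted mean over observed deaths is
    returned (with a warning).
    """
    counts = curve.live_counts if isinstance(curve, LifespanCurve) else np.asarray(curve, int)
    events = curve_to_events(counts)
    n_deaths = sum(events.values())
    if n_deaths == 0:
        raise ValueError("no deaths observed; mean lifespan undefined")
    if counts[-1] > 0:
        import warnings

        warnings.warn(
            "curve not extinct: returning the restricted mean over observed deaths",
            stacklevel=2,
        )
    return sum(d * k for d, k in events.items()) / n_deaths


def weibull_fit_baseline(
    count_prefix: np.ndarray,
    initial: float,
    horizon: int,
    *,
    a0: float = 5.0,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 1.0), (100.0, 200.0)),
) -> tuple[float, float, np.ndarray]:
    """Curve-fitting alternative to the neural forecast.

    Fits ``initial * exp(-(t/b)**a)`` to the observed prefix by nonlinear
    least squares and extrapolates over ``[0, horizon)``. Initialization:
    a0=5, b0 = the last observed day with more than 50% survival (or the
    prefix midpoint when survival never crosses 50%).

    Returns ``(a, b, extrapolated_curve)`` with the curve of length
    ``horizon``.
    """
    prefix = np.asarray(count_prefix, dtype=float)
    if len(np.unique(prefix)) < 2:
        raise ValueError("prefix shows no decline; Weibull fit is degenerate")
    t = np.arange(len(prefix), dtype=float)

    above_half = np.nonzero(prefix > 0.5 * initial)[0]
    b0 = float(above_half[-1]) if above_half.size else len(prefix) / 2.0
    b0 = min(max(b0, bounds[0][1]), bounds[1][1])

    def model(tt, a, b):
        return initial * np.exp(-((tt / b) ** a))

    (a_hat, b_hat), _ = curve_fit(
        model, t, prefix, p0=(a0, b0),
        bounds=([bounds[0][0], bounds[0][1]], [bounds[1][0], bounds[1][1]]),
        maxfev=10000,
    )
    extrapolated = initial * weibull_survival(np.arange(horizon, dtype=float), a_hat, b_hat)
    return float(a_hat), float(b_hat), extrapolated


def plot_condition(
    band,
    reference: np.ndarray,
    predicted: np.ndarray,
    k: int,
    out_path=None,
):
    """One condition's forecast panel: observed prefix, prediction with its
    confidence band, and the reference curve.

    ``band`` is the :class:`~wormcast.uncertainty.ConditionBand` at the
    current day ``k``; returns the matplotlib figure (saved to ``out_path``
    when given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = np.arange(len(band.mean_curve))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(days[: k + 1], predicted[: k + 1], color="goldenrod", lw=2,
            label="observed input (days 0..k)")
    ax.plot(days[k:], band.mean_curve[k:], color="tab:blue", lw=1.5,
            label="mean of perturbed predictions")
    ax.fill_between(days[k:], band.ci_lower[k:], band.ci_upper[k:],
                    color="tab:blue", alpha=0.25, label="confidence band")
    ax.plot(days[k:], predicted[k:], color="tab:red", lw=1.5, label="prediction")
    ax.plot(days[: len(reference)], reference, color="tab:green", lw=1.5,
            label="reference")
    ax.axvline(k, color="gray", ls=":", lw=1)
    ax.set_xlabel("assay day")
    ax.set_ylabel("live count (condition)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def evaluate_assay(
    predictor: LifespanPredictor,
    plate_curves: list[np.ndarray],
    plate_frames: list | None = None,
    noise: NoiseSpec | None = None,
    alpha: float = 0.05,
    *,
    sqrt_n_divisor: bool = True,
) -> EvaluationReport:
    """Run the full halting-and-scoring protocol on one condition.

    The halting search runs on the growing prefixes; at the proposed halting
    day the condition curve is predicted (observed prefix + per-plate
    predicted suffixes, summed) and compared with the reference condition
    curve: MAE (%) over the future period, log-rank p-value, mean lifespans,
    and the Weibull curve-fit baseline over the same period. When no day
    qualifies, metrics are computed at the final observed day.
    """
    noise = noise or NoiseSpec()
    curves = [np.asarray(c, dtype=float) for c in plate_curves]
    max_days = predictor.config.max_days

    report = find_halt_day(
        predictor, curves, plate_frames, noise, alpha, sqrt_n_divisor=sqrt_n_divisor
    )
    last_common = min(len(c) for c in curves) - 1
    k = report.halt_day if report.halt_day is not None else last_common

    # reference condition curve on the absolute-day axis
    ref = np.zeros(max_days)
    for c in curves:
        padded = np.zeros(max_days)
        padded[: len(c)] = c
        padded[len(c) :] = c[-1]
        ref += padded
    initial = ref[0]

    # predicted condition curve: observed prefix + predicted suffix per plate
    pred = np.zeros(max_days)
    for i, c in enumerate(curves):
        frames = None
        if plate_frames is not None:
            from .render import FrameSequence

            seq = plate_frames[i]
            frames = FrameSequence(frames=seq.frames[: k + 1],
                                   day_index=seq.day_index[: k + 1])
        pred += predict_plate(predictor, c[: k + 1], frames)

    extinction = int(np.max(np.nonzero(ref > 0)[0])) + 1 if ref[0] > 0 else max_days - 1
    extinction = min(extinction, max_days - 1)
    future = (k + 1, extinction)
    if future[0] > future[1]:  # halted at/after extinction: nothing left to score
        future = (extinction, extinction)

    mae_nn = mae_percent(ref, pred, future, initial=initial)
    _, p_ref_pred = logrank_test(
        round_half_up(ref).astype(int), round_half_up(pred).astype(int)
    )

    condition_prefix = np.sum([c[: k + 1] for c in curves], axis=0)
    try:
        _, _, baseline = weibull_fit_baseline(condition_prefix, initial, max_days)
        mae_base = mae_percent(ref, baseline, future, initial=initial)
    except (ValueError, RuntimeError):
        mae_base = float("nan")

    return EvaluationReport(
        mean_lifespan_ref=mean_lifespan(round_half_up(ref).astype(int)),
        mean_lifespan_pred=mean_lifespan(round_half_up(pred).astype(int)),
        halt_day=report.halt_day,
        mae_percent=mae_nn,
        p_value_ref_vs_pred=float(p_ref_pred),
        baseline_mae_percent=mae_base,
    )
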