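"""Prediction uncertainty by Monte-Carlo input perturbation.

A trained forecaster returns one curve per input; it carries no confidence
measure of its own. Uncertainty is approximated by perturbing the input
count series with i.i.d. Gaussian noise (mean 0, standard deviation
``sigma``, default 1 worm), predicting once per perturbed replicate, and
summarizing the N predicted curves by their per-day sample mean and standard
deviation (N-1 denominator).

Plate-level standard deviations are propagated to the condition level with
the law of error propagation: the condition count is the plain sum of plate
counts, so every partial derivative is 1 and

    S_C = sqrt(S_P1**2 + S_P2**2 + ... + S_Pn**2).

The confidence interval is C +/- z_{alpha/2} * S_C / sqrt(n) with n the
number of plates, exactly as the reference procedure prints it; the sqrt(n)
divisor can be disabled (``sqrt_n_divisor=False``) since it shrinks the band
relative to the usual sum-of-independent-variances convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import LifespanPredictor, postprocess_prediction

__all__ = [
    "NoiseSpec",
    "PlatePrediction",
    "ConditionBand",
    "perturb_input",
    "estimate_plate",
    "propagate_condition",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Input-perturbation settings: N replicates of N(0, sigma^2) count noise."""

    n_replicates: int = 30
    sigma: float = 1.0
    target: str = "counts"
    position_sigma: float = 1.0  # pixels, used only by "counts+positions"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates to estimate a std")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.target not in ("counts", "counts+positions"):
            raise ValueError("target must be 'counts' or 'counts+positions'")


@dataclass(frozen=True)
class PlatePrediction:
    """Per-day mean and standard deviation over N perturbed predictions."""

    mean_curve: np.ndarray
    std_curve: np.ndarray
    replicate_curves: np.ndarray  # (N, max_days)
    k: int
    initial_count: float

    def __post_init__(self) -> None:
        if self.mean_curve.shape != self.std_curve.shape:
            raise ValueError("mean and std curves must share a day axis")
        if np.any(self.std_curve < 0):
            raise ValueError("standard deviations cannot be negative")


@dataclass(frozen=True)
class ConditionBand:
    """Condition-level curve with propagated uncertainty and CI bounds."""

    mean_curve: np.ndarray
    std_curve: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    alpha: float
    n_plates: int
    initial_count: float
    k: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": np.arange(len(self.mean_curve)), "mean": self.mean_curve,
             "std": self.std_curve, "ci_lower": self.ci_lower,
             "ci_upper": self.ci_upper}
        )


def perturb_input(
    count_prefix: np.ndarray, noise: NoiseSpec, replicate: int
) -> np.ndarray:
    """One perturbed replicate of a count prefix, clipped at zero.

    Seeded per (noise.seed, replicate) so each replicate is independent yet
    reproducible. Perturbed counts stay real-valued; the model consumes
    fractional worms without complaint.
    """
    rng = np.random.default_rng(np.random.SeedSequence((noise.seed, replicate)))
    prefix = np.asarray(count_prefix, dtype=float)
    noisy = prefix + rng.normal(0.0, noise.sigma, size=prefix.shape)
    return np.maximum(noisy, 0.0)


def estimate_plate(
    predictor: LifespanPredictor,
    count_prefix: np.ndarray,
    frame_prefix=None,
    noise: NoiseSpec | None = None,
    coord_prefix: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> PlatePrediction:
    """Monte-Carlo uncertainty for one plate's prediction.

    N perturbed count prefixes are pushed through the model; each raw output
    is post-processed into a valid curve, and the per-day mean and
    (N-1)-denominator standard deviation are returned. Days up to k carry the
    observed counts with zero spread.

    By default frames are left untouched (count noise only). With
    ``noise.target == "counts+positions"`` the blob centres are additionally
    jittered by ``position_sigma`` pixels per replicate; this needs the raw
    per-day positions (``positions``, shape (k+1, n_worms, 2)).
    """
    noise = noise or NoiseSpec()
    count_prefix = np.asarray(count_prefix, dtype=float)
    max_days = predictor.config.max_days
    from .dataset import ModelSample  # local import to avoid cycle at module load
    from .render import FrameSequence, render_frame

    jitter = noise.target == "counts+positions"
    if jitter and positions is None:
        raise ValueError("position jitter needs the per-day blob positions")

    k = len(count_prefix) - 1
    samples = []
    for i in range(noise.n_replicates):
        frames_i = frame_prefix
        if jitter:
            rng = np.random.default_rng(np.random.SeedSequence((noise.seed, i, 1)))
            spec = predictor.config.image_spec
            jittered = positions + rng.normal(0.0, noise.position_sigma,
                                              size=positions.shape)
            jittered = np.clip(jittered, 0.0, spec.side - 1e-9)
            frames_i = FrameSequence(
                frames=np.stack([render_frame(day_pos, spec) for day_pos in jittered]),
                day_index=np.arange(len(jittered)),
            )
        samples.append(
            ModelSample(
                count_prefix=perturb_input(count_prefix, noise, i),
                frame_prefix=frames_i,
                label=np.zeros(max_days),
                k=k,
                plate_id=-1,
                coord_prefix=coord_prefix,
            )
        )
    raw = predictor.predict(samples)  # (N, max_days), worms
    curves = np.stack(
        [postprocess_prediction(r, count_prefix, max_days) for r in raw]
    )
    mean = curves.mean(axis=0)
    std = curves.std(axis=0, ddof=1)
    return PlatePrediction(
        mean_curve=mean, std_curve=std, replicate_curves=curves, k=k,
        initial_count=float(count_prefix[0]),
    )


def propagate_condition(
    plates: list[PlatePrediction],
    alpha: float = 0.05,
    *,
    sqrt_n_divisor: bool = True,
) -> ConditionBand:
    """Aggregate plate predictions into a condition-level confidence band.

    The condition mean is the sum of plate means; its standard deviation is
    the root-sum-of-squares of plate standard deviations (all partial
    derivatives of a sum are 1). Bounds are clipped to [0, total initial
    worms] so the band always describes a feasible count.
    """
    if not plates:
        raise ValueError("at least one plate required")
    n_days = len(plates[0].mean_curve)
    if any(len(p.mean_curve) != n_days for p in plates):
        raise ValueError("plates must share the same day axis")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    mean = np.sum([p.mean_curve for p in plates], axis=0)
    std = np.sqrt(np.sum([p.std_curve**2 for p in plates], axis=0))
    total_initial = float(sum(p.initial_count for p in plates))
    n = len(plates)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * std / (np.sqrt(n) if sqrt_n_divisor else 1.0)
    lower = np.clip(mean - half, 0.0, total_initial)
    upper = np.clip(mean + half, 0.0, total_initial)
    return ConditionBand(
        mean_curve=mean, std_curve=std, ci_lower=lower, ci_upper=upper,
        alpha=alpha, n_plates=n, initial_count=total_initial,
        k=max(p.k for p in plates),
    )
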