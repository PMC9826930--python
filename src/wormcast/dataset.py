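"""Training-sample construction from simulated assays.

One simulated plate yields a family of prediction problems: for every day k
from the first death onward, the days 0..k are the observed prefix (counts
and frames) and the days k+1..end are the regression label. A curve that goes
extinct on day L with its first drop on day F therefore yields L - F samples
(each sample must keep at least one future day to predict).

Labels live on an absolute-day axis of fixed length ``max_days``: element d
of the label vector is the plate's live count on assay day d, zero beyond
extinction, and the loss is masked to the future region d > k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .render import FrameSequence, ImageSpec, render_sequence
from .simulate import (
    ArenaSpec,
    LifespanCurve,
    SimulatorParams,
    WormTrajectory,
    apply_capture_gaps,
    generate_curve,
    sample_trajectories,
)

__all__ = [
    "NoDropError",
    "DatasetSplit",
    "ModelSample",
    "SampleSet",
    "first_drop_day",
    "make_samples",
    "default_param_law",
    "build_dataset",
]

MAX_WORMS = 16  # zero-fill width of the coordinate-matrix input variant


class NoDropError(ValueError):
    """The curve never falls below its initial count."""


@dataclass(frozen=True)
class DatasetSplit:
    """Curve-level train/validation split (no curve straddles both)."""

    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @property
    def val_fraction(self) -> float:
        return 1.0 - self.train_fraction


@dataclass
class ModelSample:
    """One (prefix, future-label) pair from one plate.

    ``count_prefix`` covers days 0..k; ``label`` is the absolute-day count
    vector padded to the horizon, supervised only where day > k.
    """

    count_prefix: np.ndarray  # (k+1,) int
    frame_prefix: FrameSequence
    label: np.ndarray  # (max_days,) float
    k: int
    plate_id: int
    params: SimulatorParams | None = None
    coord_prefix: np.ndarray | None = None  # (k+1, MAX_WORMS, 2) float

    @property
    def initial_count(self) -> int:
        return int(self.count_prefix[0])


@dataclass
class SampleSet:
    """A built dataset: split sample lists plus a per-curve manifest."""

    train: list[ModelSample]
    val: list[ModelSample]
    manifest: pd.DataFrame
    max_days: int
    image_spec: ImageSpec


def first_drop_day(curve: LifespanCurve) -> int:
    """First day the live count falls below the initial count."""
    below = np.nonzero(curve.live_counts < curve.initial_count)[0]
    if below.size == 0:
        raise NoDropError("curve never drops below its initial count")
    return int(curve.days[below[0]])


def _coord_matrix(trajectories: Sequence[WormTrajectory], day: int) -> np.ndarray:
    """Day-``day`` worm coordinates as a lexicographically sorted, zero-filled
    (MAX_WORMS, 2) matrix — the coordinate-input alternative to rendering."""
    pos = np.array([tr.positions[day] for tr in trajectories], dtype=float)
    order = np.lexsort((pos[:, 1], pos[:, 0]))  # X primary, Y secondary
    out = np.zeros((MAX_WORMS, 2), dtype=float)
    out[: len(pos)] = pos[order]
    return out


def make_samples(
    curve: LifespanCurve,
    frames: FrameSequence,
    max_days: int,
    *,
    plate_id: int = 0,
    params: SimulatorParams | None = None,
    trajectories: Sequence[WormTrajectory] | None = None,
) -> list[ModelSample]:
    """Expand one plate into its per-day prediction samples.

    Samples are generated for k from the first drop day through the
    next-to-last day; the final day offers nothing left to predict.
    """
    if len(frames) != len(curve.days):
        raise ValueError("frames must align with curve days")
    if curve.last_day >= max_days:
        raise ValueError(
            f"curve extends to day {curve.last_day} >= label horizon {max_days}"
        )
    fd = first_drop_day(curve)

    label_full = np.zeros(max_days, dtype=float)
    label_full[curve.days] = curve.live_counts

    coords = None
    if trajectories is not None:
        coords = np.stack(
            [_coord_matrix(trajectories, d) for d in range(len(curve.days))]
        )

    samples = []
    for k in range(fd, curve.last_day):
        samples.append(
            ModelSample(
                count_prefix=curve.live_counts[: k + 1].copy(),
                frame_prefix=FrameSequence(
                    frames=frames.frames[: k + 1], day_index=frames.day_index[: k + 1]
                ),
                label=label_full.copy(),
                k=k,
                plate_id=plate_id,
                params=params,
                coord_prefix=None if coords is None else coords[: k + 1],
            )
        )
    return samples


def default_param_law(rng: np.random.Generator, *, max_days: int = 120) -> SimulatorParams:
    """Reference sampling law for training plates.

    Uniform over the ranges the method is designed for: shape a in [3, 10],
    mean lifespan b in [10, 57] days, 10-15 worms per plate.
    """
    return SimulatorParams(
        n_worms=int(rng.integers(10, 16)),
        a=float(rng.uniform(3.0, 10.0)),
        b=float(rng.uniform(10.0, 57.0)),
        max_days=max_days,
        seed=int(rng.integers(2**31)),
    )


def build_dataset(
    n_curves: int,
    param_law: Callable[[np.random.Generator], SimulatorParams] | None = None,
    split: DatasetSplit | None = None,
    seed: int = 0,
    *,
    image_spec: ImageSpec | None = None,
    arena: ArenaSpec | None = None,
    max_days: int = 120,
    with_coords: bool = False,
) -> SampleSet:
    """Simulate, render and expand ``n_curves`` plates into a split dataset.

    The whole pipeline is driven by a single seeded generator, so identical
    arguments reproduce the dataset bit for bit. Curves are split between
    train and validation as whole units to rule out near-duplicate leakage
    (neighbouring samples of one curve differ by a single day).
    """
    if n_curves < 2:
        raise ValueError("need at least 2 curves to split")
    split = split or DatasetSplit()
    image_spec = image_spec or ImageSpec()
    arena = arena or ArenaSpec(side=image_spec.side)
    if arena.side != image_spec.side:
        raise ValueError("arena side must match the image side")
    # simulation horizon one short of the label horizon: day max_days-1 is the
    # last representable assay day
    param_law = param_law or (lambda rng: default_param_law(rng, max_days=max_days - 1))

    rng = np.random.default_rng(seed)
    n_train = int(round(split.train_fraction * n_curves))
    n_train = min(max(n_train, 1), n_curves - 1)
    train_ids = set(rng.permutation(n_curves)[:n_train].tolist())

    train: list[ModelSample] = []
    val: list[ModelSample] = []
    manifest_rows = []
    for cid in range(n_curves):
        params = param_law(rng)
        curve = generate_curve(params, on_horizon="truncate")
        curve = apply_capture_gaps(curve, params.gap_spec, rng)
        if curve.last_day >= max_days:
            raise ValueError(
                f"curve {cid} reaches day {curve.last_day}, beyond the label "
                f"horizon {max_days}; use a param law with max_days < horizon"
            )
        trajectories = sample_trajectories(curve, arena, rng)
        frames = render_sequence(trajectories, image_spec)
        samples = make_samples(
            curve,
            frames,
            max_days,
            plate_id=cid,
            params=params,
            trajectories=trajectories if with_coords else None,
        )
        in_train = cid in train_ids
        (train if in_train else val).extend(samples)
        manifest_rows.append(
            {
                "curve_id": cid,
                "a": params.a,
                "b": params.b,
                "n_worms": params.n_worms,
                "first_drop_day": first_drop_day(curve),
                "last_day": curve.last_day,
                "n_samples": len(samples),
                "split": "train" if in_train else "val",
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    return SampleSet(train=train, val=val, manifest=manifest, max_days=max_days,
                     image_spec=image_spec)
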