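"""Synthetic 6-axis wearable-sensor recordings for twelve daily activities.

The generator emulates a wrist-worn tri-axial accelerometer (units of g) and
tri-axial gyroscope (deg/s) recorded from a small cohort performing scripted
activity bouts: three static postures, three rhythmic dynamic activities, and
six short postural transitions.  Each activity is reduced to a per-channel
statistical model:

* static      -- constant posture offset + Gaussian sensor noise
* dynamic     -- posture offset + sinusoid (random phase) + Gaussian noise
* transitional -- hold(start posture) -> smooth logistic ramp -> hold(end
  posture), + Gaussian noise; the ramp is the recognisable signature

Long continuous bouts versus short transitional bouts reproduce the heavy
class imbalance (~5:1 in window counts) characteristic of this kind of
protocol.  All randomness flows from a single master seed through
``numpy.random.SeedSequence`` children, so a study of any size is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ACTIVITIES",
    "ACTIVITY_GROUPS",
    "STATIC_ACTIVITIES",
    "DYNAMIC_ACTIVITIES",
    "TRANSITIONAL_ACTIVITIES",
    "SensorRecording",
    "ActivityModel",
    "StudyProtocol",
    "default_activity_models",
    "generate_recording",
    "generate_study",
]

STATIC_ACTIVITIES = ("standing", "sleeping", "watching_tv")
DYNAMIC_ACTIVITIES = ("walking", "running", "sweeping")
TRANSITIONAL_ACTIVITIES = (
    "stand_to_sit",
    "sit_to_stand",
    "stand_to_walk",
    "walk_to_stand",
    "lie_to_sit",
    "sit_to_lie",
)

#: Canonical class ordering used throughout the package.
ACTIVITIES = STATIC_ACTIVITIES + DYNAMIC_ACTIVITIES + TRANSITIONAL_ACTIVITIES

ACTIVITY_GROUPS: Mapping[str, str] = {
    **{a: "static" for a in STATIC_ACTIVITIES},
    **{a: "dynamic" for a in DYNAMIC_ACTIVITIES},
    **{a: "transitional" for a in TRANSITIONAL_ACTIVITIES},
}

#: Channel ordering shared by recordings, CSV files and flattened instances.
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


@dataclass
class SensorRecording:
    """One continuous labelled 6-channel stream for a subject/activity bout.

    ``acc`` and ``gyr`` are ``(3, N)`` float arrays (g and deg/s); all six
    channels share the same length.
    """

    subject_id: str
    activity: str
    sampling_rate: float
    acc: np.ndarray
    gyr: np.ndarray
    bout: int = 0

    def __post_init__(self) -> None:
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        if self.activity not in ACTIVITIES:
            raise ValueError(
                f"unknown activity label {self.activity!r}; "
                f"expected one of {sorted(ACTIVITIES)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.acc.shape[0] != 3 or self.gyr.shape[0] != 3:
            raise ValueError("acc and gyr must each have 3 channels")
        if self.acc.shape[1] != self.gyr.shape[1]:
            raise ValueError("all six channels must have identical length")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    @property
    def group(self) -> str:
        return ACTIVITY_GROUPS[self.activity]

    def channels(self) -> np.ndarray:
        """All six channels stacked as a ``(6, N)`` array (acc first)."""
        return np.vstack([self.acc, self.gyr])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensorRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.activity == other.activity
            and self.bout == other.bout
            and np.isclose(self.sampling_rate, other.sampling_rate)
            and self.acc.shape == other.acc.shape
            and np.array_equal(self.acc, other.acc)
            and np.array_equal(self.gyr, other.gyr)
        )


@dataclass
class ActivityModel:
    """Statistical stand-in for one activity's 6-channel signal.

    ``offsets``/``noise_sd``/``amplitude`` are length-6 sequences ordered as
    :data:`CHANNELS`.  ``frequency`` (Hz) and ``amplitude`` apply only to
    dynamic models; ``start_offsets``/``end_offsets``/``ramp_s`` only to
    transitional ones.
    """

    activity: str
    group: str
    offsets: Sequence[float] = (0.0,) * 6
    noise_sd: Sequence[float] = (0.01,) * 6
    frequency: float = 0.0
    amplitude: Sequence[float] = (0.0,) * 6
    start_offsets: Sequence[float] = (0.0,) * 6
    end_offsets: Sequence[float] = (0.0,) * 6
    ramp_s: float = 2.5

    def __post_init__(self) -> None:
        if self.group not in ("static", "dynamic", "transitional"):
            raise ValueError(f"unknown activity group {self.group!r}")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be nonnegative")
        if self.group == "transitional" and self.ramp_s <= 0:
            raise ValueError("ramp_s must be positive for transitional models")
        if self.group == "static" and np.any(np.asarray(self.amplitude) != 0):
            raise ValueError("static models must have zero oscillation amplitude")


def default_activity_models() -> dict[str, ActivityModel]:
    """Default per-activity models for a left-wrist sensor placement.

    Accelerometer offsets are unit-norm-ish gravity directions for each
    posture (standing: arm hanging, z down; lying: gravity along x).  Each
    posture plateau gets a slightly different wrist orientation, reflecting
    that e.g. standing *about to sit* is not held identically to quiet
    standing.  Plateau noise is larger for transitional holds than for the
    static postures (subjects fidget around a transition), so per-window
    variance orders static < transitional plateau < dynamic.
    """
    z = (0.0,) * 6

    def acc(x, y, zz, g=0.0):
        return (x, y, zz, g, g, g)

    stand = acc(0.00, 0.00, 1.00)
    sit = acc(0.58, 0.12, 0.76)
    lie = acc(0.96, 0.04, 0.18)
    sd_static = (0.010, 0.010, 0.010, 0.6, 0.6, 0.6)
    sd_trans = (0.030, 0.030, 0.030, 3.0, 3.0, 3.0)

    models = {
        "standing": ActivityModel("standing", "static", offsets=stand, noise_sd=sd_static),
        "sleeping": ActivityModel(
            "sleeping", "static", offsets=acc(1.00, 0.00, 0.05),
            noise_sd=(0.015, 0.015, 0.015, 1.0, 1.0, 1.0),
        ),
        "watching_tv": ActivityModel(
            "watching_tv", "static", offsets=acc(0.40, 0.30, 0.85),
            noise_sd=(0.020, 0.020, 0.020, 1.5, 1.5, 1.5),
        ),
        "walking": ActivityModel(
            "walking", "dynamic", offsets=acc(0.10, 0.05, 0.97),
            noise_sd=(0.05, 0.05, 0.05, 5.0, 5.0, 5.0),
            frequency=2.0, amplitude=(0.35, 0.25, 0.30, 60.0, 40.0, 50.0),
        ),
        "running": ActivityModel(
            "running", "dynamic", offsets=acc(0.15, 0.05, 0.92),
            noise_sd=(0.10, 0.10, 0.10, 10.0, 10.0, 10.0),
            frequency=3.0, amplitude=(0.85, 0.60, 0.75, 150.0, 110.0, 130.0),
        ),
        "sweeping": ActivityModel(
            "sweeping", "dynamic", offsets=acc(0.30, 0.20, 0.90),
            noise_sd=(0.07, 0.07, 0.07, 7.0, 7.0, 7.0),
            frequency=1.0, amplitude=(0.45, 0.40, 0.25, 80.0, 70.0, 40.0),
        ),
        "stand_to_sit": ActivityModel(
            "stand_to_sit", "transitional", noise_sd=sd_trans,
            start_offsets=acc(0.06, -0.02, 0.97), end_offsets=acc(0.55, 0.12, 0.78),
        ),
        "sit_to_stand": ActivityModel(
            "sit_to_stand", "transitional", noise_sd=sd_trans,
            start_offsets=acc(0.60, 0.08, 0.76), end_offsets=acc(0.02, 0.05, 0.99),
        ),
        "stand_to_walk": ActivityModel(
            "stand_to_walk", "transitional", noise_sd=sd_trans,
            start_offsets=acc(0.04, 0.02, 0.98), end_offsets=acc(0.14, 0.09, 0.94),
        ),
        "walk_to_stand": ActivityModel(
            "walk_to_stand", "transitional", noise_sd=sd_trans,
            start_offsets=acc(0.16, 0.07, 0.93), end_offsets=acc(-0.03, 0.04, 0.99),
        ),
        "lie_to_sit": ActivityModel(
            "lie_to_sit", "transitional", noise_sd=sd_trans,
            start_offsets=lie, end_offsets=acc(0.58, 0.15, 0.74),
        ),
        "sit_to_lie": ActivityModel(
            "sit_to_lie", "transitional", noise_sd=sd_trans,
            start_offsets=sit, end_offsets=acc(0.96, 0.02, 0.14),
        ),
    }
    del z
    return models


@dataclass
class StudyProtocol:
    """The scripted collection protocol the generator replays.

    Continuous (static/dynamic) activities are held for ``continuous_bout_s``
    seconds per bout; transitional activities are hold-ramp-hold bouts with
    ``transitional_hold_s`` second holds on either side of the ramp.  The
    defaults (10 subjects, 300 s continuous bouts, 15 s transitional holds,
    2 transitional bouts, 102.4 Hz) yield roughly 1190 windows per continuous
    class and 240 per transitional class under 512-sample / 50%-overlap
    segmentation, i.e. the ~5:1 imbalance the pipeline is designed around.
    """

    n_subjects: int = 10
    continuous_bout_s: float = 300.0
    transitional_hold_s: float = 15.0
    continuous_repeats: int = 1
    transitional_repeats: int = 2
    sampling_rate: float = 102.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.continuous_bout_s <= 0 or self.transitional_hold_s <= 0:
            raise ValueError("bout durations must be positive")
        if self.continuous_repeats < 1 or self.transitional_repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(int(seed))


def generate_recording(
    model: ActivityModel,
    duration_s: float,
    sampling_rate: float,
    seed,
    subject_id: str = "S00",
    bout: int = 0,
) -> SensorRecording:
    """Simulate one bout of ``model``'s activity.

    Returns a recording of ``round(duration_s * sampling_rate)`` samples per
    channel.  For transitional models the logistic ramp is centred mid-bout
    and completes (2%..98%) within ``model.ramp_s`` seconds.  Identical
    arguments (including seed) give identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = _rng_from(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate

    sig = np.empty((6, n), dtype=float)
    if model.group == "transitional":
        start = np.asarray(model.start_offsets, dtype=float)
        end = np.asarray(model.end_offsets, dtype=float)
        # logistic reaches ~2% / ~98% at +-4*tau around the midpoint
        tau = model.ramp_s / 8.0
        ramp = 1.0 / (1.0 + np.exp(-(t - duration_s / 2.0) / tau))
        sig[:] = start[:, None] + (end - start)[:, None] * ramp[None, :]
    else:
        sig[:] = np.asarray(model.offsets, dtype=float)[:, None]
        if model.group == "dynamic":
            phase = rng.uniform(0.0, 2.0 * np.pi, size=6)
            amp = np.asarray(model.amplitude, dtype=float)
            sig += amp[:, None] * np.sin(
                2.0 * np.pi * model.frequency * t[None, :] + phase[:, None]
            )
    sd = np.asarray(model.noise_sd, dtype=float)
    sig += rng.standard_normal((6, n)) * sd[:, None]

    return SensorRecording(
        subject_id=subject_id,
        activity=model.activity,
        sampling_rate=sampling_rate,
        acc=sig[:3],
        gyr=sig[3:],
        bout=bout,
    )


def generate_study(
    protocol: StudyProtocol,
    models: Mapping[str, ActivityModel] | None = None,
) -> list[SensorRecording]:
    """Replay the full protocol: one recording per (subject, activity, bout).

    ``models`` must cover all twelve activity labels; each recording draws
    its own child seed from the protocol's master seed, so inserting or
    removing subjects does not perturb other subjects' data.
    """
    if models is None:
        models = default_activity_models()
    missing = [a for a in ACTIVITIES if a not in models]
    if missing:
        raise KeyError(f"missing activity model(s): {missing}")

    recordings: list[SensorRecording] = []
    for s in range(protocol.n_subjects):
        subject_id = f"S{s:02d}"
        for ai, activity in enumerate(ACTIVITIES):
            model = models[activity]
            if model.group == "transitional":
                repeats = protocol.transitional_repeats
                duration = 2.0 * protocol.transitional_hold_s + model.ramp_s
            else:
                repeats = protocol.continuous_repeats
                duration = protocol.continuous_bout_s
            for r in range(repeats):
                child = np.random.SeedSequence(
                    protocol.seed, spawn_key=(s, ai, r)
                )
                recordings.append(
                    generate_recording(
                        model,
                        duration,
                        protocol.sampling_rate,
                        child,
                        subject_id=subject_id,
                        bout=r,
                    )
                )
    return recordings
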