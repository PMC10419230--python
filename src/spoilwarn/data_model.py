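"""Core data model for warehouse gas-sensor acquisitions.

A single acquisition is a 500-timepoint x 6-channel recording (1 Hz for
500 s) from a sensor array measuring Temperature, Humidity, CO2, C2H4, O2
and a broadband VOC signal.  For modelling, each acquisition is flattened
sensor-major into a length-3000 feature vector: positions 1-500 hold the
Temperature trace in time order, 501-1000 Humidity, 1001-1500 CO2,
1501-2000 C2H4, 2001-2500 O2 and 2501-3000 VOC.  All public index spaces
are 1-based ("variable numbers"), matching the convention used when sparse
warning models cite characteristic variables such as 228 or 2001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_TIMEPOINTS = 500
N_CHANNELS = 6
N_FEATURES = N_TIMEPOINTS * N_CHANNELS  # 3000

DAY_LABELS = tuple(range(1, 9))


@dataclass(frozen=True)
class SensorChannel:
    """One channel of the sensing array.

    ``detection_range`` and ``resolution`` follow the sensor datasheet
    values; ``flattened_range`` is the inclusive 1-based interval this
    channel occupies in the flattened feature vector.
    """

    name: str
    unit: str
    detection_range: tuple[float, float]
    resolution: float
    flattened_range: tuple[int, int]

    def contains_index(self, index: int) -> bool:
        lo, hi = self.flattened_range
        return lo <= index <= hi


#: Canonical channel order; the six flattened ranges tile {1..3000}.
CHANNELS: tuple[SensorChannel, ...] = (
    SensorChannel("Temperature", "degC", (-20.0, 80.0), 0.1, (1, 500)),
    SensorChannel("Humidity", "%rh", (0.0, 100.0), 0.1, (501, 1000)),
    SensorChannel("CO2", "ppm", (0.0, 5000.0), 1.0, (1001, 1500)),
    SensorChannel("C2H4", "ppm", (0.0, 100.0), 0.1, (1501, 2000)),
    SensorChannel("O2", "%VOL", (0.0, 30.0), 0.1, (2001, 2500)),
    SensorChannel("VOC", "ppm", (0.0, 50.0), 0.001, (2501, 3000)),
)

CHANNEL_NAMES = tuple(ch.name for ch in CHANNELS)
CHANNEL_BY_NAME = {ch.name: ch for ch in CHANNELS}


def get_channel(name: str) -> SensorChannel:
    try:
        return CHANNEL_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown sensor channel {name!r}; expected one of {CHANNEL_NAMES}"
        ) from None


@dataclass
class AcquisitionRecord:
    """One 500 s acquisition from one warehouse on one day.

    ``values`` has shape (500, 6) with columns in canonical channel order;
    row t holds the readings at second t (t = 0..499).
    """

    values: np.ndarray
    warehouse_id: str
    day: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_TIMEPOINTS, N_CHANNELS):
            raise ValueError(
                "acquisition must be a "
                f"{N_TIMEPOINTS} x {N_CHANNELS} matrix, got shape "
                f"{self.values.shape}"
            )
        self.day = int(self.day)

    @property
    def timestamps(self) -> np.ndarray:
        """Seconds since acquisition start, 0..499."""
        return np.arange(N_TIMEPOINTS)


@dataclass
class Dataset:
    """n samples x p features with day labels and modelling targets.

    ``days`` are the integer acquisition days (1-8).  ``labels`` is the
    regression target used for model fitting; it equals ``days`` unless a
    synthetic linear signal was embedded, in which case it is the
    regenerated continuous response.  ``split`` optionally tags each sample
    as ``"calibration"`` or ``"prediction"``.
    """

    features: np.ndarray
    days: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.days = np.asarray(self.days, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if self.days.shape != (n,):
            raise ValueError("days length must match feature rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match feature rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        bad = [int(d) for d in self.days if d not in DAY_LABELS]
        if bad:
            raise ValueError(f"day labels must lie in 1..8, got {bad[:5]}")
        if self.labels is None:
            self.labels = self.days.astype(float)
        else:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape != (n,):
                raise ValueError("labels length must match feature rows")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape != (n,):
                raise ValueError("split length must match feature rows")
            bad_tags = set(self.split) - {"calibration", "prediction"}
            if bad_tags:
                raise ValueError(f"unknown split tags: {sorted(bad_tags)}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def rows(self, tag: str) -> np.ndarray:
        """Boolean mask of samples carrying split tag ``tag``."""
        if self.split is None:
            raise ValueError("dataset has no calibration/prediction split")
        return self.split == tag


def flatten_record(record: AcquisitionRecord) -> np.ndarray:
    """Flatten a 500 x 6 acquisition into a length-3000 vector.

    Sensor-major: the whole Temperature trace first (positions 1-500),
    then Humidity, CO2, C2H4, O2, VOC.
    """
    if record.values.shape != (N_TIMEPOINTS, N_CHANNELS):
        raise ValueError(f"bad acquisition shape {record.values.shape}")
    return record.values.T.reshape(-1).copy()


def unflatten(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_record`; returns the 500 x 6 matrix."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_FEATURES,):
        raise ValueError(
            f"flattened vector must have length {N_FEATURES}, got shape "
            f"{vector.shape}"
        )
    return vector.reshape(N_CHANNELS, N_TIMEPOINTS).T.copy()


def index_to_channel(index: int) -> tuple[SensorChannel, int]:
    """Map a 1-based flattened variable number to (channel, timepoint).

    The timepoint is 1-based within the channel's trace, so variable 2001
    maps to (O2, 1) and variable 228 to (Temperature, 228).
    """
    index = int(index)
    if not 1 <= index <= N_FEATURES:
        raise ValueError(
            f"flattened index must lie in 1..{N_FEATURES}, got {index}"
        )
    channel = CHANNELS[(index - 1) // N_TIMEPOINTS]
    timepoint = index - channel.flattened_range[0] + 1
    return channel, timepoint
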