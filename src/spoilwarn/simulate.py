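"""Simulated-warehouse sensor data generator.

Emulates the study design the downstream analysis assumes: nine simulated
warehouses, each sampled once per day over 8 consecutive days (2 fresh +
6 post-inoculation), one 500 s x 6-channel acquisition per (warehouse,
day).  Within an acquisition each gas channel follows a first-order
saturating approach from an ambient baseline toward a day-dependent
equilibrium level, plus i.i.d. Gaussian measurement noise, clipped to the
sensor's detection range.  Temperature and Humidity are held at the
incubation conditions (25 degC, 60 %rh).

The day-dependent equilibrium levels are the generator's only contact
with observed biology: across days their per-channel ordering reproduces
the reported sensor-response orderings (VOC 7>8>4>6>5>1>3>2,
CO2 1<4<3<2<7<5<6<8, O2 8>5>6>7>3>4>2>1, C2H4 7>6>8>5>4>3>2>1).  Only the
orderings are constrained; the absolute levels are evenly spaced within
each channel's plausible range, spaced widely enough that the orderings
survive the default noise.

For parameter-recovery experiments the generator can embed a known sparse
linear day<->signal relationship: labels are regenerated as
``intercept + sum(coef * feature[informative_indices]) + noise`` and the
construction is returned as a :class:`GroundTruth` sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CHANNEL_NAMES,
    CHANNELS,
    N_TIMEPOINTS,
    AcquisitionRecord,
    Dataset,
    flatten_record,
    get_channel,
)

#: Across-day orderings of mean sensor response, most-responsive day first.
DAY_ORDERINGS: dict[str, tuple[int, ...]] = {
    "VOC": (7, 8, 4, 6, 5, 1, 3, 2),
    "CO2": (8, 6, 5, 7, 2, 3, 4, 1),  # printed ascending 1<4<3<2<7<5<6<8
    "O2": (8, 5, 6, 7, 3, 4, 2, 1),
    "C2H4": (7, 6, 8, 5, 4, 3, 2, 1),
}

#: Evenly spaced level grids (highest..lowest), inside each detection range.
_LEVEL_GRIDS: dict[str, tuple[float, float]] = {
    # channel: (lowest level, highest level) across the 8 days
    "VOC": (5.0, 40.0),
    "CO2": (400.0, 3200.0),
    "O2": (5.0, 19.0),
    "C2H4": (10.0, 80.0),
}

#: Ambient starting values for the within-acquisition rise/fall.
AMBIENT_BASELINES: dict[str, float] = {
    "Temperature": 25.0,
    "Humidity": 60.0,
    "CO2": 400.0,
    "C2H4": 0.0,
    "O2": 21.0,
    "VOC": 0.0,
}


def default_noise_sd() -> dict[str, float]:
    """Per-channel noise sd: 1% of full scale (sensor precision class)."""
    return {
        ch.name: 0.01 * (ch.detection_range[1] - ch.detection_range[0])
        for ch in CHANNELS
    }


def default_day_level_table(
    baseline_temperature: float = 25.0, baseline_humidity: float = 60.0
) -> pd.DataFrame:
    """Per-channel, per-day equilibrium response levels (channel units).

    Rows are channels, columns are days 1-8.  Gas-channel rows reproduce
    the reported across-day orderings exactly; Temperature and Humidity
    are constant at the incubation baselines.
    """
    days = list(range(1, 9))
    table = pd.DataFrame(index=list(CHANNEL_NAMES), columns=days, dtype=float)
    table.loc["Temperature"] = baseline_temperature
    table.loc["Humidity"] = baseline_humidity
    for name, ordering in DAY_ORDERINGS.items():
        lo, hi = _LEVEL_GRIDS[name]
        levels = np.linspace(hi, lo, 8)  # highest-ranked day gets hi
        for rank, day in enumerate(ordering):
            table.loc[name, day] = levels[rank]
    return table


@dataclass
class WarehouseSimConfig:
    """Configuration of one simulated-warehouse study."""

    n_warehouses: int = 9
    days: tuple[int, ...] = tuple(range(1, 9))
    n_timepoints: int = N_TIMEPOINTS
    channels: tuple[str, ...] = CHANNEL_NAMES
    day_level_table: pd.DataFrame | None = None
    rise_time_constant: float = 60.0  # seconds
    noise_sd: dict[str, float] = field(default_factory=default_noise_sd)
    baseline_temperature: float = 25.0
    baseline_humidity: float = 60.0
    embed_signal: bool = False
    n_informative: int = 10
    informative_indices: tuple[int, ...] | None = None
    informative_coefficients: tuple[float, ...] | None = None
    label_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_warehouses < 1:
            raise ValueError("n_warehouses must be at least 1")
        if len(self.days) == 0:
            raise ValueError("days must be non-empty")
        if self.n_timepoints != N_TIMEPOINTS:
            raise ValueError(
                f"n_timepoints must be {N_TIMEPOINTS} (one 500 s acquisition "
                "at 1 Hz); the flattened feature space is fixed at 3000"
            )
        if tuple(self.channels) != CHANNEL_NAMES:
            raise ValueError(f"channels must be {CHANNEL_NAMES} in order")
        if self.rise_time_constant < 0:
            raise ValueError("rise_time_constant must be >= 0")
        if self.day_level_table is None:
            self.day_level_table = default_day_level_table(
                self.baseline_temperature, self.baseline_humidity
            )
        self._validate_levels()
        if self.informative_indices is not None:
            idx = tuple(int(i) for i in self.informative_indices)
            n_feat = self.n_features
            if len(set(idx)) != len(idx):
                raise ValueError("informative_indices must be distinct")
            if any(not 1 <= i <= n_feat for i in idx):
                raise ValueError(
                    f"informative_indices must lie in 1..{n_feat}"
                )
            self.informative_indices = idx

    def _validate_levels(self) -> None:
        for ch in CHANNELS:
            row = self.day_level_table.loc[ch.name]
            lo, hi = ch.detection_range
            if ((row < lo) | (row > hi)).any():
                raise ValueError(
                    f"day levels for {ch.name} outside detection range "
                    f"[{lo}, {hi}]"
                )

    @property
    def n_features(self) -> int:
        return self.n_timepoints * len(self.channels)


@dataclass(frozen=True)
class GroundTruth:
    """Record of an embedded sparse linear label construction."""

    informative_indices: tuple[int, ...]
    coefficients: tuple[float, ...]
    intercept: float
    day_of_sample: tuple[int, ...]
    label_noise_sd: float
    seed: int


def simulate_acquisition(
    warehouse_id: str,
    day: int,
    config: WarehouseSimConfig,
    rng: np.random.Generator,
) -> AcquisitionRecord:
    """Simulate one 500 s acquisition for one warehouse on one day.

    Each channel rises (or falls) exponentially from its ambient baseline
    toward the day's equilibrium level with time constant
    ``rise_time_constant``; Gaussian noise is added per timepoint and the
    trace is clipped to the channel's detection range.
    """
    day = int(day)
    if day not in config.days:
        raise ValueError(f"day {day} not in configured days {config.days}")
    t = np.arange(config.n_timepoints, dtype=float)
    tau = config.rise_time_constant
    approach = 1.0 - np.exp(-t / tau) if tau > 0 else np.ones_like(t)
    columns = []
    for ch in CHANNELS:
        level = float(config.day_level_table.loc[ch.name, day])
        baseline = AMBIENT_BASELINES[ch.name]
        if ch.name == "Temperature":
            baseline = level = config.baseline_temperature
        elif ch.name == "Humidity":
            baseline = level = config.baseline_humidity
        trace = baseline + (level - baseline) * approach
        sd = config.noise_sd.get(ch.name, 0.0)
        if sd > 0:
            trace = trace + rng.normal(0.0, sd, size=config.n_timepoints)
        lo, hi = ch.detection_range
        columns.append(np.clip(trace, lo, hi))
    return AcquisitionRecord(
        values=np.column_stack(columns), warehouse_id=str(warehouse_id), day=day
    )


def _default_informative_indices(
    config: WarehouseSimConfig, rng: np.random.Generator
) -> tuple[int, ...]:
    """Pick informative variables from gas-channel plateau timepoints.

    Late timepoints (past ~3 time constants) are preferred so the chosen
    features carry strong day-dependence.
    """
    t_min = int(min(3 * config.rise_time_constant, 0.6 * config.n_timepoints))
    candidates = []
    for name in ("CO2", "C2H4", "O2", "VOC"):
        lo, _hi = get_channel(name).flattened_range
        candidates.extend(range(lo + t_min, lo + config.n_timepoints))
    chosen = rng.choice(len(candidates), size=config.n_informative, replace=False)
    return tuple(sorted(candidates[i] for i in chosen))


def simulate_dataset(config: WarehouseSimConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate the full study: one flattened sample per (warehouse, day).

    Returns the dataset (labels = day, or the embedded linear response
    when ``embed_signal`` is set) and the ground-truth sidecar.
    """
    rng = np.random.default_rng(config.seed)
    rows, days, ids = [], [], []
    for w in range(1, config.n_warehouses + 1):
        warehouse_id = f"W{w}"
        for day in config.days:
            record = simulate_acquisition(warehouse_id, day, config, rng)
            rows.append(flatten_record(record))
            days.append(day)
            ids.append(f"{warehouse_id}_d{day}")
    features = np.vstack(rows)
    days_arr = np.asarray(days, dtype=int)

    if config.embed_signal:
        if config.informative_indices is None:
            indices = _default_informative_indices(config, rng)
        else:
            indices = config.informative_indices
        cols = features[:, [i - 1 for i in indices]]
        if config.informative_coefficients is None:
            raw = rng.normal(0.0, 1.0, size=len(indices))
            z = cols @ raw
            span = z.max() - z.min()
            if span <= 0:
                raise ValueError("embedded signal is degenerate (constant)")
            # affine-rescale so the noiseless response spans 1..8 (day-like)
            scale = 7.0 / span
            coefficients = tuple(float(c) for c in raw * scale)
            intercept = float(1.0 - scale * z.min())
        else:
            if len(config.informative_coefficients) != len(indices):
                raise ValueError(
                    "informative_coefficients must match informative_indices"
                )
            coefficients = tuple(float(c) for c in config.informative_coefficients)
            intercept = 0.0
        labels = intercept + cols @ np.asarray(coefficients)
        if config.label_noise_sd > 0:
            labels = labels + rng.normal(
                0.0, config.label_noise_sd, size=len(labels)
            )
    else:
        indices, coefficients, intercept = (), (), 0.0
        labels = days_arr.astype(float)

    dataset = Dataset(
        features=features,
        days=days_arr,
        sample_ids=ids,
        labels=np.asarray(labels, dtype=float),
    )
    truth = GroundTruth(
        informative_indices=tuple(indices),
        coefficients=coefficients,
        intercept=float(intercept),
        day_of_sample=tuple(int(d) for d in days_arr),
        label_noise_sd=float(config.label_noise_sd if config.embed_signal else 0.0),
        seed=int(config.seed),
    )
    return dataset, truth
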