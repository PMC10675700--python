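"""Synthetic sample records, thermal scenes, and dataset splits.

The farm dataset behind the inversion model (environment sensors + IR vulva
temperature + rectal thermometer readings) is not publicly deposited, so
this module generates data with the same statistical structure: a rectal
temperature drawn from a physiological range, environment drawn uniformly,
and a vulva surface temperature coupled to both through a documented
functional form with instrument-grade noise and an optional contaminated
(outlier) fraction mimicking equipment glitches and animal movement.

The coupling is declared plumbing — the real relationship is unknown — and
is fully parameterised so experiments are self-describing:

    t_vulva = t_rectal − b_core − b_at·max(0, t_rectal − at)
              − b_rh·(rh/100) + b_ai·log1p(ai) + ε,   ε ~ N(0, ir_noise²)

Sensor noise defaults follow the instrument accuracies of the acquisition
hardware: ±0.3 °C for the ambient thermometer, ±3 % for the hygrometer, and
±2 °C for the IR camera read as a ~2σ envelope (σ = 1 °C).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ConfigurationError, GeometryError
from .thermal import RegionMask, TemperatureMatrix

__all__ = [
    "SampleRecord",
    "GeneratorConfig",
    "generate_samples",
    "generate_thermal_scene",
    "split_dataset",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
    "FEATURE_COLUMNS",
    "TARGET_COLUMN",
]

#: Feature vector order used everywhere downstream (regression inputs).
FEATURE_COLUMNS = ("at_c", "rh_pct", "ai_lux", "t_vulva_c")
TARGET_COLUMN = "t_rectal_c"

CSV_COLUMNS = ("animal_id", "timestamp", "at_c", "rh_pct", "ai_lux",
               "t_vulva_c", "t_rectal_c", "is_outlier")


@dataclass(frozen=True)
class SampleRecord:
    """One observation: environment, vulva surface temp, rectal reference."""

    animal_id: str
    timestamp: str
    at_c: float
    rh_pct: float
    ai_lux: float
    t_vulva_c: float
    t_rectal_c: float | None = None
    is_outlier: bool = False


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic population and its sensors.

    Ranges are (low, high) uniform bounds.  ``b_*`` are the coupling
    coefficients of the vulva-temperature model; noise fields are Gaussian
    standard deviations.  ``outlier_fraction`` of records get their vulva
    temperature shifted by ±``outlier_shift_c`` (sign seeded) and are
    flagged ``is_outlier`` as generator ground truth.
    """

    n: int = 1000
    seed: int = 0
    rectal_mean_c: float = 38.6
    rectal_sd_c: float = 0.4
    rectal_range_c: tuple[float, float] = (37.0, 41.0)
    at_range_c: tuple[float, float] = (5.0, 30.0)
    rh_range_pct: tuple[float, float] = (40.0, 90.0)
    ai_range_lux: tuple[float, float] = (50.0, 500.0)
    b_core: float = 2.0
    b_at: float = 0.1
    b_rh: float = 0.5
    b_ai: float = 0.05
    sensor_noise_at_c: float = 0.3
    sensor_noise_rh_pct: float = 3.0
    ir_noise_c: float = 1.0
    outlier_fraction: float = 0.0
    outlier_shift_c: float = 3.0
    n_animals: int = 20

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigurationError(
                f"outlier_fraction must lie in [0, 1], got {self.outlier_fraction}"
            )
        for name in ("rectal_range_c", "at_range_c", "rh_range_pct",
                     "ai_range_lux"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(
                    f"{name} must be a nonempty (low, high) range, got ({lo}, {hi})"
                )
        lo, hi = self.rh_range_pct
        if lo < 0 or hi > 100:
            raise ConfigurationError(
                f"rh_range_pct must stay within [0, 100], got ({lo}, {hi})"
            )
        if self.ai_range_lux[0] < 0:
            raise ConfigurationError(
                f"ai_range_lux must be nonnegative, got {self.ai_range_lux}"
            )
        for name in ("rectal_sd_c", "sensor_noise_at_c", "sensor_noise_rh_pct",
                     "ir_noise_c"):
            if getattr(self, name) < 0:
                raise ConfigurationError(
                    f"{name} must be >= 0, got {getattr(self, name)}"
                )
        if self.n_animals < 1:
            raise ConfigurationError(
                f"n_animals must be >= 1, got {self.n_animals}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def vulva_surface_temperature(t_rectal, at_c, rh_pct, ai_lux,
                              config: GeneratorConfig):
    """Deterministic part of the vulva-temperature coupling (no noise)."""
    t_rectal = np.asarray(t_rectal, dtype=float)
    return (t_rectal
            - config.b_core
            - config.b_at * np.maximum(0.0, t_rectal - np.asarray(at_c, float))
            - config.b_rh * (np.asarray(rh_pct, float) / 100.0)
            + config.b_ai * np.log1p(np.asarray(ai_lux, float)))


def generate_samples(config: GeneratorConfig) -> list[SampleRecord]:
    """Draw ``config.n`` seeded records; identical seed → identical output.

    Exactly ``round(n · outlier_fraction)`` records are flagged as
    outliers.  Timestamps are deterministic (10-minute cadence from a fixed
    trial start), never wall clock.
    """
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return []

    lo, hi = config.rectal_range_c
    if config.rectal_sd_c == 0:
        t_rectal = np.full(n, float(np.clip(config.rectal_mean_c, lo, hi)))
    else:
        a = (lo - config.rectal_mean_c) / config.rectal_sd_c
        b = (hi - config.rectal_mean_c) / config.rectal_sd_c
        t_rectal = _sps.truncnorm.rvs(
            a, b, loc=config.rectal_mean_c, scale=config.rectal_sd_c,
            size=n, random_state=rng)

    at_true = rng.uniform(*config.at_range_c, size=n)
    rh_true = rng.uniform(*config.rh_range_pct, size=n)
    ai = rng.uniform(*config.ai_range_lux, size=n)

    t_vulva = vulva_surface_temperature(t_rectal, at_true, rh_true, ai, config)
    t_vulva = t_vulva + rng.normal(0.0, 1.0, size=n) * config.ir_noise_c

    at_meas = at_true + rng.normal(0.0, 1.0, size=n) * config.sensor_noise_at_c
    rh_meas = np.clip(
        rh_true + rng.normal(0.0, 1.0, size=n) * config.sensor_noise_rh_pct,
        0.0, 100.0)

    n_out = int(round(n * config.outlier_fraction))
    outlier_idx = rng.permutation(n)[:n_out]
    signs = rng.choice((-1.0, 1.0), size=n_out)
    is_outlier = np.zeros(n, dtype=bool)
    is_outlier[outlier_idx] = True
    t_vulva[outlier_idx] += signs * config.outlier_shift_c

    base = pd.Timestamp("2023-09-01T08:00:00")
    records = []
    for i in range(n):
        records.append(SampleRecord(
            animal_id=f"sow{(i % config.n_animals) + 1:03d}",
            timestamp=(base + pd.Timedelta(minutes=10 * i)).isoformat(),
            at_c=float(at_meas[i]),
            rh_pct=float(rh_meas[i]),
            ai_lux=float(ai[i]),
            t_vulva_c=float(t_vulva[i]),
            t_rectal_c=float(t_rectal[i]),
            is_outlier=bool(is_outlier[i]),
        ))
    return records


def generate_thermal_scene(height: int, width: int,
                           roi_center: tuple[float, float],
                           roi_axes: tuple[float, float],
                           background_c: float, roi_c: float,
                           noise_sd_c: float, seed: int,
                           ) -> tuple[TemperatureMatrix, RegionMask]:
    """Build a synthetic IR scene: warm elliptical ROI on a cool background.

    ``roi_center`` is (cx, cy) and ``roi_axes`` (ax, ay) in pixel-center
    coordinates; pixel (row i, col j) belongs to the ROI iff
    ``((j−cx)/ax)² + ((i−cy)/ay)² ≤ 1`` (boundary inclusive).  The matrix is
    background plus the ROI plateau plus seeded Gaussian noise.
    """
    if height < 1 or width < 1:
        raise GeometryError(f"grid must be at least 1x1, got {height}x{width}")
    cx, cy = roi_center
    ax, ay = roi_axes
    if ax <= 0 or ay <= 0:
        raise GeometryError(f"ellipse axes must be positive, got ({ax}, {ay})")
    if not (0 <= cx - ax and cx + ax <= width - 1
            and 0 <= cy - ay and cy + ay <= height - 1):
        raise GeometryError(
            f"ellipse center ({cx}, {cy}) axes ({ax}, {ay}) does not fit "
            f"inside the {height}x{width} grid"
        )
    if not roi_c > background_c:
        raise GeometryError(
            f"roi_c ({roi_c}) must exceed background_c ({background_c})"
        )
    jj, ii = np.meshgrid(np.arange(width), np.arange(height))
    inside = ((jj - cx) / ax) ** 2 + ((ii - cy) / ay) ** 2 <= 1.0
    values = np.full((height, width), float(background_c))
    values[inside] = float(roi_c)
    if noise_sd_c > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_c, size=values.shape)
    return TemperatureMatrix(values), RegionMask(inside.astype(np.uint8))


def split_dataset(records: Sequence, ratios: tuple[float, float, float] = (8, 1, 1),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded shuffle-and-partition into train/val/test.

    Ratios are normalised internally; sizes are ``floor(n·r_train)``,
    ``floor(n·r_val)``, remainder to test — deterministic and exhaustive.
    """
    n = len(records)
    if n == 0:
        raise ConfigurationError("cannot split an empty record sequence")
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ConfigurationError(
            f"ratios must be three positive numbers, got {ratios}"
        )
    total = float(sum(ratios))
    n_train = int(np.floor(n * ratios[0] / total))
    n_val = int(np.floor(n * ratios[1] / total))
    perm = np.random.default_rng(seed).permutation(n)
    as_list = list(records)
    train = [as_list[i] for i in perm[:n_train]]
    val = [as_list[i] for i in perm[n_train:n_train + n_val]]
    test = [as_list[i] for i in perm[n_train + n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# CSV round trip

def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for row in frame.itertuples(index=False):
        rectal = getattr(row, "t_rectal_c", None)
        records.append(SampleRecord(
            animal_id=str(row.animal_id),
            timestamp=str(row.timestamp),
            at_c=float(row.at_c),
            rh_pct=float(row.rh_pct),
            ai_lux=float(row.ai_lux),
            t_vulva_c=float(row.t_vulva_c),
            t_rectal_c=None if rectal is None or pd.isna(rectal) else float(rectal),
            is_outlier=bool(getattr(row, "is_outlier", False)),
        ))
    return records


def write_records_csv(records: Sequence[SampleRecord], path,
                      config: GeneratorConfig | None = None,
                      extra_comments: Sequence[str] = ()) -> None:
    """Write records with `#`-prefixed comment lines carrying provenance."""
    frame = records_to_frame(records)
    buf = io.StringIO()
    if config is not None:
        buf.write(f"# generator_config: {config.to_dict()}\n")
    for line in extra_comments:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_records_csv(path) -> list[SampleRecord]:
    frame = pd.read_csv(path, comment="#")
    return frame_to_records(frame)
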