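"""Temperature-matrix and region-mask I/O, and ROI temperature extraction.

A radiometric thermal camera exports a *temperature matrix*: an H×W grid of
per-pixel surface temperatures in °C.  A segmentation network (out of scope
here) supplies a binary *region mask* over the visible-light image marking
the sow's vulva; mapping that mask onto the temperature matrix and reducing
the masked pixels to a single statistic yields the surface temperature that
feeds the inversion regression.

Conventions: 0-based row-major pixel indexing, pixel centers at integer
coordinates.  Matrices may contain ``nan`` for dead/missing pixels; those
are excluded from statistics.  Masks are strictly binary after loading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyRegionError, FormatError, ShapeMismatchError

__all__ = [
    "TemperatureMatrix",
    "RegionMask",
    "RegionTemperature",
    "read_temperature_matrix",
    "write_temperature_matrix",
    "read_mask",
    "write_mask",
    "resample_mask",
    "extract_region_temperature",
]


@dataclass(frozen=True)
class TemperatureMatrix:
    """H×W grid of °C values; ``nan`` marks missing pixels."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise FormatError("temperature matrix must be a nonempty 2-D grid")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RegionMask:
    """H×W binary grid; 1 marks region-of-interest pixels."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise FormatError("region mask must be a nonempty 2-D grid")
        object.__setattr__(self, "values", (v != 0).astype(np.uint8))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class RegionTemperature:
    """The scalar ROI statistic with its provenance."""

    stat_name: str
    value_c: float
    pixel_count: int


def read_temperature_matrix(path) -> TemperatureMatrix:
    """Parse a plain CSV grid of floats (``nan`` allowed) into a matrix.

    Ragged rows, empty files and non-numeric cells raise :class:`FormatError`
    naming the 1-based line number.  Comment lines starting ``#`` are
    ignored (they carry provenance metadata when written by this package).
    """
    rows: list[list[float]] = []
    width = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            try:
                row = [float(c) for c in cells]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value at line {lineno}"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"(expected {width} values, got {len(row)})"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty temperature matrix")
    return TemperatureMatrix(np.array(rows, dtype=float))


def write_temperature_matrix(matrix: TemperatureMatrix, path,
                             header: str | None = None) -> None:
    """Write the grid as CSV with ``%.6f`` cells (``nan`` for missing)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for row in matrix.values:
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")


def read_mask(path) -> RegionMask:
    """Load a binary mask from an 8-bit PNG (0=background, nonzero=ROI)
    or a CSV grid of 0/1, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        img = Image.open(path).convert("L")
        return RegionMask(np.asarray(img))
    grid = read_temperature_matrix(path).values
    bad = ~np.isin(grid, (0.0, 1.0))
    if bad.any():
        raise FormatError(f"{path}: CSV mask values must be 0 or 1")
    return RegionMask(grid)


def write_mask(mask: RegionMask, path) -> None:
    """Write a mask as PNG (0/255) or CSV (0/1) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(path)
        return
    with open(path, "w", encoding="utf-8") as fh:
        for row in mask.values:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def resample_mask(mask: RegionMask, target_h: int, target_w: int) -> RegionMask:
    """Nearest-neighbour resample with pixel-center alignment.

    Output pixel i' reads input pixel ``floor((i' + 0.5) * H / H')``; when
    the back-projected center is exactly equidistant between two input
    pixels the larger index wins.  Output is strictly binary.
    """
    if target_h < 1 or target_w < 1:
        raise ShapeMismatchError("target mask dimensions must be >= 1")
    h, w = mask.values.shape
    if (target_h, target_w) == (h, w):
        return RegionMask(mask.values.copy())
    rows = np.minimum((np.floor((np.arange(target_h) + 0.5) * h / target_h))
                      .astype(int), h - 1)
    cols = np.minimum((np.floor((np.arange(target_w) + 0.5) * w / target_w))
                      .astype(int), w - 1)
    return RegionMask(mask.values[np.ix_(rows, cols)])


_STAT_NAMES = ("max", "mean")


def extract_region_temperature(matrix: TemperatureMatrix, mask: RegionMask,
                               stat: str = "max") -> RegionTemperature:
    """Reduce the masked temperature pixels to one statistic.

    ``stat`` is ``"max"``, ``"mean"`` or ``"p<k>"`` / ``"percentile_<k>"``
    for the k-th percentile (e.g. ``"p90"``).  The mask must already match
    the matrix dimensions (use :func:`resample_mask` first) and select at
    least one finite pixel.
    """
    if mask.values.shape != matrix.values.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.values.shape} does not match matrix shape "
            f"{matrix.values.shape}; resample the mask first"
        )
    if mask.pixel_count == 0:
        raise EmptyRegionError("mask selects no pixels")
    selected = matrix.values[mask.values != 0]
    finite = selected[np.isfinite(selected)]
    if finite.size == 0:
        raise EmptyRegionError("all masked pixels are missing (nan)")

    name = stat.lower().strip()
    if name == "max":
        value = float(finite.max())
    elif name == "mean":
        value = float(finite.mean())
    elif name.startswith(("p", "percentile_")):
        q_str = name.removeprefix("percentile_").removeprefix("p")
        try:
            q = float(q_str)
        except ValueError:
            raise FormatError(f"unrecognised statistic {stat!r}") from None
        if not 0 <= q <= 100:
            raise FormatError(f"percentile {q} outside [0, 100]")
        value = float(np.percentile(finite, q))
        name = f"p{q_str}"
    else:
        raise FormatError(f"unrecognised statistic {stat!r}")
    return RegionTemperature(stat_name=name, value_c=value,
                             pixel_count=int(finite.size))
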