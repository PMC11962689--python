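"""Core data containers for force-volume maps and grayscale images.

All mechanical quantities are stored in SI units internally: piezo positions
and deflections in metres, forces in newtons, spring constants in N/m,
moduli in pascals.  Micrometre / nanonewton values are converted at the I/O
and CLI boundaries.  Grid pixel (0, 0) is the top-left corner, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CorruptRecordError

MIN_CURVE_SAMPLES = 16

__all__ = ["ForceCurve", "ForceVolumeMap", "ImageGray", "MIN_CURVE_SAMPLES"]


@dataclass
class ForceCurve:
    """One force-distance curve at a single grid pixel.

    Parameters
    ----------
    z_piezo
        Piezo positions along the approach (m), strictly increasing.
    deflection
        Cantilever deflection (m), same length as ``z_piezo``.
    spring_constant
        Cantilever stiffness k (N/m); force is ``k * deflection``.
    pixel
        (row, col) grid index of the curve.
    direction
        ``"approach"`` or ``"retract"``.  All analysis in this package
        uses approach curves.
    """

    z_piezo: np.ndarray
    deflection: np.ndarray
    spring_constant: float
    pixel: tuple[int, int] = (0, 0)
    direction: str = "approach"

    def __post_init__(self):
        self.z_piezo = np.asarray(self.z_piezo, dtype=np.float64)
        self.deflection = np.asarray(self.deflection, dtype=np.float64)
        if self.z_piezo.shape != self.deflection.shape:
            raise CorruptRecordError(
                f"pixel {self.pixel}: z_piezo has {self.z_piezo.size} samples "
                f"but deflection has {self.deflection.size}"
            )
        if self.z_piezo.size < MIN_CURVE_SAMPLES:
            raise CorruptRecordError(
                f"pixel {self.pixel}: curve has {self.z_piezo.size} samples, "
                f"minimum is {MIN_CURVE_SAMPLES}"
            )
        if not self.spring_constant > 0:
            raise CorruptRecordError("spring_constant must be > 0")
        if self.direction not in ("approach", "retract"):
            raise CorruptRecordError(f"unknown direction {self.direction!r}")
        if not np.all(np.isfinite(self.force)):
            raise CorruptRecordError(f"pixel {self.pixel}: non-finite force")

    @property
    def force(self) -> np.ndarray:
        """Force F = k * deflection (N)."""
        return self.spring_constant * self.deflection


@dataclass
class ForceVolumeMap:
    """A grid of force-distance curves plus acquisition metadata.

    ``setpoint`` is the force threshold (N) at which each approach stops;
    the mapping default is 1.5 nN.
    """

    rows: int
    cols: int
    pitch: float
    curves: list[ForceCurve] = field(repr=False)
    setpoint: float = 1.5e-9

    def __post_init__(self):
        if len(self.curves) != self.rows * self.cols:
            raise CorruptRecordError(
                f"{self.rows}x{self.cols} grid needs {self.rows * self.cols} "
                f"curves, got {len(self.curves)}"
            )
        if not self.pitch > 0:
            raise CorruptRecordError("pitch must be > 0")
        for c in self.curves:
            if c.force.max(initial=0.0) < 0.9 * self.setpoint:
                raise CorruptRecordError(
                    f"pixel {c.pixel}: max force below 0.9 x setpoint"
                )

    def curve_at(self, row: int, col: int) -> ForceCurve:
        return self.curves[row * self.cols + col]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


@dataclass
class ImageGray:
    """A single-channel image with a physical pixel scale (um per pixel)."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise CorruptRecordError("ImageGray requires a 2-D array")
        if not self.scale > 0:
            raise CorruptRecordError("scale must be > 0")
        if not np.all(np.isfinite(self.pixels.astype(np.float64, copy=False))):
            raise CorruptRecordError("non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
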