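"""Reconstruction-kernel models for photon-counting CT image quality analysis.

A CT reconstruction kernel is characterised here by the two spatial
frequencies at which its modulation transfer function (MTF) drops to 50%
and 10% of its zero-frequency value (rho50 and rho10, in line pairs per
centimetre).  From these two anchors a continuous monotone MTF is fitted
in closed form, and simple calibrated models predict background noise as
a function of kernel sharpness, iterative-reconstruction (QIR) strength
and radiation dose (CTDI).

The packaged kernel table covers the vendor's quantitative (Qr) kernel at
sharpness levels 36-76 together with the measured maximum edge slopes of
a 5 mm iodine-filled tube, which serve as reference inputs for the
sweep-level reporting utilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "KernelSpec",
    "MtfCurve",
    "AcquisitionSpec",
    "ExtrapolationWarning",
    "load_kernel_table",
    "kernel_from_table",
    "fit_mtf",
    "nyquist_frequency",
    "noise_sd_model",
    "relative_slope_difference",
    "QIR_NOISE_FACTORS",
    "NOISE_ANCHORS_HU",
    "NOISE_ANCHOR_CTDI_MGY",
    "NOISE_ANCHOR_QIR",
]

# Background noise SD (HU) measured at the calibration point: QIR-3, 3 mGy.
NOISE_ANCHORS_HU: dict[int, float] = {44: 16.0, 60: 38.0, 72: 77.0}
NOISE_ANCHOR_CTDI_MGY: float = 3.0
NOISE_ANCHOR_QIR: int = 3

# Noise ratios between QIR strengths, measured at Qr60 / 3 mGy (51, 38,
# 25 HU for QIR-2, -3, -4) and transferred multiplicatively to all kernels.
QIR_NOISE_FACTORS: dict[int, float] = {2: 51.0 / 38.0, 3: 1.0, 4: 25.0 / 38.0}

_CALIBRATED_SHARPNESS = (36, 76)


class ExtrapolationWarning(UserWarning):
    """Raised when a noise prediction leaves the calibrated sharpness range."""


@dataclass(frozen=True)
class KernelSpec:
    """A reconstruction kernel described by its MTF anchor frequencies.

    Parameters
    ----------
    name:
        Kernel label, e.g. ``"Qr60"``.
    sharpness_level:
        Integer sharpness level encoded in the kernel name (36-76 for the
        quantitative kernel family).
    rho50, rho10:
        Spatial frequencies (Lp/cm) at which the MTF falls to 50% and 10%.
    """

    name: str
    sharpness_level: int
    rho50: float
    rho10: float

    def __post_init__(self) -> None:
        if not (self.rho10 > self.rho50 > 0):
            raise ValueError(
                f"kernel {self.name!r}: require rho10 > rho50 > 0, "
                f"got rho50={self.rho50}, rho10={self.rho10}"
            )


@dataclass(frozen=True)
class MtfCurve:
    """Monotone Butterworth-type MTF, ``MTF(rho) = 1 / (1 + (rho/a)**b)``.

    ``a`` is a frequency scale in Lp/cm (equal to rho50) and ``b`` a
    dimensionless knee exponent; both follow in closed form from the
    (rho50, rho10) anchors.  The family has the flat low-frequency
    passband a quantitative CT kernel needs for HU fidelity, is 1 at zero
    frequency and strictly decreasing for positive frequency.
    """

    a: float
    b: float
    rho_max_eval: float = 50.0

    def __call__(self, rho: np.ndarray | float) -> np.ndarray | float:
        rho = np.abs(rho)
        return 1.0 / (1.0 + (rho / self.a) ** self.b)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition/reconstruction settings relevant to the noise model.

    ``keV_label`` records the virtual monoenergetic level (55 keV for all
    simulated angiography reconstructions) and is metadata only.
    """

    ctdi: float
    qir_level: int
    keV_label: float = 55.0
    voxel_mm: float = 0.4

    def __post_init__(self) -> None:
        if not self.ctdi > 0:
            raise ValueError(f"ctdi must be positive, got {self.ctdi}")
        if self.qir_level not in (2, 3, 4):
            raise ValueError(f"qir_level must be in {{2,3,4}}, got {self.qir_level}")
        if not self.voxel_mm > 0:
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")


def load_kernel_table() -> pd.DataFrame:
    """Return the packaged quantitative-kernel table.

    Columns: name, sharpness, rho50_lp_per_cm, rho10_lp_per_cm,
    max_slope_hu_per_mm, max_slope_sd_hu_per_mm, rel_diff_pct.
    """
    with resources.files("phantomiq.data").joinpath("kernel_table.csv").open() as fh:
        return pd.read_csv(fh)


def kernel_from_table(name: str) -> KernelSpec:
    """Look up a kernel by name (e.g. ``"Qr60"``) in the packaged table."""
    table = load_kernel_table()
    row = table[table["name"] == name]
    if row.empty:
        raise KeyError(f"unknown kernel {name!r}; known: {list(table['name'])}")
    r = row.iloc[0]
    return KernelSpec(
        name=str(r["name"]),
        sharpness_level=int(r["sharpness"]),
        rho50=float(r["rho50_lp_per_cm"]),
        rho10=float(r["rho10_lp_per_cm"]),
    )


def fit_mtf(kernel: KernelSpec) -> MtfCurve:
    """Fit the two-parameter monotone MTF through the kernel's anchors.

    Solving ``1/(1+(rho50/a)**b) = 0.5`` and ``1/(1+(rho10/a)**b) = 0.1``
    gives::

        a = rho50
        b = ln 9 / ln(rho10 / rho50)

    so both anchor constraints hold exactly for any rho10 > rho50 > 0.
    """
    b = math.log(9.0) / math.log(kernel.rho10 / kernel.rho50)
    return MtfCurve(a=kernel.rho50, b=b)


def nyquist_frequency(voxel_mm: float) -> float:
    """Nyquist limit of an image sampled at ``voxel_mm``, in Lp/cm.

    One line pair needs two samples, so the maximum representable spatial
    frequency is ``1 / (2 * voxel)``; 0.4 mm voxels give 12.5 Lp/cm.
    """
    if not voxel_mm > 0:
        raise ValueError(f"voxel size must be positive, got {voxel_mm}")
    voxel_cm = voxel_mm / 10.0
    return 1.0 / (2.0 * voxel_cm)


def _anchor_sd(sharpness: float) -> float:
    """Noise SD at the calibration point (QIR-3, 3 mGy) for any sharpness.

    Log-linear interpolation between the measured Qr44/Qr60/Qr72 anchors,
    extended by the end segments outside [44, 72].  Log-linear is the
    simplest monotone model consistent with all three printed values.
    """
    levels = np.array(sorted(NOISE_ANCHORS_HU), dtype=float)
    log_sd = np.log([NOISE_ANCHORS_HU[int(v)] for v in levels])
    if sharpness <= levels[0]:
        i = 0
    elif sharpness >= levels[-1]:
        i = len(levels) - 2
    else:
        i = int(np.searchsorted(levels, sharpness, side="right")) - 1
    slope = (log_sd[i + 1] - log_sd[i]) / (levels[i + 1] - levels[i])
    return float(np.exp(log_sd[i] + slope * (sharpness - levels[i])))


def noise_sd_model(kernel: KernelSpec, acq: AcquisitionSpec) -> float:
    """Predicted background noise SD (HU) for a kernel/QIR/dose combination.

    ``SD = anchor(sharpness at QIR-3, 3 mGy) * qir_factor * sqrt(3/ctdi)``:
    quantum noise scales with the inverse square root of dose, and the QIR
    strength rescales noise by the measured Qr60 ratios.  Kernels outside
    the calibrated sharpness range 36-76 trigger an
    :class:`ExtrapolationWarning` (the value is still returned).
    """
    lo, hi = _CALIBRATED_SHARPNESS
    if not (lo <= kernel.sharpness_level <= hi):
        warnings.warn(
            f"kernel sharpness {kernel.sharpness_level} outside calibrated "
            f"range [{lo}, {hi}]; noise prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    sd = _anchor_sd(kernel.sharpness_level)
    sd *= QIR_NOISE_FACTORS[acq.qir_level]
    sd *= math.sqrt(NOISE_ANCHOR_CTDI_MGY / acq.ctdi)
    return sd


def relative_slope_difference(
    slope_value: float, reference_slope: float, *, rounded: bool = True
) -> float:
    """Relative difference of an edge slope to a reference, in percent.

    ``100 * (slope - reference) / reference``; with ``rounded=True``
    (reporting convention) the result is rounded half-away-from-zero to an
    integer percent.
    """
    if reference_slope == 0:
        raise ZeroDivisionError("reference slope must be nonzero")
    pct = 100.0 * (slope_value - reference_slope) / reference_slope
    if not rounded:
        return pct
    return float(math.copysign(math.floor(abs(pct) + 0.5), pct))
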