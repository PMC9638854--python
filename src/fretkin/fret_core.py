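"""Per-pixel sensitized-emission FRET efficiency.

Two raw channels are acquired per frame: donor emission (I_D_raw) and
acceptor emission under donor excitation (I_F_raw, the FRET channel).
Donor fluorescence leaks into the FRET detection band; the bleedthrough
fraction beta is calibrated from a donor-only specimen as

    beta = I_bth / I_D

and the corrected FRET intensity and efficiency are

    I_FRET = I_F - beta * I_D
    eta    = I_FRET / (I_D + I_FRET)

where I_D and I_F are the smoothed, background-subtracted channels.  The
pipeline order is fixed: 5x5 moving-average smoothing, background
subtraction, bleedthrough correction, ratio.  Pixels whose denominator
falls below a configurable ADU threshold, or whose corrected FRET signal
is negative beyond floating error, are flagged invalid (NaN) rather than
silently clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "BleedthroughEstimate", "CorrectionConfig", "EfficiencyStack",
    "estimate_bleedthrough", "smooth", "compute_efficiency", "calibrate_floor",
]

#: numerical slack: eta within this of [0, 1] is clipped, beyond it invalid
_EPS = 1e-9


@dataclass(frozen=True)
class BleedthroughEstimate:
    beta: float
    n_pixels_used: int
    method: str = "ratio_of_means"

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n_pixels_used < 1:
            raise ValueError("bleedthrough estimate used no pixels")


@dataclass(frozen=True)
class CorrectionConfig:
    """Correction parameters for :func:`compute_efficiency`.

    Backgrounds are either scalars per channel (``bg_donor``/``bg_fret``)
    or a boolean ``background_roi`` over which the first frame's mean is
    taken per channel; one of the two must be provided.
    """

    beta: float
    kernel_size: int = 5
    bg_donor: float | None = None
    bg_fret: float | None = None
    background_roi: np.ndarray | None = None
    min_denominator: float = 1.0

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 1, got {self.kernel_size}")
        if self.min_denominator <= 0:
            raise ValueError("min_denominator must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def backgrounds(self, first_frame_donor, first_frame_fret) -> tuple[float, float]:
        if self.background_roi is not None:
            roi = np.asarray(self.background_roi, bool)
            if not roi.any():
                raise ValueError("background_roi is empty")
            return (float(first_frame_donor[roi].mean()),
                    float(first_frame_fret[roi].mean()))
        if self.bg_donor is None or self.bg_fret is None:
            raise ValueError(
                "no background specification: set bg_donor/bg_fret scalars "
                "or a background_roi"
            )
        return float(self.bg_donor), float(self.bg_fret)


@dataclass
class EfficiencyStack:
    """Per-pixel FRET efficiency per frame; invalid pixels are NaN."""

    eta: np.ndarray           # (T, Y, X), NaN where invalid
    valid: np.ndarray         # (T, Y, X) bool
    times_min: np.ndarray     # (T,)

    def __post_init__(self):
        finite = self.eta[self.valid]
        if finite.size and (np.nanmin(finite) < 0 or np.nanmax(finite) > 1):
            raise ValueError("valid efficiencies must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.eta.shape[0]


def smooth(image: np.ndarray, kernel_size: int) -> np.ndarray:
    """Moving-average filter with edge replication; kernel 1 is identity."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {kernel_size}")
    image = np.asarray(image, dtype=float)
    if kernel_size == 1:
        return image.copy()
    return uniform_filter(image, size=kernel_size, mode="nearest")


def estimate_bleedthrough(donor_image, bleedthrough_image, mask,
                          backgrounds=(0.0, 0.0)) -> BleedthroughEstimate:
    """Calibrate beta = I_bth / I_D from a donor-only image pair.

    Both images are background-subtracted and averaged over the mask
    before taking the ratio (ratio of means, robust to near-zero donor
    pixels).

    Raises
    ------
    ValueError
        Empty mask, or non-positive mean donor signal on the mask (a sign
        of a bad mask or background).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("bleedthrough mask is empty")
    bg_donor, bg_fret = backgrounds
    donor = np.asarray(donor_image, float)[mask] - bg_donor
    leak = np.asarray(bleedthrough_image, float)[mask] - bg_fret
    donor_mean = donor.mean()
    if donor_mean <= 0:
        raise ValueError(
            f"mean background-subtracted donor signal is {donor_mean:.3g} <= 0; "
            "check mask and backgrounds"
        )
    beta = max(float(leak.mean() / donor_mean), 0.0)
    return BleedthroughEstimate(beta=beta, n_pixels_used=int(mask.sum()))


def compute_efficiency(raw, cfg: CorrectionConfig) -> EfficiencyStack:
    """Run the full correction pipeline on a two-channel time-lapse.

    Per frame: smooth both channels, subtract backgrounds, correct the
    FRET channel for donor bleedthrough, and form
    eta = I_FRET / (I_D + I_FRET).  Pixels with a denominator below
    ``cfg.min_denominator`` or eta outside [0, 1] beyond floating error
    are invalid (NaN).  An all-invalid frame is kept but logged.
    """
    data = np.asarray(raw.data, dtype=float)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError(f"expected a (T, 2, Y, X) stack, got shape {data.shape}")
    bg_donor, bg_fret = cfg.backgrounds(data[0, 0], data[0, 1])

    n_frames = data.shape[0]
    eta = np.full((n_frames,) + data.shape[2:], np.nan)
    valid = np.zeros_like(eta, dtype=bool)
    for i in range(n_frames):
        i_d = smooth(data[i, 0], cfg.kernel_size) - bg_donor
        i_f = smooth(data[i, 1], cfg.kernel_size) - bg_fret
        i_fret = i_f - cfg.beta * i_d
        denom = i_d + i_fret
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = i_fret / denom
        ok = (denom >= cfg.min_denominator) & (ratio >= -_EPS) & (ratio <= 1 + _EPS)
        eta[i, ok] = np.clip(ratio[ok], 0.0, 1.0)
        valid[i] = ok
        if not ok.any():
            logger.warning("frame %d: all pixels invalid", i)

    times = np.asarray(raw.frame_interval_min, float) * np.arange(n_frames) \
        if np.isscalar(raw.frame_interval_min) else np.asarray(raw.frame_interval_min)
    return EfficiencyStack(eta=eta, valid=valid, times_min=times)


def calibrate_floor(eta_values, method: str = "moments",
                    n_bins: int = 100) -> float:
    """Sensor floor from an ATP-insensitive-sensor efficiency sample.

    Fits a Gaussian to the sample -- either by moments (sample mean and
    SD) or by least squares on a histogram -- and returns mean - 2 * SD,
    the lowest efficiency treated as a reliable sensor reading.

    Raises
    ------
    ValueError
        Fewer than 100 values, or an unknown method.
    """
    values = np.asarray(eta_values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise ValueError(f"need >= 100 efficiency values, got {values.size}")

    if method == "moments":
        mean, sd = float(values.mean()), float(values.std(ddof=1))
    elif method == "histogram":
        counts, edges = np.histogram(values, bins=n_bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, mu, sigma, amp):
            return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        p0 = (values.mean(), max(values.std(), 1e-6),
              1.0 / (np.sqrt(2 * np.pi) * max(values.std(), 1e-6)))
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        mean, sd = float(popt[0]), abs(float(popt[1]))
    else:
        raise ValueError(f"unknown method {method!r}; use 'moments' or 'histogram'")

    if sd == 0:
        logger.warning("degenerate sample (SD = 0); floor equals the mean")
        return mean
    return mean - 2.0 * sd
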