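"""Ground-truth-annotated synthetic two-channel FRET time-lapses.

A virtual wing pouch is laid out as a rectangle crossed by two
stripes: a vertical stripe just anterior of the AP compartment boundary
(APB) and a horizontal stripe on the DV boundary (DVB); their
intersection is the organizer crossing.  The four remaining quadrants
are the non-organizer sub-regions (NO_DA, NO_DP, NO_VA, NO_VP; dorsal is
the top of the image, anterior the left).  Each region's true efficiency
follows its own four-parameter logistic decay after drug addition, flat
at the plateau before.

Frames are rendered by inverting the analysis formulas: a pixel of true
efficiency eta and corrected total intensity T emits donor
I_D = (1 - eta) * T and acceptor I_FRET = eta * T; raw channels add the
channel backgrounds, donor bleedthrough (beta * I_D into the FRET
channel) and seeded additive Gaussian noise, so the analysis pipeline
can be validated by round trip and parameter recovery.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .kinetics import four_pl
from .roi_regions import RegionTrace

__all__ = [
    "SceneSpec", "RegionKinetics", "StripeGeometry", "PouchLabels",
    "SceneGroundTruth", "RawTimelapse", "build_pouch_labels", "true_eta",
    "make_ground_truth", "render_frames", "render_calibration_pair",
    "simulate_cohort_traces", "DEFAULT_REGION_KINETICS",
]

LABEL_CODES = {
    "outside": 0, "NO_DA": 1, "NO_DP": 2, "NO_VA": 3, "NO_VP": 4,
    "APB": 5, "DVB": 6, "ORG": 7,
}


@dataclass
class RawTimelapse:
    """Two-channel raw stack: data is (T, C, Y, X), channel 0 donor, 1 FRET."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    drug_time_min: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != 2:
            raise ValueError(f"expected (T, 2, Y, X), got shape {self.data.shape}")

    @property
    def times_min(self) -> np.ndarray:
        return self.frame_interval_min * np.arange(self.data.shape[0])


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and acquisition parameters of a synthetic scene.

    Defaults emulate the live-imaging conditions the analysis was built
    for: a ~2 h time-lapse (130 frames at 1 frame/min), drug added at
    10 min, 0.22 um pixels (60x objective on an EMCCD), moderate additive
    Gaussian noise.
    """

    height_px: int = 128
    width_px: int = 128
    pixel_size_um: float = 0.22
    n_frames: int = 130
    frame_interval_min: float = 1.0
    drug_time_min: float = 10.0
    beta: float = 0.15
    bg_donor: float = 100.0
    bg_fret: float = 120.0
    total_intensity: float = 2000.0
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.height_px < 1 or self.width_px < 1 or self.n_frames < 1:
            raise ValueError("pixel counts and frame count must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if not 0 <= self.beta < 1:
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model != "gaussian":
            raise ValueError(f"unsupported noise model {self.noise_model!r}")

    @property
    def times_min(self) -> np.ndarray:
        return self.frame_interval_min * np.arange(self.n_frames)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegionKinetics:
    """4PL decay parameters of one region (hill < 0 for a decay)."""

    label: str
    base: float = 0.2827
    max_eta: float = 0.6
    t_half: float = 30.0
    hill: float = -2.3

    def __post_init__(self):
        if not 0 < self.base < self.max_eta <= 1:
            raise ValueError(
                f"require 0 < base < max_eta <= 1, got base={self.base}, "
                f"max_eta={self.max_eta} for region {self.label!r}"
            )
        if self.t_half <= 0:
            raise ValueError(f"t_half must be positive for region {self.label!r}")


#: Default regional kinetics: organizer stripes decline more slowly than
#: the surrounding pouch under OxPhos inhibition (t1/2 45 vs 30 min,
#: starting plateau ~0.6, Hill -2.3, floor at the 0.2827 sensor floor).
DEFAULT_REGION_KINETICS: tuple[RegionKinetics, ...] = (
    RegionKinetics("APB", t_half=45.0),
    RegionKinetics("DVB", t_half=45.0),
    RegionKinetics("ORG", t_half=45.0),
    RegionKinetics("NO_DA", t_half=30.0),
    RegionKinetics("NO_DP", t_half=30.0),
    RegionKinetics("NO_VA", t_half=30.0),
    RegionKinetics("NO_VP", t_half=30.0),
)


@dataclass(frozen=True)
class StripeGeometry:
    """Stripe positions/widths in um; None positions mean the midlines.

    ``ap_pos_um`` is the column of the vertical (APB) stripe centre --
    conventionally just anterior of the AP compartment boundary --
    ``dv_pos_um`` the row of the horizontal (DVB) stripe centre.
    """

    ap_width_um: float = 20.0
    dv_width_um: float = 20.0
    ap_pos_um: float | None = None
    dv_pos_um: float | None = None
    margin_um: float = 0.0


@dataclass
class PouchLabels:
    """Region label image plus per-region boolean masks.

    The stripe crossing carries the ORG code in ``label_image``; the
    ``masks`` entries for APB and DVB include it, recording membership in
    both stripes.
    """

    label_image: np.ndarray
    masks: dict[str, np.ndarray]


def build_pouch_labels(spec: SceneSpec,
                       geometry: StripeGeometry | None = None) -> PouchLabels:
    """Rasterise the stripe layout of the virtual pouch.

    Raises
    ------
    ValueError
        Non-positive stripe widths, or a stripe extending outside the
        pouch (the error names the offending stripe).
    """
    geometry = geometry or StripeGeometry()
    h, w, px = spec.height_px, spec.width_px, spec.pixel_size_um
    ap_pos = geometry.ap_pos_um if geometry.ap_pos_um is not None else 0.5 * w * px
    dv_pos = geometry.dv_pos_um if geometry.dv_pos_um is not None else 0.5 * h * px

    for name, width in (("APB", geometry.ap_width_um), ("DVB", geometry.dv_width_um)):
        if width <= 0:
            raise ValueError(f"{name} stripe width must be positive, got {width}")

    margin = int(round(geometry.margin_um / px))
    ap_lo = int(round((ap_pos - 0.5 * geometry.ap_width_um) / px))
    ap_hi = ap_lo + int(round(geometry.ap_width_um / px))
    dv_lo = int(round((dv_pos - 0.5 * geometry.dv_width_um) / px))
    dv_hi = dv_lo + int(round(geometry.dv_width_um / px))
    if ap_lo < margin or ap_hi > w - margin:
        raise ValueError(f"APB stripe [{ap_lo}, {ap_hi}) px exceeds pouch bounds")
    if dv_lo < margin or dv_hi > h - margin:
        raise ValueError(f"DVB stripe [{dv_lo}, {dv_hi}) px exceeds pouch bounds")

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pouch = (rr >= margin) & (rr < h - margin) & (cc >= margin) & (cc < w - margin)
    in_ap = (cc >= ap_lo) & (cc < ap_hi) & pouch
    in_dv = (rr >= dv_lo) & (rr < dv_hi) & pouch

    labels = np.zeros((h, w), dtype=np.uint8)
    # dorsal = top (row < dv stripe), anterior = left (col < ap stripe)
    quad = ~in_ap & ~in_dv & pouch
    labels[quad & (rr < dv_lo) & (cc < ap_lo)] = LABEL_CODES["NO_DA"]
    labels[quad & (rr < dv_lo) & (cc >= ap_hi)] = LABEL_CODES["NO_DP"]
    labels[quad & (rr >= dv_hi) & (cc < ap_lo)] = LABEL_CODES["NO_VA"]
    labels[quad & (rr >= dv_hi) & (cc >= ap_hi)] = LABEL_CODES["NO_VP"]
    labels[in_ap & ~in_dv] = LABEL_CODES["APB"]
    labels[in_dv & ~in_ap] = LABEL_CODES["DVB"]
    labels[in_ap & in_dv] = LABEL_CODES["ORG"]

    masks = {
        "APB": in_ap, "DVB": in_dv, "ORG": in_ap & in_dv,
        "NO_DA": labels == LABEL_CODES["NO_DA"],
        "NO_DP": labels == LABEL_CODES["NO_DP"],
        "NO_VA": labels == LABEL_CODES["NO_VA"],
        "NO_VP": labels == LABEL_CODES["NO_VP"],
        "NO": (labels >= LABEL_CODES["NO_DA"]) & (labels <= LABEL_CODES["NO_VP"]),
        "outside": labels == LABEL_CODES["outside"],
    }
    return PouchLabels(label_image=labels, masks=masks)


def true_eta(kin: RegionKinetics, t_min) -> float | np.ndarray:
    """True efficiency of a region at t minutes after drug addition.

    Thin wrapper over the 4PL with the region's parameters; f(0) is the
    continuous limit (the plateau ``max_eta`` for a decay).
    """
    return four_pl(t_min, kin.base, kin.max_eta, kin.t_half, kin.hill)


@dataclass
class SceneGroundTruth:
    """Per-pixel truth of a rendered scene.

    ``eta_maps`` holds the true efficiency per frame (NaN outside the
    pouch); pre-drug frames sit at each region's plateau.
    """

    labels: PouchLabels
    kinetics: dict[str, RegionKinetics]
    eta_maps: np.ndarray      # (T, Y, X)
    times_min: np.ndarray


def _region_kinetics_map(kinetics) -> dict[str, RegionKinetics]:
    table = {k.label: k for k in kinetics}
    missing = [name for name in ("APB", "DVB", "ORG", "NO_DA", "NO_DP",
                                 "NO_VA", "NO_VP") if name not in table]
    if missing:
        raise ValueError(f"kinetics table missing regions: {missing}")
    return table


def make_ground_truth(spec: SceneSpec, labels: PouchLabels,
                      kinetics=DEFAULT_REGION_KINETICS) -> SceneGroundTruth:
    """Evaluate every region's 4PL on the frame grid into truth maps."""
    table = _region_kinetics_map(kinetics)
    times = spec.times_min
    t_since = times - spec.drug_time_min
    eta_maps = np.full((spec.n_frames, spec.height_px, spec.width_px), np.nan)
    for name, kin in table.items():
        mask = labels.masks[name]
        if name in ("APB", "DVB"):
            mask = mask & ~labels.masks["ORG"]  # crossing owned by ORG
        if not mask.any():
            continue
        curve = np.where(t_since > 0,
                         true_eta(kin, np.maximum(t_since, 0.0)), kin.max_eta)
        eta_maps[:, mask] = curve[:, None]
    return SceneGroundTruth(labels=labels, kinetics=table,
                            eta_maps=eta_maps, times_min=times)


def render_frames(spec: SceneSpec, truth: SceneGroundTruth) -> RawTimelapse:
    """Render raw donor/FRET channels from a truth scene.

    Per pixel: I_D = (1 - eta) * T, I_FRET = eta * T,
    I_D_raw = bg_donor + I_D + noise,
    I_F_raw = bg_fret + I_FRET + beta * I_D + noise.
    Pixels outside the pouch carry background (and noise) only.  The RNG
    is seeded from ``spec.seed``: the same spec renders bit-identically.
    """
    if truth.eta_maps.shape[1:] != (spec.height_px, spec.width_px):
        raise ValueError("spec and ground truth disagree on image shape")
    if truth.eta_maps.shape[0] != spec.n_frames:
        raise ValueError("spec and ground truth disagree on frame count")

    eta = truth.eta_maps
    tissue = np.isfinite(eta)
    i_fret = np.where(tissue, eta * spec.total_intensity, 0.0)
    i_d = np.where(tissue, spec.total_intensity - i_fret, 0.0)

    rng = np.random.default_rng(spec.seed)
    shape = eta.shape
    donor_raw = spec.bg_donor + i_d
    fret_raw = spec.bg_fret + i_fret + spec.beta * i_d
    if spec.noise_sigma > 0:
        donor_raw = donor_raw + rng.normal(0.0, spec.noise_sigma, shape)
        fret_raw = fret_raw + rng.normal(0.0, spec.noise_sigma, shape)

    data = np.stack([donor_raw, fret_raw], axis=1)
    return RawTimelapse(data=data, pixel_size_um=spec.pixel_size_um,
                        frame_interval_min=spec.frame_interval_min,
                        drug_time_min=spec.drug_time_min)


def render_calibration_pair(spec: SceneSpec,
                            donor_intensity: float | None = None):
    """Render a donor-only scene for bleedthrough calibration.

    Returns (donor_image, bleedthrough_image):
    donor = bg_donor + D + noise, bleedthrough = bg_fret + beta * D + noise,
    with D uniform (default: the scene's total intensity).
    """
    d = spec.total_intensity if donor_intensity is None else donor_intensity
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    donor = np.full(shape, spec.bg_donor + d)
    leak = np.full(shape, spec.bg_fret + spec.beta * d)
    if spec.noise_sigma > 0:
        donor = donor + rng.normal(0.0, spec.noise_sigma, shape)
        leak = leak + rng.normal(0.0, spec.noise_sigma, shape)
    return donor, leak


def simulate_cohort_traces(kinetics, n_discs: int, times_min,
                           drug_time_min: float = 0.0,
                           noise_sigma: float = 0.005,
                           seed: int = 0) -> list[RegionTrace]:
    """Trace-level cohort: each disc's region traces are the true 4PL
    curves plus i.i.d. Gaussian trace noise (clipped to [0, 1]).

    This models between-frame measurement noise of a region-mean trace;
    disc-to-disc parameter variability is not added, so recovered fit
    parameters scatter only through the noise.
    """
    times = np.asarray(times_min, dtype=float)
    t_since = times - drug_time_min
    rng = np.random.default_rng(seed)
    traces = []
    for disc in range(n_discs):
        for kin in kinetics:
            curve = np.where(t_since > 0,
                             true_eta(kin, np.maximum(t_since, 0.0)), kin.max_eta)
            noisy = np.clip(curve + rng.normal(0.0, noise_sigma, curve.shape), 0, 1)
            traces.append(RegionTrace(
                region=kin.label, disc_id=f"disc{disc:03d}", times_min=times,
                mean_eta=noisy, n_valid=np.full(times.size, 1, dtype=int),
            ))
    return traces
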