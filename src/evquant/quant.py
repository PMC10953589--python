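"""Spot detection and total-fluorescence-intensity (TFI) quantification.

The quantification pipeline mirrors single-EV TIRF image analysis: each
frame is (optionally) wavelet-denoised, bright spots are segmented above a
local background estimate, every spot is measured against the trimmed mean
of a surrounding annulus, spots are filtered to an equivalent-diameter
window (EV-sized particles; smaller objects are noise specks, larger ones
aggregates), a net-intensity histogram cutoff removes dim residual spots,
and the per-well TFI is the mean over effective images of the summed
background-subtracted spot intensities:

    TFI = [ sum_k sum_j sum_i ( FI_in(i,j,k) - mean_FI_lbg(j,k) ) ] / l

with i over pixels of a spot, j over spots of an image, k over the l
effective images of the well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pywt
from scipy import ndimage
from scipy.stats import trim_mean
from skimage.measure import label as sk_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

CHANNELS = ("mrna", "mprotein")


@dataclass
class TIRFImage:
    """One 2-D grayscale TIRF frame with acquisition metadata."""

    pixels: np.ndarray
    well_id: str = ""
    frame_index: int = 0
    channel: str = "mrna"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("TIRFImage.pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("TIRFImage.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("TIRFImage.pixels must be non-negative")


@dataclass
class Spot:
    """A detected bright spot and its local-background-subtracted intensity.

    ``net_intensity`` is ``sum(interior_intensities) - n * local_background_mean``
    where n is the pixel count of the mask.  It may be negative for noise
    spots; those are removed later by the histogram cutoff, never clipped.
    """

    pixel_mask: np.ndarray  # (n, 2) int array of (row, col)
    centroid: tuple[float, float]
    equivalent_diameter_px: float
    interior_intensities: np.ndarray = field(default_factory=lambda: np.empty(0))
    local_background_mean: float | None = None
    net_intensity: float | None = None
    tag: str = ""

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_mask)


@dataclass
class SpotHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    cutoff: float = float("nan")


@dataclass
class WellResult:
    """Per-well aggregate: TFI over the l effective images."""

    well_id: str
    channel: str
    l: int
    m_per_image: list[int]
    tfi: float
    retained_spots: list[Spot] = field(default_factory=list)


@dataclass
class ColocalizationResult:
    coloc_area_px: int
    ch1_area_px: int
    fraction: float


@dataclass
class QuantConfig:
    """Tunable parameters of the per-frame quantification pipeline."""

    denoise: bool = True
    wavelet: str = "sym4"
    wavelet_levels: int = 3
    wavelet_k: float = 4.0
    detect_k: float = 4.0
    background: str = "block_median"  # or "global_median"
    block_px: int = 32
    aperture_pad_px: int = 3
    measure_on: str = "raw"  # or "denoised"
    annulus_gap_px: int = 1
    annulus_width_px: int = 3
    annulus_trim: float = 0.1
    d_min_px: float = 6.0
    d_max_px: float = 20.0
    cutoff: float = 0.0
    saturation_level: float | None = None
    saturation_max_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.d_min_px > self.d_max_px:
            raise ValueError("d_min_px must not exceed d_max_px")
        if self.detect_k <= 0 or self.wavelet_k <= 0:
            raise ValueError("threshold multipliers must be positive")
        if self.background not in ("block_median", "global_median"):
            raise ValueError(f"unknown background mode {self.background!r}")


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def _mad_sigma(values: np.ndarray) -> float:
    """Robust noise SD from the median absolute deviation."""
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def denoise_image(img: TIRFImage, cfg: QuantConfig | None = None) -> TIRFImage:
    """Stationary-wavelet soft-threshold denoising.

    Detail coefficients at every level are soft-thresholded at
    ``wavelet_k * sigma_hat`` with sigma_hat estimated from the MAD of the
    finest-level diagonal detail.  Output is clipped at zero.
    """
    cfg = cfg or QuantConfig()
    px = img.pixels
    levels = cfg.wavelet_levels
    if min(px.shape) < 2 ** levels:
        raise ValueError(
            f"image {px.shape} smaller than 2^{levels} in one dimension"
        )
    # swt2 needs both dimensions divisible by 2**levels: pad, then crop.
    mult = 2 ** levels
    pad_r = (-px.shape[0]) % mult
    pad_c = (-px.shape[1]) % mult
    padded = np.pad(px, ((0, pad_r), (0, pad_c)), mode="reflect")
    coeffs = pywt.swt2(padded, cfg.wavelet, level=levels, norm=True)
    sigma = _mad_sigma(coeffs[-1][1][2].ravel())  # finest diagonal detail
    thr = cfg.wavelet_k * sigma
    if thr > 0:
        coeffs = [
            (a, tuple(pywt.threshold(d, thr, mode="soft") for d in details))
            for a, details in coeffs
        ]
    out = pywt.iswt2(coeffs, cfg.wavelet, norm=True)
    out = np.clip(out[: px.shape[0], : px.shape[1]], 0.0, None)
    return replace(img, pixels=out)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def estimate_background(pixels: np.ndarray, cfg: QuantConfig | None = None) -> np.ndarray:
    """Smooth background estimate (per-block median, bilinearly upsampled)."""
    cfg = cfg or QuantConfig()
    if cfg.background == "global_median":
        return np.full_like(pixels, np.median(pixels))
    block = cfg.block_px
    H, W = pixels.shape
    hb = max(1, H // block)
    wb = max(1, W // block)
    trimmed = pixels[: hb * (H // hb), : wb * (W // wb)]
    bh, bw = trimmed.shape[0] // hb, trimmed.shape[1] // wb
    med = np.median(
        trimmed.reshape(hb, bh, wb, bw).transpose(0, 2, 1, 3).reshape(hb, wb, -1),
        axis=2,
    )
    return ndimage.zoom(med, (H / hb, W / wb), order=1, mode="nearest", grid_mode=True)


def detect_spots(
    img: TIRFImage,
    cfg: QuantConfig | None = None,
    noise_sigma: float | None = None,
) -> list[Spot]:
    """Segment candidate bright spots.

    Candidates are 4-connected components of pixels strictly above
    ``background + detect_k * sigma_hat``, with sigma_hat the MAD noise SD
    of the background-subtracted frame (pass ``noise_sigma`` to threshold a
    denoised frame at the raw-frame noise level).  Empty output is a valid
    result.
    """
    cfg = cfg or QuantConfig()
    px = img.pixels
    bg = estimate_background(px, cfg)
    resid = px - bg
    sigma = _mad_sigma(resid.ravel()) if noise_sigma is None else float(noise_sigma)
    mask = resid > cfg.detect_k * sigma
    labels = sk_label(mask, connectivity=1)
    spots: list[Spot] = []
    for prop in regionprops(labels):
        coords = prop.coords
        spots.append(
            Spot(
                pixel_mask=coords,
                centroid=tuple(prop.centroid),
                equivalent_diameter_px=2.0 * np.sqrt(len(coords) / np.pi),
            )
        )
    return spots


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _mask_bool(shape: tuple[int, int], coords: np.ndarray) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[coords[:, 0], coords[:, 1]] = True
    return m


def measure_spot(
    img: TIRFImage,
    spot: Spot,
    cfg: QuantConfig | None = None,
    occupied: np.ndarray | None = None,
) -> Spot | None:
    """Measure one candidate against its local annulus background.

    The measurement aperture is the detected mask dilated by
    ``aperture_pad_px`` (to recover the sub-threshold tails of the PSF)
    minus pixels detected as other spots.  The local background is a
    trimmed mean of an annulus ring beyond the aperture (gap
    ``annulus_gap_px``, width ``annulus_width_px``), excluding pixels
    within a pad of any candidate (``occupied``).  Pixels at exactly the
    background level contribute zero net intensity, so the padding leaves
    net intensity unbiased.  If the annulus has no usable pixels it is
    widened once; if still empty the spot is dropped (returns None) with a
    logged warning.
    """
    cfg = cfg or QuantConfig()
    px = img.pixels
    pad = cfg.aperture_pad_px
    gap = cfg.annulus_gap_px

    # work in a window around the mask: dilations stay cheap per spot
    reach = pad + gap + 2 * cfg.annulus_width_px + 1
    r0 = max(0, spot.pixel_mask[:, 0].min() - reach)
    r1 = min(px.shape[0], spot.pixel_mask[:, 0].max() + reach + 1)
    c0 = max(0, spot.pixel_mask[:, 1].min() - reach)
    c1 = min(px.shape[1], spot.pixel_mask[:, 1].max() + reach + 1)
    win = px[r0:r1, c0:c1]
    mask = np.zeros(win.shape, dtype=bool)
    mask[spot.pixel_mask[:, 0] - r0, spot.pixel_mask[:, 1] - c0] = True
    occ = occupied[r0:r1, c0:c1] if occupied is not None else mask

    aperture = ndimage.binary_dilation(mask, iterations=pad) if pad else mask
    aperture &= ~(occ & ~mask)
    occ_padded = ndimage.binary_dilation(occ, iterations=pad) if pad else occ

    def _annulus(width: int) -> np.ndarray:
        outer = ndimage.binary_dilation(mask, iterations=pad + gap + width)
        inner = ndimage.binary_dilation(mask, iterations=pad + gap)
        return outer & ~inner & ~occ_padded

    ring = _annulus(cfg.annulus_width_px)
    if not ring.any():
        ring = _annulus(2 * cfg.annulus_width_px)
    if not ring.any():
        logger.warning(
            "spot at %s: background undeterminable, dropped", spot.centroid
        )
        return None
    bg_vals = win[ring]
    lbg = float(trim_mean(bg_vals, cfg.annulus_trim)) if len(bg_vals) > 2 else float(
        np.mean(bg_vals)
    )
    interior = win[aperture]
    net = float(np.sum(interior) - len(interior) * lbg)
    return replace(
        spot,
        interior_intensities=interior,
        local_background_mean=lbg,
        net_intensity=net,
    )


def measure_spots(
    img: TIRFImage, candidates: Sequence[Spot], cfg: QuantConfig | None = None
) -> list[Spot]:
    """Measure every candidate, excluding all candidate pixels from annuli."""
    cfg = cfg or QuantConfig()
    occupied = np.zeros(img.pixels.shape, dtype=bool)
    for s in candidates:
        occupied[s.pixel_mask[:, 0], s.pixel_mask[:, 1]] = True
    out = []
    for s in candidates:
        m = measure_spot(img, s, cfg, occupied=occupied)
        if m is not None:
            out.append(m)
    return out


def filter_spots_by_size(
    spots: Sequence[Spot], d_min_px: float = 6.0, d_max_px: float = 20.0
) -> list[Spot]:
    """Keep spots with equivalent diameter in [d_min, d_max] (inclusive).

    Out-of-range spots are tagged ``aggregate-or-noise`` and excluded.
    """
    if d_min_px > d_max_px:
        raise ValueError("d_min_px must not exceed d_max_px")
    kept = []
    for s in spots:
        if d_min_px <= s.equivalent_diameter_px <= d_max_px:
            kept.append(s)
        else:
            s.tag = "aggregate-or-noise"
    return kept


def build_histogram(
    spots: Sequence[Spot], bins: int | np.ndarray = 50
) -> SpotHistogram:
    """Histogram of net intensities (half-open bins, last bin closed)."""
    if np.isscalar(bins) and int(bins) <= 0:
        raise ValueError("bin count must be positive")
    net = np.array([s.net_intensity for s in spots], dtype=float)
    if len(net) == 0 and np.isscalar(bins):
        edges = np.linspace(0.0, 1.0, int(bins) + 1)
        return SpotHistogram(bin_edges=edges, counts=np.zeros(int(bins), dtype=int))
    counts, edges = np.histogram(net, bins=bins)
    return SpotHistogram(bin_edges=edges, counts=counts)


def apply_histogram_cutoff(spots: Sequence[Spot], cutoff: float) -> list[Spot]:
    """Retain spots with net intensity strictly above the cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return [s for s in spots if s.net_intensity is not None and s.net_intensity > cutoff]


def derive_blank_cutoff(
    blank_net_intensities: Sequence[float], percentile: float = 99.9
) -> float:
    """Histogram cutoff from blank-control wells (default 99.9th percentile)."""
    vals = np.asarray(blank_net_intensities, dtype=float)
    if len(vals) == 0:
        return 0.0
    return float(np.percentile(vals, percentile))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def compute_tfi(
    images_spots: Sequence[Sequence[Spot]],
    l: int | None = None,
    well_id: str = "",
    channel: str = "mrna",
) -> WellResult:
    """TFI of one well: summed net spot intensity averaged over l images.

    ``images_spots`` holds the retained (measured, size- and
    cutoff-filtered) spots of each effective image.
    """
    if l is None:
        l = len(images_spots)
    if l < 1:
        raise ValueError("number of effective images l must be >= 1")
    total = 0.0
    m_per_image = []
    retained: list[Spot] = []
    for frame_spots in images_spots:
        m_per_image.append(len(frame_spots))
        for s in frame_spots:
            if s.net_intensity is None:
                raise ValueError("spots must be measured before compute_tfi")
            total += s.net_intensity
            retained.append(s)
    return WellResult(
        well_id=well_id,
        channel=channel,
        l=l,
        m_per_image=m_per_image,
        tfi=total / l,
        retained_spots=retained,
    )


def aggregate_sample(well_results: Sequence[WellResult]) -> dict[str, float]:
    """Per-sample TFI: arithmetic mean of well TFIs, grouped by channel."""
    if not well_results:
        raise ValueError("at least one well result required")
    by_channel: dict[str, list[float]] = {}
    for wr in well_results:
        by_channel.setdefault(wr.channel, []).append(wr.tfi)
    return {ch: float(np.mean(v)) for ch, v in by_channel.items()}


# ---------------------------------------------------------------------------
# full pipeline helpers
# ---------------------------------------------------------------------------

def _frame_passes_qc(img: TIRFImage, cfg: QuantConfig) -> bool:
    if cfg.saturation_level is None:
        return True
    frac = float(np.mean(img.pixels >= cfg.saturation_level))
    return frac <= cfg.saturation_max_frac


def quantify_image(img: TIRFImage, cfg: QuantConfig | None = None) -> list[Spot]:
    """Denoise, detect, measure, size-filter, and cutoff-filter one frame.

    When denoising is on, the detection threshold still uses the raw
    frame's noise SD: denoising suppresses the noise floor but not the
    spot tails, so thresholding a denoised frame at its own (tiny)
    residual SD would inflate every mask.
    """
    cfg = cfg or QuantConfig()
    if cfg.denoise:
        raw_sigma = _mad_sigma(
            (img.pixels - estimate_background(img.pixels, cfg)).ravel()
        )
        work = denoise_image(img, cfg)
        candidates = detect_spots(work, cfg, noise_sigma=raw_sigma)
    else:
        work = img
        candidates = detect_spots(work, cfg)
    measure_img = img if cfg.measure_on == "raw" else work
    measured = measure_spots(measure_img, candidates, cfg)
    in_range = filter_spots_by_size(measured, cfg.d_min_px, cfg.d_max_px)
    return apply_histogram_cutoff(in_range, cfg.cutoff)


def quantify_well(
    images: Sequence[TIRFImage],
    cfg: QuantConfig | None = None,
    well_id: str | None = None,
    channel: str | None = None,
) -> WellResult:
    """Run the full per-frame pipeline over a well and compute its TFI.

    Frames failing saturation QC are dropped and the effective image count
    l is reduced accordingly.
    """
    cfg = cfg or QuantConfig()
    if not images:
        raise ValueError("well must contain at least one image")
    effective = [im for im in images if _frame_passes_qc(im, cfg)]
    n_dropped = len(images) - len(effective)
    if n_dropped:
        logger.info("dropped %d frames failing QC", n_dropped)
    if not effective:
        raise ValueError("no effective images after QC")
    per_image = [quantify_image(im, cfg) for im in effective]
    return compute_tfi(
        per_image,
        l=len(effective),
        well_id=well_id if well_id is not None else images[0].well_id,
        channel=channel if channel is not None else images[0].channel,
    )


def colocalization_fraction(
    mask_ch1: np.ndarray, mask_ch2: np.ndarray
) -> ColocalizationResult:
    """Fraction of channel-1 area co-localized with channel 2 (pixel count)."""
    m1 = np.asarray(mask_ch1, dtype=bool)
    m2 = np.asarray(mask_ch2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("masks must share one pixel grid")
    a1 = int(m1.sum())
    if a1 == 0:
        raise ValueError("channel-1 mask is empty: fraction undefined")
    overlap = int((m1 & m2).sum())
    return ColocalizationResult(
        coloc_area_px=overlap, ch1_area_px=a1, fraction=overlap / a1
    )
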