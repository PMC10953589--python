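"""Synthetic TIRF images, dilution series, and diagnostic/prognostic cohorts.

Every generator is deterministic given its config and seed and returns
exact ground truth, so the full quantification and statistics stack can be
exercised without any external data.

Image model
-----------
A frame is a slowly varying background (offset plus a gentle planar
gradient) with diffraction-limited spots rendered as isotropic 2-D
Gaussians parameterized by their *integrated* intensity (photon count),
truncated at 4 sigma.  Three object categories are rendered:

* ``signal`` — EV-sized spots whose detected equivalent diameter falls in
  the 6-20 px analysis window at the default detection threshold;
* ``speck`` — sub-threshold noise specks (sub-resolution, dim);
* ``aggregate`` — oversized bright blobs that the size filter must reject.

Noise is Poisson shot noise on (background + signal) plus Gaussian read
noise; both can be switched off for exact conservation checks.

Cohort model
------------
Per-sample marker TFIs are log-normal per cohort with configurable
inter-marker correlation.  Cases are elevated in mRNA only, protein only,
or both, mirroring the H/L, L/H, H/H quadrant structure of dual-marker
positive samples.  Survival times are exponential with a log-linear hazard
in the standardized log markers, with uniform right-censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .biomarker import SampleRecord
from .quant import TIRFImage

_KERNEL_TRUNC_SIGMA = 4.0


@dataclass
class TrueSpot:
    """Ground truth for one rendered object."""

    row: float
    col: float
    intensity: float  # true integrated net intensity above background
    sigma_px: float
    diameter_px: float  # equivalent diameter at the reference detection level
    category: str  # signal | speck | aggregate


GroundTruth = list  # list[TrueSpot]; alias kept for readability


@dataclass
class ImageSimConfig:
    image_size_px: tuple[int, int] = (512, 512)  # 80 um x 80 um field
    psf_sigma_px: float = 3.0
    spot_count: int = 30
    # named amplitude distribution for signal spots (integrated counts)
    amplitude_distribution: tuple[str, dict] = (
        "lognormal",
        {"median": 11000.0, "sigma": 0.35},
    )
    background_offset: float = 100.0
    background_gradient_amplitude: float = 5.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    n_speck: int = 5
    n_aggregate: int = 1
    speck_sigma_px: float = 0.7
    speck_amplitude: float = 200.0
    aggregate_sigma_px: float = 9.0
    aggregate_amplitude: float = 1.0e5
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image size must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        for name in ("spot_count", "n_speck", "n_aggregate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "background_offset",
            "background_gradient_amplitude",
            "read_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # expected footprint coverage; > 50% means spots mostly overlap
        footprint = math.pi * (3.0 * self.psf_sigma_px) ** 2
        if self.spot_count * footprint / (h * w) > 0.5:
            raise ValueError("overcrowded: expected spot overlap fraction > 50%")


def _noise_floor(cfg: ImageSimConfig) -> float:
    """Expected pixel noise SD under the configured noise model."""
    var = cfg.read_noise_sd ** 2
    if cfg.shot_noise:
        var += cfg.background_offset
    return math.sqrt(var)


def _reference_diameter(cfg: ImageSimConfig, amplitude: float, sigma: float) -> float:
    """Equivalent diameter of the region above the reference detection level.

    The reference level is 4x the expected noise SD (the default detection
    threshold); with all noise off the truncation radius is used instead.
    """
    peak = amplitude / (2.0 * math.pi * sigma ** 2)
    floor = 4.0 * _noise_floor(cfg)
    if floor <= 0:
        return 2.0 * _KERNEL_TRUNC_SIGMA * sigma
    if peak <= floor:
        return 0.0
    return 2.0 * sigma * math.sqrt(2.0 * math.log(peak / floor))


def _draw_amplitudes(cfg: ImageSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = cfg.amplitude_distribution
    if name == "lognormal":
        med = params.get("median", 11000.0)
        s = params.get("sigma", 0.35)
        return med * np.exp(rng.normal(0.0, s, size=n))
    if name == "constant":
        return np.full(n, float(params["value"]))
    raise ValueError(f"unknown amplitude distribution {name!r}")


def _render_spot(
    field_arr: np.ndarray, row: float, col: float, amplitude: float, sigma: float
) -> None:
    """Add a truncated integrated-intensity Gaussian in place."""
    H, W = field_arr.shape
    r = _KERNEL_TRUNC_SIGMA * sigma
    r0, r1 = max(0, int(math.floor(row - r))), min(H - 1, int(math.ceil(row + r)))
    c0, c1 = max(0, int(math.floor(col - r))), min(W - 1, int(math.ceil(col + r)))
    rr = np.arange(r0, r1 + 1)[:, None] - row
    cc = np.arange(c0, c1 + 1)[None, :] - col
    d2 = rr ** 2 + cc ** 2
    kern = amplitude / (2.0 * math.pi * sigma ** 2) * np.exp(-d2 / (2.0 * sigma ** 2))
    kern[d2 > r ** 2] = 0.0
    field_arr[r0 : r1 + 1, c0 : c1 + 1] += kern


def simulate_tirf_image(
    cfg: ImageSimConfig,
    well_id: str = "",
    frame_index: int = 0,
    channel: str = "mrna",
) -> tuple[TIRFImage, GroundTruth]:
    """Render one frame plus exact ground truth.

    Identical config and seed give bit-identical output.  Spot centroids
    are placed so the truncated kernel stays inside the frame.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_size_px
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    clean = np.full((H, W), float(cfg.background_offset))
    if cfg.background_gradient_amplitude > 0:
        denom = max(H + W - 2, 1)
        clean += cfg.background_gradient_amplitude * (rows + cols) / denom

    truth: GroundTruth = []

    def _place(n: int, sigma: float, amps: np.ndarray, category: str) -> None:
        margin = min(_KERNEL_TRUNC_SIGMA * sigma, (min(H, W) - 1) / 2.0)
        rr = rng.uniform(margin, H - 1 - margin, size=n)
        cc = rng.uniform(margin, W - 1 - margin, size=n)
        for i in range(n):
            _render_spot(clean, rr[i], cc[i], amps[i], sigma)
            truth.append(
                TrueSpot(
                    row=float(rr[i]),
                    col=float(cc[i]),
                    intensity=float(amps[i]),
                    sigma_px=sigma,
                    diameter_px=_reference_diameter(cfg, amps[i], sigma),
                    category=category,
                )
            )

    _place(cfg.spot_count, cfg.psf_sigma_px, _draw_amplitudes(cfg, cfg.spot_count, rng), "signal")
    _place(cfg.n_speck, cfg.speck_sigma_px, np.full(cfg.n_speck, cfg.speck_amplitude), "speck")
    _place(
        cfg.n_aggregate,
        cfg.aggregate_sigma_px,
        np.full(cfg.n_aggregate, cfg.aggregate_amplitude),
        "aggregate",
    )

    img = clean
    if cfg.shot_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if cfg.read_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return (
        TIRFImage(pixels=img, well_id=well_id, frame_index=frame_index, channel=channel),
        truth,
    )


def simulate_well(
    cfg: ImageSimConfig,
    n_images: int = 100,
    well_id: str = "",
    channel: str = "mrna",
) -> tuple[list[TIRFImage], list[GroundTruth]]:
    """Simulate a well of n_images frames (one well = a 10 x 10 image array).

    Per-frame object counts are Poisson around the configured means
    (spatially random vesicle capture); per-frame seeds are spawned from
    the well seed so the well is reproducible as a unit.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    images: list[TIRFImage] = []
    truths: list[GroundTruth] = []
    for k in range(n_images):
        frame_cfg = replace(
            cfg,
            spot_count=int(rng.poisson(cfg.spot_count)),
            n_speck=int(rng.poisson(cfg.n_speck)) if cfg.n_speck else 0,
            n_aggregate=int(rng.poisson(cfg.n_aggregate)) if cfg.n_aggregate else 0,
            seed=int(rng.integers(2 ** 31)),
        )
        img, truth = simulate_tirf_image(
            frame_cfg, well_id=well_id, frame_index=k, channel=channel
        )
        images.append(img)
        truths.append(truth)
    return images, truths


def simulate_dilution_series(
    base_cfg: ImageSimConfig,
    concentrations: Sequence[float],
    seed: int | None = None,
    n_images: int = 10,
) -> list[tuple[float, list[TIRFImage], list[GroundTruth]]]:
    """Spike-in dilution series: expected spots/image proportional to concentration.

    ``base_cfg.spot_count`` is interpreted as the expected spots per image
    at the highest concentration in the series.  A blank analog is
    available separately via ``spot_count=0`` with specks retained.
    """
    conc = [float(c) for c in concentrations]
    if not conc:
        raise ValueError("concentration list must be non-empty")
    if any(c <= 0 for c in conc):
        raise ValueError("concentrations must be strictly positive")
    if sorted(conc) != conc:
        raise ValueError("concentrations must be sorted ascending")
    top = conc[-1]
    base_seed = base_cfg.seed if seed is None else seed
    out = []
    for i, c in enumerate(conc):
        level_cfg = replace(
            base_cfg,
            spot_count=max(0, round(base_cfg.spot_count * c / top)),
            seed=base_seed + i,
        )
        images, truths = simulate_well(level_cfg, n_images=n_images, well_id=f"dil{i}")
        out.append((c, images, truths))
    return out


def simulate_imaging_sample(
    tfi_mrna: float,
    tfi_mprotein: float,
    seed: int,
    n_wells: int = 2,
    n_images: int = 2,
    image_size_px: tuple[int, int] = (256, 256),
    mean_spot_net: float = 11000.0,
) -> dict[str, list[list[TIRFImage]]]:
    """Render the wells of one sample so its measured TFI tracks the target.

    The expected spots per image is ``target_tfi / mean_spot_net`` with the
    default amplitude distribution (median integrated intensity 11000),
    so quantifying the frames recovers a TFI near the target marker level.
    The density is capped at 40% expected footprint coverage — like the
    physical assay, the imaging field saturates at high vesicle load.
    Returns ``{channel: [well][frame]}``.
    """
    ss = np.random.SeedSequence(seed)
    psf_sigma = 3.0
    h, w_px = image_size_px
    max_count = int(0.4 * h * w_px / (math.pi * (3.0 * psf_sigma) ** 2))
    out: dict[str, list[list[TIRFImage]]] = {}
    for channel, target in (("mrna", tfi_mrna), ("mprotein", tfi_mprotein)):
        wells = []
        for w, child in enumerate(ss.spawn(n_wells)):
            cfg = ImageSimConfig(
                image_size_px=image_size_px,
                psf_sigma_px=psf_sigma,
                spot_count=min(max_count, max(0, round(target / mean_spot_net))),
                n_speck=3,
                n_aggregate=0,
                seed=int(np.random.default_rng(child).integers(2 ** 31)),
            )
            images, _ = simulate_well(
                cfg, n_images=n_images, well_id=f"{channel}_w{w}", channel=channel
            )
            wells.append(images)
        out[channel] = wells
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Study-condition parameters of the synthetic diagnostic cohort.

    Marker levels are log10-normal; cases carry a per-marker elevation in
    the quadrant fractions given (both / mRNA only / protein only; any
    remainder stays at control level in both markers).
    """

    n_control: int = 20
    n_case: int = 20
    control_log10_mean: tuple[float, float] = (4.6, 3.6)  # (mrna, mprotein)
    control_log10_sd: tuple[float, float] = (0.25, 0.25)
    case_log10_sd: tuple[float, float] = (0.35, 0.35)
    case_elevation_log10: tuple[float, float] = (1.0, 1.0)
    frac_both: float = 0.5
    frac_mrna_only: float = 0.25
    frac_mprotein_only: float = 0.25
    marker_correlation: float = 0.3
    include_ca199: bool = True
    ca199_log10_mean: tuple[float, float] = (1.0, 2.3)  # control, case
    ca199_log10_sd: tuple[float, float] = (0.4, 0.6)
    include_survival: bool = True
    baseline_hazard: float = 0.08  # events per month
    log_hazard: tuple[float, float] = (0.5, 0.5)  # per control-SD of log marker
    censoring_rate: float = 0.2
    censoring_horizon_months: float = 36.0
    control_label: str = "HD"
    case_label: str = "PDAC_I_II"
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_control + self.n_case <= 0:
            raise ValueError("cohort must contain at least one sample")
        fracs = (self.frac_both, self.frac_mrna_only, self.frac_mprotein_only)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("quadrant fractions must be non-negative, sum <= 1")
        if any(s <= 0 for s in self.control_log10_sd + self.case_log10_sd):
            raise ValueError("SDs must be positive")
        if not -1.0 <= self.marker_correlation <= 1.0:
            raise ValueError("marker correlation must be in [-1, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring rate must be in [0, 1]")


def simulate_cohort(cfg: CohortSimConfig) -> list[SampleRecord]:
    """Draw a control + case cohort of SampleRecords, deterministic by seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.marker_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    def _markers(n: int, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
        z = rng.standard_normal((n, 2)) @ chol.T
        return 10.0 ** (mean + sd * z)

    records: list[SampleRecord] = []
    c_mean = np.array(cfg.control_log10_mean)
    c_sd = np.array(cfg.control_log10_sd)

    ctrl_markers = _markers(cfg.n_control, c_mean, c_sd)
    for i in range(cfg.n_control):
        ca = (
            float(10.0 ** rng.normal(cfg.ca199_log10_mean[0], cfg.ca199_log10_sd[0]))
            if cfg.include_ca199
            else None
        )
        records.append(
            SampleRecord(
                sample_id=f"CTRL{i:03d}",
                cohort=cfg.control_label,
                tfi_mrna=float(ctrl_markers[i, 0]),
                tfi_mprotein=float(ctrl_markers[i, 1]),
                ca199=ca,
            )
        )

    # quadrant assignment of cases: both / mRNA only / protein only / neither
    u = rng.uniform(size=cfg.n_case)
    b1 = cfg.frac_both
    b2 = b1 + cfg.frac_mrna_only
    b3 = b2 + cfg.frac_mprotein_only
    elev_mrna = (u < b2).astype(float)
    elev_mprot = ((u < b1) | ((u >= b2) & (u < b3))).astype(float)
    elev = np.column_stack([elev_mrna, elev_mprot])
    case_sd = np.array(cfg.case_log10_sd)
    case_mean = c_mean + elev * np.array(cfg.case_elevation_log10)

    z = rng.standard_normal((cfg.n_case, 2)) @ chol.T
    case_markers = 10.0 ** (case_mean + case_sd * z)

    for i in range(cfg.n_case):
        ca = (
            float(10.0 ** rng.normal(cfg.ca199_log10_mean[1], cfg.ca199_log10_sd[1]))
            if cfg.include_ca199
            else None
        )
        os_months = event = None
        if cfg.include_survival:
            zmark = (np.log10(case_markers[i]) - c_mean) / c_sd
            hazard = cfg.baseline_hazard * math.exp(
                float(np.dot(cfg.log_hazard, zmark))
            )
            t = rng.exponential(1.0 / hazard)
            if rng.uniform() < cfg.censoring_rate:
                c_time = rng.uniform(0.0, cfg.censoring_horizon_months)
            else:
                c_time = cfg.censoring_horizon_months
            os_months = float(min(t, c_time))
            event = int(t <= c_time)
        records.append(
            SampleRecord(
                sample_id=f"CASE{i:03d}",
                cohort=cfg.case_label,
                tfi_mrna=float(case_markers[i, 0]),
                tfi_mprotein=float(case_markers[i, 1]),
                ca199=ca,
                os_months=os_months,
                event=event,
            )
        )
    return records
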