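"""Synthetic inputs with embedded ground truth.

Every generator here produces data in the same form the analysis functions
consume — incremental-stimulation EMG series, CMAP and torque waveforms, and
multichannel nerve cross-section images — together with the exact truth used
to build it, so downstream quantifications can be tested for parameter
recovery.  All generators are bit-reproducible under a fixed seed.

The image generator lays out simple geometric proxies for the stained
structures: NF axons as filled discs, myelin as MBP annuli hugging a subset
of axons, capillaries as CD31 rings with an endothelial DAPI nucleus in the
wall, optional GFP co-labelling of vessels and standalone GFP+ cells, and
Poisson background noise in every channel.  Objects are placed inside the
analysis ROI by rejection sampling with a separation margin large enough
that thresholded components never merge, keeping the embedded counts exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk

from .ephys import IncrementSeries, Waveform
from .errors import GenerationError, InputError
from .imaging import ImageBundle

__all__ = [
    "MotorPool",
    "SyntheticImageTruth",
    "gen_motor_pool",
    "gen_increment_series",
    "gen_cmap_trace",
    "gen_torque_trace",
    "gen_nerve_image",
]


@dataclass
class MotorPool:
    """Ground-truth motor-unit pool: per-unit SMUP amplitudes (mV) and
    recruitment thresholds (mA), sorted so units recruit in threshold order."""

    n_units: int
    unit_amplitudes: np.ndarray
    recruitment_thresholds: np.ndarray
    amplitude_cv: float
    seed: int

    @property
    def max_cmap(self) -> float:
        """Summed pool amplitude = maximal CMAP peak-to-peak (mV)."""
        return float(self.unit_amplitudes.sum())


@dataclass
class SyntheticImageTruth:
    """Exact object counts embedded in a generated nerve image."""

    n_axons: int
    n_myelinated: int
    n_vessels: int
    in_roi_counts: dict = field(default_factory=dict)
    pixel_size: float = 1.0
    n_gfp: int = 0
    n_gfp_vessels: int = 0
    roi_area_mm2: float = 0.0


def gen_motor_pool(
    n_units: int,
    mean_amp: float = 0.2,
    cv: float = 0.3,
    seed: int = 0,
    threshold_range: tuple[float, float] = (1.0, 10.0),
) -> MotorPool:
    """Lognormal motor-unit amplitudes with the stated mean and CV.

    ``cv = 0`` gives identical amplitudes.  Recruitment thresholds are
    sorted uniform draws over the stimulation intensity range (1-10 mA by
    default, 0.1 ms pulses).
    """
    if n_units < 1:
        raise InputError("n_units must be >= 1")
    if cv < 0 or mean_amp <= 0:
        raise InputError("mean_amp must be > 0 and cv >= 0")
    rng = np.random.default_rng(seed)
    if cv == 0:
        amps = np.full(n_units, mean_amp)
    else:
        s2 = np.log1p(cv**2)
        mu = np.log(mean_amp) - s2 / 2.0
        amps = rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n_units)
    thresholds = np.sort(rng.uniform(*threshold_range, size=n_units))
    return MotorPool(
        n_units=n_units,
        unit_amplitudes=amps,
        recruitment_thresholds=thresholds,
        amplitude_cv=cv,
        seed=seed,
    )


def gen_increment_series(
    pool: MotorPool,
    n_increments: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    include_baseline: bool = False,
) -> tuple[IncrementSeries, dict]:
    """Incremental submaximal responses: cumulative sums of the first k
    recruited units plus Gaussian measurement noise.

    With ``include_baseline`` a sub-recruitment zero-response level is
    prepended (also noisy), so successive differences cover all
    ``n_increments`` recruitment steps.  The returned truth dict records
    the contributing unit amplitudes.
    """
    if n_increments > pool.n_units:
        raise InputError("n_increments cannot exceed the pool size")
    if n_increments < 1:
        raise InputError("n_increments must be >= 1")
    units = pool.unit_amplitudes[:n_increments]
    levels = np.cumsum(units)
    if include_baseline:
        levels = np.concatenate([[0.0], levels])
    rng = np.random.default_rng(seed)
    noisy = levels + (noise_sd * rng.standard_normal(levels.size) if noise_sd else 0.0)
    truth = {"unit_amplitudes": units.copy(), "clean_levels": levels.copy()}
    return IncrementSeries(amplitudes=noisy, n_increments=n_increments), truth


# biphasic CMAP template support (ms after stimulus)
_CMAP_POS_MS = 4.0
_CMAP_NEG_MS = 6.0


def gen_cmap_trace(
    pool: MotorPool,
    sampling_rate: float = 20_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_ms: float = 60.0,
    stim_ms: float = 10.0,
) -> Waveform:
    """Supramaximal CMAP trace whose peak-to-peak equals the pool sum.

    A biphasic template (positive then negative lobe) is normalized on its
    own samples so that max - min is exactly 1, then scaled by the summed
    pool amplitude; Gaussian noise is added everywhere when requested.
    """
    n = int(round(duration_ms * 1e-3 * sampling_rate))
    t = np.arange(n) * 1e3 / sampling_rate
    tau = t - stim_ms
    shape = np.zeros(n)
    pos = (tau >= 0) & (tau < _CMAP_POS_MS)
    shape[pos] = 0.6 * np.sin(np.pi * tau[pos] / _CMAP_POS_MS)
    neg = (tau >= _CMAP_POS_MS) & (tau < _CMAP_POS_MS + _CMAP_NEG_MS)
    shape[neg] = -0.4 * np.sin(np.pi * (tau[neg] - _CMAP_POS_MS) / _CMAP_NEG_MS)
    pp = shape.max() - shape.min()
    if pp > 0:
        shape = shape / pp * pool.max_cmap
    rng = np.random.default_rng(seed)
    if noise_sd:
        shape = shape + noise_sd * rng.standard_normal(n)
    return Waveform(
        samples=shape, sampling_rate=sampling_rate, stimulus_times=[stim_ms], units="mV"
    )


def gen_torque_trace(
    kind: str = "twitch",
    peak: float = 10.0,
    sampling_rate: float = 2_000.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    ripple: float = 0.005,
) -> Waveform:
    """Plantar-flexion torque trace with a known peak (mN*m).

    Twitch: single rise-and-decay transient.  Tetanic: a 150 Hz train over
    1 s whose envelope fuses to a plateau at the stated peak, with a small
    unfused ripple.  The trace is renormalized on its own samples so the
    sampled maximum equals ``peak`` exactly (when ``peak > 0``).
    """
    if kind not in ("twitch", "tetanic"):
        raise InputError(f"unknown torque kind {kind!r}")
    if peak < 0:
        raise InputError("peak must be >= 0")
    if kind == "twitch":
        duration_ms, stim_ms, tau = 300.0, 50.0, 30.0
        n = int(round(duration_ms * 1e-3 * sampling_rate))
        t = np.arange(n) * 1e3 / sampling_rate
        x = np.maximum(t - stim_ms, 0.0) / tau
        shape = x * np.exp(1.0 - x)
    else:
        duration_ms, stim_ms, tau = 1300.0, 100.0, 50.0
        n = int(round(duration_ms * 1e-3 * sampling_rate))
        t = np.arange(n) * 1e3 / sampling_rate
        x = np.maximum(t - stim_ms, 0.0)
        active = (t >= stim_ms) & (t <= stim_ms + 1000.0)
        env = (1.0 - np.exp(-x / tau)) * active
        shape = env * (1.0 + ripple * np.sin(2 * np.pi * 150.0 * x * 1e-3))
        shape[t > stim_ms + 1000.0] = 0.0
    m = shape.max()
    samples = shape / m * peak if (m > 0 and peak > 0) else np.zeros(n)
    rng = np.random.default_rng(seed)
    if noise_sd:
        samples = samples + noise_sd * rng.standard_normal(n)
    return Waveform(
        samples=samples,
        sampling_rate=sampling_rate,
        stimulus_times=[stim_ms],
        units="mN*m",
    )


def _place_objects(
    rng: np.random.Generator,
    radii: list[float],
    bounds: tuple[float, float, float, float],
    margin: float = 3.0,
    max_attempts: int = 10_000,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping object centres inside ``bounds``
    (row0, row1, col0, col1), keeping centre separation >= r_i + r_j + margin."""
    r0, r1, c0, c1 = bounds
    centres: list[tuple[float, float]] = []
    area = (r1 - r0) * (c1 - c0)
    packed = sum(np.pi * (r + margin / 2) ** 2 for r in radii)
    if packed > 0.5 * area:
        raise GenerationError(
            f"requested objects pack {packed / area:.0%} of the ROI; infeasible"
        )
    for r in radii:
        lo_r, hi_r = r0 + r, r1 - r
        lo_c, hi_c = c0 + r, c1 - r
        if hi_r <= lo_r or hi_c <= lo_c:
            raise GenerationError("object larger than the placement region")
        for attempt in range(max_attempts):
            y = rng.uniform(lo_r, hi_r)
            x = rng.uniform(lo_c, hi_c)
            if all(
                np.hypot(y - yy, x - xx) >= r + rr + margin
                for (yy, xx), rr in zip(centres, radii)
            ):
                centres.append((y, x))
                break
        else:
            raise GenerationError(
                f"could not place object of radius {r} after {max_attempts} attempts"
            )
    return centres


def _paint_disc(img, centre, radius, value):
    rr, cc = disk(centre, radius, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def _paint_ring(img, centre, r_outer, r_inner, value):
    rr, cc = disk(centre, r_outer, shape=img.shape)
    ring = np.zeros(img.shape, dtype=bool)
    ring[rr, cc] = True
    rr, cc = disk(centre, r_inner, shape=img.shape)
    ring[rr, cc] = False
    img[ring] = np.maximum(img[ring], value)


def gen_nerve_image(
    n_axons: int = 50,
    n_myelinated: int = 20,
    n_vessels: int = 12,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 1.0,
    roi_area_mm2: float = 0.1,
    seed: int = 0,
    gfp_vessel_fraction: float = 0.0,
    n_gfp_only: int = 0,
    background_lam: float = 2.0,
    foreground: float = 200.0,
    n_free_nuclei: int = 20,
    axon_radius: tuple[int, int] = (2, 4),
    vessel_radius: tuple[int, int] = (5, 7),
    max_attempts: int = 10_000,
) -> tuple[ImageBundle, SyntheticImageTruth]:
    """Multichannel nerve cross-section with exact embedded counts.

    All objects are placed inside a rectangular fascicle ROI of exactly
    ``roi_area_mm2``, stored in the bundle under ``rois['fascicle']``, so
    the in-ROI counts equal the totals.  Myelinated axons receive an MBP
    annulus overlapping the rim of their NF disc; every vessel's CD31 ring
    carries a DAPI nucleus in its wall; a stated fraction of vessels is
    additionally GFP-labelled, plus optional standalone GFP+/DAPI+ cells.

    Returns the bundle and the exact truth record.
    """
    if n_myelinated > n_axons:
        raise InputError("n_myelinated cannot exceed n_axons")
    if not 0.0 <= gfp_vessel_fraction <= 1.0:
        raise InputError("gfp_vessel_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nr, nc = shape

    # rectangular ROI of exactly the requested area, centred in the field
    target_px2 = roi_area_mm2 * 1e6 / pixel_size**2
    w = min(int(np.floor(np.sqrt(target_px2 * 1.6))), nc - 40)
    h = target_px2 / w
    if w < 20 or h > nr - 40:
        raise GenerationError("ROI of the requested area does not fit the field")
    c0 = (nc - w) / 2.0
    r0 = (nr - h) / 2.0
    roi = np.array(
        [[c0, r0], [c0 + w, r0], [c0 + w, r0 + h], [c0, r0 + h]], dtype=float
    )

    ax_radii = rng.integers(axon_radius[0], axon_radius[1] + 1, size=n_axons)
    vs_radii = rng.integers(vessel_radius[0], vessel_radius[1] + 1, size=n_vessels)
    gfp_radii = np.full(n_gfp_only, 3)
    nuc_radii = np.full(n_free_nuclei, 2)
    # effective exclusion radius covers the widest painted structure
    eff = (
        [r + 2 for r in ax_radii]          # MBP annulus extends 2 px past the disc
        + [r + 1 for r in vs_radii]        # wall nucleus can poke 1 px out
        + [r + 1 for r in gfp_radii]
        + list(nuc_radii)
    )
    inset = 2.0
    bounds = (r0 + inset, r0 + h - inset, c0 + inset, c0 + w - inset)
    centres = _place_objects(rng, eff, bounds, margin=3.0, max_attempts=max_attempts)
    ax_centres = centres[:n_axons]
    vs_centres = centres[n_axons : n_axons + n_vessels]
    gfp_centres = centres[n_axons + n_vessels : n_axons + n_vessels + n_gfp_only]
    nuc_centres = centres[n_axons + n_vessels + n_gfp_only :]

    chans = {
        name: np.zeros(shape, dtype=float) for name in ("NF", "MBP", "CD31", "DAPI", "GFP")
    }
    myel_idx = set(rng.choice(n_axons, size=n_myelinated, replace=False).tolist()) if n_axons else set()
    for i, (ctr, r) in enumerate(zip(ax_centres, ax_radii)):
        amp = foreground * rng.uniform(0.8, 1.2)
        _paint_disc(chans["NF"], ctr, r, amp)
        if i in myel_idx:
            # annulus spanning radii (r-1, r+2]: guarantees >=1 px NF overlap
            _paint_ring(chans["MBP"], ctr, r + 2, max(r - 1, 1), foreground * rng.uniform(0.8, 1.2))

    n_gfp_vessels = int(round(gfp_vessel_fraction * n_vessels))
    gfp_vessel_idx = (
        set(rng.choice(n_vessels, size=n_gfp_vessels, replace=False).tolist())
        if n_vessels
        else set()
    )
    for j, (ctr, r) in enumerate(zip(vs_centres, vs_radii)):
        _paint_ring(chans["CD31"], ctr, r, r - 2, foreground * rng.uniform(0.8, 1.2))
        theta = rng.uniform(0, 2 * np.pi)
        nuc = (ctr[0] + (r - 1) * np.sin(theta), ctr[1] + (r - 1) * np.cos(theta))
        _paint_disc(chans["DAPI"], nuc, 2, foreground * rng.uniform(0.8, 1.2))
        if j in gfp_vessel_idx:
            _paint_ring(chans["GFP"], ctr, r, r - 2, foreground * rng.uniform(0.8, 1.2))
    for ctr in gfp_centres:
        amp = foreground * rng.uniform(0.8, 1.2)
        _paint_disc(chans["GFP"], ctr, 3, amp)
        _paint_disc(chans["DAPI"], ctr, 2, foreground * rng.uniform(0.8, 1.2))
    for ctr, r in zip(nuc_centres, nuc_radii):
        _paint_disc(chans["DAPI"], ctr, r, foreground * rng.uniform(0.8, 1.2))

    if background_lam > 0:
        for name in chans:
            chans[name] = chans[name] + rng.poisson(background_lam, size=shape)

    bundle = ImageBundle(channels=chans, pixel_size=pixel_size, rois={"fascicle": roi})
    truth = SyntheticImageTruth(
        n_axons=n_axons,
        n_myelinated=n_myelinated,
        n_vessels=n_vessels,
        in_roi_counts={
            "axons": n_axons,
            "myelinated": n_myelinated,
            "vessels": n_vessels,
            "gfp_cells": n_gfp_only + n_gfp_vessels,
        },
        pixel_size=pixel_size,
        n_gfp=n_gfp_only + n_gfp_vessels,
        n_gfp_vessels=n_gfp_vessels,
        roi_area_mm2=roi_area_mm2,
    )
    return bundle, truth
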