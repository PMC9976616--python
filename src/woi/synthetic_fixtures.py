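"""Seeded generators for every pipeline input, with known ground truth.

These emulate the study conditions of the reference acquisition — a 78x78
pixel field of view (156x156 binned, downsampled by 2; 11 mm across),
16.8 Hz per LED channel, 5/5/10 s stimulus blocks — so every module can be
exercised end-to-end without real data:

* null Gaussian random fields of known FWHM (cluster-statistics calibration),
* homotopically correlated resting-state movies with a closed-form target r,
* forward Beer-Lambert multi-wavelength intensities from known dHbO/dHbR,
* block-design stimulus movies with an implanted Gaussian blob,
* paired subject-map groups with a known deficit region.

All generators take a seed (or Generator) and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_mask_atlas import (DEFAULT_ATLAS_SHAPE, DEFAULT_FRAME_RATE_HZ,
                            DEFAULT_PIXEL_PITCH_MM, BrainMask, RawStack,
                            symmetric_mask)
from .preprocess import SpectroscopyModel
from .stimulus import BlockDesign

FWHM_TO_SIGMA = 1 / np.sqrt(8 * np.log(2))


@dataclass
class SimConfig:
    """Default simulated geometry and noise levels (the study conditions)."""

    shape: tuple[int, int] = DEFAULT_ATLAS_SHAPE
    n_frames: int = 1000
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    fwhm_px: float = 7.0
    noise_sd: float = 1.0
    homotopic_r_target: float = 0.7
    stim: BlockDesign = field(default_factory=BlockDesign)
    seed: int = 0


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gaussian_random_field(shape: tuple[int, int], fwhm_px: float,
                          n_frames: int = 1,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Independent standardized Gaussian random fields of known smoothness.

    White Gaussian noise is generated on a grid padded by 3 kernel sigmas,
    convolved with a Gaussian kernel of the requested FWHM, cropped, and
    standardized per frame (exact zero mean, unit variance), so the field's
    smoothness is uniform up to the frame edge.
    """
    if fwhm_px < 1:
        raise ValueError("fwhm_px must be >= 1")
    rng = _rng(seed)
    sigma = fwhm_px * FWHM_TO_SIGMA
    pad = int(np.ceil(3 * sigma))
    ny, nx = shape
    out = np.empty((ny, nx, n_frames))
    for t in range(n_frames):
        w = rng.standard_normal((ny + 2 * pad, nx + 2 * pad))
        f = ndimage.gaussian_filter(w, sigma, mode="constant")[pad:pad + ny,
                                                               pad:pad + nx]
        out[:, :, t] = (f - f.mean()) / f.std()
    return out


def simulate_homotopic(shape: tuple[int, int], mask: BrainMask,
                       midline_col: float, r_target: float,
                       n_frames: int = 1000,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Resting-state movie whose mirror pixel pairs share correlation r.

    Each left pixel's trace is ``sqrt(r) * shared + sqrt(1 - r) * idio_L``
    and its mirror ``sqrt(r) * shared + sqrt(1 - r) * idio_R`` with
    independent unit-variance components, giving
    ``corr(left, right) = r_target`` in expectation.  Unpaired masked
    pixels get independent noise.
    """
    if not 0 <= r_target <= 1:
        raise ValueError("r_target must be in [0, 1]")
    rng = _rng(seed)
    ny, nx = shape
    movie = rng.standard_normal((ny, nx, n_frames))
    w_sh, w_id = np.sqrt(r_target), np.sqrt(1 - r_target)
    rows, cols = np.nonzero(mask.mask)
    for r, c in zip(rows, cols):
        if c >= midline_col:
            continue
        mc = int(round(2 * midline_col - c))
        if mc >= nx or not mask.mask[r, mc]:
            continue
        shared = rng.standard_normal(n_frames)
        movie[r, c] = w_sh * shared + w_id * rng.standard_normal(n_frames)
        movie[r, mc] = w_sh * shared + w_id * rng.standard_normal(n_frames)
    return movie


def simulate_multiwavelength(hemo_waveforms: tuple[np.ndarray, np.ndarray],
                             model: SpectroscopyModel,
                             fluor_truth: np.ndarray | float = 1.0,
                             x_ex: float = 1.0, x_em: float = 1.0,
                             I0: float = 1000.0, F0: float = 500.0,
                             shot_noise_sd: float = 0.0,
                             seed: int | np.random.Generator = 0,
                             frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                             ) -> tuple[dict[float, RawStack], dict]:
    """Forward Beer-Lambert intensities from known hemoglobin fluctuations.

    Reflectance channel i: ``I_i = I0 * exp(-L_i (eps_i . dC))``.
    Fluorescence channel: ``F = F0 * fluor_truth *
    exp(-dmua_ex * x_ex - dmua_em * x_em)``.  Returns the per-wavelength
    stacks plus the ground truth (dHbO, dHbR, fluor movies).
    """
    rng = _rng(seed)
    dhbo, dhbr = (np.asarray(w, dtype=float) for w in hemo_waveforms)
    stacks: dict[float, RawStack] = {}
    for i, wl in enumerate(model.wavelengths):
        atten = model.L[i] * (model.E[i, 0] * dhbo + model.E[i, 1] * dhbr)
        I = I0 * np.exp(-atten)
        if shot_noise_sd:
            I = I + rng.normal(0, shot_noise_sd, I.shape)
        stacks[wl] = RawStack(I, frame_rate_hz, wl)
    truth = {"dhbo": dhbo, "dhbr": dhbr}
    if model.excitation_nm is not None and model.eps_ex is not None:
        fl = np.broadcast_to(np.asarray(fluor_truth, dtype=float), dhbo.shape)
        dmua_ex = model.eps_ex[0] * dhbo + model.eps_ex[1] * dhbr
        dmua_em = model.eps_em[0] * dhbo + model.eps_em[1] * dhbr
        F = F0 * fl * np.exp(-dmua_ex * x_ex - dmua_em * x_em)
        if shot_noise_sd:
            F = F + rng.normal(0, shot_noise_sd, F.shape)
        stacks[model.excitation_nm] = RawStack(F, frame_rate_hz,
                                               model.excitation_nm)
        truth["fluor"] = np.array(fl)
    return stacks, truth


def default_hemo_waveforms(shape: tuple[int, int] = (16, 16),
                           n_frames: int = 64,
                           frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                           amp_molar: float = 1e-6,
                           freq_hz: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean sinusoidal dHbO/dHbR (~1 uM, anticorrelated) on a spatial bump."""
    t = np.arange(n_frames) / frame_rate_hz
    ny, nx = shape
    rr, cc = np.mgrid[0:ny, 0:nx]
    pattern = np.exp(-(((rr - ny / 2) ** 2 + (cc - nx / 2) ** 2)
                       / (2 * (max(ny, nx) / 4) ** 2)))
    wave = np.sin(2 * np.pi * freq_hz * t)
    dhbo = amp_molar * pattern[:, :, None] * wave
    return dhbo, -0.4 * dhbo


def simulate_stim(shape: tuple[int, int], design: BlockDesign,
                  blob_center: tuple[float, float], blob_sigma: float,
                  amplitude: float, noise_sd: float,
                  seed: int | np.random.Generator = 0,
                  smooth_fwhm_px: float | None = None) -> tuple[np.ndarray, dict]:
    """Block-design movie: noise plus a Gaussian blob boxcar during stim-on.

    SNR (amplitude / noise_sd) of 5 or more puts the 80%-max ROI centroid
    within ~2 px of the true blob center.  Returns (movie, truth) with
    truth holding center, amplitude, sigma, and the on-frame indices.
    """
    rng = _rng(seed)
    ny, nx = shape
    nt = design.block_len_frames * design.n_blocks
    if smooth_fwhm_px:
        movie = noise_sd * gaussian_random_field(shape, smooth_fwhm_px, nt, rng)
    else:
        movie = rng.normal(0, noise_sd, (ny, nx, nt))
    rr, cc = np.mgrid[0:ny, 0:nx]
    blob = amplitude * np.exp(-(((rr - blob_center[0]) ** 2
                                 + (cc - blob_center[1]) ** 2)
                                / (2 * blob_sigma ** 2)))
    on = np.zeros(design.block_len_frames)
    on[design.on_frames] = 1.0
    boxcar = np.tile(on, design.n_blocks)
    movie += blob[:, :, None] * boxcar[None, None, :]
    truth = {"center": blob_center, "amplitude": amplitude,
             "sigma": blob_sigma, "on_frames": design.on_frames,
             "boxcar": on}
    return movie, truth


def simulate_group_difference(base_fc_field: np.ndarray,
                              deficit_region: np.ndarray,
                              effect_size: float,
                              n_subjects: int = 4,
                              noise_sd: float = 0.12,
                              fwhm_px: float = 7.0,
                              seed: int | np.random.Generator = 0,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Paired subject-map groups with a focal deficit in group B.

    Subject maps are ``base + noise_sd * GRF(fwhm)``; group B additionally
    has ``effect_size`` subtracted inside ``deficit_region``.  With the
    defaults the per-pixel paired Cohen's d inside the region is
    ``effect_size / (noise_sd * sqrt(2)) ~ 6`` — a large effect, matching
    the n = 4 paired design the method targets.  Returns (maps_a, maps_b)
    stacks with subjects on the last axis.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    rng = _rng(seed)
    base = np.asarray(base_fc_field, dtype=float)
    region = np.asarray(deficit_region, bool)
    shape = base.shape
    a = np.empty(shape + (n_subjects,))
    b = np.empty(shape + (n_subjects,))
    for i in range(n_subjects):
        a[:, :, i] = base + noise_sd * gaussian_random_field(shape, fwhm_px, 1, rng)[:, :, 0]
        b[:, :, i] = (base + noise_sd * gaussian_random_field(shape, fwhm_px, 1, rng)[:, :, 0]
                      - effect_size * region)
    return a, b


def disc_region(shape: tuple[int, int], center: tuple[float, float],
                radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2


def default_mask(shape: tuple[int, int] = DEFAULT_ATLAS_SHAPE) -> BrainMask:
    """Symmetric elliptical brain mask used by the simulations."""
    return symmetric_mask(shape)
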