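"""Raw multi-wavelength stacks -> hemoglobin and calcium contrast movies.

The processing chain mirrors the standard wide-field optical imaging
pipeline: dark-frame subtraction, spatiotemporal detrending, then two
branches — reflectance channels go through the log-mean transform and a
modified Beer-Lambert inversion to yield oxy-/deoxyhemoglobin concentration
changes, while the fluorescence channel is mean-normalized, corrected for
hemoglobin absorption of excitation and emission light, and log-mean
transformed.  System-independent steps follow: 5x5 Gaussian spatial
smoothing (sigma 1.3 px), global signal regression, optional atlas
registration, Butterworth temporal filtering and movement QC.

Log-mean transform
------------------
``logmean(F)(p, t) = ln( F(p, t) / mean_t F(p, t) )``

Modified Beer-Lambert law
-------------------------
At wavelength i, the change in optical density is
``y_i(p, t) = -logmean_i(p, t) = sum_s eps_i,s * L_i * dC_s(p, t)``
with species s in (HbO, HbR), extinction coefficients ``eps`` LED-spectrum
weighted, and differential pathlengths ``L_i``.  ``dC`` is recovered per
pixel and frame by (exact for two wavelengths) least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io_mask_atlas import BrainMask, RawStack

log = logging.getLogger("woi")

CALCIUM_BAND_HZ = (0.4, 4.0)       # delta band for GCaMP
HEMOGLOBIN_BAND_HZ = (0.009, 0.08)  # infraslow / canonical FC band
DEFAULT_BUTTER_ORDER = 5
SMOOTH_KERNEL_SIZE = 5
SMOOTH_SIGMA_PX = 1.3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectroscopyModel:
    """LED-weighted extinction matrix and pathlengths for the Beer-Lambert fit.

    ``E[i]`` is (eps_HbO, eps_HbR) in cm^-1 M^-1 for reflectance channel i;
    ``L[i]`` the differential pathlength in cm.  ``eps_ex``/``eps_em`` hold
    the band-averaged extinction pair at the fluorescence excitation LED and
    the emission band, used for hemoglobin correction of fluorescence.
    """

    wavelengths: tuple[float, ...]
    E: np.ndarray                     # (n_wavelengths, 2), species (HbO, HbR)
    L: np.ndarray                     # (n_wavelengths,)
    eps_ex: np.ndarray | None = None  # (2,) at excitation LED
    eps_em: np.ndarray | None = None  # (2,) over emission band
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.E.shape != (len(self.wavelengths), 2):
            raise ValueError("E must be n_wavelengths x 2 (HbO, HbR)")
        if np.any(self.L <= 0):
            raise ValueError("pathlengths must be positive")

    @property
    def A(self) -> np.ndarray:
        """Design matrix diag(L) @ E of the Beer-Lambert system."""
        return self.L[:, None] * self.E

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))


@dataclass
class ContrastStack:
    """Processed contrast movies sharing one mask and frame rate."""

    hbo: np.ndarray
    hbr: np.ndarray
    fluor: np.ndarray
    mask: BrainMask
    frame_rate_hz: float

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.hbo, self.hbr, self.fluor)}
        if len(shapes) != 1:
            raise ValueError("contrast movies must share shape")

    @property
    def contrasts(self) -> dict[str, np.ndarray]:
        return {"hbo": self.hbo, "hbr": self.hbr, "fluor": self.fluor}


@dataclass
class QCReport:
    """Movement / artifact surrogate metrics from the temporal derivative."""

    pixels_by_time: np.ndarray     # masked pixels x frames
    sq_deriv: np.ndarray           # masked pixels x (frames - 1)
    rms_deriv: np.ndarray          # (frames - 1,)
    global_var_deriv: float


# ---------------------------------------------------------------------------
# system-dependent steps
# ---------------------------------------------------------------------------

def subtract_dark(stack: RawStack, dark: np.ndarray) -> RawStack:
    """Subtract an ambient dark frame, clipping negatives to zero."""
    dark = np.asarray(dark, dtype=float)
    if dark.shape != stack.shape:
        raise ValueError(f"dark frame shape {dark.shape} != stack {stack.shape}")
    out = stack.data - dark[:, :, None]
    n_clip = int((out < 0).sum())
    if n_clip:
        log.info("subtract_dark: clipped %d negative samples to 0", n_clip)
    return RawStack(np.clip(out, 0, None), stack.frame_rate_hz,
                    stack.wavelength_nm, stack.pixel_pitch_mm)


def detrend_temporal(movie: np.ndarray) -> np.ndarray:
    """Remove each pixel's least-squares linear trend in time (incl. mean)."""
    movie = np.asarray(movie, dtype=float)
    if movie.shape[-1] < 3:
        raise ValueError("temporal detrend needs >= 3 frames")
    return signal.detrend(movie, axis=-1, type="linear")


def detrend_spatial(frames: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Remove the best-fit plane a + b*row + c*col (fit over mask) per frame."""
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[:, :, None]
    ny, nx, nt = frames.shape
    if mask is None:
        mask = np.ones((ny, nx), bool)
    mask = np.asarray(mask, bool)
    rr, cc = np.mgrid[0:ny, 0:nx]
    G = np.column_stack([np.ones(mask.sum()), rr[mask], cc[mask]])
    Gfull = np.stack([np.ones_like(rr, float), rr, cc], axis=-1)  # ny,nx,3
    y = frames[mask]                                              # npix, nt
    coef, *_ = np.linalg.lstsq(G, y, rcond=None)                  # 3, nt
    out = frames - Gfull @ coef
    return out[:, :, 0] if single else out


def detrend_spatiotemporal(stack: RawStack, mask: np.ndarray | None = None) -> RawStack:
    """Linear temporal detrend per pixel, then a spatial plane per frame.

    Removes global artifactual drifts (photobleaching, LED current drift)
    and static illumination/skull gradients.  Output pixel traces are
    zero-mean; the pipeline re-adds the temporal-mean baseline before
    ratio-based steps (log-mean, mean normalization), which need a
    positive baseline.
    """
    out = detrend_temporal(stack.data)
    out = detrend_spatial(out, mask)
    return RawStack(out, stack.frame_rate_hz,
                    stack.wavelength_nm, stack.pixel_pitch_mm)


def logmean(movie: np.ndarray, mask: np.ndarray | None = None,
            eps_floor: float | None = None) -> np.ndarray:
    """Pixel-wise log of intensity over its temporal mean.

    Raises if any considered sample or temporal mean is non-positive, unless
    ``eps_floor`` is given, in which case samples are floored at that value.
    """
    movie = np.asarray(movie, dtype=float)
    sel = np.ones(movie.shape[:2], bool) if mask is None else np.asarray(mask, bool)
    vals = movie[sel]
    if eps_floor is not None:
        vals = np.clip(vals, eps_floor, None)
    n_bad = int((vals <= 0).any(axis=-1).sum())
    if n_bad:
        raise ValueError(f"logmean: {n_bad} masked pixels have non-positive samples")
    mean = vals.mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("logmean: non-positive temporal mean")
    out = np.zeros_like(movie)
    out[sel] = np.log(vals / mean)
    return out


def mean_normalize(movie: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide each pixel's trace by its temporal mean (mean becomes 1)."""
    movie = np.asarray(movie, dtype=float)
    sel = np.ones(movie.shape[:2], bool) if mask is None else np.asarray(mask, bool)
    mean = movie[sel].mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("mean_normalize: non-positive temporal mean")
    out = np.zeros_like(movie)
    out[sel] = movie[sel] / mean
    return out


# ---------------------------------------------------------------------------
# spectroscopy
# ---------------------------------------------------------------------------

def _band_average_eps(ext: pd.DataFrame, weight_nm: np.ndarray,
                      weight: np.ndarray) -> np.ndarray:
    """Trapezoidal weight-averaged (eps_HbO, eps_HbR) over a band."""
    lo = max(weight_nm.min(), ext.wavelength_nm.min())
    hi = min(weight_nm.max(), ext.wavelength_nm.max())
    if hi <= lo:
        raise ValueError("spectrum does not overlap extinction wavelength range")
    grid = weight_nm[(weight_nm >= lo) & (weight_nm <= hi)]
    w = np.interp(grid, weight_nm, weight)
    norm = np.trapezoid(w, grid)
    if norm <= 0:
        raise ValueError("degenerate spectrum weight in overlap region")
    out = [np.trapezoid(np.interp(grid, ext.wavelength_nm, ext[c]) * w, grid) / norm
           for c in ("eps_hbo2", "eps_hb")]
    return np.array(out)


def build_spectroscopy_model(ext_table: pd.DataFrame,
                             led_tables: Mapping[float, pd.DataFrame],
                             L: Mapping[float, float] | Sequence[float] | float = 1.0,
                             excitation_nm: float | None = 470,
                             emission_band_nm: tuple[float, float] = (515, 560)) -> SpectroscopyModel:
    """Integrate extinction spectra over the LED emission spectra.

    ``led_tables`` maps nominal LED wavelength -> emission table.  The LED
    matching ``excitation_nm`` is excluded from the reflectance rows and
    used for the fluorescence excitation extinction pair; ``eps_em`` is a
    flat average over ``emission_band_nm`` (past the 515 nm longpass).
    Pathlengths default to 1 cm, leaving concentrations in
    concentration-times-pathlength units that cancel in correlation-based
    analyses.
    """
    hemo_wl = sorted(w for w in led_tables if w != excitation_nm)
    if len(hemo_wl) < 2:
        raise ValueError("need >= 2 reflectance wavelengths for spectroscopy")
    E = np.array([_band_average_eps(ext_table,
                                    led_tables[w].wavelength_nm.to_numpy(),
                                    led_tables[w].relative_intensity.to_numpy())
                  for w in hemo_wl])
    if np.isscalar(L):
        Lvec = np.full(len(hemo_wl), float(L))
    elif isinstance(L, Mapping):
        Lvec = np.array([float(L[w]) for w in hemo_wl])
    else:
        Lvec = np.asarray(L, dtype=float)
    eps_ex = None
    if excitation_nm is not None and excitation_nm in led_tables:
        t = led_tables[excitation_nm]
        eps_ex = _band_average_eps(ext_table, t.wavelength_nm.to_numpy(),
                                   t.relative_intensity.to_numpy())
    lo, hi = emission_band_nm
    grid = ext_table.wavelength_nm.to_numpy()
    band = np.linspace(max(lo, grid.min()), min(hi, grid.max()), 64)
    eps_em = _band_average_eps(ext_table, band, np.ones_like(band))
    model = SpectroscopyModel(tuple(hemo_wl), E, Lvec, eps_ex, eps_em, excitation_nm)
    log.info("spectroscopy model: wavelengths %s, cond(A) = %.3g",
             hemo_wl, model.condition_number)
    return model


def solve_spectroscopy(logmean_stacks: Mapping[float, np.ndarray] | Sequence[np.ndarray],
                       model: SpectroscopyModel,
                       max_condition: float = 1e8) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law per pixel and frame.

    Solves ``y = A dC`` in least squares with ``y_i = -logmean_i`` and
    ``A = diag(L) E``; exact when two wavelengths are used.  Returns
    ``(dHbO, dHbR)`` movies.
    """
    if isinstance(logmean_stacks, Mapping):
        ys = [np.asarray(logmean_stacks[w], dtype=float) for w in model.wavelengths]
    else:
        ys = [np.asarray(y, dtype=float) for y in logmean_stacks]
    if len(ys) != len(model.wavelengths):
        raise ValueError("one log-mean movie per model wavelength required")
    if len(ys) < 2:
        raise ValueError("need >= 2 wavelengths")
    A = model.A
    cond = np.linalg.cond(A)
    if cond > max_condition:
        raise ValueError(f"Beer-Lambert system is rank deficient (cond = {cond:.3g})")
    shape = ys[0].shape
    y = -np.stack([v.reshape(-1) for v in ys])          # n_wl x (pix*frames)
    dc = np.linalg.pinv(A) @ y                           # 2 x (pix*frames)
    return dc[0].reshape(shape), dc[1].reshape(shape)


def hemoglobin_correct_fluorescence(fluor_norm: np.ndarray,
                                    hbo: np.ndarray, hbr: np.ndarray,
                                    model: SpectroscopyModel,
                                    x_ex: float = 1.0, x_em: float = 1.0) -> np.ndarray:
    """Undo hemoglobin absorption of excitation and emission light.

    Measured fluorescence is attenuated by
    ``exp(-dmua_ex * x_ex - dmua_em * x_em)`` with
    ``dmua = eps_HbO * dHbO + eps_HbR * dHbR`` at the excitation LED and the
    emission band; the correction multiplies by the inverse exponential.
    """
    if model.eps_ex is None or model.eps_em is None:
        raise ValueError("model lacks excitation/emission extinction rows")
    if x_ex <= 0 or x_em <= 0:
        raise ValueError("pathlengths must be positive")
    dmua_ex = model.eps_ex[0] * hbo + model.eps_ex[1] * hbr
    dmua_em = model.eps_em[0] * hbo + model.eps_em[1] * hbr
    return np.asarray(fluor_norm, dtype=float) * np.exp(dmua_ex * x_ex + dmua_em * x_em)


# ---------------------------------------------------------------------------
# system-independent steps
# ---------------------------------------------------------------------------

def gaussian_kernel(size: int = SMOOTH_KERNEL_SIZE,
                    sigma: float = SMOOTH_SIGMA_PX) -> np.ndarray:
    """Truncated Gaussian kernel renormalized to unit sum."""
    half = (size - 1) / 2
    ax = np.arange(size) - half
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def smooth_spatial(movie: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """5x5 Gaussian smoothing (sigma 1.3 px) with masked normalization.

    Each frame is convolved with the unit-sum kernel; dividing by the
    convolved mask keeps off-brain zeros (and frame borders) from bleeding
    into brain pixels.
    """
    movie = np.asarray(movie, dtype=float)
    single = movie.ndim == 2
    if single:
        movie = movie[:, :, None]
    if mask is None:
        mask = np.ones(movie.shape[:2], bool)
    mask = np.asarray(mask, bool)
    k = gaussian_kernel()
    wsum = ndimage.convolve(mask.astype(float), k, mode="constant")
    out = np.zeros_like(movie)
    for t in range(movie.shape[2]):
        num = ndimage.convolve(movie[:, :, t] * mask, k, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            frame = np.where(wsum > 0, num / wsum, 0.0)
        out[:, :, t] = frame * mask
    return out[:, :, 0] if single else out


def global_signal_regress(movie: np.ndarray,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Regress the mask-averaged global time course out of every pixel.

    ``g(t)`` is the mean trace over masked pixels; each pixel's output is
    ``y_p - beta_p * g`` with ``beta_p`` the covariance-based slope, leaving
    every output trace with zero covariance against ``g``.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[-1] < 2:
        raise ValueError("GSR needs >= 2 frames")
    if mask is None:
        mask = np.ones(movie.shape[:2], bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    g = movie[mask].mean(axis=0)
    gc = g - g.mean()
    gg = gc @ gc
    if gg == 0:
        raise ValueError("constant global signal; regression undefined")
    y = movie[mask]
    beta = ((y - y.mean(axis=-1, keepdims=True)) @ gc) / gg
    out = np.zeros_like(movie)
    out[mask] = y - beta[:, None] * g[None, :]
    return out


def bandpass(movie: np.ndarray, low_hz: float, high_hz: float,
             frame_rate_hz: float, order: int = DEFAULT_BUTTER_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass along time."""
    nyq = frame_rate_hz / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, Nyquist={nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=frame_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(movie, dtype=float), axis=-1)


def downsample(movie: np.ndarray, spatial_factor: int = 1,
               temporal_factor: int = 1) -> np.ndarray:
    """Non-overlapping block means in space and frame means in time.

    Trailing rows/cols/frames that do not fill a block are dropped (logged).
    The caller divides the frame rate by ``temporal_factor``.
    """
    if spatial_factor < 1 or temporal_factor < 1:
        raise ValueError("factors must be >= 1")
    movie = np.asarray(movie, dtype=float)
    single = movie.ndim == 2
    if single:
        movie = movie[:, :, None]
    ny, nx, nt = movie.shape
    s, f = spatial_factor, temporal_factor
    ny2, nx2, nt2 = ny // s, nx // s, nt // f
    dropped = (ny - ny2 * s, nx - nx2 * s, nt - nt2 * f)
    if any(dropped):
        log.info("downsample: dropped trailing (rows, cols, frames) = %s", dropped)
    m = movie[:ny2 * s, :nx2 * s, :nt2 * f]
    m = m.reshape(ny2, s, nx2, s, nt2, f).mean(axis=(1, 3, 5))
    return m[:, :, 0] if single else m


def movement_metric(movie: np.ndarray, mask: np.ndarray | None = None) -> QCReport:
    """QC surrogate of motion/artifact from the temporal first difference.

    Reports the masked pixels-by-time matrix, the squared derivative per
    pixel and step, the per-step RMS derivative over the mask, and the
    variance of the global mean derivative trace.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[-1] < 2:
        raise ValueError("movement metric needs >= 2 frames")
    if mask is None:
        mask = np.ones(movie.shape[:2], bool)
    mask = np.asarray(mask, bool)
    pix = movie[mask]                       # npix x nt
    d = np.diff(pix, axis=-1)
    rms = np.sqrt((d ** 2).mean(axis=0))
    g = pix.mean(axis=0)
    gvar = float(np.var(np.diff(g)))
    return QCReport(pix, d ** 2, rms, gvar)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def process_stacks(stacks: Sequence[RawStack],
                   dark: np.ndarray,
                   mask: BrainMask,
                   model: SpectroscopyModel,
                   *,
                   fluor_nm: float | None = 470,
                   x_ex: float = 1.0, x_em: float = 1.0,
                   detrend: bool = True, smooth: bool = True, gsr: bool = True,
                   center: bool = True) -> ContrastStack:
    """Run the full system-dependent + system-independent chain.

    Order: dark subtraction -> spatiotemporal detrend -> per branch
    {log-mean -> Beer-Lambert | mean-normalize -> hemoglobin-correct ->
    log-mean} -> per-pixel temporal mean removal -> spatial smoothing ->
    global signal regression.  Atlas registration and temporal filtering
    are applied separately when needed.  Detrending, smoothing and GSR
    remove globally shared variance (artifacts on real data); disable them
    to evaluate the pure spectroscopic forward/inverse identity.
    """
    m = mask.mask
    by_wl: dict[float, RawStack] = {}
    for s in stacks:
        s = subtract_dark(s, dark)
        if detrend:
            baseline = s.data.mean(axis=-1, keepdims=True)
            s = detrend_spatiotemporal(s, m)
            s = RawStack(s.data + baseline, s.frame_rate_hz,
                         s.wavelength_nm, s.pixel_pitch_mm)
        by_wl[s.wavelength_nm] = s
    missing = [w for w in model.wavelengths if w not in by_wl]
    if missing:
        raise ValueError(f"missing reflectance channels {missing}")
    lm = {w: logmean(by_wl[w].data, m) for w in model.wavelengths}
    hbo, hbr = solve_spectroscopy(lm, model)
    if fluor_nm is not None:
        if fluor_nm not in by_wl:
            raise ValueError(f"missing fluorescence channel {fluor_nm}")
        fl = mean_normalize(by_wl[fluor_nm].data, m)
        fl = hemoglobin_correct_fluorescence(fl, hbo, hbr, model, x_ex, x_em)
        fluor = logmean(fl, m)
    else:
        fluor = np.zeros_like(hbo)
    out = {}
    for name, mv in (("hbo", hbo), ("hbr", hbr), ("fluor", fluor)):
        if center:
            mv = mv - mv.mean(axis=-1, keepdims=True)
        if smooth:
            mv = smooth_spatial(mv, m)
        if gsr:
            mv = global_signal_regress(mv, m)
        out[name] = mv * m[:, :, None]
    rate = stacks[0].frame_rate_hz
    return ContrastStack(out["hbo"], out["hbr"], out["fluor"], mask, rate)
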