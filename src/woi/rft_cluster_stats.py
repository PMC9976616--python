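"""Cluster-extent multiple-comparisons control for 2D pixel maps.

Pixel-wise tests over a field of view produce thousands of correlated
comparisons; Bonferroni correction ignores the spatial smoothness imposed by
optics and biology and is far too stringent.  Random field theory (RFT)
instead models the statistic image as a smooth Gaussian field and asks how
large a contiguous suprathreshold cluster must be before it is unlikely
under the null at family-wise error rate alpha.

For a standardized 2D Gaussian field thresholded at z-score ``Zt``:

    E[m]  = R * 4 ln 2 * (2 pi)^(-3/2) * Zt * exp(-Zt^2 / 2)   expected clusters
    R     = x^2 / FWHM^2                                       resel count
    |Lam| = [FWHM^2 / (4 ln 2)]^(-2)                           smoothness <-> FWHM
    E[n]  = 2 pi FWHM^2 / (Zt^2 * 4 ln 2)                      expected cluster size
    E[N]  = E[m] * E[n]                                        suprathreshold pixels
    P(n >= x) = exp(-beta x),   beta = Gamma(2) * Zt^2 * 4 ln 2 / (2 pi FWHM^2)
    k_alpha = (1 / beta) * ln( -E[m] / ln(1 - alpha) )

where ``Lam`` is the covariance matrix of the field's spatial partial
derivatives (estimated here from forward finite differences of one
standardized frame) and ``FWHM`` the effective point-spread width.
Clusters of at least ``ceil(k_alpha)`` pixels are declared significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

log = logging.getLogger("woi")

FOUR_LN2 = 4 * np.log(2)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFTParams:
    """Cluster-defining z threshold, FWE rate, and image side length."""

    Zt: float = 3.09          # upper-tail z at p = 0.001
    alpha: float = 0.05
    x: int = 78

    def __post_init__(self) -> None:
        if self.Zt <= 0:
            raise ValueError("Zt must be positive")
        if self.Zt < 2:
            log.warning("RFT cluster approximation is asymptotic in Zt; "
                        "Zt = %.3g is low", self.Zt)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.x < 2:
            raise ValueError("x must be >= 2")


@dataclass
class SmoothnessEstimate:
    """Derivative covariance Lambda and the FWHM it implies."""

    lambda_mat: np.ndarray
    fwhm_px: float
    fwhm_mm: float | None = None


@dataclass
class ClusterNull:
    """RFT null quantities for one (FWHM, Zt, alpha, x) setting."""

    R: float
    Em: float
    En: float
    EN: float
    beta: float
    k_alpha: float

    @property
    def k_alpha_px(self) -> int:
        """Integer cluster-size threshold (conservative ceiling)."""
        return int(np.ceil(self.k_alpha))


@dataclass
class ClusterResult:
    """Pixel-wise test maps plus cluster- and Bonferroni-corrected masks."""

    t_map: np.ndarray
    p_map: np.ndarray
    df: int
    suprathreshold_mask: np.ndarray
    labels: np.ndarray
    cluster_sizes: np.ndarray
    significant_mask: np.ndarray
    bonferroni_mask: np.ndarray
    null: ClusterNull


# ---------------------------------------------------------------------------
# thresholds & smoothness
# ---------------------------------------------------------------------------

def z_threshold(p: float) -> float:
    """Standard-normal upper-tail quantile, e.g. p = 0.001 -> 3.09."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(stats.norm.isf(p))


def fwhm_px_to_mm(fwhm_px: float, pixel_pitch_mm: float) -> float:
    return fwhm_px * pixel_pitch_mm


def estimate_fwhm(frame: np.ndarray, mask: np.ndarray | None = None,
                  pixel_pitch_mm: float | None = None) -> SmoothnessEstimate:
    """Estimate field smoothness from one frame's spatial derivatives.

    The frame is standardized over the mask (zero mean, unit variance), its
    forward finite differences taken along rows and columns, and the 2x2
    covariance ``Lambda`` of the derivative pairs computed over pixels whose
    forward neighbours are also masked.  Then
    ``FWHM = sqrt(4 ln 2) * |Lambda|^(-1/4)``.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is None:
        mask = np.ones(frame.shape, bool)
    mask = np.asarray(mask, bool)
    vals = frame[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant frame; smoothness undefined")
    f = np.where(mask, (frame - vals.mean()) / sd, 0.0)
    dy = f[1:, :-1] - f[:-1, :-1]
    dx = f[:-1, 1:] - f[:-1, :-1]
    valid = mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:]
    n = int(valid.sum())
    if n < 100:
        raise ValueError(f"only {n} interior pixels; need >= 100 for Lambda")
    lam = np.cov(np.stack([dy[valid], dx[valid]]))
    det = float(np.linalg.det(lam))
    if det <= 0:
        raise ValueError("singular derivative covariance")
    fwhm = float(np.sqrt(FOUR_LN2) * det ** -0.25)
    mm = fwhm * pixel_pitch_mm if pixel_pitch_mm else None
    return SmoothnessEstimate(lam, fwhm, mm)


# ---------------------------------------------------------------------------
# RFT null quantities
# ---------------------------------------------------------------------------

def resel_count(x: float, fwhm_px: float) -> float:
    """Resolution elements R = x^2 / FWHM^2 for an x-by-x image."""
    if x <= 0 or fwhm_px <= 0:
        raise ValueError("x and FWHM must be positive")
    return x ** 2 / fwhm_px ** 2


def expected_clusters(R: float, Zt: float) -> float:
    """Expected suprathreshold cluster count E[m] at z threshold Zt."""
    return R * FOUR_LN2 * (2 * np.pi) ** -1.5 * Zt * np.exp(-0.5 * Zt ** 2)


def expected_cluster_size(fwhm_px: float, Zt: float) -> tuple[float, float]:
    """Expected null cluster size E[n] and exponential rate beta = 1/E[n]."""
    if fwhm_px <= 0 or Zt <= 0:
        raise ValueError("FWHM and Zt must be positive")
    En = 2 * np.pi * fwhm_px ** 2 / (Zt ** 2 * FOUR_LN2)
    return En, 1.0 / En


def cluster_size_threshold(Em: float, beta: float, alpha: float) -> float:
    """Cluster-size threshold k_alpha controlling FWE at level alpha.

    Solves ``1 - exp(-E[m] exp(-beta k)) = alpha``.  If even single-pixel
    clusters are rarer than alpha demands the argument of the log drops
    below 1 and the threshold degenerates to 0 (every cluster significant).
    """
    if Em <= 0 or beta <= 0:
        raise ValueError("Em and beta must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    arg = -Em / np.log1p(-alpha)
    if arg <= 1:
        log.warning("cluster_size_threshold: degenerate regime (arg = %.3g); "
                    "k_alpha = 0", arg)
        return 0.0
    return float(np.log(arg) / beta)


def cluster_null(params: RFTParams, fwhm_px: float) -> ClusterNull:
    """All RFT null quantities for one parameter setting."""
    R = resel_count(params.x, fwhm_px)
    Em = expected_clusters(R, params.Zt)
    En, beta = expected_cluster_size(fwhm_px, params.Zt)
    k = cluster_size_threshold(Em, beta, params.alpha)
    return ClusterNull(R, Em, En, Em * En, beta, k)


# ---------------------------------------------------------------------------
# pixel-wise tests and clustering
# ---------------------------------------------------------------------------

def pixelwise_ttest(maps_a: np.ndarray, maps_b: np.ndarray | None = None,
                    mode: str = "one_sample") -> tuple[np.ndarray, np.ndarray, int]:
    """Pixel-wise t-test over subject map stacks (spatial x subjects last).

    Modes: ``one_sample`` (vs 0), ``paired`` (a - b differences), or
    ``two_sample`` (pooled-variance).  Returns (t_map, two-tailed p_map, df);
    zero-variance pixels carry NaN.
    """
    a = np.asarray(maps_a, dtype=float)
    if mode == "paired":
        if maps_b is None or np.shape(maps_b)[-1] != a.shape[-1]:
            raise ValueError("paired test needs equal subject counts")
        a = a - np.asarray(maps_b, dtype=float)
        mode = "one_sample"
        maps_b = None
    if mode == "one_sample":
        n = a.shape[-1]
        if n < 2:
            raise ValueError("need n >= 2 subjects")
        df = n - 1
        mean = a.mean(axis=-1)
        sd = a.std(axis=-1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        t[sd == 0] = np.nan
    elif mode == "two_sample":
        b = np.asarray(maps_b, dtype=float)
        n1, n2 = a.shape[-1], b.shape[-1]
        if min(n1, n2) < 2:
            raise ValueError("need n >= 2 per group")
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(axis=-1, ddof=1)
               + (n2 - 1) * b.var(axis=-1, ddof=1)) / df
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (a.mean(axis=-1) - b.mean(axis=-1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t[sp2 == 0] = np.nan
    else:
        raise ValueError(f"unknown mode '{mode}'")
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, df


def t_to_z(t_map: np.ndarray, df: int) -> np.ndarray:
    """Exact sign-preserving t -> z conversion via one-tailed p-values."""
    t = np.asarray(t_map, dtype=float)
    with np.errstate(invalid="ignore"):
        z = stats.norm.isf(stats.t.sf(t, df))
    return z


def label_clusters(suprathreshold_mask: np.ndarray,
                   connectivity: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a binary mask; labels in raster order.

    ``connectivity`` 8 (default, diagonal neighbours join) or 4.
    Returns (label image, sizes array indexed label-1).
    """
    if connectivity == 8:
        structure = np.ones((3, 3), int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(np.asarray(suprathreshold_mask, bool), structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def apply_cluster_filter(labels: np.ndarray, cluster_sizes: np.ndarray,
                         k_alpha: float, strict: bool = False) -> np.ndarray:
    """Union of clusters with size >= ceil(k_alpha) (or > if ``strict``)."""
    if k_alpha < 0:
        raise ValueError("k_alpha must be >= 0")
    k = int(np.ceil(k_alpha))
    keep = cluster_sizes > k if strict else cluster_sizes >= k
    ids = np.nonzero(keep)[0] + 1
    return np.isin(labels, ids)


def bonferroni_mask(p_map: np.ndarray, alpha: float, n_masked: int) -> np.ndarray:
    """Pixels surviving the Bonferroni-corrected threshold alpha/n."""
    if n_masked < 1:
        raise ValueError("n_masked must be >= 1")
    with np.errstate(invalid="ignore"):
        return np.asarray(p_map) < alpha / n_masked


def run_cluster_analysis(maps_a: np.ndarray, maps_b: np.ndarray | None,
                         mask: np.ndarray, params: RFTParams,
                         fwhm_px: float | None = None,
                         mode: str = "paired", tail: str = "pos",
                         connectivity: int = 8) -> ClusterResult:
    """Full inference chain: t-test -> z field -> clusters -> k_alpha filter.

    The cluster-defining threshold ``params.Zt`` is applied to the exact
    t->z converted map on the requested tail ('pos', 'neg' or 'two' via
    |z|).  ``fwhm_px`` defaults to the smoothness of the group-mean map
    (or mean difference for paired mode).
    """
    mask = np.asarray(mask, bool)
    t, p, df = pixelwise_ttest(maps_a, maps_b, mode)
    if fwhm_px is None:
        base = np.asarray(maps_a, dtype=float)
        if maps_b is not None:
            base = base - np.asarray(maps_b, dtype=float)
        fwhm_px = estimate_fwhm(np.nan_to_num(base.mean(axis=-1)), mask).fwhm_px
    null = cluster_null(params, fwhm_px)
    z = t_to_z(t, df)
    if tail == "pos":
        supra = z >= params.Zt
    elif tail == "neg":
        supra = -z >= params.Zt
    elif tail == "two":
        supra = np.abs(z) >= params.Zt
    else:
        raise ValueError("tail must be 'pos', 'neg' or 'two'")
    supra = supra & mask & np.isfinite(z)
    labels, sizes = label_clusters(supra, connectivity)
    sig = apply_cluster_filter(labels, sizes, null.k_alpha)
    bonf = bonferroni_mask(p, params.alpha, int(mask.sum())) & mask
    return ClusterResult(t, p, df, supra, labels, sizes, sig, bonf, null)


# ---------------------------------------------------------------------------
# Monte-Carlo FWE calibration
# ---------------------------------------------------------------------------

def fwe_calibration(n_sims: int, shape: tuple[int, int], fwhm_px: float,
                    Zt: float = 3.09, alpha: float = 0.05,
                    seed: int | np.random.Generator = 0,
                    connectivity: int = 8) -> float:
    """Empirical FWE of the cluster-size threshold on simulated null fields.

    Simulates ``n_sims`` independent standardized Gaussian random fields of
    the given smoothness, thresholds each at ``Zt``, labels clusters, and
    returns the fraction of simulations with at least one cluster of size
    >= ceil(k_alpha), with k_alpha computed from the same parameters.
    """
    if n_sims < 100:
        raise ValueError("need >= 100 simulations for a stable estimate")
    from .synthetic_fixtures import gaussian_random_field
    rng = np.random.default_rng(seed)
    params = RFTParams(Zt=Zt, alpha=alpha, x=shape[0])
    k = cluster_null(params, fwhm_px).k_alpha_px
    hits = 0
    for _ in range(n_sims):
        field = gaussian_random_field(shape, fwhm_px, 1, rng)[:, :, 0]
        _, sizes = label_clusters(field >= Zt, connectivity)
        if sizes.size and sizes.max() >= k:
            hits += 1
    return hits / n_sims
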