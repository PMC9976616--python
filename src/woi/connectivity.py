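"""Seed-wise and bilateral (homotopic) functional connectivity.

Seed-wise FC: average the movie over each seed disc, then Pearson-correlate
that trace against every masked pixel.  Bilateral FC: pair every left-side
masked pixel with its mirror across the sagittal midline and correlate the
two traces, writing r to both pixels so the map is mirror-symmetric by
construction.  Off-mask / undefined pixels carry NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_mask_atlas import BrainMask, SeedSet, seed_disc_mask

log = logging.getLogger("woi")


@dataclass
class FCResult:
    """Per-seed r maps, seed traces, and the symmetric bilateral r map."""

    seed_maps: dict[str, np.ndarray]
    seed_traces: dict[str, np.ndarray]
    bilateral_map: np.ndarray
    contrast_label: str = ""


def _pearson_vs_trace(pix: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``pix`` against ``trace`` (NaN if constant)."""
    pc = pix - pix.mean(axis=-1, keepdims=True)
    tc = trace - trace.mean()
    denom = np.sqrt((pc ** 2).sum(axis=-1) * (tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ tc) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def seed_traces(movie: np.ndarray, seeds: SeedSet, mask: BrainMask) -> dict[str, np.ndarray]:
    """Mean time trace over each seed disc intersected with the brain mask."""
    out: dict[str, np.ndarray] = {}
    for name, center in zip(seeds.names, seeds.centers):
        disc = seed_disc_mask(mask.mask.shape, center, seeds.radius_px) & mask.mask
        if not disc.any():
            raise ValueError(f"seed '{name}' has no masked pixels")
        out[name] = movie[disc].mean(axis=0)
    return out


def seed_fc_maps(movie: np.ndarray, traces: dict[str, np.ndarray],
                 mask: BrainMask) -> dict[str, np.ndarray]:
    """Pearson r map of every masked pixel against each seed trace."""
    if movie.shape[-1] < 3:
        raise ValueError("need >= 3 frames for correlation maps")
    pix = movie[mask.mask]
    maps: dict[str, np.ndarray] = {}
    for name, trace in traces.items():
        if np.ptp(trace) == 0:
            raise ValueError(f"seed '{name}' trace is constant")
        r = _pearson_vs_trace(pix, np.asarray(trace, dtype=float))
        n_undef = int(np.isnan(r).sum())
        if n_undef:
            log.info("seed_fc_maps[%s]: %d constant pixels -> NaN", name, n_undef)
        m = np.full(mask.mask.shape, np.nan)
        m[mask.mask] = r
        maps[name] = m
    return maps


def bilateral_pairs(mask: BrainMask, midline_col: float) -> np.ndarray:
    """Left/right mirror pixel pairs, (n, 2, 2) of (row, col), each once.

    A left pixel (col < midline) is paired with (row, 2*midline_col - col)
    when that mirror column is integral, in bounds and masked.
    """
    rows, cols = np.nonzero(mask.mask)
    left = cols < midline_col
    mirror = 2 * midline_col - cols[left]
    mirror_i = np.rint(mirror).astype(int)
    ok = (np.abs(mirror - mirror_i) < 1e-9) & (mirror_i < mask.mask.shape[1])
    r, c, mc = rows[left][ok], cols[left][ok], mirror_i[ok]
    ok2 = mask.mask[r, mc]
    pairs = np.stack([np.stack([r[ok2], c[ok2]], axis=1),
                      np.stack([r[ok2], mc[ok2]], axis=1)], axis=1)
    log.info("bilateral_pairs: %d of %d left pixels paired", len(pairs), int(left.sum()))
    return pairs


def bilateral_fc(movie: np.ndarray, pairs: np.ndarray,
                 mask: BrainMask | None = None) -> np.ndarray:
    """Homotopic r map: correlate each mirror pair, write r to both pixels."""
    if movie.shape[-1] < 3:
        raise ValueError("need >= 3 frames for correlation")
    out = np.full(movie.shape[:2], np.nan)
    if len(pairs) == 0:
        log.info("bilateral_fc: empty pair list")
        return out
    a = movie[pairs[:, 0, 0], pairs[:, 0, 1]]   # n_pairs x nt
    b = movie[pairs[:, 1, 0], pairs[:, 1, 1]]
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((ac ** 2).sum(axis=-1) * (bc ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=-1) / denom
    r[denom == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    out[pairs[:, 0, 0], pairs[:, 0, 1]] = r
    out[pairs[:, 1, 0], pairs[:, 1, 1]] = r
    return out


def fisher_z(r_map: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """Variance-stabilizing z = atanh(r); |r| = 1 clipped at 1 - ``clip``."""
    r = np.asarray(r_map, dtype=float)
    n_clip = int((np.abs(r) >= 1).sum())
    if n_clip:
        log.info("fisher_z: clipped %d pixels at |r| = 1", n_clip)
    return np.arctanh(np.clip(r, -1 + clip, 1 - clip))


def compute_fc(movie: np.ndarray, seeds: SeedSet, mask: BrainMask,
               midline_col: float, contrast_label: str = "") -> FCResult:
    """Seed-wise maps + bilateral map in one pass."""
    traces = seed_traces(movie, seeds, mask)
    maps = seed_fc_maps(movie, traces, mask)
    bil = bilateral_fc(movie, bilateral_pairs(mask, midline_col), mask)
    return FCResult(maps, traces, bil, contrast_label)
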