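"""Block-design stimulus analysis.

The reference paradigm is 5 s rest, 5 s stimulation (2 Hz electrical paw
stimuli), 10 s rest per block, 14 blocks per mouse, analyzed at 8.4 Hz after
2x temporal downsampling.  The movie is reshaped into
pixels x pixels x block_length x n_blocks, baseline-subtracted against the
stimulus-off frames, averaged over blocks and on-frames into an activation
map, thresholded at 80% of the maximum to form an ROI, and the ROI-mean
trace is extracted per block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_mask_atlas import BrainMask

log = logging.getLogger("woi")


@dataclass(frozen=True)
class BlockDesign:
    """Timing of one stimulus block and the block count."""

    rest_pre_s: float = 5.0
    stim_s: float = 5.0
    rest_post_s: float = 10.0
    n_blocks: int = 14
    frame_rate_hz: float = 8.4

    def __post_init__(self) -> None:
        if min(self.rest_pre_s, self.stim_s, self.rest_post_s) <= 0:
            raise ValueError("all block durations must be positive")
        if self.n_blocks < 1:
            raise ValueError("need >= 1 block")

    @property
    def block_len_frames(self) -> int:
        return int(round((self.rest_pre_s + self.stim_s + self.rest_post_s)
                         * self.frame_rate_hz))

    @property
    def on_frames(self) -> np.ndarray:
        """Frame indices (within a block) while the stimulus is on."""
        start = int(round(self.rest_pre_s * self.frame_rate_hz))
        stop = int(round((self.rest_pre_s + self.stim_s) * self.frame_rate_hz))
        return np.arange(start, stop)

    @property
    def off_frames(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.block_len_frames), self.on_frames)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.block_len_frames) / self.frame_rate_hz


@dataclass
class StimResult:
    """Activation map, 80%-max ROI, and ROI-mean block traces."""

    mean_on_map: np.ndarray
    roi_mask: np.ndarray
    block_trace: np.ndarray          # (block_len,)
    per_block_traces: np.ndarray     # (block_len, n_blocks)
    design: BlockDesign


def reshape_blocks(movie: np.ndarray, design: BlockDesign) -> np.ndarray:
    """Lossless reshape to pixels x pixels x block_len x n_blocks."""
    movie = np.asarray(movie, dtype=float)
    L, nb = design.block_len_frames, design.n_blocks
    if movie.shape[-1] != L * nb:
        raise ValueError(f"expected {L * nb} frames ({nb} blocks x {L}), "
                         f"got {movie.shape[-1]}")
    ny, nx = movie.shape[:2]
    return movie.reshape(ny, nx, nb, L).transpose(0, 1, 3, 2)


def flatten_blocks(blocks: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_blocks`."""
    ny, nx, L, nb = blocks.shape
    return blocks.transpose(0, 1, 3, 2).reshape(ny, nx, nb * L)


def baseline_subtract(blocks: np.ndarray, design: BlockDesign,
                      per_block: bool = True) -> np.ndarray:
    """Subtract the mean over stimulus-off frames.

    Per block by default so slow drifts between blocks cancel; with
    ``per_block=False`` one grand off-mean frame is used for all blocks.
    """
    off = design.off_frames
    if off.size == 0:
        raise ValueError("no stimulus-off frames in design")
    if per_block:
        base = blocks[:, :, off, :].mean(axis=2, keepdims=True)
    else:
        base = blocks[:, :, off, :].mean(axis=(2, 3), keepdims=True)
    return blocks - base


def activation_map(blocks: np.ndarray, design: BlockDesign,
                   subtract_baseline: bool = True) -> np.ndarray:
    """Mean over blocks and stimulus-on frames of baseline-subtracted data."""
    on = design.on_frames
    if on.size == 0:
        raise ValueError("no stimulus-on frames in design")
    if subtract_baseline:
        blocks = baseline_subtract(blocks, design)
    return blocks[:, :, on, :].mean(axis=(2, 3))


def threshold_activation(amap: np.ndarray, fraction: float = 0.8,
                         mask: BrainMask | np.ndarray | None = None,
                         use_abs: bool = False) -> np.ndarray:
    """ROI of pixels at or above ``fraction`` of the (masked) map maximum."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    amap = np.asarray(amap, dtype=float)
    if use_abs:
        amap = np.abs(amap)
    m = np.ones(amap.shape, bool)
    if mask is not None:
        m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    peak = np.nanmax(np.where(m, amap, np.nan))
    if not peak > 0:
        raise ValueError("no positive activation in masked map")
    return (amap >= fraction * peak) & m


def roi_trace(blocks: np.ndarray, roi_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROI-mean trace per block and the across-block average trace."""
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    per_block = blocks[roi_mask].mean(axis=0)     # block_len x n_blocks
    return per_block.mean(axis=-1), per_block


def analyze_stimulus(movie: np.ndarray, design: BlockDesign,
                     mask: BrainMask | np.ndarray | None = None,
                     fraction: float = 0.8) -> StimResult:
    """Full block-design analysis of one movie."""
    blocks = baseline_subtract(reshape_blocks(movie, design), design)
    amap = blocks[:, :, design.on_frames, :].mean(axis=(2, 3))
    roi = threshold_activation(amap, fraction, mask)
    trace, per_block = roi_trace(blocks, roi)
    return StimResult(amap, roi, trace, per_block, design)
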