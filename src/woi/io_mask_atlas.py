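"""Stack I/O, brain masks, landmarks, seed placement and atlas registration.

Wide-field optical imaging acquisitions interleave several LED channels
(e.g. 470/530/590/625 nm) frame by frame into one movie.  This module
de-interleaves such stacks into per-wavelength movies, rasterizes a binary
brain mask from a traced polygon, places a canonical set of mirror-paired
seed regions from two anatomical landmarks (anterior midline suture and
lambda), and registers movies into a common atlas frame with the 2-point
similarity transform those landmarks define.

Coordinate convention: 0-based ``(row, col)``, row 0 anterior, pixel centers
at integer coordinates; the sagittal midline is a (possibly half-integer)
column index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy import ndimage

log = logging.getLogger("woi")

# Default acquisition geometry: 156 px binned FOV covering ~11 mm, downsampled
# by 2 to 78 px for statistics; 16.8 Hz per wavelength.
DEFAULT_FOV_MM = 11.0
DEFAULT_ATLAS_SHAPE = (78, 78)
DEFAULT_PIXEL_PITCH_MM = DEFAULT_FOV_MM / 78
DEFAULT_FRAME_RATE_HZ = 16.8
DEFAULT_CHANNEL_ORDER = (470, 530, 590, 625)
DEFAULT_SEED_RADIUS_MM = 0.25


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawStack:
    """One wavelength channel of a raw movie, pixels_y x pixels_x x frames."""

    data: np.ndarray
    frame_rate_hz: float
    wavelength_nm: float
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("RawStack.data must be pixels_y x pixels_x x frames")
        if self.data.shape[2] < 2:
            raise ValueError("RawStack needs at least 2 frames")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class BrainMask:
    """Binary brain mask plus the polygon it was rasterized from."""

    mask: np.ndarray
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Landmarks:
    """Anatomical landmarks in image pixel coordinates (row, col)."""

    anterior_suture: tuple[float, float]
    lambda_pt: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.anterior_suture, self.lambda_pt):
            raise ValueError("landmarks coincide; similarity transform undefined")


@dataclass
class SeedSet:
    """Named seed disc centers; left/right seeds come in mirror pairs."""

    centers: np.ndarray          # (n, 2) float (row, col)
    radius_px: float
    names: list[str]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if len(self.names) != len(self.centers):
            raise ValueError("names/centers length mismatch")


@dataclass
class AtlasSpec:
    """Canonical atlas frame: shape, midline landmarks and seed template."""

    shape: tuple[int, int] = DEFAULT_ATLAS_SHAPE
    anterior_suture_atlas: tuple[float, float] = (10.0, 38.5)
    lambda_atlas: tuple[float, float] = (62.0, 38.5)
    midline_col: float = 38.5
    seed_template: SeedSet | None = None
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        for name, pt in (("anterior_suture_atlas", self.anterior_suture_atlas),
                         ("lambda_atlas", self.lambda_atlas)):
            if abs(pt[1] - self.midline_col) > 1e-9:
                raise ValueError(f"{name} must lie on midline_col")
        if self.seed_template is None:
            self.seed_template = load_seed_template(atlas=self)


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def load_stack(path: str | Path,
               n_channels: int,
               channel_order: Sequence[float] = DEFAULT_CHANNEL_ORDER,
               frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
               pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM) -> list[RawStack]:
    """Load a multi-page TIFF and de-interleave round-robin into channels.

    ``frame_rate_hz`` is the per-wavelength rate (16.8 Hz in the reference
    acquisition); raw frame i (0-based) belongs to channel ``i % n_channels``.
    """
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    frames = np.asarray(frames, dtype=float)          # pages x rows x cols
    return deinterleave(np.moveaxis(frames, 0, -1), n_channels,
                        channel_order, frame_rate_hz, pixel_pitch_mm)


def deinterleave(movie: np.ndarray,
                 n_channels: int,
                 channel_order: Sequence[float] = DEFAULT_CHANNEL_ORDER,
                 frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                 pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM) -> list[RawStack]:
    """Round-robin split of a (rows, cols, frames) movie into channels."""
    n_frames = movie.shape[2]
    rem = n_frames % n_channels
    if rem:
        raise ValueError(
            f"frame count {n_frames} not divisible by {n_channels} channels "
            f"({rem} leftover frames)")
    if len(channel_order) != n_channels:
        raise ValueError("channel_order length must equal n_channels")
    return [RawStack(movie[:, :, i::n_channels], frame_rate_hz, wl, pixel_pitch_mm)
            for i, wl in enumerate(channel_order)]


def interleave(stacks: Sequence[RawStack]) -> np.ndarray:
    """Inverse of :func:`deinterleave` (round-robin merge)."""
    n = len(stacks)
    t = stacks[0].n_frames
    out = np.empty(stacks[0].shape + (n * t,), dtype=float)
    for i, s in enumerate(stacks):
        out[:, :, i::n] = s.data
    return out


def write_stack(path: str | Path, movie: np.ndarray, **metadata) -> None:
    """Write a (rows, cols, frames) movie as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), np.moveaxis(np.asarray(movie, dtype=np.float32), -1, 0),
                     photometric="minisblack")
    meta = {"shape": list(movie.shape), **metadata}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def make_mask(shape: tuple[int, int], polygon: Sequence[tuple[float, float]]) -> BrainMask:
    """Rasterize a traced brain outline into a binary mask.

    A pixel is brain (1) iff its center (integer row/col) falls inside or on
    the closed polygon, matching a manual trace of the dorsal cortical
    surface.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    if (poly[:, 0].min() < -0.5 or poly[:, 1].min() < -0.5
            or poly[:, 0].max() > shape[0] - 0.5 or poly[:, 1].max() > shape[1] - 0.5):
        raise ValueError("polygon vertices out of image bounds")
    geom = shapely.Polygon(poly)
    if geom.area == 0:
        raise ValueError("degenerate zero-area polygon")
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    # boundary-inclusive point-in-polygon at pixel centers
    inside = shapely.intersects_xy(geom, rr.ravel(), cc.ravel()).reshape(shape)
    return BrainMask(inside, polygon=poly)


def symmetric_mask(shape: tuple[int, int] = DEFAULT_ATLAS_SHAPE,
                   midline_col: float | None = None,
                   margin: int = 6) -> BrainMask:
    """Elliptical mask symmetric about the midline (synthetic FOV helper)."""
    ny, nx = shape
    if midline_col is None:
        midline_col = (nx - 1) / 2
    rr, cc = np.mgrid[0:ny, 0:nx]
    r0, c0 = (ny - 1) / 2, midline_col
    a, b = ny / 2 - margin, nx / 2 - margin
    return BrainMask(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0)


# ---------------------------------------------------------------------------
# 2-point similarity transform & seeds
# ---------------------------------------------------------------------------

def _similarity(src: tuple, dst: tuple) -> tuple[complex, complex]:
    """Similarity transform mapping src pair -> dst pair, as z' = a*z + b.

    Points are encoded col + i*row.  Rotation + uniform scale + translation;
    the only transform two landmark pairs determine.
    """
    s1, s2 = (complex(p[1], p[0]) for p in src)
    d1, d2 = (complex(p[1], p[0]) for p in dst)
    if s1 == s2 or d1 == d2:
        raise ValueError("coincident landmarks; similarity transform undefined")
    a = (d2 - d1) / (s2 - s1)
    return a, d1 - a * s1


def _apply_similarity(a: complex, b: complex, pts: np.ndarray) -> np.ndarray:
    z = pts[:, 1] + 1j * pts[:, 0]
    w = a * z + b
    return np.column_stack([w.imag, w.real])


def load_seed_template(path: str | Path | None = None,
                       atlas: AtlasSpec | None = None,
                       radius_mm: float = DEFAULT_SEED_RADIUS_MM) -> SeedSet:
    """Read the packaged (or user) seed table and expand into mirror pairs.

    The table is whitespace-delimited with columns ``name ap_mm lat_mm``:
    anterior-posterior offset from the anterior suture along the midline and
    absolute lateral offset, both in mm.  Each row yields a left and a right
    seed mirrored about the atlas midline.
    """
    if path is None:
        path = resources.files("woi") / "data" / "seed_template.txt"
    tbl = pd.read_csv(str(path), sep=r"\s+", comment="#",
                      names=["name", "ap_mm", "lat_mm"])
    if atlas is None:
        # avoid AtlasSpec.__post_init__ recursion
        r0, mid = (10.0, 38.5), 38.5
        pitch = DEFAULT_PIXEL_PITCH_MM
    else:
        r0, mid = atlas.anterior_suture_atlas, atlas.midline_col
        pitch = atlas.pixel_pitch_mm
    centers, names = [], []
    for _, row in tbl.iterrows():
        r = r0[0] + row.ap_mm / pitch
        dc = row.lat_mm / pitch
        centers.append((r, mid - dc)); names.append(f"{row['name']}-L")
        centers.append((r, mid + dc)); names.append(f"{row['name']}-R")
    return SeedSet(np.array(centers), radius_mm / pitch, names)


def place_seeds(landmarks: Landmarks, atlas: AtlasSpec) -> SeedSet:
    """Map the atlas seed template into image space via the landmark pair.

    The transform sends (anterior_suture_atlas, lambda_atlas) onto the
    observed (anterior_suture, lambda) landmarks; mirror pairing and names
    are retained.
    """
    a, b = _similarity((atlas.anterior_suture_atlas, atlas.lambda_atlas),
                       (landmarks.anterior_suture, landmarks.lambda_pt))
    tpl = atlas.seed_template
    scale = abs(a)
    # floor at 0.75 px: any disc of that radius covers >= 1 pixel center
    return SeedSet(_apply_similarity(a, b, tpl.centers),
                   max(tpl.radius_px * scale, 0.75), list(tpl.names))


def seed_disc_mask(shape: tuple[int, int], center: tuple[float, float],
                   radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2


def affine_to_atlas(movie: np.ndarray,
                    landmarks: Landmarks,
                    atlas: AtlasSpec,
                    *,
                    is_mask: bool = False,
                    fill: float = 0.0) -> np.ndarray:
    """Resample a frame or movie onto the atlas grid.

    Uses the similarity transform sending the observed landmarks onto the
    atlas landmarks; frames use bilinear interpolation, masks nearest
    neighbour.  Out-of-view pixels get ``fill``.
    """
    a, b = _similarity((landmarks.anterior_suture, landmarks.lambda_pt),
                       (atlas.anterior_suture_atlas, atlas.lambda_atlas))
    a_inv = 1 / a
    b_inv = -b / a
    rr, cc = np.mgrid[0:atlas.shape[0], 0:atlas.shape[1]]
    src = _apply_similarity(a_inv, b_inv,
                            np.column_stack([rr.ravel(), cc.ravel()]))
    coords = [src[:, 0].reshape(atlas.shape), src[:, 1].reshape(atlas.shape)]
    movie = np.asarray(movie, dtype=float)
    single = movie.ndim == 2
    if single:
        movie = movie[:, :, None]
    order = 0 if is_mask else 1
    out = np.empty(atlas.shape + (movie.shape[2],))
    for t in range(movie.shape[2]):
        out[:, :, t] = ndimage.map_coordinates(
            movie[:, :, t], coords, order=order, mode="constant", cval=fill)
    return out[:, :, 0] if single else out


# ---------------------------------------------------------------------------
# spectra files
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path) -> pd.DataFrame:
    """Parse a whitespace-delimited spectrum table.

    Three columns -> extinction spectrum (``wavelength_nm, eps_hbo2, eps_hb``
    in cm^-1 M^-1); two columns -> LED emission spectrum
    (``wavelength_nm, relative_intensity``), renormalized so that
    sum(intensity) * grid spacing = 1.  Wavelengths must increase strictly.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric row at line {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: empty spectrum file")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows) or ncol not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 numeric columns")
    arr = np.array(rows)
    dl = np.diff(arr[:, 0])
    if np.any(dl <= 0):
        bad = int(np.argmax(dl <= 0)) + 2
        raise ValueError(f"{path}: wavelengths not strictly increasing at line {bad}")
    if ncol == 3:
        return pd.DataFrame(arr, columns=["wavelength_nm", "eps_hbo2", "eps_hb"])
    spacing = np.mean(dl) if len(dl) else 1.0
    arr[:, 1] = arr[:, 1] / (arr[:, 1].sum() * spacing)
    return pd.DataFrame(arr, columns=["wavelength_nm", "relative_intensity"])


def packaged_spectra_paths() -> dict[str, Path]:
    """Paths of the packaged synthetic extinction and LED spectra files."""
    base = resources.files("woi") / "data"
    out = {"extinction": Path(str(base / "extinction_hb_synthetic.txt"))}
    for wl in DEFAULT_CHANNEL_ORDER:
        out[f"led_{wl}"] = Path(str(base / f"led_{wl}_synthetic.txt"))
    return out
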