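"""Seeded synthetic fluorescence z-stacks with known ground truth.

Emulates the study's confocal imagery of an endothelial monolayer on the
chip so that the quantification pipeline can be validated against planted
truth instead of unavailable microscope data:

- a Voronoi-tessellated endothelium (nucleus + actin channels) whose
  marker channel carries a controllable positive-area fraction (ICAM-1-like
  patches) or a junctional line network (VE-cadherin-like);
- secondary-antibody-only "dummy" stacks containing pure background noise,
  calibrated so the projected marker channel has a prescribed 99th-percentile
  gray level (the noise floor the top-1% threshold rule recovers);
- THP-1 scenes with tracker-labelled blobs adhered to the endothelium or
  planted at known migration distances inside the gel.

Every generated quantity (positive fraction, junction ratio, counts,
distances) is recorded in a :class:`SceneTruth` recomputable from the truth
masks by brute-force counting. Identical seed and configuration give
bit-identical stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

CHANNEL_ROLES = ("nucleus", "actin", "marker", "tracker")


class ImagingError(ValueError):
    """Invalid synthetic-imaging configuration."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """8-bit multi-channel z-stack, axis order (z, channel, y, x)."""

    data: np.ndarray
    pixel_size_um: float
    channels: tuple = CHANNEL_ROLES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint8:
            raise ImagingError("stack data must be uint8")
        if self.data.ndim != 4:
            raise ImagingError("stack data must be (z, channel, y, x)")
        if self.pixel_size_um <= 0:
            raise ImagingError("pixel_size_um must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ImagingError("channel roles must be unique")
        if self.data.shape[1] != len(self.channels):
            raise ImagingError("channel axis does not match channel roles")

    def channel(self, role: str) -> np.ndarray:
        """(z, y, x) sub-stack for one channel role."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise ImagingError(f"no channel with role {role!r}") from None
        return self.data[:, idx]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def save_tiff(self, path: str | Path) -> None:
        meta = dict(self.metadata)
        meta["pixel_size_um"] = self.pixel_size_um
        meta["channels"] = list(self.channels)
        tifffile.imwrite(path, self.data, photometric="minisblack",
                         metadata=None, description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        px = meta.pop("pixel_size_um")
        channels = tuple(meta.pop("channels"))
        if data.ndim == 3:  # pages flattened to (z*c, y, x)
            data = data.reshape(-1, len(channels), *data.shape[1:])
        return cls(data=data, pixel_size_um=px, channels=channels, metadata=meta)


@dataclass
class Thp1Cell:
    """A planted THP-1 cell with its class and wall distance (um)."""

    kind: str                 # "adhered" | "transmigrated"
    distance_um: float        # closest-pixel distance to the wall; 0 if adhered
    center_yx: tuple = (0, 0)


@dataclass
class SceneTruth:
    """Ground truth accompanying a synthetic stack."""

    cell_mask: np.ndarray | None = None       # endothelial cell area
    marker_mask: np.ndarray | None = None     # marker-positive pixels
    junction_mask: np.ndarray | None = None   # full junction-line network
    thp1_mask: np.ndarray | None = None       # union of THP-1 blobs
    thp1_cells: list = field(default_factory=list)
    wall_x_px: float | None = None
    marker_fraction: float | None = None      # |marker| / |cell|
    junction_ratio: float | None = None       # |marker| / |cell u marker|
    seed: int | None = None

    def save(self, path: str | Path) -> None:
        """Sidecar: JSON scalars next to an .npz of the truth masks."""
        path = Path(path)
        masks = {k: getattr(self, k) for k in
                 ("cell_mask", "marker_mask", "junction_mask", "thp1_mask")
                 if getattr(self, k) is not None}
        npz = path.with_suffix(".masks.npz")
        np.savez_compressed(npz, **masks)
        scalars = {
            "masks_path": npz.name,
            "wall_x_px": self.wall_x_px,
            "marker_fraction": self.marker_fraction,
            "junction_ratio": self.junction_ratio,
            "seed": self.seed,
            "thp1_cells": [{"kind": c.kind, "distance_um": c.distance_um,
                            "center_yx": list(c.center_yx)} for c in self.thp1_cells],
        }
        path.write_text(json.dumps(scalars, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SceneTruth":
        path = Path(path)
        scalars = json.loads(path.read_text())
        truth = cls(wall_x_px=scalars["wall_x_px"],
                    marker_fraction=scalars["marker_fraction"],
                    junction_ratio=scalars["junction_ratio"],
                    seed=scalars["seed"],
                    thp1_cells=[Thp1Cell(c["kind"], c["distance_um"],
                                         tuple(c["center_yx"]))
                                for c in scalars["thp1_cells"]])
        npz_path = path.parent / scalars["masks_path"]
        if npz_path.exists():
            with np.load(npz_path) as npz:
                for k in npz.files:
                    setattr(truth, k, npz[k].astype(bool))
        return truth


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Background (secondary-antibody-only) noise.

    ``q99`` is the target 99th-percentile gray level of the *projected*
    marker background — the quantity the top-1% dummy rule thresholds.
    The per-slice exponential scale is chosen so that the maximum-intensity
    projection over ``n_slices`` hits that target; q99 = 0 (or kind "none")
    degenerates to an all-zero background.
    """

    kind: str = "exponential"
    q99: float = 9.0

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "none"):
            raise ImagingError(f"unknown noise kind {self.kind!r}")
        if self.q99 < 0 or self.q99 > 255:
            raise ImagingError("q99 must be within [0, 255]")

    def slice_scale(self, n_slices: int) -> float:
        if self.kind == "none" or self.q99 == 0:
            return 0.0
        # per-slice exceedance p so that P(max over z >= q99) = 1%
        p = 1.0 - 0.99 ** (1.0 / n_slices)
        return self.q99 / (-np.log(p))

    def sample(self, rng: np.random.Generator, n_slices: int,
               shape_yx: tuple) -> np.ndarray:
        """(z, y, x) uint8 background noise."""
        s = self.slice_scale(n_slices)
        if s == 0.0:
            return np.zeros((n_slices, *shape_yx), dtype=np.uint8)
        raw = rng.exponential(scale=s, size=(n_slices, *shape_yx))
        return np.clip(np.round(raw), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# endothelium layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellLayout:
    """Voronoi-style tessellation of the endothelial monolayer.

    ``n_cells`` seed points are scattered in the field; junctions are the
    tessellation edges dilated to ``2*junction_halfwidth_px + 1`` pixels.
    A small fraction of cells may be removed to create cell-free regions
    (as seen under inflammatory treatment).
    """

    n_cells: int = 350
    junction_halfwidth_px: int = 2
    cell_free_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ImagingError("n_cells must be >= 1")
        if self.junction_halfwidth_px < 1:
            raise ImagingError("junction_halfwidth_px must be >= 1")
        if not 0 <= self.cell_free_fraction < 1:
            raise ImagingError("cell_free_fraction must be in [0, 1)")


@dataclass
class _Tessellation:
    labels: np.ndarray        # per-pixel cell id, -1 in removed cells
    cell_mask: np.ndarray     # occupied cells minus junction lines
    junction_mask: np.ndarray  # dilated edges between occupied cells
    centers: np.ndarray       # (n, 2) seed points (y, x)
    kept: np.ndarray          # bool per cell id


def _tessellate(layout: CellLayout, shape_yx: tuple,
                rng: np.random.Generator) -> _Tessellation:
    h, w = shape_yx
    pts = np.column_stack([rng.uniform(0, h, layout.n_cells),
                           rng.uniform(0, w, layout.n_cells)])
    tree = cKDTree(pts)
    yy, xx = np.mgrid[0:h, 0:w]
    _, labels = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    labels = labels.reshape(h, w).astype(np.int32)

    # edges: label changes to the right or below
    edge = np.zeros(shape_yx, dtype=bool)
    edge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    r = layout.junction_halfwidth_px
    junction = ndimage.binary_dilation(edge, structure=_disk(r))

    kept = rng.random(layout.n_cells) >= layout.cell_free_fraction
    if not kept.any():
        kept[rng.integers(layout.n_cells)] = True
    occupied = kept[labels]
    cell_mask = occupied & ~junction
    junction &= occupied  # junctions only between occupied territory
    labels = np.where(occupied, labels, -1)
    return _Tessellation(labels=labels, cell_mask=cell_mask,
                         junction_mask=junction, centers=pts, kept=kept)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy * yy + xx * xx <= radius * radius


def _z_profile(n_slices: int) -> np.ndarray:
    """Relative in-focus weight per slice, peaked at the stack centre."""
    z = np.arange(n_slices)
    mid = (n_slices - 1) / 2.0
    sigma = max(n_slices / 3.0, 1.0)
    prof = np.exp(-0.5 * ((z - mid) / sigma) ** 2)
    return 0.4 + 0.6 * prof / prof.max()


def _render_volume(amplitude: np.ndarray, n_slices: int, peak_slice_only: bool = False
                   ) -> np.ndarray:
    """Spread a 2D amplitude image through z with the focus profile.

    The maximum-intensity projection of the result equals the 2D amplitude
    (the peak slice carries the full value).
    """
    prof = _z_profile(n_slices)
    prof = prof / prof.max()
    vol = np.empty((n_slices, *amplitude.shape), dtype=np.uint8)
    for k in range(n_slices):
        w = prof[k]
        if peak_slice_only and w < 1.0:
            w = 0.0
        vol[k] = np.round(amplitude * w).astype(np.uint8)
    return vol


def _render_nuclei(tess: _Tessellation, shape_yx: tuple,
                   rng: np.random.Generator) -> np.ndarray:
    """2D nucleus amplitude: one bright ellipse near each kept cell centre."""
    h, w = shape_yx
    img = np.zeros(shape_yx, dtype=float)
    for cid in np.flatnonzero(tess.kept):
        cy, cx = tess.centers[cid]
        cy += rng.normal(0, 2); cx += rng.normal(0, 2)
        a = rng.uniform(8, 12)     # semi-axes in px (~8-12 um nucleus)
        b = rng.uniform(6, 9)
        th = rng.uniform(0, np.pi)
        rad = int(np.ceil(a)) + 1
        y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
        x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[y0:y1, x0:x1][inside] = rng.uniform(160, 220)
    img = ndimage.gaussian_filter(img, 1.0)
    return np.clip(img, 0, 255)


def _render_actin(area_mask: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator, n_bright_fibers: int = 6
                  ) -> np.ndarray:
    """2D actin amplitude over ``area_mask`` with saturating stress fibers.

    The deliberately clipped bright fibers mimic the image bleeding that
    motivates the average-projection option for the actin channel.
    """
    h, w = area_mask.shape
    base = rng.uniform(90, 150, size=int(labels.max()) + 1)
    img = np.where(labels >= 0, base[np.clip(labels, 0, None)], 0.0)
    img *= rng.uniform(0.85, 1.15, size=(h, w))       # texture
    img = np.where(area_mask, img, 0.0)
    for _ in range(n_bright_fibers):
        y0, x0 = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(40, min(h, w) / 2)
        t = np.linspace(0, length, int(length * 2))
        ys = np.clip(np.round(y0 + t * np.sin(ang)).astype(int), 0, h - 1)
        xs = np.clip(np.round(x0 + t * np.cos(ang)).astype(int), 0, w - 1)
        fiber = np.zeros((h, w), dtype=bool)
        fiber[ys, xs] = True
        fiber = ndimage.binary_dilation(fiber, structure=_disk(1)) & area_mask
        img[fiber] = 255.0
    return np.clip(img, 0, 255)


def _positive_amplitudes(n: int, floor: int, mean: float, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Marker amplitudes strictly above the noise floor, clipped to 255."""
    vals = np.round(rng.normal(mean, sd, size=n))
    return np.clip(vals, floor, 255)


def _smooth_field(shape_yx: tuple, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape_yx), sigma)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

DEFAULT_SHAPE = (5, 1024, 1024)   # (z, y, x)
DEFAULT_PIXEL_SIZE_UM = 0.5


def generate_dummy_stack(noise: NoiseModel = NoiseModel(),
                         shape: tuple = DEFAULT_SHAPE,
                         pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                         seed: int = 0) -> ImageStack:
    """Secondary-antibody-only control: every channel is pure background.

    The marker channel is calibrated so its maximum-intensity projection has
    an empirical 99th percentile equal to ``noise.q99`` (within one gray
    level for fields of 512x512 and larger), which makes the downstream
    top-1% threshold land at ``q99 + 1``.
    """
    nz, h, w = shape
    rng = np.random.default_rng(seed)
    data = np.stack([noise.sample(rng, nz, (h, w)) for _ in CHANNEL_ROLES],
                    axis=1)
    meta = {"condition": "dummy", "seed": seed, "noise_q99": noise.q99,
            "degenerate_noise": noise.kind == "none" or noise.q99 == 0}
    return ImageStack(data=data, pixel_size_um=pixel_size_um, metadata=meta)


def generate_marker_stack(layout: CellLayout = CellLayout(),
                          f: float = 0.0931,
                          marker_mean: float = 60.0,
                          marker_sd: float = 18.0,
                          noise: NoiseModel = NoiseModel(q99=9.0),
                          shape: tuple = DEFAULT_SHAPE,
                          pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                          seed: int = 0,
                          condition: str = "custom") -> tuple:
    """Endothelium stack whose marker channel covers fraction ``f`` of the
    cell area (ICAM-1-like patchy expression).

    Positive pixels are the top ``round(f * |cell area|)`` pixels of a smooth
    random field restricted to the cell mask (spatially coherent patches with
    an exact planted count), with amplitudes drawn strictly above the noise
    floor so the planted fraction is recoverable by thresholding. Default
    ``f`` is the normal-condition calibration (9.31% positive area).
    """
    if not 0.0 <= f <= 1.0:
        raise ImagingError(f"target fraction f must be in [0, 1], got {f}")
    nz, h, w = shape
    if nz < 3:
        raise ImagingError("need >= 3 z-slices so projection modes differ")
    rng = np.random.default_rng(seed)
    tess = _tessellate(layout, (h, w), rng)

    # cell area = the occupied monolayer footprint (cortical actin makes the
    # junction lines part of the visible cell area in these images)
    footprint = tess.cell_mask | tess.junction_mask
    cell_area = int(footprint.sum())
    n_pos = int(round(f * cell_area))
    fld = _smooth_field((h, w), sigma=8.0, rng=rng)
    fld = np.where(footprint, fld, -np.inf)
    marker_mask = np.zeros((h, w), dtype=bool)
    if n_pos > 0:
        flat = np.argpartition(fld.ravel(), -n_pos)[-n_pos:]
        marker_mask.ravel()[flat] = True

    floor = int(np.ceil(noise.q99)) + 1
    amp = np.zeros((h, w))
    amp[marker_mask] = _positive_amplitudes(n_pos, floor, marker_mean,
                                            marker_sd, rng)

    nucleus = _render_volume(_render_nuclei(tess, (h, w), rng), nz)
    actin = _render_volume(_render_actin(footprint, tess.labels, rng), nz)
    marker = _render_volume(amp, nz, peak_slice_only=True)
    tracker = np.zeros((nz, h, w), dtype=np.uint8)

    stacks = {"nucleus": nucleus, "actin": actin, "marker": marker,
              "tracker": tracker}
    data = np.stack([np.maximum(stacks[r], noise.sample(rng, nz, (h, w)))
                     for r in CHANNEL_ROLES], axis=1)
    truth = SceneTruth(cell_mask=footprint, marker_mask=marker_mask,
                       junction_mask=tess.junction_mask,
                       marker_fraction=n_pos / cell_area if cell_area else 0.0,
                       seed=seed)
    meta = {"condition": condition, "seed": seed, "target_fraction": f,
            "noise_q99": noise.q99}
    return ImageStack(data=data, pixel_size_um=pixel_size_um,
                      metadata=meta), truth


def generate_junction_stack(layout: CellLayout = CellLayout(
                                n_cells=600, junction_halfwidth_px=4),
                            j: float = 0.258,
                            marker_mean: float = 70.0,
                            marker_sd: float = 20.0,
                            noise: NoiseModel = NoiseModel(q99=14.0),
                            shape: tuple = DEFAULT_SHAPE,
                            pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                            seed: int = 0,
                            condition: str = "custom") -> tuple:
    """Endothelium stack with junctional (VE-cadherin-like) marker signal.

    Marker signal is confined to the tessellation-edge network; the planted
    junction pixels are chosen so that
    ``|marker| / (|cell area| + |marker|) == j`` where the cell area is the
    endothelial footprint not claimed by junction signal (actin is rendered
    into unclaimed junction gaps, as neighbouring cells close the contact
    when junctional staining retracts). Default ``j`` is the
    normal-condition calibration (25.80%).
    """
    if not 0.0 <= j < 1.0:
        raise ImagingError(f"target ratio j must be in [0, 1), got {j}")
    nz, h, w = shape
    if nz < 3:
        raise ImagingError("need >= 3 z-slices so projection modes differ")
    rng = np.random.default_rng(seed)
    tess = _tessellate(layout, (h, w), rng)

    footprint = tess.cell_mask | tess.junction_mask
    total = int(footprint.sum())
    j_network = int(tess.junction_mask.sum())
    n_pos = int(round(j * total))
    j_max = j_network / total
    if n_pos > j_network:
        raise ImagingError(
            f"target junction ratio {j:.3f} exceeds the maximum achievable "
            f"{j_max:.3f} for this layout; increase junction_halfwidth_px "
            f"or n_cells")

    fld = _smooth_field((h, w), sigma=4.0, rng=rng)
    fld = np.where(tess.junction_mask, fld, -np.inf)
    marker_mask = np.zeros((h, w), dtype=bool)
    if n_pos > 0:
        flat = np.argpartition(fld.ravel(), -n_pos)[-n_pos:]
        marker_mask.ravel()[flat] = True

    # unclaimed junction gaps belong to the cell area (actin closes the gap)
    cell_mask = tess.cell_mask | (tess.junction_mask & ~marker_mask)

    floor = int(np.ceil(noise.q99)) + 1
    amp = np.zeros((h, w))
    amp[marker_mask] = _positive_amplitudes(n_pos, floor, marker_mean,
                                            marker_sd, rng)

    nucleus = _render_volume(_render_nuclei(tess, (h, w), rng), nz)
    actin = _render_volume(_render_actin(cell_mask, tess.labels, rng), nz)
    marker = _render_volume(amp, nz, peak_slice_only=True)
    tracker = np.zeros((nz, h, w), dtype=np.uint8)
    stacks = {"nucleus": nucleus, "actin": actin, "marker": marker,
              "tracker": tracker}
    data = np.stack([np.maximum(stacks[r], noise.sample(rng, nz, (h, w)))
                     for r in CHANNEL_ROLES], axis=1)

    denom = int(cell_mask.sum()) + n_pos
    truth = SceneTruth(cell_mask=cell_mask, marker_mask=marker_mask,
                       junction_mask=tess.junction_mask,
                       junction_ratio=n_pos / denom if denom else 0.0,
                       seed=seed)
    meta = {"condition": condition, "seed": seed, "target_ratio": j,
            "noise_q99": noise.q99}
    return ImageStack(data=data, pixel_size_um=pixel_size_um,
                      metadata=meta), truth


def generate_thp1_scene(wall_x_px: int = 410,
                        n_adhered: int = 50,
                        distances_um: list | None = None,
                        blob_radius_px: int = 10,
                        tracker_mean: float = 150.0,
                        tracker_sd: float = 20.0,
                        noise: NoiseModel = NoiseModel(q99=9.0),
                        shape: tuple = DEFAULT_SHAPE,
                        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                        seed: int = 0,
                        max_attempts_per_cell: int = 200,
                        condition: str = "custom") -> tuple:
    """THP-1 adhesion/migration scene.

    The field spans the BV channel (``x <= wall_x_px``) and the gel
    (``x > wall_x_px``). ``n_adhered`` tracker blobs are placed wholly on the
    channel side; one blob per entry of ``distances_um`` is placed in the gel
    with its closest pixel at the requested perpendicular distance from the
    wall (within half a pixel). Blobs do not overlap; if rejection sampling
    cannot place a blob within ``max_attempts_per_cell`` tries an error asks
    for a lower density.
    """
    distances_um = list(distances_um or [])
    if any(d < 0 for d in distances_um):
        raise ImagingError("migration distances must be >= 0")
    nz, h, w = shape
    if not 0 < wall_x_px < w - 1:
        raise ImagingError("wall_x_px must lie inside the field")
    rng = np.random.default_rng(seed)
    r = blob_radius_px

    placed = []   # (cy, cx)

    def try_place(x_lo: float, x_hi: float, cx_fixed: float | None = None):
        # integer centers so a radius-r disk has its extreme pixel exactly
        # r pixels from the centre (keeps planted distances pixel-exact)
        for _ in range(max_attempts_per_cell):
            cy = round(rng.uniform(r, h - 1 - r))
            cx = cx_fixed if cx_fixed is not None else round(
                rng.uniform(x_lo, x_hi))
            if all((cy - py) ** 2 + (cx - px) ** 2 > (2 * r + 2) ** 2
                   for py, px in placed):
                placed.append((cy, cx))
                return cy, cx
        raise ImagingError("could not place a THP-1 blob without overlap; "
                           "lower the cell density or enlarge the field")

    cells = []
    # adhered: entire blob on the channel side (x <= wall)
    for _ in range(n_adhered):
        cy, cx = try_place(r, wall_x_px - r - 1)
        cells.append(Thp1Cell("adhered", 0.0, (cy, cx)))
    # transmigrated: closest pixel at the planted distance on the gel side
    for d_um in distances_um:
        d_px = d_um / pixel_size_um
        cx = round(wall_x_px + d_px + r)
        if cx + r >= w:
            raise ImagingError(f"distance {d_um} um does not fit in the field")
        cy, cx = try_place(0, 0, cx_fixed=float(cx))
        cells.append(Thp1Cell("transmigrated", d_um, (cy, cx)))

    amp = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    floor = int(np.ceil(noise.q99)) + 1
    for c in cells:
        cy, cx = c.center_yx
        y0, y1 = max(0, int(cy) - r - 1), min(h, int(cy) + r + 2)
        x0, x1 = max(0, int(cx) - r - 1), min(w, int(cx) + r + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask[y0:y1, x0:x1] |= blob
        amp[y0:y1, x0:x1][blob] = _positive_amplitudes(
            int(blob.sum()), floor, tracker_mean, tracker_sd, rng)

    tracker = _render_volume(amp, nz, peak_slice_only=True)
    nucleus = np.zeros((nz, h, w), dtype=np.uint8)
    actin = np.zeros((nz, h, w), dtype=np.uint8)
    stacks = {"nucleus": nucleus, "actin": actin,
              "marker": np.zeros((nz, h, w), dtype=np.uint8),
              "tracker": tracker}
    data = np.stack([np.maximum(stacks[role], noise.sample(rng, nz, (h, w)))
                     for role in CHANNEL_ROLES], axis=1)

    truth = SceneTruth(thp1_mask=mask, thp1_cells=cells, wall_x_px=wall_x_px,
                       seed=seed)
    meta = {"condition": condition, "seed": seed, "wall_x_px": wall_x_px,
            "n_adhered": n_adhered, "noise_q99": noise.q99}
    return ImageStack(data=data, pixel_size_um=pixel_size_um,
                      metadata=meta), truth


# ---------------------------------------------------------------------------
# condition calibration (between-image spread = SEM * sqrt(n))
# ---------------------------------------------------------------------------

#: Per-condition generator set-points. Marker fractions / ratios are percent,
#: intensities are relative to the normal condition, counts are per device,
#: distances in um. These are calibration inputs to the generator, not
#: measurements.
CONDITION_TABLE = {
    "normal": dict(icam1_pct=9.31, icam1_pct_sd=4.11, icam1_rel_int=1.00,
                   vecad_pct=25.80, vecad_pct_sd=4.82,
                   n_affected=1103.5, n_affected_sd=190.8,
                   n_migrated=20.0, n_migrated_sd=6.8,
                   mig_dist_um=16.79, mig_dist_sd_um=15.21),
    "lps_4h": dict(icam1_pct=22.04, icam1_pct_sd=12.15, icam1_rel_int=1.24,
                   vecad_pct=14.71, vecad_pct_sd=2.36,
                   n_affected=1360.5, n_affected_sd=197.0,
                   n_migrated=26.0, n_migrated_sd=13.0,
                   mig_dist_um=32.82, mig_dist_sd_um=22.84),
    "lps_8h": dict(icam1_pct=36.25, icam1_pct_sd=16.53, icam1_rel_int=1.73,
                   vecad_pct=16.37, vecad_pct_sd=1.71,
                   n_affected=1737.6, n_affected_sd=366.6,
                   n_migrated=34.8, n_migrated_sd=12.8,
                   mig_dist_um=22.98, mig_dist_sd_um=17.21),
    "lps_12h": dict(icam1_pct=61.81, icam1_pct_sd=20.43, icam1_rel_int=1.82,
                    vecad_pct=None, vecad_pct_sd=None,
                    n_affected=None, n_affected_sd=None,
                    n_migrated=None, n_migrated_sd=None,
                    mig_dist_um=None, mig_dist_sd_um=None),
}


def sample_condition_fraction(condition: str, metric: str,
                              rng: np.random.Generator) -> float:
    """Draw a per-image planted fraction (0-1) for a condition and metric."""
    row = CONDITION_TABLE[condition]
    key = {"icam1": "icam1_pct", "vecad": "vecad_pct"}[metric]
    mean, sd = row[key], row[key + "_sd"]
    if mean is None:
        raise ImagingError(f"{metric} not modelled for condition {condition}")
    # junction ratios are capped by the junction-network capacity of the
    # default layout; area fractions only by the 8-bit field itself
    hi = 35.0 if metric == "vecad" else 95.0
    pct = float(np.clip(rng.normal(mean, sd), 0.5, hi))
    return pct / 100.0


def sample_migration_distances(condition: str, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-cell migration distances (um) from a gamma matched to the
    condition's mean and between-cell spread."""
    row = CONDITION_TABLE[condition]
    mean, sd = row["mig_dist_um"], row["mig_dist_sd_um"]
    if mean is None:
        raise ImagingError(f"migration not modelled for condition {condition}")
    shape_k = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape_k, scale, size=n)
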