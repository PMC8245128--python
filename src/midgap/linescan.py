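"""Line-scan intensity extraction from fluorescence images.

Implements the measurement conventions used to quantify apical-midline
signal in an epithelial tube: z-projection of a confocal stack, uniform
arc-length sampling of a segmented-line (polyline) path, width-averaged
bilinear interpolation perpendicular to the path, slide-background
estimation from off-specimen ROIs, and cytoplasmic background statistics
pooled over short reference lines.

Coordinates are 0-based ``(x, y) = (col, row)`` pixels; index intervals are
half-open ``[start, end)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImagePlane",
    "MidlinePath",
    "Rect",
    "RoiSet",
    "IntensityTrace",
    "MeasurementLog",
    "project_z",
    "sample_path",
    "measure_line",
    "slide_background",
    "cytoplasm_stats",
    "extract_trace",
]

DEFAULT_CHANNELS = ("chA", "chB")


@dataclass(frozen=True)
class ImagePlane:
    """A single-channel 2D image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity values in arbitrary units (AU).
    pixel_size : float
        Micrometres per pixel (> 0).
    channel : str
        Channel label, e.g. ``"chA"``.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    channel: str = "chA"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MidlinePath:
    """A segmented measurement line in pixel coordinates.

    ``vertices`` is an ordered ``(N, 2)`` array of ``(x, y)`` points;
    ``width_px`` is the measurement width (2 by default, 4 for the
    wide-line profile).
    """

    vertices: np.ndarray
    width_px: int = 2

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("path needs >= 2 (x, y) vertices")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive path vertices must be distinct")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        object.__setattr__(self, "vertices", v)

    @property
    def total_length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, half-open: ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty ROI rectangle")

    def mean(self, plane: ImagePlane) -> float:
        rows, cols = plane.shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > cols or self.y1 > rows:
            raise ValueError(f"ROI {self} outside image of shape {plane.shape}")
        return float(plane.pixels[self.y0 : self.y1, self.x0 : self.x1].mean())


@dataclass(frozen=True)
class RoiSet:
    """Reference regions accompanying a midline measurement.

    ``slide_rois`` are three large off-specimen rectangles used for
    slide-background subtraction; ``cyto_lines`` are short polylines in
    the cytoplasm (avoiding the midline and nuclei) used to estimate the
    cytoplasmic background distribution.  ``lateral_lines`` and
    ``surface_lines`` are optional extra measurement lines.
    """

    slide_rois: tuple[Rect, ...]
    cyto_lines: tuple[MidlinePath, ...]
    lateral_lines: tuple[MidlinePath, ...] = ()
    surface_lines: tuple[MidlinePath, ...] = ()
    require_three_slide_rois: bool = True

    def __post_init__(self) -> None:
        if self.require_three_slide_rois and len(self.slide_rois) != 3:
            raise ValueError("exactly 3 slide ROIs are required")
        if len(self.cyto_lines) < 1:
            raise ValueError("at least one cytoplasm line is required")

    @staticmethod
    def from_json(path: str) -> tuple["RoiSet", MidlinePath | None]:
        """Load an ROI/path spec written as JSON.

        Expected keys: ``slide_rois`` (list of [x0, y0, x1, y1]),
        ``cyto_lines`` (list of vertex lists), optional ``lateral_lines``,
        ``surface_lines``, ``midline`` (vertex list) and ``width_px``.
        Returns the ROI set and the midline path (``None`` if absent).
        """
        with open(path) as fh:
            spec = json.load(fh)
        rois = RoiSet(
            slide_rois=tuple(Rect(*map(int, r)) for r in spec["slide_rois"]),
            cyto_lines=tuple(MidlinePath(np.asarray(v)) for v in spec["cyto_lines"]),
            lateral_lines=tuple(
                MidlinePath(np.asarray(v)) for v in spec.get("lateral_lines", [])
            ),
            surface_lines=tuple(
                MidlinePath(np.asarray(v)) for v in spec.get("surface_lines", [])
            ),
        )
        midline = None
        if "midline" in spec:
            midline = MidlinePath(
                np.asarray(spec["midline"]), width_px=int(spec.get("width_px", 2))
            )
        return rois, midline


@dataclass
class IntensityTrace:
    """Ordered per-point multi-channel intensities along a midline.

    Layers: ``raw`` intensities as measured, ``bg_subtracted`` after the
    per-image slide background was removed, and ``normalized`` (filled by
    the gap-calling stage) which expresses each point relative to the
    cytoplasmic background mean.  All layers are ``(n_points, n_channels)``.
    """

    positions_um: np.ndarray
    raw: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    bg_subtracted: np.ndarray | None = None
    normalized: np.ndarray | None = None
    source: str = "image"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        if raw.ndim == 1:
            raw = raw[:, None]
        if pos.ndim != 1 or raw.shape[0] != pos.shape[0]:
            raise ValueError("positions and intensity layers must have equal length")
        if raw.shape[1] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if pos.shape[0] >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions_um must be strictly increasing")
        self.positions_um = pos
        self.raw = raw
        for layer in ("bg_subtracted", "normalized"):
            arr = getattr(self, layer)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != raw.shape:
                    raise ValueError(f"{layer} layer shape mismatch")
                setattr(self, layer, arr)

    @property
    def n_points(self) -> int:
        return int(self.raw.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.raw.shape[1])

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def with_background_subtracted(self, slide_bg: float | Sequence[float]) -> "IntensityTrace":
        """Return a copy with the slide background removed from ``raw``.

        ``slide_bg`` is a scalar or per-channel sequence; no clamping is
        applied (slightly negative corrected values are legitimate noise).
        """
        bg = np.broadcast_to(np.asarray(slide_bg, dtype=float), (self.n_channels,))
        return IntensityTrace(
            positions_um=self.positions_um.copy(),
            raw=self.raw.copy(),
            channel_names=self.channel_names,
            bg_subtracted=self.raw - bg[None, :],
            normalized=None,
            source=self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"point_index": np.arange(self.n_points), "position_um": self.positions_um})
        for j, name in enumerate(self.channel_names):
            df[f"{name}_raw"] = self.raw[:, j]
        if self.bg_subtracted is not None:
            for j, name in enumerate(self.channel_names):
                df[f"{name}_bgsub"] = self.bg_subtracted[:, j]
        if self.normalized is not None:
            for j, name in enumerate(self.channel_names):
                df[f"{name}_norm"] = self.normalized[:, j]
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "csv") -> "IntensityTrace":
        channels = tuple(c[:-4] for c in df.columns if c.endswith("_raw"))
        if not channels:
            raise ValueError("no *_raw columns found")
        raw = np.column_stack([df[f"{c}_raw"].to_numpy(float) for c in channels])
        kwargs: dict = {}
        if all(f"{c}_bgsub" in df.columns for c in channels):
            kwargs["bg_subtracted"] = np.column_stack(
                [df[f"{c}_bgsub"].to_numpy(float) for c in channels]
            )
        if all(f"{c}_norm" in df.columns for c in channels):
            kwargs["normalized"] = np.column_stack(
                [df[f"{c}_norm"].to_numpy(float) for c in channels]
            )
        return cls(
            positions_um=df["position_um"].to_numpy(float),
            raw=raw,
            channel_names=channels,
            source=source,
            **kwargs,
        )

    @classmethod
    def from_csv(cls, path: str) -> "IntensityTrace":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class MeasurementLog:
    """Per-image measurement provenance: slide background and cytoplasm stats."""

    slide_bg: dict = field(default_factory=dict)  # channel -> AU
    cyto_mean: dict = field(default_factory=dict)
    cyto_sd: dict = field(default_factory=dict)
    cyto_n: dict = field(default_factory=dict)
    width_px: int = 2
    step_px: float = 1.0
    profile: str = "default"

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slide_bg": self.slide_bg,
                    "cyto_mean": self.cyto_mean,
                    "cyto_sd": self.cyto_sd,
                    "cyto_n": self.cyto_n,
                    "width_px": self.width_px,
                    "step_px": self.step_px,
                    "profile": self.profile,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def project_z(stack: Sequence[ImagePlane], mode: str = "max") -> ImagePlane:
    """Elementwise max- or min-projection of congruent z-slices."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    shapes = {p.shape for p in stack}
    if len(shapes) != 1:
        raise ValueError(f"slice shape mismatch: {shapes}")
    arr = np.stack([p.pixels for p in stack])
    if mode == "max":
        out = arr.max(axis=0)
    elif mode == "min":
        out = arr.min(axis=0)
    else:
        raise ValueError("mode must be 'max' or 'min'")
    return replace(stack[0], pixels=out)


def sample_path(
    path: MidlinePath, step_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a polyline at uniform arc-length spacing.

    Returns ``(points, tangents, arc)`` where ``points`` is ``(m, 2)`` in
    ``(x, y)``, ``tangents`` are unit vectors of the local segment, and
    ``arc`` the cumulative arc length in pixels.  The first sample sits on
    vertex 0; samples follow at multiples of ``step_px``; the final vertex
    is appended when the last multiple falls short of the total length.
    """
    if step_px <= 0:
        raise ValueError("step_px must be > 0")
    v = path.vertices
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total == 0:
        raise ValueError("degenerate zero-length path")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_whole = int(np.floor(total / step_px + 1e-9))
    arc = np.arange(n_whole + 1, dtype=float) * step_px
    if total - arc[-1] > 1e-9 * max(total, 1.0):
        arc = np.append(arc, total)
    # locate each arc position on its segment; samples exactly at an interior
    # vertex take the outgoing segment's tangent
    seg_idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seg_len) - 1)
    frac = (arc - cum[seg_idx]) / seg_len[seg_idx]
    points = v[seg_idx] + frac[:, None] * seg[seg_idx]
    tangents = seg[seg_idx] / seg_len[seg_idx, None]
    return points, tangents, arc


def _width_offsets(width_px: int) -> np.ndarray:
    # symmetric unit-spaced sub-samples: width 2 -> (-0.5, +0.5)
    return np.arange(width_px, dtype=float) - (width_px - 1) / 2.0


def measure_line(
    plane: ImagePlane, path: MidlinePath, step_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Width-averaged intensity profile along a segmented line.

    At each arc-length sample, ``width_px`` sub-samples are placed
    symmetrically about the point along the local normal (unit spacing)
    and bilinearly interpolated; their mean is the measurement.  Returns
    ``(arc_px, values)``.
    """
    points, tangents, arc = sample_path(path, step_px)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = _width_offsets(path.width_px)
    xy = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    rows, cols = plane.shape
    x, y = xy[..., 0], xy[..., 1]
    bad = (x < 0) | (x > cols - 1) | (y < 0) | (y > rows - 1)
    if np.any(bad):
        idx = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValueError(
            f"sample point {idx} (arc={arc[idx]:.2f} px) falls outside the image"
        )
    vals = ndimage.map_coordinates(plane.pixels, [y.ravel(), x.ravel()], order=1)
    return arc, vals.reshape(xy.shape[:2]).mean(axis=1)


def slide_background(plane: ImagePlane, slide_rois: Sequence[Rect]) -> float:
    """Mean of the per-ROI mean intensities of off-specimen regions."""
    if len(slide_rois) == 0:
        raise ValueError("no slide ROIs given")
    return float(np.mean([r.mean(plane) for r in slide_rois]))


def cytoplasm_stats(
    plane: ImagePlane,
    cyto_lines: Sequence[MidlinePath],
    slide_bg: float,
    step_px: float = 1.0,
    profile: str = "default",
    min_n: int = 10,
) -> tuple[float, float, int]:
    """Pooled cytoplasmic background statistics after slide subtraction.

    Samples every cytoplasm line at ``step_px`` spacing, subtracts the
    slide background, and returns ``(mean, sd, n)`` with the sample SD
    (n-1 denominator).  The ``"fig3"`` profile (wide-line gap analysis)
    enforces a single cytoplasm line longer than 10 um.
    """
    if len(cyto_lines) == 0:
        raise ValueError("at least one cytoplasm line required")
    if profile == "fig3":
        if len(cyto_lines) != 1:
            raise ValueError("fig3 profile uses a single cytoplasm line")
        if cyto_lines[0].total_length * plane.pixel_size <= 10.0:
            raise ValueError("fig3 profile requires a cytoplasm line > 10 um")
    pooled = np.concatenate(
        [measure_line(plane, line, step_px)[1] for line in cyto_lines]
    ) - slide_bg
    n = pooled.size
    if n < min_n:
        raise ValueError(f"only {n} cytoplasm samples; >= {min_n} required for calibration")
    return float(pooled.mean()), float(pooled.std(ddof=1)), int(n)


def extract_trace(
    planes: Mapping[str, ImagePlane],
    path: MidlinePath,
    rois: RoiSet,
    step_px: float = 1.0,
    profile: str = "default",
) -> tuple[IntensityTrace, MeasurementLog]:
    """Measure a midline trace plus background statistics for every channel.

    Returns the slide-subtracted trace and a :class:`MeasurementLog` with
    the per-channel slide background and cytoplasm (mean, sd, n).
    """
    channels = tuple(planes.keys())
    if not channels:
        raise ValueError("no image planes given")
    slide = {}
    cmean: dict[str, float] = {}
    csd: dict[str, float] = {}
    cn: dict[str, int] = {}
    raws = []
    arc = None
    pixel_size = next(iter(planes.values())).pixel_size
    for name in channels:
        plane = planes[name]
        slide[name] = slide_background(plane, rois.slide_rois)
        arc, vals = measure_line(plane, path, step_px)
        raws.append(vals)
        cmean[name], csd[name], cn[name] = cytoplasm_stats(
            plane, rois.cyto_lines, slide[name], step_px, profile=profile
        )
    assert arc is not None
    trace = IntensityTrace(
        positions_um=arc * pixel_size,
        raw=np.column_stack(raws),
        channel_names=channels,
        source="image",
    ).with_background_subtracted([slide[c] for c in channels])
    log = MeasurementLog(
        slide_bg=slide,
        cyto_mean=cmean,
        cyto_sd=csd,
        cyto_n=cn,
        width_px=path.width_px,
        step_px=step_px,
        profile=profile,
    )
    return trace, log
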