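"""Synthetic midline traces, images, cohorts, and time-lapse series.

The generator emulates the statistical structure the gap analysis
assumes: a bright apical midline in two channels over a dimmer
cytoplasmic background with independent Gaussian noise, an additive
off-specimen slide offset, implanted gap intervals where the midline
signal drops to the cytoplasmic distribution (not to zero — a real gap
still contains cytoplasm), per-embryo ring-ring interface positions, and
time-lapse series at a 4-minute frame interval.  Every output carries
its ground truth so recovery tests need no re-generation.

Default intensity regime (arbitrary units): apical mean 500, cytoplasm
mean 100 with SD 10 (6-SD apical/background separation), slide offset
20, 200 sample points at 0.11 um per point (~22 um midline, the scale of
an elongating embryonic intestine).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .gapcall import FRAME_INTERVAL_MIN, TimelapseSeries
from .interfaces import BLOCKED_STAR_SITES, DEFAULT_STAR_SITES, InterfaceMap
from .linescan import DEFAULT_CHANNELS, ImagePlane, IntensityTrace, MidlinePath, Rect, RoiSet

__all__ = [
    "TraceParams",
    "SyntheticEmbryo",
    "SceneSpec",
    "RenderedScene",
    "GenotypePlan",
    "SyntheticTimelapse",
    "generate_trace",
    "generate_cohort",
    "make_interface_map",
    "render_image",
    "scene_rois",
    "generate_timelapse",
    "write_embryo",
]

MAX_SEED = 2**31

#: default implanted gap length range (points); at 0.11 um/point this is
#: ~0.9-2.2 um, the scale of an interface-spanning midline gap
DEFAULT_GAP_LENGTH_RANGE = (8, 20)


def _per_channel(value, n: int = 2) -> tuple[float, ...]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,))
    return tuple(float(x) for x in arr)


@dataclass(frozen=True)
class TraceParams:
    """Generating parameters for one synthetic two-channel midline trace.

    ``gap_intervals`` are half-open index intervals where the midline
    intensity is drawn from the cytoplasmic distribution instead of the
    apical one.  Scalars given for per-channel fields broadcast to both
    channels.
    """

    n_points: int = 200
    pixel_size: float = 0.11  # um per sample point
    apical_mean: tuple[float, float] = (500.0, 500.0)
    cyto_mean: tuple[float, float] = (100.0, 100.0)
    cyto_sd: tuple[float, float] = (10.0, 10.0)
    slide_offset: float = 20.0
    gap_intervals: tuple[tuple[int, int], ...] = ()
    n_background: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("apical_mean", "cyto_mean", "cyto_sd"):
            object.__setattr__(self, name, _per_channel(getattr(self, name)))
        ivs = tuple((int(a), int(b)) for a, b in self.gap_intervals)
        object.__setattr__(self, "gap_intervals", ivs)
        if self.n_points < 20:
            raise ValueError("n_points must be >= 20")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.slide_offset < 0:
            raise ValueError("slide_offset must be >= 0")
        if self.n_background < 30:
            raise ValueError("n_background must be >= 30")
        for a, c, s in zip(self.apical_mean, self.cyto_mean, self.cyto_sd):
            if s < 0:
                raise ValueError("cyto_sd must be >= 0")
            if not a > c + 2 * s:
                raise ValueError(
                    "apical_mean must exceed cyto_mean + 2*cyto_sd (separation guarantee)"
                )
        last = 0
        for a, b in sorted(ivs):
            if a < 0 or b > self.n_points or a >= b:
                raise ValueError(f"gap interval [{a}, {b}) outside [0, {self.n_points})")
            if a < last:
                raise ValueError("gap intervals must be pairwise disjoint")
            last = b

    def gap_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_points, dtype=bool)
        for a, b in self.gap_intervals:
            mask[a:b] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "pixel_size": self.pixel_size,
            "apical_mean": list(self.apical_mean),
            "cyto_mean": list(self.cyto_mean),
            "cyto_sd": list(self.cyto_sd),
            "slide_offset": self.slide_offset,
            "gap_intervals": [list(iv) for iv in self.gap_intervals],
            "n_background": self.n_background,
            "seed": self.seed,
        }


@dataclass
class SyntheticEmbryo:
    """One generated embryo: trace, background draws, and ground truth."""

    embryo_id: str
    genotype: str
    trace: IntensityTrace
    truth_gaps: tuple[tuple[int, int], ...]
    background_samples: dict  # channel -> raw AU array (slide offset included)
    interface_truth: InterfaceMap
    params: TraceParams

    @property
    def slide_offset(self) -> float:
        return self.params.slide_offset

    def bg_subtracted_samples(self) -> dict:
        return {c: v - self.slide_offset for c, v in self.background_samples.items()}

    def corrected_trace(self) -> IntensityTrace:
        """Trace with the known slide offset subtracted."""
        return self.trace.with_background_subtracted(self.slide_offset)


def make_interface_map(
    n_points: int, division_blocked: bool = False, n_cells: int | None = None
) -> InterfaceMap:
    """Evenly spaced ring-ring interfaces along an n_points trace.

    Normal embryos carry 8 interfaces between 9 rings with star sites
    int1/2, int7/8, int8/9.  Division-blocked embryos carry 16 cells (7
    interfaces) or 14 cells (6 interfaces; one middle non-star interface
    missing), with star sites int1/2 and int7/8.
    """
    if division_blocked:
        n_cells = 16 if n_cells is None else n_cells
        if not 14 <= n_cells <= 16:
            raise ValueError("division-blocked embryos must have 14-16 cells")
        names = [f"int{i}/{i + 1}" for i in range(1, 8)]
        if n_cells == 14:
            names.remove("int4/5")
        star = BLOCKED_STAR_SITES
    else:
        n_cells = 20 if n_cells is None else n_cells
        names = [f"int{i}/{i + 1}" for i in range(1, 9)]
        star = DEFAULT_STAR_SITES
    k = len(names) + 1
    indices = [int(round(j * n_points / k)) for j in range(1, k)]
    return InterfaceMap(
        interfaces=tuple(zip(names, indices)),
        star_sites=star,
        division_blocked=division_blocked,
        n_cells=n_cells,
    )


def generate_trace(
    params: TraceParams,
    embryo_id: str = "embryo-000",
    genotype: str = "synthetic",
    division_blocked: bool = False,
) -> SyntheticEmbryo:
    """Draw one two-channel trace plus calibration background samples.

    Non-gap midline points are ``Normal(apical_mean, cyto_sd)``, gap
    points ``Normal(cyto_mean, cyto_sd)``, background samples
    ``Normal(cyto_mean, cyto_sd)``, all plus the slide offset.  Identical
    seeds give identical output.
    """
    rng = np.random.default_rng(params.seed)
    gap = params.gap_mask()
    raw = np.empty((params.n_points, 2))
    bg_samples = {}
    for j, name in enumerate(DEFAULT_CHANNELS):
        mean = np.where(gap, params.cyto_mean[j], params.apical_mean[j])
        raw[:, j] = rng.normal(mean, params.cyto_sd[j]) + params.slide_offset
        bg_samples[name] = (
            rng.normal(params.cyto_mean[j], params.cyto_sd[j], params.n_background)
            + params.slide_offset
        )
    trace = IntensityTrace(
        positions_um=np.arange(params.n_points) * params.pixel_size,
        raw=raw,
        channel_names=DEFAULT_CHANNELS,
        source="synthetic",
    )
    return SyntheticEmbryo(
        embryo_id=embryo_id,
        genotype=genotype,
        trace=trace,
        truth_gaps=params.gap_intervals,
        background_samples=bg_samples,
        interface_truth=make_interface_map(params.n_points, division_blocked),
        params=params,
    )


@dataclass(frozen=True)
class GenotypePlan:
    """Per-genotype cohort plan: one gap-interval list per embryo."""

    label: str
    gaps_per_embryo: tuple[tuple[tuple[int, int], ...], ...]
    base: TraceParams = TraceParams()
    division_blocked: bool = False

    @property
    def n_embryos(self) -> int:
        return len(self.gaps_per_embryo)

    @classmethod
    def no_gaps(cls, label: str, n_embryos: int, base: TraceParams = TraceParams(),
                **kw) -> "GenotypePlan":
        return cls(label, tuple(() for _ in range(n_embryos)), base, **kw)

    @classmethod
    def with_single_gap(
        cls,
        label: str,
        n_embryos: int,
        n_gapped: int,
        gap_length: int = 12,
        gap_start: int | None = None,
        base: TraceParams = TraceParams(),
        **kw,
    ) -> "GenotypePlan":
        """First ``n_gapped`` embryos carry one centred implanted gap."""
        if not 0 <= n_gapped <= n_embryos:
            raise ValueError("n_gapped out of range")
        start = (base.n_points - gap_length) // 2 if gap_start is None else gap_start
        gap = ((start, start + gap_length),)
        plans = tuple(gap if i < n_gapped else () for i in range(n_embryos))
        return cls(label, plans, base, **kw)


def generate_cohort(
    genotype_specs: Sequence[GenotypePlan], seed: int
) -> list[SyntheticEmbryo]:
    """Generate a labelled multi-genotype cohort, deterministically under seed.

    All randomness flows from one root seed, expanded into an independent
    child seed per embryo.
    """
    if len(genotype_specs) == 0:
        raise ValueError("empty genotype spec list")
    rng = np.random.default_rng(seed)
    embryos = []
    for plan in genotype_specs:
        for i, gaps in enumerate(plan.gaps_per_embryo):
            params = replace(
                plan.base, gap_intervals=gaps, seed=int(rng.integers(MAX_SEED))
            )
            embryos.append(
                generate_trace(
                    params,
                    embryo_id=f"{plan.label}-{i:03d}",
                    genotype=plan.label,
                    division_blocked=plan.division_blocked,
                )
            )
    return embryos


@dataclass(frozen=True)
class SceneSpec:
    """Rendering geometry for a synthetic image of one embryo midline."""

    image_shape: tuple[int, int] = (128, 256)  # (rows, cols)
    midline_vertices: np.ndarray = field(
        default_factory=lambda: np.array([[20.0, 64.0], [236.0, 64.0]])
    )
    line_sigma: float = 5.0  # Gaussian cross-section SD of the midline (px)
    specimen_halfwidth: float = 25.0  # px; cytoplasm haze extent around the path
    pixel_size: float = 0.11  # um per pixel
    z_slices: int = 1
    noise: bool = True

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.midline_vertices, dtype=float))
        object.__setattr__(self, "midline_vertices", v)
        if self.line_sigma <= 0:
            raise ValueError("line_sigma must be > 0")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")
        rows, cols = self.image_shape
        margin = 3 * self.line_sigma
        if (
            v[:, 0].min() < margin
            or v[:, 1].min() < margin
            or v[:, 0].max() > cols - 1 - margin
            or v[:, 1].max() > rows - 1 - margin
        ):
            raise ValueError("midline must lie inside the image with a 3*sigma margin")


@dataclass
class RenderedScene:
    """Rendered image stack plus the ground-truth measurement path."""

    stacks: dict  # channel -> (z, rows, cols) array
    path: MidlinePath
    scene: SceneSpec
    embryo: SyntheticEmbryo

    def planes(self, channel: str, project: str = "max") -> ImagePlane:
        from .linescan import project_z

        stack = self.stacks[channel]
        slices = [
            ImagePlane(stack[z], pixel_size=self.scene.pixel_size, channel=channel)
            for z in range(stack.shape[0])
        ]
        return project_z(slices, mode=project)


def _distance_to_path(shape: tuple[int, int], vertices: np.ndarray):
    """Per-pixel distance to the polyline and arc position of the nearest point."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    best_d2 = np.full(px.shape[0], np.inf)
    best_arc = np.zeros(px.shape[0])
    arc0 = 0.0
    for p0, p1 in zip(vertices[:-1], vertices[1:]):
        seg = p1 - p0
        seg_len = float(np.hypot(*seg))
        t = np.clip(((px - p0) @ seg) / seg_len**2, 0.0, 1.0)
        diff = px - (p0 + t[:, None] * seg)
        d2 = (diff**2).sum(axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = arc0 + t[closer] * seg_len
        arc0 += seg_len
    return np.sqrt(best_d2).reshape(shape), best_arc.reshape(shape), arc0


def render_image(scene: SceneSpec, embryo: SyntheticEmbryo) -> RenderedScene:
    """Render an embryo trace as a two-channel image (optionally a z-stack).

    Pixel value = slide offset + cytoplasm haze inside the specimen mask
    + a midline contribution with Gaussian cross-section whose on-path
    peak equals the generating trace value at the nearest path point
    (gap intervals therefore render with no midline bump).  With
    ``z_slices > 1`` the midline contribution is attenuated away from the
    central slice while the base image is shared, so the max-projection
    reproduces the single-plane rendering exactly.
    """
    params = embryo.params
    path = MidlinePath(scene.midline_vertices)
    dist, arc, total_len = _distance_to_path(scene.image_shape, scene.midline_vertices)
    # map arc position to the nearest generating trace point
    trace_pos = np.linspace(0.0, total_len, params.n_points)
    nearest = np.clip(
        np.round(arc / total_len * (params.n_points - 1)).astype(int),
        0,
        params.n_points - 1,
    )
    inside = dist <= scene.specimen_halfwidth
    cross = np.exp(-(dist**2) / (2 * scene.line_sigma**2))
    rng = np.random.default_rng(params.seed + 1)
    # midline bump fully in the central slice, attenuated in the others
    mid_z = (scene.z_slices - 1) // 2
    z_weight = np.exp(-0.5 * ((np.arange(scene.z_slices) - mid_z) / 1.0) ** 2)
    z_weight[mid_z] = 1.0
    stacks = {}
    for j, name in enumerate(DEFAULT_CHANNELS):
        base = np.full(scene.image_shape, params.slide_offset)
        cyto = np.full(scene.image_shape, params.cyto_mean[j])
        if scene.noise and params.cyto_sd[j] > 0:
            cyto = cyto + rng.normal(0.0, params.cyto_sd[j], scene.image_shape)
        base = base + inside * cyto
        peak = embryo.trace.raw[nearest, j] - params.slide_offset - params.cyto_mean[j]
        bump = peak * cross
        stacks[name] = np.stack(
            [base + w * bump for w in z_weight], axis=0
        )
    return RenderedScene(stacks=stacks, path=path, scene=scene, embryo=embryo)


def scene_rois(scene: SceneSpec, cyto_offset_px: float = 18.0) -> RoiSet:
    """Reference ROIs for a rendered scene: corner slide ROIs and a
    cytoplasm line parallel to the midline, offset into the specimen but
    clear of the midline bump."""
    rows, cols = scene.image_shape
    s = 10
    slide = (
        Rect(1, 1, 1 + s, 1 + s),
        Rect(cols - 1 - s, 1, cols - 1, 1 + s),
        Rect(1, rows - 1 - s, 1 + s, rows - 1),
    )
    if cyto_offset_px <= 3 * scene.line_sigma:
        raise ValueError("cytoplasm line too close to the midline")
    cyto_vertices = scene.midline_vertices + np.array([0.0, cyto_offset_px])
    return RoiSet(slide_rois=slide, cyto_lines=(MidlinePath(cyto_vertices, width_px=1),))


@dataclass
class SyntheticTimelapse:
    """A generated time-lapse with its ground-truth gap events."""

    series: TimelapseSeries
    background_samples: dict  # channel -> raw AU (slide offset included)
    slide_offset: float
    events: tuple  # ((frame_start, frame_stop), (gap_start, gap_end)) ...
    truth: list  # per-event dicts: duration_min, present_at_end, persistent

    def bg_subtracted_samples(self) -> dict:
        return {c: v - self.slide_offset for c, v in self.background_samples.items()}

    def corrected_series(self) -> TimelapseSeries:
        return TimelapseSeries(
            frames=[t.with_background_subtracted(self.slide_offset) for t in self.series.frames],
            frame_interval_min=self.series.frame_interval_min,
        )


def generate_timelapse(
    base: TraceParams,
    events: Sequence[tuple[tuple[int, int], tuple[int, int]]],
    n_frames: int,
    frame_interval_min: float = FRAME_INTERVAL_MIN,
    persistence_min: float = 24.0,
) -> SyntheticTimelapse:
    """Generate a time-lapse where each event implants one gap interval
    over a half-open range of frames.

    Ground truth per event: duration ``(n_frames_covered - 1) *
    frame_interval_min``, presence in the final frame, and the resulting
    persistent/transient verdict at the ``persistence_min`` cutoff.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    evs = []
    for (f0, f1), (g0, g1) in events:
        if not (0 <= f0 < f1 <= n_frames):
            raise ValueError(f"event frame range [{f0}, {f1}) outside series")
        evs.append(((int(f0), int(f1)), (int(g0), int(g1))))
    for i, (_, iv_a) in enumerate(evs):
        for _, iv_b in evs[i + 1 :]:
            if iv_a[0] < iv_b[1] and iv_b[0] < iv_a[1]:
                raise ValueError("events with overlapping gap intervals are ambiguous")
    rng = np.random.default_rng(base.seed)
    frames = []
    for f in range(n_frames):
        gaps = tuple(sorted(iv for (f0, f1), iv in evs if f0 <= f < f1))
        p = replace(base, gap_intervals=gaps, seed=int(rng.integers(MAX_SEED)))
        frames.append(generate_trace(p).trace)
    bg_params = replace(base, gap_intervals=(), seed=int(rng.integers(MAX_SEED)))
    bg = generate_trace(bg_params).background_samples
    truth = []
    for (f0, f1), iv in evs:
        duration = (f1 - f0 - 1) * frame_interval_min
        present = f1 == n_frames
        truth.append(
            {
                "gap_interval": iv,
                "frames": (f0, f1),
                "duration_min": duration,
                "present_at_end": present,
                "persistent": present and duration >= persistence_min,
            }
        )
    return SyntheticTimelapse(
        series=TimelapseSeries(frames=frames, frame_interval_min=frame_interval_min),
        background_samples=bg,
        slide_offset=base.slide_offset,
        events=tuple(evs),
        truth=truth,
    )


def write_embryo(embryo: SyntheticEmbryo, outdir) -> None:
    """Write trace CSV plus a ground-truth JSON sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    embryo.trace.to_csv(str(outdir / f"{embryo.embryo_id}_trace.csv"))
    np.savetxt(
        outdir / f"{embryo.embryo_id}_background.csv",
        np.column_stack([embryo.background_samples[c] for c in DEFAULT_CHANNELS]),
        delimiter=",",
        header=",".join(DEFAULT_CHANNELS),
        comments="",
    )
    sidecar = {
        "embryo_id": embryo.embryo_id,
        "genotype": embryo.genotype,
        "truth_gaps": [list(iv) for iv in embryo.truth_gaps],
        "params": embryo.params.to_dict(),
        "seed": embryo.params.seed,
        "interfaces": [[n, int(i)] for n, i in embryo.interface_truth.interfaces],
        "star_sites": sorted(embryo.interface_truth.star_sites),
    }
    with open(outdir / f"{embryo.embryo_id}_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
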