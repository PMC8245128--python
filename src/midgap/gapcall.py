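"""Background-calibrated two-channel gap calling along a midline trace.

The measurement chain: each slide-subtracted midline measurement is
normalized against the mean cytoplasmic background of its own image,
``(measurement - cyto_mean) / cyto_mean``, so apical signal sits well
above 0 and cytoplasm scatters around 0.  The per-channel threshold is 2
sample standard deviations of the normalized background (for Gaussian
background about 97.7% of background samples fall below it).  A point is
"background level" only when both marker channels fall strictly below
their thresholds, and a gap is a maximal run of at least 3 consecutive
background-level points.  Gap calling always operates on the raw-index
trace; length-normalized profiles are for plotting only.

Time-lapse series (4-minute frame interval by default) link gap calls
across consecutive frames by index overlap; a linked gap locus is
"persistent" when it is present in the final frame and has lasted at
least 24 minutes, otherwise "transient".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .linescan import IntensityTrace

__all__ = [
    "THRESHOLD_K",
    "MIN_RUN",
    "FRAME_INTERVAL_MIN",
    "PERSISTENCE_MIN",
    "ChannelBackground",
    "BackgroundModel",
    "GapCall",
    "EmbryoGapSummary",
    "PairedComparison",
    "TimelapseSeries",
    "GapLocus",
    "GapAnalysis",
    "calibrate_threshold",
    "normalize_trace",
    "classify_background_level",
    "call_gaps",
    "summarize_embryo",
    "run_gap_analysis",
    "compare_timepoints",
    "track_persistence",
    "analyze_timelapse",
    "gap_colocalization",
    "length_normalize",
]

THRESHOLD_K = 2.0        #: threshold in SDs of the normalized background
MIN_RUN = 3              #: minimum consecutive background-level points per gap
FRAME_INTERVAL_MIN = 4.0  #: minutes between time-lapse frames
PERSISTENCE_MIN = 24.0   #: minimum duration (min) of a persistent gap


@dataclass(frozen=True)
class ChannelBackground:
    """Cytoplasmic background statistics and derived threshold for one channel.

    ``norm_sd`` is the sample SD of the background after normalization
    (cyto_sd / cyto_mean up to sampling error), ``threshold`` is
    ``k * norm_sd`` and ``coverage`` the fraction of normalized background
    samples strictly below the threshold — a calibration diagnostic that
    should sit near 0.977 for Gaussian background at k = 2.
    """

    channel: str
    cyto_mean: float
    cyto_sd: float
    n: int
    norm_sd: float
    threshold: float
    coverage: float


@dataclass(frozen=True)
class BackgroundModel:
    """Per-channel background calibration for one image/embryo."""

    channels: tuple[ChannelBackground, ...]
    threshold_k: float = THRESHOLD_K

    def __getitem__(self, name: str) -> ChannelBackground:
        for ch in self.channels:
            if ch.channel == name:
                return ch
        raise KeyError(name)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.channel for ch in self.channels)


def calibrate_threshold(
    background_samples: Mapping[str, np.ndarray],
    k: float = THRESHOLD_K,
    min_n: int = 10,
) -> BackgroundModel:
    """Derive per-channel background-level thresholds from cytoplasm samples.

    ``background_samples`` maps channel name to slide-subtracted
    cytoplasmic intensities (AU).  Each channel's samples are normalized
    by their own mean; the threshold is ``k`` sample SDs of the
    normalized values above 0.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be > 0")
    channels = []
    for name, samples in background_samples.items():
        s = np.asarray(samples, dtype=float)
        if s.size < min_n:
            raise ValueError(
                f"channel {name}: {s.size} background samples; >= {min_n} required"
            )
        mean = float(s.mean())
        if mean <= 0:
            raise ValueError(f"channel {name}: non-positive background mean {mean}")
        sd = float(s.std(ddof=1))
        if sd == 0:
            raise ValueError(f"channel {name}: degenerate background (sd = 0)")
        normalized = s / mean - 1.0
        norm_sd = float(normalized.std(ddof=1))
        threshold = k * norm_sd
        channels.append(
            ChannelBackground(
                channel=name,
                cyto_mean=mean,
                cyto_sd=sd,
                n=int(s.size),
                norm_sd=norm_sd,
                threshold=threshold,
                coverage=float(np.mean(normalized < threshold)),
            )
        )
    return BackgroundModel(channels=tuple(channels), threshold_k=k)


def normalize_trace(trace: IntensityTrace, bg: BackgroundModel) -> IntensityTrace:
    """Fill the normalized layer: (bg_subtracted - cyto_mean) / cyto_mean.

    The trace must already be slide-background subtracted (same correction
    the background samples received).
    """
    if trace.bg_subtracted is None:
        raise ValueError("subtract the slide background before normalizing")
    norm = np.empty_like(trace.bg_subtracted)
    for j, name in enumerate(trace.channel_names):
        cm = bg[name].cyto_mean
        if cm <= 0:
            raise ValueError(f"channel {name}: cyto_mean must be > 0")
        norm[:, j] = (trace.bg_subtracted[:, j] - cm) / cm
    return IntensityTrace(
        positions_um=trace.positions_um.copy(),
        raw=trace.raw.copy(),
        channel_names=trace.channel_names,
        bg_subtracted=trace.bg_subtracted.copy(),
        normalized=norm,
        source=trace.source,
    )


def classify_background_level(trace: IntensityTrace, bg: BackgroundModel) -> np.ndarray:
    """Boolean mask of two-channel background-level points.

    A point is background level when its normalized value is strictly
    below the channel threshold in *both* channels.
    """
    if trace.normalized is None:
        raise ValueError("normalize the trace first")
    if trace.n_channels != 2:
        raise ValueError(
            f"two-channel conjunction requires 2 channels, got {trace.n_channels}"
        )
    mask = np.ones(trace.n_points, dtype=bool)
    for j, name in enumerate(trace.channel_names):
        mask &= trace.normalized[:, j] < bg[name].threshold
    return mask


@dataclass
class GapCall:
    """A maximal run of >= min_run consecutive two-channel background points.

    Indices are half-open trace indices.  ``length_um`` counts one sample
    spacing per point (so a 3-point run at 0.11 um spacing spans 0.33 um).
    ``context`` and ``spans_interface`` are filled by the interface-mapping
    stage.
    """

    start_idx: int
    end_idx: int
    length_points: int
    length_um: float
    channels: tuple[str, ...]
    context: str = "unassigned"
    spans_interface: bool | None = None

    def __post_init__(self) -> None:
        if self.end_idx - self.start_idx != self.length_points:
            raise ValueError("length_points must equal end_idx - start_idx")


def call_gaps(
    mask: np.ndarray,
    min_run: int = MIN_RUN,
    positions_um: np.ndarray | None = None,
    channels: tuple[str, ...] = ("chA", "chB"),
) -> list[GapCall]:
    """Maximal true-runs of length >= min_run, in trace order."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 1:
        raise ValueError("mask must be 1D")
    edges = np.diff(np.concatenate([[0], m.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if positions_um is not None:
        positions_um = np.asarray(positions_um, dtype=float)
        step = float(np.median(np.diff(positions_um))) if positions_um.size > 1 else np.nan
    gaps = []
    for s, e in zip(starts, ends):
        if e - s < min_run:
            continue
        if positions_um is None:
            length_um = float("nan")
        else:
            length_um = float(positions_um[e - 1] - positions_um[s]) + step
        gaps.append(
            GapCall(
                start_idx=int(s),
                end_idx=int(e),
                length_points=int(e - s),
                length_um=length_um,
                channels=channels,
            )
        )
    return gaps


@dataclass(frozen=True)
class EmbryoGapSummary:
    """Embryo-level gap statistics."""

    embryo_id: str
    genotype: str
    n_gaps: int
    has_gap: bool
    n_background_level: int
    frac_background_level: float
    trace_length_um: float


def summarize_embryo(
    embryo_id: str,
    genotype: str,
    trace: IntensityTrace,
    gaps: Sequence[GapCall],
    mask: np.ndarray,
) -> EmbryoGapSummary:
    n_bg = int(np.asarray(mask, dtype=bool).sum())
    return EmbryoGapSummary(
        embryo_id=embryo_id,
        genotype=genotype,
        n_gaps=len(gaps),
        has_gap=len(gaps) >= 1,
        n_background_level=n_bg,
        frac_background_level=n_bg / trace.n_points,
        trace_length_um=float(trace.positions_um[-1] - trace.positions_um[0]),
    )


@dataclass
class GapAnalysis:
    """Full single-embryo gap-calling result."""

    trace: IntensityTrace  # with normalized layer filled
    background: BackgroundModel
    mask: np.ndarray
    gaps: list[GapCall]
    summary: EmbryoGapSummary


def run_gap_analysis(
    trace: IntensityTrace,
    background_samples: Mapping[str, np.ndarray],
    embryo_id: str = "embryo",
    genotype: str = "unknown",
    k: float = THRESHOLD_K,
    min_run: int = MIN_RUN,
) -> GapAnalysis:
    """Calibrate, normalize, classify, and call gaps for one embryo.

    ``trace`` must be slide-background subtracted; ``background_samples``
    are slide-subtracted cytoplasm intensities from the same image.
    """
    bg = calibrate_threshold(background_samples, k=k)
    norm = normalize_trace(trace, bg)
    mask = classify_background_level(norm, bg)
    gaps = call_gaps(
        mask, min_run=min_run, positions_um=norm.positions_um, channels=norm.channel_names
    )
    return GapAnalysis(
        trace=norm,
        background=bg,
        mask=mask,
        gaps=gaps,
        summary=summarize_embryo(embryo_id, genotype, norm, gaps, mask),
    )


@dataclass(frozen=True)
class PairedComparison:
    """Two-timepoint change in background-level point count for one embryo."""

    embryo_id: str
    n_t1: int
    n_t2: int
    increased: bool


def compare_timepoints(
    summary_t1: EmbryoGapSummary, summary_t2: EmbryoGapSummary
) -> PairedComparison:
    """Did the embryo's background-level point count increase between timepoints?"""
    if summary_t1.embryo_id != summary_t2.embryo_id:
        raise ValueError(
            f"mismatched embryo ids: {summary_t1.embryo_id!r} vs {summary_t2.embryo_id!r}"
        )
    return PairedComparison(
        embryo_id=summary_t1.embryo_id,
        n_t1=summary_t1.n_background_level,
        n_t2=summary_t2.n_background_level,
        increased=summary_t2.n_background_level > summary_t1.n_background_level,
    )


@dataclass
class TimelapseSeries:
    """Ordered midline traces at a uniform frame interval."""

    frames: list[IntensityTrace]
    frame_interval_min: float = FRAME_INTERVAL_MIN
    frame_times_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("time-lapse needs >= 2 frames")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.frame_times_min is not None:
            t = np.asarray(self.frame_times_min, dtype=float)
            if t.size != len(self.frames):
                raise ValueError("frame_times_min length mismatch")
            dt = np.diff(t)
            if not np.allclose(dt, self.frame_interval_min):
                raise ValueError("non-uniform frame spacing")
            self.frame_times_min = t

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class GapLocus:
    """Gap calls linked across consecutive frames by index overlap."""

    frame_indices: list[int]
    gap_calls: list[GapCall]
    duration_min: float
    present_at_end: bool
    persistent: bool

    @property
    def verdict(self) -> str:
        return "persistent" if self.persistent else "transient"


def track_persistence(
    frame_gaps: Sequence[Sequence[GapCall]],
    frame_interval_min: float = FRAME_INTERVAL_MIN,
    min_duration_min: float = PERSISTENCE_MIN,
) -> list[GapLocus]:
    """Link per-frame gap calls into loci and score persistence.

    Gap calls in consecutive frames belong to the same locus when their
    index ranges share at least one trace index (loci merge if one call
    overlaps several).  Duration is ``(n_consecutive_frames - 1) *
    frame_interval_min``.  A locus is persistent iff it is present in the
    final frame and its duration is at least ``min_duration_min``;
    otherwise transient.  A locus that disappears and a later gap at the
    same position are distinct loci (no bridging across absent frames).
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    n_frames = len(frame_gaps)
    finished: list[GapLocus] = []
    # active loci represented as dicts with their last-frame intervals
    active: list[dict] = []
    for f in range(n_frames):
        new_active: list[dict] = []
        claimed = [False] * len(active)
        for gap in frame_gaps[f]:
            hits = [
                i
                for i, loc in enumerate(active)
                if any(
                    gap.start_idx < e and s < gap.end_idx
                    for s, e in loc["last_intervals"]
                )
            ]
            if hits:
                base = active[hits[0]]
                for i in hits[1:]:  # merge loci bridged by one call
                    base["frames"].extend(active[i]["frames"])
                    base["calls"].extend(active[i]["calls"])
                    claimed[i] = True
                    new_active = [e for e in new_active if e is not active[i]]
                claimed[hits[0]] = True
                base["frames"].append(f)
                base["calls"].append(gap)
                base.setdefault("_new_intervals", []).append(
                    (gap.start_idx, gap.end_idx)
                )
                if not any(entry is base for entry in new_active):
                    new_active.append(base)
            else:
                new_active.append(
                    {
                        "frames": [f],
                        "calls": [gap],
                        "_new_intervals": [(gap.start_idx, gap.end_idx)],
                    }
                )
        for i, loc in enumerate(active):
            if not claimed[i]:
                finished.append(_close_locus(loc, n_frames, frame_interval_min, min_duration_min))
        for loc in new_active:
            loc["last_intervals"] = loc.pop("_new_intervals")
        active = new_active
    for loc in active:
        finished.append(_close_locus(loc, n_frames, frame_interval_min, min_duration_min))
    finished.sort(key=lambda l: (l.frame_indices[0], l.gap_calls[0].start_idx))
    return finished


def _close_locus(
    loc: dict, n_frames: int, frame_interval_min: float, min_duration_min: float
) -> GapLocus:
    frames = sorted(set(loc["frames"]))
    duration = (len(frames) - 1) * frame_interval_min
    present_at_end = frames[-1] == n_frames - 1
    return GapLocus(
        frame_indices=frames,
        gap_calls=loc["calls"],
        duration_min=duration,
        present_at_end=present_at_end,
        persistent=present_at_end and duration >= min_duration_min,
    )


def analyze_timelapse(
    series: TimelapseSeries,
    background_samples: Mapping[str, np.ndarray],
    k: float = THRESHOLD_K,
    min_run: int = MIN_RUN,
    min_duration_min: float = PERSISTENCE_MIN,
) -> tuple[list[list[GapCall]], list[GapLocus]]:
    """Call gaps in every frame and score gap-locus persistence."""
    bg = calibrate_threshold(background_samples, k=k)
    frame_gaps = []
    for trace in series.frames:
        norm = normalize_trace(trace, bg)
        mask = classify_background_level(norm, bg)
        frame_gaps.append(
            call_gaps(mask, min_run=min_run, positions_um=norm.positions_um,
                      channels=norm.channel_names)
        )
    loci = track_persistence(
        frame_gaps, series.frame_interval_min, min_duration_min=min_duration_min
    )
    return frame_gaps, loci


def gap_colocalization(
    gap: GapCall, other_normalized: np.ndarray, other_bg: ChannelBackground
) -> bool:
    """Does a third marker localize to a gap called in the reference channels?

    The marker counts as localized when its mean normalized intensity
    over the gap interval is at least its own background threshold, i.e.
    above background level on average.
    """
    other = np.asarray(other_normalized, dtype=float)
    if gap.start_idx < 0 or gap.end_idx > other.size:
        raise ValueError("gap lies outside the other channel's trace")
    return bool(other[gap.start_idx : gap.end_idx].mean() >= other_bg.threshold)


def length_normalize(
    values: np.ndarray,
    positions_um: np.ndarray | None = None,
    n_out: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a profile onto ``n_out`` points spanning [0, 1] of arc length.

    For cross-embryo overlay plots only; gap calling always uses the
    raw-index trace.  Returns ``(fraction_of_length, resampled_values)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("profile needs >= 2 points")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if positions_um is None:
        frac_in = np.linspace(0.0, 1.0, v.size)
    else:
        p = np.asarray(positions_um, dtype=float)
        if p.shape != v.shape:
            raise ValueError("positions length mismatch")
        frac_in = (p - p[0]) / (p[-1] - p[0])
    frac_out = np.linspace(0.0, 1.0, n_out)
    return frac_out, np.interp(frac_out, frac_in, v)
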