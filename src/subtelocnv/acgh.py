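"""Tiling array-CGH track smoothing and two-class copy-number calling.

The validation arm of the workflow: per-probe log2(test/reference) ratios are
smoothed with a centered moving average, compared against a reference
envelope estimated from a panel of copy-neutral individuals (per-probe median
center, per-probe SD scale), and probes whose smoothed ratio falls more than
1 SD below the center are classed as copy-number loss. Only two classes are
emitted — "unchanged copy number" and "copy number loss" — because upward
deviations (gains) were not observed on this platform and are deliberately
left out of the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import ProbeManifest, RegionSet
from .segments import (
    STATE_LOSS,
    STATE_MISSING,
    STATE_NORMAL,
    CnvSegmentCall,
    call_segments,
)
from .status import RegionStatusMatrix


@dataclass
class Log2RatioTrack:
    """One subject's per-probe log2(test/reference) ratios on a manifest.

    ``values`` is aligned to the manifest's probe order; NaN marks probes in
    low-coverage gap intervals where no ratio could be measured.
    """

    subject_id: str
    values: np.ndarray
    manifest: ProbeManifest | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.manifest is not None and len(self.values) != len(self.manifest):
            raise ValueError("track length does not match manifest probe count")


@dataclass
class ReferenceEnvelope:
    """Per-probe center ± scale band estimated from a copy-neutral panel."""

    center: np.ndarray
    scale: np.ndarray
    panel_size: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.panel_size < 3:
            raise ValueError("reference panel must contain >= 3 tracks")
        if np.nanmin(self.scale) <= 0:
            raise ValueError("envelope scale must be positive")


@dataclass
class CopyNumberClassTrack:
    """Per-probe labels: 0 missing, 1 loss, 2 unchanged (gains not emitted)."""

    subject_id: str
    labels: np.ndarray

    def as_strings(self) -> np.ndarray:
        out = np.full(len(self.labels), "unchanged", dtype="<U9")
        out[self.labels == STATE_LOSS] = "loss"
        out[self.labels == STATE_MISSING] = "missing"
        return out


def moving_average(track: Log2RatioTrack, window: int) -> Log2RatioTrack:
    """Centered moving average, truncated at the track ends.

    ``window`` must be odd and >= 1. Missing probes contribute nothing to the
    windows they fall in; a probe whose entire window is missing stays
    missing. ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    v = track.values
    if window == 1:
        return Log2RatioTrack(track.subject_id, v.copy(), track.manifest)
    ok = np.isfinite(v)
    filled = np.where(ok, v, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(ok.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    return Log2RatioTrack(track.subject_id, out, track.manifest)


def build_reference_envelope(
    panel: list[Log2RatioTrack],
    scale_floor: float = 0.05,
    center_stat: str = "median",
    pooled_scale: bool = False,
) -> ReferenceEnvelope:
    """Estimate the per-probe normal envelope from copy-neutral tracks.

    Center is the per-probe median over the panel (``center_stat="mean"``
    restores mean-centering). Scale is the per-probe sample SD, floored at
    ``scale_floor`` so a zero-dispersion panel never yields a zero-width
    envelope; ``pooled_scale=True`` replaces per-probe SDs with their
    common pooled value.
    """
    if len(panel) < 3:
        raise ValueError("reference envelope requires >= 3 panel tracks")
    stack = np.vstack([t.values for t in panel])
    with np.errstate(invalid="ignore"):
        if center_stat == "median":
            center = np.nanmedian(stack, axis=0)
        elif center_stat == "mean":
            center = np.nanmean(stack, axis=0)
        else:
            raise ValueError(f"unknown center_stat {center_stat!r}")
        scale = np.nanstd(stack, axis=0, ddof=1)
    if pooled_scale:
        scale = np.full_like(scale, np.sqrt(np.nanmean(scale**2)))
    scale = np.maximum(scale, scale_floor)
    scale = np.where(np.isnan(scale), scale_floor, scale)
    return ReferenceEnvelope(center=center, scale=scale, panel_size=len(panel))


def classify_copy_number(
    smoothed: Log2RatioTrack, env: ReferenceEnvelope
) -> CopyNumberClassTrack:
    """Two-class call: loss iff the value falls strictly below center − 1·SD.

    The exceedance is strict, so a value exactly on the threshold is
    "unchanged" — ties resolve conservatively toward no call. Upward
    deviations are also "unchanged" (gains are outside the two-class scheme).
    """
    v = smoothed.values
    if len(v) != len(env.center):
        raise ValueError("track and envelope are not aligned")
    labels = np.full(len(v), STATE_NORMAL, dtype=int)
    missing = ~np.isfinite(v)
    labels[missing] = STATE_MISSING
    with np.errstate(invalid="ignore"):
        labels[~missing & (v < env.center - env.scale)] = STATE_LOSS
    return CopyNumberClassTrack(smoothed.subject_id, labels)


def extract_loss_segments(
    classes: CopyNumberClassTrack, manifest: ProbeManifest, min_probes: int = 2
) -> list[CnvSegmentCall]:
    """Maximal runs of >= ``min_probes`` consecutive loss probes.

    Runs broken by missing-label gaps are not merged; each segment spans from
    its first to its last supporting probe.
    """
    if min_probes < 2:
        raise ValueError("min_probes must be >= 2")
    return call_segments(
        classes.labels, manifest, subject_id=classes.subject_id, min_probes=min_probes
    )


def call_acgh_cohort(
    tracks: list[Log2RatioTrack],
    manifest: ProbeManifest,
    panel_ids: list[str],
    regions: RegionSet,
    groups: dict[str, str] | None = None,
    window: int = 11,
    min_probes: int = 2,
    scale_floor: float = 0.05,
    smooth_before_classify: bool = True,
    envelope_from: str = "raw",
    center_stat: str = "median",
    pooled_scale: bool = False,
) -> tuple[RegionStatusMatrix, dict[str, list[CnvSegmentCall]]]:
    """Smooth, classify and segment a cohort of log2-ratio tracks.

    The reference envelope scale is, by default, the per-probe SD of the
    *raw* probe ratios across the panel — the dispersion of the probe-ratio
    distribution itself — while classification is applied to the smoothed
    track. Smoothing then strictly shrinks a null subject's excursions
    relative to the fixed 1-SD band, suppressing the ~16% per-probe null
    exceedance a raw track would show. ``envelope_from="smoothed"`` instead
    estimates the band from panel tracks smoothed identically to the
    classified ones. Returns the subjects × regions status matrix and
    per-subject segment calls.
    """
    from .segments import region_status_from_calls

    if smooth_before_classify:
        processed = [moving_average(t, window) for t in tracks]
    else:
        processed = tracks
    by_id = {t.subject_id: t for t in tracks}
    if envelope_from == "smoothed":
        by_id = {t.subject_id: t for t in processed}
    elif envelope_from != "raw":
        raise ValueError(f"unknown envelope_from {envelope_from!r}")
    missing_panel = [p for p in panel_ids if p not in by_id]
    if missing_panel:
        raise ValueError(f"panel subjects without tracks: {missing_panel[:3]}")
    env = build_reference_envelope(
        [by_id[p] for p in panel_ids],
        scale_floor=scale_floor,
        center_stat=center_stat,
        pooled_scale=pooled_scale,
    )
    statuses: dict[str, dict[str, str]] = {}
    calls: dict[str, list[CnvSegmentCall]] = {}
    for t in processed:
        classes = classify_copy_number(t, env)
        segs = extract_loss_segments(classes, manifest, min_probes=min_probes)
        calls[t.subject_id] = segs
        statuses[t.subject_id] = region_status_from_calls(
            segs, regions, manifest, min_overlap_probes=min_probes
        )
    frame = pd.DataFrame.from_dict(statuses, orient="index")[regions.labels]
    groups = groups or {}
    group_series = pd.Series(
        {s: groups.get(s, "case") for s in frame.index}, name="group"
    )
    return RegionStatusMatrix(frame, group_series), calls


def concordance(
    primary: RegionStatusMatrix, validation: RegionStatusMatrix
) -> dict[str, float]:
    """Fraction of primary-platform loss subjects confirmed by validation.

    Computed per region over subjects present in both matrices, plus an
    "overall" pooled fraction. Regions with no primary-loss subject in the
    intersection are reported as NaN.
    """
    shared = primary.statuses.index.intersection(validation.statuses.index)
    out: dict[str, float] = {}
    n_conf = n_loss = 0
    for region in primary.statuses.columns:
        if region not in validation.statuses.columns:
            continue
        p = primary.statuses.loc[shared, region] == "loss"
        v = validation.statuses.loc[shared, region] == "loss"
        k = int(p.sum())
        if k == 0:
            out[region] = float("nan")
        else:
            out[region] = float((p & v).sum() / k)
            n_conf += int((p & v).sum())
        n_loss += k
    out["overall"] = float(n_conf / n_loss) if n_loss else float("nan")
    return out


def plot_track(
    smoothed: Log2RatioTrack,
    env: ReferenceEnvelope,
    segments: list[CnvSegmentCall],
    manifest: ProbeManifest,
    path,
    region: "GenomicInterval | None" = None,
) -> None:
    """Log2 ratio vs genome position with envelope lines and loss bars.

    Optional image output; requires matplotlib. Restricting to ``region``
    plots only its probes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = manifest.probes_in(region) if region is not None else np.ones(
        len(manifest), dtype=bool
    )
    pos = manifest.probes["start"].to_numpy()[mask]
    fig, ax = plt.subplots(figsize=(9, 2.8))
    ax.vlines(pos, 0, smoothed.values[mask], color="black", lw=0.6)
    ax.plot(pos, (env.center - env.scale)[mask], color="lightsteelblue", lw=1)
    ax.plot(pos, (env.center + env.scale)[mask], color="lightsteelblue", lw=1)
    for seg in segments:
        if region is not None and seg.interval.chromosome != region.chromosome:
            continue
        ax.axvspan(seg.interval.start, seg.interval.end, color="red", alpha=0.25)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("log2 ratio (moving average)")
    ax.set_title(smoothed.subject_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def tracks_to_frame(tracks: list[Log2RatioTrack], manifest: ProbeManifest) -> pd.DataFrame:
    """Wide probe_id × subject table of log2 ratios."""
    return pd.DataFrame(
        {t.subject_id: t.values for t in tracks}, index=manifest.probe_ids
    )


def tracks_from_frame(frame: pd.DataFrame, manifest: ProbeManifest) -> list[Log2RatioTrack]:
    frame = frame.reindex(manifest.probe_ids)
    return [
        Log2RatioTrack(str(col), frame[col].to_numpy(float), manifest)
        for col in frame.columns
    ]
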