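"""Segment calls shared by both calling tracks, and the consecutive-marker rule.

A single aberrant probe is never called: evidence of a deletion or gain
requires at least ``min_probes`` (default 2) consecutive probes in the same
aberrant state. Runs never extend across missing-value gaps or chromosome
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomicInterval, ProbeManifest

# per-probe copy states
STATE_MISSING = 0
STATE_LOSS = 1
STATE_NORMAL = 2
STATE_GAIN = 3

STATE_LABELS = {STATE_LOSS: "loss", STATE_GAIN: "gain"}


@dataclass(frozen=True)
class CnvSegmentCall:
    """A called loss/gain stretch spanning its supporting probes."""

    subject_id: str
    interval: GenomicInterval
    state: str  # "loss" | "gain"
    n_probes: int

    def __post_init__(self) -> None:
        if self.n_probes < 2:
            raise ValueError("a segment call requires >= 2 supporting probes")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"unknown state {self.state!r}")


def aberrant_runs(states: np.ndarray, min_probes: int = 2) -> list[tuple[int, int, int]]:
    """Maximal runs of >= ``min_probes`` consecutive identical aberrant states.

    ``states`` is an integer array over {0 missing, 1 loss, 2 normal, 3 gain}.
    Returns (start_index, end_index_inclusive, state) triples in order.
    Missing values break runs; normal probes terminate them.
    """
    states = np.asarray(states)
    runs: list[tuple[int, int, int]] = []
    i, n = 0, len(states)
    while i < n:
        s = states[i]
        j = i
        while j + 1 < n and states[j + 1] == s:
            j += 1
        if s in (STATE_LOSS, STATE_GAIN) and (j - i + 1) >= min_probes:
            runs.append((i, j, int(s)))
        i = j + 1
    return runs


def call_segments(
    states: np.ndarray,
    manifest: ProbeManifest,
    subject_id: str = "",
    min_probes: int = 2,
) -> list[CnvSegmentCall]:
    """Apply the consecutive-marker rule to one subject's probe-state sequence.

    ``states`` must be aligned to ``manifest`` order. Runs are additionally
    broken at chromosome boundaries so a call never spans two chromosomes.
    """
    states = np.asarray(states)
    if len(states) != len(manifest):
        raise ValueError(
            f"state sequence length {len(states)} != manifest size {len(manifest)}"
        )
    chroms = manifest.probes["chrom"].to_numpy()
    starts = manifest.probes["start"].to_numpy()
    ends = manifest.probes["end"].to_numpy()
    calls: list[CnvSegmentCall] = []
    # break the sequence at chromosome changes, then extract runs per block
    block_start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or chroms[k] != chroms[k - 1]:
            for i, j, s in aberrant_runs(states[block_start:k], min_probes=min_probes):
                i += block_start
                j += block_start
                calls.append(
                    CnvSegmentCall(
                        subject_id=subject_id,
                        interval=GenomicInterval(
                            chroms[i], int(starts[i]), int(ends[j])
                        ),
                        state=STATE_LABELS[s],
                        n_probes=j - i + 1,
                    )
                )
            block_start = k
    return calls


def region_status_from_calls(
    calls: list[CnvSegmentCall],
    regions,
    manifest: ProbeManifest,
    min_overlap_probes: int = 2,
) -> dict[str, str]:
    """Dichotomize one subject's segment calls into per-region statuses.

    A region is "loss" when at least one loss call overlaps it by
    ``min_overlap_probes`` supporting probes (the stretch rule applied at
    region scope — a single-probe overlap is treated as noise), "gain"
    likewise for gain calls, else "unchanged". Loss takes precedence over
    gain if both somehow overlap one region.
    """
    df = manifest.probes
    status = {label: "unchanged" for label in regions.labels}
    for call in calls:
        in_call = (
            (df["chrom"] == call.interval.chromosome)
            & (df["start"] >= call.interval.start)
            & (df["end"] <= call.interval.end)
        ).to_numpy()
        for label in regions.labels:
            region = regions[label]
            n_overlap = int((in_call & manifest.probes_in(region)).sum())
            if n_overlap >= min_overlap_probes:
                if call.state == "loss":
                    status[label] = "loss"
                elif status[label] != "loss":
                    status[label] = "gain"
    return status


def calls_to_frame(calls: list[CnvSegmentCall]) -> pd.DataFrame:
    """BED-like table (chrom, start, end, subject, state, n_probes)."""
    return pd.DataFrame(
        [
            {
                "chrom": c.interval.chromosome,
                "start": c.interval.start,
                "end": c.interval.end,
                "subject": c.subject_id,
                "state": c.state,
                "n_probes": c.n_probes,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "subject", "state", "n_probes"],
    )
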