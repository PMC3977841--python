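"""Genomic coordinate types, probe manifests and the subtelomeric target regions.

Coordinates are 1-based and inclusive throughout (NCBI Build 36 convention);
conversion to 0-based half-open happens only when writing BED. Strand is
ignored: array probes are treated as strandless genomic anchors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ASSEMBLY = "NCBI36/hg18"

MANIFEST_COLUMNS = ["chrom", "start", "end", "probe_id", "gc_fraction"]


class ManifestParseError(ValueError):
    """Raised when a probe manifest file cannot be parsed; names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chromosome: str
    start: int
    end: int
    assembly: str = DEFAULT_ASSEMBLY

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _chrom_key(chrom: str):
    # natural ordering: chr1 < chr2 < ... < chr22 < chrX
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass
class ProbeManifest:
    """Ordered genomic probes with GC fractions.

    ``probes`` is a DataFrame with columns chrom, start, end, probe_id,
    gc_fraction, sorted by (chromosome, start). This is the coordinate
    backbone shared by the bead-array and tiling platforms.
    """

    probes: pd.DataFrame
    platform: str = "tiling"

    def __post_init__(self) -> None:
        df = self.probes
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        gc = df["gc_fraction"].to_numpy(float)
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("gc_fraction outside [0, 1]")
        if (df["start"].to_numpy() < 1).any():
            raise ValueError("probe start < 1")
        if (df["end"].to_numpy() < df["start"].to_numpy()).any():
            raise ValueError("probe end < start")
        key = df["chrom"].map(_chrom_key)
        order = pd.DataFrame({"k": key, "s": df["start"]}).sort_values(
            ["k", "s"], kind="stable"
        ).index
        self.probes = df.loc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.probes["probe_id"].to_numpy()

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.probes.itertuples()
        ]

    def probes_in(self, region: GenomicInterval) -> np.ndarray:
        """Boolean mask of probes overlapping ``region`` by >= 1 bp."""
        df = self.probes
        return (
            (df["chrom"] == region.chromosome)
            & (df["end"] >= region.start)
            & (df["start"] <= region.end)
        ).to_numpy()

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
            self.probes[MANIFEST_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)

    def to_bed(self, path) -> None:
        """BED5 export, 0-based half-open, score column carries GC*1000."""
        bed = pd.DataFrame(
            {
                "chrom": self.probes["chrom"],
                "start": self.probes["start"] - 1,
                "end": self.probes["end"],
                "name": self.probes["probe_id"],
                "score": (self.probes["gc_fraction"] * 1000).round().astype(int),
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


def parse_probe_manifest(path, platform: str = "tiling") -> ProbeManifest:
    """Read a probe manifest TSV (chrom, start, end, probe_id, gc_fraction).

    A header line is optional; rows out of coordinate order are sorted, not
    rejected. Malformed rows raise :class:`ManifestParseError` naming the
    offending line number (1-based, counting every physical line).
    """
    rows = []
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    seen_content = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if not seen_content:
            seen_content = True
            if _looks_like_header(parts):
                continue
        if len(parts) != 5:
            raise ManifestParseError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}"
            )
        chrom, start_s, end_s, probe_id, gc_s = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ManifestParseError(f"line {lineno}: non-numeric coordinate") from None
        try:
            gc = float(gc_s)
        except ValueError:
            raise ManifestParseError(f"line {lineno}: non-numeric gc_fraction") from None
        if not 0.0 <= gc <= 1.0:
            raise ManifestParseError(f"line {lineno}: gc_fraction {gc} outside [0, 1]")
        if start < 1 or end < start:
            raise ManifestParseError(f"line {lineno}: invalid interval {start}-{end}")
        rows.append((chrom, start, end, probe_id, gc))
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    try:
        return ProbeManifest(df, platform=platform)
    except ValueError as exc:  # manifest-level invariants (e.g. duplicate ids)
        raise ManifestParseError(str(exc)) from None


def _looks_like_header(parts: list[str]) -> bool:
    if len(parts) < 2:
        return False
    try:
        int(parts[1])
    except ValueError:
        return True
    return False


@dataclass
class RegionSet:
    """Named target regions plus intervals flagged as low-coverage gaps."""

    regions: dict[str, GenomicInterval]
    gap_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gap in self.gap_intervals:
            if not any(r.contains(gap) for r in self.regions.values()):
                raise ValueError(f"gap {gap} lies outside every region")

    def __getitem__(self, label: str) -> GenomicInterval:
        return self.regions[label]

    def __iter__(self):
        return iter(self.regions)

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tchrom\tstart\tend\n")
            for label, iv in self.regions.items():
                fh.write(f"{label}\t{iv.chromosome}\t{iv.start}\t{iv.end}\n")

    @classmethod
    def from_tsv(cls, path, gaps_path=None) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        regions = {
            str(r.label): GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()
        }
        gaps: list[GenomicInterval] = []
        if gaps_path is not None:
            gdf = pd.read_csv(gaps_path, sep="\t", comment="#")
            gaps = [
                GenomicInterval(str(r.chrom), int(r.start), int(r.end))
                for r in gdf.itertuples()
            ]
        return cls(regions, gaps)


#: Default stand-in for the chromosome 4 subtelomere. Its published source
#: gives only the span ("1.3-Mb subtelomeric region on 4p16.3"), not
#: coordinates, so this placeholder anchors the span at the telomere and is
#: meant to be overridden by configuration when real bounds are available.
DEFAULT_4P163 = GenomicInterval("chr4", 1, 1_300_000)


def builtin_regions(
    four_p: GenomicInterval = DEFAULT_4P163,
    gap_intervals: list[GenomicInterval] | None = None,
) -> RegionSet:
    """The three subtelomeric target regions on NCBI Build 36.

    16q24.2-3 (1.75 Mb) and 22q13.31-33 (4.8 Mb) carry their published
    Build-36 coordinates; 4p16.3 is configuration-supplied (see
    :data:`DEFAULT_4P163`).
    """
    return RegionSet(
        {
            "4p16.3": four_p,
            "16q24.2-3": GenomicInterval("chr16", 86_950_000, 88_700_000),
            "22q13.31-33": GenomicInterval("chr22", 44_750_000, 49_550_000),
        },
        gap_intervals=gap_intervals or [],
    )
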