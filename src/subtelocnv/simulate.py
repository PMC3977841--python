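"""Synthetic cohorts and array signals with the structure the callers assume.

The study's raw arrays were never deposited, so every downstream stage is
exercised on simulated data carrying the same statistical structure: a
case/control cohort with per-region heterozygous-deletion prevalences,
two-channel aCGH log2-ratio tracks (single-copy loss shifts the expected
ratio to log2(1/2) = −1), bead-array intensities with copy number scaling
expected intensity (1 copy -> half of the 2-copy baseline), GC-content bias,
per-batch probe signatures, Gaussian probe noise, and explicit missing
values at low-coverage gap intervals.

Defaults reproduce the reported study conditions: 100 cases and 100
controls with loss prevalences 15%/3% (16q24.2-3), 22%/6% (22q13.31-33) and
11%/0% (4p16.3). Per-region loss flags are drawn independently; the joint
co-occurrence structure observed in the study is not emulated (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acgh import Log2RatioTrack
from .beadchip import BeadIntensities
from .regions import GenomicInterval, ProbeManifest, RegionSet, overlap_length

#: (case, control) loss prevalence per region, matching the reported counts
#: out of 100 subjects per group. 4p16.3 uses the all-three-region carrier
#: count for cases (the only count tied to that region in this cohort) and
#: zero for controls.
DEFAULT_LOSS_PREVALENCE: dict[str, tuple[float, float]] = {
    "4p16.3": (0.11, 0.0),
    "16q24.2-3": (0.15, 0.03),
    "22q13.31-33": (0.22, 0.06),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Cohort size, per-region loss prevalences and deletion geometry."""

    n_cases: int = 100
    n_controls: int = 100
    loss_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_PREVALENCE)
    )
    #: absolute base-pair span range for simulated deletions, or None to use
    #: ``deletion_span_fraction`` of each region's length
    deletion_span: tuple[int, int] | None = None
    deletion_span_fraction: tuple[float, float] = (0.6, 0.95)
    n_batches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        for region, (p_case, p_ctrl) in self.loss_prevalence.items():
            if not (0 <= p_case <= 1 and 0 <= p_ctrl <= 1):
                raise ConfigurationError(f"prevalence outside [0,1] for {region}")
        if self.deletion_span is not None:
            lo, hi = self.deletion_span
            if lo <= 0 or hi < lo:
                raise ConfigurationError("deletion_span must be positive and ordered")
        lo, hi = self.deletion_span_fraction
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("deletion_span_fraction must lie in (0, 1]")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")


@dataclass
class NoiseModel:
    """Probe-level noise and systematic biases for both platforms.

    ``probe_sd``: per-probe Gaussian SD on the log2 scale. ``gc_coefficients``
    (c0, c1, c2): GC bias on raw intensity as the multiplicative factor
    2**(c0 + c1·gc + c2·gc²). ``batch_effect_sd``: SD of the per-(batch,
    probe) additive intensity signature shared by subjects of a batch.
    ``loss_shift``: expected log2 ratio inside a single-copy deletion,
    log2(1/2) = −1 by default.
    """

    probe_sd: float = 0.2
    gc_coefficients: tuple[float, float, float] = (0.0, 0.3, -0.2)
    batch_effect_sd: float = 0.05
    loss_shift: float = -1.0

    def __post_init__(self) -> None:
        if self.probe_sd < 0:
            raise ConfigurationError("probe_sd must be >= 0")
        if self.loss_shift >= 0:
            raise ConfigurationError("loss_shift must be negative")
        if self.batch_effect_sd < 0:
            raise ConfigurationError("batch_effect_sd must be >= 0")


@dataclass
class SubjectTruth:
    """Ground-truth deletion carriage for one simulated subject."""

    subject_id: str
    group: str  # "case" | "control"
    losses: dict[str, GenomicInterval | None]
    batch_id: int

    def has_loss(self, region: str) -> bool:
        return self.losses.get(region) is not None


def simulate_cohort(spec: CohortSpec, regions: RegionSet) -> list[SubjectTruth]:
    """Draw ground truth for a case/control cohort.

    Loss flags are independent Bernoulli draws per region with the group's
    prevalence; deletion breakpoints are uniform within the region subject
    to the span limits; batches are assigned cyclically so every batch mixes
    cases and controls. Fully reproducible under ``spec.seed``.
    """
    missing = [r for r in regions.labels if r not in spec.loss_prevalence]
    if missing:
        raise ConfigurationError(f"loss_prevalence missing regions: {missing}")
    rng = np.random.default_rng(spec.seed)
    truths: list[SubjectTruth] = []
    groups = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    width = max(3, len(str(max(spec.n_cases, spec.n_controls, 1))))
    counters = {"case": 0, "control": 0}
    for idx, group in enumerate(groups):
        counters[group] += 1
        prefix = "case" if group == "case" else "ctrl"
        subject_id = f"{prefix}_{counters[group]:0{width}d}"
        losses: dict[str, GenomicInterval | None] = {}
        for region in regions.labels:
            p = spec.loss_prevalence[region][0 if group == "case" else 1]
            if rng.random() < p:
                losses[region] = _draw_deletion(rng, regions[region], spec)
            else:
                losses[region] = None
        truths.append(
            SubjectTruth(
                subject_id=subject_id,
                group=group,
                losses=losses,
                batch_id=idx % spec.n_batches,
            )
        )
    return truths


def _draw_deletion(
    rng: np.random.Generator, region: GenomicInterval, spec: CohortSpec
) -> GenomicInterval:
    if spec.deletion_span is not None:
        lo = min(spec.deletion_span[0], region.length)
        hi = min(spec.deletion_span[1], region.length)
    else:
        lo = max(1, int(round(spec.deletion_span_fraction[0] * region.length)))
        hi = max(lo, int(round(spec.deletion_span_fraction[1] * region.length)))
    span = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(region.start, region.end - span + 2))
    return GenomicInterval(region.chromosome, start, start + span - 1)


def truths_to_frame(truths: list[SubjectTruth]) -> pd.DataFrame:
    """Long truth table (subject, group, region, loss, del_start, del_end, batch)."""
    rows = []
    for t in truths:
        for region, interval in t.losses.items():
            rows.append(
                {
                    "subject": t.subject_id,
                    "group": t.group,
                    "region": region,
                    "loss": interval is not None,
                    "del_start": interval.start if interval else pd.NA,
                    "del_end": interval.end if interval else pd.NA,
                    "batch": t.batch_id,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probe manifests

def make_tiling_manifest(
    regions: RegionSet,
    probes_per_region: int = 150,
    probe_length: int = 60,
    seed: int = 0,
) -> ProbeManifest:
    """Evenly spaced 60-mer tiling probes across each target region."""
    return _make_manifest(regions, probes_per_region, probe_length, seed, "tiling", "t")


def make_beadchip_manifest(
    regions: RegionSet,
    probes_per_region: int = 40,
    probe_length: int = 50,
    n_background: int = 120,
    seed: int = 1,
) -> ProbeManifest:
    """Bead-array CNV probes across each target region plus diploid backbone.

    The genome-wide chip carries far more probes outside any one CNV region
    than inside it; ``n_background`` copy-neutral backbone probes (placed on
    a chromosome without target regions) emulate that, anchoring per-subject
    median normalization on the diploid level even for subjects deleted in
    every target region.
    """
    mani = _make_manifest(regions, probes_per_region, probe_length, seed, "beadchip", "b")
    if n_background == 0:
        return mani
    rng = np.random.default_rng(seed + 1)
    used_chroms = {regions[label].chromosome for label in regions.labels}
    chrom = next(c for c in ("chr2", "chr5", "chr7") if c not in used_chroms)
    starts = (10_000_000 + 500_000 * np.arange(n_background)).astype(int)
    gc = rng.uniform(0.3, 0.7, n_background).round(3)
    bg = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + probe_length - 1,
            "probe_id": [f"b_bg_{i:04d}" for i in range(n_background)],
            "gc_fraction": gc,
        }
    )
    df = pd.concat([mani.probes, bg], ignore_index=True)
    return ProbeManifest(df, platform="beadchip")


def _make_manifest(
    regions: RegionSet,
    probes_per_region: int,
    probe_length: int,
    seed: int,
    platform: str,
    prefix: str,
) -> ProbeManifest:
    rng = np.random.default_rng(seed)
    rows = []
    for label in regions.labels:
        region = regions[label]
        starts = np.linspace(
            region.start, region.end - probe_length + 1, probes_per_region
        ).astype(int)
        gc = rng.uniform(0.3, 0.7, probes_per_region).round(3)
        tag = label.replace(".", "").replace("-", "_")
        for i, (s, g) in enumerate(zip(starts, gc)):
            rows.append(
                (region.chromosome, int(s), int(s) + probe_length - 1,
                 f"{prefix}_{tag}_{i:04d}", float(g))
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "gc_fraction"])
    return ProbeManifest(df, platform=platform)


# ---------------------------------------------------------------------------
# signal simulation

def _deleted_probe_mask(truth: SubjectTruth, manifest: ProbeManifest) -> np.ndarray:
    mask = np.zeros(len(manifest), dtype=bool)
    intervals = manifest.intervals()
    for deletion in truth.losses.values():
        if deletion is None:
            continue
        mask |= np.array([overlap_length(p, deletion) > 0 for p in intervals])
    return mask


def _gap_probe_mask(manifest: ProbeManifest, gaps: RegionSet | None) -> np.ndarray:
    mask = np.zeros(len(manifest), dtype=bool)
    if gaps is None or not gaps.gap_intervals:
        return mask
    intervals = manifest.intervals()
    for gap in gaps.gap_intervals:
        mask |= np.array([overlap_length(p, gap) > 0 for p in intervals])
    return mask


def simulate_log2_track(
    truth: SubjectTruth,
    manifest: ProbeManifest,
    noise: NoiseModel,
    gaps: RegionSet | None = None,
    rng: np.random.Generator | int | None = None,
) -> Log2RatioTrack:
    """One subject's tiling-aCGH log2-ratio track.

    Probes inside a true deletion have mean ``loss_shift``, all others mean
    0, with additive Gaussian noise of SD ``probe_sd``; probes overlapping a
    gap interval are emitted as missing (NaN).
    """
    if manifest.platform != "tiling":
        raise ValueError("simulate_log2_track requires a tiling manifest")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(manifest)
    values = rng.normal(0.0, noise.probe_sd, n) if noise.probe_sd > 0 else np.zeros(n)
    values[_deleted_probe_mask(truth, manifest)] += noise.loss_shift
    values[_gap_probe_mask(manifest, gaps)] = np.nan
    return Log2RatioTrack(truth.subject_id, values, manifest)


def simulate_log2_cohort(
    truths: list[SubjectTruth],
    manifest: ProbeManifest,
    noise: NoiseModel,
    gaps: RegionSet | None = None,
    seed: int = 0,
) -> list[Log2RatioTrack]:
    rng = np.random.default_rng(seed)
    return [simulate_log2_track(t, manifest, noise, gaps, rng) for t in truths]


def simulate_bead_intensities(
    truth: SubjectTruth,
    manifest: ProbeManifest,
    noise: NoiseModel,
    baseline: float = 2.0,
    batch_offsets: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One subject's two-channel bead intensities; (2, n_probes) array.

    Copy number scales expected total intensity (2 copies -> ``baseline``,
    1 copy -> half); GC bias multiplies raw intensity by
    2**(c0 + c1·gc + c2·gc²); ``batch_offsets`` (per probe, shared by the
    subject's batch) add on the raw scale; log-normal probe noise of log2-SD
    ``probe_sd``. Channels split the total equally.
    """
    if manifest.platform != "beadchip":
        raise ValueError("simulate_bead_intensities requires a beadchip manifest")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(manifest)
    copies = np.where(_deleted_probe_mask(truth, manifest), 1.0, 2.0)
    gc = manifest.probes["gc_fraction"].to_numpy(float)
    c0, c1, c2 = noise.gc_coefficients
    gc_factor = 2.0 ** (c0 + c1 * gc + c2 * gc**2)
    expected = baseline * (copies / 2.0) * gc_factor
    if batch_offsets is not None:
        expected = expected + batch_offsets
    expected = np.maximum(expected, 1e-9)
    if noise.probe_sd > 0:
        total = expected * 2.0 ** rng.normal(0.0, noise.probe_sd, n)
    else:
        total = expected
    return np.vstack([total / 2.0, total / 2.0])


def simulate_bead_cohort(
    truths: list[SubjectTruth],
    manifest: ProbeManifest,
    noise: NoiseModel,
    baseline: float = 2.0,
    seed: int = 0,
) -> BeadIntensities:
    """Bead intensities for a whole cohort with shared batch signatures.

    Each batch draws one per-probe additive offset vector of SD
    ``batch_effect_sd``; all subjects of a batch share it, so batch
    membership leaves a consistent multi-probe signature for the PCA stage
    to remove.
    """
    rng = np.random.default_rng(seed)
    n_batches = max((t.batch_id for t in truths), default=0) + 1
    signatures = (
        rng.normal(0.0, noise.batch_effect_sd, (n_batches, len(manifest)))
        if noise.batch_effect_sd > 0
        else np.zeros((n_batches, len(manifest)))
    )
    a_cols, b_cols = [], []
    for t in truths:
        ab = simulate_bead_intensities(
            t, manifest, noise, baseline=baseline,
            batch_offsets=signatures[t.batch_id], rng=rng,
        )
        a_cols.append(ab[0])
        b_cols.append(ab[1])
    return BeadIntensities(
        np.column_stack(a_cols),
        np.column_stack(b_cols),
        [t.subject_id for t in truths],
        manifest,
    )


# ---------------------------------------------------------------------------
# clinical covariates

#: Group-level distributions for simulated clinical covariates
#: (mean, sd) for continuous traits, proportion for binary ones.
CLINICAL_PROFILE = {
    "case": {
        "male": 0.59, "family_history": 0.94, "insulin_therapy": 0.63,
        "onset_age": (21.9, 7.3), "exam_age": (37.1, 13.0),
        "max_bmi": (28.0, 4.2), "hba1c_ngsp": (8.4, 2.2),
        "postprandial_glucose": (171.4, 79.7), "urinary_c_peptide": (60.0, 90.0),
    },
    "control": {
        "male": 0.35, "family_history": 0.0, "insulin_therapy": 0.0,
        "onset_age": None, "exam_age": (72.8, 6.4),
        "max_bmi": (25.2, 3.2), "hba1c_ngsp": (5.5, 0.3),
        "postprandial_glucose": (99.4, 15.6), "urinary_c_peptide": None,
    },
}


def simulate_clinical(truths: list[SubjectTruth], seed: int = 0) -> pd.DataFrame:
    """Clinical covariate table with group-typical means and proportions.

    Continuous traits are Gaussian draws truncated at physiological floors;
    traits undefined for a group (e.g. onset age in controls) are NA.
    """
    rng = np.random.default_rng(seed)
    rows = []
    floors = {"onset_age": 1.0, "exam_age": 18.0, "max_bmi": 15.0,
              "hba1c_ngsp": 4.0, "postprandial_glucose": 50.0,
              "urinary_c_peptide": 0.0}
    for t in truths:
        prof = CLINICAL_PROFILE[t.group]
        row: dict = {"subject": t.subject_id, "group": t.group}
        for trait in ("male", "family_history", "insulin_therapy"):
            row[trait] = bool(rng.random() < prof[trait])
        for trait in ("onset_age", "exam_age", "max_bmi", "hba1c_ngsp",
                      "postprandial_glucose", "urinary_c_peptide"):
            if prof[trait] is None:
                row[trait] = pd.NA
            else:
                mu, sd = prof[trait]
                row[trait] = round(max(floors[trait], rng.normal(mu, sd)), 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def truth_status_matrix(truths: list[SubjectTruth], regions: RegionSet):
    """Ground-truth subjects × regions status matrix (for recovery scoring)."""
    from .status import RegionStatusMatrix

    frame = pd.DataFrame(
        {
            region: ["loss" if t.has_loss(region) else "unchanged" for t in truths]
            for region in regions.labels
        },
        index=[t.subject_id for t in truths],
    )
    groups = pd.Series({t.subject_id: t.group for t in truths}, name="group")
    return RegionStatusMatrix(frame, groups)
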