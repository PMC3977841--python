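"""End-to-end orchestration: simulate -> screen -> validate -> associate.

A single master seed deterministically spawns per-stage seeds, so the whole
run is byte-reproducible and each stage can also be re-run standalone with
its logged seed. Configuration is a flat YAML document; unknown keys are
errors (fail-fast against silent typos in threshold names).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import acgh, beadchip, simulate
from .regions import DEFAULT_4P163, GenomicInterval, RegionSet, builtin_regions
from .segments import calls_to_frame
from .status import RegionStatusMatrix
from .association import association_report


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, with study-condition defaults."""

    out_dir: str = "run"
    seed: int = 0
    # cohort
    n_cases: int = 100
    n_controls: int = 100
    loss_prevalence: dict = field(
        default_factory=lambda: dict(simulate.DEFAULT_LOSS_PREVALENCE)
    )
    deletion_span_fraction: tuple = (0.6, 0.95)
    n_batches: int = 4
    # noise
    probe_sd: float = 0.2
    gc_coefficients: tuple = (0.0, 0.3, -0.2)
    batch_effect_sd: float = 0.05
    loss_shift: float = -1.0
    # regions (4p16.3 placeholder is configuration-supplied)
    region_4p_start: int = DEFAULT_4P163.start
    region_4p_end: int = DEFAULT_4P163.end
    # manifests
    beadchip_probes_per_region: int = 40
    beadchip_background_probes: int = 120
    tiling_probes_per_region: int = 150
    # beadchip caller
    n_pcs: int = 2
    mixture_restarts: int = 10
    # aCGH caller
    window: int = 11
    min_probes: int = 2
    scale_floor: float = 0.05
    # statistics
    alpha: float = 0.05
    simulate_clinical: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("deletion_span_fraction", "gc_coefficients"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "loss_prevalence" in data:
            data["loss_prevalence"] = {
                k: tuple(v) for k, v in data["loss_prevalence"].items()
            }
        return cls(**data)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write every intermediate artifact.

    Stages: simulate cohort -> bead-array screen -> tiling-aCGH validation of
    screen-positive subjects -> cross-platform concordance -> association
    report. Identical config + seed yields byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"subtelocnv seed={config.seed} config={config.config_hash()}"
    seeds = stage_seeds(config.seed)

    regions = builtin_regions(
        four_p=GenomicInterval("chr4", config.region_4p_start, config.region_4p_end)
    )
    regions.to_tsv(out / "regions.tsv")

    bead_manifest = simulate.make_beadchip_manifest(
        regions,
        probes_per_region=config.beadchip_probes_per_region,
        n_background=config.beadchip_background_probes,
        seed=seeds[0],
    )
    tiling_manifest = simulate.make_tiling_manifest(
        regions, probes_per_region=config.tiling_probes_per_region, seed=seeds[1]
    )
    bead_manifest.to_tsv(out / "beadchip_manifest.tsv", header_comment=header)
    tiling_manifest.to_tsv(out / "tiling_manifest.tsv", header_comment=header)

    spec = simulate.CohortSpec(
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        loss_prevalence=config.loss_prevalence,
        deletion_span_fraction=tuple(config.deletion_span_fraction),
        n_batches=config.n_batches,
        seed=seeds[2],
    )
    noise = simulate.NoiseModel(
        probe_sd=config.probe_sd,
        gc_coefficients=tuple(config.gc_coefficients),
        batch_effect_sd=config.batch_effect_sd,
        loss_shift=config.loss_shift,
    )
    truths = simulate.simulate_cohort(spec, regions)
    groups = {t.subject_id: t.group for t in truths}
    truth_frame = simulate.truths_to_frame(truths)
    _write_tsv(truth_frame, out / "truth.tsv", header)

    # stage: bead-array screen
    bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=seeds[3])
    bead.to_tsv(out / "bead_channel_a.tsv", out / "bead_channel_b.tsv", header)
    screen_status, screen_calls = beadchip.call_beadchip_cohort(
        bead, regions, groups=groups,
        n_pcs=config.n_pcs, seed=seeds[4], n_init=config.mixture_restarts,
        min_probes=config.min_probes,
    )
    screen_status.to_tsv(out / "beadchip_status.tsv", header_comment=header)
    all_calls = [c for calls in screen_calls.values() for c in calls]
    _write_tsv(calls_to_frame(all_calls), out / "beadchip_calls.tsv", header)

    # stage: aCGH validation on screen-positive subjects (controls form the panel)
    tracks = simulate.simulate_log2_cohort(
        truths, tiling_manifest, noise, gaps=regions, seed=seeds[5]
    )
    _write_tsv(
        acgh.tracks_to_frame(tracks, tiling_manifest).reset_index(names="probe_id"),
        out / "log2_tracks.tsv", header,
    )
    panel_ids = [t.subject_id for t in truths if t.group == "control"]
    positives = [
        s for s in screen_status.subjects
        if (screen_status.statuses.loc[s] == "loss").any()
    ]
    validation_status, validation_calls = acgh.call_acgh_cohort(
        tracks, tiling_manifest, panel_ids, regions, groups=groups,
        window=config.window, min_probes=config.min_probes,
        scale_floor=config.scale_floor,
    )
    validation_subset = validation_status.subset(positives) if positives else validation_status
    validation_status.to_tsv(out / "acgh_status.tsv", header_comment=header)
    conc = acgh.concordance(screen_status, validation_status)

    clinical = (
        simulate.simulate_clinical(truths, seed=seeds[6])
        if config.simulate_clinical else None
    )
    if clinical is not None:
        _write_tsv(clinical.reset_index(), out / "clinical.tsv", header)

    report = association_report(screen_status, clinical=clinical, alpha=config.alpha)
    report["seed"] = config.seed
    report["config_hash"] = config.config_hash()
    report["concordance"] = conc
    report["n_screen_positive"] = len(positives)
    report["n_validated"] = int(
        sum(
            (validation_subset.statuses.loc[s] == "loss").any()
            for s in validation_subset.subjects
        )
    ) if positives else 0
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, float) and np.isnan(o):
        return None
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_tsv(df, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
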