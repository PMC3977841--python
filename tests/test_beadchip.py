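import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subtelocnv import simulate
from subtelocnv.beadchip import (
    BeadIntensities,
    NormalizedIntensityMatrix,
    call_beadchip_cohort,
    fit_probe_mixture,
    normalize_and_gc_correct,
    remove_batch_components,
)
from subtelocnv.regions import builtin_regions
from subtelocnv.segments import call_segments, region_status_from_calls
from subtelocnv.simulate import CohortSpec, NoiseModel


@pytest.fixture(scope="module")
def regions():
    return builtin_regions()


@pytest.fixture(scope="module")
def bead_manifest(regions):
    return simulate.make_beadchip_manifest(regions, probes_per_region=20, n_background=40)


def _null_cohort(regions, n=40, seed=0):
    prev = {r: (0.0, 0.0) for r in regions.labels}
    return simulate.simulate_cohort(
        CohortSpec(n_cases=n // 2, n_controls=n // 2, loss_prevalence=prev, seed=seed),
        regions,
    )


class TestNormalizeAndGcCorrect:
    def test_fixed_point_without_gc_trend(self, regions, bead_manifest):
        """Median-1 input with no GC structure passes through (log2 scale)."""
        truths = _null_cohort(regions)
        noise = NoiseModel(probe_sd=0.1, gc_coefficients=(0, 0, 0), batch_effect_sd=0.0)
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=3)
        norm = normalize_and_gc_correct(bead)
        med = np.median(bead.total, axis=0)
        expected = np.log2(bead.total / med)
        assert np.allclose(norm.values.to_numpy(), expected, atol=0.02)

    def test_global_scale_invariance(self, regions, bead_manifest):
        truths = _null_cohort(regions, n=10)
        noise = NoiseModel(probe_sd=0.1, gc_coefficients=(0, 0, 0), batch_effect_sd=0.0)
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=4)
        doubled = BeadIntensities(
            bead.channel_a * 2, bead.channel_b * 2, bead.subject_ids, bead.manifest
        )
        assert np.allclose(
            normalize_and_gc_correct(bead).values.to_numpy(),
            normalize_and_gc_correct(doubled).values.to_numpy(),
        )

    def test_gc_trend_removed(self, regions, bead_manifest):
        """Injected quadratic GC bias leaves |rank correlation| < 0.05."""
        truths = _null_cohort(regions, n=60)
        noise = NoiseModel(
            probe_sd=0.1, gc_coefficients=(0.0, 1.2, -0.8), batch_effect_sd=0.0
        )
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=5)
        gc = bead_manifest.probes["gc_fraction"].to_numpy()
        rho_before = stats.spearmanr(gc, np.log2(bead.total).mean(axis=1)).statistic
        assert abs(rho_before) > 0.3
        norm = normalize_and_gc_correct(bead)
        rho_after = stats.spearmanr(gc, norm.values.mean(axis=1)).statistic
        assert abs(rho_after) < 0.05

    def test_nonpositive_intensity_rejected(self, regions, bead_manifest):
        truths = _null_cohort(regions, n=10)
        noise = NoiseModel(gc_coefficients=(0, 0, 0), batch_effect_sd=0.0)
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=6)
        bead.channel_a[0, 0] = -bead.channel_a[0, 0]
        with pytest.raises(ValueError, match="positive"):
            normalize_and_gc_correct(bead)


class TestRemoveBatchComponents:
    def _norm_matrix(self, regions, bead_manifest, batch_sd, seed=7, n=60):
        truths = _null_cohort(regions, n=n, seed=seed)
        noise = NoiseModel(
            probe_sd=0.1, gc_coefficients=(0, 0, 0), batch_effect_sd=batch_sd
        )
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=seed)
        return normalize_and_gc_correct(bead), truths

    def test_k0_is_identity(self, regions, bead_manifest):
        m, _ = self._norm_matrix(regions, bead_manifest, 0.1)
        out = remove_batch_components(m, 0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_residual_orthogonal_to_removed_scores(self, regions, bead_manifest):
        m, _ = self._norm_matrix(regions, bead_manifest, 0.1)
        out = remove_batch_components(m, 2, robust=False)
        xc = out.values.to_numpy() - out.values.to_numpy().mean(axis=1, keepdims=True)
        cross = xc @ out.removed_components.T
        assert np.abs(cross).max() < 1e-8

    def test_k_too_large_rejected(self, regions, bead_manifest):
        m, _ = self._norm_matrix(regions, bead_manifest, 0.0, n=10)
        with pytest.raises(ValueError):
            remove_batch_components(m, 10)

    def test_strong_batch_axis_suppressed(self, regions, bead_manifest):
        """One strong batch axis: k=1 cuts the between-batch share >10-fold."""
        prev = {r: (0.0, 0.0) for r in regions.labels}
        truths = simulate.simulate_cohort(
            CohortSpec(n_cases=30, n_controls=30, loss_prevalence=prev,
                       n_batches=2, seed=8),
            regions,
        )
        noise = NoiseModel(probe_sd=0.1, gc_coefficients=(0, 0, 0), batch_effect_sd=0.4)
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=8)
        m = normalize_and_gc_correct(bead)
        batches = np.array([t.batch_id for t in truths])

        def between_batch_share(mat):
            x = mat.values.to_numpy()
            means = np.vstack(
                [x[:, batches == b].mean(axis=1) for b in np.unique(batches)]
            )
            return means.var(axis=0).mean() / x.var()

        before = between_batch_share(m)
        after = between_batch_share(remove_batch_components(m, 1))
        assert after < 0.1 * before


class TestFitProbeMixture:
    def test_constant_input_single_component_all_normal(self):
        call = fit_probe_mixture(np.full(50, 0.7))
        assert call.n_components == 1
        assert (call.states == 2).all()

    def test_well_separated_loss_cluster_fully_recovered(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(0.0, 0.05, 85), rng.normal(-1.0, 0.05, 15)]
        )
        call = fit_probe_mixture(values, random_state=1)
        assert call.n_components == 2
        assert (call.states[:85] == 2).all()
        assert (call.states[85:] == 1).all()
        assert np.all(np.diff(call.means) > 0)
        assert call.weights.sum() == pytest.approx(1.0)

    def test_diploid_cluster_split_not_called_loss(self):
        """Components within half a copy-shift of normal merge into normal."""
        rng = np.random.default_rng(3)
        # skewed-ish diploid cluster that BIC may split in two
        values = np.concatenate(
            [rng.normal(0.0, 0.12, 140), rng.normal(-0.3, 0.12, 60)]
        )
        call = fit_probe_mixture(values, random_state=2)
        assert (call.states == 2).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="10 subjects"):
            fit_probe_mixture(np.zeros(5))

    def test_mean_recovery_across_replicates(self):
        """Fitted component means unbiased: within 3 SE of (−1, 0) over reps."""
        fitted = []
        for rep in range(60):
            rng = np.random.default_rng(100 + rep)
            values = np.concatenate(
                [rng.normal(0.0, 0.2, 170), rng.normal(-1.0, 0.2, 30)]
            )
            call = fit_probe_mixture(values, random_state=rep)
            if call.n_components == 2:
                fitted.append(call.means)
        fitted = np.array(fitted)
        assert len(fitted) > 50
        for j, target in enumerate([-1.0, 0.0]):
            se = fitted[:, j].std(ddof=1) / np.sqrt(len(fitted))
            assert abs(fitted[:, j].mean() - target) < 3 * se


class TestCallSegments:
    def test_isolated_aberrant_probe_is_not_called(self, toy_manifest):
        states = np.array([2, 2, 1, 2, 2, 2, 2, 2, 2, 2])
        assert call_segments(states, toy_manifest) == []

    def test_two_adjacent_loss_probes_one_call(self, toy_manifest):
        states = np.array([2, 2, 1, 1, 2, 2, 2, 2, 2, 2])
        calls = call_segments(states, toy_manifest, subject_id="s")
        assert len(calls) == 1
        assert calls[0].n_probes == 2
        assert calls[0].state == "loss"
        assert calls[0].interval.start == 1200  # first supporting probe start
        assert calls[0].interval.end == 1359  # last supporting probe end

    def test_alternating_states_produce_no_call(self, toy_manifest):
        states = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2])
        assert call_segments(states, toy_manifest) == []

    def test_missing_breaks_runs(self, toy_manifest):
        states = np.array([1, 1, 0, 1, 1, 2, 2, 2, 2, 2])
        calls = call_segments(states, toy_manifest)
        assert [c.n_probes for c in calls] == [2, 2]

    def test_length_mismatch_rejected(self, toy_manifest):
        with pytest.raises(ValueError, match="length"):
            call_segments(np.array([2, 2]), toy_manifest)


class TestRegionStatus:
    def test_full_region_loss(self, toy_manifest, toy_regions):
        states = np.full(10, 1)
        calls = call_segments(states, toy_manifest)
        status = region_status_from_calls(calls, toy_regions, toy_manifest)
        assert status["toy"] == "loss"

    def test_no_calls_all_unchanged(self, toy_manifest, toy_regions):
        status = region_status_from_calls([], toy_regions, toy_manifest)
        assert status["toy"] == "unchanged"

    def test_single_probe_overlap_below_rule_is_unchanged(self, toy_manifest, toy_regions):
        # run on probes p0..p2; region covers p2..p7 -> one-probe overlap
        states = np.array([1, 1, 1, 2, 2, 2, 2, 2, 2, 2])
        calls = call_segments(states, toy_manifest)
        status = region_status_from_calls(calls, toy_regions, toy_manifest)
        assert status["toy"] == "unchanged"


class TestPipelineInvariance:
    def test_subject_permutation_permutes_outputs(self, regions, bead_manifest):
        prev = {"4p16.3": (0.3, 0.3), "16q24.2-3": (0.3, 0.3), "22q13.31-33": (0.3, 0.3)}
        truths = simulate.simulate_cohort(
            CohortSpec(n_cases=15, n_controls=15, loss_prevalence=prev, seed=12), regions
        )
        noise = NoiseModel(probe_sd=0.15, gc_coefficients=(0, 0, 0), batch_effect_sd=0.0)
        bead = simulate.simulate_bead_cohort(truths, bead_manifest, noise, seed=13)
        groups = {t.subject_id: t.group for t in truths}
        status, _ = call_beadchip_cohort(bead, regions, groups=groups, n_pcs=0, seed=1)

        perm = np.random.default_rng(5).permutation(len(truths))
        bead_perm = BeadIntensities(
            bead.channel_a[:, perm],
            bead.channel_b[:, perm],
            [bead.subject_ids[i] for i in perm],
            bead.manifest,
        )
        status_perm, _ = call_beadchip_cohort(
            bead_perm, regions, groups=groups, n_pcs=0, seed=1
        )
        pd.testing.assert_frame_equal(
            status.statuses.sort_index(), status_perm.statuses.sort_index()
        )
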