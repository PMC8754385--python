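import numpy as np
import pandas as pd
import pytest

from twinconn import (
    ACEParams,
    simulate_ace_phenotypes,
    simulate_cohort,
    simulate_fc_phenotypes,
    simulate_roi_timeseries,
    simulate_task_events,
)
from twinconn.containers import CS_PLUS_NOUS, CS_PLUS_US, US

from conftest import pair_correlations


class TestACEPhenotypes:
    def test_twin_correlations_match_theory(self, big_cohort, big_pheno):
        """rMZ -> A + C and rDZ -> A/2 + C for (A,C,E) = (0.5, 0.2, 0.3)."""
        vals = big_pheno.to_numpy()[:, 0]
        r_mz, r_dz = pair_correlations(big_cohort, vals)
        assert r_mz == pytest.approx(0.7, abs=0.03)
        assert r_dz == pytest.approx(0.45, abs=0.03)
        assert vals.var(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_pure_noise_has_no_pair_correlation(self, big_cohort):
        ph = simulate_ace_phenotypes(big_cohort, ACEParams(0, 0, 1), seed=5)
        r_mz, r_dz = pair_correlations(big_cohort, ph.to_numpy()[:, 0])
        assert abs(r_mz) < 0.05 and abs(r_dz) < 0.05

    def test_pure_genetic_limit_makes_mz_twins_identical(self):
        c = simulate_cohort(50, 0, seed=2)
        ph = simulate_ace_phenotypes(c, ACEParams(1 - 1e-6, 0, 1e-6), seed=3)
        first, second, _ = c.pair_index()
        v = ph.to_numpy()[:, 0]
        assert np.allclose(v[first], v[second], atol=1e-2)

    def test_deterministic_under_seed(self, small_cohort):
        a = simulate_ace_phenotypes(small_cohort, ACEParams(0.4, 0.1, 0.5), seed=8)
        b = simulate_ace_phenotypes(small_cohort, ACEParams(0.4, 0.1, 0.5), seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ACEParams(0.5, 0.6, 0.3)
        with pytest.raises(ValueError):
            ACEParams(0.7, 0.3, 0.0)
        with pytest.raises(ValueError):
            ACEParams(-0.1, 0.3, 0.8)


class TestTaskEvents:
    def test_trial_counts_and_durations(self):
        ev = simulate_task_events(seed=4)
        counts = ev["trial_type"].value_counts()
        assert counts[CS_PLUS_US] == 8
        assert counts[CS_PLUS_NOUS] == 8
        assert counts[US] == 8
        cues = ev[ev["trial_type"] != US]
        assert (cues["duration"] == 6.0).all()
        assert (ev.loc[ev["trial_type"] == US, "duration"] == 3.0).all()

    def test_us_immediately_follows_reinforced_cue(self):
        ev = simulate_task_events(seed=4)
        cs = ev[ev["trial_type"] == CS_PLUS_US].reset_index(drop=True)
        us = ev[ev["trial_type"] == US].reset_index(drop=True)
        assert np.allclose(us["onset"], cs["onset"] + cs["duration"])

    def test_isi_within_jitter_range_and_run_fits(self):
        ev = simulate_task_events(seed=10)
        cues = ev[ev["trial_type"] != US].reset_index(drop=True)
        ends = []
        for _, row in ev.iterrows():
            ends.append(row["onset"] + row["duration"])
        # gap between one trial's end (incl. US) and the next cue onset
        cue_onsets = cues["onset"].to_numpy()
        all_ends = np.array(ends)
        for k in range(1, len(cue_onsets)):
            prev_end = all_ends[all_ends <= cue_onsets[k] + 1e-9].max()
            gap = cue_onsets[k] - prev_end
            assert 8.0 - 1e-9 <= gap <= 12.0 + 1e-9
        assert (ev["onset"] + ev["duration"]).max() <= 587.0

    def test_seeding_contract(self):
        a, b = simulate_task_events(seed=1), simulate_task_events(seed=1)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_task_events(seed=2)
        assert not a["onset"].equals(c["onset"])


class TestFCPhenotypes:
    def test_shapes_at_parcellation_scale(self):
        c = simulate_cohort(2, 2, seed=0)
        stack = simulate_fc_phenotypes(
            c, 400, [(0, 1)], ACEParams(0.6, 0, 0.4), ACEParams(0, 0.2, 0.8), seed=1
        )
        assert stack.data.shape == (8, 400, 400)
        assert np.allclose(stack.data[0], stack.data[0].T)

    def test_planted_edges_more_heritable_than_background(self):
        from twinconn import edgewise_h2

        c = simulate_cohort(200, 200, seed=3)
        edges = [(i, i + 1) for i in range(20)]
        stack = simulate_fc_phenotypes(
            c, 25, edges, ACEParams(0.6, 0, 0.4), ACEParams(0, 0.2, 0.8), seed=4
        )
        h2 = edgewise_h2(stack, c).values
        planted = np.array([h2[i, j] for i, j in edges])
        iu, ju = np.triu_indices(25, k=1)
        mask = np.ones(len(iu), bool)
        for i, j in edges:
            mask &= ~((iu == i) & (ju == j))
        assert planted.mean() > h2[iu[mask], ju[mask]].mean() + 0.2

    def test_out_of_range_edges_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            simulate_fc_phenotypes(
                small_cohort, 10, [(0, 10)], ACEParams(0.5, 0, 0.5), ACEParams(0, 0, 1), seed=0
            )


class TestRoiTimeSeries:
    def test_boost_raises_contrast_on_designated_edge(self):
        from twinconn import contrast_fc_stack

        c = simulate_cohort(25, 25, seed=6)
        ev = simulate_task_events(seed=6)
        ts, _ = simulate_roi_timeseries(
            c, ev, n_nodes=8, tr=2.4, condition_edge_boost=2.0,
            pair_share=ACEParams(0.5, 0.2, 0.3), seed=7, boosted_edges=[(0, 1)],
        )
        stack = contrast_fc_stack(ts, ev, band=None)
        assert stack.data[:, 0, 1].mean() > 0.1

    def test_zero_boost_contrast_centered_on_zero(self):
        from twinconn import contrast_fc_stack

        c = simulate_cohort(25, 25, seed=8)
        ev = simulate_task_events(seed=8)
        ts, _ = simulate_roi_timeseries(
            c, ev, n_nodes=8, tr=2.4, condition_edge_boost=0.0,
            pair_share=ACEParams(0.5, 0.2, 0.3), seed=9, boosted_edges=[(0, 1)],
        )
        stack = contrast_fc_stack(ts, ev, band=None)
        m = stack.data[:, 0, 1]
        assert abs(m.mean()) < 3 * m.std(ddof=1) / np.sqrt(len(m))

    def test_injected_spike_exceeds_fd_threshold(self):
        from twinconn import framewise_displacement

        c = simulate_cohort(1, 1, seed=10)
        ev = simulate_task_events(seed=10)
        sid = c.subject_ids[0]
        _, motion = simulate_roi_timeseries(
            c, ev, n_nodes=4, tr=2.4, condition_edge_boost=0.0,
            pair_share=ACEParams(0.5, 0.2, 0.3), seed=11, spikes={sid: [50]},
        )
        fd = framewise_displacement(motion[sid])
        assert fd[50] > 0.5
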