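import collections

import numpy as np
import pandas as pd
import pytest

from uapipe.errors import ConfigurationError, ConstraintError
from uapipe.task_synth import (EffectConfig, GroupEffects, StimulusConfig,
                               generate_session_design, generate_stimulus_evidence,
                               simulate_behavior, simulate_bold, simulate_eeg,
                               simulate_pupil)


class TestSessionDesign:
    def test_default_counts(self, default_design):
        assert len(default_design) == 256
        frame = default_design.to_frame()
        assert frame.groupby(["run", "block"]).ngroups == 32

    def test_dominant_option_balance(self, default_design):
        frame = default_design.to_frame()
        combos = frame[[c for c in frame.columns if c.startswith("dominant_")]] \
            .apply(tuple, axis=1)
        counts = collections.Counter(combos)
        assert len(counts) == 16
        assert set(counts.values()) == {16}

    @pytest.mark.parametrize("seed", range(8))
    def test_no_adjacent_same_set_size(self, seed):
        design = generate_session_design(seed=seed)
        sizes = design.to_frame().groupby(["run", "block"], sort=True)["load"] \
            .first().tolist()
        assert all(a != b for a, b in zip(sizes, sizes[1:]))

    def test_cue_set_constant_within_block(self, default_design):
        frame = default_design.to_frame()
        assert (frame.groupby(["run", "block"])["cue_set"].nunique() == 1).all()

    def test_every_cued_feature_probed_per_block(self, default_design):
        frame = default_design.to_frame()
        for _, blk in frame.groupby(["run", "block"]):
            cue = set(blk["cue_set"].iloc[0].split("+"))
            assert cue <= set(blk["probe_feature"])

    def test_single_block_full_load_probes_each_feature_once(self):
        # force a size-4 cue set by retrying seeds (membership is random)
        for seed in range(50):
            design = generate_session_design(n_runs=1, blocks_per_run=4,
                                             trials_per_block=4, seed=seed)
            first = design.to_frame().query("run == 1 and block == 1")
            if first["load"].iloc[0] == 4:
                assert sorted(first["probe_feature"]) == \
                    ["color", "direction", "saturation", "size"]
                return
        pytest.fail("no size-4 first block found across seeds")

    def test_deterministic(self):
        a = generate_session_design(seed=3).to_frame()
        b = generate_session_design(seed=3).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_probe_balance_raises(self):
        with pytest.raises(ConstraintError, match="probe coverage"):
            generate_session_design(trials_per_block=3)

    def test_unbalanced_combo_count_raises(self):
        with pytest.raises(ConstraintError, match="dominant-option balance"):
            generate_session_design(n_runs=1, blocks_per_run=4, trials_per_block=5)

    def test_setsize_balance_raises(self):
        with pytest.raises(ConstraintError, match="set-size balance"):
            generate_session_design(blocks_per_run=6, trials_per_block=8, n_runs=4)


class TestStimulusEvidence:
    def test_evidence_ratios(self, stim_config, default_design):
        sums = {f: 0 for f in stim_config.evidence_ratio}
        total = 0
        for trial in default_design.trials[:40]:
            ev = generate_stimulus_evidence(trial, stim_config, seed=5)
            for f, arr in ev.options.items():
                sums[f] += arr.sum()
            total += arr.size
        for f, ratio in stim_config.evidence_ratio.items():
            se = np.sqrt(ratio * (1 - ratio) / total)
            assert abs(sums[f] / total - ratio) < 5 * se

    def test_motion_coherence_fraction(self, stim_config, default_design):
        ev = generate_stimulus_evidence(default_design.trials[0], stim_config, seed=2)
        frac = ev.coherent.mean()
        se = np.sqrt(0.2 * 0.8 / ev.coherent.size)
        assert abs(frac - 0.2) < 5 * se

    def test_symmetric_ratio_allowed_and_balanced(self, default_design):
        cfg = StimulusConfig(evidence_ratio={"color": 0.5, "direction": 0.5,
                                             "size": 0.5, "saturation": 0.5})
        counts = 0
        total = 0
        for trial in default_design.trials[:30]:
            ev = generate_stimulus_evidence(trial, cfg, seed=9)
            counts += ev.options["color"].sum()
            total += ev.options["color"].size
        se = np.sqrt(0.25 / total)
        assert abs(counts / total - 0.5) < 5 * se

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusConfig(evidence_ratio={"color": 0.4, "direction": 0.8,
                                           "size": 0.65, "saturation": 0.6})

    def test_deterministic(self, stim_config, default_design):
        t = default_design.trials[3]
        a = generate_stimulus_evidence(t, stim_config, seed=11)
        b = generate_stimulus_evidence(t, stim_config, seed=11)
        assert all(np.array_equal(a.options[f], b.options[f]) for f in a.options)
        assert np.array_equal(a.coherent, b.coherent)


class TestBehavior:
    def test_accuracy_decreases_with_load(self, effects):
        # Monte-Carlo oracle: >= 10^4 trials across loads
        design = generate_session_design(n_runs=160, seed=4)
        trials = simulate_behavior(design, effects, seed=4, group="young",
                                   p_outlier=0.0)
        acc = pd.DataFrame({"load": [t.load for t in trials],
                            "correct": [t.correct for t in trials]}) \
            .groupby("load")["correct"].mean()
        assert len(trials) >= 10_000
        assert all(acc.loc[l] > acc.loc[l + 1] for l in (1, 2, 3))

    def test_flat_parameters_give_no_load_effect(self, small_design):
        flat = GroupEffects(drift_slope=0.0, boundary_slope=0.0, ndt_slope=0.0)
        eff = EffectConfig(groups={"young": flat, "old": flat})
        design = generate_session_design(n_runs=8, seed=6)
        trials = simulate_behavior(design, eff, seed=6, p_outlier=0.0)
        df = pd.DataFrame({"load": [t.load for t in trials],
                           "correct": [t.correct for t in trials]})
        acc = df.groupby("load")["correct"].mean()
        slope = np.polyfit(acc.index, acc.values, 1)[0]
        assert abs(slope) < 0.02

    def test_rt_exceeds_ndt(self, small_design, effects):
        trials = simulate_behavior(small_design, effects, seed=1, p_outlier=0.0)
        ge = effects.group("young")
        for t in trials:
            assert t.rt > ge.at_load("ndt", t.load)

    def test_missing_group_raises(self, small_design, effects):
        with pytest.raises(ConfigurationError, match="no effect parameters"):
            simulate_behavior(small_design, effects, group="middle")

    def test_deterministic(self, small_design, effects):
        a = simulate_behavior(small_design, effects, seed=2)
        b = simulate_behavior(small_design, effects, seed=2)
        assert [(t.rt, t.correct) for t in a] == [(t.rt, t.correct) for t in b]


class TestSimulateEEG:
    def test_shapes_and_metadata(self, small_design, effects):
        out = simulate_eeg(small_design, effects, seed=1)
        stim = out["stimulus"]
        assert stim.data.shape[2] == len(small_design)
        assert stim.alignment == "stimulus"
        assert out["response"].alignment == "response"
        assert np.allclose(np.diff(stim.times), 1.0 / stim.srate)

    def test_channel_neighbor_mismatch_raises(self, small_design, effects):
        with pytest.raises(ConfigurationError, match="neighbor"):
            simulate_eeg(small_design, effects, channels=("Fz", "Cz", "Pz", "XX"))

    def test_srate_contract(self, small_design, effects):
        with pytest.raises(ConfigurationError):
            simulate_eeg(small_design, effects, srate=100.0)

    def test_deterministic(self, small_design, effects):
        a = simulate_eeg(small_design, effects, seed=9)
        b = simulate_eeg(small_design, effects, seed=9)
        assert np.array_equal(a["stimulus"].data, b["stimulus"].data)
        assert np.array_equal(a["response"].data, b["response"].data)


class TestSimulatePupil:
    def test_zero_blink_rate_no_annotations(self, small_design, effects):
        eff = EffectConfig(blink_rate=0.0)
        traces = simulate_pupil(small_design, eff, seed=1)
        assert all(len(t.blinks) == 0 for t in traces)

    def test_blinks_annotated_in_bounds(self, small_design, effects):
        traces = simulate_pupil(small_design, effects, seed=1)
        assert any(len(t.blinks) > 0 for t in traces)  # rate 0.15/s over 7.5 s

    def test_deterministic(self, small_design, effects):
        a = simulate_pupil(small_design, effects, seed=5)
        b = simulate_pupil(small_design, effects, seed=5)
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_srate_contract(self, small_design, effects):
        with pytest.raises(ConfigurationError):
            simulate_pupil(small_design, effects, srate=50.0)


class TestSimulateBold:
    def test_shapes(self, small_design, effects):
        bold = simulate_bold(small_design, effects, seed=1)
        assert bold.patterns.shape[0] == len(small_design)
        assert bold.betas.shape == (200, 4)

    def test_min_voxels(self, small_design, effects):
        with pytest.raises(ConfigurationError):
            simulate_bold(small_design, effects, n_voxels=10)

    def test_rank1_plant_dominates_betas(self, small_design):
        eff = EffectConfig(bold_noise_sd=1e-9)
        bold = simulate_bold(small_design, eff, seed=2)
        u, s, vt = np.linalg.svd(bold.betas, full_matrices=False)
        cos = abs(np.dot(u[:, 0], bold.latent_pattern))
        assert cos > 0.999
        assert s[0] > 1e3 * s[1]

    def test_deterministic(self, small_design, effects):
        a = simulate_bold(small_design, effects, seed=3)
        b = simulate_bold(small_design, effects, seed=3)
        assert np.array_equal(a.patterns, b.patterns)
        assert np.array_equal(a.betas, b.betas)
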