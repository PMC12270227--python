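"""Quality-control checkpoints: prefilters, activation classifier,
decision gates and reproducibility metrics."""

import numpy as np
import pandas as pd
import pytest

import cpscreen as cp
from cpscreen.qc import chp5_gate
from cpscreen.synthetic_screen import BRIGHTFIELD_FEATURES


def _bf(fractions, cells=300, seed=0, **kw):
    return cp.simulate_brightfield_cells(fractions, cells_per_well=cells, seed=seed, **kw)


class TestPrefilter:
    def test_boundary_conventions(self):
        df = _bf({"A02": 0.5}, cells=10, seed=1)
        df.loc[0, "area"] = 2000.0       # retained: strict >
        df.loc[1, "area"] = 2000.1       # removed
        df.loc[2, "intensity_mean"] = 10000.0  # retained: strict <
        df.loc[3, "intensity_mean"] = 9999.0   # removed
        kept = cp.prefilter_cells(df)
        assert len(kept) == 8
        assert (kept["area"] <= 2000.0).all()
        assert (kept["intensity_mean"] >= 10000.0).all()

    def test_empty_table_passes_through(self):
        df = _bf({"A02": 0.5}, cells=5, seed=1).iloc[0:0]
        assert len(cp.prefilter_cells(df)) == 0


class TestActivationClassifier:
    def test_separable_populations_reach_full_training_accuracy(self):
        df = _bf({"A02": 0.0, "A03": 1.0}, cells=200, seed=3, separation=12.0)
        model = cp.train_activation_classifier(df)
        assert model.training_accuracy == 1.0

    def test_overlapping_populations_envelope(self):
        accs = [
            cp.train_activation_classifier(
                _bf({"A02": 0.0, "A03": 1.0}, cells=200, seed=s, separation=0.35)
            ).training_accuracy
            for s in range(25)
        ]
        assert 0.60 <= np.mean(accs) <= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(7)
        df = _bf({"A02": 0.0, "A03": 1.0}, cells=400, seed=5, separation=2.0)
        df["truth_label"] = rng.permutation(df["truth_label"].to_numpy())
        model = cp.train_activation_classifier(df)
        n = len(df)
        assert abs(model.training_accuracy - 0.5) < 2.5 * np.sqrt(0.25 / n) + 0.05

    def test_single_class_training_rejected(self):
        df = _bf({"A02": 0.0}, cells=100, seed=1)
        with pytest.raises(cp.CPScreenError, match="both"):
            cp.train_activation_classifier(df)

    def test_recovers_well_ordering(self):
        df = _bf({"A02": 0.05, "A03": 0.6}, cells=400, seed=9, separation=3.0)
        model = cp.train_activation_classifier(df)
        p_low = cp.percent_activated(model, df[df["well"] == "A02"])
        p_high = cp.percent_activated(model, df[df["well"] == "A03"])
        assert p_low < p_high


class TestPercentActivated:
    def _constant_model(self, positive: bool):
        w = np.zeros(len(BRIGHTFIELD_FEATURES))
        return cp.LinearClassifierModel(
            feature_names=tuple(BRIGHTFIELD_FEATURES),
            weights=w,
            offset=1.0 if positive else -1.0,
            training_accuracy=1.0,
        )

    def test_printed_formula(self):
        df = _bf({"A02": 0.5}, cells=400, seed=11, separation=6.0)
        model = cp.train_activation_classifier(df)
        cells = df[df["well"] == "A02"]
        kept = cp.prefilter_cells(cells)
        a = int(model.predict_activated(kept).sum())
        b = len(kept) - a
        assert cp.percent_activated(model, cells) == pytest.approx(100.0 * a / (a + b))

    def test_all_activated_gives_100(self):
        df = _bf({"A02": 1.0}, cells=50, seed=1)
        assert cp.percent_activated(self._constant_model(True), df) == 100.0

    def test_balanced_split_gives_50(self):
        # a model splitting on the median area: a == b exactly
        df = _bf({"A02": 0.5}, cells=40, seed=1)
        w = np.zeros(len(BRIGHTFIELD_FEATURES))
        w[list(BRIGHTFIELD_FEATURES).index("area")] = 1.0
        model = cp.LinearClassifierModel(
            feature_names=tuple(BRIGHTFIELD_FEATURES),
            weights=w,
            offset=-float(np.median(df["area"])),
            training_accuracy=1.0,
        )
        assert cp.percent_activated(model, df) == pytest.approx(50.0, abs=2.5)

    def test_no_retained_cells_is_missing(self):
        df = _bf({"A02": 0.5}, cells=20, seed=1)
        df["area"] = 3000.0
        assert np.isnan(cp.percent_activated(self._constant_model(True), df))

    def test_invariant_to_cell_ordering(self):
        df = _bf({"A02": 0.3}, cells=200, seed=13, separation=2.0)
        model = cp.train_activation_classifier(
            _bf({"A02": 0.0, "A03": 1.0}, cells=200, seed=13, separation=2.0)
        )
        shuffled = df.sample(frac=1.0, random_state=0)
        assert cp.percent_activated(model, df) == pytest.approx(
            cp.percent_activated(model, shuffled)
        )


def _chp2_frame(resting_percents, activated_percents):
    rows = [
        {"well": f"A{i + 2:02d}", "condition": "resting", "percent_activated": p}
        for i, p in enumerate(resting_percents)
    ] + [
        {"well": f"B{i + 2:02d}", "condition": "activated", "percent_activated": p}
        for i, p in enumerate(activated_percents)
    ]
    return pd.DataFrame(rows)


class TestChP2Gate:
    @pytest.mark.parametrize(
        "n_bad_resting,n_bad_activated,expected",
        [
            (0, 0, "pass"),
            (2, 0, "pass"),
            (3, 0, "rescreen"),
            (0, 2, "pass"),
            (0, 3, "rescreen"),
            (2, 2, "pass"),
            (3, 3, "rescreen"),
        ],
    )
    def test_enumerated_rule_grid(self, n_bad_resting, n_bad_activated, expected):
        resting = [20.0] * n_bad_resting + [5.0] * (16 - n_bad_resting)
        activated = [10.0] * n_bad_activated + [60.0] * (16 - n_bad_activated)
        decision = cp.chp2_gate(_chp2_frame(resting, activated), plate_id="P1")
        assert decision.verdict == expected
        assert decision.evidence["offending_resting_controls"] == n_bad_resting

    def test_boundary_percentages_do_not_offend(self):
        # strict comparisons: exactly 15% resting and exactly 30% activated are fine
        frame = _chp2_frame([15.0] * 16, [30.0] * 16)
        d = cp.chp2_gate(frame)
        assert d.verdict == "pass"
        assert d.evidence["offending_resting_controls"] == 0
        assert d.evidence["offending_activated_controls"] == 0


class TestChP5Gate:
    def _controls(self, n_ref, n_pos, n_ref_abnormal, n_pos_abnormal, threshold=1.0):
        rows = []
        for i in range(n_ref):
            rows.append({"role": "reference_control", "cp_score": 2.0 if i < n_ref_abnormal else 0.1})
        for i in range(n_pos):
            rows.append({"role": "activator_control", "cp_score": 0.1 if i < n_pos_abnormal else 2.0})
        return pd.DataFrame(rows)

    def test_repeat_when_over_22_percent_at_outset(self):
        controls = self._controls(52, 10, 15, 0)  # 15/62 = 24.2% > 22%
        assert cp.chp5_gate(controls, 1.0).verdict == "repeat"

    def test_renormalize_path_succeeds(self):
        # 4/62 abnormal (>10%): drop them, recompute; none abnormal after
        controls = self._controls(52, 10, 4, 0)
        d = cp.chp5_gate(controls, 1.0, recompute=lambda s: 1.0)
        assert d.verdict == "renormalize"
        assert d.evidence["n_abnormal_after"] == 0

    def test_rescreen_when_abnormal_persists(self):
        controls = self._controls(52, 10, 4, 3)
        # recompute drops threshold so the 3 remaining positives stay abnormal
        d = cp.chp5_gate(controls, 1.0, recompute=lambda s: 10.0)
        assert d.verdict == "rescreen"

    def test_zero_abnormal_passes(self):
        controls = self._controls(52, 10, 0, 0)
        assert cp.chp5_gate(controls, 1.0).verdict == "pass"

    def test_no_controls_rejected(self):
        with pytest.raises(cp.CPScreenError):
            cp.chp5_gate(pd.DataFrame(columns=["role", "cp_score"]), 1.0)

    @pytest.mark.parametrize("n_controls", [38, 62, 64])
    def test_full_decision_table_enumerated(self, n_controls):
        """The gate is a pure function of counts: enumerate abnormal counts
        0..n and assert the printed decision rules hold exactly."""
        for n_abn in range(n_controls + 1):
            controls = self._controls(n_controls, 0, n_abn, 0)
            d = cp.chp5_gate(controls, 1.0, recompute=lambda s: 1.0)
            frac = n_abn / n_controls
            if frac > 0.22:
                assert d.verdict == "repeat", (n_controls, n_abn)
            elif n_abn > 3:  # the printed "more than 10% (3 wells)" rule
                # all abnormal wells dropped; recompute leaves none abnormal
                assert d.verdict == "renormalize", (n_controls, n_abn)
            else:
                assert d.verdict == "pass", (n_controls, n_abn)


class TestPairedConditionTable:
    def test_quadrant_rules(self):
        rest = pd.DataFrame(
            {
                "well": ["A02", "A03", "A04", "A05"],
                "compound_id": ["a", "b", "c", "d"],
                "role": ["experimental"] * 4,
                "cp_score": [0.0, 0.05, 0.2, 0.3],
            }
        )
        act = pd.DataFrame(
            {
                "well": ["A02", "A03", "A04", "A05"],
                "compound_id": ["a", "b", "c", "d"],
                "role": ["experimental"] * 4,
                "cp_score": [0.0, 0.2, 0.05, 0.4],
            }
        )
        out = cp.paired_condition_table(rest, act, 0.1)
        assert list(out["quadrant"]) == ["dark", "activated_only", "resting_only", "both"]
        assert out.attrs["axis_convention"] == {"x": "resting", "y": "activated"}

    def test_unmatched_wells_rejected(self):
        rest = pd.DataFrame({"well": ["A02"], "compound_id": ["a"], "role": ["experimental"], "cp_score": [0.1]})
        act = pd.DataFrame({"well": ["A03"], "compound_id": ["a"], "role": ["experimental"], "cp_score": [0.1]})
        with pytest.raises(cp.CPScreenError, match="unmatched"):
            cp.paired_condition_table(rest, act, 0.1)

    def test_quadrants_agree_with_illumination_partition(self, rng):
        wells = [f"B{i + 2:02d}" for i in range(20)]
        compounds = [f"c{i}" for i in range(20)]
        base = {
            "well": wells,
            "compound_id": compounds,
            "role": ["experimental"] * 20,
            "dose_uM": 10.0,
            "cytotoxic": False,
            "n_cells": 100,
        }
        thr = 0.1
        rest = pd.DataFrame({**base, "condition": "resting", "cp_score": rng.uniform(0, 0.2, 20)})
        act = pd.DataFrame({**base, "condition": "activated", "cp_score": rng.uniform(0, 0.2, 20)})
        rest["active"] = rest["cp_score"] > thr
        act["active"] = act["cp_score"] > thr
        paired = cp.paired_condition_table(rest, act, thr)
        venn = cp.illumination_summary(rest, act)
        counts = paired["quadrant"].value_counts().to_dict()
        for cat in ("both", "activated_only", "resting_only", "dark"):
            assert counts.get(cat, 0) == venn["counts"][cat]


class TestJumpReproducibility:
    def _meta(self, n, compound="J1"):
        return pd.DataFrame(
            {
                "compound_id": [compound] * n,
                "plate_id": [f"P{i % 2 + 1}" for i in range(n)],
                "batch": [f"B{i % 2 + 1}" for i in range(n)],
            }
        )

    def test_identical_replicates_correlate_perfectly(self, rng):
        row = rng.normal(size=50)
        fp = pd.DataFrame([row] * 4)
        meta = pd.DataFrame(
            {"compound_id": ["J1"] * 4, "plate_id": ["P1"] * 4, "batch": ["B1"] * 4}
        )
        out = cp.jump_reproducibility(fp, meta, "within_plate")
        assert np.allclose(out["pearson_r"], 1.0)

    def test_independent_fingerprints_center_at_zero(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fp = pd.DataFrame(rng.normal(size=(6, 482)))
            meta = pd.DataFrame(
                {"compound_id": ["J1"] * 6, "plate_id": ["P1"] * 6, "batch": ["B1"] * 6}
            )
            out = cp.jump_reproducibility(fp, meta, "within_plate")
            means.append(out["pearson_r"].mean())
        assert abs(np.mean(means)) < 0.05

    def test_shared_signal_with_small_noise_correlates_high(self, rng):
        signal = rng.normal(size=482)
        signal /= np.linalg.norm(signal)
        fp = pd.DataFrame([signal + rng.normal(scale=0.1 / np.sqrt(482), size=482) for _ in range(6)])
        meta = pd.DataFrame(
            {"compound_id": ["J1"] * 6, "plate_id": ["P1"] * 6, "batch": ["B1"] * 6}
        )
        out = cp.jump_reproducibility(fp, meta, "within_plate")
        assert out["pearson_r"].median() > 0.9

    def test_grouping_levels_partition_pairs(self, rng):
        fp = pd.DataFrame(rng.normal(size=(8, 30)))
        meta = pd.DataFrame(
            {
                "compound_id": ["J1"] * 8,
                "plate_id": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
                "batch": ["B1", "B1", "B1", "B1", "B2", "B2", "B2", "B2"],
            }
        )
        n_within = len(cp.jump_reproducibility(fp, meta, "within_plate"))
        n_between = len(cp.jump_reproducibility(fp, meta, "between_plate"))
        n_batch = len(cp.jump_reproducibility(fp, meta, "between_batch"))
        assert n_within == 4
        assert n_between == 8
        assert n_batch == 16
        assert n_within + n_between + n_batch == 8 * 7 // 2

    def test_singleton_compound_skipped(self, rng):
        fp = pd.DataFrame(rng.normal(size=(1, 30)))
        out = cp.jump_reproducibility(fp, self._meta(1), "within_plate")
        assert out.empty
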