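"""QC and normalization contracts for AOI protein count matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

import timetopo as tt
from timetopo.dsp import AOIMatrix, MarkerRoles


def toy_matrix(counts_dict, nuclei=None, segment=None, hyb=("H1", "H2")):
    counts = pd.DataFrame(counts_dict)
    counts.index = [f"A{i}" for i in range(len(counts))]
    counts.index.name = "aoi_id"
    n = len(counts)
    meta = pd.DataFrame(
        {
            "roi_id": [f"R{i}" for i in range(n)],
            "patient_id": [f"P{i}" for i in range(n)],
            "segment": segment or ["tumor"] * n,
            "nuclei_count": nuclei if nuclei is not None else [100.0] * n,
            "area": [1e4] * n,
            "slide_id": ["TMA1"] * n,
        },
        index=counts.index,
    )
    return AOIMatrix(
        counts=counts,
        meta=meta,
        roles=MarkerRoles(housekeepers=["GAPDH", "S6"], isotypes=["iso"],
                          hyb_controls=list(hyb)),
    )


class TestHybNormalize:
    def test_identical_controls_leave_matrix_unchanged(self):
        m = toy_matrix({"X": [10.0, 20.0, 30.0], "H1": [5.0] * 3, "H2": [5.0] * 3,
                        "GAPDH": [4.0] * 3, "S6": [9.0] * 3, "iso": [1.0] * 3})
        out = tt.hyb_normalize(m)
        pd.testing.assert_frame_equal(out.counts, m.counts)
        assert np.allclose(out.meta["hyb_norm_factor"], 1.0)

    def test_doubled_controls_halve_that_aoi(self):
        m = toy_matrix({"X": [10.0, 10.0], "H1": [5.0, 10.0], "H2": [5.0, 10.0],
                        "GAPDH": [4.0] * 2, "S6": [9.0] * 2, "iso": [1.0] * 2})
        out = tt.hyb_normalize(m)
        # factors re-centered at the cohort geomean: sqrt(2) and 2/sqrt(2)
        assert out.counts.loc["A1", "X"] / out.counts.loc["A0", "X"] == pytest.approx(0.5)

    def test_nonpositive_control_flags_aoi(self):
        m = toy_matrix({"X": [10.0, 10.0], "H1": [5.0, 0.0], "H2": [5.0, 5.0],
                        "GAPDH": [4.0] * 2, "S6": [9.0] * 2, "iso": [1.0] * 2})
        out = tt.hyb_normalize(m)
        assert np.isnan(out.meta.loc["A1", "hyb_norm_factor"])
        assert "A1" in set(out.qc_log["aoi_id"])

    def test_lane_effect_reduces_constant_marker_cv(self):
        """Simulated multiplicative lane effects: normalization shrinks the CV."""
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = tt.DSPSimConfig(markers=["M1"], lane_sd=0.4, noise_sd=0.05,
                                  patient_sd=0.0, seed=rep)
            design = tt.make_design(30, rois_per_patient=(1, 1), seed=rep,
                                    nuclei_log_sd=0.0)
            m = tt.simulate_counts(cfg, design)
            pre = m.counts["M1"].std() / m.counts["M1"].mean()
            out = tt.hyb_normalize(m)
            post = out.counts["M1"].std() / out.counts["M1"].mean()
            wins += post < pre
        assert wins / n_rep >= 0.95


class TestQCFilter:
    def base(self, nuclei, hyb_scale):
        n = len(nuclei)
        m = toy_matrix(
            {"X": [10.0] * n,
             "H1": list(5.0 * np.asarray(hyb_scale)),
             "H2": list(5.0 * np.asarray(hyb_scale)),
             "GAPDH": [4.0] * n, "S6": [9.0] * n, "iso": [1.0] * n},
            nuclei=nuclei,
        )
        return tt.hyb_normalize(m)

    def test_nineteen_nuclei_excluded_twenty_retained(self):
        m = self.base(nuclei=[19.0, 20.0, 100.0], hyb_scale=[1, 1, 1])
        out = tt.qc_filter(m)
        assert list(out.aoi_ids) == ["A1", "A2"]
        assert "nuclei_count < 20" in set(out.qc_log["reason"])

    def test_factor_boundary_is_strict(self):
        # one AOI with hyb controls high enough that its factor exceeds 3
        m = self.base(nuclei=[100.0] * 4, hyb_scale=[1, 1, 1, 40])
        factors = m.meta["hyb_norm_factor"]
        assert (factors > 3).sum() == 1
        out = tt.qc_filter(m)
        assert len(out.counts) == 3

    def test_exactly_the_violating_aois_removed(self):
        m = self.base(nuclei=[19.0, 50.0, 5.0, 200.0, 100.0], hyb_scale=[1] * 5)
        out = tt.qc_filter(m)
        assert len(out.counts) == 3
        excluded = set(out.qc_log["aoi_id"])
        assert excluded == {"A0", "A2"}

    def test_idempotent(self):
        m = self.base(nuclei=[19.0, 50.0, 100.0], hyb_scale=[1, 1, 1])
        once = tt.qc_filter(m)
        twice = tt.qc_filter(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_all_failing_raises(self):
        m = self.base(nuclei=[5.0, 5.0], hyb_scale=[1, 1])
        with pytest.raises(ValueError, match="threshold"):
            tt.qc_filter(m)


class TestSplitBySegment:
    def test_partition_sizes_and_roundtrip(self):
        m = toy_matrix(
            {"X": list(range(17)), "H1": [5.0] * 17, "H2": [5.0] * 17,
             "GAPDH": [4.0] * 17, "S6": [9.0] * 17, "iso": [1.0] * 17},
            segment=["tumor"] * 10 + ["immune"] * 7,
        )
        tumor, immune = tt.split_by_segment(m)
        assert (len(tumor.counts), len(immune.counts)) == (10, 7)
        rejoined = pd.concat([tumor.counts, immune.counts]).sort_index()
        pd.testing.assert_frame_equal(rejoined, m.counts.sort_index())

    def test_all_tumor_input_gives_empty_immune(self):
        m = toy_matrix({"X": [1.0, 2.0], "H1": [5.0] * 2, "H2": [5.0] * 2,
                        "GAPDH": [4.0] * 2, "S6": [9.0] * 2, "iso": [1.0] * 2})
        tumor, immune = tt.split_by_segment(m)
        assert len(tumor.counts) == 2 and len(immune.counts) == 0


class TestSelectHousekeepers:
    def test_collinear_pair_wins_with_r_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 100, 30)
        m = toy_matrix({"A": a, "B": 2 * a, "C": rng.uniform(10, 100, 30),
                        "H1": [5.0] * 30, "H2": [5.0] * 30,
                        "GAPDH": [4.0] * 30, "S6": [9.0] * 30, "iso": [1.0] * 30})
        pair, corr = tt.select_housekeepers(m, ["A", "B", "C"])
        assert set(pair) == {"A", "B"}
        assert corr.loc["A", "B"] == pytest.approx(1.0)

    def test_two_candidates_returned_regardless_of_r(self):
        rng = np.random.default_rng(1)
        m = toy_matrix({"A": rng.uniform(1, 9, 20), "B": rng.uniform(1, 9, 20),
                        "H1": [5.0] * 20, "H2": [5.0] * 20,
                        "GAPDH": [4.0] * 20, "S6": [9.0] * 20, "iso": [1.0] * 20})
        pair, _ = tt.select_housekeepers(m, ["A", "B"])
        assert set(pair) == {"A", "B"}

    def test_constant_candidate_ineligible(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(10, 100, 30)
        m = toy_matrix({"A": a, "B": 1.5 * a, "C": [7.0] * 30,
                        "H1": [5.0] * 30, "H2": [5.0] * 30,
                        "GAPDH": [4.0] * 30, "S6": [9.0] * 30, "iso": [1.0] * 30})
        pair, corr = tt.select_housekeepers(m, ["A", "B", "C"])
        assert set(pair) == {"A", "B"}
        assert corr.loc["C"].isna().all()

    def test_lowest_noise_housekeepers_selected(self):
        """Housekeepers all proportional to nuclei; the two quietest win."""
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = tt.DSPSimConfig(
                markers=["M1"],
                housekeepers=["HK1", "HK2", "HK3"],
                marker_noise_sd={"HK1": 0.05, "HK2": 0.05, "HK3": 0.5},
                patient_sd=0.0, seed=rep,
            )
            design = tt.make_design(40, rois_per_patient=(1, 1), seed=rep)
            m = tt.simulate_counts(cfg, design)
            pair, _ = tt.select_housekeepers(m, ["HK1", "HK2", "HK3"])
            wins += set(pair) == {"HK1", "HK2"}
        assert wins / n_rep >= 0.9


class TestHousekeeperNormalize:
    def test_geomean_divisor(self):
        m = toy_matrix({"X": [6.0], "H1": [5.0], "H2": [5.0],
                        "GAPDH": [4.0], "S6": [9.0], "iso": [1.0]})
        out = tt.housekeeper_normalize(m)
        # geomean(4, 9) = 6
        assert out.meta["housekeeper_factor"].iloc[0] == pytest.approx(6.0)
        assert out.counts["X"].iloc[0] == pytest.approx(1.0)

    def test_marker_equal_to_geomean_normalizes_to_one(self):
        rng = np.random.default_rng(3)
        g, s = rng.uniform(2, 50, 10), rng.uniform(2, 50, 10)
        m = toy_matrix({"X": np.sqrt(g * s), "H1": [5.0] * 10, "H2": [5.0] * 10,
                        "GAPDH": g, "S6": s, "iso": [1.0] * 10})
        out = tt.housekeeper_normalize(m)
        assert np.allclose(out.counts["X"], 1.0)

    def test_row_scale_equivariance(self):
        rng = np.random.default_rng(4)
        base = {"X": rng.uniform(5, 50, 5), "H1": [5.0] * 5, "H2": [5.0] * 5,
                "GAPDH": rng.uniform(2, 9, 5), "S6": rng.uniform(2, 9, 5),
                "iso": rng.uniform(1, 3, 5)}
        m = toy_matrix(base)
        scaled = toy_matrix({k: np.asarray(v, dtype=float) for k, v in base.items()})
        scaled.counts.iloc[2] *= 7.0
        a = tt.housekeeper_normalize(m)
        b = tt.housekeeper_normalize(scaled)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_nonpositive_housekeeper_flagged_and_dropped(self):
        m = toy_matrix({"X": [1.0, 2.0], "H1": [5.0] * 2, "H2": [5.0] * 2,
                        "GAPDH": [0.0, 4.0], "S6": [9.0, 9.0], "iso": [1.0] * 2})
        out = tt.housekeeper_normalize(m)
        assert list(out.aoi_ids) == ["A1"]
        assert "A0" in set(out.qc_log["aoi_id"])

    def test_background_nuclei_correlation_neutralized(self):
        """|r|(isotype, nuclei) drops from > 0.5 to < 0.2 after normalization."""
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = tt.DSPSimConfig(background_slope=1.0, seed=rep)
            design = tt.make_design(50, rois_per_patient=(1, 1), seed=rep)  # 100 AOIs
            m = tt.simulate_counts(cfg, design)
            pre, _ = pearsonr(m.counts["msIgG1"], m.meta["nuclei_count"])
            norm = tt.housekeeper_normalize(m)
            post, _ = pearsonr(norm.counts["msIgG1"], norm.meta["nuclei_count"])
            wins += (abs(pre) > 0.5) and (abs(post) < 0.2)
        assert wins / n_rep >= 0.9


def test_pipeline_order_runs_end_to_end():
    cfg = tt.DSPSimConfig(seed=6, lane_sd=0.2)
    design = tt.make_design(20, seed=6)
    m = tt.simulate_counts(cfg, design)
    tumor, immune = tt.normalize_pipeline(m)
    assert "housekeeper_factor" in tumor.meta.columns
    assert set(tumor.meta["segment"]) <= {"tumor"}
    assert set(immune.meta["segment"]) <= {"immune"}
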