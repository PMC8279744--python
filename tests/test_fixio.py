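"""Fixation parsing, AOI assignment, and the 1-ms binning oracle."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazecourse.fixio import (
    ALL_LABELS,
    FormatError,
    assign_aoi,
    bin_experiment,
    expand_and_bin,
    read_fixation_report,
    write_fixation_report,
)


def brute_force_bins(fixes, noun_onset, window=(-2000, 1000), bin_ms=100):
    """Literal 1-ms indicator oracle: materialize one sample per ms relative
    to noun onset, label it by the covering fixation (or elsewhere), then
    average each 100-ms stretch."""
    w0, w1 = window
    labels = np.full(w1 - w0, 4)  # elsewhere
    covered = np.zeros(w1 - w0, dtype=bool)
    for start, end, aoi in fixes:
        for k, w in enumerate(range(w0, w1)):
            if start - noun_onset <= w < end - noun_onset:
                labels[k] = ALL_LABELS.index(aoi)
                covered[k] = True
    n_bins = (w1 - w0) // bin_ms
    rows = []
    for b in range(n_bins):
        seg = labels[b * bin_ms : (b + 1) * bin_ms]
        cov = covered[b * bin_ms : (b + 1) * bin_ms]
        rows.append(
            {
                **{f"p_{name}": (seg == i).mean() for i, name in enumerate(ALL_LABELS[:4])},
                "p_elsewhere": (seg == 4).mean(),
                "n_valid": int(cov.sum()),
            }
        )
    return pd.DataFrame(rows)


def random_trial(rng, n_fix=6, window=(-2000, 1000)):
    """Random non-overlapping fixations around a random noun onset; float
    times exercise the sub-millisecond edge handling."""
    noun = rng.uniform(2500, 3500)
    t = rng.uniform(0, 800)
    rows = []
    for _ in range(n_fix):
        t += rng.uniform(0, 150)  # gap
        dur = rng.uniform(30, 600)
        rows.append((t, t + dur, ALL_LABELS[rng.integers(0, 5)]))
        t += dur
    df = pd.DataFrame(rows, columns=["fix_start", "fix_end", "aoi"])
    return df, noun


class TestExpandAndBin:
    def test_full_coverage_single_bin(self):
        fx = pd.DataFrame({"fix_start": [1000.0], "fix_end": [1100.0], "aoi": ["female"]})
        out = expand_and_bin(fx, noun_onset=3000.0)
        row = out[out.bin_start == -2000].iloc[0]
        assert row.p_female == 1.0 and row.p_male == 0.0 and row.n_valid == 100

    def test_half_coverage(self):
        fx = pd.DataFrame({"fix_start": [3000.0], "fix_end": [3050.0], "aoi": ["male"]})
        out = expand_and_bin(fx, noun_onset=3000.0)
        row = out[out.bin_start == 0].iloc[0]
        assert row.p_male == 0.5 and row.n_valid == 50

    def test_no_fixations_flagged_not_raised(self):
        out = expand_and_bin(pd.DataFrame(columns=["fix_start", "fix_end", "aoi"]), 3000.0)
        assert (out.n_valid == 0).all()
        assert (out.p_elsewhere == 1.0).all()
        assert len(out) == 30

    def test_three_fixation_toy_matches_oracle(self):
        fixes = [(500.0, 900.0, "female"), (950.0, 1400.0, "object1"), (1400.0, 2600.0, "male")]
        fx = pd.DataFrame(fixes, columns=["fix_start", "fix_end", "aoi"])
        got = expand_and_bin(fx, noun_onset=2500.0)
        want = brute_force_bins(fixes, 2500.0)
        for col in ["p_female", "p_male", "p_object1", "p_object2", "p_elsewhere", "n_valid"]:
            assert np.allclose(got[col], want[col]), col

    def test_random_trials_match_oracle(self, rng):
        for _ in range(50):
            fx, noun = random_trial(rng)
            got = expand_and_bin(fx, noun)
            want = brute_force_bins(list(fx.itertuples(index=False)), noun)
            for col in ["p_female", "p_male", "p_object1", "p_object2", "p_elsewhere", "n_valid"]:
                assert np.allclose(got[col], want[col]), col

    def test_noun_shift_moves_bins_by_one(self, rng):
        fx, noun = random_trial(rng)
        a = expand_and_bin(fx, noun)
        b = expand_and_bin(fx, noun + 100.0)
        # moving the reference 100 ms later shifts trial content one bin
        # earlier: bin k of the shifted series holds bin k+1 of the original
        assert np.allclose(a.p_female.to_numpy()[1:], b.p_female.to_numpy()[:-1])

    def test_conservation_for_fully_tracked_trial(self):
        fx = pd.DataFrame({"fix_start": [0.0], "fix_end": [7000.0], "aoi": ["object2"]})
        out = expand_and_bin(fx, noun_onset=3000.0)
        assert out.n_valid.sum() == 3000
        assert np.allclose(out.p_object2, 1.0)

    def test_bad_window_raises(self):
        with pytest.raises(ValueError, match="multiples"):
            expand_and_bin(pd.DataFrame(columns=["fix_start", "fix_end", "aoi"]),
                           0.0, window=(-2000, 1000), bin_ms=130)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        fx, noun = random_trial(rng, n_fix=4, window=(-300, 300))
        got = expand_and_bin(fx, noun, window=(-300, 300))
        want = brute_force_bins(list(fx.itertuples(index=False)), noun, window=(-300, 300))
        assert np.allclose(got[[f"p_{n}" for n in ALL_LABELS]], want[[f"p_{n}" for n in ALL_LABELS]])


class TestBinExperiment:
    def test_matches_per_trial_binning(self, small_experiment):
        fixations, meta = small_experiment["fixations"], small_experiment["meta"]
        allbins = bin_experiment(fixations, meta)
        trial = meta[meta.trial_type == "experimental"].iloc[5]
        one = fixations[
            (fixations.participant == trial.participant) & (fixations.trial_id == trial.trial_id)
        ]
        single = expand_and_bin(one, trial.noun_onset)
        sub = allbins[
            (allbins.participant == trial.participant) & (allbins.trial_id == trial.trial_id)
        ].reset_index(drop=True)
        assert np.allclose(sub.p_female, single.p_female)
        assert np.allclose(sub.n_valid, single.n_valid)

    def test_produces_thirty_bins_per_trial(self, small_experiment):
        bins = bin_experiment(small_experiment["fixations"], small_experiment["meta"])
        assert (bins.groupby(["participant", "trial_id"]).size() == 30).all()
        assert bins.bin_start.min() == -2000 and bins.bin_start.max() == 900


class TestReadFixationReport:
    def test_round_trips_simulator_output(self, small_experiment, tmp_path):
        path = tmp_path / "fix.tsv"
        write_fixation_report(small_experiment["fixations"], path)
        back = read_fixation_report(path)
        pd.testing.assert_frame_equal(back, small_experiment["fixations"])

    def test_well_formed_rows_parse(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(
            "participant\ttrial_id\tfix_start\tfix_end\taoi\n"
            "1\t1\t0\t120\tfemale\n1\t1\t120\t300\tmale\n1\t2\t10\t50\tobject1\n"
        )
        assert len(read_fixation_report(path)) == 3

    def test_invalid_rows_dropped_and_logged(self, tmp_path, caplog):
        path = tmp_path / "f.tsv"
        path.write_text(
            "participant\ttrial_id\tfix_start\tfix_end\taoi\n"
            "1\t1\t100\t50\tfemale\n"  # end <= start
            "1\t1\tx\t50\tfemale\n"  # non-numeric
            "1\t1\t0\t50\tfemale\n"
        )
        with caplog.at_level("WARNING"):
            out = read_fixation_report(path)
        assert len(out) == 1
        assert sum("invalid fixation" in r.message for r in caplog.records) == 2

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("participant\ttrial_id\tfix_start\n1\t1\t0\n")
        with pytest.raises(FormatError, match="fix_end"):
            read_fixation_report(path)


class TestAssignAoi:
    RECTS = pd.DataFrame(
        {
            "aoi_name": ["female", "male"],
            "x0": [0, 100],
            "y0": [0, 0],
            "x1": [100, 200],
            "y1": [100, 100],
        }
    )

    def test_interior_point(self):
        assert assign_aoi(50, 50, self.RECTS) == "female"

    def test_outside_all_is_elsewhere(self):
        assert assign_aoi(500, 500, self.RECTS) == "elsewhere"

    def test_shared_edge_goes_to_exactly_one(self):
        assert assign_aoi(100, 50, self.RECTS) == "male"

    def test_overlap_strict_raises_lenient_prioritizes(self):
        rects = self.RECTS.copy()
        rects.loc[1, "x0"] = 50
        with pytest.raises(ValueError, match="multiple"):
            assign_aoi(75, 50, rects, strict=True)
        assert assign_aoi(75, 50, rects, strict=False) == "female"
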