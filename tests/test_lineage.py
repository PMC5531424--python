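"""Dynamic-phenotype summaries, inheritance estimation, rate recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scfate import (
    CycleLaw,
    MorphologyTrack,
    PedigreeSimConfig,
    classify_phenotypes,
    cycle_length_stats,
    estimate_switch_rates,
    simulate_pedigrees,
    sister_similarity,
    summarize_cell,
    summarize_pedigrees,
    transition_frequencies,
)
from scfate.reference import founder_division_times, founder_pedigrees

from conftest import make_pedigree, make_track


class TestSummarizeCell:
    def test_stable_polarised_cell(self):
        track = make_track("c", [(0, 20, "polarised")])
        s = summarize_cell(track)
        assert s.roundness == 0.0
        assert s.switch_freq == 0.0
        assert s.cycle_length == pytest.approx(20.0)

    def test_hand_computed_mixed_track(self):
        track = make_track(
            "c", [(0, 10, "polarised"), (10, 15, "round"), (15, 20, "polarised")]
        )
        s = summarize_cell(track)
        assert s.roundness == pytest.approx(0.25)
        assert s.switch_freq == pytest.approx(2 / 20)

    def test_censored_cell_has_no_cycle_length(self):
        track = make_track("c", [(0, 12, "round")], end_event="censored")
        s = summarize_cell(track)
        assert s.cycle_length is None
        assert s.censored
        assert s.roundness == 1.0

    def test_non_contiguous_track_rejected(self):
        track = MorphologyTrack(
            "c", [(0, 5, "round"), (7, 10, "polarised")], 0, 10, "division"
        )
        with pytest.raises(ValueError, match="non-contiguous"):
            summarize_cell(track)

    @given(
        cut=st.floats(min_value=0.5, max_value=9.5),
        shift=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_split_and_shift_invariance(self, cut, shift):
        """Splitting a same-shape interval or shifting all timestamps
        changes nothing after normalisation."""
        base = make_track("c", [(0, 10, "polarised"), (10, 16, "round")])
        split = make_track(
            "c", [(0, cut, "polarised"), (cut, 10, "polarised"), (10, 16, "round")]
        ) if cut < 10 else base
        shifted = make_track(
            "c", [(shift, 10 + shift, "polarised"), (10 + shift, 16 + shift, "round")]
        )
        ref = summarize_cell(base)
        for other in (split, shifted):
            s = summarize_cell(other)
            assert s.roundness == pytest.approx(ref.roundness)
            assert s.switch_freq == pytest.approx(ref.switch_freq)
            assert s.cycle_length == pytest.approx(ref.cycle_length)

    def test_founder_trim_option(self):
        track = make_track("c", [(0, 3, "round"), (3, 13, "polarised")])
        untrimmed = summarize_cell(track)
        trimmed = summarize_cell(track, trim_first_hours=3.0)
        assert untrimmed.roundness == pytest.approx(3 / 13)
        assert trimmed.roundness == 0.0
        assert trimmed.switch_freq == 0.0


class TestClassifyPhenotypes:
    def archetype_frame(self, n=10):
        rows = []
        rng = np.random.default_rng(0)
        for label, (rd, sw) in {
            "P": (0.05, 0.02), "R": (0.95, 0.02), "S": (0.5, 0.5)
        }.items():
            for i in range(n):
                rows.append(
                    {
                        "cell_id": f"{label}{i}",
                        "roundness": np.clip(rd + 0.02 * rng.standard_normal(), 0, 1),
                        "switch_freq": abs(sw + 0.01 * rng.standard_normal()),
                        "truth": label,
                    }
                )
        return pd.DataFrame(rows).set_index("cell_id")

    def test_archetypes_recovered_exactly(self):
        frame = self.archetype_frame()
        labels = classify_phenotypes(frame, seed=0)
        assert (labels == frame["truth"]).all()

    def test_identical_cells_refused(self):
        frame = pd.DataFrame(
            {"roundness": [0.5] * 8, "switch_freq": [0.1] * 8},
            index=[f"c{i}" for i in range(8)],
        )
        with pytest.raises(ValueError, match="degenerate"):
            classify_phenotypes(frame)

    def test_too_few_cells_refused(self):
        frame = self.archetype_frame(n=1)
        with pytest.raises(ValueError, match="6 cells"):
            classify_phenotypes(frame.iloc[:3])

    def test_threshold_mode(self):
        frame = self.archetype_frame()
        labels = classify_phenotypes(frame, method="thresholds")
        assert (labels == frame["truth"]).all()

    def test_simulated_recovery_accuracy(self, default_pedigrees):
        """Label accuracy >= 90% against generator truth at default rates."""
        peds, truth = default_pedigrees
        summaries = summarize_pedigrees(peds)
        labels = classify_phenotypes(summaries, seed=0)
        truth_labels = pd.Series(truth.cell_phenotypes).reindex(labels.index)
        assert (labels == truth_labels).mean() >= 0.90


class TestTransitionFrequencies:
    def test_round_row_exact_closure(self, default_pedigrees):
        peds, truth = default_pedigrees
        tm = transition_frequencies(peds, pd.Series(truth.cell_phenotypes))
        assert tm.frequencies.loc["R"].tolist() == [0.0, 0.0, 1.0]

    def test_switcher_conservation_near_quarter(self, default_pedigrees):
        peds, truth = default_pedigrees
        tm = transition_frequencies(peds, pd.Series(truth.cell_phenotypes))
        assert tm.counts.loc["S"].sum() >= 400
        assert abs(tm.frequencies.loc["S", "S"] - 0.25) <= 0.05

    def test_row_consistency_against_generator(self, default_pedigrees):
        """Max row-wise |estimated - generating| <= 0.05 at >= 400 edges/row."""
        peds, truth = default_pedigrees
        tm = transition_frequencies(peds, pd.Series(truth.cell_phenotypes))
        gen = pd.DataFrame(
            truth.inheritance, index=tm.frequencies.index, columns=tm.frequencies.columns
        )
        rows = tm.counts.sum(axis=1)
        err = (tm.frequencies - gen).abs().max(axis=1)
        assert (err[rows >= 400] <= 0.05).all()

    def test_founder_only_clone_has_no_data(self):
        ped = make_pedigree(
            "solo", [("solo.1", None, 1, 0.0, 50.0, "censored", None)]
        )
        tm = transition_frequencies([ped], pd.Series({"solo.1": "P"}))
        assert tm.counts.to_numpy().sum() == 0
        assert set(tm.no_data_rows) == {"P", "S", "R"}

    def test_orphan_non_founder_rejected(self):
        ped = make_pedigree(
            "bad",
            [
                ("bad.1", None, 1, 0.0, 50.0, "division", None),
                ("bad.1.1", "ghost", 2, 50.0, 70.0, "division", None),
            ],
        )
        with pytest.raises(ValueError, match="unknown"):
            transition_frequencies([ped], pd.Series({"bad.1": "P", "bad.1.1": "P"}))

    def test_classified_pipeline_respects_closure(self, default_pedigrees):
        """classify -> transition never yields a P/S daughter of an R mother
        on data generated with the closure constraint."""
        peds, _ = default_pedigrees
        summaries = summarize_pedigrees(peds)
        labels = classify_phenotypes(summaries, seed=0)
        tm = transition_frequencies(peds, labels)
        assert tm.counts.loc["R", ["P", "S"]].sum() == 0


class TestSisterSimilarity:
    def make_pair_pedigrees(self, specs):
        """specs: list of ((roundness profile a), (profile b)) archetypes."""
        peds = []
        for i, (a, b) in enumerate(specs):
            clone = f"cl{i}"
            records = [(f"{clone}.1", None, 1, 0.0, 50.0, "division", None)]
            for j, intervals in ((1, a), (2, b)):
                cid = f"{clone}.1.{j}"
                records.append(
                    (cid, f"{clone}.1", 2, 50.0, 70.0, "division",
                     make_track(cid, intervals))
                )
            peds.append(make_pedigree(clone, records))
        return peds

    def polarised(self):
        return [(50.0, 70.0, "polarised")]

    def round_(self):
        return [(50.0, 70.0, "round")]

    def switchy(self, rng):
        times = np.sort(rng.uniform(50.5, 69.5, size=8))
        bounds = [50.0, *times, 70.0]
        shapes = ["polarised", "round"] * 5
        return [(a, b, s) for a, b, s in zip(bounds[:-1], bounds[1:], shapes)]

    def test_duplicate_sisters_similar_and_archetypes_divergent(self):
        rng = np.random.default_rng(0)
        specs = [(self.polarised(), self.polarised()) for _ in range(3)]
        specs += [(self.round_(), self.round_()) for _ in range(3)]
        specs += [(self.polarised(), self.round_()) for _ in range(3)]
        specs += [(self.switchy(rng), self.polarised())]
        peds = self.make_pair_pedigrees(specs)
        summaries = summarize_pedigrees(peds)
        pairs = sister_similarity(peds, summaries, seed=0)
        dup = pairs[pairs["clone_id"].isin([f"cl{i}" for i in range(6)])]
        assert (dup["distance"] < 1e-9).all()
        assert (dup["class"] == "similar").all()
        div = pairs[pairs["clone_id"].isin(["cl6", "cl7", "cl8"])]
        assert (div["class"] == "divergent").all()

    def test_censored_pairs_excluded_with_warning(self):
        specs = [(self.polarised(), self.polarised()) for _ in range(5)]
        peds = self.make_pair_pedigrees(specs)
        # censor one daughter
        cell = peds[0].cells["cl0.1.1"]
        cell.end_event = "censored"
        cell.track.end_event = "censored"
        summaries = summarize_pedigrees(peds)
        with pytest.warns(UserWarning, match="censored"):
            pairs = sister_similarity(peds, summaries, seed=0)
        assert "cl0" not in set(pairs["clone_id"])

    def test_divergent_pairs_ride_on_high_switch_frequency(self, default_pedigrees):
        """Divergent sisters show higher mean switch frequency than similar."""
        peds, _ = default_pedigrees
        summaries = summarize_pedigrees(peds)
        pairs = sister_similarity(peds, summaries, seed=0)
        merged = pairs.assign(
            max_switch=[
                summaries.loc[[a, b], "switch_freq"].max()
                for a, b in zip(pairs["cell_a"], pairs["cell_b"])
            ]
        )
        grouped = merged.groupby("class")["max_switch"].mean()
        assert grouped["divergent"] > grouped["similar"]


class TestSwitchRates:
    def test_single_track_mle_by_hand(self):
        track = make_track("c", [(0, 10, "polarised"), (10, 20, "round")])
        rates = estimate_switch_rates({"g": [track]})
        assert rates.loc["g", "rate_PR"] == pytest.approx(0.1)
        assert rates.loc["g", "rate_RP"] == pytest.approx(0.0)

    def test_no_transitions_gives_zero_rates(self):
        track = make_track("c", [(0, 30, "polarised")])
        rates = estimate_switch_rates({"g": [track]})
        assert rates.loc["g", "rate_PR"] == 0.0
        assert np.isnan(rates.loc["g", "rate_RP"])  # never round: undefined

    def test_recovery_within_ten_percent(self):
        """200 cells x 20 h at (0.3, 0.3)/h: MLE within 10% relative error."""
        config = PedigreeSimConfig(
            n_clones=200,
            max_generations=1,
            first_cycle_law=CycleLaw("lognormal", median=20.0, sigma_log=0.0),
            observation_end=21.0,
            switch_rates={"P": (0.01, 0.5), "S": (0.3, 0.3), "R": (0, 0)},
            initial_phenotype_dist=(0.0, 1.0, 0.0),
            seed=12,
        )
        peds, _ = simulate_pedigrees(config)
        tracks = [p.founder.track for p in peds]
        rates = estimate_switch_rates({"S": tracks})
        assert abs(rates.loc["S", "rate_PR"] - 0.3) / 0.3 < 0.10
        assert abs(rates.loc["S", "rate_RP"] - 0.3) / 0.3 < 0.10
        # reported standard errors are coherent with the MLE formula
        assert rates.loc["S", "se_PR"] == pytest.approx(
            rates.loc["S", "rate_PR"] / np.sqrt(rates.loc["S", "n_PR"])
        )


class TestCycleLengthStats:
    def test_reference_founder_cohort_summary(self):
        """The 32-founder cohort reproduces the printed division statistics."""
        stats = cycle_length_stats(founder_pedigrees())
        assert stats.loc[1, "n"] == 32
        assert stats.loc[1, "median"] == pytest.approx(58.0)
        assert stats.loc[1, "min"] >= 35.0
        assert stats.loc[1, "max"] <= 80.0
        times = np.array(founder_division_times())
        assert (times <= 48.0).sum() == 11
        assert (times > 72.0).sum() == 3

    def test_all_censored_warns_and_returns_empty(self):
        ped = make_pedigree(
            "c", [("c.1", None, 1, 0.0, 50.0, "censored", None)]
        )
        with pytest.warns(UserWarning, match="censored"):
            stats = cycle_length_stats([ped])
        assert stats.empty

    def test_per_generation_structure(self, default_pedigrees):
        peds, _ = default_pedigrees
        stats = cycle_length_stats(peds)
        assert list(stats.index) == [1, 2, 3]
        assert stats.loc[1, "median"] > stats.loc[2, "median"]
        assert (stats["q1"] <= stats["median"]).all()
        assert (stats["median"] <= stats["q3"]).all()
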