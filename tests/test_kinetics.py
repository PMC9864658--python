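"""Dwell bookkeeping, exponential fits, rate tables, TDP/TODP summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smfretkin.hmm import IdealizedPath
from smfretkin.kinetics import (
    DwellRecord,
    TooFewDwellsError,
    TransitionRecord,
    build_rate_table,
    build_tdp,
    build_todp,
    extract_dwells,
    fit_exponential,
    state_histogram,
)

DT = 0.05


def path_from_labels(labels, trace_id="t", dt=DT, label_map=("N", "C", "E", "F")):
    idx = {l: i for i, l in enumerate(label_map)}
    states = np.array([idx[l] for l in labels], dtype=np.int32)
    return IdealizedPath(
        trace_id=trace_id,
        states=states,
        frame_period=dt,
        log_likelihood=0.0,
        state_labels={i: l for l, i in idx.items()},
        segments=[(0, len(states))],
    )


class TestExtractDwells:
    def test_direct_construction_with_censoring_flags(self):
        path = path_from_labels(["N"] * 10 + ["C"] * 4 + ["N"] * 8)
        dwells, transitions = extract_dwells(path, min_frames=2)
        assert [(d.state_label, d.duration) for d in dwells] == [
            ("N", pytest.approx(0.5)),
            ("C", pytest.approx(0.2)),
            ("N", pytest.approx(0.4)),
        ]
        assert dwells[0].censored_left and not dwells[0].censored_right
        assert not dwells[1].censored_left and not dwells[1].censored_right
        assert dwells[2].censored_right
        assert [(t.from_label, t.to_label) for t in transitions] == [
            ("N", "C"), ("C", "N")
        ]
        assert transitions[0].frame == 10

    def test_single_frame_blip_removed_and_neighbors_merged(self):
        path = path_from_labels(["N"] * 10 + ["C"] + ["N"] * 10)
        dwells, transitions = extract_dwells(path, min_frames=2)
        assert len(dwells) == 1 and transitions == []
        assert dwells[0].n_frames == 21  # merged span includes the blip

    def test_blip_between_different_neighbors_leaves_censoring_gap(self):
        path = path_from_labels(["N"] * 10 + ["C"] + ["E"] * 10)
        dwells, transitions = extract_dwells(path, min_frames=2)
        assert [d.state_label for d in dwells] == ["N", "E"]
        assert dwells[0].censored_right and dwells[1].censored_left
        assert transitions == []

    def test_empty_path_yields_empty_outputs(self):
        path = IdealizedPath("t", np.full(10, -1, np.int32), DT, 0.0,
                             state_labels={}, segments=[])
        assert extract_dwells(path) == ([], [])

    @given(st.lists(st.sampled_from("NC"), min_size=1, max_size=60))
    def test_min_frames_one_is_identity(self, labels):
        path = path_from_labels(labels)
        dwells, _ = extract_dwells(path, min_frames=1)
        assert sum(d.n_frames for d in dwells) == len(labels)
        rebuilt = []
        for d in dwells:
            rebuilt.extend([d.state_label] * d.n_frames)
        assert rebuilt == list(labels)

    @given(st.lists(st.sampled_from("NCE"), min_size=1, max_size=60),
           st.integers(1, 4))
    def test_time_budget_conserved_exactly(self, labels, min_frames):
        path = path_from_labels(labels)
        dwells, _ = extract_dwells(path, min_frames=min_frames)
        kept = sum(d.n_frames for d in dwells)
        assert kept <= len(labels)
        # removed time = blips whose neighbors disagreed (or whole segment)
        removed = len(labels) - kept
        assert removed >= 0
        assert kept * DT == pytest.approx(sum(d.duration for d in dwells))

    def test_segment_edges_censor_dwells(self):
        path = path_from_labels(["N"] * 20 + ["C"] * 20)
        path.segments = [(0, 20), (20, 40)]
        dwells, transitions = extract_dwells(path, min_frames=2)
        assert all(d.censored_left and d.censored_right for d in dwells)
        assert transitions == []  # the switch sits on a segment boundary


def make_dwells(durations, state="C", trace_ids=None, dt=DT):
    out = []
    for i, dur in enumerate(durations):
        tid = trace_ids[i] if trace_ids else f"m{i}"
        n = max(int(round(dur / dt)), 1)
        out.append(DwellRecord(tid, state, 0, n, n * dt, "F", "F", False, False))
    return out


class TestFitExponential:
    def test_mle_is_reciprocal_mean(self):
        fit = fit_exponential(make_dwells([1.0, 1.0, 1.0]), min_dwells=3,
                              bootstrap_n=0)
        assert fit.k == pytest.approx(1.0)

    @given(st.lists(st.floats(0.05, 30.0), min_size=10, max_size=40))
    def test_mle_equals_reciprocal_mean_to_machine_precision(self, durations):
        dwells = []
        for i, dur in enumerate(durations):
            dwells.append(DwellRecord(f"m{i}", "C", 0, 1, dur, "F", "F", False, False))
        fit = fit_exponential(dwells, bootstrap_n=0)
        assert fit.k == pytest.approx(1.0 / np.mean(durations), rel=1e-14)

    def test_large_sample_recovers_rate(self, rng):
        durations = rng.exponential(1 / 2.0, 10_000)
        fit = fit_exponential(make_dwells(durations, dt=1e-4), bootstrap_n=0)
        assert fit.k == pytest.approx(2.0, abs=0.05)

    def test_histogram_fit_agrees_with_mle_on_large_sample(self, rng):
        durations = rng.exponential(1 / 1.5, 5_000)
        dwells = make_dwells(durations, dt=1e-4)
        k_hist = fit_exponential(dwells, method="histogram_lsq", bootstrap_n=0).k
        assert k_hist == pytest.approx(1.5, rel=0.1)

    def test_too_few_dwells_raises(self):
        with pytest.raises(TooFewDwellsError, match="5"):
            fit_exponential(make_dwells([1.0] * 5), min_dwells=10)

    def test_censored_dwells_do_not_enter_the_fit(self):
        dwells = make_dwells([1.0] * 10)
        dwells.append(DwellRecord("mX", "C", 0, 2000, 100.0, None, None, True, True))
        fit = fit_exponential(dwells, min_dwells=10, bootstrap_n=0)
        assert fit.k == pytest.approx(1.0)
        assert fit.n == 10

    def test_bootstrap_ci_brackets_truth(self, rng):
        durations = rng.exponential(1 / 3.0, 500)
        ids = [f"m{i % 40}" for i in range(500)]
        fit = fit_exponential(make_dwells(durations, trace_ids=ids, dt=1e-4),
                              bootstrap_n=100)
        lo, hi = fit.ci95
        assert lo < 3.0 < hi


class TestRateTable:
    def test_deterministic_alternation_gives_unit_rates(self):
        labels = (["A"] * 20 + ["B"] * 20) * 25
        path = path_from_labels(labels, label_map=("A", "B"))
        dwells, transitions = extract_dwells(path, min_frames=2)
        table = build_rate_table(dwells, transitions, min_molecules=1,
                                 correct_discretization=False, bootstrap_n=0)
        assert table.rate("A", "B") == pytest.approx(1.0)
        assert table.rate("B", "A") == pytest.approx(1.0)

    def test_sparse_pair_excluded_with_reason(self):
        dwells, transitions = [], []
        for m in range(30):
            path = path_from_labels((["N"] * 10 + ["C"] * 10) * 4, trace_id=f"m{m}")
            d, t = extract_dwells(path, min_frames=2)
            dwells.extend(d)
            transitions.extend(t)
        # a rare class seen in only 3 molecules
        for m in range(3):
            path = path_from_labels(["C"] * 10 + ["E"] * 10 + ["C"] * 10,
                                    trace_id=f"r{m}")
            d, t = extract_dwells(path, min_frames=2)
            dwells.extend(d)
            transitions.extend(t)
        table = build_rate_table(dwells, transitions, min_molecules=20,
                                 bootstrap_n=0)
        assert not table.entries[("N", "C")].excluded
        rare = table.entries[("C", "E")]
        assert rare.excluded and "3 molecules" in rare.reason
        with pytest.raises(KeyError):
            table.rate("C", "E")

    def test_geometric_correction_recovers_fast_sampled_chain(self, rng):
        # sampled two-state chain at 20 Hz with k_AB near the frame rate
        k_ab, k_ba, dt = 6.0, 1.5, 0.05
        p_stay_a, p_stay_b = np.exp(-k_ab * dt), np.exp(-k_ba * dt)
        dwells, transitions = [], []
        for m in range(200):
            s, labels = 0, []
            for _ in range(600):
                labels.append("AB"[s])
                stay = p_stay_a if s == 0 else p_stay_b
                if rng.random() > stay:
                    s = 1 - s
            path = path_from_labels(labels, trace_id=f"m{m}", label_map=("A", "B"))
            d, t = extract_dwells(path, min_frames=1)
            dwells.extend(d)
            transitions.extend(t)
        table = build_rate_table(dwells, transitions, min_molecules=1,
                                 dead_frames=1, bootstrap_n=0)
        assert table.rate("A", "B") == pytest.approx(k_ab, rel=0.05)
        assert table.rate("B", "A") == pytest.approx(k_ba, rel=0.05)


class TestTransitionMaps:
    def tr(self, frm, to, e1, e2, tid="m0"):
        return TransitionRecord(tid, frm, to, 0, e1, e2)

    def test_identical_transitions_fill_single_normalized_bin(self):
        tdp = build_tdp([self.tr("F", "C", 0.47, 0.58)] * 3, bin_width=0.02)
        assert tdp.n_transitions == 3
        assert tdp.matrix.sum() == pytest.approx(1.0)
        assert tdp.matrix.max() == pytest.approx(1.0)
        i, j = np.unravel_index(tdp.matrix.argmax(), tdp.matrix.shape)
        assert tdp.edges[i] == pytest.approx(0.47, abs=0.021)
        assert tdp.edges[j] == pytest.approx(0.58, abs=0.021)

    def test_reversed_records_transpose_the_map(self):
        fwd = [self.tr("F", "C", 0.47, 0.58), self.tr("F", "E", 0.47, 0.12)]
        rev = [self.tr("C", "F", 0.58, 0.47), self.tr("E", "F", 0.12, 0.47)]
        np.testing.assert_allclose(
            build_tdp(fwd).matrix, build_tdp(rev).matrix.T
        )

    def test_diagonal_is_empty(self):
        trs = [self.tr("F", "C", 0.47, 0.58), self.tr("C", "F", 0.58, 0.47)]
        tdp = build_tdp(trs, bin_width=0.02)
        assert np.trace(tdp.matrix) == 0.0

    def test_todp_counts_each_molecule_once_per_class(self):
        trs = [self.tr("F", "C", 0.47, 0.58, "A")] * 5
        trs += [self.tr("C", "F", 0.58, 0.47, "B")]
        todp = build_todp(trs, n_molecules_total=2)
        assert todp.classes[("C", "F")] == (2, 1.0)
        assert todp.matrix.max() == pytest.approx(1.0)

    def test_molecule_in_two_classes_contributes_to_both(self):
        trs = [
            self.tr("F", "C", 0.47, 0.58, "A"),
            self.tr("F", "E", 0.47, 0.12, "A"),
            self.tr("F", "C", 0.47, 0.58, "B"),
        ]
        todp = build_todp(trs, n_molecules_total=4)
        assert todp.classes[("C", "F")] == (2, 0.5)
        assert todp.classes[("E", "F")] == (1, 0.25)

    def test_todp_fractions_recover_population_composition(self, rng):
        # 60% of molecules show F<->C, 50% F<->E, independently
        trs = []
        n_fc = n_fe = 0
        for m in range(400):
            if rng.random() < 0.6:
                n_fc += 1
                for _ in range(rng.integers(1, 6)):
                    trs.append(self.tr("F", "C", 0.47, 0.58, f"m{m}"))
            if rng.random() < 0.5:
                n_fe += 1
                trs.append(self.tr("F", "E", 0.47, 0.12, f"m{m}"))
        todp = build_todp(trs, n_molecules_total=400)
        assert todp.classes[("C", "F")] == (n_fc, n_fc / 400)
        assert abs(todp.classes[("C", "F")][1] - 0.6) < 1.96 * np.sqrt(0.6 * 0.4 / 400) + 0.01
        assert todp.classes[("E", "F")] == (n_fe, n_fe / 400)

    def test_todp_weights_stay_in_unit_interval(self, rng):
        trs = [self.tr("F", "C", 0.47, 0.58, f"m{i}") for i in range(10)]
        todp = build_todp(trs, n_molecules_total=10)
        assert np.all(todp.matrix >= 0) and np.all(todp.matrix <= 1)


class TestStateHistogram:
    def test_labeled_values_report_group_gaussians(self, rng):
        vals = np.concatenate([rng.normal(0.47, 0.05, 4000),
                               rng.normal(0.12, 0.05, 1000)])
        labels = np.array(["F"] * 4000 + ["E"] * 1000)
        hist = state_histogram(vals, labels=labels, bins=60)
        assert hist.peaks["F"][0] == pytest.approx(0.47, abs=0.01)
        assert hist.peaks["E"][0] == pytest.approx(0.12, abs=0.01)
        assert hist.counts.sum() == 5000

    def test_two_noiseless_levels_fill_two_bins(self):
        vals = np.array([0.2] * 50 + [0.8] * 30)
        hist = state_histogram(vals, bins=np.linspace(0, 1, 51))
        assert (hist.counts > 0).sum() == 2
        assert sorted(hist.counts[hist.counts > 0]) == [30, 50]

    def test_unlabeled_mixture_fit_finds_peaks(self, rng):
        vals = np.concatenate([rng.normal(0.25, 0.04, 3000),
                               rng.normal(0.6, 0.04, 3000)])
        hist = state_histogram(vals, k=2, bins=50)
        mus = sorted(m for m, _ in hist.peaks.values())
        assert mus[0] == pytest.approx(0.25, abs=0.02)
        assert mus[1] == pytest.approx(0.6, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            state_histogram(np.array([np.nan]))
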