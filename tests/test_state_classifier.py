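import numpy as np
import pytest

from bpfray.errors import ValidationError
from bpfray.io_formats import read_segments, write_segments
from bpfray.state_classifier import (
    CLOSED,
    OPEN,
    TRANSITION,
    StateDefinition,
    classify,
    label_frames,
    resolve_unassigned,
    segment,
    summarize,
)
from bpfray.synthetic import reference_markov_config, simulate_markov

from conftest import codes, make_series, series_from_labels

DEFS = StateDefinition()


class TestLabelFrames:
    @pytest.mark.parametrize(
        "rmsd, zeta, expected",
        [
            (0.7, -75.0, CLOSED),
            (5.0, 50.0, OPEN),
            (3.0, -75.0, TRANSITION),
            (0.5, 150.0, 3),  # outside both windows -> unassigned
        ],
    )
    def test_archetypes(self, rmsd, zeta, expected):
        series = make_series([rmsd, rmsd], [zeta, zeta])
        assert label_frames(series, DEFS)[0] == expected

    def test_labeling_is_total(self):
        rng = np.random.default_rng(0)
        series = make_series(rng.uniform(0, 15, 500), rng.uniform(-179, 180, 500))
        labels = label_frames(series, DEFS)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}

    def test_window_validation(self):
        with pytest.raises(ValidationError):
            StateDefinition(zeta_closed_window=(-100.0, 10.0))  # overlaps open window
        with pytest.raises(ValidationError):
            StateDefinition(rmsd_closed_max=3.0)  # exceeds open range low edge


class TestResolveUnassigned:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ("CUC", "CCC"),
            ("CUO", "CCO"),  # tie goes to the preceding frame's label
            ("UUO", "OOO"),  # leading run takes the nearest assigned label
            ("CUUUUO", "CCCOOO"),  # split by distance to nearest assigned frame
        ],
    )
    def test_nearest_assignment(self, labels, expected):
        got = resolve_unassigned(codes(labels))
        np.testing.assert_array_equal(got, codes(expected))

    def test_all_unassigned_rejected(self):
        with pytest.raises(ValidationError):
            resolve_unassigned(codes("UUU"))


class TestSegment:
    def test_eleven_frame_toy(self):
        # hand-enumerated: C C T T C C O O T O O at 2 ps step; ctc of 2
        # frames inside the closed residence, oto of 1 frame inside the
        # open residence, one direct C->O crossing between frames 5 and 6
        labels = codes("CCTTCCOOTOO")
        times = 0.002 * np.arange(11)
        seg = segment(labels, times, DEFS)
        assert seg.total_time == pytest.approx(0.022)
        assert seg.n_cl == 1 and seg.n_op == 1
        [ctc] = [e for e in seg.excursions if e.subtype == "ctc"]
        [oto] = [e for e in seg.excursions if e.subtype == "oto"]
        assert ctc.duration == pytest.approx(0.004)  # 2 frames
        assert oto.duration == pytest.approx(0.002)  # 1 frame
        closed, open_ = seg.residences
        assert closed.label == "closed" and open_.label == "open"
        # boundary at the midpoint between frames 5 (C) and 6 (O)
        assert closed.end == pytest.approx(0.011)
        assert closed.duration == pytest.approx(0.012)
        assert open_.duration == pytest.approx(0.010)

    def test_all_closed(self):
        labels = codes("CCCCC")
        seg = segment(labels, 0.002 * np.arange(5), DEFS)
        assert seg.n_cl == 1 and seg.n_op == 0
        assert seg.no_crossings
        assert seg.tau_cl == pytest.approx(seg.total_time)

    def test_cto_split_at_transition_midpoint(self):
        labels = codes("CTO")
        seg = segment(labels, 0.002 * np.arange(3), DEFS)
        closed, open_ = seg.residences
        assert closed.end == pytest.approx(0.002)  # midpoint of the ts interval
        assert closed.duration == pytest.approx(open_.duration)
        [exc] = seg.excursions
        assert exc.subtype == "cto"

    def test_residences_alternate_and_tile(self):
        rng = np.random.default_rng(1)
        labels = rng.choice([CLOSED, OPEN, TRANSITION], size=2000,
                            p=[0.45, 0.45, 0.1]).astype(np.int8)
        times = 0.002 * np.arange(2000)
        seg = segment(labels, times, DEFS)
        assert abs(seg.n_cl - seg.n_op) <= 1
        for a, b in zip(seg.residences, seg.residences[1:]):
            assert a.label != b.label
            assert b.start == pytest.approx(a.end)
        assert sum(r.duration for r in seg.residences) == pytest.approx(seg.total_time)
        assert seg.tau_cl + seg.tau_op == pytest.approx(seg.total_time)

    def test_excursions_nested_in_matching_residences(self):
        rng = np.random.default_rng(2)
        labels = rng.choice([CLOSED, OPEN, TRANSITION], size=3000,
                            p=[0.45, 0.45, 0.1]).astype(np.int8)
        seg = segment(labels, 0.002 * np.arange(3000), DEFS)
        for exc in seg.excursions:
            if exc.subtype not in ("ctc", "oto"):
                continue
            want = "closed" if exc.subtype == "ctc" else "open"
            [host] = [r for r in seg.residences
                      if r.start <= exc.start and exc.end <= r.end + 1e-12]
            assert host.label == want

    def test_min_excursion_filter_monotone(self):
        rng = np.random.default_rng(3)
        labels = rng.choice([CLOSED, OPEN, TRANSITION], size=5000,
                            p=[0.42, 0.42, 0.16]).astype(np.int8)
        times = 0.002 * np.arange(5000)
        counts = []
        for m in (1, 2, 3, 5, 8):
            defs = StateDefinition(min_excursion_frames=m)
            seg = segment(labels, times, defs)
            counts.append(sum(1 for e in seg.excursions if e.subtype in ("ctc", "oto")))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSummarize:
    def test_population_identity(self):
        rng = np.random.default_rng(4)
        labels = rng.choice([CLOSED, OPEN, TRANSITION], size=4000,
                            p=[0.45, 0.45, 0.1]).astype(np.int8)
        seg = segment(labels, 0.002 * np.arange(4000), DEFS)
        summary = summarize(seg)
        for state in ("closed", "open", "ctc", "oto"):
            s = summary[state]
            if s.n == 0:
                assert s.tau_ave is None
                continue
            # p == tau_ave * N / tau: the bookkeeping of the occupancy table
            assert s.p == pytest.approx(s.tau_ave * s.n / seg.total_time, rel=1e-12)
        assert summary["closed"].p + summary["open"].p == pytest.approx(1.0)

    def test_single_residence(self):
        seg = segment(codes("CCCC"), 0.002 * np.arange(4), DEFS)
        s = summarize(seg)["closed"]
        assert s.p == pytest.approx(1.0)
        assert s.n == 1
        assert s.tau_ave == pytest.approx(seg.total_time)

    def test_round_trip_through_segments_file(self, tmp_path):
        series = series_from_labels("CCTTCCOOTOOCCOOT")
        seg = classify(series)
        p = tmp_path / "seg.tsv"
        write_segments(seg, p)
        df = read_segments(p)
        res = df[df.kind == "residence"]
        assert res["duration_ns"].sum() == pytest.approx(seg.total_time)
        by_label = res.groupby("label")["duration_ns"].agg(["sum", "count"])
        assert by_label.loc["closed", "sum"] == pytest.approx(seg.tau_cl)
        assert int(by_label.loc["closed", "count"]) == seg.n_cl


class TestHiddenStateRecovery:
    def test_classifier_recovers_generated_states(self):
        # well-separated emission windows: the raw labels should match the
        # generator's hidden states on essentially every frame
        cfg = reference_markov_config(370.0, seed=8, total_time_ns=400.0)
        series, truth = simulate_markov(cfg)
        labels = resolve_unassigned(label_frames(series, DEFS))
        assert (labels == truth).mean() > 0.99
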