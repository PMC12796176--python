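"""Population statistics: windowed ratios, peaks, survival arithmetic,
stereology, section counting and the cluster-table arithmetic."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ovoselect as ov
from ovoselect.quantify import (cluster_fraction, compute_event_frequencies,
                                compute_purple_ratio, compute_single_ratio,
                                compute_survival_ratio, engulfment_fate_stats,
                                find_peak_window, measure_growth,
                                section_count_estimate,
                                stereology_total_mitochondria, StereologyInput)
from ovoselect.track import track_and_call


# ----------------------------------------------------------------------
# single-oocyte fraction
# ----------------------------------------------------------------------

def _co_moving_pair(offset_y, base=(10.0, 20.0, 20.0), n=16):
    rng = np.random.default_rng(int(offset_y))
    rows_a, rows_b = [], []
    p = np.asarray(base)
    for f in range(n):
        u = rng.normal(size=3)
        p = p + 1.5 * u / np.linalg.norm(u)
        rows_a.append((f, *p))
        rows_b.append((f, *(p + np.array([0.0, 14.0, 0.0]))))
    return rows_a, rows_b


def _build_population(n_singles, n_pairs):
    """Synthetic tracked population: independent singles plus rigidly
    co-moving touching pairs."""
    rows = []
    oid = 0
    tid = 0
    contacts = []
    rng = np.random.default_rng(7)
    for k in range(n_singles):
        p = np.array([10.0, 40.0 + 20 * k, 150.0])
        for f in range(16):
            u = rng.normal(size=3)
            p = p + 1.5 * u / np.linalg.norm(u)
            rows.append((tid, f, oid, *p, 14.0, "oocyte", ""))
            oid += 1
        tid += 1
    for k in range(n_pairs):
        a, b = _co_moving_pair(30.0 + 40 * k, base=(10.0, 30.0 + 40 * k, 30.0))
        ta, tb = tid, tid + 1
        for (f, *pa), (_, *pb) in zip(a, b):
            rows.append((ta, f, oid, *pa, 14.0, "oocyte", "")); oid += 1
            rows.append((tb, f, oid, *pb, 14.0, "oocyte", "")); oid += 1
            contacts.append((f, ta, tb))
        tid += 2
    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "object_id",
                                         "z", "y", "x",
                                         "equivalent_diameter", "cls",
                                         "agent_id"])
    summary = []
    for t, g in tracks.groupby("track_id"):
        summary.append((t, "oocyte", 0, 15, 0, 0, 0, 14.0, "alive_at_end"))
    summary = pd.DataFrame(summary, columns=["track_id", "kind", "start",
                                             "end", "z", "y", "x",
                                             "last_diameter", "end_reason"])
    contacts = pd.DataFrame(contacts, columns=["frame", "track_a", "track_b"])
    return tracks, summary, contacts


def test_single_ratio_counts_unconnected_oocytes():
    tracks, summary, contacts = _build_population(n_singles=6, n_pairs=2)
    ratio = compute_single_ratio(tracks, summary, contacts, (0, 16))
    assert ratio == pytest.approx(6 / 10)


def test_single_ratio_all_singletons_is_one():
    tracks, summary, contacts = _build_population(n_singles=5, n_pairs=0)
    assert compute_single_ratio(tracks, summary, contacts, (0, 16)) == 1.0


def test_single_ratio_empty_window_raises():
    tracks, summary, contacts = _build_population(2, 0)
    with pytest.raises(ValueError):
        compute_single_ratio(tracks, summary, contacts, (16, 16))


# ----------------------------------------------------------------------
# event frequencies and peaks
# ----------------------------------------------------------------------

def test_event_frequencies_direct_counts():
    tracks, summary, _ = _build_population(n_singles=30, n_pairs=0)
    events = pd.DataFrame([
        {"type": "burst", "frame": 3, "track_a": 0, "track_b": -1,
         "payload": 4, "member_tracks": ""},
        {"type": "burst", "frame": 5, "track_a": 1, "track_b": -1,
         "payload": 3, "member_tracks": ""},
        {"type": "burst", "frame": 9, "track_a": 2, "track_b": -1,
         "payload": 5, "member_tracks": ""},
    ])
    objects = pd.DataFrame({"frame": [], "object_id": [], "fl_lengths": []})
    freq = compute_event_frequencies(tracks, summary, events, objects,
                                     [(0, 16)])
    assert freq.od_event_freq.iloc[0] == pytest.approx(3 / 30)
    assert freq.death_freq.iloc[0] == pytest.approx(3 / 30)
    assert freq.fl_ratio.iloc[0] == 0.0


def test_no_events_means_zero_frequencies():
    tracks, summary, _ = _build_population(n_singles=4, n_pairs=0)
    events = pd.DataFrame(columns=["type", "frame", "track_a", "track_b",
                                   "payload", "member_tracks"])
    objects = pd.DataFrame({"frame": [], "object_id": [], "fl_lengths": []})
    freq = compute_event_frequencies(tracks, summary, events, objects,
                                     [(0, 8), (8, 16)])
    assert (freq.od_event_freq == 0).all()
    assert (freq.death_freq == 0).all()


def test_peak_window_80_percent_rule():
    assert find_peak_window([0.02, 0.05, 0.20, 0.22, 0.19, 0.04]) == (2, 4)
    assert find_peak_window([0.1, 0.1, 0.1]) == (0, 2)       # constant: full
    assert find_peak_window([0.0, 0.0]) is None              # all-zero: empty
    # ties resolve toward the earlier span
    assert find_peak_window([0.2, 0.05, 0.2]) == (0, 0)


# ----------------------------------------------------------------------
# survival and engulfment-fate statistics
# ----------------------------------------------------------------------

def test_survival_ratio_ledger_arithmetic():
    reps = [{"n_complete": 1000, "n_survivors": 147,
             "engulf_counts": [15] * 147, "survivor_tracks": []}]
    fs = compute_survival_ratio(reps)
    assert fs.survival_ratio_mean == pytest.approx(0.147)


def test_survival_ratio_drops_empty_replicates():
    reps = [{"n_complete": 10, "n_survivors": 10,
             "engulf_counts": [6] * 10, "survivor_tracks": []},
            {"n_complete": 0, "n_survivors": 0, "engulf_counts": [],
             "survivor_tracks": []}]
    with pytest.warns(UserWarning):
        fs = compute_survival_ratio(reps)
    assert fs.per_replicate == [1.0]


def test_engulfment_fate_stats_direct():
    mn, mean, dist = engulfment_fate_stats([5, 15, 25])
    assert mn == 5 and mean == 15
    mn, mean, _ = engulfment_fate_stats([])
    assert math.isnan(mn) and math.isnan(mean)


# ----------------------------------------------------------------------
# purple ratio
# ----------------------------------------------------------------------

def test_purple_ratio_from_mixing_scenario():
    sc = ov.make_scenario("purple_mixing")
    res = track_and_call(sc.objects, arena_xy=sc.arena_xy)
    pr = compute_purple_ratio(sc.objects, res.tracks, res.summary,
                              [(0, 6), (6, 12)])
    assert pr.purple_ratio.iloc[0] == 0.0      # not yet mixed enough
    assert pr.purple_ratio.iloc[1] > 0.0       # purple after 3 engulfments


def test_purple_ratio_requires_rainbow_input():
    sc = ov.make_scenario("treated_silent")
    res = track_and_call(sc.objects, arena_xy=sc.arena_xy)
    with pytest.raises(ValueError, match="rainbow"):
        compute_purple_ratio(sc.objects, res.tracks, res.summary, [(0, 12)])


def test_no_engulfment_means_no_purple():
    cfg = ov.default_calibration(n_oocytes_init=40, duration=48.0,
                                 color_mode="rainbow",
                                 sacrifice_hazard=(0.0,) * 7,
                                 fl_formation_prob=(0.0,) * 7, exit_prob=0.0)
    log = ov.simulate(cfg, seed=2)
    objects = ov.observe(log)
    res = track_and_call(objects, arena_xy=cfg.arena_xy)
    pr = compute_purple_ratio(objects, res.tracks, res.summary, cfg.windows())
    assert (pr.purple_ratio.fillna(0) == 0).all()


# ----------------------------------------------------------------------
# growth
# ----------------------------------------------------------------------

def test_growth_flat_when_growth_disabled():
    cfg = ov.default_calibration(n_oocytes_init=40, duration=48.0,
                                 sacrifice_hazard=(0.0,) * 7,
                                 fl_formation_prob=(0.0,) * 7,
                                 growth_per_engulfment=0.0,
                                 survivor_growth_rate=0.0, exit_prob=0.0)
    log = ov.simulate(cfg, seed=2)
    objects = ov.observe(log)
    res = track_and_call(objects, arena_xy=cfg.arena_xy)
    g = measure_growth(res.tracks, res.summary, cfg.windows())
    assert g.mean_diameter.std() == pytest.approx(0.0, abs=1e-9)


# ----------------------------------------------------------------------
# stereology
# ----------------------------------------------------------------------

def test_total_mitochondria_formula_example():
    # Voo/(Sloo*D)*N = (4R)/(3D)*N: R=10, D=0.5, N=30 -> 800
    assert stereology_total_mitochondria(10.0, 0.5, 30) == pytest.approx(800.0)
    assert stereology_total_mitochondria(10.0, 0.5, 0) == 0.0


@given(st.floats(1.0, 50.0), st.floats(0.1, 2.0), st.integers(0, 500))
@settings(max_examples=200, deadline=None)
def test_total_mitochondria_matches_closed_form(R, D, N):
    si = StereologyInput(R, D, N)
    assert si.Voo == pytest.approx(4 / 3 * math.pi * R ** 3)
    assert si.Sloo == pytest.approx(math.pi * R ** 2)
    assert si.Nmit_total == pytest.approx(4 * R / (3 * D) * N)


def test_total_mitochondria_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        stereology_total_mitochondria(-1.0, 0.5, 10)
    with pytest.raises(ValueError):
        stereology_total_mitochondria(10.0, 0.0, 10)


def test_stereology_recovers_planted_total_on_sphere_phantom():
    """Monte-Carlo oracle: scatter punctae uniformly in a sphere, count in
    an equatorial slab one mitochondrion-diameter thick, estimate."""
    rng = np.random.default_rng(0)
    R, D, N = 10.0, 0.5, 400
    estimates = []
    for _ in range(100):
        u = rng.normal(size=(N, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = R * rng.random(N) ** (1 / 3)
        pts = u * r[:, None]
        n_section = int((np.abs(pts[:, 0]) <= D / 2).sum())
        estimates.append(stereology_total_mitochondria(R, D, n_section))
    assert abs(np.mean(estimates) - N) <= 0.10 * N


# ----------------------------------------------------------------------
# serial-section counting
# ----------------------------------------------------------------------

def test_section_count_single_oocyte_expectation_over_phase():
    # one oocyte: counted 5 (its centroid section sampled) or 0; the mean
    # over a uniform phase equals 5 x (1/5) = 1
    agents = pd.DataFrame({"z": [123.0], "diameter": [20.0]})
    vals = [section_count_estimate(agents, 8.0, 5, phase=ph)
            for ph in np.linspace(0, 40, 200, endpoint=False)]
    assert set(vals) <= {0, 5}
    assert np.mean(vals) == pytest.approx(1.0, rel=0.1)


def test_section_count_recovers_planted_thousand():
    rng = np.random.default_rng(3)
    agents = pd.DataFrame({"z": rng.uniform(0, 400, 1000),
                           "diameter": rng.uniform(12, 30, 1000)})
    ests = [section_count_estimate(agents, 8.0, 5,
                                   phase=float(rng.uniform(0, 40)))
            for _ in range(60)]
    assert abs(np.mean(ests) - 1000) <= 100


def test_section_count_edge_cases():
    assert section_count_estimate(pd.DataFrame({"z": []}), 8.0, 5) == 0
    with pytest.raises(ValueError):
        section_count_estimate(pd.DataFrame({"z": [1.0]}), 0.0, 5)


# ----------------------------------------------------------------------
# printed cluster-table arithmetic
# ----------------------------------------------------------------------

def test_cluster_fraction_worked_example():
    sizes = {"C0": 354, "C1": 225, "C2": 313, "C3": 146, "C4": 142,
             "C5": 127}
    assert cluster_fraction(sizes, ["C2", "C3"], total=1307) == 35.1
    assert cluster_fraction({"A": 50}, ["A"]) == 100.0
    assert cluster_fraction(sizes, []) == 0.0
    with pytest.raises(ValueError):
        cluster_fraction({"A": 0}, ["A"], total=0)
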