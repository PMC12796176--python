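"""Generator contracts: degenerate limits, determinism, debris sampling,
conservation, calibration recovery and fate rules."""
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import ovoselect as ov
from ovoselect.config import SimConfig
from ovoselect.sim import (DebrisState, OocyteState, assign_fate,
                           resolve_engulfment, sample_debris_set,
                           simulate, simulate_whole_ovary,
                           update_connectivity)


def test_zero_hazard_run_is_eventless_and_everyone_is_candidate(quiet_config):
    log = simulate(quiet_config, seed=5)
    assert len(log.events) == 0
    fates = log.final_fates()
    assert (fates == "candidate").all()
    # final state equals initial state up to positions
    first = log.oocytes[log.oocytes.frame == 0]
    last = log.oocytes[log.oocytes.frame == log.final_frame()]
    assert len(first) == len(last) == quiet_config.n_oocytes_init
    assert np.allclose(np.sort(first.diameter), np.sort(last.diameter))


def test_same_seed_runs_are_identical():
    cfg = ov.default_calibration(n_oocytes_init=60, duration=48.0)
    a = simulate(cfg, seed=11)
    b = simulate(cfg, seed=11)
    pd.testing.assert_frame_equal(a.oocytes, b.oocytes)
    pd.testing.assert_frame_equal(a.debris, b.debris)
    pd.testing.assert_frame_equal(a.events, b.events)
    c = simulate(cfg, seed=12)
    assert not a.oocytes.equals(c.oocytes)


def test_debris_sets_respect_count_bounds_and_volume():
    cfg = SimConfig()
    rng = np.random.default_rng(0)
    parent = 15.0
    parent_vol = math.pi / 6 * parent ** 3
    lo, hi = cfg.debris_diameter_range
    for _ in range(10_000):
        diams = sample_debris_set(parent, cfg, rng)
        assert len(diams) >= 3
        assert all(lo <= d <= hi for d in diams)
        assert sum(math.pi / 6 * d ** 3 for d in diams) <= parent_vol


def test_debris_sampling_rejects_bad_parent():
    with pytest.raises(ValueError):
        sample_debris_set(0.0, SimConfig(), np.random.default_rng(0))


def test_conservation_living_plus_eliminated(default_run):
    log = default_run["log"]
    n = default_run["cfg"].n_oocytes_init
    deaths = log.events[log.events.type.isin(["burst", "shrinkage_death"])]
    for frame in range(0, log.n_frames, 9):
        living = log.oocytes[log.oocytes.frame == frame].oocyte_id.nunique()
        eliminated = int((deaths.frame <= frame).sum())
        assert living + eliminated == n


def test_burst_debris_counts_match_ledger(default_run):
    log = default_run["log"]
    bursts = log.events[log.events.type == "burst"]
    born = log.debris.groupby("debris_id").first()
    for r in bursts.itertuples():
        created = born[(born.parent_id == r.oocyte_id)
                       & (born.frame == r.frame)]
        assert len(created) == int(r.count)


def test_color_conservation_under_pure_mixing():
    # with growth disabled, engulfment mixing conserves labeled volume
    cfg = ov.default_calibration(
        n_oocytes_init=80, color_mode="rainbow", exit_prob=0.0,
        growth_per_engulfment=0.0, survivor_growth_rate=0.0)
    log = simulate(cfg, seed=3)
    def labeled_volume(frame):
        oo = log.oocytes[log.oocytes.frame == frame]
        v_o = (math.pi / 6 * oo.diameter ** 3 * (oo.cfp + oo.rfp)).sum()
        od = log.debris[log.debris.frame == frame]
        v_d = (math.pi / 6 * od.diameter ** 3 * (od.cfp + od.rfp)).sum() \
            if len(od) else 0.0
        return v_o + v_d
    vols = [labeled_volume(f) for f in range(0, log.n_frames, 8)]
    assert all(b <= a + 1e-6 for a, b in zip(vols, vols[1:]))


def test_update_connectivity_limits():
    g = nx.Graph([(0, 1), (2, 3), (4, 5)])
    rng = np.random.default_rng(0)
    cfg = SimConfig(bridge_dissolution_prob=(1.0,))
    evs = update_connectivity(g, 0, cfg, rng)
    assert g.number_of_edges() == 0 and len(evs) == 3
    g2 = nx.Graph([(0, 1), (2, 3)])
    cfg0 = SimConfig(bridge_dissolution_prob=(0.0,))
    assert update_connectivity(g2, 0, cfg0, rng) == []
    assert g2.number_of_edges() == 2


def test_planted_dissolution_hazards_recovered_from_ledger():
    """Brute-force oracle: attached fractions at window starts recover the
    planted per-boundary probabilities within Monte-Carlo error."""
    planted = (0.490, 0.616, 0.702)
    est = np.zeros(3)
    reps = 4
    for seed in range(20, 20 + reps):
        log = simulate(ov.default_calibration(exit_prob=0.0), seed=seed)
        att = []
        for w in range(4):
            a = log.config.windows()[w][0]
            g = log.oocytes[log.oocytes.frame == a]
            att.append((g.n_bridges > 0).mean())
        est += np.array([1 - att[i + 1] / att[i] for i in range(3)]) / reps
    assert np.allclose(est, planted, atol=0.10)


def test_resolve_engulfment_mixing_arithmetic():
    # red debris of 10% of the oocyte volume -> RFP fraction 1/11
    d_oo = 20.0
    d_od = d_oo * 0.1 ** (1 / 3)
    cfg = SimConfig(growth_per_engulfment=0.0)
    oo = OocyteState(0, 0, np.zeros(3), d_oo, "surviving", cfp=1.0, rfp=0.0,
                     mito_density=0.3)
    od = DebrisState(0, 9, np.array([0.0, 0.0, d_oo / 2 + 1.0]), d_od,
                     mito_density=0.5, cfp=0.0, rfp=1.0)
    oo.fl_set = [(np.array([0.0, 0.0, 1.0]), 3.0)]
    ev = resolve_engulfment(oo, od, cfg)
    assert ev["type"] == "engulfment"
    assert od.status == "engulfed"
    assert oo.engulf_count == 1
    assert oo.rfp == pytest.approx(1 / 11)
    assert oo.cfp == pytest.approx(10 / 11)
    assert oo.mito_density == pytest.approx((10 * 0.3 + 1 * 0.5) / 11)


def test_resolve_engulfment_zero_volume_debris_changes_nothing():
    cfg = SimConfig()
    oo = OocyteState(0, 0, np.zeros(3), 20.0, "surviving", cfp=1.0)
    oo.fl_set = [(np.array([0.0, 0.0, 1.0]), 3.0)]
    od = DebrisState(0, 9, np.array([0.0, 0.0, 11.0]), 0.0, 0.5, 0.0, 1.0)
    resolve_engulfment(oo, od, cfg)
    assert oo.diameter == 20.0 and oo.cfp == 1.0 and oo.engulf_count == 1


def test_resolve_engulfment_contract_violations():
    cfg = SimConfig()
    oo = OocyteState(0, 0, np.zeros(3), 20.0, "surviving")
    oo.fl_set = [(np.array([0.0, 0.0, 1.0]), 3.0)]
    od = DebrisState(0, 9, np.array([0.0, 0.0, 11.0]), 4.0, 0.5, 0.0, 1.0)
    od.status = "engulfed"
    with pytest.raises(ValueError):
        resolve_engulfment(oo, od, cfg)
    od2 = DebrisState(1, 9, np.array([0.0, 0.0, 40.0]), 4.0, 0.5, 0.0, 1.0)
    with pytest.raises(ValueError):        # out of capture range
        resolve_engulfment(oo, od2, cfg)
    od3 = DebrisState(2, 9, np.array([0.0, 0.0, -11.0]), 4.0, 0.5, 0.0, 1.0)
    with pytest.raises(ValueError):        # no FL in the capture cone
        resolve_engulfment(oo, od3, cfg)


def _history(lineage, engulf, frames, death=None):
    df = pd.DataFrame({
        "frame": list(range(frames)),
        "diameter": [15.0] * frames,
        "lineage": [lineage] * frames,
        "engulf_count": [engulf] * frames,
        "death_mode": [""] * frames,
    })
    if death:
        df.loc[df.index[-1], "death_mode"] = death
    return df


def test_fate_rules():
    cfg = SimConfig(duration=162.0)
    n = cfg.n_frames
    assert assign_fate(_history("surviving", 15, n), cfg) == "surviving"
    assert assign_fate(_history("surviving", 3, n), cfg) != "surviving"
    burst = _history("surviving", 20, 40, death="burst")
    assert assign_fate(burst, cfg) == "sacrificed_burst"  # death overrides
    shrink = _history("sacrificed", 0, 50, death="shrinkage")
    assert assign_fate(shrink, cfg) == "sacrificed_shrinkage"


def test_fates_consistent_with_generative_rules(default_run):
    log = default_run["log"]
    cfg = default_run["cfg"]
    last = log.oocytes[log.oocytes.frame == log.final_frame()]
    fates = log.final_fates()
    for r in last.itertuples():
        if fates[r.oocyte_id] == "surviving":
            assert r.lineage == "surviving"
            assert r.engulf_count >= cfg.survival_min_engulfments


def test_whole_ovary_mode_population_sizes():
    cfg = ov.default_calibration()
    control = simulate_whole_ovary(cfg, seed=1)
    treated = simulate_whole_ovary(
        cfg.replace(treatment_mode="phagocytosis_blocked"), seed=1)
    assert len(control) == round(cfg.ovary_n_oocytes
                                 * (1 - cfg.ovary_death_fraction))
    assert len(treated) > len(control)          # suppressed death
    sz = cfg.ovary_size
    assert (control.z.between(0, sz[0])).all()
    assert (control.diameter > 0).all()
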