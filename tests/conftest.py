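"""Shared fixtures: one default-calibration replicate run through the
agent-level pipeline, reused by the tracking/quantification tests."""
import numpy as np
import pandas as pd
import pytest

import ovoselect as ov
from ovoselect.track import track_and_call


@pytest.fixture(scope="session")
def default_run():
    """Ground truth + observed objects + tracking result for one seed."""
    cfg = ov.default_calibration()
    log = ov.simulate(cfg, seed=1)
    objects = ov.observe(log)
    res = track_and_call(objects, arena_xy=cfg.arena_xy)
    return {"cfg": cfg, "log": log, "objects": objects, "res": res}


@pytest.fixture(scope="session")
def quiet_config():
    """Degenerate zero-hazard configuration: no deaths, no cyst breakdown,
    no FLs, no field exits."""
    return ov.default_calibration(
        sacrifice_hazard=(0.0,) * 7,
        bridge_dissolution_prob=(0.0, 0.0, 0.0),
        fl_formation_prob=(0.0,) * 7,
        exit_prob=0.0,
        survivor_growth_rate=0.0,
        n_oocytes_init=40,
        duration=48.0,
    )


def event_match(called: pd.DataFrame, expected: list[dict],
                tol_frames: int = 0) -> bool:
    """Exact (or frame-tolerant) match of a called event table against an
    expected event list, over the scored event types."""
    scored = ("burst", "engulfment", "separation", "shrinkage_death")
    got = [dict(type=r.type, frame=int(r.frame), payload=int(r.payload))
           for r in called.itertuples() if r.type in scored]
    exp = [dict(e) for e in expected]
    if len(got) != len(exp):
        return False
    used = set()
    for e in exp:
        found = None
        for i, g in enumerate(got):
            if i in used or g["type"] != e["type"]:
                continue
            if abs(g["frame"] - e["frame"]) > tol_frames:
                continue
            if e["type"] == "burst" and "payload" in e \
                    and g["payload"] != e["payload"]:
                continue
            found = i
            break
        if found is None:
            return False
        used.add(found)
    return True


def engulfment_prf(log, objects, res):
    """Precision/recall of called engulfments against the ledger, matched
    on (engulfing oocyte agent, debris agent, frame +-2)."""
    tr = res.tracks
    tfa = {(r.track_id, r.frame): r.agent_id for r in tr.itertuples()}
    gt = log.events[(log.events.type == "engulfment")
                    & (log.events.observable == True)]  # noqa: E712
    gt_set = {(f"o{int(r.oocyte_id)}", f"d{int(r.debris_id)}", int(r.frame))
              for r in gt.itertuples()}
    called = res.events[res.events.type == "engulfment"]
    tp = 0
    matched = set()
    for r in called.itertuples():
        da = tfa.get((r.track_b, r.frame), "?")
        oa = None
        for fr in (r.frame, r.frame + 1, r.frame + 2, r.frame - 1):
            oa = tfa.get((r.track_a, fr))
            if oa:
                break
        for t in gt_set:
            if t in matched:
                continue
            if t[1] == da and t[0] == oa and abs(t[2] - r.frame) <= 2:
                tp += 1
                matched.add(t)
                break
    if not len(called) or not gt_set:
        return 1.0, 1.0
    return tp / len(called), len(matched) / len(gt_set)
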