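"""Linking of per-frame objects into tracks, and event calling.

Tracks are built by frame-to-frame optimal assignment (Hungarian algorithm)
on centroid displacement with a hard gate, plus single-frame gap closing.
Event callers then identify the behaviors scored in 4D ovary imaging:
bursts (an oocyte degrading into >= 3 debris), engulfments (an OD enclosed
by an oocyte and disappearing), separations/attachments of touching
oocytes, death modes, and motion-correlation connectedness used to exclude
potentially bridge-connected oocytes from single-oocyte counts.

Object tables only need ``frame, object_id, z, y, x, equivalent_diameter,
cls`` columns; ``contact_ids`` enables the contact-based callers.  A track
is typed by its first frame: tracks present at frame 0 are oocytes (debris
only arise from bursts), later-born OD-class tracks are debris.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import TrackParams

__all__ = [
    "build_tracks",
    "summarize_tracks",
    "detect_burst",
    "detect_engulfment",
    "classify_death_mode",
    "detect_separation",
    "infer_connected",
    "contact_pairs",
    "call_events",
    "track_and_call",
    "TrackingResult",
]

_BIG = 1e9


def build_tracks(objects: pd.DataFrame, params: TrackParams | None = None) -> pd.DataFrame:
    """Link per-frame objects into tracks.

    One-to-one assignment per consecutive frame pair minimizing total
    centroid displacement, displacement capped at ``gate_radius``; objects
    unmatched against frame f-1 are retried against tracks last seen at
    f-2 with gate ``gate_radius x gap_gate_factor`` (one closed gap per
    track at a time).  Remaining objects start new tracks.
    """
    params = params or TrackParams()
    if objects.empty:
        return pd.DataFrame(columns=["track_id", "frame", "object_id", "z", "y",
                                     "x", "equivalent_diameter", "cls", "agent_id"])
    has_agent = "agent_id" in objects.columns
    frames = sorted(objects.frame.unique())
    by_frame = {f: g.reset_index(drop=True) for f, g in objects.groupby("frame")}

    next_tid = 0
    # per track: last frame, last/predicted position, row buffer
    last_frame: dict[int, int] = {}
    last_pos: dict[int, np.ndarray] = {}
    prev_pos: dict[int, np.ndarray] = {}
    last_diam: dict[int, float] = {}
    rows: list[tuple] = []

    def add(tid, r):
        rows.append((tid, int(r.frame), r.object_id, r.z, r.y, r.x,
                     r.equivalent_diameter, r.cls,
                     getattr(r, "agent_id", "") if has_agent else ""))
        p = np.array([r.z, r.y, r.x])
        if tid in last_pos and last_frame.get(tid) == int(r.frame) - 1:
            prev_pos[tid] = last_pos[tid]
        else:
            prev_pos[tid] = p
        last_frame[tid] = int(r.frame)
        last_pos[tid] = p
        last_diam[tid] = float(r.equivalent_diameter)

    def predicted(tid):
        # constant-velocity prediction stabilizes convergent streams
        return last_pos[tid] + 0.8 * (last_pos[tid] - prev_pos[tid])

    def assign(track_ids, obj_rows, gate):
        """Optimal gated assignment; returns (matched obj index -> tid).

        Besides the displacement gate, links must be size-consistent
        (diameter ratio >= 0.5 frame to frame), so a burst parent is never
        continued by one of its much smaller debris.
        """
        if not track_ids or not len(obj_rows):
            return {}
        tp = np.array([last_pos[t] for t in track_ids])
        tpred = np.array([predicted(t) for t in track_ids])
        td = np.array([last_diam[t] for t in track_ids])
        op = obj_rows[["z", "y", "x"]].to_numpy(float)
        od = obj_rows["equivalent_diameter"].to_numpy(float)
        cost = cdist(tpred, op)
        gate_dist = cdist(tp, op)
        ratio = np.minimum(td[:, None], od[None, :]) / np.maximum(
            td[:, None], od[None, :])
        cost[(gate_dist > gate) | (ratio < params.size_ratio_gate)] = _BIG
        ri, ci = linear_sum_assignment(cost)
        return {int(c): track_ids[int(r)] for r, c in zip(ri, ci)
                if cost[r, c] < _BIG}

    for f in frames:
        g = by_frame[f]
        primary = [t for t, lf in last_frame.items() if lf == f - 1]
        matched = assign(primary, g, params.gate_radius)
        unmatched_idx = [i for i in range(len(g)) if i not in matched]
        if params.gap_max >= 1 and unmatched_idx:
            gappy = [t for t, lf in last_frame.items() if lf == f - 2]
            sub = g.iloc[unmatched_idx]
            gm = assign(gappy, sub, params.gate_radius * params.gap_gate_factor)
            for local, tid in gm.items():
                matched[unmatched_idx[local]] = tid
            unmatched_idx = [i for i in range(len(g)) if i not in matched]
        for i in range(len(g)):
            r = g.iloc[i]
            if i in matched:
                add(matched[i], r)
            else:
                add(next_tid, r)
                next_tid += 1

    return pd.DataFrame(rows, columns=["track_id", "frame", "object_id", "z",
                                       "y", "x", "equivalent_diameter", "cls",
                                       "agent_id"])


def summarize_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track summary: span, type, last state. Type from the first frame
    (frame-0 tracks are oocytes; later-born OD-class tracks are debris)."""
    if tracks.empty:
        return pd.DataFrame(columns=["track_id", "kind", "start", "end",
                                     "z", "y", "x", "last_diameter", "end_reason"])
    out = []
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        first, last = g.iloc[0], g.iloc[-1]
        if first.frame == 0:
            kind = "oocyte"
        else:
            kind = "OD" if first.cls == "OD" else "oocyte"
        out.append((tid, kind, int(first.frame), int(last.frame),
                    last.z, last.y, last.x, last.equivalent_diameter, ""))
    return pd.DataFrame(out, columns=["track_id", "kind", "start", "end",
                                      "z", "y", "x", "last_diameter", "end_reason"])


def _track_state(tracks: pd.DataFrame):
    """dict track_id -> {frame: (pos, radius)} for quick lookups."""
    state = {}
    for tid, g in tracks.groupby("track_id"):
        state[tid] = {int(r.frame): (np.array([r.z, r.y, r.x]),
                                     r.equivalent_diameter / 2.0)
                      for r in g.itertuples()}
    return state


def detect_burst(tracks: pd.DataFrame, summary: pd.DataFrame,
                 params: TrackParams | None = None) -> list[dict]:
    """Burst calls: an oocyte track ends and >= 3 new OD tracks begin within
    ``last radius + r_burst_extra`` of its last centroid within 2 frames.
    Each new OD track is attributed to its nearest eligible ending oocyte."""
    params = params or TrackParams()
    if tracks.empty:
        return []
    last_frame_all = int(tracks.frame.max())
    endings = summary[(summary.kind == "oocyte") & (summary.end < last_frame_all)]
    births = summary[(summary.kind == "OD")]
    if endings.empty or births.empty:
        return []
    pairs = []  # (debris tid, oocyte tid, dist)
    for o in endings.itertuples():
        p_o = np.array([o.z, o.y, o.x])
        r_search = o.last_diameter / 2.0 + params.r_burst_extra
        cand = births[(births.start >= o.end + 1) & (births.start <= o.end + 2)]
        for d in cand.itertuples():
            first = tracks[(tracks.track_id == d.track_id)
                           & (tracks.frame == d.start)].iloc[0]
            dist = float(np.linalg.norm(np.array([first.z, first.y, first.x]) - p_o))
            if dist <= r_search:
                pairs.append((d.track_id, o.track_id, o.end, dist))
    if not pairs:
        return []
    best: dict[int, tuple] = {}
    for d_tid, o_tid, o_end, dist in pairs:
        if d_tid not in best or dist < best[d_tid][2]:
            best[d_tid] = (o_tid, o_end, dist)
    grouped: dict[int, list[int]] = {}
    ends: dict[int, int] = {}
    for d_tid, (o_tid, o_end, _) in best.items():
        grouped.setdefault(o_tid, []).append(d_tid)
        ends[o_tid] = o_end
    events = []
    for o_tid, debris_tids in sorted(grouped.items()):
        if len(debris_tids) >= 3:
            events.append({"type": "burst", "frame": ends[o_tid] + 1,
                           "oocyte_track": o_tid,
                           "debris_tracks": sorted(debris_tids),
                           "count": len(debris_tids)})
    return events


def detect_engulfment(tracks: pd.DataFrame, summary: pd.DataFrame,
                      params: TrackParams | None = None,
                      arena_xy: float | None = None) -> list[dict]:
    """Engulfment calls: an OD track terminates with its final centroid
    inside an oocyte boundary expanded by epsilon (at termination or within
    the following 2 frames); ties broken by smallest boundary distance.
    OD tracks ending at the field edge are excluded (left the field)."""
    params = params or TrackParams()
    if tracks.empty:
        return []
    last_frame_all = int(tracks.frame.max())
    od_ends = summary[(summary.kind == "OD") & (summary.end < last_frame_all)]
    oo = summary[summary.kind == "oocyte"]
    if od_ends.empty or oo.empty:
        return []
    state = _track_state(tracks[tracks.track_id.isin(oo.track_id)])
    events = []
    for d in od_ends.itertuples():
        p = np.array([d.z, d.y, d.x])
        best_tid, best_bd = None, np.inf
        for o_tid, frames_map in state.items():
            for fr in (d.end, d.end + 1, d.end + 2):
                if fr in frames_map:
                    pos, rad = frames_map[fr]
                    bd = float(np.linalg.norm(p - pos)) - rad
                    if bd < best_bd:
                        best_bd, best_tid = bd, o_tid
                    break
        if best_tid is not None and best_bd <= params.engulf_epsilon:
            events.append({"type": "engulfment", "frame": int(d.end),
                           "oocyte_track": best_tid, "debris_track": d.track_id})
    return events


def classify_death_mode(track: pd.DataFrame, has_burst: bool = False) -> str | None:
    """Death mode of a terminated oocyte track.

    degradation iff a burst event is associated; shrinkage iff the diameter
    decreased over at least the final 4 frames (one <=5% single-frame
    reversal tolerated) with a clear net decline; otherwise None.
    """
    if has_burst:
        return "degradation"
    d = track.sort_values("frame").equivalent_diameter.to_numpy(float)
    if len(d) < 4:
        return None
    tail = d[-8:] if len(d) >= 8 else d
    # longest trailing run of decreasing steps, tolerating one small reversal
    reversals = 0
    run = 0
    for i in range(len(tail) - 1, 0, -1):
        step_ok = tail[i] < tail[i - 1]
        if not step_ok:
            if reversals == 0 and tail[i] <= tail[i - 1] * 1.05:
                reversals = 1
            else:
                break
        run += 1
    frames_in_run = run + 1
    if frames_in_run >= 4 and tail[-1] <= tail[-frames_in_run] * 0.8:
        return "shrinkage"
    return None


def contact_pairs(objects: pd.DataFrame, tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-frame contacting track pairs from the objects' contact_ids."""
    if objects.empty or "contact_ids" not in objects.columns or tracks.empty:
        return pd.DataFrame(columns=["frame", "track_a", "track_b"])
    obj2track = dict(zip(tracks.object_id, tracks.track_id))
    rows = []
    for r in objects.itertuples():
        if not isinstance(r.contact_ids, str) or not r.contact_ids:
            continue
        ta = obj2track.get(r.object_id)
        if ta is None:
            continue
        for other in r.contact_ids.split(";"):
            tb = obj2track.get(int(other))
            if tb is None or tb <= ta:
                continue
            rows.append((int(r.frame), ta, tb))
    return pd.DataFrame(rows, columns=["frame", "track_a", "track_b"]).drop_duplicates()


def detect_separation(tracks: pd.DataFrame, summary: pd.DataFrame,
                      contacts: pd.DataFrame,
                      params: TrackParams | None = None) -> list[dict]:
    """Separation/attachment calls for oocyte track pairs with hysteresis.

    Separation: in contact >= 2 consecutive frames, then out of contact with
    surface distance > d_sep for >= 2 consecutive frames; attachment is the
    symmetric transition.  Single-frame contact flicker produces no events.
    """
    params = params or TrackParams()
    if contacts.empty:
        return []
    oo_ids = set(summary[summary.kind == "oocyte"].track_id)
    state = _track_state(tracks)
    events = []
    h = params.hysteresis_frames
    for (ta, tb), g in contacts.groupby(["track_a", "track_b"]):
        if ta not in oo_ids or tb not in oo_ids:
            continue
        contact_frames = set(g.frame)
        common = sorted(set(state[ta]) & set(state[tb]))
        if len(common) < 2 * h:
            continue

        def surface_gap(f):
            pa, ra = state[ta][f]
            pb, rb = state[tb][f]
            return float(np.linalg.norm(pa - pb)) - ra - rb

        status = [f in contact_frames for f in common]
        far = [surface_gap(f) > params.d_sep for f in common]
        i = 0
        n = len(common)
        while i < n:
            # find a contact run
            if not status[i]:
                i += 1
                continue
            j = i
            while j < n and status[j]:
                j += 1
            contact_len = j - i
            if contact_len >= h and j < n:
                # require >= h consecutive non-contact, far frames
                k = j
                while k < n and not status[k] and far[k]:
                    k += 1
                if k - j >= h:
                    events.append({"type": "separation", "frame": int(common[j]),
                                   "track_a": ta, "track_b": tb})
            i = j
        # attachments: non-contact run (>= h) followed by contact run (>= h)
        i = 0
        while i < n:
            if status[i]:
                i += 1
                continue
            j = i
            while j < n and not status[j]:
                j += 1
            if j - i >= h and j < n:
                k = j
                while k < n and status[k]:
                    k += 1
                if k - j >= h:
                    events.append({"type": "attachment", "frame": int(common[j]),
                                   "track_a": ta, "track_b": tb})
            i = j
    return events


def infer_connected(track_a: pd.DataFrame, track_b: pd.DataFrame,
                    window: tuple[int, int],
                    contact_frames: set[int] | None = None,
                    params: TrackParams | None = None) -> bool | None:
    """Motion-correlation connectedness of a contacting oocyte pair.

    Over the window's frames where both tracks exist (and are in contact,
    when contact frames are supplied), the pair is *connected* iff the mean
    cosine similarity of per-frame displacements >= c_corr and the relative
    surface-gap variation <= d_var.  Fewer than k_min_frames shared frames
    -> None (indeterminate, excluded from single-oocyte counts entirely).
    """
    params = params or TrackParams()
    a, b = window
    ga = track_a[(track_a.frame >= a) & (track_a.frame < b)].sort_values("frame")
    gb = track_b[(track_b.frame >= a) & (track_b.frame < b)].sort_values("frame")
    common = sorted(set(ga.frame) & set(gb.frame))
    if contact_frames is not None:
        common = [f for f in common if f in contact_frames]
    if len(common) < params.k_min_frames:
        return None
    pa = ga.set_index("frame").loc[common, ["z", "y", "x"]].to_numpy(float)
    pb = gb.set_index("frame").loc[common, ["z", "y", "x"]].to_numpy(float)
    ra = ga.set_index("frame").loc[common, "equivalent_diameter"].to_numpy(float) / 2
    rb = gb.set_index("frame").loc[common, "equivalent_diameter"].to_numpy(float) / 2
    da = np.diff(pa, axis=0)
    db = np.diff(pb, axis=0)
    na = np.linalg.norm(da, axis=1)
    nb = np.linalg.norm(db, axis=1)
    ok = (na > 1e-9) & (nb > 1e-9)
    if ok.sum() < max(params.k_min_frames - 1, 1):
        return None
    cos = (da[ok] * db[ok]).sum(axis=1) / (na[ok] * nb[ok])
    gap = np.linalg.norm(pa - pb, axis=1) - ra - rb
    rel_var = float(np.std(gap) / (np.mean(np.abs(gap)) + 1.0))
    return bool(cos.mean() >= params.c_corr and rel_var <= params.d_var)


def _left_field(summary_row, arena_xy: float, margin: float) -> bool:
    return (summary_row.y < margin or summary_row.y > arena_xy - margin
            or summary_row.x < margin or summary_row.x > arena_xy - margin)


@dataclass
class TrackingResult:
    tracks: pd.DataFrame
    summary: pd.DataFrame
    events: pd.DataFrame
    contacts: pd.DataFrame


def call_events(tracks: pd.DataFrame, summary: pd.DataFrame,
                objects: pd.DataFrame, params: TrackParams | None = None,
                arena_xy: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run all event callers, then assign per-track end reasons.

    Returns (events, summary-with-end-reasons, contacts).
    """
    params = params or TrackParams()
    contacts = contact_pairs(objects, tracks)
    bursts = detect_burst(tracks, summary, params)
    engulf = detect_engulfment(tracks, summary, params, arena_xy=arena_xy)
    seps = detect_separation(tracks, summary, contacts, params)

    burst_oocytes = {e["oocyte_track"] for e in bursts}
    burst_debris = {d for e in bursts for d in e["debris_tracks"]}
    engulfed = {e["debris_track"] for e in engulf}
    last_frame_all = int(tracks.frame.max()) if len(tracks) else 0

    reasons = {}
    by_tid = {tid: g for tid, g in tracks.groupby("track_id")}
    for s in summary.itertuples():
        tid = s.track_id
        if s.end >= last_frame_all:
            reasons[tid] = "alive_at_end"
        elif s.kind == "oocyte" and tid in burst_oocytes:
            reasons[tid] = "burst"
        elif s.kind == "OD" and tid in engulfed:
            reasons[tid] = "engulfed"
        elif s.kind == "oocyte" and classify_death_mode(by_tid[tid]) == "shrinkage":
            reasons[tid] = "shrinkage"
        elif arena_xy is not None and _left_field(s, arena_xy, params.left_field_margin):
            reasons[tid] = "left_field"
        else:
            reasons[tid] = "gap_lost"
    summary = summary.copy()
    summary["end_reason"] = summary.track_id.map(reasons)
    summary["complete"] = ((summary.start == 0)
                           & summary.end_reason.isin(["alive_at_end", "burst",
                                                      "shrinkage"]))

    rows = []
    for e in bursts:
        rows.append({"type": "burst", "frame": e["frame"],
                     "track_a": e["oocyte_track"], "track_b": -1,
                     "payload": e["count"],
                     "member_tracks": ";".join(map(str, e["debris_tracks"]))})
    for e in engulf:
        rows.append({"type": "engulfment", "frame": e["frame"],
                     "track_a": e["oocyte_track"], "track_b": e["debris_track"],
                     "payload": 1, "member_tracks": ""})
    for e in seps:
        rows.append({"type": e["type"], "frame": e["frame"],
                     "track_a": e["track_a"], "track_b": e["track_b"],
                     "payload": 0, "member_tracks": ""})
    for s in summary.itertuples():
        if s.end_reason == "shrinkage":
            rows.append({"type": "shrinkage_death", "frame": int(s.end) + 1,
                         "track_a": s.track_id, "track_b": -1,
                         "payload": 0, "member_tracks": ""})
    events = pd.DataFrame(rows, columns=["type", "frame", "track_a", "track_b",
                                         "payload", "member_tracks"])
    events = events.sort_values(["frame", "type", "track_a"]).reset_index(drop=True)
    return events, summary, contacts


def track_and_call(objects: pd.DataFrame, params: TrackParams | None = None,
                   arena_xy: float | None = None) -> TrackingResult:
    """objects -> tracks, end-reasons, typed events, contacts."""
    params = params or TrackParams()
    tracks = build_tracks(objects, params)
    summary = summarize_tracks(tracks)
    events, summary, contacts = call_events(tracks, summary, objects, params,
                                            arena_xy=arena_xy)
    return TrackingResult(tracks, summary, events, contacts)
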