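"""Deterministic micro-scenarios and the default calibration config.

Each scenario is a fully scripted (non-stochastic) set of per-frame object
records with its expected event list, exercising exactly one behavior of
the event callers: minimal bursts, engulfment geometry, separation
hysteresis, shrinkage classification, cytoplasm mixing, a crowded field and
a silenced (treated) field.  Scenarios are agent-script-first; their object
tables are also renderable for image-path cross-checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .sim import classify_diameter

__all__ = ["Scenario", "make_scenario", "SCENARIO_NAMES", "default_calibration",
           "low_label_calibration", "treated_calibration",
           "extended_culture_calibration"]

SCENARIO_NAMES = (
    "burst_minimal", "burst_subthreshold", "engulf_single", "engulf_edge_case",
    "separation_pair", "flicker_contact", "shrinkage_track", "purple_mixing",
    "crowded_field", "treated_silent",
)


@dataclass
class Scenario:
    """A scripted trajectory set with its ground-truth expectations."""

    name: str
    description: str
    objects: pd.DataFrame
    expected_events: list[dict] = field(default_factory=list)
    arena_xy: float = 100.0


class _Script:
    """Collects scripted per-frame object states and derives contacts."""

    def __init__(self, contact_gap: float = 0.8):
        self.rows: list[dict] = []
        self.contact_gap = contact_gap

    def add(self, key: str, frame: int, z: float, y: float, x: float,
            d: float, fl: str = "", cfp: float = 0.0, rfp: float = 0.0,
            mito: float = 0.3):
        self.rows.append(dict(frame=frame, key=key, z=z, y=y, x=x, d=d,
                              fl=fl, cfp=cfp, rfp=rfp, mito=mito))

    def path(self, key: str, frames, start, step, d, **kw):
        """Straight-line motion: position(f) = start + (f - frames[0]) * step."""
        start = np.asarray(start, float)
        step = np.asarray(step, float)
        for f in frames:
            p = start + (f - frames[0]) * step
            self.add(key, f, *p, d, **kw)

    def build(self) -> pd.DataFrame:
        rows = sorted(self.rows, key=lambda r: r["frame"])
        out = []
        oid = 0
        by_frame: dict[int, list[dict]] = {}
        for r in rows:
            rec = {
                "frame": r["frame"], "object_id": oid,
                "z": r["z"], "y": r["y"], "x": r["x"],
                "equivalent_diameter": r["d"],
                "volume": math.pi / 6 * r["d"] ** 3,
                "cls": classify_diameter(r["d"]),
                "fl_lengths": r["fl"],
                "cfp_mean": r["cfp"], "rfp_mean": r["rfp"],
                "mito_density": r["mito"],
                "contact_ids": "", "agent_id": r["key"],
            }
            oid += 1
            out.append(rec)
            by_frame.setdefault(r["frame"], []).append(rec)
        for frame_rows in by_frame.values():
            for i, a in enumerate(frame_rows):
                ids = []
                for j, b in enumerate(frame_rows):
                    if i == j:
                        continue
                    dist = math.dist((a["z"], a["y"], a["x"]),
                                     (b["z"], b["y"], b["x"]))
                    if dist - (a["equivalent_diameter"]
                               + b["equivalent_diameter"]) / 2 <= self.contact_gap:
                        ids.append(str(b["object_id"]))
                a["contact_ids"] = ";".join(ids)
        return pd.DataFrame(out)


def _burst(n_debris: int) -> Scenario:
    s = _Script()
    center = np.array([15.0, 50.0, 50.0])
    s.path("parent", range(0, 6), center, (0, 0.5, 0.5), 16.0)
    last = center + 5 * np.array([0, 0.5, 0.5])
    for k in range(n_debris):
        ang = 2 * math.pi * k / max(n_debris, 1)
        u = np.array([0.0, math.cos(ang), math.sin(ang)])
        s.path(f"od{k}", range(6, 13), last + 6 * u, u * 0.8, 4.0)
    # a far bystander keeps the field alive to the final frame
    s.path("bystander", range(0, 13), (15, 15, 15), (0, 0.3, 0.0), 15.0)
    expected = []
    if n_debris >= 3:
        expected.append({"type": "burst", "frame": 6, "payload": n_debris})
    return Scenario(
        name="burst_minimal" if n_debris >= 3 else "burst_subthreshold",
        description=f"one oocyte degrading into {n_debris} debris",
        objects=s.build(), expected_events=expected)


def _engulf_single() -> Scenario:
    s = _Script()
    s.path("oocyte", range(0, 15), (15, 50, 50), (0, 0, 0), 18.0)
    # OD born at frame 2, homing 4 um/frame along -x; holds at a 1.2 um
    # surface gap at frame 7 (its last image-detectable position), then is
    # enclosed 5 um from the center at frame 8
    for f in range(2, 7):
        s.add("od", f, 15, 50, 77 - 4 * (f - 2), 4.0)
    s.add("od", 7, 15, 50, 60.2, 4.0)
    s.add("od", 8, 15, 50, 55.0, 4.0)
    return Scenario(
        name="engulf_single",
        description="one OD converging into an oocyte and disappearing",
        objects=s.build(),
        expected_events=[{"type": "engulfment", "frame": 8}])


def _engulf_edge_case() -> Scenario:
    s = _Script()
    s.path("oocyte", range(0, 15), (15, 50, 30), (0, 0, 0), 18.0)
    # OD drifts to the field edge and is lost there: no engulfment call
    for f in range(2, 10):
        s.add("od", f, 15, 50, 33 - 4 * (f - 2), 4.0)
    return Scenario(
        name="engulf_edge_case",
        description="an OD track ending at the field edge is not an engulfment",
        objects=s.build(), expected_events=[])


def _separation_pair() -> Scenario:
    s = _Script()
    a0 = np.array([15.0, 40.0, 40.0])
    u = np.array([0.0, 1.0, 0.0])
    for f in range(0, 6):          # co-moving, touching (centers 14 um apart)
        p = a0 + f * np.array([0, 0.5, 0.5])
        s.add("a", f, *p, 14.0)
        s.add("b", f, *(p + 14.0 * u), 14.0)
    pa = a0 + 5 * np.array([0, 0.5, 0.5])
    for f in range(6, 13):         # diverging 2.5 um/frame each
        k = f - 5
        s.add("a", f, *(pa - 2.5 * k * u), 14.0)
        s.add("b", f, *(pa + 14.0 * u + 2.5 * k * u), 14.0)
    return Scenario(
        name="separation_pair",
        description="a touching pair separating and moving apart",
        objects=s.build(),
        expected_events=[{"type": "separation", "frame": 6}])


def _flicker_contact() -> Scenario:
    s = _Script()
    base = np.array([15.0, 50.0, 40.0])
    u = np.array([0.0, 0.0, 1.0])
    for f in range(0, 12):
        gap = 0.0 if f % 2 == 0 else 3.0
        s.add("a", f, *base, 14.0)
        s.add("b", f, *(base + (14.0 + gap) * u), 14.0)
    return Scenario(
        name="flicker_contact",
        description="single-frame contact flicker produces no events",
        objects=s.build(), expected_events=[])


def _shrinkage_track() -> Scenario:
    s = _Script()
    for f, d in enumerate([20.0, 17.0, 14.0, 10.0]):
        s.add("dying", f, 15, 50, 50, d)
    s.path("bystander", range(0, 9), (15, 20, 20), (0, 0.4, 0), 15.0)
    return Scenario(
        name="shrinkage_track",
        description="monotonic diameter loss classified as shrinkage death",
        objects=s.build(),
        expected_events=[{"type": "shrinkage_death", "frame": 4}])


def _purple_mixing() -> Scenario:
    s = _Script()
    v0 = 1.0
    d0 = 20.0
    cfp_v, rfp_v = 1.0, 0.0      # label volumes in units of the initial volume
    center = np.array([15.0, 50.0, 50.0])
    engulf_frames = {5: "r0", 7: "r1", 9: "r2"}
    starts = {"r0": 1, "r1": 3, "r2": 5}
    vol = 1.0
    for f in range(0, 12):
        if f in engulf_frames:
            vol += 0.1
            rfp_v += 0.1
        cfp_frac = cfp_v / vol
        rfp_frac = rfp_v / vol
        d = d0 * vol ** (1 / 3)
        s.add("blue", f, *center, d, cfp=100 * cfp_frac, rfp=100 * rfp_frac)
    dv = 0.1 * math.pi / 6 * d0 ** 3
    d_od = (6 * dv / math.pi) ** (1 / 3)
    for key, f0 in starts.items():
        fe = [f for f, k in engulf_frames.items() if k == key][0]
        # approach at 4 um/frame, reaching 8 um from the center one frame
        # before the 5-um-deep enclosure (every step below the 6 um gate)
        for f in range(f0, fe):
            dist = 8.0 + 4.0 * (fe - 1 - f)
            s.add(key, f, 15, 50, 50 + dist, d_od, cfp=0.0, rfp=100.0)
        s.add(key, fe, 15, 50, 50 + 5.0, d_od, cfp=0.0, rfp=100.0)
    return Scenario(
        name="purple_mixing",
        description="a blue oocyte turning purple by engulfing red debris",
        objects=s.build(),
        expected_events=[{"type": "engulfment", "frame": f}
                         for f in sorted(engulf_frames)])


def _crowded_field() -> Scenario:
    s = _Script()
    # A: bursts at frame 7 into 4 debris
    s.path("A", range(0, 7), (15, 25, 25), (0, 0.4, 0.4), 16.0)
    pa = np.array([15.0, 25.0, 25.0]) + 6 * np.array([0, 0.4, 0.4])
    for k in range(4):
        ang = 2 * math.pi * k / 4
        u = np.array([0.0, math.cos(ang), math.sin(ang)])
        s.path(f"A_od{k}", range(7, 15), pa + 6 * u, u * 0.6, 3.0)
    # B: engulfs one OD at frame 9
    s.path("B", range(0, 15), (15, 75, 75), (0, 0, 0), 18.0)
    for f in range(3, 9):
        s.add("B_od", f, 15, 75, 99 - 4 * (f - 3), 4.0)
    s.add("B_od", 9, 15, 75, 78.0, 4.0)
    # C, D: separate at frame 6
    c0 = np.array([30.0, 30.0, 75.0])
    u = np.array([0.0, 1.0, 0.0])
    for f in range(0, 6):
        s.add("C", f, *(c0 + f * np.array([0, 0.4, 0.4])), 14.0)
        s.add("D", f, *(c0 + f * np.array([0, 0.4, 0.4]) + 14.0 * u), 14.0)
    pc = c0 + 5 * np.array([0, 0.4, 0.4])
    for f in range(6, 15):
        k = f - 5
        s.add("C", f, *(pc - 2.5 * k * u), 14.0)
        s.add("D", f, *(pc + 14.0 * u + 2.5 * k * u), 14.0)
    # E, F: lone drifters
    s.path("E", range(0, 15), (30, 75, 25), (0, 0.5, -0.3), 15.0)
    s.path("F", range(0, 15), (30, 50, 50), (0, -0.4, 0.4), 17.0)
    return Scenario(
        name="crowded_field",
        description="burst, engulfment and separation in one field",
        objects=s.build(),
        expected_events=[
            {"type": "burst", "frame": 7, "payload": 4},
            {"type": "engulfment", "frame": 9},
            {"type": "separation", "frame": 6},
        ])


def _treated_silent() -> Scenario:
    s = _Script()
    rngless = [(15, 20, 20), (15, 20, 80), (15, 80, 20), (15, 80, 80), (25, 50, 50)]
    for i, p in enumerate(rngless):
        s.path(f"o{i}", range(0, 12), p, (0, 0.3 * (-1) ** i, 0.2), 15.0)
    return Scenario(
        name="treated_silent",
        description="a silenced field with no phagocytosis events",
        objects=s.build(), expected_events=[])


_BUILDERS = {
    "burst_minimal": lambda: _burst(3),
    "burst_subthreshold": lambda: _burst(2),
    "engulf_single": _engulf_single,
    "engulf_edge_case": _engulf_edge_case,
    "separation_pair": _separation_pair,
    "flicker_contact": _flicker_contact,
    "shrinkage_track": _shrinkage_track,
    "purple_mixing": _purple_mixing,
    "crowded_field": _crowded_field,
    "treated_silent": _treated_silent,
}


def make_scenario(name: str) -> Scenario:
    """Build a scenario from the documented catalogue by name."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"catalogue: {', '.join(SCENARIO_NAMES)}")
    return _BUILDERS[name]()


# ----------------------------------------------------------------------
# default calibration
# ----------------------------------------------------------------------

def default_calibration(**overrides) -> SimConfig:
    """The packaged configuration planting the reference statistics:
    per-boundary bridge dissolution 0.490/0.616/0.702 (single-oocyte time
    course 57.1 -> 78.1 -> 91.6 -> 97.5%), survival fraction 0.147,
    engulfment minimum 5 / target mean 15, burst and FL frequencies peaking
    over c-19.5 dpc -> c-PD2, extended-culture growth endpoints
    52.4 / 37.4 um, whole-ovary endpoint counts 3768 / 5996."""
    return SimConfig(**overrides)


def low_label_calibration(**overrides) -> SimConfig:
    """Low labeling density variant: a small labeled subset (~55 oocytes,
    whole cysts labeled together) for tracing single-oocyte fractions."""
    kw = dict(n_oocytes_init=55)
    kw.update(overrides)
    return SimConfig(**kw)


def treated_calibration(**overrides) -> SimConfig:
    """Autophagy-inhibitor (3-MA-like) mode: bursts and FLs suppressed."""
    kw = dict(treatment_mode="phagocytosis_blocked")
    kw.update(overrides)
    return SimConfig(**kw)


def extended_culture_calibration(treated: bool = False, **overrides) -> SimConfig:
    """Extended culture: 7 additional days beyond c-PD4 (330 h total)."""
    kw = dict(duration=330.0)
    if treated:
        kw["treatment_mode"] = "phagocytosis_blocked"
    kw.update(overrides)
    return SimConfig(**kw)
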