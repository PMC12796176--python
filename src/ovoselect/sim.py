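"""Agent-based generator of ground-truth 4D oocyte dynamics.

The simulator plants the statistical structure of perinatal oocyte selection
in cultured mouse ovaries: germline-cyst breakdown into single oocytes,
per-window sacrifice (burst into oocyte debris, or shrinkage), filopodia-like
structure (FL) formation by the surviving lineage, FL-guided engulfment of
debris with cytoplasm (color) and mitochondria mixing, growth, and an
autophagy-inhibitor treatment mode that silences phagocytosis.

Fate lineage is a planted label; an oocyte only ends up *surviving* if it is
on the surviving lineage AND actually engulfed at least
``survival_min_engulfments`` debris, which the dynamics deliver.

Per-window rates (sacrifice hazards, FL exhibition) are realized by quota
sampling — round(rate x alive at window start) agents are drawn per window —
so the planted per-window frequency curves carry sampling noise only from the
observation layer, not from the generator itself.  Bridge dissolution follows
the per-bridge independent-Bernoulli contract of :func:`update_connectivity`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimConfig, window_of_frame

__all__ = [
    "OocyteState",
    "DebrisState",
    "GroundTruthLog",
    "simulate",
    "sample_debris_set",
    "update_connectivity",
    "resolve_engulfment",
    "assign_fate",
    "observe",
    "simulate_whole_ovary",
]


def _sphere_volume(d: float) -> float:
    return math.pi / 6.0 * d ** 3


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


@dataclass
class OocyteState:
    """Ground-truth record of one oocyte agent."""

    oocyte_id: int
    cyst_id: int
    position: np.ndarray           # (z, y, x) um
    diameter: float
    lineage: str                   # "surviving" | "sacrificed"
    fate: str = "candidate"
    engulf_count: int = 0
    fl_set: list = field(default_factory=list)   # [(unit direction, length um)]
    cfp: float = 0.0               # cytoplasm label fractions
    rfp: float = 0.0
    mito_density: float = 0.3
    bridge_partners: set = field(default_factory=set)
    alive: bool = True
    exit_frame: int | None = None  # observation-layer field exit

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return _sphere_volume(self.diameter)


@dataclass
class DebrisState:
    """Ground-truth record of one oocyte-debris (OD) fragment."""

    debris_id: int
    parent_id: int
    position: np.ndarray
    diameter: float
    mito_density: float
    cfp: float
    rfp: float
    status: str = "free"           # free | engulfed | decayed
    born_frame: int = 0
    target_id: int | None = None   # claimed by a surviving oocyte's FL
    engulfed_frame: int | None = None
    free_since: int = 0            # decay clock restarts when a claim is released

    @property
    def volume(self) -> float:
        return _sphere_volume(self.diameter)


class GroundTruthLog:
    """Full per-frame agent tables plus the typed event ledger."""

    def __init__(self, oocytes: pd.DataFrame, debris: pd.DataFrame,
                 events: pd.DataFrame, config: SimConfig, seed: int):
        self.oocytes = oocytes
        self.debris = debris
        self.events = events
        self.config = config
        self.seed = seed

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def final_frame(self) -> int:
        return self.n_frames - 1

    def oocyte_history(self, oocyte_id: int) -> pd.DataFrame:
        h = self.oocytes[self.oocytes.oocyte_id == oocyte_id]
        return h.sort_values("frame").reset_index(drop=True)

    def final_fates(self) -> pd.Series:
        """fate label per oocyte id, via :func:`assign_fate`."""
        out = {}
        for oid, h in self.oocytes.groupby("oocyte_id"):
            out[oid] = assign_fate(h, self.config)
        return pd.Series(out).sort_index()

    def save(self, out_dir) -> None:
        from . import io as _io
        _io.save_ground_truth(self, out_dir)


# ----------------------------------------------------------------------
# core operations, usable standalone
# ----------------------------------------------------------------------

def sample_debris_set(parent_diameter: float, config: SimConfig, rng) -> list[float]:
    """Diameters of the debris set produced by one burst.

    At least ``debris_count_min`` (>=3) fragments, each with diameter inside
    the configured truncation bounds, jointly fitting inside the parent
    sphere (excess mass is unlabeled loss).  Resamples until the volume
    constraint holds; raises after a bounded retry count.
    """
    if parent_diameter <= 0:
        raise ValueError("parent_diameter must be > 0")
    lo, hi = config.debris_diameter_range
    # a fragment is distinctly smaller than its source oocyte
    hi = max(min(hi, 0.65 * parent_diameter), lo)
    parent_vol = _sphere_volume(parent_diameter)
    mu = math.log(config.debris_diameter_median)
    sig = config.debris_diameter_sigma_log
    for _ in range(200):
        count = config.debris_count_min + int(rng.poisson(config.debris_count_extra_mean))
        diams = []
        while len(diams) < count:
            d = float(rng.lognormal(mu, sig))
            if lo <= d <= hi:
                diams.append(d)
        if sum(_sphere_volume(d) for d in diams) <= parent_vol:
            return diams
    raise RuntimeError(
        f"could not fit >= {config.debris_count_min} debris inside a "
        f"{parent_diameter:.2f} um parent after 200 attempts"
    )


def update_connectivity(cyst_graph: nx.Graph, window_index: int,
                        config: SimConfig, rng) -> list[dict]:
    """Dissolve each intercellular bridge independently with the window's
    probability; returns the bridge_dissolved event records (graph mutated)."""
    p = config.dissolution_prob(window_index)
    events = []
    for u, v in sorted(cyst_graph.edges()):
        if rng.random() < p:
            cyst_graph.remove_edge(u, v)
            events.append({"type": "bridge_dissolved", "ids": (u, v),
                           "window": window_index})
    return events


def resolve_engulfment(oocyte: OocyteState, debris: DebrisState,
                       config: SimConfig) -> dict:
    """Engulf ``debris`` into ``oocyte``: volume-weighted color and
    mitochondria mixing, diameter growth, counter increment.

    Preconditions: debris free, within capture range of the surface, and an
    FL oriented within the capture cone toward it.  Mutates both states and
    returns the event record.
    """
    if debris.status != "free":
        raise ValueError("debris already engulfed or decayed")
    gap = float(np.linalg.norm(debris.position - oocyte.position)) - oocyte.radius
    if gap > config.capture_radius + 1e-9:
        raise ValueError("debris outside capture radius")
    to_debris = _unit(debris.position - oocyte.position)
    cone = math.cos(math.radians(config.capture_cone_half_angle))
    if not any(float(np.dot(d, to_debris)) >= cone - 1e-9 for d, _ in oocyte.fl_set):
        raise ValueError("no FL oriented toward the debris")
    v_o, v_d = oocyte.volume, debris.volume
    tot = v_o + v_d
    if tot > 0 and v_d > 0:
        oocyte.cfp = (v_o * oocyte.cfp + v_d * debris.cfp) / tot
        oocyte.rfp = (v_o * oocyte.rfp + v_d * debris.rfp) / tot
        oocyte.mito_density = (v_o * oocyte.mito_density
                               + v_d * debris.mito_density) / tot
        oocyte.diameter += config.growth_per_engulfment
    oocyte.engulf_count += 1
    debris.status = "engulfed"
    return {"type": "engulfment", "oocyte_id": oocyte.oocyte_id,
            "debris_id": debris.debris_id}


def assign_fate(oocyte_history: pd.DataFrame, config: SimConfig) -> str:
    """Final fate label as a pure function of one oocyte's per-frame history.

    Death overrides everything; otherwise an oocyte is *surviving* iff it is
    on the surviving lineage and engulfed at least
    ``survival_min_engulfments`` debris by the final frame.
    """
    h = oocyte_history.sort_values("frame")
    death = h.death_mode.iloc[-1] if "death_mode" in h else None
    if isinstance(death, str) and death == "burst":
        return "sacrificed_burst"
    if isinstance(death, str) and death == "shrinkage":
        return "sacrificed_shrinkage"
    n_frames = int(round(config.duration / config.frame_interval)) + 1
    if int(h.frame.iloc[-1]) < n_frames - 1:
        return "eliminated"
    if (h.lineage.iloc[-1] == "surviving"
            and int(h.engulf_count.iloc[-1]) >= config.survival_min_engulfments):
        return "surviving"
    return "candidate"


# ----------------------------------------------------------------------
# scheduling helpers
# ----------------------------------------------------------------------

def _build_cysts(cfg: SimConfig, rng) -> list[list[int]]:
    """Partition oocyte ids into cysts by quota on the oocyte shares."""
    n = cfg.n_oocytes_init
    sizes = sorted(cfg.cyst_size_dist)
    # oocyte share of each cyst size
    w = np.array([cfg.cyst_size_dist[s] * s for s in sizes], float)
    w = w / w.sum()
    counts = {}
    assigned = 0
    for s, share in zip(sizes, w):
        k = int(round(share * n / s))
        counts[s] = k
        assigned += k * s
    # fix up remainder with singles
    counts[1] = counts.get(1, 0) + (n - assigned)
    if counts[1] < 0:  # pathological dist; drop largest cysts
        while counts[1] < 0:
            big = max(s for s in counts if s > 1 and counts[s] > 0)
            counts[big] -= 1
            counts[1] += big
    ids = list(rng.permutation(n))
    cysts, i = [], 0
    for s in sorted(counts):
        for _ in range(counts[s]):
            cysts.append([int(x) for x in ids[i:i + s]])
            i += s
    return [c for c in cysts if c]


class _Component:
    """Rigidly co-moving connected component of bridged oocytes.

    Members sit as a touching chain along ``axis``; offsets are recomputed
    from the current radii every frame so growing oocytes stay
    surface-touching instead of interpenetrating.
    """

    __slots__ = ("members", "heading", "centroid", "axis")

    def __init__(self, members, heading, centroid, axis):
        self.members = members
        self.heading = heading
        self.centroid = centroid
        self.axis = axis

    def offsets(self, oocytes) -> dict:
        if len(self.members) == 1:
            return {self.members[0]: np.zeros(3)}
        radii = [oocytes[m].radius for m in self.members]
        pos, s = [], 0.0
        for i, r in enumerate(radii):
            if i > 0:
                s += radii[i - 1] + r
            pos.append(s)
        pos = np.array(pos)
        pos -= pos.mean()
        return {m: self.axis * p for m, p in zip(self.members, pos)}


def _schedule_deaths(cfg: SimConfig, sacrificed: list[int], rng):
    """Per-window quota scheduling of sacrifice (burst/shrink) deaths."""
    windows = cfg.windows()
    nw = cfg.n_windows
    supp = cfg.treatment_burst_suppression if cfg.treated else 1.0
    pool = list(rng.permutation(sacrificed)) if sacrificed else []
    idx = 0
    alive = cfg.n_oocytes_init
    death_frame, death_mode = {}, {}

    def assign(oid, mode, w):
        a, b = windows[w]
        lo = max(a, cfg.shrink_frames + 1 if mode == "shrinkage" else 1)
        hi = max(b - 1, lo)
        f = int(rng.integers(lo, hi + 1))
        death_frame[oid] = f
        death_mode[oid] = mode

    for w in range(nw):
        h = cfg.hazard(w) * supp
        d = int(round(h * alive))
        d = min(d, len(pool) - idx)
        if d <= 0:
            continue
        nb = int(round(cfg.burst_fraction * d))
        for j in range(d):
            assign(int(pool[idx + j]), "burst" if j < nb else "shrinkage", w)
        idx += d
        alive -= d
    # cleanup: remaining sacrificed shrink away in stage windows 5-6 (c-PD3/4)
    if not cfg.treated and any(h > 0 for h in cfg.sacrifice_hazard):
        rest = [int(x) for x in pool[idx:]]
        cw = [w for w in (5, 6) if w < nw] or [nw - 1]
        for j, oid in enumerate(rest):
            assign(oid, "shrinkage", cw[j % len(cw)])
    return death_frame, death_mode


def _sample_quota(cfg: SimConfig, rng) -> int:
    """Engulfment quota of one survivor: shifted negative binomial with
    minimum survival_min_engulfments and mean target_mean_engulfments."""
    extra_mean = max(cfg.target_mean_engulfments - cfg.survival_min_engulfments, 0.0)
    if extra_mean == 0:
        return cfg.survival_min_engulfments
    r = 5.0
    p = r / (r + extra_mean)          # numpy's convention: mean = r(1-p)/p
    return cfg.survival_min_engulfments + int(rng.negative_binomial(r, p))


# ----------------------------------------------------------------------
# the simulator
# ----------------------------------------------------------------------

def simulate(config: SimConfig, seed: int | None = None) -> GroundTruthLog:
    """Run the agent-based generator and return the full ground-truth log."""
    cfg = config
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = cfg.n_oocytes_init
    n_frames = cfg.n_frames
    dt = cfg.frame_interval
    bounds = np.array([cfg.arena_z, cfg.arena_xy, cfg.arena_xy])
    windows = cfg.windows()

    # --- initial population -------------------------------------------
    cysts = _build_cysts(cfg, rng)
    lo_d, hi_d = cfg.oocyte_diameter_range
    diams = np.clip(rng.normal(cfg.oocyte_diameter_mean, cfg.oocyte_diameter_sd, n),
                    lo_d, hi_d)
    oocytes: dict[int, OocyteState] = {}
    graph = nx.Graph()
    comps: list[_Component] = []
    margin = 14.0
    for cyst_id, members in enumerate(cysts):
        centroid = np.array([
            rng.uniform(min(margin, bounds[0] / 2), max(bounds[0] - margin, bounds[0] / 2)),
            rng.uniform(margin, bounds[1] - margin),
            rng.uniform(margin, bounds[2] - margin),
        ])
        for m in members:
            graph.add_node(m)
            oocytes[m] = OocyteState(
                oocyte_id=m, cyst_id=cyst_id, position=centroid.copy(),
                diameter=float(diams[m]), lineage="sacrificed",
                mito_density=float(np.clip(
                    rng.normal(cfg.mito_oocyte_mean, cfg.mito_oocyte_sd), 0.01, 0.95)),
            )
        for u, v in zip(members[:-1], members[1:]):
            graph.add_edge(u, v)
            oocytes[u].bridge_partners.add(v)
            oocytes[v].bridge_partners.add(u)
        comp = _Component(list(members), _random_unit(rng), centroid.copy(),
                          _random_unit(rng))
        for m, off in comp.offsets(oocytes).items():
            oocytes[m].position = centroid + off
        comps.append(comp)

    if cfg.color_mode == "rainbow":
        for oid in sorted(oocytes):
            if rng.random() < 0.5:
                oocytes[oid].cfp = 1.0
            else:
                oocytes[oid].rfp = 1.0

    # --- planted lineage, deaths, exits, FL schedule, quotas ----------
    n_surv = int(round(cfg.survival_fraction * n))
    survivors = sorted(int(x) for x in rng.choice(n, size=n_surv, replace=False))
    for s in survivors:
        oocytes[s].lineage = "surviving"
    sacrificed = [i for i in range(n) if i not in set(survivors)]

    death_frame, death_mode = _schedule_deaths(cfg, sacrificed, rng)

    n_exit = int(round(cfg.exit_prob * n))
    exit_ids = [int(x) for x in rng.choice(n, size=n_exit, replace=False)]
    exit_frame: dict[int, int] = {}
    for oid in exit_ids:
        hi = n_frames - 12
        if hi <= 9:
            continue
        f = int(rng.integers(8, hi))
        # exits before the scheduled death censor the death
        exit_frame[oid] = f
        oocytes[oid].exit_frame = f

    fl_stretch: dict[int, list[tuple[int, int]]] = {s: [] for s in survivors}
    quota = {s: _sample_quota(cfg, rng) for s in survivors}
    growth_mult = {i: max(0.0, 1.0 + cfg.growth_rate_cv * rng.normal())
                   for i in range(n)}

    # shrink phase bookkeeping
    shrink_start = {oid: death_frame[oid] - cfg.shrink_frames
                    for oid, m in death_mode.items() if m == "shrinkage"}

    # --- state ---------------------------------------------------------
    debris: dict[int, DebrisState] = {}
    next_debris_id = 0
    oo_rows, od_rows, ev_rows = [], [], []
    inbound: dict[int, list[int]] = {s: [] for s in survivors}
    last_capture: dict[int, int] = {}

    def fl_active(oid: int, f: int) -> bool:
        return any(a <= f < b for a, b in fl_stretch.get(oid, []))

    def _select_exhibitors(w: int, f: int) -> None:
        a_w, b_w = windows[w]
        span = b_w - a_w
        supp = cfg.treatment_fl_suppression if cfg.treated else 1.0
        alive_now = sum(1 for oid in oocytes if oocytes[oid].alive)
        k = int(round(cfg.fl_prob(w) * alive_now * supp))
        eligible = [s for s in survivors
                    if oocytes[s].alive and observed(s, f)]
        if eligible and k > 0:
            order = sorted(eligible, key=lambda s: (
                0 if oocytes[s].engulf_count < cfg.survival_min_engulfments
                else 1,
                oocytes[s].engulf_count, rng.random()))
            for s in order[:min(k, len(eligible))]:
                start = f + int(rng.integers(0, 3))
                fl_stretch[s].append((start, b_w))
        if w >= 5 and not cfg.treated:
            # post-peak survival pressure: judged on realized engulfments
            # only, since in-flight claims may still fail
            for s in eligible:
                if (oocytes[s].engulf_count < cfg.survival_min_engulfments
                        and not any(a < b_w and b > f for a, b in fl_stretch[s])):
                    fl_stretch[s].append((f, b_w))
        # FLs retract at the stage transition: survivors not exhibiting in
        # the new window release their in-flight debris (re-claimable)
        for s in survivors:
            if inbound[s] and not any(a <= f + 2 and f < b
                                      for a, b in fl_stretch[s] if b > f):
                for did in inbound[s]:
                    if debris[did].status == "free":
                        debris[did].target_id = None
                        debris[did].free_since = f
                inbound[s] = []

    def observed(oid: int, f: int) -> bool:
        ef = exit_frame.get(oid)
        return ef is None or f < ef

    def record_frame(f: int):
        for oid in sorted(oocytes):
            o = oocytes[oid]
            if not o.alive:
                continue
            fl_len = ";".join(f"{l:.3f}" for _, l in o.fl_set)
            oo_rows.append((f, oid, o.cyst_id, *o.position, o.diameter,
                            o.lineage, o.engulf_count, len(o.fl_set), fl_len,
                            o.cfp, o.rfp, o.mito_density,
                            len(o.bridge_partners), observed(oid, f), ""))
        for did in sorted(debris):
            d = debris[did]
            if d.status == "decayed":
                continue
            if d.status == "engulfed" and d.engulfed_frame != f:
                continue
            od_rows.append((f, did, d.parent_id, *d.position, d.diameter,
                            d.mito_density, d.cfp, d.rfp, d.status, True))

    def emit(f, etype, **kw):
        ev_rows.append({"frame": f, "type": etype, **kw})

    def rebuild_components_after():
        """Recompute components after bridge removal/death, keeping positions."""
        nonlocal comps
        new = []
        for cc in nx.connected_components(graph):
            members = sorted(cc)
            pos = np.array([oocytes[m].position for m in members])
            centroid = pos.mean(axis=0)
            if len(members) > 1:
                # chain axis from the two farthest members; order along it
                d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
                i, j = np.unravel_index(np.argmax(d2), d2.shape)
                axis = _unit(pos[j] - pos[i])
                if not np.any(np.abs(pos[j] - pos[i]) > 1e-9):
                    axis = _random_unit(rng)
                proj = (pos - centroid) @ axis
                members = [m for _, m in sorted(zip(proj, members))]
            else:
                axis = _random_unit(rng)
            new.append(_Component(members, _random_unit(rng), centroid, axis))
        comps = new

    record_frame(0)
    _select_exhibitors(0, 0)

    cone = math.cos(math.radians(cfg.capture_cone_half_angle))
    step_len = cfg.motion_speed * dt
    home_step = cfg.debris_homing_speed * dt
    wander_step = cfg.debris_speed * dt
    lifetime_frames = int(round(cfg.debris_lifetime / dt))

    nw = cfg.n_windows
    for f in range(1, n_frames):
        w = min(window_of_frame(f, dt), nw - 1)
        prev_w = min(window_of_frame(f - 1, dt), nw - 1)

        # 1. cyst breakdown at window boundaries -----------------------
        if w > prev_w and graph.number_of_edges() > 0:
            evs = update_connectivity(graph, prev_w, cfg, rng)
            if evs:
                for e in evs:
                    u, v = e["ids"]
                    oocytes[u].bridge_partners.discard(v)
                    oocytes[v].bridge_partners.discard(u)
                    emit(f, "bridge_dissolved", ids=f"{u};{v}",
                         observable=observed(u, f) and observed(v, f))
                rebuild_components_after()

        # 1b. FL exhibition for this stage window: round(prob x alive)
        # surviving-lineage oocytes exhibit FLs, drawn preferring those
        # still below the survival minimum, then the least-fed, so the
        # planted per-window FL frequency also delivers the engulfment
        # quotas.  Post-peak, a still-hungry survivor keeps reaching
        # (absent under phagocytosis blockade).
        if w > prev_w:
            _select_exhibitors(w, f)

        # 2. oocyte motion (rigid per connected component) -------------
        for c in comps:
            if not any(oocytes[m].alive for m in c.members):
                continue
            c.heading = _unit(cfg.heading_persistence * c.heading
                              + (1 - cfg.heading_persistence) * _random_unit(rng))
            c.centroid = c.centroid + step_len * c.heading
            for ax in range(3):
                m = min(margin, 0.2 * bounds[ax])
                lo, hi = m, bounds[ax] - m
                if lo >= hi:
                    c.centroid[ax] = bounds[ax] / 2
                    continue
                # reflective walls: flip the heading and return gently so a
                # component never teleports (bounded correction per frame)
                if c.centroid[ax] < lo:
                    c.heading[ax] = abs(c.heading[ax])
                    c.centroid[ax] = min(c.centroid[ax] + 2.0, lo)
                elif c.centroid[ax] > hi:
                    c.heading[ax] = -abs(c.heading[ax])
                    c.centroid[ax] = max(c.centroid[ax] - 2.0, hi)
            offs = c.offsets(oocytes)
            for m in c.members:
                o = oocytes[m]
                if o.alive:
                    o.position = (c.centroid + offs[m]
                                  + rng.normal(0, cfg.position_jitter, 3))

        # 2b. excluded volume: push apart overlapping components so two
        # oocytes never deeply interpenetrate (max 1.5 um correction per
        # frame to stay within the tracking gate)
        alive_ids = [oid for oid in sorted(oocytes) if oocytes[oid].alive]
        if len(alive_ids) > 1:
            pos_arr = np.array([oocytes[i].position for i in alive_ids])
            rad_arr = np.array([oocytes[i].radius for i in alive_ids])
            comp_of = {}
            for ci, c in enumerate(comps):
                for m in c.members:
                    comp_of[m] = ci
            diff = pos_arr[:, None, :] - pos_arr[None, :, :]
            dist = np.sqrt((diff ** 2).sum(-1))
            overlap = rad_arr[:, None] + rad_arr[None, :] - dist
            ii, jj = np.nonzero(np.triu(overlap > 0.5, k=1))
            shift: dict[int, np.ndarray] = {}
            for i, j in zip(ii, jj):
                a, b = alive_ids[int(i)], alive_ids[int(j)]
                ca, cb = comp_of.get(a), comp_of.get(b)
                if ca is None or cb is None or ca == cb:
                    continue
                push = min(float(overlap[i, j]) / 2, 1.5)
                u = _unit(pos_arr[i] - pos_arr[j])
                shift[ca] = shift.get(ca, 0.0) + push * u
                shift[cb] = shift.get(cb, 0.0) - push * u
            for ci, s in shift.items():
                comps[ci].centroid = comps[ci].centroid + s
                for m in comps[ci].members:
                    if oocytes[m].alive:
                        oocytes[m].position = oocytes[m].position + s

        # 3. scheduled deaths ------------------------------------------
        dead_now = []
        for oid, fd in death_frame.items():
            o = oocytes[oid]
            if not o.alive:
                continue
            if death_mode[oid] == "shrinkage":
                if shrink_start[oid] <= f < fd:
                    o.diameter = max(o.diameter * cfg.shrink_factor, 0.5)
                elif f >= fd:
                    o.alive = False
                    o.fate = "sacrificed_shrinkage"
                    emit(f, "shrinkage_death", oocyte_id=oid,
                         observable=observed(oid, f))
                    dead_now.append(oid)
            elif death_mode[oid] == "burst" and f >= fd:
                diams_d = sample_debris_set(o.diameter, cfg, rng)
                for dd in diams_d:
                    u = _random_unit(rng)
                    pos = o.position + u * (0.6 * o.radius)
                    lo_m, hi_m = cfg.mito_debris_range
                    debris[next_debris_id] = DebrisState(
                        debris_id=next_debris_id, parent_id=oid,
                        position=pos, diameter=dd,
                        mito_density=float(rng.uniform(lo_m, hi_m)),
                        cfp=o.cfp, rfp=o.rfp, born_frame=f)
                    next_debris_id += 1
                o.alive = False
                o.fate = "sacrificed_burst"
                emit(f, "burst", oocyte_id=oid, count=len(diams_d),
                     observable=observed(oid, f))
                dead_now.append(oid)
        if dead_now:
            for oid in dead_now:
                for p in list(oocytes[oid].bridge_partners):
                    graph.remove_edge(oid, p)
                    oocytes[p].bridge_partners.discard(oid)
                    oocytes[oid].bridge_partners.discard(p)
            rebuild_components_after()

        # 4. debris motion, capture, decay -----------------------------
        # engulfment is a sequential enclose-and-disappear behavior: one
        # capture per oocyte every 2 frames; later arrivals hold just
        # outside the membrane until their turn
        for did in sorted(debris):
            d = debris[did]
            if d.status != "free":
                continue
            tgt = d.target_id
            if tgt is not None:
                o = oocytes[tgt]
                to_o = o.position - d.position
                gap = float(np.linalg.norm(to_o)) - o.radius
                crowded = any(
                    did2 != did and debris[did2].status == "free"
                    and float(np.linalg.norm(debris[did2].position
                                             - d.position)) < 8.0
                    for did2 in inbound.get(tgt, []))
                if (gap <= cfg.capture_radius
                        and (f - last_capture.get(tgt, -99) >= 2
                             or not crowded)):
                    last_capture[tgt] = f
                    # the FL tracks its debris continuously; refresh its
                    # direction at the enclose step
                    u_d = _unit(d.position - o.position)
                    length = float(np.clip(gap, cfg.fl_length_min,
                                           cfg.fl_length_max))
                    o.fl_set = [fl for fl in o.fl_set] + [(u_d, length)]
                    resolve_engulfment(o, d, cfg)
                    # enclose: last observable position is inside the oocyte
                    depth = max(o.radius - 2.0, 0.3 * o.radius)
                    d.position = o.position - _unit(to_o) * depth
                    d.engulfed_frame = f
                    if did in inbound.get(tgt, []):
                        inbound[tgt].remove(did)
                    emit(f, "engulfment", oocyte_id=tgt, debris_id=did,
                         observable=observed(tgt, f))
                else:
                    # approach, then hold just outside the membrane until a
                    # capture slot frees up (enclosure is the capture step);
                    # the hold distance is maintained as the oocyte grows
                    step = float(np.clip(gap - (cfg.capture_radius - 0.4),
                                         -2.0, home_step))
                    d.position = d.position + _unit(to_o) * step
            else:
                d.position = d.position + _random_unit(rng) * wander_step
                if f - max(d.born_frame, d.free_since) > lifetime_frames:
                    d.status = "decayed"

        # free debris sit between oocytes, never inside one
        wander_ids = [did for did in sorted(debris)
                      if debris[did].status == "free"
                      and debris[did].target_id is None]
        if wander_ids and alive_ids:
            dpos = np.array([debris[did].position for did in wander_ids])
            opos = np.array([oocytes[i].position for i in alive_ids])
            orad = np.array([oocytes[i].radius for i in alive_ids])
            diff = dpos[:, None, :] - opos[None, :, :]
            dist = np.sqrt((diff ** 2).sum(-1))
            depth = orad[None, :] - dist
            nearest = np.argmax(depth, axis=1)
            for k, did in enumerate(wander_ids):
                dep = float(depth[k, nearest[k]])
                if dep > -2.5:
                    away = diff[k, nearest[k]]
                    debris[did].position = (debris[did].position
                                            + _unit(away) * min(dep + 2.5, 2.0))

        # drop stale claims from exited/dead targets
        for s in survivors:
            ef = exit_frame.get(s)
            if ef is not None and f >= ef and inbound[s]:
                for did in inbound[s]:
                    if debris[did].status == "free":
                        debris[did].target_id = None
                        debris[did].free_since = f
                inbound[s] = []

        # 5. FL-guided claiming ----------------------------------------
        # Claims only during a survivor's FL-active frames, with reach
        # limited so the approach finishes inside the current stage window.
        # Round-robin so no oocyte hoards the free debris: one claim per
        # eligible survivor per round, concurrent inbound capped.
        a_w, b_w = windows[w]
        free_ids = [did for did in sorted(debris)
                    if debris[did].status == "free" and debris[did].target_id is None]
        if free_ids:
            free_pos = np.array([debris[did].position for did in free_ids])
            frames_left_window = max(b_w - f - 1, 0)
            frames_left_run = max(n_frames - f - 2, 0)
            inbound_cap = 8
            window_range = min(cfg.attraction_radius,
                               frames_left_window * home_step + cfg.capture_radius)

            # phagocytosis blockade disables the capture machinery: the few
            # FLs that still form are exploratory and recruit nothing
            claimers = []
            for s in survivors if not cfg.treated else ():
                o = oocytes[s]
                if not (o.alive and observed(s, f) and fl_active(s, f)):
                    continue
                if o.engulf_count + len(inbound[s]) >= quota[s]:
                    continue
                if o.engulf_count < cfg.survival_min_engulfments:
                    # survival pressure: a hungry FL keeps its reach even
                    # when the approach will cross into the next window
                    rr = min(cfg.attraction_radius,
                             frames_left_run * home_step + cfg.capture_radius)
                else:
                    rr = window_range
                if rr > 0:
                    claimers.append((s, rr))
            claimers.sort(key=lambda sr: (
                0 if oocytes[sr[0]].engulf_count + len(inbound[sr[0]])
                < cfg.survival_min_engulfments else 1, rng.random()))
            taken: set[int] = set()
            progressed = True
            while progressed and len(taken) < len(free_ids):
                progressed = False
                for s, rr in claimers:
                    o = oocytes[s]
                    if (o.engulf_count + len(inbound[s]) >= quota[s]
                            or len(inbound[s]) >= inbound_cap):
                        continue
                    dists = np.linalg.norm(free_pos - o.position, axis=1) - o.radius
                    best_j, best_d = -1, rr
                    for j in np.argsort(dists):
                        if j in taken:
                            continue
                        if dists[j] > rr:
                            break
                        best_j, best_d = int(j), dists[j]
                        break
                    if best_j >= 0:
                        did = free_ids[best_j]
                        debris[did].target_id = s
                        inbound[s].append(did)
                        taken.add(best_j)
                        progressed = True

        # 6. FL bookkeeping --------------------------------------------
        for oid in sorted(oocytes):
            o = oocytes[oid]
            if not o.alive:
                o.fl_set = []
                continue
            had = bool(o.fl_set)
            fls = []
            if oid in quota and (fl_active(oid, f) or inbound[oid]):
                if inbound[oid]:
                    for did in inbound[oid]:
                        d = debris[did]
                        u = _unit(d.position - o.position)
                        gap = float(np.linalg.norm(d.position - o.position)) - o.radius
                        length = float(np.clip(gap, cfg.fl_length_min,
                                               cfg.fl_length_max))
                        fls.append((u, length))
                else:
                    u = _random_unit(rng)
                    length = float(rng.triangular(cfg.fl_length_min,
                                                  cfg.fl_length_mode,
                                                  cfg.fl_length_max))
                    fls.append((u, length))
            o.fl_set = fls
            if fls and not had:
                emit(f, "fl_appeared", oocyte_id=oid,
                     length=max(l for _, l in fls),
                     observable=observed(oid, f))

        # 7. growth -----------------------------------------------------
        for oid in sorted(oocytes):
            o = oocytes[oid]
            if not o.alive or oid in shrink_start and f >= shrink_start[oid]:
                continue
            if cfg.treated:
                o.diameter += cfg.treated_growth_rate * growth_mult[oid] * dt
            elif o.lineage == "surviving":
                o.diameter += cfg.survivor_growth_rate * growth_mult[oid] * dt

        record_frame(f)

    # --- finalize -------------------------------------------------------
    for oid in sorted(oocytes):
        o = oocytes[oid]
        if o.alive:
            if (o.lineage == "surviving"
                    and o.engulf_count >= cfg.survival_min_engulfments):
                o.fate = "surviving"
            else:
                o.fate = "candidate"

    oo = pd.DataFrame(oo_rows, columns=[
        "frame", "oocyte_id", "cyst_id", "z", "y", "x", "diameter", "lineage",
        "engulf_count", "n_fl", "fl_lengths", "cfp", "rfp", "mito_density",
        "n_bridges", "observed", "death_mode"])
    # annotate terminal death mode on each oocyte's last row
    if death_mode:
        last_idx = oo.groupby("oocyte_id")["frame"].idxmax()
        for oid, mode in death_mode.items():
            if oid in last_idx.index and oocytes[oid].fate.startswith("sacrificed"):
                oo.loc[last_idx[oid], "death_mode"] = mode
    od = pd.DataFrame(od_rows, columns=[
        "frame", "debris_id", "parent_id", "z", "y", "x", "diameter",
        "mito_density", "cfp", "rfp", "status", "observed"])
    ev = pd.DataFrame(ev_rows)
    if ev.empty:
        ev = pd.DataFrame(columns=["frame", "type", "oocyte_id", "debris_id",
                                   "count", "ids", "length", "observable"])
    return GroundTruthLog(oo, od, ev, cfg, seed)


# ----------------------------------------------------------------------
# observation layer (agent-level measurement path)
# ----------------------------------------------------------------------

def observe(log: GroundTruthLog, contact_gap: float = 0.8) -> pd.DataFrame:
    """Project the ground-truth log into per-frame measured object tables.

    Emulates ideal per-frame detection on the agent level: positions,
    equivalent diameters, size class, FL lengths, channel means (percent of
    label), mitochondria density and contact ids.  Oocytes that moved out of
    the field stop being observed at their exit frame; the ``agent_id``
    column is carried along solely as a ground-truth oracle for validation
    and is never used by the tracker.
    """
    rows = []
    object_id = 0
    oo = log.oocytes[log.oocytes.observed]
    od = log.debris[log.debris.observed] if len(log.debris) else log.debris
    for frame in range(log.n_frames):
        frame_rows = []
        foo = oo[oo.frame == frame]
        for r in foo.itertuples():
            frame_rows.append({
                "frame": frame, "object_id": object_id,
                "z": r.z, "y": r.y, "x": r.x,
                "equivalent_diameter": r.diameter,
                "volume": _sphere_volume(r.diameter),
                "cls": classify_diameter(r.diameter),
                "fl_lengths": r.fl_lengths,
                "cfp_mean": 100.0 * r.cfp, "rfp_mean": 100.0 * r.rfp,
                "mito_density": r.mito_density,
                "contact_ids": "", "agent_id": f"o{r.oocyte_id}",
            })
            object_id += 1
        if len(od):
            fod = od[od.frame == frame]
            for r in fod.itertuples():
                frame_rows.append({
                    "frame": frame, "object_id": object_id,
                    "z": r.z, "y": r.y, "x": r.x,
                    "equivalent_diameter": r.diameter,
                    "volume": _sphere_volume(r.diameter),
                    "cls": classify_diameter(r.diameter),
                    "fl_lengths": "",
                    "cfp_mean": 100.0 * r.cfp, "rfp_mean": 100.0 * r.rfp,
                    "mito_density": r.mito_density,
                    "contact_ids": "", "agent_id": f"d{r.debris_id}",
                })
                object_id += 1
        # contacts: surface gap below threshold
        if len(frame_rows) > 1:
            pos = np.array([[rr["z"], rr["y"], rr["x"]] for rr in frame_rows])
            rad = np.array([rr["equivalent_diameter"] / 2 for rr in frame_rows])
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.sqrt((diff ** 2).sum(-1))
            gap = dist - rad[:, None] - rad[None, :]
            np.fill_diagonal(gap, np.inf)
            for i, rr in enumerate(frame_rows):
                nbr = np.nonzero(gap[i] <= contact_gap)[0]
                rr["contact_ids"] = ";".join(
                    str(frame_rows[j]["object_id"]) for j in nbr)
        rows.extend(frame_rows)
    return pd.DataFrame(rows)


def classify_diameter(d: float, od_range: tuple[float, float] = (1.2, 14.0),
                      min_object: float = 1.2) -> str:
    """Size rule: OD in [1.2, 14) um, oocyte >= 14 um, discard below."""
    if d < min_object:
        return "discard"
    if od_range[0] <= d < od_range[1]:
        return "OD"
    return "oocyte"


# ----------------------------------------------------------------------
# whole-ovary (stereology) mode
# ----------------------------------------------------------------------

def simulate_whole_ovary(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Endpoint (c-PD4) oocyte population of a whole ovary.

    The live-imaging runs cover labeled subfields; the whole organ carries
    its own planted death fraction (see docs).  Returns one row per
    surviving oocyte with its 3D centroid and diameter, for the virtual
    serial-sectioning estimator.
    """
    cfg = config
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    d = cfg.ovary_death_fraction
    if cfg.treated:
        d = d * cfg.treatment_burst_suppression
    n_alive = int(round(cfg.ovary_n_oocytes * (1.0 - d)))
    sz = np.array(cfg.ovary_size)
    pos = rng.uniform(0, 1, size=(n_alive, 3)) * sz
    if cfg.treated:
        diam = np.clip(rng.normal(26.0, 3.0, n_alive), 12, 45)
    else:
        diam = np.clip(rng.normal(32.0, 4.0, n_alive), 14, 55)
    return pd.DataFrame({
        "oocyte_id": np.arange(n_alive),
        "z": pos[:, 0], "y": pos[:, 1], "x": pos[:, 2],
        "diameter": diam,
    })
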