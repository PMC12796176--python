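"""Population statistics of 4D oocyte-selection imaging.

All windowed ratios follow the counting convention of the source assays:
each 24 h interval is a separate imaging unit, and the denominator is the
number of oocytes alive at the start of the interval.  Percentages are
reported to one decimal, diameters to one decimal micrometre.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DetectionParams, TrackParams, stage_label
from .track import infer_connected

__all__ = [
    "StageStats",
    "FateSummary",
    "StereologyInput",
    "alive_oocytes_at",
    "compute_single_ratio",
    "compute_event_frequencies",
    "find_peak_window",
    "replicate_fates",
    "compute_survival_ratio",
    "engulfment_fate_stats",
    "compute_purple_ratio",
    "measure_growth",
    "final_mean_diameter",
    "stereology_total_mitochondria",
    "section_count_estimate",
    "cluster_fraction",
    "stage_stats",
]


@dataclass
class StageStats:
    """Per-window population statistics."""

    window: int
    label: str
    n_start: int
    single_ratio: float = math.nan
    fl_ratio: float = math.nan
    od_event_freq: float = math.nan
    death_freq: float = math.nan
    purple_ratio: float = math.nan
    mean_diameter: float = math.nan
    sd_diameter: float = math.nan


@dataclass
class FateSummary:
    """Survival and engulfment-fate summary over replicate ovaries."""

    survival_ratio_mean: float
    survival_ratio_sd: float
    per_replicate: list[float]
    survivor_engulf_counts: list[int]
    min_engulfments: float
    mean_engulfments: float
    contingency: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class StereologyInput:
    """Inputs of the total-mitochondria estimator.

    Voo = 4/3 pi R^3 and Sloo = pi R^2 are derived from the mean oocyte
    radius; Nmit_total = Voo / (Sloo * Dave_mit) * Nmit_s.
    """

    Rave_oo: float      # mean oocyte radius, um
    Dave_mit: float     # mean mitochondrion diameter, um
    Nmit_s: float       # mitochondria in the maximal-nucleus cross-section

    def __post_init__(self):
        if self.Rave_oo <= 0 or self.Dave_mit <= 0 or self.Nmit_s < 0:
            raise ValueError("stereology inputs must be positive (Nmit_s >= 0)")

    @property
    def Voo(self) -> float:
        return 4.0 / 3.0 * math.pi * self.Rave_oo ** 3

    @property
    def Sloo(self) -> float:
        return math.pi * self.Rave_oo ** 2

    @property
    def Nmit_total(self) -> float:
        return self.Voo / (self.Sloo * self.Dave_mit) * self.Nmit_s


def alive_oocytes_at(summary: pd.DataFrame, frame: int) -> pd.DataFrame:
    oo = summary[summary.kind == "oocyte"]
    return oo[(oo.start <= frame) & (oo.end >= frame)]


# ----------------------------------------------------------------------
# single-oocyte fraction
# ----------------------------------------------------------------------

def compute_single_ratio(tracks: pd.DataFrame, summary: pd.DataFrame,
                         contacts: pd.DataFrame, window: tuple[int, int],
                         params: TrackParams | None = None) -> float:
    """Fraction of single oocytes in a 24 h window.

    Numerator: oocytes alive at window start that are not motion-correlation
    connected (:func:`infer_connected`) to any contact partner during the
    window.  Oocytes whose every contacting pair is indeterminate are
    excluded from numerator and denominator; transient (<2 frame) contacts
    count as no contact.
    """
    params = params or TrackParams()
    a, b = window
    if b <= a:
        raise ValueError("empty window")
    alive = alive_oocytes_at(summary, a)
    if alive.empty:
        raise ValueError("no oocytes alive at window start")
    oo_ids = set(alive.track_id)
    by_tid = {tid: g for tid, g in tracks.groupby("track_id") if tid in oo_ids}

    verdicts: dict[int, list] = defaultdict(list)
    if len(contacts):
        cw = contacts[(contacts.frame >= a) & (contacts.frame < b)]
        for (ta, tb), g in cw.groupby(["track_a", "track_b"]):
            if ta not in oo_ids or tb not in oo_ids:
                continue
            if len(g) < params.k_min_frames:
                # transient touch: bridged oocytes stay in contact for most
                # of a window, so a brief contact is evidence of
                # independence, not an unresolvable connection
                continue
            res = infer_connected(by_tid[ta], by_tid[tb], window,
                                  set(g.frame), params)
            verdicts[ta].append(res)
            verdicts[tb].append(res)

    single = 0
    denom = 0
    for tid in oo_ids:
        vs = verdicts.get(tid, [])
        if vs and all(v is None for v in vs):
            continue  # indeterminate only: excluded from both counts
        denom += 1
        if not any(v is True for v in vs):
            single += 1
    if denom == 0:
        raise ValueError("all oocytes indeterminate in window")
    return single / denom


# ----------------------------------------------------------------------
# per-window event frequencies
# ----------------------------------------------------------------------

def _track_has_fl(objects: pd.DataFrame, tracks: pd.DataFrame,
                  window: tuple[int, int]) -> set[int]:
    """Track ids showing >= 1 FL during the window."""
    if "fl_lengths" not in objects.columns:
        return set()
    a, b = window
    w_obj = objects[(objects.frame >= a) & (objects.frame < b)]
    w_obj = w_obj[w_obj.fl_lengths.astype(str).str.len() > 0]
    if w_obj.empty:
        return set()
    obj2track = dict(zip(tracks.object_id, tracks.track_id))
    return {obj2track[o] for o in w_obj.object_id if o in obj2track}


def compute_event_frequencies(tracks: pd.DataFrame, summary: pd.DataFrame,
                              events: pd.DataFrame, objects: pd.DataFrame,
                              windows: list[tuple[int, int]]) -> pd.DataFrame:
    """Per-window FL ratio, OD-formation (burst) frequency and death frequency.

    FL ratio: oocytes with >= 1 FL in the window / oocytes at window start.
    OD-event frequency: cell bursts in the window / oocytes at window start.
    Death frequency: bursts + shrinkage deaths / oocytes at window start.
    """
    rows = []
    for w, (a, b) in enumerate(windows):
        alive = alive_oocytes_at(summary, a)
        n0 = len(alive)
        if n0 == 0:
            rows.append((w, stage_label(w), 0, math.nan, math.nan, math.nan))
            continue
        ev_w = events[(events.frame >= a) & (events.frame < b)] if len(events) else events
        bursts = len(ev_w[ev_w.type == "burst"]) if len(ev_w) else 0
        shrinks = len(ev_w[ev_w.type == "shrinkage_death"]) if len(ev_w) else 0
        fl_tracks = _track_has_fl(objects, tracks, (a, b))
        fl_n = len(fl_tracks & set(alive.track_id))
        rows.append((w, stage_label(w), n0, fl_n / n0, bursts / n0,
                     (bursts + shrinks) / n0))
    return pd.DataFrame(rows, columns=["window", "label", "n_start",
                                       "fl_ratio", "od_event_freq", "death_freq"])


def find_peak_window(freqs) -> tuple[int, int] | None:
    """Maximal contiguous span of windows with frequency >= 80% of the
    series maximum; ties resolved toward the earlier span.  All-zero
    series -> None (empty span).  Returns inclusive (start, end) indices."""
    f = np.asarray(list(freqs), float)
    if len(f) < 1 or np.all(np.nan_to_num(f) <= 0):
        return None
    thr = 0.8 * np.nanmax(f)
    mask = np.nan_to_num(f) >= thr
    best = None
    i = 0
    while i < len(f):
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < len(f) and mask[j]:
            j += 1
        if best is None or (j - i) > (best[1] - best[0] + 1):
            best = (i, j - 1)
        i = j
    return best


# ----------------------------------------------------------------------
# survival and engulfment-fate statistics
# ----------------------------------------------------------------------

def replicate_fates(tracks: pd.DataFrame, summary: pd.DataFrame,
                    events: pd.DataFrame) -> dict:
    """Per-replicate fate accounting on measured tracks.

    Complete tracks start at frame 0 and either die by a classified mode or
    reach the final frame; survivors are complete oocyte tracks alive at the
    final frame.  Engulfment counts come from the called engulfment events.
    """
    oo = summary[summary.kind == "oocyte"]
    complete = oo[oo.complete]
    survivors = complete[complete.end_reason == "alive_at_end"]
    eng = events[events.type == "engulfment"] if len(events) else events
    counts = {tid: 0 for tid in survivors.track_id}
    if len(eng):
        for tid, g in eng.groupby("track_a"):
            if tid in counts:
                counts[tid] = len(g)
    deaths = complete[complete.end_reason.isin(["burst", "shrinkage"])]
    return {
        "n_complete": len(complete),
        "n_survivors": len(survivors),
        "survivor_tracks": list(survivors.track_id),
        "engulf_counts": [counts[t] for t in survivors.track_id],
        "n_burst_deaths": int((deaths.end_reason == "burst").sum()),
        "n_shrink_deaths": int((deaths.end_reason == "shrinkage").sum()),
    }


def compute_survival_ratio(replicates: list[dict]) -> FateSummary:
    """Mean +- SD survival ratio over replicate ovaries, with pooled
    per-survivor engulfment counts.  Replicates without complete tracks are
    dropped (with a warning)."""
    import warnings
    ratios, pooled = [], []
    for rep in replicates:
        if rep["n_complete"] < 1:
            warnings.warn("replicate without complete tracks dropped")
            continue
        ratios.append(rep["n_survivors"] / rep["n_complete"])
        pooled.extend(rep["engulf_counts"])
    if not ratios:
        raise ValueError("no replicate with complete tracks")
    mn, mean = engulfment_fate_stats(pooled)[:2]
    bins = [0, 1, 5, 10, 15, 20, 30, 10 ** 9]
    tbl = pd.DataFrame({
        "engulfment_bin": [f"[{a},{b})" for a, b in zip(bins[:-1], bins[1:])],
        "survivors": np.histogram(pooled, bins=bins)[0] if pooled else 0,
    })
    return FateSummary(
        survival_ratio_mean=float(np.mean(ratios)),
        survival_ratio_sd=float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
        per_replicate=ratios,
        survivor_engulf_counts=pooled,
        min_engulfments=mn,
        mean_engulfments=mean,
        contingency=tbl,
    )


def engulfment_fate_stats(counts) -> tuple[float, float, pd.Series]:
    """min and mean engulfments among survivors plus the count distribution;
    (nan, nan) when there are no survivors."""
    counts = list(counts)
    if not counts:
        return math.nan, math.nan, pd.Series(dtype=int)
    return (float(min(counts)), float(np.mean(counts)),
            pd.Series(counts).value_counts().sort_index())


# ----------------------------------------------------------------------
# cytoplasm-color (rainbow) statistics
# ----------------------------------------------------------------------

def compute_purple_ratio(objects: pd.DataFrame, tracks: pd.DataFrame,
                         summary: pd.DataFrame, windows: list[tuple[int, int]],
                         params: DetectionParams | None = None) -> pd.DataFrame:
    """Per-window fraction of oocytes with mixed (purple) cytoplasm.

    An oocyte counts as purple in a window if any of its frames in that
    window shows min(CFP,RFP)/max(CFP,RFP) >= the purple threshold;
    denominator is oocytes alive at window start.  Raises on non-rainbow
    input (no CFP/RFP signal anywhere).
    """
    params = params or DetectionParams()
    if "cfp_mean" not in objects.columns or (
            objects.cfp_mean.max() <= 0 and objects.rfp_mean.max() <= 0):
        raise ValueError("purple ratio requires rainbow-mode (CFP/RFP) input")
    obj2track = dict(zip(tracks.object_id, tracks.track_id))
    lo = np.minimum(objects.cfp_mean, objects.rfp_mean)
    hi = np.maximum(objects.cfp_mean, objects.rfp_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(hi > params.channel_background, lo / hi, 0.0)
    purple_obj = objects[ratio >= params.purple_ratio_threshold]
    rows = []
    for w, (a, b) in enumerate(windows):
        alive = alive_oocytes_at(summary, a)
        n0 = len(alive)
        if n0 == 0:
            rows.append((w, stage_label(w), 0, math.nan))
            continue
        po = purple_obj[(purple_obj.frame >= a) & (purple_obj.frame < b)]
        ptracks = {obj2track[o] for o in po.object_id if o in obj2track}
        rows.append((w, stage_label(w), n0,
                     len(ptracks & set(alive.track_id)) / n0))
    return pd.DataFrame(rows, columns=["window", "label", "n_start", "purple_ratio"])


# ----------------------------------------------------------------------
# growth
# ----------------------------------------------------------------------

def measure_growth(tracks: pd.DataFrame, summary: pd.DataFrame,
                   windows: list[tuple[int, int]]) -> pd.DataFrame:
    """Mean +- SD oocyte diameter at each window start (alive oocytes)."""
    rows = []
    state = {tid: g.set_index("frame") for tid, g in tracks.groupby("track_id")}
    for w, (a, b) in enumerate(windows):
        alive = alive_oocytes_at(summary, a)
        ds = []
        for tid in alive.track_id:
            g = state[tid]
            if a in g.index:
                ds.append(float(g.loc[a, "equivalent_diameter"]))
        if ds:
            rows.append((w, stage_label(w), len(ds), float(np.mean(ds)),
                         float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0))
        else:
            rows.append((w, stage_label(w), 0, math.nan, math.nan))
    return pd.DataFrame(rows, columns=["window", "label", "n",
                                       "mean_diameter", "sd_diameter"])


def final_mean_diameter(tracks: pd.DataFrame, summary: pd.DataFrame,
                        survivors_only: bool = True) -> tuple[float, float, int]:
    """Mean +- SD diameter at the final frame (survivor tracks, or all
    oocytes alive at the end)."""
    last = int(tracks.frame.max())
    oo = summary[(summary.kind == "oocyte") & (summary.end == last)]
    if survivors_only:
        oo = oo[oo.complete & (oo.end_reason == "alive_at_end")]
    ds = []
    for tid in oo.track_id:
        g = tracks[(tracks.track_id == tid) & (tracks.frame == last)]
        if len(g):
            ds.append(float(g.equivalent_diameter.iloc[0]))
    if not ds:
        return math.nan, math.nan, 0
    sd = float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0
    return float(np.mean(ds)), sd, len(ds)


# ----------------------------------------------------------------------
# stereology
# ----------------------------------------------------------------------

def stereology_total_mitochondria(Rave_oo: float, Dave_mit: float,
                                  Nmit_s: float) -> float:
    """Total mitochondria per oocyte from a maximal cross-section count:
    Nmit_total = Voo / (Sloo * Dave_mit) * Nmit_s = 4R/(3D) * Nmit_s."""
    return StereologyInput(Rave_oo, Dave_mit, Nmit_s).Nmit_total


def section_count_estimate(agents: pd.DataFrame, section_thickness: float = 8.0,
                           step: int = 5, phase: float = 0.0) -> int:
    """Whole-ovary oocyte count from virtual serial sections.

    The volume is cut into ``section_thickness``-um sections along z; oocytes
    are counted in every ``step``-th section and the sum multiplied by
    ``step``.  Counting uses each oocyte's centroid section, so an oocyte can
    be counted in exactly one section and the estimator is unbiased under a
    uniform section phase.
    """
    if section_thickness <= 0:
        raise ValueError("section thickness must be > 0")
    if agents.empty:
        return 0
    z = agents["z"].to_numpy(float)
    sec = np.floor((z - phase) / section_thickness).astype(int)
    counted = np.mod(sec, step) == 0
    return int(step * counted.sum())


def section_count_estimate_labels(labels: np.ndarray, spacing_z: float,
                                  section_thickness: float = 8.0,
                                  step: int = 5, phase: float = 0.0) -> int:
    """Label-volume variant of :func:`section_count_estimate`: each label's
    z-centroid (in um) determines its section."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    zs = []
    for i in ids:
        zi = np.nonzero((labels == i).any(axis=(1, 2)))[0]
        zs.append(float(zi.mean()) * spacing_z)
    return section_count_estimate(pd.DataFrame({"z": zs}), section_thickness,
                                  step, phase)


def cluster_fraction(cluster_sizes: dict, selected, total: float | None = None) -> float:
    """Percentage of cells in the selected clusters, one decimal."""
    if total is None:
        total = sum(cluster_sizes.values())
    if total <= 0:
        raise ValueError("total must be positive")
    s = sum(cluster_sizes[c] for c in selected)
    return round(100.0 * s / total, 1)


# ----------------------------------------------------------------------
# combined per-window table
# ----------------------------------------------------------------------

def stage_stats(tracks: pd.DataFrame, summary: pd.DataFrame,
                events: pd.DataFrame, objects: pd.DataFrame,
                contacts: pd.DataFrame, windows: list[tuple[int, int]],
                track_params: TrackParams | None = None,
                det_params: DetectionParams | None = None,
                include_purple: bool | None = None) -> pd.DataFrame:
    """One row per 24 h window with every population statistic."""
    track_params = track_params or TrackParams()
    freq = compute_event_frequencies(tracks, summary, events, objects, windows)
    growth = measure_growth(tracks, summary, windows)
    singles = []
    for win in windows:
        try:
            singles.append(compute_single_ratio(tracks, summary, contacts,
                                                win, track_params))
        except ValueError:
            singles.append(math.nan)
    df = freq.merge(growth[["window", "mean_diameter", "sd_diameter"]], on="window")
    df["single_ratio"] = singles
    if include_purple is None:
        include_purple = ("cfp_mean" in objects.columns
                          and (objects.cfp_mean.max() > 0
                               or objects.rfp_mean.max() > 0))
    if include_purple:
        pr = compute_purple_ratio(objects, tracks, summary, windows, det_params)
        df = df.merge(pr[["window", "purple_ratio"]], on="window")
    else:
        df["purple_ratio"] = math.nan
    return df
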