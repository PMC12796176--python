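"""Configuration objects for the oocyte-selection pipeline.

All lengths are micrometres, all times hours. The time axis starts at t=0 h
(culture-equivalent 17.5 dpc, "c-17.5 dpc"); 24 h stage windows map onto the
perinatal staging used for mouse ovaries: c-17.5 dpc, c-18.5 dpc, c-19.5 dpc,
then c-PD1, c-PD2, ... (postnatal days in culture).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

WINDOW_HOURS = 24.0

__all__ = [
    "SimConfig",
    "OpticsParams",
    "DetectionParams",
    "TrackParams",
    "PipelineConfig",
    "stage_label",
    "stage_windows",
    "window_of_frame",
    "load_config",
    "config_hash",
    "WINDOW_HOURS",
]


def stage_label(window_index: int) -> str:
    """Stage name for a 24 h window index (0 -> c-17.5 dpc, 3 -> c-PD1, ...)."""
    if window_index < 0:
        raise ValueError("window_index must be >= 0")
    if window_index == 0:
        return "c-17.5 dpc"
    if window_index == 1:
        return "c-18.5 dpc"
    if window_index == 2:
        return "c-19.5 dpc"
    return f"c-PD{window_index - 2}"


def n_stage_windows(duration: float) -> int:
    return int(math.ceil(duration / WINDOW_HOURS - 1e-9))


def stage_windows(duration: float, frame_interval: float) -> list[tuple[int, int]]:
    """Half-open frame ranges [start, stop) for each 24 h window.

    The final window may be shorter than 24 h (e.g. [144, 162] h for the
    default 162 h run); the frame at t=duration belongs to the last window.
    """
    n_frames = int(round(duration / frame_interval)) + 1
    per = WINDOW_HOURS / frame_interval
    out = []
    for w in range(n_stage_windows(duration)):
        a = int(round(w * per))
        b = min(int(round((w + 1) * per)), n_frames)
        if w == n_stage_windows(duration) - 1:
            b = n_frames
        out.append((a, b))
    return out


def window_of_frame(frame: int, frame_interval: float) -> int:
    return int(frame * frame_interval // WINDOW_HOURS)


def _aslist(x) -> list[float]:
    if isinstance(x, (int, float)):
        return [float(x)]
    return [float(v) for v in x]


@dataclass
class SimConfig:
    """Parameters of the agent-based 4D ovary generator.

    Per-window sequences are indexed by 24 h stage window; sequences shorter
    than the number of windows are padded (hazards with 0, bridge dissolution
    with its last value).
    """

    # geometry / time base
    arena_xy: float = 308.72          # field side, um
    arena_z: float = 40.0             # imaging depth, um
    frame_interval: float = 1.5       # h
    duration: float = 162.0           # h (c-17.5 dpc -> c-PD4)

    # initial population
    n_oocytes_init: int = 200
    oocyte_diameter_mean: float = 15.0
    oocyte_diameter_sd: float = 2.0
    oocyte_diameter_range: tuple[float, float] = (10.0, 25.0)
    # distribution over cyst sizes (per cyst).  The default puts 42.9% of
    # oocytes in 2-cysts, i.e. 57.1% of oocytes start single.
    cyst_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.727, 2: 0.273}
    )

    # cyst breakdown: per-boundary bridge dissolution probability, applied
    # between window w and w+1 (calibrated from the attached-fraction ratios
    # of the printed single-oocyte time course 57.1/78.1/91.6/97.5%).
    bridge_dissolution_prob: tuple[float, ...] = (0.490, 0.616, 0.702)

    # death scheduling: per-window sacrifice hazard, expressed as the
    # fraction of oocytes alive at window start that die during the window;
    # burst_fraction of scheduled deaths burst (degradation), the rest shrink.
    sacrifice_hazard: tuple[float, ...] = (0.015, 0.05, 0.28, 0.28, 0.28, 0.0, 0.0)
    burst_fraction: float = 0.643
    # sacrificed oocytes still alive after the hazard windows shrink away in
    # stage windows 5-6 (c-PD3/c-PD4) so that only the surviving lineage
    # remains at the end of a control run.
    survival_fraction: float = 0.147

    # debris (OD) generation
    debris_count_min: int = 3
    debris_count_extra_mean: float = 5.0     # count = min + Poisson(extra)
    debris_diameter_median: float = 4.5      # lognormal median, um
    debris_diameter_sigma_log: float = 0.45
    debris_diameter_range: tuple[float, float] = (1.2, 14.0)
    debris_lifetime: float = 24.0            # h before a free OD decays
    debris_speed: float = 0.35               # free wander, um/h
    debris_homing_speed: float = 3.9         # claimed OD approach, um/h

    # filopodia-like structures and engulfment
    fl_formation_prob: tuple[float, ...] = (0.005, 0.01, 0.16, 0.16, 0.16, 0.01, 0.005)
    fl_length_min: float = 2.5
    fl_length_mode: float = 4.0
    fl_length_max: float = 8.0
    capture_radius: float = 3.0              # surface-to-centroid gap, um
    capture_cone_half_angle: float = 60.0    # degrees
    attraction_radius: float = 80.0          # FL-guided recruitment range
    growth_per_engulfment: float = 0.8       # um diameter per engulfment
    survival_min_engulfments: int = 5
    target_mean_engulfments: float = 15.0

    # motion
    motion_speed: float = 1.0                # um/h
    heading_persistence: float = 0.8
    position_jitter: float = 0.2             # um per frame, per oocyte

    # growth rates (um/h); survivors additionally gain growth_per_engulfment
    survivor_growth_rate: float = 0.082
    treated_growth_rate: float = 0.0679
    growth_rate_cv: float = 0.15
    shrink_frames: int = 6
    shrink_factor: float = 0.75

    # observation layer
    exit_prob: float = 0.10                  # fraction of tracks leaving the field

    # treatment (autophagy-inhibitor, e.g. 3-MA) mode
    treatment_mode: str = "none"             # {"none", "phagocytosis_blocked"}
    treatment_burst_suppression: float = 0.1
    treatment_fl_suppression: float = 0.05

    # labels
    color_mode: str = "membrane"             # {"membrane", "rainbow"}
    mito_oocyte_mean: float = 0.30
    mito_oocyte_sd: float = 0.03
    mito_debris_range: tuple[float, float] = (0.05, 0.60)

    # whole-ovary (stereology) mode
    ovary_n_oocytes: int = 6244
    ovary_death_fraction: float = 0.3965
    ovary_size: tuple[float, float, float] = (400.0, 600.0, 600.0)  # z, y, x um

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self):
        self.bridge_dissolution_prob = tuple(_aslist(self.bridge_dissolution_prob))
        self.sacrifice_hazard = tuple(_aslist(self.sacrifice_hazard))
        self.fl_formation_prob = tuple(_aslist(self.fl_formation_prob))
        self.oocyte_diameter_range = tuple(self.oocyte_diameter_range)
        self.debris_diameter_range = tuple(self.debris_diameter_range)
        self.mito_debris_range = tuple(self.mito_debris_range)
        self.ovary_size = tuple(self.ovary_size)
        self.cyst_size_dist = {int(k): float(v) for k, v in self.cyst_size_dist.items()}
        self.validate()

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9 or self.duration <= 0:
            raise ValueError("duration must be a positive integer multiple of frame_interval")
        m = WINDOW_HOURS / self.frame_interval
        if abs(m - round(m)) > 1e-9:
            raise ValueError("24 h stage windows must tile onto the frame grid")
        if self.n_oocytes_init <= 0:
            raise ValueError("n_oocytes_init must be >= 1")
        lo, hi = self.debris_diameter_range
        if lo < 1.2 - 1e-9 or hi > 14.0 + 1e-9 or lo >= hi:
            raise ValueError("debris_diameter_range must lie within [1.2, 14] um")
        if self.debris_count_min < 3:
            raise ValueError("a burst produces at least three debris")
        for name in ("bridge_dissolution_prob", "sacrifice_hazard", "fl_formation_prob"):
            for p in getattr(self, name):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} entries must be probabilities in [0, 1]")
        for name in ("survival_fraction", "burst_fraction", "exit_prob",
                     "treatment_burst_suppression", "treatment_fl_suppression",
                     "ovary_death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.treatment_mode not in ("none", "phagocytosis_blocked"):
            raise ValueError("treatment_mode must be 'none' or 'phagocytosis_blocked'")
        if self.color_mode not in ("membrane", "rainbow"):
            raise ValueError("color_mode must be 'membrane' or 'rainbow'")
        if self.fl_length_min < 2.5 - 1e-9:
            raise ValueError("filopodia-like structures are defined as >= 2.5 um")
        if abs(sum(self.cyst_size_dist.values()) - 1.0) > 1e-6:
            raise ValueError("cyst_size_dist probabilities must sum to 1")
        if any(k < 1 for k in self.cyst_size_dist):
            raise ValueError("cyst sizes must be >= 1")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    @property
    def n_windows(self) -> int:
        return n_stage_windows(self.duration)

    def windows(self) -> list[tuple[int, int]]:
        return stage_windows(self.duration, self.frame_interval)

    def window_labels(self) -> list[str]:
        return [stage_label(w) for w in range(self.n_windows)]

    def hazard(self, w: int) -> float:
        h = self.sacrifice_hazard
        return h[w] if w < len(h) else 0.0

    def fl_prob(self, w: int) -> float:
        p = self.fl_formation_prob
        return p[w] if w < len(p) else 0.0

    def dissolution_prob(self, boundary: int) -> float:
        p = self.bridge_dissolution_prob
        if not p:
            return 0.0
        return p[boundary] if boundary < len(p) else p[-1]

    @property
    def treated(self) -> bool:
        return self.treatment_mode == "phagocytosis_blocked"

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cyst_size_dist"] = {str(k): v for k, v in d["cyst_size_dist"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "cyst_size_dist" in d:
            d["cyst_size_dist"] = {int(k): float(v) for k, v in d["cyst_size_dist"].items()}
        return cls(**d)


@dataclass
class OpticsParams:
    """Simple optics for the synthetic renderer."""

    psf_sigma: tuple[float, float, float] = (0.6, 0.25, 0.25)  # z, y, x um
    photon_scale: float = math.inf   # expected photons at full label; inf = noiseless
    background: float = 0.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.psf_sigma = tuple(float(s) for s in self.psf_sigma)
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")

    @property
    def noiseless(self) -> bool:
        return (
            math.isinf(self.photon_scale)
            and self.read_noise_sd == 0
            and self.background == 0
            and all(s == 0 for s in self.psf_sigma)
        )

    def to_dict(self):
        d = dataclasses.asdict(self)
        if math.isinf(self.photon_scale):
            d["photon_scale"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown OpticsParams keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("photon_scale") in ("inf", "Infinity"):
            d["photon_scale"] = math.inf
        return cls(**d)


@dataclass
class DetectionParams:
    """Operational definitions used by the per-frame measurements."""

    od_diameter_range: tuple[float, float] = (1.2, 14.0)
    fl_min_length: float = 2.5
    min_object_diameter: float = 1.2
    membrane_threshold: float = 40.0       # counts on the 0-255 render scale
    purple_ratio_threshold: float = 0.2    # min(CFP,RFP)/max(CFP,RFP) for "purple"
    mito_intensity_threshold: float = 60.0
    channel_background: float = 5.0
    split_min_radius: float = 4.0          # watershed marker separation, um

    def __post_init__(self):
        self.od_diameter_range = tuple(self.od_diameter_range)
        if self.od_diameter_range[0] < self.min_object_diameter - 1e-9:
            raise ValueError("od_diameter_range lower bound must be >= min_object_diameter")
        if self.fl_min_length <= 0:
            raise ValueError("fl_min_length must be > 0")
        if not 0 < self.purple_ratio_threshold <= 1:
            raise ValueError("purple_ratio_threshold must be in (0, 1]")

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown DetectionParams keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrackParams:
    """Linking and event-calling parameters."""

    gate_radius: float = 6.0        # max displacement um/frame
    size_ratio_gate: float = 0.66   # min frame-to-frame diameter ratio
    gap_max: int = 1
    gap_gate_factor: float = 1.5
    r_burst_extra: float = 10.0     # burst search radius = parent radius + this
    engulf_epsilon: float = 1.5     # boundary expansion for engulfment calls
    d_sep: float = 2.0              # surface distance for separation hysteresis
    hysteresis_frames: int = 2
    contact_gap: float = 0.8        # surface gap counted as contact, um
    c_corr: float = 0.8             # mean displacement cosine for connectedness
    d_var: float = 0.5              # relative surface-gap variation bound
    k_min_frames: int = 6           # min shared in-contact frames to classify
    left_field_margin: float = 10.0  # um from an xy bound

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TrackParams keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Composed configuration for an end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    optics: OpticsParams = field(default_factory=OpticsParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackParams = field(default_factory=TrackParams)
    mode: str = "agent_level"        # {"agent_level", "image_level"}
    out_dir: str = "results"
    seeds: tuple[int, ...] = (1,)

    def __post_init__(self):
        self.seeds = tuple(int(s) for s in self.seeds)
        if not self.seeds:
            raise ValueError("seed list must be non-empty")
        if self.mode not in ("agent_level", "image_level"):
            raise ValueError("mode must be 'agent_level' or 'image_level'")

    def to_dict(self):
        return {
            "sim": self.sim.to_dict(),
            "optics": self.optics.to_dict(),
            "detection": self.detection.to_dict(),
            "tracking": self.tracking.to_dict(),
            "mode": self.mode,
            "out_dir": self.out_dir,
            "seeds": list(self.seeds),
        }

    @classmethod
    def from_dict(cls, d):
        known = {"sim", "optics", "detection", "tracking", "mode", "out_dir", "seeds"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(
            sim=SimConfig.from_dict(d.get("sim", {})),
            optics=OpticsParams.from_dict(d.get("optics", {})),
            detection=DetectionParams.from_dict(d.get("detection", {})),
            tracking=TrackParams.from_dict(d.get("tracking", {})),
            mode=d.get("mode", "agent_level"),
            out_dir=d.get("out_dir", "results"),
            seeds=tuple(d.get("seeds", (1,))),
        )


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected at every level."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def config_hash(cfg) -> str:
    """Stable hash of any config object with a to_dict()."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
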