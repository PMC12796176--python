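"""Voxelization of agents into multichannel 3D stacks with simple optics.

Channels (in order): ``membrane`` (a one-voxel shell on every oocyte/debris
surface plus FL line segments), ``cytoplasm`` (total label fill), ``cfp`` and
``rfp`` (cytoplasm fill weighted by the label fractions), and ``mito``
(punctae at the agent's mitochondria density).  Disjoint agents compose by
voxelwise maximum, so the noiseless render of a scene equals the maximum of
the per-agent renders.

The default scene is a desk-scale 100 x 100 x 30 um subvolume at
(0.7, 0.3, 0.3) um spacing; full-field statistics use the agent-level path.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .config import OpticsParams

__all__ = ["VoxelFrame", "CHANNELS", "render_frame", "add_noise",
           "write_ome_tiff", "read_ome_tiff", "small_scene_geometry"]

CHANNELS = ("membrane", "cytoplasm", "cfp", "rfp", "mito")
_FULL = 200.0       # label intensity on the 8-bit-like render scale
_MITO = 255.0


@dataclass
class VoxelFrame:
    """One multichannel 3D stack with physical spacing.

    data: float array (C, Z, Y, X); spacing in um per voxel (z, y, x).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.7, 0.3, 0.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_index: int = 0
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.data.ndim != 4 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (C, Z, Y, X) matching channels")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def small_scene_geometry(size_um=(30.0, 100.0, 100.0),
                         spacing=(0.7, 0.3, 0.3)) -> dict:
    """Default desk-scale scene geometry (z, y, x extents in um)."""
    shape = tuple(int(round(s / sp)) for s, sp in zip(size_um, spacing))
    return {"shape": shape, "spacing": tuple(spacing), "size_um": tuple(size_um)}


def _axes_grids(shape, spacing, origin):
    return [ (np.arange(n) + 0.5) * sp + o
             for n, sp, o in zip(shape, spacing, origin) ]


def render_frame(agents, geometry: dict | None = None,
                 optics: OpticsParams | None = None,
                 frame_index: int = 0, seed: int = 0) -> VoxelFrame:
    """Rasterize one frame's agents into a noiseless VoxelFrame.

    ``agents`` is an iterable of mappings with keys ``z, y, x,
    equivalent_diameter`` and optionally ``cfp_mean, rfp_mean`` (percent),
    ``mito_density`` and ``fl_list`` (list of (direction zyx, length um)
    or plain lengths, rendered along +x).  Agents outside the grid are
    clipped with a warning.  Apply :func:`add_noise` for optics.
    """
    import warnings
    geometry = geometry or small_scene_geometry()
    shape = geometry["shape"]
    spacing = geometry["spacing"]
    origin = (0.0, 0.0, 0.0)
    data = np.zeros((len(CHANNELS),) + tuple(shape), dtype=np.float32)
    size_um = [n * s for n, s in zip(shape, spacing)]
    shell_half = 0.5 * max(spacing)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, frame_index])

    for agent in agents:
        a = dict(agent)
        c = np.array([a["z"], a["y"], a["x"]], float)
        r = float(a["equivalent_diameter"]) / 2.0
        if np.any(c + r < -1) or np.any(c - r > np.array(size_um) + 1):
            warnings.warn("agent outside the rendered volume; clipped")
            continue
        fls = _parse_fls(a.get("fl_list") or a.get("fl_lengths"))
        reach = r + shell_half + max([l for _, l in fls], default=0.0) + 1.0
        lo = [max(int((c[i] - reach) / spacing[i]) - 1, 0) for i in range(3)]
        hi = [min(int((c[i] + reach) / spacing[i]) + 2, shape[i]) for i in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        zz, yy, xx = np.meshgrid(
            *[(np.arange(l, h) + 0.5) * sp for l, h, sp in zip(lo, hi, spacing)],
            indexing="ij")
        dist = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        shell = np.abs(dist - r) <= shell_half
        interior = dist <= r

        mem = data[0][box]
        np.maximum(mem, np.where(shell, _FULL, 0.0), out=mem)
        cyt = data[1][box]
        np.maximum(cyt, np.where(interior, _FULL, 0.0), out=cyt)
        cfp = float(a.get("cfp_mean", 0.0)) / 100.0
        rfp = float(a.get("rfp_mean", 0.0)) / 100.0
        if cfp > 0:
            ch = data[2][box]
            np.maximum(ch, np.where(interior, _FULL * cfp, 0.0), out=ch)
        if rfp > 0:
            ch = data[3][box]
            np.maximum(ch, np.where(interior, _FULL * rfp, 0.0), out=ch)
        mito = float(a.get("mito_density", 0.0))
        if mito > 0:
            punctae = interior & (rng.random(interior.shape) < mito)
            ch = data[4][box]
            np.maximum(ch, np.where(punctae, _MITO, 0.0), out=ch)

        # FL structures: ~2-voxel-wide cylinders from the surface outward
        for direction, length in fls:
            _paint_segment(data[0], c + direction * r,
                           c + direction * (r + length), spacing, shape,
                           radius=1.5 * max(spacing[1], spacing[2]))
    return VoxelFrame(data=data, spacing=tuple(spacing),
                      frame_index=frame_index)


def _parse_fls(fl) -> list[tuple[np.ndarray, float]]:
    """Normalize FL specs to (unit direction zyx, length) pairs.

    Accepts pairs, plain lengths (rendered along +x) or the semicolon
    string used in object tables.
    """
    if fl is None:
        return []
    if isinstance(fl, str):
        fl = [float(t) for t in fl.split(";") if t]
    out = []
    for k, item in enumerate(fl):
        if isinstance(item, (tuple, list)) and len(item) == 2 \
                and not np.isscalar(item[0]):
            d = np.asarray(item[0], float)
            d = d / (np.linalg.norm(d) or 1.0)
            out.append((d, float(item[1])))
        else:
            # plain length: spread directions in the xy plane
            ang = 2 * math.pi * k / max(len(fl), 1)
            out.append((np.array([0.0, math.sin(ang), math.cos(ang)]),
                        float(item)))
    return out


def _paint_segment(channel, p0, p1, spacing, shape, radius):
    """Rasterize a cylinder of the given physical radius along p0->p1."""
    step = 0.5 * min(spacing)
    n = max(int(np.linalg.norm(p1 - p0) / step), 1)
    rad_vox = [max(int(math.ceil(radius / sp)), 1) for sp in spacing]
    offs = np.meshgrid(*[np.arange(-r, r + 1) for r in rad_vox],
                       indexing="ij")
    offs = np.stack([o.ravel() for o in offs], axis=1)
    phys = offs * np.asarray(spacing)
    near = np.linalg.norm(phys, axis=1) <= radius + 0.5 * min(spacing)
    offs = offs[near]
    for t in np.linspace(0.0, 1.0, n + 1):
        p = p0 + t * (p1 - p0)
        idx = np.array([int(p[i] / spacing[i]) for i in range(3)])
        vox = offs + idx
        ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        v = vox[ok]
        channel[v[:, 0], v[:, 1], v[:, 2]] = _FULL


def add_noise(frame: VoxelFrame, optics: OpticsParams) -> VoxelFrame:
    """PSF blur, photon (Poisson) noise, background and read noise.

    Deterministic under a fixed optics seed; with zero psf, infinite
    photon_scale and zero background/read noise the frame is returned
    unchanged (noiseless limit).
    """
    if optics.noiseless:
        return frame
    rng = np.random.default_rng(optics.seed & 0x7FFFFFFF)
    out = frame.data.astype(np.float64).copy()
    sig_vox = [s / sp for s, sp in zip(optics.psf_sigma, frame.spacing)]
    for ci in range(out.shape[0]):
        if any(s > 0 for s in sig_vox):
            out[ci] = ndi.gaussian_filter(out[ci], sigma=sig_vox)
        if math.isfinite(optics.photon_scale):
            lam = out[ci] / _MITO * optics.photon_scale
            out[ci] = rng.poisson(lam) / optics.photon_scale * _MITO
        out[ci] += optics.background
        if optics.read_noise_sd > 0:
            out[ci] += rng.normal(0, optics.read_noise_sd, out[ci].shape)
    return VoxelFrame(data=np.clip(out, 0, None).astype(np.float32),
                      spacing=frame.spacing, origin=frame.origin,
                      frame_index=frame.frame_index, channels=frame.channels)


# ----------------------------------------------------------------------
# OME-TIFF I/O
# ----------------------------------------------------------------------

def write_ome_tiff(path, frames: "VoxelFrame | list[VoxelFrame]") -> None:
    """Write one frame as 4D (C,Z,Y,X) or a series as 5D (T,C,Z,Y,X)
    OME-TIFF with the physical spacing recorded in the metadata."""
    single = isinstance(frames, VoxelFrame)
    fl = [frames] if single else list(frames)
    spacing = fl[0].spacing
    arr = np.stack([f.data for f in fl]).astype(np.float32)
    axes = "TCZYX"
    if single:
        arr = arr[0]
        axes = "CZYX"
    tifffile.imwrite(
        path, arr, ome=True,
        metadata={
            "axes": axes,
            "PhysicalSizeZ": spacing[0], "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": spacing[1], "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": spacing[2], "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(fl[0].channels)},
        })


def read_ome_tiff(path) -> list[VoxelFrame]:
    """Round-trip reader for :func:`write_ome_tiff` output."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        ome = tf.ome_metadata or ""
    spacing = [0.7, 0.3, 0.3]
    import re
    for i, ax in enumerate("ZYX"):
        m = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', ome)
        if m:
            spacing[i] = float(m.group(1))
    if arr.ndim == 4:
        arr = arr[None]
    return [VoxelFrame(data=np.asarray(a, dtype=np.float32),
                       spacing=tuple(spacing), frame_index=t)
            for t, a in enumerate(arr)]
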