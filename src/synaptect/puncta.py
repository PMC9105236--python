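"""Sub-resolution puncta detection and confocal false-positive removal.

The detection convention: a voxel is a punctum candidate iff

* no 26-neighbour has greater intensity, and every equal-intensity neighbour
  has lexicographically larger ``(z, y, x)`` index (plateau tie-break), and
* its intensity is at or above the detection threshold, and
* it is the brightest candidate within ``min_separation_nm`` (greedy
  exclusion in descending intensity order).

Candidates detected on the STED volume are then validated against the
deconvolved confocal volume of the same channel: a punctum is kept iff the
confocal intensity within a validation radius of its position reaches a
threshold.  This removes STED-only false maxima, which have no confocal
counterpart.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import ImageVolume

DEFAULT_INTENSITY_PERCENTILE = 90.0
DEFAULT_MIN_SEPARATION_NM = 100.0
DEFAULT_VALIDATION_RADIUS_NM = 250.0
DEFAULT_CONF_PERCENTILE = 50.0


@dataclasses.dataclass
class PunctaSet:
    """Detected punctae with physical coordinates and peak intensities."""

    coords_um: np.ndarray        # (n, 3) x, y, z in µm
    peak_intensity: np.ndarray   # (n,)
    channel: str
    provenance: str              # "raw_maxima" or "confocal_validated"
    frame_size_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords_um = np.asarray(self.coords_um, dtype=float).reshape(-1, 3)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=float).reshape(-1)
        if len(self.coords_um) != len(self.peak_intensity):
            raise ValueError("coords and intensities must have equal length")
        if self.frame_size_um is not None:
            self.frame_size_um = np.asarray(self.frame_size_um, dtype=float)

    def __len__(self) -> int:
        return len(self.coords_um)

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "x_um": self.coords_um[:, 0],
                "y_um": self.coords_um[:, 1],
                "z_um": self.coords_um[:, 2],
                "intensity": self.peak_intensity,
                "channel": self.channel,
                "provenance": self.provenance,
            }
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def read_puncta_csv(path: str | Path) -> PunctaSet:
    df = pd.read_csv(path)
    channel = str(df["channel"].iloc[0]) if len(df) else "pre"
    provenance = str(df["provenance"].iloc[0]) if len(df) else "raw_maxima"
    return PunctaSet(
        coords_um=df[["x_um", "y_um", "z_um"]].to_numpy() if len(df) else np.empty((0, 3)),
        peak_intensity=df["intensity"].to_numpy() if len(df) else np.empty(0),
        channel=channel,
        provenance=provenance,
    )


def _local_maxima_mask(data: np.ndarray, min_intensity: float) -> np.ndarray:
    """Thresholded 26-neighbourhood maxima with lexicographic plateau tie-break."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(data, footprint=footprint, mode="constant", cval=-np.inf)
    mask = (data > neigh_max) & (data >= min_intensity)
    plateau = np.argwhere((data == neigh_max) & (data >= min_intensity) & (data > 0))
    nz, ny, nx = data.shape
    for z, y, x in plateau:
        val = data[z, y, x]
        keep = True
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        if data[zz, yy, xx] == val and (zz, yy, xx) < (z, y, x):
                            keep = False
                            break
                if not keep:
                    break
            if not keep:
                break
        if keep:
            mask[z, y, x] = True
    return mask


def detect_maxima(
    vol: ImageVolume,
    min_intensity: float | None = None,
    min_separation_nm: float = DEFAULT_MIN_SEPARATION_NM,
    intensity_percentile: float = DEFAULT_INTENSITY_PERCENTILE,
    refine_subvoxel: bool = True,
) -> PunctaSet:
    """Detect punctae as thresholded 3D local maxima on a STED volume.

    ``min_intensity`` is an absolute threshold; when omitted, the
    ``intensity_percentile`` of the nonzero voxel intensities is used.
    Maxima closer than ``min_separation_nm`` (3D physical distance) to a
    brighter maximum are suppressed.  Coordinates are voxel centres in µm,
    optionally refined by an intensity-weighted centre of mass over the 3³
    neighbourhood; the result is sorted by descending intensity.
    """
    if vol.modality != "STED":
        raise ValueError(f"detect_maxima expects a STED volume, got {vol.modality!r}")
    data = np.asarray(vol.data, dtype=float)
    if min_intensity is None:
        nonzero = data[data > 0]
        if len(nonzero) == 0:
            return PunctaSet(np.empty((0, 3)), np.empty(0), vol.channel, "raw_maxima",
                             frame_size_um=vol.size_um)
        min_intensity = float(np.percentile(nonzero, intensity_percentile))

    mask = _local_maxima_mask(data, float(min_intensity))
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return PunctaSet(np.empty((0, 3)), np.empty(0), vol.channel, "raw_maxima",
                         frame_size_um=vol.size_um)
    intensities = data[mask]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -intensities))
    idx, intensities = idx[order], intensities[order]
    coords = vol.index_to_um(idx)

    # greedy exclusion: keep the brighter of any two maxima within the radius
    if min_separation_nm > 0 and len(coords) > 1:
        radius_um = min_separation_nm / 1000.0
        tree = cKDTree(coords)
        keep = np.ones(len(coords), dtype=bool)
        for i in range(len(coords)):
            if not keep[i]:
                continue
            for j in tree.query_ball_point(coords[i], radius_um):
                if j > i:
                    keep[j] = False
        idx, intensities, coords = idx[keep], intensities[keep], coords[keep]

    if refine_subvoxel:
        coords = np.array([_centre_of_mass(data, vol, i) for i in idx]).reshape(-1, 3)

    return PunctaSet(coords, intensities, vol.channel, "raw_maxima", frame_size_um=vol.size_um)


def _centre_of_mass(data: np.ndarray, vol: ImageVolume, idx_zyx: np.ndarray) -> np.ndarray:
    z, y, x = (int(v) for v in idx_zyx)
    sl = (
        slice(max(0, z - 1), min(data.shape[0], z + 2)),
        slice(max(0, y - 1), min(data.shape[1], y + 2)),
        slice(max(0, x - 1), min(data.shape[2], x + 2)),
    )
    w = data[sl]
    total = w.sum()
    if total <= 0:
        return vol.index_to_um(np.array([z, y, x]))[0]
    zz, yy, xx = np.meshgrid(
        np.arange(sl[0].start, sl[0].stop),
        np.arange(sl[1].start, sl[1].stop),
        np.arange(sl[2].start, sl[2].stop),
        indexing="ij",
    )
    idx_com = np.array([(w * a).sum() / total for a in (zz, yy, xx)])
    return vol.index_to_um(idx_com)[0]


def confocal_crosscheck(
    punctae: PunctaSet,
    conf: ImageVolume,
    validation_radius_nm: float = DEFAULT_VALIDATION_RADIUS_NM,
    conf_threshold: float | None = None,
    conf_percentile: float = DEFAULT_CONF_PERCENTILE,
) -> PunctaSet:
    """Remove punctae without confocal support (STED-only false positives).

    A punctum is retained iff the maximum confocal intensity within
    ``validation_radius_nm`` (3D physical ellipsoid) of its coordinate reaches
    ``conf_threshold`` — by default the ``conf_percentile`` of the nonzero
    confocal intensities.  An identically zero confocal volume therefore
    validates nothing.
    """
    if conf.modality != "confocal":
        raise ValueError(f"confocal_crosscheck expects a confocal volume, got {conf.modality!r}")
    if punctae.channel != conf.channel:
        raise ValueError(
            f"channel mismatch: punctae are {punctae.channel!r}, confocal is {conf.channel!r}"
        )
    if punctae.frame_size_um is not None and not np.allclose(
        punctae.frame_size_um, conf.size_um, rtol=1e-3
    ):
        raise ValueError(
            f"physical frame mismatch: punctae frame {punctae.frame_size_um} µm vs "
            f"confocal {conf.size_um} µm"
        )
    if len(punctae) == 0:
        return PunctaSet(np.empty((0, 3)), np.empty(0), punctae.channel,
                         "confocal_validated", frame_size_um=conf.size_um)

    data = np.asarray(conf.data, dtype=float)
    if conf_threshold is None:
        nonzero = data[data > 0]
        conf_threshold = (
            float(np.percentile(nonzero, conf_percentile)) if len(nonzero) else np.inf
        )

    r_um = validation_radius_nm / 1000.0
    voxel = conf.voxel_um  # (vx, vy, vz)
    r_vox = np.maximum(np.ceil(r_um / voxel).astype(int), 0)
    nz, ny, nx = data.shape
    keep = np.zeros(len(punctae), dtype=bool)
    for k, (cx, cy, cz) in enumerate(punctae.coords_um):
        ix, iy, iz = (int(np.floor(c / v)) for c, v in zip((cx, cy, cz), voxel))
        x0, x1 = max(0, ix - r_vox[0]), min(nx, ix + r_vox[0] + 1)
        y0, y1 = max(0, iy - r_vox[1]), min(ny, iy + r_vox[1] + 1)
        z0, z1 = max(0, iz - r_vox[2]), min(nz, iz + r_vox[2] + 1)
        if x1 <= x0 or y1 <= y0 or z1 <= z0:
            continue
        box = data[z0:z1, y0:y1, x0:x1]
        # ellipsoid mask in physical units around the punctum coordinate
        zz = (np.arange(z0, z1) + 0.5) * voxel[2] - cz
        yy = (np.arange(y0, y1) + 0.5) * voxel[1] - cy
        xx = (np.arange(x0, x1) + 0.5) * voxel[0] - cx
        dist2 = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        )
        inside = dist2 <= r_um**2
        if not inside.any():
            continue
        keep[k] = float(box[inside].max()) >= conf_threshold
    return PunctaSet(
        punctae.coords_um[keep],
        punctae.peak_intensity[keep],
        punctae.channel,
        "confocal_validated",
        frame_size_um=conf.size_um,
    )
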