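"""3D image volumes with physical voxel metadata.

A volume is a non-negative intensity grid indexed ``data[z, y, x]`` with a
physical voxel size given in µm as ``(vx, vy, vz)`` (x, y, z order — the same
order used for all physical coordinates in this package).  Voxel centres sit at
``(i + 0.5) * voxel`` so that a voxel index maps to the middle of the voxel it
names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

MODALITIES = ("STED", "confocal")
CHANNELS = ("pre", "post")


@dataclasses.dataclass
class ImageVolume:
    """One modality/channel 3D intensity grid with physical voxel size.

    Parameters
    ----------
    data:
        3D array, axes ``(z, y, x)``, finite and non-negative.
    voxel_um:
        Physical voxel size ``(vx, vy, vz)`` in µm, strictly positive.
    modality:
        ``"STED"`` or ``"confocal"``.
    channel:
        ``"pre"`` or ``"post"``.
    marker:
        Free-text marker name (e.g. ``VGlut1``, ``Homer1``, ``Gad67``,
        ``Gephyrin``).
    """

    data: np.ndarray
    voxel_um: np.ndarray
    modality: str
    channel: str
    marker: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.voxel_um = np.asarray(self.voxel_um, dtype=float)
        if self.voxel_um.shape != (3,) or not np.all(self.voxel_um > 0):
            raise ValueError("voxel_um must be a strictly positive 3-vector (vx, vy, vz)")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if float(self.data.min(initial=0.0)) < 0:
            raise ValueError("volume intensities must be non-negative")

    # -- geometry -----------------------------------------------------------

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def size_um(self) -> np.ndarray:
        """Physical extent ``(sx, sy, sz)`` in µm."""
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz]) * self.voxel_um

    @property
    def physical_volume_um3(self) -> float:
        return float(np.prod(self.size_um))

    def index_to_um(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map voxel indices ``(z, y, x)`` rows to voxel-centre coords ``(x, y, z)`` µm."""
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        return (idx[:, ::-1] + 0.5) * self.voxel_um

    def um_to_index(self, coords_xyz: np.ndarray) -> np.ndarray:
        """Map physical ``(x, y, z)`` µm rows to nearest voxel indices ``(z, y, x)``."""
        xyz = np.atleast_2d(np.asarray(coords_xyz, dtype=float))
        idx = np.floor(xyz / self.voxel_um).astype(int)
        idx = np.clip(idx, 0, np.array(self.data.shape)[::-1] - 1)
        return idx[:, ::-1]

    def same_frame(self, other: "ImageVolume", rtol: float = 1e-6) -> bool:
        """True when both volumes share grid shape and voxel size."""
        return self.data.shape == other.data.shape and np.allclose(
            self.voxel_um, other.voxel_um, rtol=rtol
        )


def write_tiff(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF with voxel size + role metadata.

    Lateral voxel size goes into the TIFF resolution tags, the z step into the
    ImageJ ``spacing`` field, and modality/channel/marker into the image
    description, so :func:`read_tiff` can round-trip the object.
    """
    path = Path(path)
    meta = {
        "spacing": float(vol.voxel_um[2]),
        "unit": "um",
        "synaptect": json.dumps(
            {
                "voxel_um": vol.voxel_um.tolist(),
                "modality": vol.modality,
                "channel": vol.channel,
                "marker": vol.marker,
            }
        ),
    }
    tifffile.imwrite(
        path,
        vol.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / vol.voxel_um[0], 1.0 / vol.voxel_um[1]),
        metadata=meta,
    )
    return path


def read_tiff(path: str | Path) -> ImageVolume:
    """Read a volume written by :func:`write_tiff`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ij = tif.imagej_metadata or {}
    if data.ndim == 2:
        data = data[None]
    try:
        extra = json.loads(ij["synaptect"])
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path}: missing synaptect voxel/role metadata") from exc
    return ImageVolume(
        data=data,
        voxel_um=np.asarray(extra["voxel_um"], dtype=float),
        modality=extra["modality"],
        channel=extra["channel"],
        marker=extra.get("marker", ""),
    )
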