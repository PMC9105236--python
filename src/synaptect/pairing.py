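"""Pre/post punctae pairing into synapse calls and density computation.

A synapse is assigned wherever a presynaptic and a postsynaptic punctum lie
within a distance threshold of each other (default 300 nm, sub-synaptic
scale); its locus is the midpoint of the two punctae.  Distances are 3D
Euclidean in physical µm — never voxel units, so anisotropic voxels cannot
bias the matching.

Two matching modes:

* ``mutual`` (default): (i, j) is a call iff j is i's nearest post punctum,
  i is j's nearest pre punctum, and their distance is within threshold —
  a one-to-one matching by construction.
* ``greedy``: all within-threshold candidate pairs sorted by distance,
  accepted while both members are unmatched; shipped for sensitivity
  analysis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .puncta import PunctaSet

DEFAULT_PAIRING_THRESHOLD_NM = 300.0

#: Marker pairs mapping to synapse classes.
SYNAPSE_CLASS_BY_MARKERS = {
    ("VGlut1", "Homer1"): "excitatory",
    ("Gad67", "Gephyrin"): "inhibitory",
}


@dataclasses.dataclass
class SynapseCallSet:
    """Paired pre/post punctae with assigned synapse loci.

    ``calls`` is ``(pre_index, post_index)`` rows into the input punctae
    sets; ``loci_um`` the midpoint coordinates ``(x, y, z)``.
    """

    calls: np.ndarray              # (n, 2) int indices
    loci_um: np.ndarray            # (n, 3) µm midpoints
    pairing_threshold_nm: float
    synapse_class: str = "unknown"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int).reshape(-1, 2)
        self.loci_um = np.asarray(self.loci_um, dtype=float).reshape(-1, 3)
        if len(self.calls) != len(self.loci_um):
            raise ValueError("calls and loci must have equal length")
        for col in (0, 1):
            if len(np.unique(self.calls[:, col])) != len(self.calls):
                raise ValueError("one-to-one violation: repeated punctum index in calls")

    @property
    def n_synapses(self) -> int:
        return len(self.calls)

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "pre_index": self.calls[:, 0],
                "post_index": self.calls[:, 1],
                "x_um": self.loci_um[:, 0],
                "y_um": self.loci_um[:, 1],
                "z_um": self.loci_um[:, 2],
            }
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def pair_punctae(
    pre: PunctaSet,
    post: PunctaSet,
    threshold_nm: float = DEFAULT_PAIRING_THRESHOLD_NM,
    mode: str = "mutual",
    synapse_class: str | None = None,
) -> SynapseCallSet:
    """Match pre and post punctae within ``threshold_nm`` into synapse calls.

    Empty input on either side yields an empty call set (not an error).  Each
    punctum participates in at most one call.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be > 0")
    if mode not in ("mutual", "greedy"):
        raise ValueError("mode must be 'mutual' or 'greedy'")
    if pre.channel == post.channel:
        raise ValueError("pre and post sets must come from different channels")
    if (
        pre.frame_size_um is not None
        and post.frame_size_um is not None
        and not np.allclose(pre.frame_size_um, post.frame_size_um, rtol=1e-3)
    ):
        raise ValueError("pre and post punctae do not share a physical frame")
    cls = synapse_class or "unknown"

    a, b = pre.coords_um, post.coords_um
    if len(a) == 0 or len(b) == 0:
        return SynapseCallSet(np.empty((0, 2), int), np.empty((0, 3)), threshold_nm, cls)
    r = threshold_nm / 1000.0

    if mode == "mutual":
        tree_a, tree_b = cKDTree(a), cKDTree(b)
        d_ab, nn_ab = tree_b.query(a, k=1)
        d_ba, nn_ba = tree_a.query(b, k=1)
        pairs = [
            (i, j)
            for i, (j, d) in enumerate(zip(nn_ab, d_ab))
            if d <= r and nn_ba[j] == i
        ]
    else:
        tree_b = cKDTree(b)
        cand = []
        for i, p in enumerate(a):
            for j in tree_b.query_ball_point(p, r):
                cand.append((float(np.linalg.norm(p - b[j])), i, j))
        cand.sort()
        used_a, used_b = set(), set()
        pairs = []
        for _, i, j in cand:
            if i not in used_a and j not in used_b:
                pairs.append((i, j))
                used_a.add(i)
                used_b.add(j)

    calls = np.array(pairs, dtype=int).reshape(-1, 2)
    loci = (a[calls[:, 0]] + b[calls[:, 1]]) / 2.0 if len(calls) else np.empty((0, 3))
    return SynapseCallSet(calls, loci, threshold_nm, cls)


@dataclasses.dataclass
class DensityResult:
    """Synapse counts per ROI volume, in synapses/µm³.

    ``density_per_um3`` is exactly ``n_synapses / roi_volume_um3`` (pooled
    over ROIs); ``mean_roi_density`` averages the per-ROI densities, the
    convention used when ROIs represent repeated fields of one animal.
    """

    n_synapses: int
    roi_volume_um3: float
    density_per_um3: float
    per_roi: list[tuple[int, float, float]]  # (n, volume, density) per ROI

    @property
    def mean_roi_density(self) -> float:
        return float(np.mean([d for _, _, d in self.per_roi]))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def compute_density(
    calls: SynapseCallSet | list[SynapseCallSet],
    roi_volume_um3: float | list[float],
) -> DensityResult:
    """Synapse density as the exact quotient count / ROI volume.

    Multi-ROI input (lists of call sets and volumes, e.g. the nine imaged
    regions of one animal) yields per-ROI densities plus their mean density
    and pooled counts.
    """
    if isinstance(calls, SynapseCallSet):
        calls_list = [calls]
        volumes = [float(roi_volume_um3)]  # type: ignore[arg-type]
    else:
        calls_list = list(calls)
        volumes = [float(v) for v in np.atleast_1d(roi_volume_um3)]
        if len(volumes) == 1:
            volumes = volumes * len(calls_list)
    if len(volumes) != len(calls_list):
        raise ValueError("need one ROI volume per call set")
    if any(v <= 0 for v in volumes):
        raise ValueError("ROI volume must be > 0")
    per_roi = [(c.n_synapses, v, c.n_synapses / v) for c, v in zip(calls_list, volumes)]
    n_total = sum(n for n, _, _ in per_roi)
    vol_total = sum(v for _, v, _ in per_roi)
    return DensityResult(
        n_synapses=n_total,
        roi_volume_um3=vol_total,
        density_per_um3=n_total / vol_total,
        per_roi=per_roi,
    )
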