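"""Ground-truthed synthetic inputs for every pipeline stage.

Four families of generator, all pure functions of their spec (including the
seed):

* two-modality / two-channel synapse image volumes with exact ground truth
  (paired pre/post punctae, unpaired distractors, STED-only artifacts),
* paired-pulse field-potential sweeps (stimulus artifact, fiber volley,
  fEPSP with a controlled initial slope),
* plasticity time courses (baseline → induction → transient + plateau),
* two-group expression matrices with a planted enriched gene set.

Punctae are rendered as isotropic 3D Gaussians by exact per-voxel integration
(an erf product), so the deposited energy of a punctum is independent of the
PSF width — blur redistributes signal, it does not create it.  Noise is
additive Gaussian at a stated peak-signal-to-noise ratio; the deconvolved
confocal channel is rendered noiseless by default (deconvolution output is
heavily denoised), which can be overridden via ``conf_snr``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import erf

from .ephys import SweepSeries
from .volume import ImageVolume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Markers by synapse class (pre, post).
MARKERS = {
    "excitatory": ("VGlut1", "Homer1"),
    "inhibitory": ("Gad67", "Gephyrin"),
}

MAX_EXPECTED_PUNCTAE = 1e7  # resource guard


# ===========================================================================
# Image volumes
# ===========================================================================

@dataclasses.dataclass
class VolumeSpec:
    """Parameters of one synthetic two-modality ROI volume.

    Defaults emulate a 500 µm³ CA1 field (the imaging convention is ROIs of
    roughly 400–700 µm³) sampled at 20 nm laterally with a 100 nm z-step.
    Densities are per µm³; separations and PSF widths in nm.
    """

    size_um: tuple[float, float, float] = (10.0, 10.0, 5.0)
    voxel_um: tuple[float, float, float] = (0.02, 0.02, 0.1)
    synapse_density: float = 0.85
    distractor_density_pre: float = 0.3
    distractor_density_post: float = 0.3
    pair_sep_mean_nm: float = 150.0
    pair_sep_sd_nm: float = 50.0
    psf_sted_fwhm_nm: float = 60.0
    psf_conf_fwhm_nm: float = 250.0
    sted_only_artifact_density: float = 0.1
    snr: float = 15.0
    conf_snr: float | None = None
    synapse_class: str = "excitatory"
    seed: int = 0

    def validate(self) -> None:
        size = np.asarray(self.size_um, dtype=float)
        voxel = np.asarray(self.voxel_um, dtype=float)
        if size.shape != (3,) or np.any(size <= 0):
            raise ValueError("size_um must be a positive 3-vector (zero-extent volume rejected)")
        if voxel.shape != (3,) or np.any(voxel <= 0):
            raise ValueError("voxel_um must be strictly positive elementwise")
        for name in ("synapse_density", "distractor_density_pre", "distractor_density_post",
                     "sted_only_artifact_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pair_sep_sd_nm < 0:
            raise ValueError("pair_sep_sd_nm must be >= 0")
        if self.psf_conf_fwhm_nm < self.psf_sted_fwhm_nm:
            raise ValueError("confocal PSF FWHM must be >= STED PSF FWHM")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.synapse_class not in MARKERS:
            raise ValueError(f"synapse_class must be one of {sorted(MARKERS)}")
        volume = float(np.prod(size))
        expected = volume * (
            2 * self.synapse_density
            + self.distractor_density_pre
            + self.distractor_density_post
            + 2 * self.sted_only_artifact_density
        )
        if expected > MAX_EXPECTED_PUNCTAE:
            raise ValueError(
                f"spec implies ~{expected:.2e} punctae (> {MAX_EXPECTED_PUNCTAE:.0e}); "
                "refusing to allocate"
            )

    @property
    def volume_um3(self) -> float:
        return float(np.prod(np.asarray(self.size_um, dtype=float)))


@dataclasses.dataclass
class GroundTruth:
    """Exact punctum geometry behind one synthetic volume.

    ``pre_loci`` / ``post_loci`` hold all true punctae of the channel (paired
    synapses first, then distractors) as ``(x, y, z)`` µm rows;
    ``pre_paired`` / ``post_paired`` flag membership in a pre/post couple.
    STED-only artifacts are kept separately — they are not punctae, merely
    false maxima of the STED modality.
    """

    synapse_loci: np.ndarray
    pre_loci: np.ndarray
    post_loci: np.ndarray
    pre_paired: np.ndarray
    post_paired: np.ndarray
    pre_artifact_loci: np.ndarray
    post_artifact_loci: np.ndarray

    @property
    def n_synapses(self) -> int:
        return self.synapse_loci.shape[0]

    def to_csv(self, path: str | Path) -> Path:
        rows = []
        for coords, paired, channel in (
            (self.pre_loci, self.pre_paired, "pre"),
            (self.post_loci, self.post_paired, "post"),
        ):
            for (x, y, z), p in zip(coords, paired):
                rows.append((x, y, z, channel, "paired" if p else "unpaired"))
        for coords, channel in (
            (self.pre_artifact_loci, "pre"),
            (self.post_artifact_loci, "post"),
        ):
            for x, y, z in coords:
                rows.append((x, y, z, channel, "sted_artifact"))
        df = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "channel", "paired_flag"])
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def sample_ground_truth(spec: VolumeSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw punctum geometry only (no rendering) — a homogeneous Poisson process.

    Paired synapse loci are uniform in the box at ``synapse_density``; each
    pair is split into a pre and a post locus separated by a random offset of
    length ~ Normal(pair_sep_mean, pair_sep_sd) (truncated at 0) along a
    uniform random direction.  Distractors are drawn independently per
    channel; STED-only artifact positions independently per channel.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    size = np.asarray(spec.size_um, dtype=float)
    vol = spec.volume_um3

    def uniform_points(n: int) -> np.ndarray:
        return rng.uniform(0.0, 1.0, size=(n, 3)) * size

    n_syn = rng.poisson(spec.synapse_density * vol)
    loci = uniform_points(n_syn)
    lengths_um = np.maximum(
        rng.normal(spec.pair_sep_mean_nm, spec.pair_sep_sd_nm, size=n_syn), 0.0
    ) / 1000.0
    offsets = _unit_vectors(rng, n_syn) * lengths_um[:, None]
    pre_pair = loci + 0.5 * offsets
    post_pair = loci - 0.5 * offsets

    pre_dis = uniform_points(rng.poisson(spec.distractor_density_pre * vol))
    post_dis = uniform_points(rng.poisson(spec.distractor_density_post * vol))
    pre_art = uniform_points(rng.poisson(spec.sted_only_artifact_density * vol))
    post_art = uniform_points(rng.poisson(spec.sted_only_artifact_density * vol))

    return GroundTruth(
        synapse_loci=loci,
        pre_loci=np.vstack([pre_pair, pre_dis]),
        post_loci=np.vstack([post_pair, post_dis]),
        pre_paired=np.r_[np.ones(n_syn, bool), np.zeros(len(pre_dis), bool)],
        post_paired=np.r_[np.ones(n_syn, bool), np.zeros(len(post_dis), bool)],
        pre_artifact_loci=pre_art,
        post_artifact_loci=post_art,
    )


def peak_voxel_fraction(fwhm_nm: float, voxel_um: tuple[float, float, float]) -> float:
    """Fraction of a unit-energy punctum landing in its centre voxel (spot centred)."""
    sigma = fwhm_nm * _FWHM_TO_SIGMA / 1000.0
    v = np.asarray(voxel_um, dtype=float)
    return float(np.prod(erf(v / 2.0 / (sigma * np.sqrt(2.0)))))


def render_spots(
    grid: np.ndarray,
    voxel_um: tuple[float, float, float],
    centers_xyz: np.ndarray,
    fwhm_nm: float,
    energy: float,
) -> None:
    """Deposit ``energy`` per punctum into ``grid`` as an integrated 3D Gaussian.

    Each voxel receives the exact integral of the Gaussian over its extent
    (product of per-axis erf differences), truncated at 4σ, so total deposited
    intensity is independent of FWHM to well under 1%.
    """
    sigma = fwhm_nm * _FWHM_TO_SIGMA / 1000.0
    vx, vy, vz = (float(v) for v in voxel_um)
    nz, ny, nx = grid.shape
    centers = np.atleast_2d(np.asarray(centers_xyz, dtype=float))
    sq2 = sigma * np.sqrt(2.0)

    def axis_profile(c: float, v: float, n: int) -> tuple[int, np.ndarray]:
        r = max(4.0 * sigma, v)
        lo = max(0, int(np.floor((c - r) / v)))
        hi = min(n, int(np.ceil((c + r) / v)))
        if hi <= lo:
            return lo, np.empty(0)
        edges = np.arange(lo, hi + 1) * v
        cdf = 0.5 * (1.0 + erf((edges - c) / sq2))
        return lo, np.diff(cdf)

    for cx, cy, cz in centers:
        x0, px = axis_profile(cx, vx, nx)
        y0, py = axis_profile(cy, vy, ny)
        z0, pz = axis_profile(cz, vz, nz)
        if min(len(px), len(py), len(pz)) == 0:
            continue
        patch = energy * pz[:, None, None] * py[None, :, None] * px[None, None, :]
        grid[z0:z0 + len(pz), y0:y0 + len(py), x0:x0 + len(px)] += patch


def generate_synapse_volume(
    spec: VolumeSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, ImageVolume, GroundTruth]:
    """Render one ROI as four volumes (STED/confocal × pre/post) plus ground truth.

    True punctae appear in both modalities; STED-only artifacts only in STED.
    Peak (spot-centred) signal is ``snr`` noise-SD units in each modality; STED
    noise SD is 1, the confocal channel is noiseless unless ``conf_snr`` is set.
    Noise is clipped at zero to keep intensities non-negative.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = sample_ground_truth(spec, rng)

    size = np.asarray(spec.size_um, dtype=float)
    voxel = np.asarray(spec.voxel_um, dtype=float)
    nx, ny, nz = (int(round(s / v)) for s, v in zip(size, voxel))
    shape = (nz, ny, nx)

    peak = spec.snr if np.isfinite(spec.snr) else 1.0
    e_sted = peak / peak_voxel_fraction(spec.psf_sted_fwhm_nm, tuple(voxel))
    e_conf = peak / peak_voxel_fraction(spec.psf_conf_fwhm_nm, tuple(voxel))
    sd_sted = 1.0 if np.isfinite(spec.snr) else 0.0
    sd_conf = peak / spec.conf_snr if spec.conf_snr else 0.0

    pre_marker, post_marker = MARKERS[spec.synapse_class]
    out = {}
    for channel, marker, loci, art in (
        ("pre", pre_marker, truth.pre_loci, truth.pre_artifact_loci),
        ("post", post_marker, truth.post_loci, truth.post_artifact_loci),
    ):
        sted = np.zeros(shape, dtype=np.float64)
        render_spots(sted, tuple(voxel), loci, spec.psf_sted_fwhm_nm, e_sted)
        render_spots(sted, tuple(voxel), art, spec.psf_sted_fwhm_nm, e_sted)
        conf = np.zeros(shape, dtype=np.float64)
        render_spots(conf, tuple(voxel), loci, spec.psf_conf_fwhm_nm, e_conf)
        if sd_sted > 0:
            sted += rng.normal(0.0, sd_sted, size=shape)
        if sd_conf > 0:
            conf += rng.normal(0.0, sd_conf, size=shape)
        np.clip(sted, 0.0, None, out=sted)
        np.clip(conf, 0.0, None, out=conf)
        out[("STED", channel)] = ImageVolume(sted.astype(np.float32), voxel, "STED", channel, marker)
        out[("confocal", channel)] = ImageVolume(conf.astype(np.float32), voxel, "confocal", channel, marker)

    return (
        out[("STED", "pre")],
        out[("STED", "post")],
        out[("confocal", "pre")],
        out[("confocal", "post")],
        truth,
    )


# ===========================================================================
# Field-potential traces
# ===========================================================================

# Response template layout, ms relative to stimulus onset.  The artifact is a
# 0.4 ms biphasic square pulse; the fiber volley a narrow negative Gaussian;
# the fEPSP a linear falling phase (constant initial slope) followed by an
# exponential recovery.
ARTIFACT_MS = 0.4
VOLLEY_CENTER_MS = 1.2
VOLLEY_SIGMA_MS = 0.2
FEPSP_ONSET_MS = 2.5
RECOVERY_TAU_MS = 4.0


@dataclasses.dataclass
class TraceSpec:
    """Parameters of a synthetic evoked field-potential sweep."""

    sampling_khz: float = 10.0
    baseline_ms: float = 10.0
    artifact_amp_mv: float = 1.0
    volley_amp_mv: float = 0.3
    fepsp_amp_mv: float = 0.6
    fepsp_slope_mv_per_ms: float = 0.5
    ppf_factor: float = 1.0
    interpulse_ms: float = 40.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_khz < 10:
            raise ValueError("sampling_khz must be >= 10 (10 kHz digitization convention)")
        if self.interpulse_ms <= 0:
            raise ValueError("interpulse_ms must be > 0")
        if self.ppf_factor <= 0:
            raise ValueError("ppf_factor must be > 0")
        if self.fepsp_amp_mv <= 0 or self.fepsp_slope_mv_per_ms <= 0:
            raise ValueError("fEPSP amplitude and slope must be > 0")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")

    @property
    def fall_ms(self) -> float:
        return self.fepsp_amp_mv / self.fepsp_slope_mv_per_ms

    @property
    def template_span_ms(self) -> float:
        """Duration after the stimulus over which the response is non-negligible."""
        return FEPSP_ONSET_MS + self.fall_ms + 4.0 * RECOVERY_TAU_MS


def _add_response(
    v: np.ndarray,
    sampling_khz: float,
    stim_ms: float,
    spec: TraceSpec,
    fepsp_gain: float = 1.0,
    volley_gain: float = 1.0,
) -> None:
    # relative times from the stimulus *sample* so that every epoch sees the
    # same bit-exact time grid regardless of its absolute position
    t = (np.arange(len(v)) - int(round(stim_ms * sampling_khz))) / sampling_khz
    half = ARTIFACT_MS / 2.0
    v[(t >= 0) & (t < half)] += spec.artifact_amp_mv
    v[(t >= half) & (t < ARTIFACT_MS)] -= spec.artifact_amp_mv
    v -= (volley_gain * spec.volley_amp_mv) * np.exp(
        -0.5 * ((t - VOLLEY_CENTER_MS) / VOLLEY_SIGMA_MS) ** 2
    )
    amp = fepsp_gain * spec.fepsp_amp_mv
    slope = fepsp_gain * spec.fepsp_slope_mv_per_ms
    fall = spec.fall_ms  # amp/slope: gain cancels, shape scales linearly
    on_fall = (t >= FEPSP_ONSET_MS) & (t < FEPSP_ONSET_MS + fall)
    v[on_fall] -= slope * (t[on_fall] - FEPSP_ONSET_MS)
    on_rec = t >= FEPSP_ONSET_MS + fall
    v[on_rec] -= amp * np.exp(-(t[on_rec] - FEPSP_ONSET_MS - fall) / RECOVERY_TAU_MS)


def generate_paired_pulse_trace(spec: TraceSpec) -> SweepSeries:
    """One sweep with two stimulus epochs at ``interpulse_ms`` spacing.

    The second fEPSP is scaled by ``ppf_factor``; the artifact and fiber
    volley are presynaptic and not facilitated.  Rejected when the interpulse
    interval is shorter than the response template (overlapping responses are
    unsupported).
    """
    spec.validate()
    if spec.interpulse_ms < spec.template_span_ms:
        raise ValueError(
            f"interpulse {spec.interpulse_ms} ms shorter than the fEPSP template "
            f"({spec.template_span_ms:.1f} ms); overlapping responses unsupported"
        )
    rng = np.random.default_rng(spec.seed)
    khz = spec.sampling_khz
    span_ms = spec.baseline_ms + spec.interpulse_ms + spec.template_span_ms + 5.0
    n = int(round(span_ms * khz))
    v = np.zeros(n)
    stim1 = spec.baseline_ms
    stim2 = spec.baseline_ms + spec.interpulse_ms
    _add_response(v, khz, stim1, spec)
    _add_response(v, khz, stim2, spec, fepsp_gain=spec.ppf_factor)
    if spec.noise_sd_mv > 0:
        v += rng.normal(0.0, spec.noise_sd_mv, size=n)
    return SweepSeries(
        sampling_khz=khz,
        sweeps=v[None, :],
        timestamps_s=np.array([0.0]),
        stimulus_times_ms=[[stim1, stim2]],
        protocol="PPF",
    )


def generate_io_series(
    spec: TraceSpec,
    stimulus_scales: np.ndarray | list[float],
    response_gain: float = 1.0,
) -> SweepSeries:
    """One single-stimulus sweep per stimulus intensity scale.

    The fiber volley scales with stimulus intensity; the fEPSP with intensity
    times ``response_gain`` — a proportional I/O law whose gain can be reduced
    to emulate impaired basal transmission.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    khz = spec.sampling_khz
    span_ms = spec.baseline_ms + spec.template_span_ms + 5.0
    n = int(round(span_ms * khz))
    sweeps, stims = [], []
    for scale in stimulus_scales:
        v = np.zeros(n)
        _add_response(v, khz, spec.baseline_ms, spec,
                      fepsp_gain=float(scale) * response_gain, volley_gain=float(scale))
        if spec.noise_sd_mv > 0:
            v += rng.normal(0.0, spec.noise_sd_mv, size=n)
        sweeps.append(v)
        stims.append([spec.baseline_ms])
    return SweepSeries(
        sampling_khz=khz,
        sweeps=np.vstack(sweeps),
        timestamps_s=np.arange(len(sweeps), dtype=float) * 20.0,
        stimulus_times_ms=stims,
        protocol="IO",
    )


# ===========================================================================
# Plasticity time courses
# ===========================================================================

@dataclasses.dataclass
class TimeCourseSpec:
    """Parameters of a plasticity experiment time course.

    The normalized fEPSP slope is 100% during the baseline, then
    ``plateau_pct + transient_pct * exp(-t/transient_tau_min)`` (t in minutes
    after induction).  Sweeps are full voltage traces whose fEPSP component is
    scaled accordingly, so the downstream slope measurement is exercised
    end-to-end.
    """

    protocol: str = "LTP"
    baseline_min: float = 10.0
    total_min: float = 70.0
    sweep_interval_s: float = 20.0
    plateau_pct: float = 140.0
    transient_pct: float = 0.0
    transient_tau_min: float = 2.0
    noise_sd_pct: float = 0.0
    trace: TraceSpec = dataclasses.field(default_factory=TraceSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.protocol not in ("LTP", "LTD", "PTP"):
            raise ValueError("protocol must be LTP, LTD or PTP")
        if self.baseline_min < 10:
            raise ValueError("baseline_min must be >= 10 (10 min online baseline convention)")
        if self.total_min <= self.baseline_min:
            raise ValueError("total_min must exceed baseline_min")
        if self.plateau_pct <= 0:
            raise ValueError("plateau_pct must be > 0")
        if self.transient_tau_min <= 0:
            raise ValueError("transient_tau_min must be > 0")
        self.trace.validate()


def normalized_pct_at(spec: TimeCourseSpec, minutes_post: float) -> float:
    """The generator's noise-free normalized slope (%) at a time after induction."""
    if minutes_post < 0:
        return 100.0
    return spec.plateau_pct + spec.transient_pct * np.exp(-minutes_post / spec.transient_tau_min)


def generate_plasticity_timecourse(spec: TimeCourseSpec) -> SweepSeries:
    """Sweep series whose fEPSP slope follows the plasticity schedule.

    Induction happens at ``baseline_min`` (recorded in the series); sweeps are
    evoked every ``sweep_interval_s``.  Multiplicative Gaussian noise of
    ``noise_sd_pct`` percent is applied per sweep to the response scale.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    khz = spec.trace.sampling_khz
    span_ms = spec.trace.baseline_ms + spec.trace.template_span_ms + 5.0
    n = int(round(span_ms * khz))
    induction_s = spec.baseline_min * 60.0
    times_s = np.arange(0.0, spec.total_min * 60.0, spec.sweep_interval_s)
    sweeps, stims = [], []
    for t_s in times_s:
        pct = normalized_pct_at(spec, (t_s - induction_s) / 60.0) if t_s >= induction_s else 100.0
        factor = pct / 100.0
        if spec.noise_sd_pct > 0:
            factor *= 1.0 + rng.normal(0.0, spec.noise_sd_pct / 100.0)
        factor = max(factor, 0.05)
        v = np.zeros(n)
        _add_response(v, khz, spec.trace.baseline_ms, spec.trace, fepsp_gain=factor)
        if spec.trace.noise_sd_mv > 0:
            v += rng.normal(0.0, spec.trace.noise_sd_mv, size=n)
        sweeps.append(v)
        stims.append([spec.trace.baseline_ms])
    return SweepSeries(
        sampling_khz=khz,
        sweeps=np.vstack(sweeps),
        timestamps_s=times_s,
        stimulus_times_ms=stims,
        protocol=spec.protocol,
        induction_time_s=induction_s,
    )


# ===========================================================================
# Expression matrices
# ===========================================================================

def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene names G00000, G00001, ..."""
    return [f"G{i:05d}" for i in range(n_genes)]


def generate_expression_matrix(
    n_genes: int,
    n_per_group: int | tuple[int, int],
    enriched_set: list[str],
    effect_sd_units: float,
    seed: int = 0,
    group_names: tuple[str, str] = ("WT", "KO"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group expression matrix with a planted enriched gene set.

    Background genes are N(0, 1) in both groups; genes of ``enriched_set``
    are shifted up by ``effect_sd_units`` in the first group, so the planted
    set is enriched in ``group_names[0]``.  Returns ``(matrix, labels)`` with
    genes as rows and samples as columns.
    """
    if isinstance(n_per_group, int):
        n_a = n_b = n_per_group
    else:
        n_a, n_b = n_per_group
    if min(n_a, n_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    genes = gene_universe(n_genes)
    if len(set(enriched_set)) != len(enriched_set):
        raise ValueError("duplicate gene names in enriched_set")
    missing = set(enriched_set) - set(genes)
    if missing:
        raise ValueError(f"enriched_set genes outside the universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_genes, n_a + n_b))
    idx = [genes.index(g) for g in enriched_set]
    x[idx, :n_a] += effect_sd_units
    cols = [f"{group_names[0]}_{i + 1:02d}" for i in range(n_a)] + [
        f"{group_names[1]}_{i + 1:02d}" for i in range(n_b)
    ]
    matrix = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=cols)
    labels = pd.Series([group_names[0]] * n_a + [group_names[1]] * n_b,
                       index=cols, name="group")
    return matrix, labels


# ===========================================================================
# Spec (de)serialization
# ===========================================================================

_SPEC_TYPES = {cls.__name__: cls for cls in (VolumeSpec, TraceSpec, TimeCourseSpec)}


def save_spec(spec, path: str | Path) -> Path:
    """Write any generator spec as YAML (round-trips with :func:`load_spec`)."""
    d = dataclasses.asdict(spec)
    payload = {"kind": type(spec).__name__, "params": d}
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_spec(path: str | Path):
    payload = yaml.safe_load(Path(path).read_text())
    kind = payload.get("kind")
    if kind not in _SPEC_TYPES:
        raise ValueError(f"unknown spec kind {kind!r}")
    params = dict(payload.get("params") or {})
    if kind == "TimeCourseSpec" and isinstance(params.get("trace"), dict):
        params["trace"] = TraceSpec(**params["trace"])
    for key in ("size_um", "voxel_um"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    return _SPEC_TYPES[kind](**params)
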