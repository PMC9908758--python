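"""Synthetic factorial SEP studies with known ground truth.

The generator emulates the statistical structure of a 2x2 within-subject
visuo-motor conflict experiment with median-nerve somatosensory evoked
potentials: a small number of focal dipole sources with Gaussian
amplitude time courses (P45/N60-like early components), projected
through the homogeneous-sphere forward model, with per-subject gain and
latency variability, sensor and spatially-correlated background noise,
occasional high-amplitude artifact epochs, plus questionnaire ratings
and hand-trajectory kinematics with configurable condition effects.

Everything is reproducible from a single integer seed, and the returned
ground-truth record contains every derived random quantity needed to
rebuild each epoch exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    CONDITIONS,
    BehavioralTable,
    EpochedEEG,
    condition_factors,
)
from .montage import ElectrodeMontage, default_montage
from .sources import LeadField, SourceSpace, build_source_space, leadfield_single_sphere

__all__ = [
    "Dipole",
    "SourceConfig",
    "NoiseConfig",
    "BehavioralConfig",
    "simulate_evoked_study",
    "iter_evoked_study",
    "simulate_behavior",
    "simulate_trajectories",
    "default_source_config",
    "default_noise_config",
    "default_behavioral_config",
    "default_forward_model",
]


@dataclass(frozen=True)
class Dipole:
    """One focal source: position (mm), unit orientation, Gaussian burst.

    ``condition_gain`` maps a factor level ("congruent", "asynchronous",
    ...) or a full condition id to a multiplicative amplitude gain; gains
    for all matching keys multiply, unmatched cells get 1.
    """

    position_mm: tuple[float, float, float]
    orientation: tuple[float, float, float]
    latency_ms: float
    width_ms: float
    peak_nam: float
    condition_gain: dict = field(default_factory=dict)

    def cell_gain(self, condition: str) -> float:
        congruency, synchrony = condition_factors(condition)
        g = 1.0
        for key, val in self.condition_gain.items():
            if key in (condition, congruency, synchrony):
                g *= float(val)
        return g


@dataclass(frozen=True)
class SourceConfig:
    dipoles: tuple[Dipole, ...]
    gain_sd: float = 0.1  # per-subject multiplicative gain SD
    latency_jitter_sd_ms: float = 2.0  # per-subject latency shift SD

    def validate(self, epoch_window_s: tuple[float, float]) -> None:
        lo, hi = epoch_window_s[0] * 1e3, epoch_window_s[1] * 1e3
        for d in self.dipoles:
            if not lo <= d.latency_ms < hi:
                raise ValueError(f"dipole latency {d.latency_ms} ms outside epoch window")
            if d.width_ms <= 0:
                raise ValueError("dipole width must be positive")
            if d.peak_nam <= 0:
                raise ValueError("dipole peak amplitude must be positive")
            for g in d.condition_gain.values():
                if g <= 0:
                    raise ValueError("condition gains must be positive")
        if self.gain_sd < 0 or self.latency_jitter_sd_ms < 0:
            raise ValueError("variability SDs must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    sensor_sd_uv: float = 3.0
    spatial_sd_uv: float = 2.0
    spatial_scale: float = 0.8  # correlation length as unit-sphere chord
    artifact_rate: float = 0.02
    artifact_amp_uv: float = 40.0
    seed: int | None = None

    def validate(self) -> None:
        if self.sensor_sd_uv < 0 or self.spatial_sd_uv < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact rate must be in [0, 1]")


@dataclass(frozen=True)
class BehavioralConfig:
    """Per-cell mean/SD of each behavioural outcome.

    ``means[outcome]`` maps condition id -> mean; ``sds[outcome]`` is a
    scalar SD.  Ratings are truncated to [0, 10]; kinematics to >= 0.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> None:
        for outcome, cell_means in self.means.items():
            for cond, m in cell_means.items():
                condition_factors(cond)
                if outcome.endswith("_rating") and not 0 <= m <= 10:
                    raise ValueError(f"{outcome} mean {m} outside [0, 10]")
            if self.sds.get(outcome, 0.0) < 0:
                raise ValueError("SDs must be >= 0")


# ---------------------------------------------------------------------------
# default study conditions


def default_forward_model(
    montage: ElectrodeMontage | None = None,
    radius_mm: float = 60.0,
    spacing_mm: float = 8.0,
) -> tuple[SourceSpace, LeadField]:
    """Spherical source volume + homogeneous-sphere lead field.

    Default: 60 mm source sphere on an 8 mm grid (~900 nodes) inside an
    85 mm scalp sphere -- a desk-scale stand-in for a template brain.
    """
    montage = montage or default_montage()
    space = build_source_space(radius_mm, spacing_mm, connectivity=26)
    lead = leadfield_single_sphere(space, montage)
    return space, lead


def default_source_config() -> SourceConfig:
    """Two early sources; the right-posterior one gains 1.5x when congruent.

    A left-central source models the somatosensory response contralateral
    to right-wrist stimulation (P45-like, 45 ms); a right-posterior
    parietal source (38 ms) carries the congruency effect, so congruent
    cells show a distinct early topography and stronger posterior
    current density -- the planted analogue of the study's effect.
    """
    return SourceConfig(
        dipoles=(
            Dipole(
                position_mm=(-32.0, -24.0, 40.0),
                orientation=(-0.4, 0.2, 0.89),
                latency_ms=45.0,
                width_ms=8.0,
                peak_nam=25.0,
            ),
            Dipole(
                position_mm=(32.0, -40.0, 32.0),
                orientation=(0.5, -0.5, 0.71),
                latency_ms=38.0,
                width_ms=9.0,
                peak_nam=18.0,
                condition_gain={"congruent": 1.5},
            ),
        ),
        gain_sd=0.1,
        latency_jitter_sd_ms=2.0,
    )


def default_noise_config() -> NoiseConfig:
    return NoiseConfig()


def default_behavioral_config() -> BehavioralConfig:
    """Agency with congruency and synchrony effects (delta = 2, SD = 1);
    flat control ratings; kinematics around 10.6 cm and 6.7 cm/s."""
    agency = {}
    for cond in CONDITIONS:
        congruency, synchrony = condition_factors(cond)
        agency[cond] = 4.0 + 2.0 * (congruency == "congruent") + 2.0 * (
            synchrony == "synchronous"
        )
    flat = lambda v: {cond: v for cond in CONDITIONS}  # noqa: E731
    return BehavioralConfig(
        means={
            "agency_rating": agency,
            "control_rating": flat(5.0),
            "trajectory_norm_cm": flat(10.6),
            "velocity_cm_s": flat(6.7),
        },
        sds={
            "agency_rating": 1.0,
            "control_rating": 1.5,
            "trajectory_norm_cm": 1.9,
            "velocity_cm_s": 0.95,
        },
    )


# ---------------------------------------------------------------------------
# EEG simulation


def _snap_to_node(space: SourceSpace, pos_mm: np.ndarray) -> int:
    d = np.linalg.norm(space.nodes - pos_mm, axis=1)
    i = int(np.argmin(d))
    if d[i] > space.spacing:
        raise ValueError(
            f"dipole at {tuple(pos_mm)} mm lies outside the source space "
            f"(nearest node {d[i]:.1f} mm away)"
        )
    return i


def _gaussian_burst(t_ms: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - latency) / width) ** 2)


def _noise_chol(montage: ElectrodeMontage, cfg: "NoiseConfig") -> np.ndarray | None:
    """Cholesky factor of the total sensor-noise covariance.

    Independent sensor noise (sd^2 I) plus a smooth spatially correlated
    background with squared-exponential covariance over electrode
    positions; one factor, one Gaussian draw per epoch.
    """
    C = montage.n_channels
    K = cfg.sensor_sd_uv**2 * np.eye(C)
    if cfg.spatial_sd_uv > 0:
        diff = montage.positions[:, None, :] - montage.positions[None, :, :]
        Ks = np.exp(-(np.linalg.norm(diff, axis=2) ** 2) / (2.0 * cfg.spatial_scale**2))
        K += cfg.spatial_sd_uv**2 * Ks + 1e-10 * np.eye(C)
    if not K.any():
        return None
    return np.linalg.cholesky(K)


def noiseless_evoked(
    source_cfg: SourceConfig,
    lead: LeadField,
    condition: str,
    t_ms: np.ndarray,
    subject_gain: float = 1.0,
    latency_shift_ms: float = 0.0,
) -> np.ndarray:
    """Deterministic (n_channels, n_samples) cell waveform, in microvolt."""
    space = lead.space
    out = np.zeros((lead.n_channels, t_ms.size))
    for d in source_cfg.dipoles:
        node = _snap_to_node(space, np.asarray(d.position_mm, float))
        ori = np.asarray(d.orientation, float)
        ori = ori / np.linalg.norm(ori)
        pattern = lead.matrix[:, 3 * node : 3 * node + 3] @ ori
        amp = d.peak_nam * d.cell_gain(condition) * subject_gain
        out += np.outer(pattern, amp * _gaussian_burst(t_ms, d.latency_ms + latency_shift_ms, d.width_ms))
    return out


def iter_evoked_study(
    n_subjects: int,
    source_cfg: SourceConfig,
    noise_cfg: NoiseConfig,
    montage: ElectrodeMontage,
    lead: LeadField,
    epochs_per_condition: int = 480,
    sfreq: float = 512.0,
    epoch_window_s: tuple[float, float] = (-0.050, 0.300),
    seed: int | None = None,
    artifact_log: list | None = None,
):
    """Yield simulated subject x condition cells one at a time.

    Streaming twin of :func:`simulate_evoked_study` (identical random
    sequence for a given seed); lets a pipeline preprocess each cell and
    discard the raw epochs without holding the whole study in memory.
    """
    source_cfg.validate(epoch_window_s)
    noise_cfg.validate()
    if lead.montage != montage:
        raise ValueError("lead field was built for a different montage")
    rng = np.random.default_rng(seed if seed is not None else noise_cfg.seed)

    n_samples = int(round((epoch_window_s[1] - epoch_window_s[0]) * sfreq))
    t_ms = (epoch_window_s[0] + np.arange(n_samples) / sfreq) * 1e3

    subj_gain = np.maximum(1.0 + source_cfg.gain_sd * rng.standard_normal(n_subjects), 0.2)
    subj_shift = source_cfg.latency_jitter_sd_ms * rng.standard_normal(n_subjects)
    chol = _noise_chol(montage, noise_cfg)

    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for cond in CONDITIONS:
            evoked = noiseless_evoked(
                source_cfg, lead, cond, t_ms, subj_gain[s], subj_shift[s]
            )
            data = np.broadcast_to(
                evoked, (epochs_per_condition, *evoked.shape)
            ).copy()
            if chol is not None:
                z = rng.standard_normal((epochs_per_condition, montage.n_channels, n_samples))
                data += np.einsum("ij,ejt->eit", chol, z)
            if noise_cfg.artifact_rate > 0:
                hit = rng.random(epochs_per_condition) < noise_cfg.artifact_rate
                for e in np.flatnonzero(hit):
                    ch = int(rng.integers(montage.n_channels))
                    centre = float(rng.uniform(t_ms[0], t_ms[-1]))
                    data[e, ch] += noise_cfg.artifact_amp_uv * _gaussian_burst(
                        t_ms, centre, 15.0
                    )
                    if artifact_log is not None:
                        artifact_log.append((subject, cond, int(e), ch))
            yield EpochedEEG(
                data=data,
                sfreq=sfreq,
                t0_offset=epoch_window_s[0],
                subject_id=subject,
                condition_id=cond,
                montage=montage,
            ), {"subject_gain": subj_gain[s], "latency_shift_ms": subj_shift[s]}


def simulate_evoked_study(
    n_subjects: int,
    source_cfg: SourceConfig,
    noise_cfg: NoiseConfig,
    montage: ElectrodeMontage,
    lead: LeadField,
    epochs_per_condition: int = 480,
    sfreq: float = 512.0,
    epoch_window_s: tuple[float, float] = (-0.050, 0.300),
    seed: int | None = None,
) -> tuple[list[EpochedEEG], dict]:
    """Simulate the full multi-subject factorial SEP study.

    Per subject x condition, each epoch is the lead-field projection of
    the dipole time courses (with once-per-subject gain and latency
    jitter) plus sensor noise, spatially correlated background noise and
    occasional artifact bursts.  Returns the epoched collection and a
    ground-truth record (configs, seeds, per-subject parameters, true
    node indices, per-cell gains) sufficient to rebuild every epoch.
    """
    artifact_log: list = []
    cells = iter_evoked_study(
        n_subjects,
        source_cfg,
        noise_cfg,
        montage,
        lead,
        epochs_per_condition,
        sfreq,
        epoch_window_s,
        seed,
        artifact_log=artifact_log,
    )
    collection: list[EpochedEEG] = []
    subj_gain: dict[str, float] = {}
    subj_shift: dict[str, float] = {}
    for cell, params in cells:
        collection.append(cell)
        subj_gain[cell.subject_id] = float(params["subject_gain"])
        subj_shift[cell.subject_id] = float(params["latency_shift_ms"])

    true_nodes = [
        _snap_to_node(lead.space, np.asarray(d.position_mm, float))
        for d in source_cfg.dipoles
    ]
    ground_truth = {
        "seed": seed,
        "source_config": asdict(source_cfg),
        "noise_config": asdict(noise_cfg),
        "epochs_per_condition": epochs_per_condition,
        "sfreq": sfreq,
        "epoch_window_s": list(epoch_window_s),
        "true_nodes": true_nodes,
        "subject_gain": subj_gain,
        "subject_latency_shift_ms": subj_shift,
        "cell_gain": {
            cond: [d.cell_gain(cond) for d in source_cfg.dipoles] for cond in CONDITIONS
        },
        "artifact_epochs": artifact_log,
    }
    return collection, ground_truth


# ---------------------------------------------------------------------------
# behavioural simulation


def _truncate(outcome: str, values: np.ndarray) -> np.ndarray:
    if outcome.endswith("_rating"):
        return np.clip(values, 0.0, 10.0)
    return np.maximum(values, 0.0)


def simulate_behavior(
    n_subjects: int, cfg: BehavioralConfig | None = None, seed: int | None = None
) -> BehavioralTable:
    """Truncated-normal per-cell draws of every configured outcome."""
    cfg = cfg or default_behavioral_config()
    cfg.validate()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    rows = []
    subjects = [f"S{s + 1:02d}" for s in range(n_subjects)]
    for subject in subjects:
        for cond in CONDITIONS:
            congruency, synchrony = condition_factors(cond)
            row = {"subject": subject, "congruency": congruency, "synchrony": synchrony}
            for outcome, cell_means in cfg.means.items():
                sd = cfg.sds.get(outcome, 0.0)
                val = cell_means[cond] + sd * rng.standard_normal()
                row[outcome] = float(_truncate(outcome, np.asarray(val)))
            rows.append(row)
    return BehavioralTable(pd.DataFrame(rows))


def simulate_trajectories(
    n_subjects: int,
    cfg: BehavioralConfig | None = None,
    trial_duration_s: float = 15.0,
    sample_rate_hz: float = 50.0,
    n_trials: int = 4,
    noise_cm: float = 0.05,
    seed: int | None = None,
) -> dict[tuple[str, str], list[np.ndarray]]:
    """Left-right sinusoidal hand paths matching the configured kinematics.

    For a sweep (peak-to-peak) amplitude A and mean speed v, the sinusoid
    frequency is f = v / (2 A), since a sinusoid travels 2 A per cycle.
    Returns (subject, condition) -> list of (n_samples, 4) arrays with
    columns t (s), x, y, z (cm).
    """
    cfg = cfg or default_behavioral_config()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, trial_duration_s, 1.0 / sample_rate_hz)
    out: dict[tuple[str, str], list[np.ndarray]] = {}
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        subj_amp = rng.normal(0.0, cfg.sds.get("trajectory_norm_cm", 0.0))
        subj_vel = rng.normal(0.0, cfg.sds.get("velocity_cm_s", 0.0))
        for cond in CONDITIONS:
            A = max(cfg.means["trajectory_norm_cm"][cond] + subj_amp, 1.0)
            v = max(cfg.means["velocity_cm_s"][cond] + subj_vel, 0.5)
            f = v / (2.0 * A)
            trials = []
            for _ in range(n_trials):
                phase = rng.uniform(0, 2 * np.pi)
                x = 0.5 * A * np.sin(2 * np.pi * f * t + phase)
                xyz = np.column_stack(
                    [x, np.zeros_like(x), np.zeros_like(x)]
                ) + noise_cm * rng.standard_normal((t.size, 3))
                trials.append(np.column_stack([t, xyz]))
            out[(subject, cond)] = trials
    return out
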