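"""Synthetic TMS-EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes: a cohort
of middle-aged adults with pre- and intra-pandemic PHQ-4 scores, PSS-14
perceived stress, and per-target evoked responses whose late local component
(around the P180-vicinity response) scales with a latent vulnerability score
for the L-DLPFC target only.  Subject-average evoked series are generated
directly — the noise level is interpreted as the residual noise of a
~120-trial average — with AR(1)-filtered Gaussian noise so that neighbouring
timepoints are correlated, which is the situation cluster correction exists
for.

Group labels are never drawn: they emerge from applying the resilience
classification rule to the generated PHQ-4 trajectories, so classification
and group-difference machinery are exercised jointly.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .groupstats import classify_resilience, mean_pandemic_score
from .io import (
    CohortTable,
    ROIDefinition,
    TEPTimeSeries,
    tep_filename,
    write_cohort,
    write_tep,
)


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass
class Component:
    """One Gaussian bump of the evoked response."""

    latency_ms: float
    width_ms: float
    amplitude_uv: float
    roi_weight: float = 1.0


@dataclass
class NoiseConfig:
    """Coloured noise of the trial-averaged series: AR(1)-filtered Gaussian.

    ``sd_uv`` is the marginal (stationary) standard deviation per series.
    """

    ar1: float = 0.95
    sd_uv: float = 2.0


def default_components() -> list[Component]:
    """Canonical TEP deflection sequence (alternating polarity, late bump at 230 ms)."""
    return [
        Component(30.0, 8.0, 2.0),
        Component(45.0, 10.0, -3.0),
        Component(60.0, 12.0, 2.5),
        Component(100.0, 20.0, -3.5),
        Component(185.0, 28.0, 2.0),
        Component(230.0, 26.0, 2.5),
    ]


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    PHQ dynamics: each pandemic timepoint is
    ``clip(round(phq_pre + phq_drift + vulnerability_link * v
    - education_effect * (education - 18) + noise), 0, 12)`` with latent
    vulnerability ``v ~ N(0, 1)``.  PSS-14 is a monotone rescaling of the
    mean pandemic PHQ plus noise (``pss_noise_sd``), calibrated so the
    cohort-level Spearman correlation between the two sits near .69.
    """

    n_subjects: int = 74
    seed: int = 0
    fs_hz: float = 1000.0
    epoch_ms: tuple[float, float] = (-1000.0, 2000.0)
    components: list[Component] = field(default_factory=default_components)
    late_window_ms: tuple[float, float] = (202.0, 269.0)
    effect_size: float = 1.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    # questionnaire dynamics
    vulnerability_link: float = 1.5
    education_effect: float = 0.12
    phq_drift: float = -0.4
    phq_noise_sd: float = 1.0
    phq_pre_p: float = 0.15
    pss_noise_sd: float = 1.6
    pss_intercept: float = 10.5
    pss_slope: float = 2.6
    # demographics
    age_range: tuple[int, int] = (42, 66)
    education_range: tuple[int, int] = (8, 28)
    female_fraction: float = 34 / 74
    anatomical_fraction: float = 29 / 74
    months_since_tms_range: tuple[int, int] = (1, 20)
    # completion structure
    timepoint_fractions: tuple[float, float, float] = (0.08, 0.23, 0.69)
    p_dlpfc: float = 0.76
    p_ipl: float = 0.74
    p_both: float = 0.50
    # spatial layout
    n_roi_vertices: int = 100
    n_sensors: int = 64
    off_roi_weight: float = 0.3
    gain_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigError("n_subjects must be >= 4")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        t0, t1 = self.epoch_ms
        if not (t0 < t1):
            raise ConfigError("epoch must be a non-empty interval")
        for a, b in (self.late_window_ms, (-500.0, -3.0), (15.0, 400.0)):
            if a < t0 or b > t1:
                raise ConfigError(f"window [{a}, {b}] ms outside epoch {self.epoch_ms}")
        fr = self.timepoint_fractions
        if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigError(f"timepoint_fractions must be a distribution, got {fr}")
        for name in ("p_dlpfc", "p_ipl", "p_both"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.p_both > min(self.p_dlpfc, self.p_ipl):
            raise ConfigError("p_both cannot exceed either marginal completion rate")
        if self.p_dlpfc + self.p_ipl - self.p_both > 1 + 1e-9:
            raise ConfigError("completion fractions imply a negative 'neither' cell")
        if not 0 <= self.noise.ar1 < 1:
            raise ConfigError("AR(1) coefficient must be in [0, 1)")
        if self.noise.sd_uv < 0 or self.phq_noise_sd < 0 or self.pss_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_ms
        return int(round((t1 - t0) / 1000.0 * self.fs_hz)) + 1

    def times(self) -> np.ndarray:
        return self.epoch_ms[0] + np.arange(self.n_samples) / self.fs_hz * 1000.0

    def late_component_index(self) -> int:
        """Index of the component whose latency falls in the late window."""
        a, b = self.late_window_ms
        for i, c in enumerate(self.components):
            if a <= c.latency_ms <= b:
                return i
        raise ConfigError(f"no component latency inside late window [{a}, {b}] ms")


@dataclass
class LatentProfile:
    """Ground truth for one simulated subject (for recovery tests only)."""

    subject_id: str
    vulnerability: float
    group_truth: str | None = None  # filled in after PHQ generation


def make_roi(target: str, config: SimulationConfig) -> ROIDefinition:
    """Fixed ROI vertex ids used by the generator: a disjoint block per target."""
    n = config.n_roi_vertices
    if target == "DLPFC":
        ids = [f"v{i:04d}" for i in range(n)]
    elif target == "IPL":
        ids = [f"v{i:04d}" for i in range(n, 2 * n)]
    else:
        raise ConfigError(f"unknown target {target!r}")
    return ROIDefinition(target=target, vertex_ids=ids)


def _source_series_ids(config: SimulationConfig) -> list[str]:
    return [f"v{i:04d}" for i in range(2 * config.n_roi_vertices)]


def _sensor_series_ids(config: SimulationConfig) -> list[str]:
    return [f"ch{i:02d}" for i in range(config.n_sensors)]


def _component_waveforms(config: SimulationConfig) -> np.ndarray:
    """(n_components, n_samples) unit-amplitude Gaussian bumps."""
    t = config.times()
    return np.stack(
        [np.exp(-0.5 * ((t - c.latency_ms) / c.width_ms) ** 2) for c in config.components]
    )


def _ar1_noise(rng: np.random.Generator, n_series: int, n_samples: int,
               noise: NoiseConfig) -> np.ndarray:
    """(n_samples, n_series) stationary AR(1) noise with marginal sd sd_uv."""
    if noise.sd_uv == 0:
        return np.zeros((n_samples, n_series))
    innov_sd = noise.sd_uv * np.sqrt(1.0 - noise.ar1**2)
    eps = rng.normal(0.0, innov_sd, size=(n_series, n_samples))
    # warm start from the stationary distribution to avoid a transient
    eps[:, 0] = rng.normal(0.0, noise.sd_uv, size=n_series)
    x = lfilter([1.0], [1.0, -noise.ar1], eps, axis=1)
    return x.T


def simulate_subject_tep(
    profile: LatentProfile,
    target: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    spaces: tuple[str, ...] = ("source_roi", "sensor"),
) -> tuple[TEPTimeSeries | None, TEPTimeSeries | None]:
    """Simulate one subject x target evoked response in source and sensor space.

    The source-space array carries both target ROIs; vertices of the
    stimulated target's ROI receive full component weight, the remaining
    vertices the attenuated ``off_roi_weight``.  For target DLPFC the late
    component amplitude in the stimulated ROI is scaled by
    ``1 + effect_size * vulnerability``; the IPL response and all sensor
    channels carry no vulnerability dependence.
    """
    if target not in ("DLPFC", "IPL"):
        raise ConfigError(f"unknown target {target!r}")
    waves = _component_waveforms(config)  # (n_comp, n_samples)
    amps = np.array([c.amplitude_uv for c in config.components])
    roi_w = np.array([c.roi_weight for c in config.components])
    late = config.late_component_index()
    n = config.n_samples

    tep_source = None
    tep_sensor = None

    if "source_roi" in spaces:
        ids = _source_series_ids(config)
        n_series = len(ids)
        roi = make_roi(target, config)
        in_roi = np.isin(ids, roi.vertex_ids)
        gains = 1.0 + config.gain_jitter_sd * rng.normal(size=n_series)
        # per-vertex, per-component amplitude
        amp_vc = np.outer(np.where(in_roi, 1.0, config.off_roi_weight) * gains,
                          amps)
        amp_vc[in_roi] *= roi_w
        if target == "DLPFC":
            amp_vc[in_roi, late] *= 1.0 + config.effect_size * profile.vulnerability
        signal = amp_vc @ waves  # (n_series, n_samples)
        data = signal.T + _ar1_noise(rng, n_series, n, config.noise)
        tep_source = TEPTimeSeries(
            subject_id=profile.subject_id, target=target, data=data,
            t0_ms=config.epoch_ms[0], fs_hz=config.fs_hz,
            space="source_roi", series_ids=ids,
        )

    if "sensor" in spaces:
        ids = _sensor_series_ids(config)
        n_series = len(ids)
        # fixed scalp projection per subject x target, no vulnerability term
        mix = rng.normal(0.6, 0.3, size=(n_series, len(amps)))
        signal = (mix * amps) @ waves
        data = signal.T + _ar1_noise(rng, n_series, n, config.noise)
        tep_sensor = TEPTimeSeries(
            subject_id=profile.subject_id, target=target, data=data,
            t0_ms=config.epoch_ms[0], fs_hz=config.fs_hz,
            space="sensor", series_ids=ids,
        )

    return tep_source, tep_sensor


def _split_subscales(total: int, rng: np.random.Generator) -> tuple[int, int]:
    """Binomial thinning of a PHQ-4 total into (phq2, gad2), both capped at 6."""
    lo = max(0, total - 6)
    hi = min(6, total)
    phq2 = int(np.clip(rng.binomial(total, 0.5), lo, hi))
    return phq2, total - phq2


def simulate_cohort_table(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[CohortTable, pd.DataFrame]:
    """Generate the questionnaire/demographic table and latent profiles.

    Returns (cohort, profiles) where profiles carries the latent vulnerability
    and the resilient/vulnerable label obtained by applying the classification
    rule to the generated trajectories.
    """
    n = config.n_subjects
    edu_center = 18.0
    rows = []
    profs = []
    for i in range(n):
        sid = f"sub-{i + 1:03d}"
        v = float(rng.normal())
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        edu = int(rng.integers(config.education_range[0], config.education_range[1] + 1))
        gender = "female" if rng.random() < config.female_fraction else "male"
        method = "anatomical" if rng.random() < config.anatomical_fraction else "functional"
        months = int(rng.integers(config.months_since_tms_range[0],
                                  config.months_since_tms_range[1] + 1))
        phq_pre = int(rng.binomial(12, config.phq_pre_p))
        n_tp = int(rng.choice([1, 2, 3], p=config.timepoint_fractions))
        shift = (config.phq_drift + config.vulnerability_link * v
                 - config.education_effect * (edu - edu_center))
        pan = [
            int(np.clip(round(phq_pre + shift + rng.normal(0.0, config.phq_noise_sd)), 0, 12))
            for _ in range(n_tp)
        ]
        pre2 = _split_subscales(phq_pre, rng)
        pan2 = [_split_subscales(p, rng) for p in pan]
        pan_mean = mean_pandemic_score(pan)
        pss_latent = pan_mean + rng.normal(0.0, config.pss_noise_sd)
        pss = int(np.clip(round(config.pss_intercept + config.pss_slope * pss_latent), 0, 56))
        u = rng.random()
        p_d_only = config.p_dlpfc - config.p_both
        p_i_only = config.p_ipl - config.p_both
        if u < config.p_both:
            completed = ["DLPFC", "IPL"]
        elif u < config.p_both + p_d_only:
            completed = ["DLPFC"]
        elif u < config.p_both + p_d_only + p_i_only:
            completed = ["IPL"]
        else:
            completed = ["DLPFC"]  # degenerate 'neither' cell folded into DLPFC
        rows.append(dict(
            subject_id=sid, phq_pre=phq_pre, phq_pandemic=pan,
            phq2_pre=pre2[0], gad2_pre=pre2[1],
            phq2_pandemic=[a for a, _ in pan2], gad2_pandemic=[b for _, b in pan2],
            pss14=pss, age=age, gender=gender, education_years=edu,
            months_since_tms=months, targeting_method=method,
            completed_targets=completed,
        ))
        label = classify_resilience(phq_pre, pan).label
        profs.append(dict(subject_id=sid, vulnerability=v, group_truth=label))
    cohort = CohortTable(pd.DataFrame(rows))
    return cohort, pd.DataFrame(profs)


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    profiles: pd.DataFrame
    teps: dict  # (subject_id, target, space) -> TEPTimeSeries
    config: SimulationConfig
    seed: int


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    out_dir: str | os.PathLike | None = None,
    spaces: tuple[str, ...] = ("source_roi", "sensor"),
    keep_in_memory: bool = True,
) -> SimulatedCohort:
    """Generate a full synthetic dataset: TEP files + cohort + latent profiles.

    With ``out_dir`` set, TEP arrays, cohort.csv, profiles.csv and a manifest
    (file list + SHA-256 checksums + seed) are written there.  Identical
    (config, seed) produce identical files.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cohort, profiles = simulate_cohort_table(config, rng)
    teps: dict = {}
    manifest_files: list[dict] = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for _, row in cohort.df.iterrows():
        sid = row["subject_id"]
        v = float(profiles.loc[profiles["subject_id"] == sid, "vulnerability"].iloc[0])
        prof = LatentProfile(subject_id=sid, vulnerability=v)
        for target in row["completed_targets"]:
            src, sen = simulate_subject_tep(prof, target, config, rng, spaces=spaces)
            for tep in (src, sen):
                if tep is None:
                    continue
                if keep_in_memory:
                    teps[(sid, target, tep.space)] = tep
                if out_dir is not None:
                    fname = tep_filename(sid, target, tep.space)
                    fpath = os.path.join(out_dir, fname)
                    write_tep(tep, fpath, overwrite=True)
                    manifest_files.append(
                        {"file": fname, "sha256": _file_sha256(fpath)}
                    )
    if out_dir is not None:
        cpath = os.path.join(out_dir, "cohort.csv")
        write_cohort(cohort, cpath, overwrite=True)
        manifest_files.append({"file": "cohort.csv", "sha256": _file_sha256(cpath)})
        ppath = os.path.join(out_dir, "profiles.csv")
        profiles.to_csv(ppath, index=False)
        manifest_files.append({"file": "profiles.csv", "sha256": _file_sha256(ppath)})
        manifest = {
            "seed": seed,
            "n_subjects": config.n_subjects,
            "config": _config_to_jsonable(config),
            "files": manifest_files,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return SimulatedCohort(cohort=cohort, profiles=profiles, teps=teps,
                           config=config, seed=seed)


def _file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=list))


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    if "components" in d:
        d["components"] = [
            c if isinstance(c, Component) else Component(**c) for c in d["components"]
        ]
    if "noise" in d and not isinstance(d["noise"], NoiseConfig):
        d["noise"] = NoiseConfig(**d["noise"])
    for key in ("epoch_ms", "late_window_ms", "age_range", "education_range",
                "months_since_tms_range", "timepoint_fractions"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
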