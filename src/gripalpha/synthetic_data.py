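"""Synthetic stand-in for the grip-force EEG study.

No recordings from the original experiment are distributable, so this
module generates a study with the same design — 11 subjects x 3 grip
levels (20/40/60% MVC) x 10 trials of a 15-s sustained hold, single
channel at 1000 Hz — and *known* ground truth.  The alpha source of each
trial is the neural mass model itself, simulated at a grip-level-
dependent index k along the same synchronous (J, Ge, Gi) ray the fitting
procedure searches; recovering k from the generated recordings is then a
parameter-recovery problem with exact ground truth.

On top of the scaled model output each trial carries the nuisance
structure of real scalp EEG: a 1/f (pink) background, a slow baseline
drift, 50 Hz mains interference, and occasional high-amplitude artifact
transients (annotated, so rejection can be scored).  What the generator
does **not** emulate: ocular/myogenic mixtures, electrode pops,
non-stationarity of the alpha source within a hold, or volume-conduction
effects — conclusions about those do not follow from passing tests here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import NoiseSpec, SimulationConfig, simulate
from .preprocessing import EEGRecording
from .sweep_fit import RayPowerEvaluator, ray_parameters

__all__ = ["GeneratorSpec", "SyntheticStudy", "generate_trial", "generate_study"]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class GeneratorSpec:
    """Study design and nuisance amplitudes for the synthetic cohort.

    ``level_to_k`` maps grip level (% MVC) to the ground-truth ray index;
    it must be strictly increasing in level and stay inside the model's
    alpha-oscillatory window (alpha power is strictly increasing in k up
    to k ~ 48; past it the oscillation slows out of the 8-12 Hz band),
    with margin for subject jitter and fit bias.  ``scale_uV`` converts the
    model's mV-scale output to scalp microvolts; with the default 1.0
    a clean trial has ~5.8 µV² alpha power, in the plausible scalp range.
    """

    n_subjects: int = 11
    grip_levels: tuple = (20, 40, 60)
    trials_per_level: int = 10
    hold_duration_s: float = 15.0
    fs: float = 1000.0
    level_to_k: dict = field(default_factory=lambda: {20: 0, 40: 15, 60: 30})
    subject_k_jitter: int = 4
    scale_uV: float = 1.0
    pink_uV: float = 2.0
    drift_uV: float = 50.0
    drift_hz: float = 0.1
    line_uV: float = 10.0
    artifact_rate: float = 0.05
    artifact_uV: float = 500.0
    artifact_dur_s: float = 0.2
    seg_len_s: float = 5.0
    burn_in_s: float = 2.0
    noise_mean: float = 220.0
    noise_std: float = 22.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        levels = sorted(self.grip_levels)
        ks = [self.level_to_k[lv] for lv in levels]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("level_to_k must be strictly increasing in grip level")
        for name in ("scale_uV", "pink_uV", "drift_uV", "line_uV", "artifact_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated cohort plus its ground truth.

    ``ground_truth`` has one row per (subject, level) with the generating
    ray index ``k`` and, when requested, the seed-averaged clean alpha
    power ``expected_alpha_power`` (model units, mV²) at that index.
    """

    recordings: tuple
    ground_truth: pd.DataFrame
    spec: GeneratorSpec

    def __post_init__(self) -> None:
        levels = len(self.spec.grip_levels)
        expected = self.spec.n_subjects * levels * self.spec.trials_per_level
        if len(self.recordings) != expected:
            raise ValueError(
                f"expected {expected} recordings, got {len(self.recordings)}"
            )


def _pink_noise(rng: np.random.Generator, n: int, fs: float, std: float,
                f_lo: float = 1.0, f_hi: float = 100.0) -> np.ndarray:
    """1/f-shaped Gaussian noise band-limited to [f_lo, f_hi] Hz."""
    if std == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    shape[band] = 1.0 / np.sqrt(freqs[band])
    pink = np.fft.irfft(spectrum * shape, n)
    return pink * (std / pink.std())


def generate_trial(subject_k: int, spec: GeneratorSpec, seed: int, *,
                   subject_id: str = "S1", grip_level: int = 20,
                   trial_index: int = 0) -> EEGRecording:
    """One 15-s hold trial at ray index ``subject_k``.

    Output (µV) = scale_uV * model output + pink background + drift
    sinusoid + 50 Hz line + annotated artifact transients.  Each 5-s
    segment independently carries an artifact with probability
    ``artifact_rate``.  Fully determined by ``(subject_k, spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    nmm_seed = int(rng.integers(_SEED_MOD))
    config = SimulationConfig(
        fs=spec.fs, duration=spec.hold_duration_s, burn_in=spec.burn_in_s
    )
    sig = simulate(
        ray_parameters(subject_k),
        NoiseSpec(spec.noise_mean, spec.noise_std, nmm_seed),
        config,
    )
    n = sig.samples.size
    t = np.arange(n) / spec.fs
    x = spec.scale_uV * sig.samples
    x = x + _pink_noise(rng, n, spec.fs, spec.pink_uV)
    x = x + spec.drift_uV * np.sin(
        2 * np.pi * spec.drift_hz * t + rng.uniform(0, 2 * np.pi)
    )
    x = x + spec.line_uV * np.sin(
        2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
    )
    annotations = []
    seg_samples = round(spec.seg_len_s * spec.fs)
    pulse_samples = round(spec.artifact_dur_s * spec.fs)
    pulse = spec.artifact_uV * np.hanning(pulse_samples)
    for seg_start in range(0, n - seg_samples + 1, seg_samples):
        if rng.random() < spec.artifact_rate:
            offset = int(rng.integers(0, seg_samples - pulse_samples))
            i0 = seg_start + offset
            x[i0:i0 + pulse_samples] += pulse
            annotations.append(
                (i0 / spec.fs, (i0 + pulse_samples) / spec.fs, "artifact")
            )
    return EEGRecording(
        samples=x,
        fs=spec.fs,
        subject_id=subject_id,
        grip_level=grip_level,
        trial_index=trial_index,
        annotations=tuple(annotations),
    )


def generate_study(spec: GeneratorSpec | None = None, *,
                   compute_expected: bool = True,
                   expected_seeds=range(5)) -> SyntheticStudy:
    """Generate the full cohort under ``spec.master_seed``.

    Per subject a ray-index jitter (integer, uniform on
    [-subject_k_jitter, +subject_k_jitter], shared across that subject's
    levels) models between-subject variability; each trial then runs at
    ``k = level_to_k[level] + jitter``.  Ground-truth expected alpha
    power per distinct k is evaluated once on a common seed list.
    """
    if spec is None:
        spec = GeneratorSpec()
    master = np.random.default_rng(spec.master_seed)
    j = spec.subject_k_jitter
    jitters = master.integers(-j, j + 1, size=spec.n_subjects)
    recordings = []
    truth_rows = []
    for si in range(spec.n_subjects):
        subject_id = f"S{si + 1}"
        for level in spec.grip_levels:
            k = int(spec.level_to_k[level] + jitters[si])
            truth_rows.append(
                {"subject_id": subject_id, "grip_level": level, "k": k}
            )
            for trial in range(spec.trials_per_level):
                seed = int(master.integers(_SEED_MOD))
                recordings.append(
                    generate_trial(
                        k, spec, seed,
                        subject_id=subject_id, grip_level=level,
                        trial_index=trial,
                    )
                )
    truth = pd.DataFrame(truth_rows)
    if compute_expected:
        evaluator = RayPowerEvaluator(
            config=SimulationConfig(
                fs=spec.fs, duration=spec.hold_duration_s,
                burn_in=spec.burn_in_s,
            ),
            seeds=expected_seeds,
            noise_mean=spec.noise_mean,
            noise_std=spec.noise_std,
        )
        truth["expected_alpha_power"] = [evaluator(k) for k in truth["k"]]
    return SyntheticStudy(
        recordings=tuple(recordings), ground_truth=truth, spec=spec
    )
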