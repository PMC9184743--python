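"""Synthetic multichannel EEG with controllable spectral and entropy structure.

Each group x condition cell is described by a :class:`SynthProfile`: a
1/f^alpha background (spectral-shaped Gaussian noise), a set of
band-limited oscillations given as (center_Hz, bandwidth_Hz,
relative_amplitude) triples, white measurement noise, and optional
high-amplitude transient artifacts injected into a known fraction of
epochs.  A :class:`SynthStudySpec` lays out a full study (groups x
conditions x subjects) and one seed determines every sample.

The default profiles emulate the statistical signatures of aging and
training seen in resting-state EEG:

* the "old" profile has a flatter 1/f background (smaller alpha) with
  relatively more 15-30 Hz and less 1-7 Hz power, which yields higher
  fine-timescale and lower coarse-timescale sample entropy than the
  steeper "young" profile;
* the training effect raises the 3-14 Hz (high-delta/theta/alpha) band
  amplitudes and steepens the background from pre to post in exactly
  one group, raising coarse-timescale entropy and low-frequency power
  there only.

These parameter values are tuning targets chosen so the generated
groups reproduce those qualitative directions; no generative model of
the real recordings is implied.

Randomness is hierarchical and fully deterministic: the study seed
spawns per-subject streams (subject-level band-amplitude scalings,
kept identical across that subject's conditions to mimic the repeated-
measures pre/post design) and per-epoch streams, so regenerating any
subject or epoch in isolation reproduces it bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .preprocess import EpochedRecording, TASK_CHANNELS_20

__all__ = [
    "SynthProfile",
    "SynthStudySpec",
    "generate_colored_noise",
    "generate_band_noise",
    "generate_epoched_subject",
    "generate_continuous_subject",
    "generate_study",
    "young_profile",
    "old_profile",
    "trained_profile",
    "default_aging_spec",
    "default_training_spec",
    "spec_from_yaml",
    "spec_to_yaml",
]


@dataclass(frozen=True)
class SynthProfile:
    """Generative parameters for one group x condition cell.

    ``spectral_slope`` is the exponent alpha of the 1/f^alpha background;
    ``band_components`` are (center_Hz, bandwidth_Hz, relative_amplitude)
    oscillations whose SD is relative_amplitude times the background SD;
    ``background_sd_uV`` sets the absolute scale; ``noise_sd`` is white
    measurement noise in µV; ``artifact_rate`` epochs (rounded) receive a
    transient of ``artifact_amplitude`` µV peak-to-peak.
    """

    spectral_slope: float
    band_components: tuple[tuple[float, float, float], ...] = ()
    background_sd_uV: float = 6.0
    noise_sd: float = 1.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 150.0

    def validate(self, fs: float) -> None:
        if self.spectral_slope < 0:
            raise ValueError("spectral_slope must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        for c, bw, amp in self.band_components:
            if amp < 0:
                raise ValueError("relative_amplitude must be >= 0")
            if bw <= 0:
                raise ValueError("bandwidth_Hz must be positive")
            if c >= fs / 2:
                raise ValueError(f"band center {c} Hz is at/above Nyquist ({fs / 2} Hz)")


@dataclass(frozen=True)
class SynthStudySpec:
    """Full study layout: groups x conditions x subjects, one profile per cell."""

    groups: tuple[str, ...]
    conditions: tuple[str, ...]
    n_subjects_per_group: int
    profiles: dict[tuple[str, str], SynthProfile]
    n_epochs: int = 48
    epoch_ms: float = 2500.0
    fs: float = 1000.0
    channels: tuple[str, ...] = tuple(TASK_CHANNELS_20)
    seed: int = 0
    subject_amp_sd: float = 0.10  # SD of per-subject band-amplitude scaling

    def validate(self) -> None:
        for g in self.groups:
            for c in self.conditions:
                if (g, c) not in self.profiles:
                    raise ValueError(f"missing profile for cell {(g, c)}")
                self.profiles[(g, c)].validate(self.fs)
        n = self.epoch_ms * self.fs / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_ms * fs / 1000 must be an integer")
        if len(self.channels) == 0:
            raise ValueError("channel list is empty")


def _shaped_noise(n: int, amplitude_of_freq, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise whose spectrum follows ``amplitude_of_freq``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)  # scaled below by caller via closure
    amp = amplitude_of_freq(freqs)
    spec *= amp
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate shaped-noise draw (zero variance)")
    return x / sd


def generate_colored_noise(
    n_samples: int, alpha: float, fs: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-SD 1/f^alpha noise of length ``n_samples``.

    Spectral shaping of white Gaussian noise in the frequency domain:
    amplitudes are scaled by f^(-alpha/2) (DC removed), giving exact
    slope control in O(n log n).  alpha=0 is white noise.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def shape(freqs_cycles):
        f_hz = freqs_cycles * fs
        amp = np.zeros_like(f_hz)
        nz = f_hz > 0
        amp[nz] = f_hz[nz] ** (-alpha / 2.0)
        return amp

    return _shaped_noise(n_samples, shape, rng)


def generate_band_noise(
    n_samples: int,
    center_Hz: float,
    bandwidth_Hz: float,
    fs: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Unit-SD narrow-band noise: Gaussian spectral bump at ``center_Hz``.

    The amplitude profile is exp(-(f - c)^2 / (2 sigma^2)) with
    sigma = bandwidth/2, i.e. ``bandwidth_Hz`` is roughly the full width
    at ~0.6 of the peak amplitude.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = bandwidth_Hz / 2.0

    def shape(freqs_cycles):
        f_hz = freqs_cycles * fs
        amp = np.exp(-((f_hz - center_Hz) ** 2) / (2.0 * sigma**2))
        amp[f_hz == 0] = 0.0
        return amp

    return _shaped_noise(n_samples, shape, rng)


def _artifact_pulse(n: int, amplitude: float, rng: np.random.Generator, fs: float) -> np.ndarray:
    """A biphasic Hann-windowed transient with exact peak-to-peak ``amplitude``."""
    width = min(n, max(8, int(round(0.2 * fs))))  # ~200 ms
    t = np.arange(width)
    shape = np.sin(2 * np.pi * t / width) * np.hanning(width)
    shape /= shape.max() - shape.min()  # unit peak-to-peak
    start = int(rng.integers(0, n - width + 1))
    pulse = np.zeros(n)
    pulse[start : start + width] = amplitude * shape
    return pulse


def _subject_band_scales(
    profile: SynthProfile, rng: np.random.Generator, sd: float
) -> np.ndarray:
    """Per-subject Gaussian scaling of band amplitudes (clipped positive)."""
    k = len(profile.band_components)
    return np.clip(rng.normal(1.0, sd, size=k), 0.05, None)


def _epoch_signal(
    profile: SynthProfile,
    band_scales: np.ndarray,
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One channel-epoch: background + oscillations + measurement noise (µV)."""
    x = generate_colored_noise(n, profile.spectral_slope, fs, rng)
    for (c, bw, amp), scale in zip(profile.band_components, band_scales):
        if amp > 0:
            x = x + amp * scale * generate_band_noise(n, c, bw, fs, rng)
    x = profile.background_sd_uV * x
    if profile.noise_sd > 0:
        x = x + rng.normal(0.0, profile.noise_sd, size=n)
    return x


def generate_epoched_subject(
    profile: SynthProfile,
    n_epochs: int,
    epoch_ms: float,
    fs: float,
    channels: list[str],
    seed: int | np.random.SeedSequence,
    band_scales: np.ndarray | None = None,
) -> EpochedRecording:
    """Synthesize one subject-condition recording as independent epochs.

    Epochs are drawn independently (no continuous record) so stage tests
    stay decoupled; :func:`generate_continuous_subject` provides the
    continuous mode for segmentation testing.  The indices of artifact-
    contaminated epochs are recorded in ``rec.info["artifact_epochs"]``.
    """
    if len(channels) == 0:
        raise ValueError("channel list is empty")
    profile.validate(fs)
    n = int(round(epoch_ms * fs / 1000.0))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(ss)
    if band_scales is None:
        band_scales = np.ones(len(profile.band_components))
    n_artifact = int(round(profile.artifact_rate * n_epochs))
    artifact_epochs = sorted(
        int(i) for i in subj_rng.choice(n_epochs, size=n_artifact, replace=False)
    )
    data = np.empty((n_epochs, len(channels), n))
    epoch_seeds = ss.spawn(n_epochs)
    for e in range(n_epochs):
        erng = np.random.default_rng(epoch_seeds[e])
        for c in range(len(channels)):
            data[e, c] = _epoch_signal(profile, band_scales, n, fs, erng)
        if e in artifact_epochs:
            pulse = _artifact_pulse(n, profile.artifact_amplitude, erng, fs)
            data[e] += pulse[None, :]
    rec = EpochedRecording(
        data, fs, list(channels), epoch_ms,
        provenance=[f"synthgen(slope={profile.spectral_slope}, n_epochs={n_epochs})"],
        info={"artifact_epochs": artifact_epochs},
    )
    return rec


def generate_continuous_subject(
    profile: SynthProfile,
    duration_ms: float,
    fs: float,
    channels: list[str],
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Continuous mode: one long channels x samples record (no artifacts)."""
    if len(channels) == 0:
        raise ValueError("channel list is empty")
    profile.validate(fs)
    n = int(round(duration_ms * fs / 1000.0))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    band_scales = np.ones(len(profile.band_components))
    return np.stack(
        [_epoch_signal(profile, band_scales, n, fs, rng) for _ in channels]
    )


def generate_study(
    spec: SynthStudySpec,
) -> dict[tuple[str, str, str], EpochedRecording]:
    """Generate every (group, condition, subject) recording of a study.

    Subject identity is preserved across conditions: the subject-level
    band-amplitude scaling is drawn once per subject and applied in
    every condition, while the condition's profile supplies the means.
    Keys are (group, condition, subject_id) with ids ``"{group}_s{i:02d}"``.
    """
    spec.validate()
    out: dict[tuple[str, str, str], EpochedRecording] = {}
    for gi, g in enumerate(spec.groups):
        for si in range(spec.n_subjects_per_group):
            subj_id = f"{g}_s{si:02d}"
            # subject-level stream: shared across conditions
            subj_ss = np.random.SeedSequence([spec.seed, gi, si])
            subj_rng = np.random.default_rng(subj_ss)
            ref_profile = spec.profiles[(g, spec.conditions[0])]
            scales = _subject_band_scales(ref_profile, subj_rng, spec.subject_amp_sd)
            for ci, c in enumerate(spec.conditions):
                profile = spec.profiles[(g, c)]
                if len(profile.band_components) != len(scales):
                    # condition changed the band set: redraw deterministically
                    cond_rng = np.random.default_rng(
                        np.random.SeedSequence([spec.seed, gi, si, 7])
                    )
                    cond_scales = _subject_band_scales(profile, cond_rng, spec.subject_amp_sd)
                else:
                    cond_scales = scales
                key = (g, c, subj_id)
                if key in out:
                    raise ValueError(f"duplicate subject id {key}")
                out[key] = generate_epoched_subject(
                    profile,
                    spec.n_epochs,
                    spec.epoch_ms,
                    spec.fs,
                    list(spec.channels),
                    np.random.SeedSequence([spec.seed, gi, si, 100 + ci]),
                    band_scales=cond_scales,
                )
    return out


# ---------------------------------------------------------------------------
# default study profiles
# ---------------------------------------------------------------------------

def young_profile() -> SynthProfile:
    """Younger-adult resting profile: steep 1/f, strong low-frequency bands."""
    return SynthProfile(
        spectral_slope=1.6,
        band_components=(
            (2.0, 1.5, 0.8),   # delta
            (5.5, 2.0, 0.8),   # theta
            (10.0, 2.0, 1.0),  # alpha
            (20.0, 8.0, 0.25), # beta (weak)
        ),
    )


def old_profile() -> SynthProfile:
    """Older-adult resting profile: flatter 1/f, beta up, delta/theta down."""
    return SynthProfile(
        spectral_slope=1.0,
        band_components=(
            (2.0, 1.5, 0.35),
            (5.5, 2.0, 0.35),
            (10.0, 2.0, 1.0),
            (20.0, 8.0, 0.75),
        ),
    )


def trained_profile(pre: SynthProfile, slope_gain: float = 0.3, low_gain: float = 1.8) -> SynthProfile:
    """Post-training profile: steeper background and boosted 3-14 Hz bands.

    Raises coarse-timescale entropy (via the slope) and theta/alpha
    relative power (via ``low_gain`` on bands centered in 3-14 Hz).
    """
    bands = tuple(
        (c, bw, amp * low_gain if 3.0 <= c <= 14.0 else amp)
        for c, bw, amp in pre.band_components
    )
    return replace(pre, spectral_slope=pre.spectral_slope + slope_gain, band_components=bands)


def default_aging_spec(
    n_subjects_per_group: int = 20,
    n_epochs: int = 48,
    channels: tuple[str, ...] = tuple(TASK_CHANNELS_20),
    seed: int = 0,
    **kw,
) -> SynthStudySpec:
    """Pre-training cross-sectional comparison: young vs old, one condition."""
    return SynthStudySpec(
        groups=("young", "old"),
        conditions=("pre",),
        n_subjects_per_group=n_subjects_per_group,
        profiles={("young", "pre"): young_profile(), ("old", "pre"): old_profile()},
        n_epochs=n_epochs,
        channels=channels,
        seed=seed,
        **kw,
    )


def default_training_spec(
    n_subjects_per_group: int = 20,
    n_epochs: int = 48,
    channels: tuple[str, ...] = tuple(TASK_CHANNELS_20),
    seed: int = 0,
    groups: tuple[str, ...] = ("young_control", "young_training", "old_control", "old_training"),
    trained_group: str = "old_training",
    **kw,
) -> SynthStudySpec:
    """Pre/post design with the training effect in ``trained_group`` only."""
    profiles: dict[tuple[str, str], SynthProfile] = {}
    for g in groups:
        base = young_profile() if g.startswith("young") else old_profile()
        profiles[(g, "pre")] = base
        profiles[(g, "post")] = trained_profile(base) if g == trained_group else base
    return SynthStudySpec(
        groups=groups,
        conditions=("pre", "post"),
        n_subjects_per_group=n_subjects_per_group,
        profiles=profiles,
        n_epochs=n_epochs,
        channels=channels,
        seed=seed,
        **kw,
    )


def null_spec(
    n_subjects_per_group: int = 10,
    n_epochs: int = 4,
    n_channels: int = 4,
    epoch_ms: float = 1000.0,
    fs: float = 250.0,
    seed: int = 0,
    groups: tuple[str, ...] = ("g1", "g2"),
    conditions: tuple[str, ...] = ("c1", "c2"),
) -> SynthStudySpec:
    """Identical profiles in every cell: the null study for calibration runs."""
    p = SynthProfile(
        spectral_slope=1.0,
        band_components=((10.0, 2.0, 0.8),),
    )
    return SynthStudySpec(
        groups=groups,
        conditions=conditions,
        n_subjects_per_group=n_subjects_per_group,
        profiles={(g, c): p for g in groups for c in conditions},
        n_epochs=n_epochs,
        epoch_ms=epoch_ms,
        fs=fs,
        channels=tuple(f"ch{i}" for i in range(n_channels)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text config round-trip
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: SynthStudySpec, path: str) -> None:
    doc = {
        "groups": list(spec.groups),
        "conditions": list(spec.conditions),
        "n_subjects_per_group": spec.n_subjects_per_group,
        "n_epochs": spec.n_epochs,
        "epoch_ms": spec.epoch_ms,
        "fs": spec.fs,
        "channels": list(spec.channels),
        "seed": spec.seed,
        "subject_amp_sd": spec.subject_amp_sd,
        "profiles": {
            f"{g}|{c}": {
                "spectral_slope": p.spectral_slope,
                "band_components": [list(b) for b in p.band_components],
                "background_sd_uV": p.background_sd_uV,
                "noise_sd": p.noise_sd,
                "artifact_rate": p.artifact_rate,
                "artifact_amplitude": p.artifact_amplitude,
            }
            for (g, c), p in spec.profiles.items()
        },
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def spec_from_yaml(path: str) -> SynthStudySpec:
    with open(path) as f:
        doc = yaml.safe_load(f)
    profiles = {}
    for key, p in doc["profiles"].items():
        g, c = key.split("|")
        profiles[(g, c)] = SynthProfile(
            spectral_slope=p["spectral_slope"],
            band_components=tuple(tuple(b) for b in p["band_components"]),
            background_sd_uV=p.get("background_sd_uV", 6.0),
            noise_sd=p.get("noise_sd", 1.0),
            artifact_rate=p.get("artifact_rate", 0.0),
            artifact_amplitude=p.get("artifact_amplitude", 150.0),
        )
    spec = SynthStudySpec(
        groups=tuple(doc["groups"]),
        conditions=tuple(doc["conditions"]),
        n_subjects_per_group=doc["n_subjects_per_group"],
        profiles=profiles,
        n_epochs=doc["n_epochs"],
        epoch_ms=doc["epoch_ms"],
        fs=doc["fs"],
        channels=tuple(doc["channels"]),
        seed=doc["seed"],
        subject_amp_sd=doc.get("subject_amp_sd", 0.10),
    )
    spec.validate()
    return spec
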