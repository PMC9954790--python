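"""Synthetic motor-imagery EEG with lateralised mu-band desynchronisation.

Imagining a left- or right-hand movement suppresses the mu rhythm
(8-12 Hz) over the *contralateral* sensorimotor cortex — event-related
desynchronisation (ERD).  This generator reproduces exactly that
discriminative structure and nothing more: each trial is independent
pink (1/f) background noise per channel plus a mu-band sinusoid with a
random phase per trial and channel, whose amplitude on the class's
contralateral channels is attenuated by a factor ``1 - erd_depth``.

Because the class information lives in a spatial-by-spectral power
pattern (not in phase, not in broadband amplitude), a classifier must
integrate over time within channels and contrast across channels to
solve the task — the same demands the real benchmark places on the
network, at a scale where training takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trial_data import DatasetSpec, TrialSet, dataset_descriptor

__all__ = [
    "SynthConfig",
    "pink_noise",
    "generate_dataset",
    "default_lateral_map",
    "learnability_fixture",
]


def pink_noise(
    n_samples: int, exponent: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Zero-mean unit-RMS noise with spectral density ~ 1/f^exponent.

    Gaussian white noise is shaped in the frequency domain by
    ``f^(-exponent/2)`` (DC removed), transformed back and normalised to
    RMS 1.  ``exponent=0`` recovers white noise; ``exponent=1`` is the
    pink background typical of resting EEG spectra.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2; got {n_samples}")
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0; got {exponent}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n=n_samples)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("degenerate all-zero noise draw")
    return x / rms


def default_lateral_map(
    channel_names: tuple[str, ...], classes: tuple[str, ...]
) -> dict[str, tuple[int, ...]]:
    """Contralateral channel sets inferred from 10-20 electrode names.

    Odd-numbered electrodes (C3, FC1, ...) sit over the left hemisphere and
    desynchronise for *right*-hand imagery; even-numbered ones (C4, ...)
    over the right hemisphere desynchronise for *left*-hand imagery.
    Midline electrodes (Cz, Fz, ...) belong to neither set.
    """
    left_hemi, right_hemi = [], []
    for i, name in enumerate(channel_names):
        digits = "".join(ch for ch in name if ch.isdigit())
        if not digits:
            continue
        (left_hemi if int(digits) % 2 == 1 else right_hemi).append(i)
    mapping = {}
    for cls in classes:
        if cls == "left":
            mapping[cls] = tuple(right_hemi)
        elif cls == "right":
            mapping[cls] = tuple(left_hemi)
        else:
            raise ValueError(f"no default lateral map for class {cls!r}")
    return mapping


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic motor-imagery generator.

    ``snr`` is the RMS of the (unattenuated) mu component over the RMS of
    the background noise on a modulated channel; ``erd_depth`` is the
    fractional mu-amplitude attenuation applied on the class's
    contralateral channels (0 = no class information, 1 = complete
    suppression).
    """

    n_channels: int = 3
    n_timestamps: int = 500
    sampling_rate_hz: float = 250.0
    n_trials_per_class: int = 50
    classes: tuple[str, ...] = ("left", "right")
    channel_names: tuple[str, ...] = ()
    mu_freq_hz: float = 10.0
    erd_depth: float = 0.6
    snr: float = 1.0
    noise_exponent: float = 1.0
    lateral_channel_map: dict[str, tuple[int, ...]] = field(default_factory=dict)
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth <= 1:
            raise ValueError(f"erd_depth must be in [0, 1]; got {self.erd_depth}")
        if self.snr <= 0:
            raise ValueError(f"snr must be > 0; got {self.snr}")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        names = self.channel_names
        if not names:
            spec = (
                dataset_descriptor("BCI-IV-2B")
                if self.n_channels == 3
                else dataset_descriptor("BCI-IV-2A")
                if self.n_channels == 22
                else None
            )
            names = (
                spec.channel_names
                if spec is not None
                else tuple(f"ch{i + 1:02d}" for i in range(self.n_channels))
            )
        object.__setattr__(self, "channel_names", tuple(names))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        lat = self.lateral_channel_map or default_lateral_map(
            self.channel_names, self.classes
        )
        lat = {c: tuple(int(i) for i in idx) for c, idx in lat.items()}
        object.__setattr__(self, "lateral_channel_map", lat)
        for cls in self.classes:
            if not lat.get(cls):
                raise ValueError(f"lateral channel map for class {cls!r} is empty")

    @classmethod
    def from_dataset_spec(
        cls, spec: DatasetSpec | str, n_timestamps: int = 1000, **kwargs
    ) -> "SynthConfig":
        if isinstance(spec, str):
            spec = dataset_descriptor(spec)
        classes = kwargs.pop("classes", ("left", "right"))
        return cls(
            n_channels=spec.n_channels,
            n_timestamps=n_timestamps,
            sampling_rate_hz=spec.sampling_rate_hz,
            channel_names=spec.channel_names,
            classes=classes,
            **kwargs,
        )


def generate_dataset(cfg: SynthConfig) -> TrialSet:
    """Draw a balanced, label-shuffled TrialSet from the generator.

    Per trial and channel: unit-RMS pink noise plus a mu sinusoid of RMS
    ``snr`` (amplitude ``snr * sqrt(2)``) with an independent uniform random
    phase; channels in the trial class's contralateral set have the mu
    amplitude multiplied by ``1 - erd_depth``.  Deterministic in
    ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EE6]))
    n_classes = len(cfg.classes)
    n_trials = n_classes * cfg.n_trials_per_class
    T, C = cfg.n_timestamps, cfg.n_channels
    t = np.arange(T) / cfg.sampling_rate_hz
    labels = np.repeat(np.arange(n_classes), cfg.n_trials_per_class)
    labels = labels[rng.permutation(n_trials)].astype(np.int32)
    X = np.empty((n_trials, T, C), dtype=np.float32)
    base_amp = cfg.snr * np.sqrt(2.0)
    for i in range(n_trials):
        cls_name = cfg.classes[labels[i]]
        attenuated = set(cfg.lateral_channel_map[cls_name])
        for c in range(C):
            noise = pink_noise(T, cfg.noise_exponent, rng)
            amp = base_amp * ((1.0 - cfg.erd_depth) if c in attenuated else 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            X[i, :, c] = noise + amp * np.sin(2.0 * np.pi * cfg.mu_freq_hz * t + phase)
    return TrialSet(
        trials=X,
        labels=labels,
        class_names=cfg.classes,
        sampling_rate_hz=cfg.sampling_rate_hz,
        subject_id=cfg.subject_id,
        channel_names=cfg.channel_names,
    )


#: Canned generator settings for the two learnability fixtures.
FIXTURE_CONFIGS = {
    "easy": dict(erd_depth=0.8, snr=2.0, n_train_per_class=100, n_test_per_class=50),
    "hard": dict(erd_depth=0.1, snr=0.25, n_train_per_class=100, n_test_per_class=50),
}


def learnability_fixture(
    difficulty: str, seed: int = 0
) -> tuple[TrialSet, TrialSet]:
    """Fixed train/test TrialSet pair on the 3-channel geometry (T=500).

    ``easy`` (erd_depth 0.8, snr 2.0; 200 train + 100 test trials) is
    designed to be comfortably learnable; ``hard`` (erd_depth 0.1,
    snr 0.25) to land near chance.  Class balance is exact; determinism
    follows from the seed.
    """
    try:
        params = FIXTURE_CONFIGS[difficulty]
    except KeyError:
        raise ValueError(
            f"difficulty must be one of {sorted(FIXTURE_CONFIGS)}; got {difficulty!r}"
        ) from None
    common = dict(
        n_channels=3,
        n_timestamps=500,
        erd_depth=params["erd_depth"],
        snr=params["snr"],
        subject_id=f"synthetic-{difficulty}",
    )
    train = generate_dataset(
        SynthConfig(
            n_trials_per_class=params["n_train_per_class"], seed=seed * 2 + 1, **common
        )
    )
    test = generate_dataset(
        SynthConfig(
            n_trials_per_class=params["n_test_per_class"], seed=seed * 2 + 2, **common
        )
    )
    return train, test
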