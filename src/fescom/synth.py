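"""Synthetic labeled IMU datasets for exercising the full pipeline.

The study protocol this generator emulates: five upper-limb exercise classes,
21 participants, 3 valid repetitions of each exercise per participant,
repetitions lasting 1-4 s, six channels (tri-axial acceleration and angular
velocity) sampled at 20 Hz.  Each class x channel pair carries a parametric
waveform template — a Hann-enveloped fundamental plus a second harmonic over
a constant offset:

    x(t) = offset + A * env(t)**shape * [sin(2*pi*f*t + phi)
                                         + h * sin(4*pi*f*t + phi2)]

On *informative* channels the template parameters (offset, amplitude ``A``,
fundamental frequency ``f``, harmonic ratio ``h``, envelope shape) differ
across classes, so every feature type has a class-dependent expectation:
offsets separate the mean, amplitudes separate spread-type features,
frequencies separate the spectral-location features, and the harmonic ratio
and envelope shape separate skewness and kurtosis.  *Distractor* channels
share one template across all classes and carry no class information.

Per-subject variability is modelled as multiplicative amplitude jitter and a
small time-scale warp; measurement noise is i.i.d. Gaussian per sample.
Optional outlier spikes exercise the median filter.  Everything is fully
determined by the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .signal_io import SignalWindow

#: Default class labels mirroring a five-exercise protocol.
DEFAULT_CLASSES = ("exe1", "exe2", "exe3", "exe4", "exe5")


@dataclass(frozen=True)
class ChannelTemplate:
    """Parametric waveform for one class on one channel."""

    offset: float
    amplitude: float
    frequency_hz: float
    phase: float = 0.0
    harmonic_ratio: float = 0.0
    harmonic_phase: float = 1.5707963267948966  # pi/2: harmonic drives skewness
    envelope_shape: float = 1.0

    def evaluate(
        self, t: np.ndarray, amp_scale: float = 1.0, time_scale: float = 1.0
    ) -> np.ndarray:
        duration = t[-1] if t[-1] > 0 else 1.0
        env = np.sin(np.pi * t / duration) ** 2  # Hann bump over the repetition
        carrier = np.sin(2 * np.pi * self.frequency_hz * time_scale * t + self.phase)
        harmonic = self.harmonic_ratio * np.sin(
            4 * np.pi * self.frequency_hz * time_scale * t + self.harmonic_phase
        )
        return self.offset + self.amplitude * amp_scale * env**self.envelope_shape * (
            carrier + harmonic
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a simulated dataset.

    ``templates[class_label][channel]`` gives the waveform for each of the 6
    channels; ``informative_mask`` marks channels whose templates differ
    across classes.  ``noise_sd`` is the per-channel Gaussian noise SD;
    ``subject_jitter`` scales per-subject amplitude and timing perturbations.
    """

    n_classes: int = 5
    reps_per_class_per_subject: int = 3
    n_subjects: int = 21
    fs_hz: float = 20.0
    duration_range_s: tuple[float, float] = (1.0, 4.0)
    class_labels: tuple[str, ...] = DEFAULT_CLASSES
    templates: dict[str, tuple[ChannelTemplate, ...]] = field(default_factory=dict)
    informative_mask: tuple[bool, ...] = (True,) * 6
    noise_sd: tuple[float, ...] = (0.05,) * 6
    subject_jitter: float = 0.1
    rep_jitter: float = 0.07
    offset_jitter: float = 0.07
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if len(self.class_labels) != self.n_classes:
            raise ValidationError("class_labels must match n_classes")
        if not any(self.informative_mask):
            raise ValidationError("at least one channel must be informative")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValidationError("duration_range_s must satisfy 0 < lo <= hi")
        if not self.fs_hz > 0:
            raise ValidationError("fs_hz must be positive")
        if self.templates and set(self.templates) != set(self.class_labels):
            raise ValidationError("templates must cover exactly the class labels")
        for label, chans in self.templates.items():
            if len(chans) != 6:
                raise ValidationError(f"class '{label}' needs 6 channel templates")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["templates"] = {
            label: [asdict(t) for t in chans] for label, chans in self.templates.items()
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["templates"] = {
            label: tuple(ChannelTemplate(**t) for t in chans)
            for label, chans in d.get("templates", {}).items()
        }
        for key in (
            "duration_range_s",
            "class_labels",
            "informative_mask",
            "noise_sd",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls.from_dict(json.loads(text))


def default_protocol_spec(seed: int = 0) -> SyntheticSpec:
    """A ready-made five-class spec mirroring the study protocol.

    Channels 0-3 (acc_x, acc_y, acc_z, gyr_x) are informative: per class, the
    offset steps by 0.2, the amplitude by 0.2 from 0.8, the fundamental
    frequency by 0.6 Hz from 0.6 Hz (staying below 4 Hz), the harmonic ratio
    by 0.15 from 0.2, and the envelope shape by 0.25 from 0.5 — so between any
    two classes every feature type differs in expectation, with mean shifts of
    roughly 2-10 within-class SDs at the default noise level.  Channels 4-5
    (gyr_y, gyr_z) are identical-template distractors.
    """
    templates: dict[str, tuple[ChannelTemplate, ...]] = {}
    informative = (True, True, True, True, False, False)
    for c, label in enumerate(DEFAULT_CLASSES):
        chans = []
        for ch in range(6):
            if informative[ch]:
                chans.append(
                    ChannelTemplate(
                        offset=0.2 * c + 0.05 * ch,
                        amplitude=0.8 + 0.2 * c + 0.05 * ch,
                        frequency_hz=0.6 + 0.6 * c + 0.1 * ch,
                        phase=0.3 * ch,
                        harmonic_ratio=0.2 + 0.15 * c,
                        envelope_shape=0.5 + 0.25 * c,
                    )
                )
            else:
                # distractor: one template shared by all classes
                chans.append(
                    ChannelTemplate(
                        offset=0.1,
                        amplitude=1.0,
                        frequency_hz=1.0 + 0.2 * (ch - 4),
                        phase=0.3 * ch,
                        harmonic_ratio=0.3,
                        envelope_shape=1.0,
                    )
                )
        templates[label] = tuple(chans)
    return SyntheticSpec(
        templates=templates,
        informative_mask=informative,
        noise_sd=(0.05,) * 6,
        subject_jitter=0.1,
        seed=seed,
    )


def generate_dataset(spec: SyntheticSpec) -> tuple[list[SignalWindow], SyntheticSpec]:
    """Simulate one labeled dataset: ``n_classes x reps x n_subjects`` windows.

    Window sample ``t`` of channel ``c`` is the class template evaluated under
    the subject's amplitude/timing perturbation plus Gaussian noise; durations
    are drawn uniformly from ``duration_range_s``.  Output is fully determined
    by ``spec.seed`` and returned with the spec echoed back.
    """
    if not spec.templates:
        spec = replace(spec, templates=default_protocol_spec(spec.seed).templates)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.duration_range_s
    windows: list[SignalWindow] = []
    for subj in range(spec.n_subjects):
        # per-subject perturbation shared across that subject's repetitions
        amp_scale = 1.0 + spec.subject_jitter * rng.standard_normal()
        amp_scale = max(amp_scale, 0.1)
        time_scale = 1.0 + 0.5 * spec.subject_jitter * rng.standard_normal()
        time_scale = min(max(time_scale, 0.5), 1.5)
        for label in spec.class_labels:
            chans = spec.templates[label]
            for _rep in range(spec.reps_per_class_per_subject):
                duration = rng.uniform(lo, hi)
                n = max(int(round(duration * spec.fs_hz)), 4)
                t = np.arange(n) / spec.fs_hz
                # repetition-to-repetition execution variability
                rep_amp = 1.0 + spec.rep_jitter * rng.standard_normal()
                rep_time = 1.0 + spec.rep_jitter * rng.standard_normal()
                rep_amp = max(rep_amp, 0.1)
                rep_time = min(max(rep_time, 0.5), 1.5)
                samples = np.column_stack(
                    [
                        chans[ch].evaluate(
                            t, amp_scale * rep_amp, time_scale * rep_time
                        )
                        + spec.offset_jitter * rng.standard_normal()
                        + spec.noise_sd[ch] * rng.standard_normal(n)
                        for ch in range(6)
                    ]
                )
                if spec.outlier_rate > 0:
                    spikes = rng.random(samples.shape) < spec.outlier_rate
                    samples = samples + spikes * spec.outlier_scale * rng.standard_normal(
                        samples.shape
                    )
                windows.append(
                    SignalWindow(
                        samples=samples,
                        label=label,
                        sampling_rate_hz=spec.fs_hz,
                        subject_id=f"subject_{subj:02d}",
                    )
                )
    return windows, spec


def informative_feature_indices(
    spec: SyntheticSpec, feature_names: Sequence[str] | None = None
) -> list[int]:
    """Indices of features extracted from informative channels (channel-major layout)."""
    from .features import FEATURE_TYPES  # local import to avoid a cycle

    n_types = len(FEATURE_TYPES)
    return [
        ch * n_types + k
        for ch, informative in enumerate(spec.informative_mask)
        if informative
        for k in range(n_types)
    ]
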