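"""Two-state multichannel EEG-like signal generator.

Each subject contributes one block per state: an alert block whose channels
are broadband-noise dominated (high signal irregularity, hence high sample
entropy) and a fatigue block dominated by a narrowband 8-13 Hz oscillation
with reduced noise (low irregularity, low sample entropy). The complexity
contrast is implemented purely as the oscillation-to-noise ratio — the
minimal mechanism that guarantees the entropy separation the downstream
method assumes — with per-subject and per-channel multiplicative jitter on
both the oscillation amplitude and the noise level, so the ratio (and thus
the entropy) varies realistically across channels and subjects.

A ``contrast`` dial in [0, 1] interpolates the fatigue recipe between the
alert recipe (0: the two states are statistically identical, so any
classifier must fall to chance) and the full fatigue recipe (1, default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .entropy import EntropyParams, epoch_feature_matrix
from .errors import ConfigurationError
from .features import FeatureMatrix, RawSignals

__all__ = ["SimSpec", "generate", "generate_features"]


@dataclass(frozen=True)
class SimSpec:
    """Simulation settings.

    Per subject, ``seconds_per_state`` seconds of alert signal are followed
    by the same duration of fatigue signal, across ``n_channels`` channels at
    ``rate`` Hz; 1-second epochs then give ``2 * seconds_per_state`` labelled
    rows per subject (10 subjects -> a 600 x 30 feature matrix).
    """

    n_subjects: int = 10
    seconds_per_state: int = 30
    n_channels: int = 30
    rate: float = 1000.0
    contrast: float = 1.0
    noise_sd: float = 1.0  # alert-state noise level (amplitude units)
    alert_osc_amp: float = 0.3  # residual alpha in the alert state
    fatigue_osc_amp: float = 2.0  # dominant alpha in the fatigue state
    fatigue_noise_sd: float = 0.4
    osc_band: tuple[float, float] = (8.0, 13.0)  # Hz
    subject_jitter_sd: float = 0.05  # log-scale gain jitter shared within a subject
    channel_jitter_sd: float = 0.05  # log-scale gain jitter per channel
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.seconds_per_state, self.n_channels) < 1:
            raise ConfigurationError("all counts must be positive")
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")
        if not 0 <= self.contrast <= 1:
            raise ConfigurationError("contrast must lie in [0, 1]")
        if self.noise_sd <= 0 and self.alert_osc_amp <= 0:
            raise ConfigurationError("alert recipe would have zero variance")


def _state_recipe(spec: SimSpec, state: int) -> tuple[float, float]:
    """(oscillation amplitude, noise SD) for a state, interpolated by contrast."""
    if state == 0:
        return spec.alert_osc_amp, spec.noise_sd
    c = spec.contrast
    osc = spec.alert_osc_amp + c * (spec.fatigue_osc_amp - spec.alert_osc_amp)
    noise = spec.noise_sd + c * (spec.fatigue_noise_sd - spec.noise_sd)
    return osc, noise


def generate(spec: SimSpec) -> RawSignals:
    """Deterministic (given ``spec.seed``) two-state multichannel recording.

    Rows are ordered subject by subject, alert block first; ``epoch_labels``
    carries one 0/1 label per 1-second epoch.
    """
    rng = np.random.default_rng(spec.seed)
    n_sec = spec.seconds_per_state
    samples_per_state = int(round(n_sec * spec.rate))
    t = np.arange(samples_per_state) / spec.rate

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for _ in range(spec.n_subjects):
        subj_gain_osc = float(np.exp(rng.normal(0.0, spec.subject_jitter_sd)))
        subj_gain_noise = float(np.exp(rng.normal(0.0, spec.subject_jitter_sd)))
        # oscillation frequency/phase fixed per subject-channel, shared by states
        freqs = rng.uniform(*spec.osc_band, size=spec.n_channels)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
        ch_gain_osc = np.exp(rng.normal(0.0, spec.channel_jitter_sd, spec.n_channels))
        ch_gain_noise = np.exp(rng.normal(0.0, spec.channel_jitter_sd, spec.n_channels))
        for state in (0, 1):
            osc_amp, noise_sd = _state_recipe(spec, state)
            osc = np.sin(2.0 * np.pi * t[:, None] * freqs[None, :] + phases[None, :])
            block = (
                osc_amp * subj_gain_osc * ch_gain_osc[None, :] * osc
                + noise_sd
                * subj_gain_noise
                * ch_gain_noise[None, :]
                * rng.standard_normal((samples_per_state, spec.n_channels))
            )
            if np.any(block.std(axis=0) == 0):
                raise ConfigurationError("spec yields a degenerate (flat) channel")
            blocks.append(block)
            labels.append(np.full(n_sec, state, dtype=int))

    return RawSignals(
        values=np.vstack(blocks),
        rate=spec.rate,
        epoch_labels=np.concatenate(labels),
    )


def generate_features(
    spec: SimSpec, params: EntropyParams | None = None, epoch_len: float = 1.0
) -> FeatureMatrix:
    """Generate signals and reduce them to a labelled entropy feature matrix.

    With defaults this yields ``n_subjects * 60`` rows by ``n_channels``
    columns, half the rows per class.
    """
    sim = generate(spec)
    return epoch_feature_matrix(
        sim.values,
        rate=sim.rate,
        epoch_len=epoch_len,
        params=params or EntropyParams(),
        labels=sim.epoch_labels,
        channel_names=sim.channel_names,
    )


def with_contrast(spec: SimSpec, contrast: float) -> SimSpec:
    """Copy of ``spec`` with the contrast dial moved."""
    return replace(spec, contrast=contrast)
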