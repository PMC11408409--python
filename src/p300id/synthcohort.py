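"""Synthetic two-group oddball-paradigm ERP cohorts.

Real P300 recordings from a methamphetamine (MA) / healthy-control (HC)
oddball study are not publicly available, so the pipeline is exercised on
generated cohorts that reproduce the statistical structure the analysis
assumes: multichannel epochs of background EEG noise plus, after deviant
(S2) stimuli, a delta-band P300 bump whose amplitude and latency differ
between groups.  Everything else about real EEG (artifacts, volume
conduction, inter-channel correlation) is deliberately absent.

Epochs span -200..1000 ms around stimulus onset at 250 Hz; the P300 is a
Gaussian bump scaled per channel by a fronto-central gain profile, with
per-epoch amplitude and latency jitter.  Background noise is 1/f ("pink")
by default, white on request, independent across channels and epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import MONTAGE_62, default_frontal_weighting

__all__ = ["SynthConfig", "EpochSet", "p300_template", "generate_cohort"]

GROUP_MA = "MA"
GROUP_HC = "HC"
STIM_S1 = "S1"
STIM_S2_ADDICTION = "S2-addiction"
STIM_S2_NEUTRAL = "S2-neutral"


@dataclass
class SynthConfig:
    """Generative parameters of a synthetic oddball ERP cohort.

    Defaults mirror the scale of the study design this pipeline targets:
    18 MA and 22 HC subjects, 40 retained deviant epochs each (so that
    non-overlapping 5-epoch averaging yields 8 averaged samples/subject,
    i.e. 144 MA samples), 62 channels at 250 Hz.

    The group P300 parameters (HC 6 uV at 330 ms, MA 9 uV at 360 ms) are
    working defaults chosen for clear but not trivial separability; they
    are not biological estimates.  ``p300_width`` is the Gaussian standard
    deviation of the bump in ms.  Setting both groups' amplitude and
    latency equal yields a null cohort with exchangeable groups.
    """

    n_subjects_ma: int = 18
    n_subjects_hc: int = 22
    epochs_per_subject: int = 40
    n_channels: int = 62
    fs: float = 250.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    p300_amp_ma: float = 9.0
    p300_amp_hc: float = 6.0
    p300_lat_ma: float = 360.0
    p300_lat_hc: float = 330.0
    p300_width: float = 60.0
    frontal_weighting: np.ndarray | None = None
    noise_sd: float = 5.0
    noise_spectrum: str = "pink"
    amp_jitter_sd: float = 1.0
    lat_jitter_sd: float = 15.0
    include_nontarget: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        t0, t1 = self.epoch_window
        if not (t0 < t1 and t0 <= 0.0 <= t1):
            raise ValueError("epoch_window must be a nonempty interval containing 0 ms")
        for name in ("n_subjects_ma", "n_subjects_hc", "epochs_per_subject", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.p300_width <= 0:
            raise ValueError("p300_width must be positive")
        if self.noise_spectrum not in ("pink", "white"):
            raise ValueError("noise_spectrum must be 'pink' or 'white'")

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.fs / 1000.0)) + 1
        return t0 + np.arange(n) * 1000.0 / self.fs

    def channel_gains(self, channel_names) -> np.ndarray:
        if self.frontal_weighting is not None:
            g = np.asarray(self.frontal_weighting, dtype=float)
            if g.shape != (self.n_channels,):
                raise ValueError("frontal_weighting length must equal n_channels")
            return g
        if self.n_channels == len(MONTAGE_62):
            return default_frontal_weighting(channel_names)
        return np.ones(self.n_channels)


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``data`` is (epochs, channels, samples) in uV."""

    data: np.ndarray
    times: np.ndarray
    fs: float
    stimulus_code: np.ndarray
    group: np.ndarray
    subject_id: np.ndarray
    channel_names: tuple[str, ...]
    block_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_ep, n_ch, n_s = self.data.shape
        if len(self.times) != n_s:
            raise ValueError("times length must match sample axis")
        dt = np.diff(self.times)
        if not np.allclose(dt, 1000.0 / self.fs, rtol=0, atol=1e-6):
            raise ValueError("times must be uniformly spaced at 1000/fs ms")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length must match channel axis")
        for name in ("stimulus_code", "group", "subject_id"):
            if len(getattr(self, name)) != n_ep:
                raise ValueError(f"{name} must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, idx) -> "EpochSet":
        return replace(
            self,
            data=self.data[idx],
            stimulus_code=self.stimulus_code[idx],
            group=self.group[idx],
            subject_id=self.subject_id[idx],
            block_index=None if self.block_index is None else self.block_index[idx],
        )


def p300_template(
    amplitude: float, latency_ms: float, width_ms: float, times: np.ndarray
) -> np.ndarray:
    """Gaussian P300 bump: peak ``amplitude`` uV at ``latency_ms``, sd ``width_ms``.

    The bump is effectively zero outside latency +- 3 widths; with the
    default width (60 ms) its spectral energy is almost entirely below
    4 Hz, i.e. the template is a delta-band component by construction.
    """
    times = np.asarray(times, dtype=float)
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    if not (0.0 <= latency_ms <= times[-1]):
        raise ValueError(
            f"latency outside epoch: {latency_ms} ms not in post-stimulus [0, {times[-1]:g}] ms"
        )
    return amplitude * np.exp(-0.5 * ((times - latency_ms) / width_ms) ** 2)


def _noise(rng: np.random.Generator, shape, sd: float, spectrum: str, fs: float) -> np.ndarray:
    """Unit-variance background noise scaled to ``sd``; pink = 1/f amplitude."""
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if spectrum == "white":
        return sd * white
    n = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    # exact per-sample sd of irfft(rfft(white) * gain): double interior bins
    w = np.full(len(gain), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    shaped /= np.sqrt(np.sum(w * gain**2) / n)
    return sd * shaped


def generate_cohort(config: SynthConfig) -> EpochSet:
    """Draw a full two-group cohort; deterministic for a fixed config/seed.

    Each epoch is background noise plus the group's P300 template (with
    per-epoch amplitude/latency jitter, amplitude floored at 0) scaled by
    the per-channel gain profile.  The pre-stimulus interval carries noise
    only (the Gaussian tail before 0 ms is negligible at the default
    latency/width).
    """
    rng = np.random.default_rng(config.seed)
    times = config.times
    n_ch = config.n_channels
    channel_names = (
        MONTAGE_62 if n_ch == len(MONTAGE_62) else tuple(f"ch{i:02d}" for i in range(n_ch))
    )
    gains = config.channel_gains(channel_names)

    n_subj = config.n_subjects_ma + config.n_subjects_hc
    eps = config.epochs_per_subject
    n_epochs = n_subj * eps

    groups = np.array(
        [GROUP_MA] * config.n_subjects_ma + [GROUP_HC] * config.n_subjects_hc
    ).repeat(eps)
    subject_id = np.array(
        [f"{g}{i:02d}" for i, g in enumerate([GROUP_MA] * config.n_subjects_ma
                                             + [GROUP_HC] * config.n_subjects_hc)]
    ).repeat(eps)
    stim = np.full(n_epochs, STIM_S2_ADDICTION)

    is_ma = groups == GROUP_MA
    amp = np.where(is_ma, config.p300_amp_ma, config.p300_amp_hc)
    lat = np.where(is_ma, config.p300_lat_ma, config.p300_lat_hc)
    amp = np.maximum(amp + config.amp_jitter_sd * rng.standard_normal(n_epochs), 0.0)
    lat = np.clip(
        lat + config.lat_jitter_sd * rng.standard_normal(n_epochs),
        3 * config.p300_width,
        times[-1] - 1000.0 / config.fs,
    )

    # (epochs, samples) templates, broadcast over channels with the gain profile
    bump = amp[:, None] * np.exp(-0.5 * ((times[None, :] - lat[:, None]) / config.p300_width) ** 2)
    data = _noise(rng, (n_epochs, n_ch, len(times)), config.noise_sd,
                  config.noise_spectrum, config.fs)
    data += gains[None, :, None] * bump[:, None, :]

    if config.include_nontarget:
        # frequent standards (no P300) and neutral deviants (a common P300
        # with the control parameters in both groups), in the paradigm's
        # 70 : 15 : 15 stimulus proportions relative to the retained
        # addiction deviants; the analysis path filters these out
        n_s1 = int(round(eps * 70 / 15)) * n_subj
        n_neu = eps * n_subj
        subj_once = subject_id[::eps]
        group_once = groups[::eps]
        s1_data = _noise(rng, (n_s1, n_ch, len(times)), config.noise_sd,
                         config.noise_spectrum, config.fs)
        neu_amp = np.maximum(
            config.p300_amp_hc + config.amp_jitter_sd * rng.standard_normal(n_neu), 0.0
        )
        neu_lat = np.clip(
            config.p300_lat_hc + config.lat_jitter_sd * rng.standard_normal(n_neu),
            3 * config.p300_width, times[-1] - 1000.0 / config.fs,
        )
        neu_bump = neu_amp[:, None] * np.exp(
            -0.5 * ((times[None, :] - neu_lat[:, None]) / config.p300_width) ** 2
        )
        neu_data = _noise(rng, (n_neu, n_ch, len(times)), config.noise_sd,
                          config.noise_spectrum, config.fs)
        neu_data += gains[None, :, None] * neu_bump[:, None, :]
        data = np.concatenate([data, s1_data, neu_data])
        stim = np.concatenate([stim, np.full(n_s1, STIM_S1), np.full(n_neu, STIM_S2_NEUTRAL)])
        groups = np.concatenate([groups, np.repeat(group_once, n_s1 // n_subj),
                                 np.repeat(group_once, eps)])
        subject_id = np.concatenate([subject_id, np.repeat(subj_once, n_s1 // n_subj),
                                     np.repeat(subj_once, eps)])

    return EpochSet(
        data=data.astype(np.float32),
        times=times,
        fs=config.fs,
        stimulus_code=stim,
        group=groups,
        subject_id=subject_id,
        channel_names=channel_names,
    )
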