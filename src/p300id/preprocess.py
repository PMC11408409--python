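"""Offline conditioning of epoch tensors.

The chain mirrors a standard ERP workflow: zero-phase 30 Hz low-pass,
anti-aliased downsampling to 250 Hz, baseline correction against the
pre-stimulus interval, selection of deviant (S2) epochs, block averaging
of five consecutive epochs per subject to raise signal-to-noise, and
finally seeded subsampling of the majority class so both groups enter
classification with equal sample counts.

Zero-phase (forward-backward) filtering is used so that latency features
are not biased by filter delay.  "Overlapped and averaged" blocks default
to non-overlapping (stride = size), which gives determinate record counts
and no shared epochs between averaged samples; a sliding mode
(stride < size) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .synthcohort import EpochSet, STIM_S2_ADDICTION

__all__ = [
    "PreprocConfig",
    "lowpass",
    "resample_epochs",
    "baseline_correct",
    "block_average",
    "subsample_to_balance",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    lowpass_hz: float = 30.0
    target_fs: float = 250.0
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    block_size: int = 5
    block_stride: int = 5
    keep_stimulus: str = STIM_S2_ADDICTION
    balance_classes: bool = True
    balance_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lowpass_hz < self.target_fs / 2:
            raise ValueError("need 0 < lowpass_hz < target_fs/2")
        if not 1 <= self.block_stride <= self.block_size:
            raise ValueError("need 1 <= block_stride <= block_size")


def lowpass(epochs: EpochSet, cutoff: float = 30.0, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth low-pass per channel per epoch; unit DC gain."""
    if cutoff >= epochs.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {epochs.fs / 2} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data.astype(float), axis=-1)
    return replace(epochs, data=filtered)


def resample_epochs(epochs: EpochSet, target_fs: float = 250.0) -> EpochSet:
    """Polyphase anti-aliased downsampling; no-op when rates already match."""
    if target_fs > epochs.fs:
        raise ValueError(f"upsampling {epochs.fs} -> {target_fs} Hz not supported")
    if target_fs == epochs.fs:
        return epochs
    ratio = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    data = signal.resample_poly(epochs.data.astype(float), ratio.numerator,
                                ratio.denominator, axis=-1)
    times = epochs.times[0] + np.arange(data.shape[-1]) * 1000.0 / target_fs
    return replace(epochs, data=data, times=times, fs=target_fs)


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    t0, t1 = window
    mask = (epochs.times >= t0) & (epochs.times <= t1)
    if not mask.any():
        raise ValueError(f"baseline window {window} ms contains no samples")
    baseline = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - baseline)


def select_stimulus(epochs: EpochSet, code: str = STIM_S2_ADDICTION) -> EpochSet:
    kept = np.flatnonzero(epochs.stimulus_code == code)
    if kept.size == 0:
        raise ValueError(f"no epochs with stimulus code {code!r}")
    return epochs.select(kept)


def block_average(epochs: EpochSet, block_size: int = 5, block_stride: int = 5) -> EpochSet:
    """Average windows of ``block_size`` consecutive epochs within each subject.

    Windows advance by ``block_stride`` epochs (non-overlapping when
    stride = size).  Subjects contributing fewer than ``block_size``
    epochs are dropped with a warning.  Blocks never mix subjects.
    """
    if not 1 <= block_stride <= block_size:
        raise ValueError("need 1 <= block_stride <= block_size")
    out, groups, subjects, blocks = [], [], [], []
    # preserve first-appearance subject order
    _, first = np.unique(epochs.subject_id, return_index=True)
    for subj in epochs.subject_id[np.sort(first)]:
        idx = np.flatnonzero(epochs.subject_id == subj)
        if idx.size < block_size:
            logger.warning(
                "subject %s dropped: %d epochs < block size %d", subj, idx.size, block_size
            )
            continue
        n_blocks = (idx.size - block_size) // block_stride + 1
        for b in range(n_blocks):
            win = idx[b * block_stride : b * block_stride + block_size]
            out.append(epochs.data[win].mean(axis=0))
            groups.append(epochs.group[idx[0]])
            subjects.append(subj)
            blocks.append(b)
    if not out:
        raise ValueError("no subject has enough epochs to form a block")
    return replace(
        epochs,
        data=np.stack(out),
        stimulus_code=np.full(len(out), epochs.stimulus_code[0]),
        group=np.array(groups),
        subject_id=np.array(subjects),
        block_index=np.array(blocks),
    )


def subsample_to_balance(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Seeded subsampling of the majority class to the minority count.

    Applied after block averaging so both classes contribute the same
    number of averaged samples to classification.
    """
    rng = np.random.default_rng(seed)
    labels = np.unique(epochs.group)
    if len(labels) != 2:
        raise ValueError("balancing requires exactly two groups")
    idx_by = {g: np.flatnonzero(epochs.group == g) for g in labels}
    n_min = min(len(v) for v in idx_by.values())
    keep = []
    for g in labels:
        idx = idx_by[g]
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    return epochs.select(np.sort(np.concatenate(keep)))


def run_pipeline(epochs: EpochSet, cfg: PreprocConfig | None = None) -> EpochSet:
    """Full conditioning chain in the fixed order: low-pass -> resample ->
    baseline -> S2 selection -> block average -> (optional) class balance."""
    cfg = cfg or PreprocConfig()
    logger.info("preprocess: lowpass %.1f Hz", cfg.lowpass_hz)
    x = lowpass(epochs, cfg.lowpass_hz)
    logger.info("preprocess: resample -> %.1f Hz", cfg.target_fs)
    x = resample_epochs(x, cfg.target_fs)
    logger.info("preprocess: baseline %s ms", cfg.baseline_window)
    x = baseline_correct(x, cfg.baseline_window)
    x = select_stimulus(x, cfg.keep_stimulus)
    logger.info("preprocess: block average size=%d stride=%d", cfg.block_size, cfg.block_stride)
    x = block_average(x, cfg.block_size, cfg.block_stride)
    if cfg.balance_classes:
        x = subsample_to_balance(x, cfg.balance_seed)
    return x
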