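"""From raw fluorescence to analysis-ready series.

Covers -dF/F normalization against the 1 s pre-stimulus baseline, cutting
the seven 1 s analysis windows and concatenating trials within a window,
zero-phase IIR decomposition into slow and fast components, and the
node-centered (per-glomerulus amplitude) response map.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .synthdata import RawRecording

__all__ = [
    "WINDOW_NAMES",
    "TrialTensor",
    "WindowedSeries",
    "decompose",
    "dff_normalize",
    "node_response_map",
    "window_concatenate",
    "window_interval",
]

#: The seven 1 s analysis windows, by time relative to stimulus onset:
#: ON = 0-1 s, earlyOFF = 1-2 s, OFF2..OFF6 = 2-3 .. 6-7 s.
WINDOW_NAMES = ("ON", "earlyOFF", "OFF2", "OFF3", "OFF4", "OFF5", "OFF6")


def window_interval(window: str | int) -> tuple[float, float]:
    """(start, stop) in seconds relative to stimulus onset for a window."""
    if isinstance(window, str):
        try:
            idx = WINDOW_NAMES.index(window)
        except ValueError:
            raise ValueError(f"unknown window {window!r}; "
                             f"expected one of {WINDOW_NAMES}") from None
    else:
        idx = int(window)
        if not 0 <= idx < len(WINDOW_NAMES):
            raise ValueError(f"window index {idx} out of range")
    return float(idx), float(idx + 1)


@dataclasses.dataclass
class TrialTensor:
    """-dF/F series, (subject x odor x trial x glomerulus x time).

    ``time_zero`` is the stimulus onset in seconds from the start of the
    trace; masked glomeruli are NaN throughout and excluded downstream.
    """

    dff: np.ndarray            # (S, O, R, M, T)
    mask: np.ndarray           # (S, M) bool
    sampling_rate: float
    time_zero: float           # s, stimulus onset within each trial trace
    glomerulus_ids: tuple = ()
    odor_names: tuple = ()
    component: str = "unfiltered"

    @property
    def n_trials(self) -> int:
        return self.dff.shape[2]

    @property
    def samples_per_second(self) -> int:
        return int(round(self.sampling_rate))


@dataclasses.dataclass
class WindowedSeries:
    """Trial-concatenated 1 s window for one subject and odor.

    ``data`` is T x m with T = n_trials x samples-per-second and columns
    the subject's available glomeruli in the order of ``labels``.
    """

    data: np.ndarray
    window: str
    component: str
    labels: tuple
    sampling_rate: float
    samples_per_trial: int     # samples contributed by each trial (one second)
    subject: int | None = None
    odor: str | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def dff_normalize(raw: RawRecording, baseline_length: float = 1.0) -> TrialTensor:
    """Normalize each trial to the negative relative fluorescence change.

    Per trial and glomerulus, output = -(F - Fbar) / Fbar with Fbar the
    mean over the ``baseline_length`` window immediately preceding
    stimulus onset.  With the Fura-2 convention (calcium rise dims
    fluorescence) excitatory responses map to positive -dF/F.

    Channels whose baseline mean is not strictly positive cannot be
    normalized; they are flagged with a warning and masked out.
    """
    fs = raw.sampling_rate
    onset_idx = int(round(raw.stimulus_onset * fs))
    nb = int(round(baseline_length * fs))
    if nb < 1 or onset_idx < nb:
        raise ValueError("each trial must include >= baseline_length of "
                         "pre-stimulus samples")
    F = raw.fluorescence
    base = F[..., onset_idx - nb:onset_idx].mean(axis=-1, keepdims=True)
    mask = raw.mask.copy()
    with np.errstate(invalid="ignore"):
        bad = np.any(base <= 0, axis=(1, 2, 4))  # (S, M): any trial non-positive
    if np.any(bad & mask):
        warnings.warn(f"masking {int(np.sum(bad & mask))} channel(s) with "
                      "non-positive baseline mean", RuntimeWarning)
        mask &= ~bad
    with np.errstate(invalid="ignore", divide="ignore"):
        dff = -(F - base) / base
    for s in range(dff.shape[0]):
        dff[s, :, :, ~mask[s], :] = np.nan
    return TrialTensor(dff=dff, mask=mask, sampling_rate=fs,
                       time_zero=raw.stimulus_onset,
                       glomerulus_ids=tuple(raw.glomerulus_ids),
                       odor_names=tuple(raw.odor_names))


def _odor_index(tensor: TrialTensor, odor: str | int) -> int:
    if isinstance(odor, str):
        return tensor.odor_names.index(odor)
    return int(odor)


def window_concatenate(tensor: TrialTensor, window: str | int,
                       subject: int, odor: str | int,
                       trials: Sequence[int] | None = None) -> WindowedSeries:
    """Cut one 1 s window from every trial and concatenate in trial order.

    ``trials`` restricts to a subset of trials (used for the trial-group
    splitting of the template analysis); by default all trials enter.
    """
    lo, hi = window_interval(window)
    name = WINDOW_NAMES[int(lo)]
    fs = tensor.sampling_rate
    start = int(round((tensor.time_zero + lo) * fs))
    stop = int(round((tensor.time_zero + hi) * fs))
    T = tensor.dff.shape[-1]
    if stop > T:
        raise ValueError(f"window {name} ({lo}-{hi} s after onset) extends "
                         f"beyond the recorded trial ({T / fs:.2f} s)")
    o = _odor_index(tensor, odor)
    cols = np.flatnonzero(tensor.mask[subject])
    block = tensor.dff[subject, o][:, cols, start:stop]  # (R, m, n)
    if trials is not None:
        block = block[np.asarray(trials, dtype=int)]
    data = np.concatenate([block[r].T for r in range(block.shape[0])], axis=0)
    labels = tuple(tensor.glomerulus_ids[c] for c in cols) if tensor.glomerulus_ids \
        else tuple(str(c) for c in cols)
    return WindowedSeries(data=data, window=name, component=tensor.component,
                          labels=labels, sampling_rate=fs,
                          samples_per_trial=stop - start, subject=subject,
                          odor=(tensor.odor_names[o] if tensor.odor_names
                                else str(o)))


def decompose(tensor: TrialTensor, low_cut: float = 1.5,
              high_cut: float = 2.5, order: int = 4):
    """Split -dF/F into slow and fast components with zero-phase IIR filters.

    The slow component is a forward-backward (zero-phase) Butterworth
    low-pass at ``low_cut`` applied per trial.  For the fast component the
    mean response across trials is first subtracted from each trial
    (removing the stereotyped stimulus transient), then a zero-phase
    Butterworth high-pass at ``high_cut`` is applied.  Filtering is done
    per trial, with reflective padding at the trial edges, so nothing
    smears across concatenation seams.
    """
    fs = tensor.sampling_rate
    nyq = fs / 2.0
    if not 0 < low_cut < nyq or not 0 < high_cut < nyq:
        raise ValueError("filter cutoffs must lie strictly between 0 and "
                         f"the Nyquist frequency ({nyq:g} Hz)")
    sos_lo = _signal.butter(order, low_cut, btype="lowpass", fs=fs, output="sos")
    sos_hi = _signal.butter(order, high_cut, btype="highpass", fs=fs, output="sos")
    slow = _signal.sosfiltfilt(sos_lo, tensor.dff, axis=-1, padtype="even")
    trial_mean = tensor.dff.mean(axis=2, keepdims=True)
    fast = _signal.sosfiltfilt(sos_hi, tensor.dff - trial_mean, axis=-1,
                               padtype="even")
    mk = dict(mask=tensor.mask.copy(), sampling_rate=fs,
              time_zero=tensor.time_zero,
              glomerulus_ids=tensor.glomerulus_ids,
              odor_names=tensor.odor_names)
    return (TrialTensor(dff=slow, component="slow", **mk),
            TrialTensor(dff=fast, component="fast", **mk))


def node_response_map(tensor: TrialTensor, window: str | int = "ON",
                      subject: int = 0, odor: str | int = 0,
                      trials: Sequence[int] | None = None) -> np.ndarray:
    """Time-averaged -dF/F per glomerulus over one window (node-centered map).

    Returns a length-M vector (full glomerulus order) with NaN for masked
    glomeruli; averaging runs over the window samples and the designated
    trials.
    """
    lo, hi = window_interval(window)
    fs = tensor.sampling_rate
    start = int(round((tensor.time_zero + lo) * fs))
    stop = int(round((tensor.time_zero + hi) * fs))
    o = _odor_index(tensor, odor)
    block = tensor.dff[subject, o, :, :, start:stop]  # (R, M, n)
    if trials is not None:
        block = block[np.asarray(trials, dtype=int)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=(0, 2))
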