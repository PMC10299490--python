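"""Synthetic glomerular calcium recordings with planted directed coupling.

The generator emulates multi-trial Fura-2 recordings from antennal-lobe
glomeruli.  Each channel is the fluorescence of one glomerulus over a
stimulation trial: an odor-evoked slow transient (fast rise, slow decay,
per-subject response latency) rides on a coupled fast-fluctuation process
generated by a stable vector autoregression (VAR) whose off-diagonal
coefficients encode a sparse planted directed network.  The Fura-2 dye
dims as calcium rises, so excitation appears as a fluorescence *decrease*;
downstream normalization to -dF/F flips it back to positive.

The planted :class:`GroundTruthNetwork` is returned alongside the data so
that connectivity recovery can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Union

import numpy as np

__all__ = [
    "DEFAULT_GLOMERULUS_IDS",
    "DEFAULT_ODOR_NAMES",
    "GenerationError",
    "GroundTruthNetwork",
    "RawRecording",
    "SimulationConfig",
    "make_network",
    "simulate_dataset",
    "stationarity_check",
    "var_companion",
]

# Atlas-style glomerulus ID labels (T1 tract numbering) so that real
# recordings labelled against the reference atlas could be dropped in.
DEFAULT_GLOMERULUS_IDS = ("17", "23", "24", "28", "29", "33", "35", "36", "37", "45")
DEFAULT_ODOR_NAMES = ("1HEX", "3HEX", "1NON", "ISOA", "ACTP", "BZDA")

_BURN_IN = 300  # VAR warm-up samples discarded before each trial


class GenerationError(RuntimeError):
    """Requested dynamics cannot be simulated (e.g. unstable planted VAR)."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-design and signal-model parameters of the generator.

    Defaults reproduce the recording protocol the analysis is built for:
    15 subjects, 6 odorants, 30 trials each, 10 glomeruli sampled at
    100 Hz with a 1 s odor pulse, and a sparse (~12% density) planted
    directed network.  Each trial trace covers ``baseline_length`` seconds
    of pre-stimulus baseline followed by the stimulus and the off phase.
    """

    n_subjects: int = 15
    n_glomeruli: int = 10
    n_trials: int = 30
    n_odors: int = 6
    sampling_rate: float = 100.0  # Hz
    trial_length: float = 10.0    # s, includes the pre-stimulus baseline
    baseline_length: float = 1.0  # s of pre-stimulus baseline per trial
    stimulus_duration: float = 1.0  # s odor ON
    coupling_density: float = 0.12
    coupling_strength: float = 0.2   # magnitude of planted VAR coefficients
    var_order_true: int = 2
    self_coupling: float = 0.5       # total own-lag coefficient mass per channel
    on_coupling_gain: float = 1.5    # off-diagonal coupling multiplier during ON
    transient_amplitude: float = 0.15  # peak -dF/F of the odor transient
    tau_rise: float = 0.01   # s, calcium-indicator onset
    tau_decay: float = 0.5   # s, calcium-indicator offset
    latency_jitter_sd: float = 0.05  # s, per-subject response latency offset
    trial_latency_sd: float = 0.01   # s, trial-to-trial latency jitter
    amplitude_jitter_sd: float = 0.2  # lognormal sigma of per-trial amplitude
    fast_sd: float = 0.02    # VAR innovation sd, fractional fluorescence units
    noise_sd: float = 0.005  # observation noise sd, fractional units
    baseline_f: float = 100.0  # raw fluorescence baseline, arbitrary units
    missing_prob: float = 0.05  # P(subject x glomerulus not identifiable)
    responsive_min: int = 2
    responsive_max: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_glomeruli", "n_trials", "n_odors",
                     "var_order_true"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.coupling_density <= 1.0:
            raise ValueError("coupling_density must lie in [0, 1]")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must lie in [0, 1]")
        sps = self.sampling_rate * 1.0
        if abs(sps - round(sps)) > 1e-9:
            raise ValueError("sampling_rate x 1 s must be an integer sample count")
        if self.trial_length <= self.baseline_length + self.stimulus_duration:
            raise ValueError("trial_length must exceed baseline + stimulus duration")
        if not 1 <= self.responsive_min <= self.responsive_max:
            raise ValueError("need 1 <= responsive_min <= responsive_max")

    @property
    def samples_per_second(self) -> int:
        return int(round(self.sampling_rate))

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_length * self.sampling_rate))

    @property
    def onset_sample(self) -> int:
        return int(round(self.baseline_length * self.sampling_rate))


@dataclasses.dataclass(frozen=True)
class GroundTruthNetwork:
    """Planted directed adjacency and signed coupling weights (no self-loops)."""

    adjacency: np.ndarray  # (M, M) bool, adjacency[i, j] means link i -> j
    weights: np.ndarray    # (M, M) float, zero where no link

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        w = np.asarray(self.weights, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1] or adj.shape != w.shape:
            raise ValueError("adjacency and weights must be square and matching")
        if np.any(np.diag(adj)):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "weights", np.where(adj, w, 0.0))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        m = self.n_nodes
        return self.n_links / (m * (m - 1)) if m > 1 else 0.0

    def to_json(self, path: Union[str, Path], labels=None) -> None:
        m = self.n_nodes
        labels = list(labels) if labels is not None else [str(i) for i in range(m)]
        links = [[labels[i], labels[j], float(self.weights[i, j])]
                 for i in range(m) for j in range(m) if self.adjacency[i, j]]
        payload = {"labels": labels, "links": links}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruthNetwork":
        payload = json.loads(Path(path).read_text())
        labels = payload["labels"]
        m = len(labels)
        idx = {lab: k for k, lab in enumerate(labels)}
        adj = np.zeros((m, m), dtype=bool)
        w = np.zeros((m, m))
        for src, dst, weight in payload["links"]:
            adj[idx[src], idx[dst]] = True
            w[idx[src], idx[dst]] = weight
        return cls(adjacency=adj, weights=w)


@dataclasses.dataclass
class RawRecording:
    """Raw fluorescence traces, (subject x odor x trial x glomerulus x time).

    Masked (unidentifiable) glomeruli carry NaN and ``mask`` False; the
    mask is per subject x glomerulus, shared across odors and trials.
    """

    fluorescence: np.ndarray   # (S, O, R, M, T), raw F units, positive
    mask: np.ndarray           # (S, M) bool, True = glomerulus available
    sampling_rate: float       # Hz
    stimulus_onset: float      # s from trace start
    stimulus_offset: float     # s from trace start
    glomerulus_ids: tuple = ()
    odor_names: tuple = ()
    responsive: dict | None = None          # odor name -> planted responsive indices
    subject_latencies: np.ndarray | None = None  # (S,) s

    @property
    def shape(self):
        return self.fluorescence.shape


def make_network(M: int, density: float, strength: float,
                 seed: int | None = 0,
                 rng: np.random.Generator | None = None) -> GroundTruthNetwork:
    """Draw a random directed network with ``round(density * M(M-1))`` links.

    Link positions are uniform over ordered off-diagonal pairs; weights
    have magnitude ``strength`` and random sign.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    if M < 2:
        raise ValueError("need at least 2 nodes for a directed network")
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(M) for j in range(M) if i != j]
    n_links = int(round(density * M * (M - 1)))
    chosen = rng.choice(len(pairs), size=n_links, replace=False)
    adj = np.zeros((M, M), dtype=bool)
    w = np.zeros((M, M))
    signs = rng.choice([-1.0, 1.0], size=n_links)
    for k, pair_idx in enumerate(chosen):
        i, j = pairs[int(pair_idx)]
        adj[i, j] = True
        w[i, j] = signs[k] * strength
    return GroundTruthNetwork(adjacency=adj, weights=w)


def _self_coefficients(p: int, total: float, ratio: float = 0.4) -> np.ndarray:
    """Own-lag coefficients decaying geometrically over lags, summing to ``total``."""
    w = ratio ** np.arange(p)
    return total * w / w.sum()


def _coeffs_from_weights(weights: np.ndarray,
                         config: SimulationConfig) -> np.ndarray:
    """VAR coefficient stack (p, M, M) from an off-diagonal weight matrix.

    ``A[k][j, i]`` drives i -> j at lag k+1; cross-coupling sits at lag 1
    only, own-lag decay spreads over the ``var_order_true`` lags.
    """
    M = weights.shape[0]
    p = config.var_order_true
    d = _self_coefficients(p, config.self_coupling)
    A = np.zeros((p, M, M))
    for k in range(p):
        A[k][np.diag_indices(M)] = d[k]
    A[0] += weights.T  # weights[i, j] = i -> j, coefficient row is target
    return A


def _var_coefficients(network: GroundTruthNetwork, config: SimulationConfig,
                      gain: float = 1.0) -> np.ndarray:
    return _coeffs_from_weights(gain * network.weights, config)


def var_companion(A: np.ndarray) -> np.ndarray:
    """Companion matrix of a VAR(p) coefficient stack (p, M, M)."""
    p, M, _ = A.shape
    comp = np.zeros((M * p, M * p))
    comp[:M, :] = np.hstack(list(A))
    if p > 1:
        comp[M:, :-M] = np.eye(M * (p - 1))
    return comp


def stationarity_check(network: GroundTruthNetwork,
                       config: SimulationConfig) -> bool:
    """True iff the planted VAR is stable at the strongest applied coupling.

    Stability is evaluated at the stimulus-ON coupling gain (the operative
    worst case), via the spectral radius of the companion matrix.
    """
    gain = max(1.0, config.on_coupling_gain)
    comp = var_companion(_var_coefficients(network, config, gain=gain))
    radius = float(np.max(np.abs(np.linalg.eigvals(comp))))
    return radius < 1.0


def _transient_envelope(t: np.ndarray, t0: float, tau_rise: float,
                        tau_decay: float) -> np.ndarray:
    """Double-exponential calcium transient starting at t0, peak-normalized to 1."""
    dt = t - t0
    env = np.where(dt > 0.0,
                   np.exp(-np.clip(dt, 0.0, None) / tau_decay)
                   - np.exp(-np.clip(dt, 0.0, None) / tau_rise),
                   0.0)
    peak = env.max()
    return env / peak if peak > 0 else env


def _simulate_var(A_base: np.ndarray, A_on: np.ndarray, on_mask: np.ndarray,
                  n_series: int, rng: np.random.Generator,
                  innovation_sd: float) -> np.ndarray:
    """Simulate ``n_series`` parallel runs of a (possibly ON-modulated) VAR.

    Returns (n_series, M, T) with T = len(on_mask); a burn-in of
    ``_BURN_IN`` samples under the baseline coefficients is discarded.
    """
    p, M, _ = A_base.shape
    T = on_mask.size
    total = T + _BURN_IN
    e = rng.normal(0.0, innovation_sd, size=(total, n_series, M))
    x = np.zeros((total, n_series, M))
    for n in range(total):
        on = n >= _BURN_IN and on_mask[n - _BURN_IN]
        A = A_on if on else A_base
        acc = e[n]
        for k in range(min(p, n)):
            acc = acc + x[n - 1 - k] @ A[k].T
        x[n] = acc
    return np.moveaxis(x[_BURN_IN:], 0, -1)  # (n_series, M, T)


def _radius(weights: np.ndarray, config: SimulationConfig) -> float:
    comp = var_companion(_coeffs_from_weights(weights, config))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_dataset(config: SimulationConfig,
                     network: GroundTruthNetwork | None = None,
                     odor_networks: Mapping[int, GroundTruthNetwork]
                     | None = None):
    """Generate a full multi-subject recording with known ground truth.

    Parameters
    ----------
    config
        Study-design and signal-model parameters.
    network
        Background directed network, active throughout the trial and
        amplified by ``on_coupling_gain`` during the stimulus; drawn from
        ``config`` (density ``coupling_density``, magnitude
        ``coupling_strength``) when None.
    odor_networks
        Optional odor-specific networks (odor index -> network), shared
        across subjects and superimposed on the background *only while
        the stimulus is on* - connectivity then carries odor identity
        during the ON phase but not after offset.

    Returns
    -------
    (RawRecording, truth)
        ``truth`` is the background :class:`GroundTruthNetwork`, or a
        dict ``{"background": ..., "odor_specific": {...}}`` when
        odor-specific networks were supplied.
    """
    rng = np.random.default_rng(config.seed)
    S, O, R, M = (config.n_subjects, config.n_odors, config.n_trials,
                  config.n_glomeruli)
    T = config.samples_per_trial
    fs = config.sampling_rate

    if network is None:
        network = make_network(M, config.coupling_density,
                               config.coupling_strength, rng=rng)
    if network.n_nodes != M:
        raise ValueError("network size does not match n_glomeruli")
    if odor_networks is not None:
        odor_networks = {int(o): net for o, net in odor_networks.items()}
        if sorted(odor_networks) != list(range(O)):
            raise ValueError("odor-specific networks must cover odors "
                             "0..n_odors-1")
        for net in odor_networks.values():
            if net.n_nodes != M:
                raise ValueError("odor network size does not match n_glomeruli")
        truth: object = {"background": network, "odor_specific": odor_networks}
    else:
        truth = network

    weights_on = {}
    for o in range(O):
        w_on = config.on_coupling_gain * network.weights
        if odor_networks is not None:
            w_on = w_on + odor_networks[o].weights
        weights_on[o] = w_on
        radius = max(_radius(network.weights, config),
                     _radius(w_on, config))
        if radius >= 1.0:
            raise GenerationError(
                f"planted VAR for odor {o} is unstable: companion spectral "
                f"radius {radius:.4f} >= 1; reduce coupling_strength, "
                f"self_coupling or on_coupling_gain")

    odor_names = tuple(DEFAULT_ODOR_NAMES[:O]) if O <= len(DEFAULT_ODOR_NAMES) \
        else tuple(f"ODOR{k}" for k in range(O))
    glom_ids = tuple(DEFAULT_GLOMERULUS_IDS[:M]) if M <= len(DEFAULT_GLOMERULUS_IDS) \
        else tuple(str(i) for i in range(M))

    # Odor-specific responsive sets, conserved across subjects (stereotypy).
    responsive = {}
    for o in range(O):
        k = int(rng.integers(config.responsive_min, config.responsive_max + 1))
        responsive[odor_names[o]] = np.sort(
            rng.choice(M, size=min(k, M), replace=False)).tolist()

    # One latency offset per subject, applied to all its trials.
    latencies = rng.normal(0.0, config.latency_jitter_sd, size=S)

    t = np.arange(T) / fs
    onset = config.baseline_length
    offset = onset + config.stimulus_duration
    on_mask = (t >= onset) & (t < offset)

    F = np.empty((S, O, R, M, T))
    for o in range(O):
        A_base = _coeffs_from_weights(network.weights, config)
        A_on = _coeffs_from_weights(weights_on[o], config)
        fast = _simulate_var(A_base, A_on, on_mask, S * R, rng,
                             config.fast_sd).reshape(S, R, M, T)
        resp_idx = responsive[odor_names[o]]
        for s in range(S):
            # trial-to-trial response variability: latency jitter around the
            # subject offset and lognormal amplitude scaling (median 1)
            t0s = onset + latencies[s] + rng.normal(
                0.0, config.trial_latency_sd, size=R)
            amps = config.transient_amplitude * np.exp(rng.normal(
                0.0, config.amplitude_jitter_sd, size=R))
            signal = np.zeros((R, M, T))
            for r in range(R):
                env = _transient_envelope(t, t0s[r], config.tau_rise,
                                          config.tau_decay)
                signal[r, resp_idx] = amps[r] * env
            # Fura-2 convention: calcium rise dims fluorescence.
            F[s, o] = config.baseline_f * (1.0 - signal - fast[s])
        F[:, o] += rng.normal(0.0, config.noise_sd * config.baseline_f,
                              size=(S, R, M, T))

    if np.min(F) <= 0:
        raise GenerationError(
            "generated fluorescence is not strictly positive; reduce "
            "transient_amplitude, fast_sd or noise_sd")

    mask = rng.random((S, M)) >= config.missing_prob
    for s in range(S):
        F[s, :, :, ~mask[s], :] = np.nan

    raw = RawRecording(
        fluorescence=F, mask=mask, sampling_rate=fs,
        stimulus_onset=onset, stimulus_offset=offset,
        glomerulus_ids=glom_ids, odor_names=odor_names,
        responsive=responsive, subject_latencies=latencies)
    return raw, truth
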