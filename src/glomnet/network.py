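"""Connectivity summaries: density, cross-subject edge maps, controls.

Network density is the fraction of FDR-validated directed links among all
ordered glomerulus pairs.  Edge-probability maps average *binarized* link
detections across subjects (a link's probability is the fraction of
subjects showing it, among subjects in which both endpoint glomeruli were
available).  The glomerulus-shuffling control builds artificial subjects
whose channels come from different real subjects, preserving stereotyped
response maps while destroying within-subject co-recording.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .gc_core import ConnectivityResult
from .preprocess import TrialTensor

__all__ = [
    "EdgeProbabilityMap",
    "KruskalResult",
    "density",
    "density_table",
    "edge_probability",
    "kruskal_wallis_density",
    "shuffle_glomeruli",
]


def density(result: ConnectivityResult | np.ndarray,
            m_available: int | None = None) -> float:
    """Fraction of significant directed links among possible ordered pairs."""
    if isinstance(result, ConnectivityResult):
        mask = np.asarray(result.significant, dtype=bool)
    else:
        mask = np.asarray(result, dtype=bool)
    m = m_available if m_available is not None else mask.shape[0]
    if m < 2:
        raise ValueError("density needs at least 2 available glomeruli")
    off = ~np.eye(mask.shape[0], dtype=bool)
    return float(mask[off].sum()) / (m * (m - 1))


def density_table(results: Mapping[tuple, ConnectivityResult]) -> pd.DataFrame:
    """Tabulate density per (subject, odor, window, component) key."""
    rows = []
    for (subject, odor, window, component), res in results.items():
        rows.append({"subject": subject, "odor": odor, "window": window,
                     "component": component, "m_available": len(res.labels),
                     "density": density(res)})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class EdgeProbabilityMap:
    """Per-odor fraction of subjects exhibiting each directed link."""

    probs: np.ndarray               # (M, M) in [0, 1], NaN where untestable
    n_subjects_per_edge: np.ndarray  # (M, M) int, both endpoints available
    labels: tuple
    odor: str | None = None
    window: str | None = None
    component: str | None = None

    def to_dict(self) -> dict:
        probs = [[None if not np.isfinite(v) else float(v) for v in row]
                 for row in self.probs]
        return {"labels": list(self.labels), "probs": probs,
                "n_subjects_per_edge": self.n_subjects_per_edge.astype(int).tolist(),
                "odor": self.odor, "window": self.window,
                "component": self.component}


def edge_probability(results: Mapping[int, ConnectivityResult] |
                     Sequence[ConnectivityResult],
                     labels: Sequence[str],
                     odor: str | None = None, window: str | None = None,
                     component: str | None = None) -> EdgeProbabilityMap:
    """Average binarized link detections across subjects.

    Each subject's significant mask is embedded into the global glomerulus
    order given by ``labels``; an edge's denominator counts only the
    subjects for which both endpoint glomeruli were recorded.
    """
    labels = list(labels)
    M = len(labels)
    counts = np.zeros((M, M))
    avail = np.zeros((M, M), dtype=int)
    items = results.values() if isinstance(results, Mapping) else results
    for res in items:
        try:
            idx = [labels.index(l) for l in res.labels]
        except ValueError as exc:
            raise ValueError(f"subject glomerulus label not in global set: "
                             f"{exc}") from exc
        ix = np.ix_(idx, idx)
        avail[ix] += 1
        counts[ix] += np.asarray(res.significant, dtype=float)
    off = ~np.eye(M, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(avail > 0, counts / np.maximum(avail, 1), np.nan)
    probs[~off] = np.nan
    avail[~off] = 0
    return EdgeProbabilityMap(probs=probs, n_subjects_per_edge=avail,
                              labels=tuple(labels), odor=odor, window=window,
                              component=component)


def shuffle_glomeruli(tensor: TrialTensor,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> TrialTensor:
    """Build artificial subjects by drawing each glomerulus from a random donor.

    Each artificial subject's glomeruli are taken whole (all odors and
    trials) from real subjects, sampled without replacement across donors
    when there are at least as many subjects as glomeruli (falling back to
    with-replacement sampling otherwise, with a warning).  Glomerulus
    identity is preserved, so stereotyped response maps persist, but
    within-subject co-recording - and hence any genuine coupling - is
    destroyed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    S, M = tensor.mask.shape
    if S == 1:
        warnings.warn("glomerulus shuffling with a single subject is the "
                      "identity", RuntimeWarning)
        return dataclasses.replace(tensor, dff=tensor.dff.copy(),
                                   mask=tensor.mask.copy())
    # Latin-style donor assignment: every glomerulus column is a permutation
    # of the subjects (each series is moved, never duplicated or dropped),
    # and each artificial subject's donors are pairwise distinct whenever
    # S >= M (cyclic offsets are then distinct per glomerulus).
    if S >= M:
        offsets = rng.permutation(S)[:M]
    else:
        warnings.warn(f"only {S} subjects for {M} glomeruli; artificial "
                      "subjects reuse donors", RuntimeWarning)
        offsets = rng.integers(0, S, size=M)
    row_perm = rng.permutation(S)
    relabel = rng.permutation(S)
    donors = relabel[(row_perm[:, None] + offsets[None, :]) % S]
    dff = np.empty_like(tensor.dff)
    mask = np.empty_like(tensor.mask)
    for s in range(S):
        for g in range(M):
            dff[s, :, :, g, :] = tensor.dff[donors[s, g], :, :, g, :]
            mask[s, g] = tensor.mask[donors[s, g], g]
    return dataclasses.replace(tensor, dff=dff, mask=mask)


class KruskalResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def kruskal_wallis_density(table: pd.DataFrame,
                           component: str | None = None) -> KruskalResult:
    """Kruskal-Wallis H comparison of density across time windows.

    Observations are the per-(subject x odor) densities, grouped by
    window; the tie-corrected H statistic is referred to chi-square with
    (#windows - 1) degrees of freedom.  Fully tied data degenerate to
    H = 0, p = 1 with a warning.
    """
    if component is not None:
        table = table[table["component"] == component]
    groups = [g["density"].to_numpy(dtype=float)
              for _, g in table.groupby("window", sort=False)]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 windows with >= 1 observation each")
    df = len(groups) - 1
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        warnings.warn("all densities tied; Kruskal-Wallis is degenerate",
                      RuntimeWarning)
        return KruskalResult(0.0, df, 1.0)
    stat, p = _stats.kruskal(*groups)
    return KruskalResult(float(stat), df, float(p))
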