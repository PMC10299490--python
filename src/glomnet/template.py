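"""Best-match-to-template odor identification.

A response map - either edge-centered (the FDR-validated weighted GC
matrix, flattened off-diagonal) or node-centered (per-glomerulus response
amplitudes) - is classified by Pearson-correlating it against per-odor
template maps and awarding a score of 1 to the best-matching odor (split
equally on exact ties).  Templates never include the tested map
(leave-one-out within subjects, leave-one-subject-out across subjects).
Per-odor correct-match probabilities are tested against the 1/6 chance
level with a one-sample Wilcoxon signed-rank test, BH-FDR corrected
across odors.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .gc_core import ConnectivityResult

__all__ = [
    "across_subject_scores",
    "best_match",
    "build_template",
    "edge_map_vector",
    "pearson_pairwise",
    "significance_vs_chance",
    "split_trial_groups",
    "within_subject_scores",
]

TIE_DECIMALS = 12  # correlations equal after this rounding are exact ties

_logger = logging.getLogger(__name__)


def split_trial_groups(n_trials: int = 30, n_groups: int = 6) -> list[list[int]]:
    """Contiguous equal-size trial groups in acquisition order."""
    if n_groups < 1 or n_trials % n_groups != 0:
        raise ValueError(f"{n_trials} trials cannot be split into "
                         f"{n_groups} equal groups")
    size = n_trials // n_groups
    return [list(range(g * size, (g + 1) * size)) for g in range(n_groups)]


def edge_map_vector(result: ConnectivityResult,
                    labels: Sequence[str]) -> np.ndarray:
    """Flattened off-diagonal weighted-GC vector in a global glomerulus order.

    Entries whose endpoint glomeruli were not recorded for this subject
    are NaN; comparisons later use pairwise-complete entries.
    """
    labels = list(labels)
    M = len(labels)
    mat = np.full((M, M), np.nan)
    idx = [labels.index(l) for l in result.labels]
    mat[np.ix_(idx, idx)] = result.weighted
    return mat[~np.eye(M, dtype=bool)]


def pearson_pairwise(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r over entries finite in both vectors; NaN when undefined."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 3:
        return np.nan
    uu, vv = u[ok], v[ok]
    if np.ptp(uu) == 0 or np.ptp(vv) == 0:
        return np.nan
    return float(np.corrcoef(uu, vv)[0, 1])


def best_match(test: np.ndarray,
               templates: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Score 1 split among the template(s) with the highest Pearson r.

    Templates with undefined correlation (zero variance or too few shared
    entries) are excluded from the competition; if none is defined the
    score is split uniformly (degenerate, warned).  Scores always sum to 1.
    """
    if len(templates) < 2:
        raise ValueError("need at least 2 candidate templates")
    r = {odor: pearson_pairwise(test, tpl) for odor, tpl in templates.items()}
    defined = {odor: round(val, TIE_DECIMALS)
               for odor, val in r.items() if np.isfinite(val)}
    scores = {odor: 0.0 for odor in templates}
    if not defined:
        _logger.debug("no template has a defined correlation with the test "
                      "map; splitting the score uniformly")
        for odor in scores:
            scores[odor] = 1.0 / len(scores)
        return scores
    best = max(defined.values())
    winners = [odor for odor, val in defined.items() if val == best]
    for odor in winners:
        scores[odor] = 1.0 / len(winners)
    return scores


def build_template(maps: Mapping, keys: Sequence) -> np.ndarray:
    """Entry-wise NaN-aware mean map over ``maps[k] for k in keys``."""
    stack = np.stack([np.asarray(maps[k], dtype=float) for k in keys])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=0)


def within_subject_scores(maps: Mapping[tuple, np.ndarray]) -> pd.DataFrame:
    """Leave-one-out template matching within each subject.

    ``maps`` is keyed by (subject, odor, replicate) where a replicate is a
    trial-group connectivity map (edge-centered) or a single-trial
    response map (node-centered).  Each map is tested against per-odor
    templates averaged over all maps of that odor except, for the tested
    odor, the tested map itself.  Returns per-(subject, odor) correct-match
    probabilities.
    """
    subjects = sorted({k[0] for k in maps})
    rows = []
    for s in subjects:
        odors = sorted({k[1] for k in maps if k[0] == s})
        if len(odors) < 2:
            warnings.warn(f"subject {s}: fewer than 2 odors, skipped",
                          RuntimeWarning)
            continue
        reps = {o: sorted(k[2] for k in maps if k[0] == s and k[1] == o)
                for o in odors}
        correct = {o: 0.0 for o in odors}
        for o in odors:
            for g in reps[o]:
                templates = {}
                for o2 in odors:
                    keys = [(s, o2, g2) for g2 in reps[o2]
                            if not (o2 == o and g2 == g)]
                    if keys:
                        templates[o2] = build_template(maps, keys)
                scores = best_match(maps[(s, o, g)], templates)
                correct[o] += scores.get(o, 0.0)
        for o in odors:
            rows.append({"subject": s, "odor": o,
                         "probability": correct[o] / len(reps[o]),
                         "n_tests": len(reps[o])})
    return pd.DataFrame(rows)


def across_subject_scores(maps: Mapping[tuple, np.ndarray]) -> pd.DataFrame:
    """Leave-one-subject-out template matching at the population level.

    ``maps`` is keyed by (subject, odor), one trial-averaged map per
    combination.  Each map is tested against per-odor templates averaged
    over all other subjects.
    """
    subjects = sorted({k[0] for k in maps})
    if len(subjects) < 3:
        raise ValueError("across-subject matching needs >= 3 subjects")
    odors = sorted({k[1] for k in maps})
    rows = []
    for s in subjects:
        for o in odors:
            if (s, o) not in maps:
                warnings.warn(f"missing map for subject {s}, odor {o}; "
                              "skipped", RuntimeWarning)
                continue
            templates = {}
            for o2 in odors:
                keys = [(s2, o2) for s2 in subjects
                        if s2 != s and (s2, o2) in maps]
                if keys:
                    templates[o2] = build_template(maps, keys)
            scores = best_match(maps[(s, o)], templates)
            rows.append({"subject": s, "odor": o,
                         "probability": scores.get(o, 0.0), "n_tests": 1})
    return pd.DataFrame(rows)


def significance_vs_chance(scores: pd.DataFrame, chance: float = 1.0 / 6.0,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon signed-rank test of per-subject probabilities against chance.

    One test per odor on the per-subject correct-match probabilities, with
    Benjamini-Hochberg FDR correction across odors.  Returns the signed
    rank statistic W, raw and adjusted p-values, and the significance flag.
    """
    rows = []
    for odor, grp in scores.groupby("odor", sort=True):
        x = grp["probability"].to_numpy(dtype=float)
        d = x - chance
        if np.allclose(d, 0.0):
            w_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = _stats.wilcoxon(d, zero_method="wilcox",
                                      alternative="two-sided")
            w_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"odor": odor, "n": len(x), "W": w_stat, "p_raw": p})
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_raw"].to_numpy(), alpha=alpha,
                                        method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out
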