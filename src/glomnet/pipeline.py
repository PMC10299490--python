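"""End-to-end pipeline: simulate, preprocess, GC, summaries, report.

Stages communicate through files in an output directory, so each can be
rerun independently; ``run_pipeline`` composes them.  Every artifact
embeds the configuration hash and seed for provenance, and a fixed seed
reproduces every artifact deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .gc_core import ConnectivityResult, connectivity
from .network import (density, density_table, edge_probability,
                      kruskal_wallis_density, shuffle_glomeruli)
from .preprocess import (WINDOW_NAMES, decompose, dff_normalize,
                         node_response_map, window_concatenate)
from .synthdata import SimulationConfig, make_network, simulate_dataset
from .template import (across_subject_scores, edge_map_vector,
                       significance_vs_chance, split_trial_groups,
                       within_subject_scores)

__all__ = [
    "AnalysisConfig",
    "PipelineConfig",
    "run_pipeline",
    "stage_density",
    "stage_gc",
    "stage_maps",
    "stage_preprocess",
    "stage_report",
    "stage_shuffle",
    "stage_simulate",
    "stage_template",
]

_STAGE_SEEDS = {"simulate": 0, "shuffle": 1}


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side knobs (significance level, model order, filters...)."""

    alpha: float = 0.05
    order: int | None = None          # None -> information-criterion selection
    max_order: int = 20
    order_criterion: str = "bic"
    low_cut: float = 1.5              # Hz, slow-component low-pass
    high_cut: float = 2.5             # Hz, fast-component high-pass
    filter_order: int = 4
    windows: tuple = WINDOW_NAMES
    components: tuple = ("unfiltered", "slow", "fast")
    mask_seams: bool = False
    n_template_groups: int = 6
    template_windows: tuple = ("ON", "earlyOFF", "OFF6")

    def __post_init__(self) -> None:
        for w in tuple(self.windows) + tuple(self.template_windows):
            if w not in WINDOW_NAMES:
                raise ValueError(f"unknown window {w!r}")
        for c in self.components:
            if c not in ("unfiltered", "slow", "fast"):
                raise ValueError(f"unknown component {c!r}")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    seed: int = 0
    odor_specific_networks: bool = False

    def to_dict(self) -> dict:
        return {"simulation": dataclasses.asdict(self.simulation),
                "analysis": dataclasses.asdict(self.analysis),
                "seed": self.seed,
                "odor_specific_networks": self.odor_specific_networks}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        sim = SimulationConfig(**d.get("simulation", {}))
        ana_d = dict(d.get("analysis", {}))
        for key in ("windows", "components", "template_windows"):
            if key in ana_d:
                ana_d[key] = tuple(ana_d[key])
        ana = AnalysisConfig(**ana_d)
        return cls(simulation=sim, analysis=ana, seed=int(d.get("seed", 0)),
                   odor_specific_networks=bool(
                       d.get("odor_specific_networks", False)))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence([config.seed, _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.hash, "seed": config.seed}


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# glomnet config_hash={config.hash} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Generate the synthetic recording and write raw data + ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation,
                              seed=_stage_seed(config, "simulate"))
    odor_networks = None
    if config.odor_specific_networks:
        rng = np.random.default_rng(sim.seed + 1)
        odor_networks = {
            o: make_network(sim.n_glomeruli, sim.coupling_density,
                            sim.coupling_strength, rng=rng)
            for o in range(sim.n_odors)}
    raw, truth = simulate_dataset(sim, odor_networks=odor_networks)
    _io.write_raw_hdf5(raw, outdir / "raw.h5")
    _io.write_networks_json(truth, raw.glomerulus_ids, outdir / "truth.json")
    _io.dump_json(_provenance(config), outdir / "simulate.meta.json")


def stage_preprocess(config: PipelineConfig, outdir: Path) -> None:
    """-dF/F normalize and (if configured) slow/fast decompose."""
    outdir = Path(outdir)
    raw = _io.read_raw_hdf5(outdir / "raw.h5")
    tensor = dff_normalize(raw, baseline_length=config.simulation.baseline_length)
    tensors = {"unfiltered": tensor}
    if {"slow", "fast"} & set(config.analysis.components):
        slow, fast = decompose(tensor, low_cut=config.analysis.low_cut,
                               high_cut=config.analysis.high_cut,
                               order=config.analysis.filter_order)
        tensors["slow"], tensors["fast"] = slow, fast
    _io.write_tensors_hdf5(tensors, outdir / "tensors.h5")
    _io.dump_json(_provenance(config), outdir / "preprocess.meta.json")


def _run_connectivity(series, ana: AnalysisConfig) -> ConnectivityResult:
    return connectivity(series, order=ana.order, max_order=ana.max_order,
                        criterion=ana.order_criterion, alpha=ana.alpha,
                        mask_seams=ana.mask_seams)


def _iter_subject_odor(tensor):
    S = tensor.dff.shape[0]
    for s in range(S):
        if tensor.mask[s].sum() < 2:
            warnings.warn(f"subject {s}: fewer than 2 available glomeruli; "
                          "skipped", RuntimeWarning)
            continue
        for odor in tensor.odor_names:
            yield s, odor


def stage_gc(config: PipelineConfig, outdir: Path) -> None:
    """Connectivity per (subject, odor, window, component)."""
    outdir = Path(outdir)
    tensors = _io.read_tensors_hdf5(outdir / "tensors.h5")
    ana = config.analysis
    results = {}
    for component in ana.components:
        tensor = tensors[component]
        for window in ana.windows:
            for s, odor in _iter_subject_odor(tensor):
                key = f"{s}|{odor}|{window}|{component}"
                try:
                    series = window_concatenate(tensor, window, s, odor)
                    results[key] = _run_connectivity(series, ana).to_dict()
                except Exception as exc:
                    raise RuntimeError(
                        f"stage gc failed at {key}: {exc}") from exc
    _io.dump_json({"meta": _provenance(config), "results": results},
                  outdir / "connectivity.json")


def _load_results(outdir: Path) -> dict[tuple, ConnectivityResult]:
    payload = _io.load_json(Path(outdir) / "connectivity.json")
    out = {}
    for key, d in payload["results"].items():
        s, odor, window, component = key.split("|")
        out[(int(s), odor, window, component)] = ConnectivityResult.from_dict(d)
    return out


def stage_density(config: PipelineConfig, outdir: Path) -> None:
    """Density table over all connectivity results."""
    outdir = Path(outdir)
    table = density_table(_load_results(outdir))
    _write_csv(table, outdir / "density.csv", config)


def stage_maps(config: PipelineConfig, outdir: Path) -> None:
    """Cross-subject edge-probability maps per (odor, window, component)."""
    outdir = Path(outdir)
    results = _load_results(outdir)
    tensors = _io.read_tensors_hdf5(outdir / "tensors.h5")
    labels = tensors["unfiltered"].glomerulus_ids
    maps = {}
    keys = sorted({(odor, window, component)
                   for (_, odor, window, component) in results})
    for odor, window, component in keys:
        subject_results = {s: res for (s, o, w, c), res in results.items()
                           if (o, w, c) == (odor, window, component)}
        emap = edge_probability(subject_results, labels, odor=odor,
                                window=window, component=component)
        maps[f"{odor}|{window}|{component}"] = emap.to_dict()
    _io.dump_json({"meta": _provenance(config), "maps": maps},
                  outdir / "edge_maps.json")


def stage_template(config: PipelineConfig, outdir: Path) -> None:
    """Within- and across-subject best-match-to-template tests.

    Edge-centered maps use the FDR-validated weighted GC matrices from
    5-trial-group fits (within) or the all-trial fits (across); node maps
    use per-trial (within) or trial-averaged (across) response amplitudes.
    Both run on the unfiltered component, for the configured windows.
    """
    outdir = Path(outdir)
    tensors = _io.read_tensors_hdf5(outdir / "tensors.h5")
    tensor = tensors["unfiltered"]
    ana = config.analysis
    labels = tensor.glomerulus_ids
    results = _load_results(outdir)
    groups = split_trial_groups(tensor.n_trials, ana.n_template_groups)
    score_rows = []
    stats = {}
    for window in ana.template_windows:
        # --- edge-centered, within subject: one map per 5-trial group
        edge_group_maps = {}
        for s, odor in _iter_subject_odor(tensor):
            for g, trials in enumerate(groups):
                series = window_concatenate(tensor, window, s, odor,
                                            trials=trials)
                res = _run_connectivity(series, ana)
                edge_group_maps[(s, odor, g)] = edge_map_vector(res, labels)
        edge_within = within_subject_scores(edge_group_maps)
        # --- edge-centered, across subjects: all-trial map per subject/odor
        edge_subject_maps = {
            (s, odor): edge_map_vector(results[(s, odor, window,
                                                "unfiltered")], labels)
            for s, odor in _iter_subject_odor(tensor)
            if (s, odor, window, "unfiltered") in results}
        edge_across = across_subject_scores(edge_subject_maps)
        # --- node-centered, within subject: one map per trial
        node_trial_maps = {
            (s, odor, r): node_response_map(tensor, window, s, odor,
                                            trials=[r])
            for s, odor in _iter_subject_odor(tensor)
            for r in range(tensor.n_trials)}
        node_within = within_subject_scores(node_trial_maps)
        # --- node-centered, across subjects: trial-averaged map
        node_subject_maps = {
            (s, odor): node_response_map(tensor, window, s, odor)
            for s, odor in _iter_subject_odor(tensor)}
        node_across = across_subject_scores(node_subject_maps)

        for kind, scope, df in (("edge", "within", edge_within),
                                ("edge", "across", edge_across),
                                ("node", "within", node_within),
                                ("node", "across", node_across)):
            df = df.copy()
            df["window"] = window
            df["kind"] = kind
            df["scope"] = scope
            score_rows.append(df)
            stats[f"{kind}|{scope}|{window}"] = significance_vs_chance(
                df, chance=1.0 / config.simulation.n_odors,
                alpha=ana.alpha).to_dict(orient="records")
    scores = pd.concat(score_rows, ignore_index=True)
    _write_csv(scores, outdir / "template_scores.csv", config)
    _io.dump_json({"meta": _provenance(config), "stats": stats},
                  outdir / "template_stats.json")


def stage_shuffle(config: PipelineConfig, outdir: Path) -> None:
    """Glomerulus-shuffling control: density on artificial subjects."""
    outdir = Path(outdir)
    tensors = _io.read_tensors_hdf5(outdir / "tensors.h5")
    shuffled = shuffle_glomeruli(tensors["unfiltered"],
                                 seed=_stage_seed(config, "shuffle"))
    ana = config.analysis
    results = {}
    for window in ana.windows:
        for s, odor in _iter_subject_odor(shuffled):
            series = window_concatenate(shuffled, window, s, odor)
            results[(s, odor, window, "unfiltered")] = \
                _run_connectivity(series, ana)
    _write_csv(density_table(results), outdir / "shuffle_density.csv", config)


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    """Summary report: densities, Kruskal-Wallis, shuffle and template tests."""
    outdir = Path(outdir)
    table = _read_csv(outdir / "density.csv")
    report: dict = {"meta": _provenance(config)}
    report["mean_density"] = {
        component: {window: float(grp["density"].mean())
                    for window, grp in comp_grp.groupby("window")}
        for component, comp_grp in table.groupby("component")}
    report["kruskal_wallis"] = {}
    for component in table["component"].unique():
        kw = kruskal_wallis_density(table, component=component)
        report["kruskal_wallis"][component] = {
            "H": kw.statistic, "df": kw.df, "p": kw.pvalue}
    shuffle_path = outdir / "shuffle_density.csv"
    if shuffle_path.exists():
        shuf = _read_csv(shuffle_path)
        report["shuffle_control"] = {
            "mean_density_unshuffled": float(
                table[table["component"] == "unfiltered"]["density"].mean()),
            "mean_density_shuffled": float(shuf["density"].mean())}
    stats_path = outdir / "template_stats.json"
    if stats_path.exists():
        payload = _io.load_json(stats_path)
        report["template_tests"] = payload["stats"]
        scores = _read_csv(outdir / "template_scores.csv")
        report["template_mean_probability"] = {
            f"{kind}|{scope}|{window}": float(grp["probability"].mean())
            for (kind, scope, window), grp in
            scores.groupby(["kind", "scope", "window"])}
    _io.dump_json(report, outdir / "report.json")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; returns the loaded final report."""
    outdir = Path(outdir)
    for stage in (stage_simulate, stage_preprocess, stage_gc, stage_density,
                  stage_maps, stage_template, stage_shuffle, stage_report):
        try:
            stage(config, outdir)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage.__name__} failed: {exc}") from exc
    return _io.load_json(outdir / "report.json")
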