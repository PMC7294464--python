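"""End-to-end orchestration on synthetic data.

``run_all`` executes generate -> preprocess -> cluster -> TANOVA ->
mass-univariate -> behavior on a synthetic scenario, writes tidy TSVs and a
deterministic JSON report, and appends a planted-vs-recovered comparison
block (onsets, selected K, contrast differences) since the generator's
ground truth is known.  Wall-times go to a separate timings sidecar so the
main report is byte-for-byte reproducible under a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import behavior, cluster, massuni, preprocess, synth, tanova
from .data import ERPSet

__all__ = ["RunConfig", "run_all", "validate_config", "derive_seed"]

log = logging.getLogger("chunkdyn")

_STAGE_NAMES = ("synth_eeg", "synth_rt", "preprocess", "cluster", "tanova",
                "massuni", "behavior")

_DEFAULTS = {
    "seed": 0,
    "n_subjects": 16,
    "n_trials": 80,
    "noise_sd_uv": 8.0,
    "blink_prob": 0.15,
    "stages": list(_STAGE_NAMES),
    "reject_threshold_uv": 50.0,
    "tanova_window_ms": 10.0,
    "tanova_shuffles": 1000,
    "precluster_p": 0.1,
    "corrected_alpha": 0.05,
    "massuni_window_ms": 20.0,
    "fdr_level": 0.05,
    "analysis_range_ms": [0.0, 600.0],
    "behavior_n_subjects": 21,
    "behavior_n_per_type": 80,
}


@dataclass
class RunConfig:
    params: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __getitem__(self, key: str):
        return self.params[key]


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config, fill defaults, reject unknown keys."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update(overrides)
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = dict(_DEFAULTS)
    params.update(raw)
    if params["tanova_shuffles"] < 1:
        raise ValueError("tanova_shuffles must be >= 1")
    if params["reject_threshold_uv"] <= 0:
        raise ValueError("reject_threshold_uv must be positive")
    if not 0 < params["precluster_p"] < 1:
        raise ValueError("precluster_p must be in (0, 1)")
    bad = set(params["stages"]) - set(_STAGE_NAMES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    return RunConfig(params=params)


def derive_seed(global_seed: int, stage: str) -> int:
    """Counter-based fan-out of the global seed to one per stage."""
    idx = _STAGE_NAMES.index(stage)
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _subject_erps(epoch_sets, cfg) -> tuple[list[ERPSet], list[float]]:
    pcfg = preprocess.PreprocConfig(
        reject_threshold_uv=cfg["reject_threshold_uv"])
    erps, fractions = [], []
    for es in epoch_sets:
        kept, rlog = preprocess.preprocess_epochs(es, pcfg)
        erps.append(preprocess.average_erp(kept))
        fractions.append(rlog.fraction_dropped)
    return erps, fractions


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run all enabled stages in dependency order; returns the report dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    seed = cfg["seed"]
    report: dict = {"config": cfg.params, "stages": {}}
    timings: dict[str, float] = {}

    def _stage(name):
        return name in stages

    erps: list[ERPSet] | None = None
    truth = None

    if _stage("synth_eeg"):
        t0 = time.perf_counter()
        spec = synth.default_scenario(seed=derive_seed(seed, "synth_eeg"),
                                      n_subjects=cfg["n_subjects"],
                                      n_trials=cfg["n_trials"],
                                      noise_sd_uv=cfg["noise_sd_uv"],
                                      blink_prob=cfg["blink_prob"])
        epoch_sets, truth = synth.simulate_eeg(spec)
        report["stages"]["synth_eeg"] = {
            "seed": derive_seed(seed, "synth_eeg"),
            "n_subjects": spec.n_subjects, "n_trials": spec.n_trials,
            "conditions": list(spec.conditions),
        }
        timings["synth_eeg"] = time.perf_counter() - t0
        log.info("synth_eeg: %d subjects x %d trials x %d conditions",
                 spec.n_subjects, spec.n_trials, len(spec.conditions))

        if _stage("preprocess"):
            t0 = time.perf_counter()
            erps, fractions = _subject_erps(epoch_sets, cfg)
            report["stages"]["preprocess"] = {
                "threshold_uv": cfg["reject_threshold_uv"],
                "mean_rejected_fraction": round(float(np.mean(fractions)), 4),
            }
            timings["preprocess"] = time.perf_counter() - t0

    if erps is not None and _stage("cluster"):
        t0 = time.perf_counter()
        grand = ERPSet(
            montage=erps[0].montage,
            erps={c: np.mean([e.erps[c] for e in erps], axis=0)
                  for c in erps[0].conditions},
            n_trials_used={c: len(erps) for c in erps[0].conditions},
            time_ms=erps[0].time_ms, subject_id="grand")
        m = cluster.build_samples(grand)
        bmask = cluster.baseline_mask_from_meta(m)
        k_star, sol = cluster.select_k(m, bmask,
                                       seed=derive_seed(seed, "cluster"),
                                       restarts=10)
        sol = cluster.rank_clusters(sol, bmask)
        table = cluster.solution_table(m, sol)
        table.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        report["stages"]["cluster"] = {
            "k_star": int(k_star),
            "baseline_cluster_id": int(sol.baseline_cluster_id),
        }
        timings["cluster"] = time.perf_counter() - t0

    lo, hi = cfg["analysis_range_ms"]
    tcfg = tanova.TanovaConfig(window_ms=cfg["tanova_window_ms"],
                               n_shuffles=cfg["tanova_shuffles"],
                               precluster_p=cfg["precluster_p"],
                               corrected_alpha=cfg["corrected_alpha"],
                               seed=derive_seed(seed, "tanova"))
    onsets: dict[str, float | None] = {}
    if erps is not None and _stage("tanova"):
        t0 = time.perf_counter()
        rows = []
        comparisons = {
            "global_lex": (("Gw", ["GwLw", "GwLn"]), ("Gn", ["GnLw", "GnLn"])),
            "local_lex": (("Lw", ["GwLw", "GnLw"]), ("Ln", ["GwLn", "GnLn"])),
        }
        for name, ((la, ma), (lb, mb)) in comparisons.items():
            pooled = massuni.pool_conditions(erps, {la: ma, lb: mb})
            res = tanova.cluster_correct(
                tanova.tanova_series(pooled, la, lb, (lo, hi), tcfg), tcfg)
            onsets[name] = res.earliest_significant_onset_ms()
            for w in range(res.n_windows):
                cl = next((c for c in res.clusters
                           if c.start_ms <= res.window_starts_ms[w] < c.end_ms),
                          None)
                rows.append({
                    "comparison": name,
                    "window_start": res.window_starts_ms[w],
                    "window_end": res.window_starts_ms[w] + res.window_ms,
                    "d_obs": res.d_obs[w], "p": res.p[w],
                    "cluster_p": cl.p_corrected if cl else "",
                    "significant": bool(cl.significant) if cl else False,
                })
        import pandas as pd
        pd.DataFrame(rows).to_csv(out_dir / "tanova.tsv", sep="\t",
                                  index=False)
        report["stages"]["tanova"] = {
            "onsets_ms": {k: (None if v is None else float(v))
                          for k, v in onsets.items()},
            "window_ms": tcfg.window_ms, "n_shuffles": tcfg.n_shuffles,
        }
        timings["tanova"] = time.perf_counter() - t0

    if erps is not None and _stage("massuni"):
        t0 = time.perf_counter()
        pooled = massuni.pool_conditions(
            erps, {"Gw": ["GwLw", "GwLn"], "Gn": ["GnLw", "GnLn"],
                   "Lw": ["GwLw", "GnLw"], "Ln": ["GwLn", "GnLn"]})
        means, starts = massuni.window_means(
            pooled, ["Gw", "Gn", "Lw", "Ln"],
            window_ms=cfg["massuni_window_ms"], time_range_ms=(lo, hi))
        mu_onsets = {}
        for name, (a, b) in {"global_lex": ("Gw", "Gn"),
                             "local_lex": ("Lw", "Ln")}.items():
            res = massuni.paired_t_map(
                means, a, b, starts, window_ms=cfg["massuni_window_ms"],
                channel_names=erps[0].montage.channel_names)
            res = massuni.fdr_correct(res, level=cfg["fdr_level"])
            rep = massuni.detect_onset(res, min_consecutive_windows=3)
            mu_onsets[name] = rep.onset_ms
        report["stages"]["massuni"] = {
            "onsets_ms": mu_onsets, "window_ms": cfg["massuni_window_ms"],
            "fdr_level": cfg["fdr_level"],
        }
        timings["massuni"] = time.perf_counter() - t0

    if _stage("synth_rt") and _stage("behavior"):
        t0 = time.perf_counter()
        design = synth.build_design(cfg["behavior_n_per_type"],
                                    seed=derive_seed(seed, "synth_rt"))
        cell_means, accuracy = synth.default_rt_cells()
        trials = synth.simulate_rt(design, cell_means, accuracy,
                                   seed=derive_seed(seed, "synth_rt"),
                                   n_subjects=cfg["behavior_n_subjects"])
        if truth is not None:
            truth.rt_cell_means = cell_means
        trials.df.to_csv(out_dir / "trials.tsv", sep="\t", index=False)
        kept, _rep = behavior.filter_trials(trials)
        anova = behavior.rm_anova_2x2x2(kept)
        contrasts = behavior.planned_contrasts(kept)
        import pandas as pd
        pd.DataFrame([asdict(e) for e in anova.effects.values()]).to_csv(
            out_dir / "anova.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(c) for c in contrasts]).to_csv(
            out_dir / "contrasts.tsv", sep="\t", index=False)
        report["stages"]["behavior"] = {
            "anova": {name: {"F": round(e.F, 4), "df": [e.df1, e.df2],
                             "p": round(e.p, 6)}
                      for name, e in anova.effects.items()},
            "contrasts": {c.name: {"diff_ms": round(c.mean_diff_ms, 2),
                                   "t": round(c.t, 4), "df": c.df,
                                   "p": round(c.p, 6)}
                          for c in contrasts},
        }
        timings["behavior"] = time.perf_counter() - t0

    # planted-vs-recovered comparison block for synthetic runs
    if truth is not None:
        comparison: dict = {}
        if onsets:
            comparison["tanova_onsets"] = {
                "global_lex": {"planted_ms": truth.onset_of("GwLw",
                                                            "global_lex"),
                               "recovered_ms": onsets.get("global_lex")},
                "local_lex": {"planted_ms": truth.onset_of("GwLw",
                                                           "local_lex"),
                              "recovered_ms": onsets.get("local_lex")},
            }
        if truth.rt_cell_means:
            planted = {
                "GnLw-GwLw (local task)":
                    truth.rt_cell_means[("n", "w", "local")][0]
                    - truth.rt_cell_means[("w", "w", "local")][0],
                "GwLn-GnLn (local task)":
                    truth.rt_cell_means[("w", "n", "local")][0]
                    - truth.rt_cell_means[("n", "n", "local")][0],
                "GnLw-GnLn (global task)":
                    truth.rt_cell_means[("n", "w", "global")][0]
                    - truth.rt_cell_means[("n", "n", "global")][0],
            }
            comparison["planted_rt_differences_ms"] = planted
        report["ground_truth_comparison"] = comparison

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float))
    (out_dir / "timings.json").write_text(
        json.dumps({k: round(v, 3) for k, v in timings.items()}, indent=1))
    return report
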