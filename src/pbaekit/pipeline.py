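"""End-to-end orchestration: simulate → cluster → PLS → diffusion → efficacy.

One entry point, :func:`run_full_analysis`, runs every analysis stage from a
:class:`RunConfig`, writes all result files into the output directory and
returns a reproducibility manifest (config, per-stage seeds, SHA-256 of every
file written, key outputs).  The run is deterministic under a fixed master
seed: each stage draws randomness from a sub-seed derived by a documented
counter scheme, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import diffusion as _diffusion
from . import efficacy as _efficacy
from . import pls as _pls
from .library import standardize, write_descriptor_table
from .simulate import (
    LibrarySimConfig,
    generate_library,
    simulate_diffusion_trace,
    simulate_gag_timecourses,
    simulate_uptake_experiment,
)

log = logging.getLogger("pbaekit.pipeline")

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]

_STAGES = ("simulate", "cluster", "pls", "diffusion", "uptake", "gag")

# GAG treatment arms and daily exponential rates: controls gain up to ~70%
# GAG over 8 days, IL-1α degrades >50%, continuous DEX arms gain ~50%,
# polymer alone holds tissue at baseline.
DEFAULT_GAG_EFFECTS = {
    "control": float(np.log(1.7) / 8.0),
    "IL1a": float(np.log(0.5) / 8.0),
    "IL1a_DEXP_cont": float(np.log(1.5) / 8.0),
    "IL1a_A5e2DEX_cont": float(np.log(1.5) / 8.0),
    "IL1a_A5e2": 0.0,
}


@dataclass
class RunConfig:
    """Full-analysis configuration (all stages simulated by default)."""

    seed: int = 0
    outdir: str = "pbae_run"
    library: LibrarySimConfig = field(default_factory=LibrarySimConfig)
    max_components: int = 10
    variance_threshold: float = 0.80
    alpha: float = 0.05
    scale_descriptors: bool = True
    log_responses: bool = True
    uptake_cv: float = 0.1
    uptake_n_reps: int = 3
    uptake_times: tuple[int, ...] = (1, 5, 10)
    diffusion_noise_sd: float = 0.005
    diffusion_thickness_mm: float = 0.4
    diffusion_n_polymers: int = 6
    diffusion_n_reps: int = 3
    gag_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAG_EFFECTS))
    gag_n_samples: int = 6
    gag_noise_sd: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        lib = doc.pop("library", {})
        cfg = cls(**{k: v for k, v in doc.items() if k != "library"})
        cfg.library = LibrarySimConfig(**lib)
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: (master·10007 + stage index) mod 2³¹."""
    return (master_seed * 10007 + _STAGES.index(stage)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage, write results under ``config.outdir``, return manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    key_outputs: dict = {}

    def save_csv(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)
        return p

    # --- simulate ------------------------------------------------------
    lib_cfg = LibrarySimConfig(
        **{**asdict(config.library), "noise_seed": stage_seed(config.seed, "simulate")}
    )
    table, responses, truth = generate_library(lib_cfg)
    write_descriptor_table(table, out / "descriptors.csv")
    written.append(out / "descriptors.csv")
    responses.to_csv(out / "responses.csv")
    written.append(out / "responses.csv")
    log.info("simulate: %d polymers x %d descriptors", table.n_polymers, table.n_descriptors)

    # --- cluster -------------------------------------------------------
    std = standardize(table)
    z = std.z_values if config.scale_descriptors else table.values
    dm = _cluster.manhattan_distance_matrix(z, table.polymer_ids)
    tree = _cluster.complete_linkage(dm)
    save_csv(_cluster.tree_to_merge_table(tree), "cluster_merges.csv")
    (out / "cluster_tree.nwk").write_text(_cluster.tree_to_newick(tree) + "\n")
    written.append(out / "cluster_tree.nwk")
    log.info("cluster: %d leaves, max height %.3f", tree.n_leaves, tree.heights[-1])

    # --- pls -----------------------------------------------------------
    X = std.to_frame()
    Y = np.log(responses) if config.log_responses else responses
    H = min(config.max_components, X.shape[0] - 1, X.shape[1])
    model = _pls.fit_pls(X, Y, H)
    scree = _pls.rmse_scree(model)
    selection = _pls.select_components(
        scree, model.r2x_cumulative, config.variance_threshold
    )
    save_csv(_pls.variance_tables(model), "pls_variance.csv")
    save_csv(
        pd.DataFrame({"h": scree.h, "rmse": scree.rmse}), "pls_scree.csv"
    )
    save_csv(_pls.loading_map(model), "pls_loadings.csv")
    save_csv(
        _pls.variable_response_correlations(model, selection.h_selected),
        "pls_correlations.csv",
    )
    (out / "pls_model.json").write_text(model.to_json())
    written.append(out / "pls_model.json")
    (out / "pls_selection.json").write_text(
        json.dumps(
            {
                "h_selected": selection.h_selected,
                "h_elbow": selection.h_elbow,
                "h_inflection_x": selection.h_inflection_x,
                "h_variance": selection.h_variance,
                "threshold": selection.threshold,
                "rationale": selection.rationale,
            },
            indent=1,
        )
    )
    written.append(out / "pls_selection.json")
    key_outputs["h_selected"] = selection.h_selected
    key_outputs["y_r2_cum_at_h"] = float(model.r2y_cumulative[selection.h_selected - 1])
    log.info("pls: h_selected=%d (%s)", selection.h_selected, selection.rationale)

    # --- diffusion -----------------------------------------------------
    dseed = stage_seed(config.seed, "diffusion")
    rng = np.random.default_rng(dseed)
    times = np.arange(0.0, 101.0, 2.0)
    fit_rows = []
    for i in range(config.diffusion_n_polymers):
        D_true = float(np.exp(rng.uniform(np.log(1e-3), np.log(1e-2))))
        pid = table.polymer_ids[i]
        fits = []
        for rep in range(1, config.diffusion_n_reps + 1):
            tr = simulate_diffusion_trace(
                D_true, config.diffusion_thickness_mm, times,
                noise_sd=config.diffusion_noise_sd,
                seed=int(rng.integers(2**31)), polymer=pid, replicate=rep,
            )
            fits.append(_diffusion.fit_breakthrough(tr))
        pooled = _diffusion.pool_replicates(fits)
        df = _diffusion.fits_to_frame(fits)
        df["D_true"] = D_true
        df["D_pooled_mean"] = pooled.mean_D
        fit_rows.append(df)
    diffusion_df = pd.concat(fit_rows, ignore_index=True)
    save_csv(diffusion_df, "diffusion_fits.csv")
    key_outputs["mean_D_mm2_per_min"] = float(diffusion_df["D_mm2_per_min"].mean())
    log.info("diffusion: %d fits, mean D=%.3e", len(diffusion_df), key_outputs["mean_D_mm2_per_min"])

    # --- uptake --------------------------------------------------------
    useed = stage_seed(config.seed, "uptake")
    ratio_map = {}
    for i, pid in enumerate(table.polymer_ids):
        for k, endcap in enumerate(("e1", "e2")):
            for t in config.uptake_times:
                ratio_map[(str(pid), endcap, t)] = float(truth.true_uptake_ratio[i, k])
    measurements = simulate_uptake_experiment(
        ratio_map, n_reps=config.uptake_n_reps, cv=config.uptake_cv, seed=useed
    )
    save_csv(measurements, "uptake_measurements.csv")
    comparisons = _efficacy.uptake_ratios_from_table(measurements, alpha=config.alpha)
    flagged = _efficacy.flag_significant_uptake(comparisons, alpha=config.alpha)
    save_csv(flagged, "uptake_comparisons.csv")
    key_outputs["n_significant_uptake"] = int(flagged["significant"].sum())
    key_outputs["max_uptake_ratio"] = float(flagged["ratio"].max())
    log.info(
        "uptake: %d comparisons, %d significant",
        len(flagged), key_outputs["n_significant_uptake"],
    )

    # --- gag -----------------------------------------------------------
    gseed = stage_seed(config.seed, "gag")
    tc = simulate_gag_timecourses(
        config.gag_effects, n_samples=config.gag_n_samples,
        noise_sd=config.gag_noise_sd, seed=gseed,
    )
    save_csv(tc, "gag_timecourses.csv")
    variation = _efficacy.gag_cumulative_variation(tc)
    save_csv(_efficacy.gag_group_summary(variation, alpha=config.alpha), "gag_summary.csv")
    anova_rows, tukey_frames = [], []
    for day in sorted(variation["day"].unique()):
        if day == 0:
            continue
        day_groups = {
            g: sub["gag_variation_pct"].to_numpy()
            for g, sub in variation[variation["day"] == day].groupby("group")
        }
        a = _efficacy.one_way_anova(day_groups)
        anova_rows.append(
            {"day": day, "F": a.F, "df_between": a.df_between,
             "df_within": a.df_within, "p": a.p}
        )
        tk = _efficacy.tukey_hsd(day_groups, alpha=config.alpha).comparisons
        tk.insert(0, "day", day)
        tukey_frames.append(tk)
    save_csv(pd.DataFrame(anova_rows), "gag_anova.csv")
    save_csv(pd.concat(tukey_frames, ignore_index=True), "gag_tukey.csv")
    key_outputs["gag_anova_p_day8"] = float(
        [r["p"] for r in anova_rows if r["day"] == 8][0]
    )
    log.info("gag: ANOVA day-8 p=%.3g", key_outputs["gag_anova_p_day8"])

    # --- manifest ------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "config": _jsonable(asdict(config)),
        "files": {p.name: _sha256(p) for p in sorted(written)},
        "key_outputs": key_outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
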