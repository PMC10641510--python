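"""End-to-end orchestration: simulate -> preprocess -> FC -> graphs -> stats.

Each stage writes its artifacts under the output directory and a provenance
manifest (config hash, per-stage seeds, package version) ties the outputs
to the run. Stages consume the previous stage's on-disk outputs, so a run
can be resumed or partially re-executed.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .connectivity import fisher_transform, regress_age, residual_matrix, subject_fc
from .cohortstats import (
    clinical_correlations,
    edgewise_permutation_test,
    moderation_regression,
    simple_slopes,
    univariate_group_tests,
    zscore_subgroup_maps,
)
from .core import default_montage
from .io import read_fc_matrix, write_fc_matrix, write_hemo, write_snirf
from .netmetrics import cohort_network_analysis, sparsity_range
from .preprocess import preprocess_recording
from .simcohort import generate_cohort

log = logging.getLogger("nirsnet")

__all__ = ["run_pipeline", "render_reports"]


def _write_manifest(out: Path, cfg: PipelineConfig, stages: list[str]) -> None:
    manifest = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": {s: cfg.seed_for(s) for s in stages},
        "stages_completed": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full chain on a synthetic cohort; returns key result frames."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    results: dict = {}

    # --- simulate -----------------------------------------------------
    log.info("simulating cohort (%d patients, %d controls)", cfg.n_patients, cfg.n_controls)
    subjects, cohort, gt = generate_cohort(
        cfg.n_patients,
        cfg.n_controls,
        cfg.sim,
        cfg.effects,
        seed=cfg.seed_for("simulate"),
        signals=True,
    )
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    raw_dir = out / "raw"
    raw_dir.mkdir(exist_ok=True)
    for per_cond in subjects:
        for cond, (rec, ann, sgt) in per_cond.items():
            stem = raw_dir / f"{rec.subject['id']}_{cond}"
            write_snirf(rec, stem.with_suffix(".snirf"))
            ann.to_tsv(stem.with_suffix(".annotations.tsv"))
            sgt.to_json(stem.with_suffix(".groundtruth.json"))
    stages.append("simulate")
    _write_manifest(out, cfg, stages)

    # --- preprocess ---------------------------------------------------
    hemo_dir = out / "hemo"
    hemo_dir.mkdir(exist_ok=True)
    hemo_all = []
    qc_rows = []
    for per_cond in subjects:
        per_cond_hemo = {}
        for cond, (rec, ann, _) in per_cond.items():
            series, report = preprocess_recording(
                rec, ann, cfg.preprocess, seed=cfg.seed_for("preprocess")
            )
            write_hemo(series, hemo_dir / f"{rec.subject['id']}_{cond}.h5")
            qc = report.to_dict()
            qc.update(subject=rec.subject["id"], condition=cond)
            qc_rows.append(qc)
            per_cond_hemo[cond] = series
        hemo_all.append(per_cond_hemo)
    (out / "qc_report.json").write_text(json.dumps(qc_rows, indent=2))
    stages.append("preprocess")
    _write_manifest(out, cfg, stages)

    # --- connectivity -------------------------------------------------
    fc_dir = out / "fc"
    fc_dir.mkdir(exist_ok=True)
    montage = default_montage(cfg.sim.n_channels)
    ages = cohort["age"].to_numpy()
    b_matrices: dict[str, list] = {}
    for cond in ("rest", "task"):
        z_list = []
        for i, per_cond_hemo in enumerate(hemo_all):
            a = subject_fc(
                per_cond_hemo[cond],
                n_windows=cfg.n_bootstrap_windows,
                win_s=cfg.window_s,
                seed=cfg.seed_for(f"bootstrap/{cond}/{i}"),
                condition=cond,
            )
            z_list.append(fisher_transform(a))
        _, b_list = regress_age(z_list, ages)
        b_matrices[cond] = b_list
        for b in b_list:
            write_fc_matrix(b, fc_dir / f"{b.subject}_{cond}_B.tsv")
    residuals = [
        residual_matrix(bt, br) for bt, br in zip(b_matrices["task"], b_matrices["rest"])
    ]
    for r in residuals:
        write_fc_matrix(r, fc_dir / f"{r.subject}_residual_R.tsv")
    results["residuals"] = residuals
    stages.append("connect")
    _write_manifest(out, cfg, stages)

    # --- network metrics ----------------------------------------------
    groups = cohort["group"].tolist()
    names = cohort["subject"].tolist()
    try:
        validated, range_report = sparsity_range(
            b_matrices["task"],
            cfg.grid,
            n_random=cfg.n_random_graphs,
            seed=cfg.seed_for("nullmodel"),
            hemisphere=montage.hemisphere,
            groups=groups,
        )
    except ValueError as err:
        log.warning("sparsity validation failed (%s); using the full grid", err)
        validated, range_report = cfg.grid, pd.DataFrame()
    profiles, summaries = cohort_network_analysis(
        b_matrices["task"],
        groups,
        names,
        montage=montage,
        grid=validated,
        n_random=cfg.n_random_graphs,
        seed=cfg.seed_for("nullmodel"),
    )
    profiles.to_csv(out / "metric_profiles.tsv", sep="\t", index=False)
    summaries.to_csv(out / "auc_summaries.tsv", sep="\t", index=False)
    range_report.to_csv(out / "sparsity_report.tsv", sep="\t", index=False)
    results["profiles"] = profiles
    results["summaries"] = summaries
    results["validated_grid"] = validated
    stages.append("graph")
    _write_manifest(out, cfg, stages)

    # --- statistics ---------------------------------------------------
    pat = [r for r, g in zip(residuals, groups) if g == "epilepsy"]
    ctl = [r for r, g in zip(residuals, groups) if g == "control"]
    edge_stats = edgewise_permutation_test(
        pat, ctl, n_perm=cfg.n_permutations, seed=cfg.seed_for("permutation")
    )
    edge_stats.edge_table(montage.channels).to_csv(
        out / "edge_significance.tsv", sep="\t", index=False
    )
    ctl_stack = np.stack([r.values for r in ctl])
    mu, sd = ctl_stack.mean(axis=0), ctl_stack.std(axis=0, ddof=1)
    z_tables = []
    pat_table = cohort[cohort["group"] == "epilepsy"]
    for sub_col, sub_val in (
        ("epilepsy_type", "FLE"),
        ("epilepsy_type", "TLE"),
        ("lateralization", "left"),
        ("lateralization", "right"),
    ):
        members = [
            r
            for r, (_, row) in zip(pat, pat_table.iterrows())
            if row[sub_col] == sub_val
        ]
        if members:
            zmap = zscore_subgroup_maps(members, mu, sd, subgroup=sub_val)
            z_tables.append(zmap.edge_table(montage.channels))
    if z_tables:
        pd.concat(z_tables).to_csv(out / "zscore_edges.tsv", sep="\t", index=False)

    group_tests = univariate_group_tests(
        cohort, ["age", "ses_income", "ses_parent_edu", "estimated_iq", "sex"]
    )
    group_tests.to_csv(out / "group_tests.tsv", sep="\t", index=False)

    moderation_rows, slope_rows = [], []
    wide = summaries.pivot(index="subject", columns="metric", values="auc")
    wide = wide.loc[cohort["subject"]]
    for metric in wide.columns:
        y = wide[metric].to_numpy()
        if not np.all(np.isfinite(y)):
            continue
        res = moderation_regression(y, cohort["estimated_iq"].to_numpy(), cohort["group"].to_numpy())
        moderation_rows.append(
            {
                "metric": metric,
                "beta_iq": res.params["x"],
                "beta_group": res.params["group"],
                "beta_interaction": res.params["x:group"],
                "p_interaction": res.pvalues["x:group"],
                "adj_r2": res.adj_r2,
                "f": res.f_stat,
            }
        )
        ss = simple_slopes(res)
        ss.insert(0, "metric", metric)
        slope_rows.append(ss)
    pd.DataFrame(moderation_rows).to_csv(out / "moderation.tsv", sep="\t", index=False)
    if slope_rows:
        pd.concat(slope_rows).to_csv(out / "simple_slopes.tsv", sep="\t", index=False)

    clin = clinical_correlations(summaries, cohort)
    clin.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)
    results["edge_stats"] = edge_stats
    results["cohort"] = cohort
    stages.append("stats")
    _write_manifest(out, cfg, stages)
    return results


def render_reports(out_dir: str | Path) -> list[Path]:
    """Figures from a completed run: FC heatmap, metric curves, AUC bars.

    Missing inputs are skipped with a warning; re-rendering is idempotent.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    written = []

    residual_paths = sorted(out.glob("fc/*_residual_R.tsv"))
    if residual_paths:
        mats = [read_fc_matrix(p).values for p in residual_paths]
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(np.mean(mats, axis=0), cmap="RdBu_r", vmin=-0.3, vmax=0.3)
        ax.set_title("mean residual FC (task - rest)")
        fig.colorbar(im, ax=ax, label="z difference")
        p = fig_dir / "residual_fc_heatmap.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("no residual matrices found; skipping FC heatmap")

    prof_path = out / "metric_profiles.tsv"
    if prof_path.exists():
        prof = pd.read_csv(prof_path, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        for metric in ("gamma", "lambda", "sigma"):
            sub = prof[prof.metric == metric].groupby("tau")["normalized"].mean()
            ax.plot(sub.index, sub.values, label=metric)
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("sparsity threshold tau")
        ax.set_ylabel("normalized metric")
        ax.legend()
        p = fig_dir / "metric_profiles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("no metric profiles found; skipping curves")

    auc_path = out / "auc_summaries.tsv"
    if auc_path.exists():
        summ = pd.read_csv(auc_path, sep="\t")
        pivot = summ.groupby(["metric", "group"])["auc"].mean().unstack()
        fig, ax = plt.subplots(figsize=(7, 4))
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("AUC of normalized metric")
        fig.tight_layout()
        p = fig_dir / "auc_summary.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        warnings.warn("no AUC summaries found; skipping bars")
    return written
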