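"""End-to-end pipeline: simulate -> assemble -> fit -> summarize -> classify.

Each stage writes its artifacts plus a ``meta.json`` provenance record
(config hash, master seed, package version) and is exactly reproducible
from the configuration alone.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .data_model import (assemble_analysis_table, filter_cohort, follow_up_summary,
                         link_exposures, write_scaling_meta)
from .diagnostics import RHAT_GATE, convergence_summary, posterior_predictive_check
from .effects import (classify_participants, diagnosis_breakdown, forest_plot_data,
                      population_summary, sensitivity_profile)
from .exceptions import DataError
from .probit import build_design
from .sampler import PosteriorDraws, run_sampler
from .synthetic import SyntheticTruth, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

REQUIRED_FILES = ["baselines.csv", "reports.csv", "pings.csv",
                  "stations.csv", "observations.csv"]


def _write_meta(cfg: PipelineConfig, outdir: Path) -> None:
    meta = {"config_sha256": cfg.sha256(), "seed": cfg.seed, "version": __version__}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def simulate(cfg: PipelineConfig, outdir) -> Path:
    """Write the five synthetic CSVs, truth.json and the echoed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(cfg.generator, seed=cfg.seed)
    write_dataset(data, outdir)
    (outdir / "config.yaml").write_text(cfg.to_yaml())
    _write_meta(cfg, outdir)
    return outdir


def load_tables(data_dir) -> dict:
    data_dir = Path(data_dir)
    tables = {}
    for fname in REQUIRED_FILES:
        path = data_dir / fname
        if not path.exists():
            raise DataError(f"missing input file: {fname}")
        tables[fname.removesuffix(".csv")] = pd.read_csv(path)
    return tables


def fit(data_dir, cfg: PipelineConfig, outdir) -> Path:
    """Filter the cohort, link exposures, assemble the table, run the sampler."""
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = load_tables(data_dir)

    included = filter_cohort(tables["baselines"], tables["reports"])
    if len(included) == 0:
        raise DataError("cohort is empty after applying inclusion criteria")
    logger.info("cohort: %d of %d participants included",
                len(included), len(tables["baselines"]))

    baselines = tables["baselines"][tables["baselines"]["participant_id"].isin(included)]
    reports = tables["reports"][tables["reports"]["participant_id"].isin(included)]
    pings = tables["pings"][tables["pings"]["participant_id"].isin(included)]

    exposures = link_exposures(pings, tables["stations"], tables["observations"])
    table, scaling = assemble_analysis_table(baselines, reports, exposures)
    if table.empty:
        raise DataError("no participant-days with both a pain report and an exposure")

    table.to_csv(outdir / "analysis_table.csv", index=False)
    write_scaling_meta(scaling, outdir / "scaling_meta.txt")
    follow_up_summary(reports).to_csv(outdir / "followup_summary.csv", index=False)
    baselines.to_csv(outdir / "baselines.csv", index=False)
    if (data_dir / "truth.json").exists():
        shutil.copy(data_dir / "truth.json", outdir / "truth.json")

    design = build_design(table, cfg.model)
    draws = run_sampler(table, cfg.model, cfg.sampler, design=design)
    draws.save(outdir / "draws.npz")

    conv = convergence_summary(draws)
    conv.to_csv(outdir / "convergence.csv", index=False)
    worst = conv["rhat"].max()
    if worst >= RHAT_GATE:
        logger.warning("max population R-hat %.3f >= %.2f: summaries may be "
                       "unreliable", worst, RHAT_GATE)

    rng = np.random.default_rng(cfg.seed + 2)
    ppc = posterior_predictive_check(draws, design, rng, n_rep=cfg.report.n_ppc)
    pd.DataFrame({"category": np.arange(1, 6), "observed": ppc["observed"],
                  "band_lower": ppc["interval"][0],
                  "band_upper": ppc["interval"][1]}).to_csv(
        outdir / "ppc_frequencies.csv", index=False)
    if cfg.report.make_figures:
        from .plots import ppc_plot
        ppc_plot(ppc, outdir / "ppc.svg")

    _write_meta(cfg, outdir)
    return outdir


def report(fit_dir, cfg: PipelineConfig, outdir) -> Path:
    """Coefficient table, forest-plot data, sensitivity profile, diagnosis
    breakdown, and (when truth is available) a recovery/coverage table."""
    fit_dir, outdir = Path(fit_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        draws = PosteriorDraws.load(fit_dir / "draws.npz")
    except Exception as exc:
        raise DataError(f"cannot load draws container: {exc}") from exc
    baselines = pd.read_csv(fit_dir / "baselines.csv")

    summary = population_summary(draws, cri_level=cfg.report.cri_level,
                                 mem_threshold=cfg.report.mem_threshold)
    summary.to_csv(outdir / "population_summary.csv", index=False)

    labels = classify_participants(draws, cri_level=cfg.report.cri_level)
    labels.to_csv(outdir / "labels.csv", index=False)

    profile = sensitivity_profile(labels)
    profile["proportions"].to_csv(outdir / "sensitivity_proportions.csv")
    hist = profile["multi_parameter_histogram"]
    pd.DataFrame({"n_parameters": hist.index, "n_participants": hist.to_numpy()}
                 ).to_csv(outdir / "multi_parameter_histogram.csv", index=False)

    breakdown = diagnosis_breakdown(labels, baselines)
    breakdown.to_csv(outdir / "breakdown.csv", index=False)

    forest_frames = []
    for col in draws.weather_cols:
        forest = forest_plot_data(labels, summary, col)
        rows = forest["rows"].assign(reference=forest["reference"])
        forest_frames.append(rows)
        if cfg.report.make_figures:
            from .plots import forest_plot
            forest_plot(forest, outdir / f"forest_{col}.svg")
    pd.concat(forest_frames, ignore_index=True).to_csv(
        outdir / "forest_data.csv", index=False)
    if cfg.report.make_figures and not breakdown.empty:
        from .plots import breakdown_bars
        breakdown_bars(breakdown, outdir / "breakdown.svg")

    truth_path = fit_dir / "truth.json"
    if truth_path.exists():
        truth = SyntheticTruth.from_json(truth_path.read_text())
        recovery_table(draws, truth, cfg.report.cri_level).to_csv(
            outdir / "recovery.csv", index=False)

    _write_meta(cfg, outdir)
    return outdir


def recovery_table(draws: PosteriorDraws, truth: SyntheticTruth,
                   cri_level: float = 0.95) -> pd.DataFrame:
    """Truth vs posterior for the population weather effects and the
    random-effect standard deviations, with interval-coverage flags."""
    lo_q, hi_q = (1 - cri_level) / 2, 1 - (1 - cri_level) / 2
    rows = []
    g = draws.pooled("gamma")
    for k, col in enumerate(draws.weather_cols):
        lo, hi = np.quantile(g[:, k], [lo_q, hi_q])
        rows.append({"parameter": col, "truth": float(truth.gamma[k]),
                     "posterior_mean": float(g[:, k].mean()),
                     "cri_lower": float(lo), "cri_upper": float(hi),
                     "covered": bool(lo <= truth.gamma[k] <= hi)})
    if draws.Sigma is not None:
        S = draws.pooled("Sigma")
        names = ["intercept"] + list(draws.weather_cols)
        for q, name in enumerate(names):
            sd_draws = np.sqrt(S[:, q, q])
            lo, hi = np.quantile(sd_draws, [lo_q, hi_q])
            t = float(np.sqrt(truth.Sigma[q][q]))
            rows.append({"parameter": f"sd({name})", "truth": t,
                         "posterior_mean": float(sd_draws.mean()),
                         "cri_lower": float(lo), "cri_upper": float(hi),
                         "covered": bool(lo <= t <= hi)})
    return pd.DataFrame(rows)


def run_all(cfg: PipelineConfig, outdir) -> Path:
    """simulate -> fit -> report under one output directory."""
    outdir = Path(outdir)
    data_dir = simulate(cfg, outdir / "data")
    fit_dir = fit(data_dir, cfg, outdir / "fit")
    report(fit_dir, cfg, outdir / "report")
    return outdir
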