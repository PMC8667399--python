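"""Stage orchestration: simulate -> call-loy -> score -> associate -> concordance.

Each stage reads and writes plain-text tables (TSV / BED-like / JSON) in a
run directory, carries the master seed and a configuration hash in its
manifest, and is individually re-runnable.  ``run_analysis`` executes the
analysis stages in order and assembles a JSON run report with the headline
numbers: LOY prevalence, per-SD and quintile odds ratios, the two AUCs with
the DeLong comparison, and the array/WGS concordance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from loyprs import array_loy, prs, stats, wgs
from loyprs.simulate import SimulationConfig, SyntheticDataset, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "cmd_simulate",
    "read_dataset",
    "run_analysis",
    "write_dataset",
]

ALL_STAGES = ("call-loy", "score", "associate", "concordance")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    threshold: object = "reflected_null"  # or a fixed LRR value such as -0.06
    percentile: float = 0.005
    response_factor: float = 0.46
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    r2_min: float = 0.30
    missing_policy: str = "mean_impute"
    wgs_agg: str = "mean"
    stages: tuple = ALL_STAGES

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.threshold, str) and cfg.threshold != "reflected_null":
            raise ConfigError("threshold must be 'reflected_null' or a number")
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _prepare_outdir(outdir: Path, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(f"output directory {outdir} is not empty; use --force to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def write_dataset(ds: SyntheticDataset, outdir: Path, force: bool = False) -> dict:
    """Write a synthetic dataset as TSV/BED text files plus a manifest."""
    outdir = _prepare_outdir(outdir, force)
    ds.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    ds.dosages.to_csv(outdir / "dosages.tsv", sep="\t")
    ds.dosage_meta.to_csv(outdir / "dosage_meta.tsv", sep="\t", index=False)
    ds.score_file.to_csv(outdir / "score.tsv", sep="\t", index=False)
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    ds.lrr.to_csv(outdir / "lrr_matrix.tsv", sep="\t")
    ds.probe_annotation.to_csv(outdir / "probes.bed", sep="\t", index=False, header=False)
    ds.wgs_depth.to_csv(outdir / "wgs_depth.tsv", sep="\t", index=False)
    manifest = {
        "seed": ds.config.seed,
        "config": dataclasses.asdict(ds.config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(ds.config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def cmd_simulate(config: RunConfig, outdir: Path, force: bool = False) -> dict:
    """Generate and write the full synthetic dataset for ``config.seed``."""
    try:
        sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation parameters: {exc}") from exc
    ds = simulate_dataset(sim_cfg)
    return write_dataset(ds, outdir, force=force)


def read_dataset(datadir: Path) -> SyntheticDataset:
    """Load a dataset previously written by :func:`write_dataset`."""
    datadir = Path(datadir)
    manifest = json.loads((datadir / "manifest.json").read_text())
    cfg = SimulationConfig(**manifest["config"])
    covariates = pd.read_csv(datadir / "covariates.tsv", sep="\t")
    dosages = pd.read_csv(datadir / "dosages.tsv", sep="\t", index_col="sample_id")
    dosage_meta = pd.read_csv(datadir / "dosage_meta.tsv", sep="\t")
    score_file = pd.read_csv(datadir / "score.tsv", sep="\t")
    truth = pd.read_csv(datadir / "truth.tsv", sep="\t")
    lrr = pd.read_csv(datadir / "lrr_matrix.tsv", sep="\t", index_col="probe_id")
    annotation = pd.read_csv(
        datadir / "probes.bed",
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "probe_id", "is_msy"],
    )
    depth = pd.read_csv(datadir / "wgs_depth.tsv", sep="\t")
    return SyntheticDataset(
        config=cfg,
        covariates=covariates,
        dosages=dosages,
        dosage_meta=dosage_meta,
        score_file=score_file,
        truth=truth,
        lrr=lrr,
        probe_annotation=annotation,
        wgs_depth=depth,
    )


def _covariate_design(covariates: pd.DataFrame, with_age: bool = True) -> pd.DataFrame:
    """Current-vs-never/former coding for smoking and alcohol, plus age."""
    X = pd.DataFrame(index=covariates.index)
    if with_age:
        X["age"] = covariates["age"].to_numpy(dtype=float)
    X["smoking_current"] = (covariates["smoking"] == "current").astype(float).to_numpy()
    X["alcohol_current"] = (covariates["alcohol"] == "current").astype(float).to_numpy()
    return X


def _stage_call_loy(ds: SyntheticDataset, config: RunConfig, outdir: Path) -> pd.DataFrame:
    mlrry = array_loy.compute_mlrry(ds.lrr, ds.probe_annotation)
    if config.threshold == "reflected_null":
        thr = array_loy.estimate_threshold(mlrry["mlrry"], config.percentile)
    else:
        thr = array_loy.ThresholdEstimate(
            mode=max(0.0, float(config.threshold)),
            threshold=float(config.threshold),
            percentile=config.percentile,
            method="fixed",
        )
    calls = array_loy.call_loy(mlrry, thr, config.response_factor)
    calls = calls.assign(conversion_c=config.response_factor)
    calls.to_csv(outdir / "loy_calls.tsv", sep="\t", index=False)
    (outdir / "threshold.json").write_text(
        json.dumps(dataclasses.asdict(thr), indent=2, sort_keys=True)
    )
    prev = array_loy.prevalence_by_age(calls, ds.covariates)
    prev.to_csv(outdir / "prevalence_by_age.tsv", sep="\t", index=False)
    return calls


def _stage_score(ds: SyntheticDataset, config: RunConfig, outdir: Path) -> pd.DataFrame:
    scorer = prs.PRSScorer(
        score_variants=ds.score_file,
        call_rate_min=config.call_rate_min,
        hwe_p_min=config.hwe_p_min,
        r2_min=config.r2_min,
        missing_policy=config.missing_policy,
    )
    scorer.fit(ds.dosages, dosage_meta=ds.dosage_meta)
    table = scorer.transform(ds.dosages)
    table.to_csv(outdir / "prs.tsv", sep="\t", index=False)
    scorer.meta_.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    (outdir / "qc_summary.json").write_text(
        json.dumps({**scorer.qc_report_, **scorer.alignment_report_}, indent=2, sort_keys=True)
    )
    return table


def _stage_associate(
    ds: SyntheticDataset, config: RunConfig, outdir: Path, calls: pd.DataFrame, prs_table: pd.DataFrame
) -> dict:
    merged = (
        calls.merge(prs_table, on="sample_id")
        .merge(ds.covariates, on="sample_id")
        .dropna(subset=["mlrry", "z_score"])
    )
    merged = merged[merged["is_loy"].notna()].reset_index(drop=True)
    y = merged["is_loy"].astype(float).to_numpy()

    table1 = stats.baseline_table(merged, y)
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)

    X2 = _covariate_design(merged)
    X2.insert(0, "prs_z", merged["z_score"].to_numpy(dtype=float))
    fit2 = stats.fit_logistic(y, X2)
    fit2.table.to_csv(outdir / "table2.tsv", sep="\t")

    X3 = stats.risk_group_design(merged["risk_group"])
    X3 = pd.concat([X3, _covariate_design(merged)], axis=1)
    fit3 = stats.fit_logistic(y, X3)
    fit3.table.to_csv(outdir / "table3.tsv", sep="\t")

    # continuous (mLRRY) counterpart of the binary models
    fit_lin = stats.fit_linear(merged["mlrry"].to_numpy(dtype=float), X2)
    fit_lin.table.to_csv(outdir / "table_linear.tsv", sep="\t")

    ancova = stats.ancova_prs(merged["z_score"].to_numpy(dtype=float), y, _covariate_design(merged))

    strata = stats.age_stratified_association(merged, merged["risk_group"], y)
    strata_rows = []
    for label, res in strata.items():
        if isinstance(res, stats.AssociationResult):
            for term, row in res.table.iterrows():
                strata_rows.append({"age_bin": label, "term": term, **row.to_dict()})
        else:
            strata_rows.append({"age_bin": label, "term": "unestimable", **res})
    pd.DataFrame(strata_rows).to_csv(outdir / "age_stratified.tsv", sep="\t", index=False)

    base_fit = stats.fit_logistic(y, _covariate_design(merged))
    full_fit = fit2
    pred_base = _predict_proba(base_fit, _covariate_design(merged))
    pred_full = _predict_proba(full_fit, X2)
    roc_base = stats.roc_auc(pred_base, y)
    roc_full = stats.roc_auc(pred_full, y)
    dl = stats.delong_test(pred_full, pred_base, y)
    roc_report = {
        "auc_base": roc_base.auc,
        "auc_base_ci": [roc_base.ci_low, roc_base.ci_high],
        "auc_full": roc_full.auc,
        "auc_full_ci": [roc_full.ci_low, roc_full.ci_high],
        "delong_z": dl.statistic,
        "delong_p": dl.pvalue,
        "n": int(len(y)),
    }
    (outdir / "roc_report.json").write_text(json.dumps(roc_report, indent=2, sort_keys=True))

    return {
        "n_analyzed": int(len(y)),
        "loy_prevalence_pct": float(100.0 * y.mean()),
        "per_sd_or": float(fit2.table.loc["prs_z", "odds_ratio"]),
        "per_sd_or_ci": [
            float(fit2.table.loc["prs_z", "or_ci_low"]),
            float(fit2.table.loc["prs_z", "or_ci_high"]),
        ],
        "quintile_middle_or": float(fit3.table.loc["prs_middle", "odds_ratio"]),
        "quintile_high_or": float(fit3.table.loc["prs_high", "odds_ratio"]),
        "ancova_p": ancova.pvalue,
        "roc": roc_report,
    }


def _predict_proba(fit: stats.AssociationResult, X: pd.DataFrame) -> np.ndarray:
    """In-sample predicted probabilities from a fitted logistic model."""
    import statsmodels.api as sm
    from scipy.special import expit

    Xc = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
    coef = fit.table["coef"].reindex(Xc.columns).to_numpy()
    return expit(Xc.to_numpy() @ coef)


def _stage_concordance(ds: SyntheticDataset, config: RunConfig, outdir: Path, calls: pd.DataFrame) -> dict:
    wgs_est = wgs.depth_log_ratio(ds.wgs_depth, agg=config.wgs_agg)
    wgs_est.to_csv(outdir / "wgs_loy.tsv", sep="\t", index=False)
    array_frac = calls.set_index("sample_id")["fraction_pct"]
    wgs_frac = wgs_est.set_index("sample_id")["fraction_pct"]
    result = wgs.concordance(array_frac.loc[array_frac.index.intersection(wgs_frac.index)], wgs_frac)
    payload = {"pearson_r": result.r, "n": result.n, "n_excluded": result.n_excluded}
    (outdir / "concordance.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def run_analysis(datadir: Path, outdir: Path, config: RunConfig, force: bool = False) -> dict:
    """Execute the enabled analysis stages on a dataset directory.

    Returns the run report (also written as ``run_report.json``).  A stage
    failure raises :class:`StageError` naming the stage; outputs written so
    far are marked invalid in the report.
    """
    outdir = _prepare_outdir(outdir, force)
    ds = read_dataset(datadir)
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "counts": {"n_samples": int(len(ds.covariates)), "n_variants": int(ds.dosages.shape[1])},
    }
    calls = prs_table = None
    stage = None
    try:
        if "call-loy" in config.stages:
            stage = "call-loy"
            calls = _stage_call_loy(ds, config, outdir)
            report["counts"]["n_scored"] = int(calls["mlrry"].notna().sum())
        if "score" in config.stages:
            stage = "score"
            prs_table = _stage_score(ds, config, outdir)
            report["counts"]["n_variants_pass_qc"] = int(
                json.loads((outdir / "qc_summary.json").read_text())["n_pass"]
            )
        if "associate" in config.stages:
            stage = "associate"
            if calls is None or prs_table is None:
                raise StageError("associate requires the call-loy and score stages")
            report["association"] = _stage_associate(ds, config, outdir, calls, prs_table)
        if "concordance" in config.stages:
            stage = "concordance"
            if calls is None:
                raise StageError("concordance requires the call-loy stage")
            report["concordance"] = _stage_concordance(ds, config, outdir, calls)
    except StageError:
        raise
    except Exception as exc:
        report["invalid"] = True
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise StageError(f"stage '{stage}' failed: {exc}") from exc
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
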