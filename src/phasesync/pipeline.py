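"""End-to-end orchestration: simulate/load a cohort, compute phase metrics,
run group statistics, mediation models and connectome PCA, and write a
reproducible results bundle.

A run is fully determined by its :class:`RunConfig` (serialized into the
manifest together with a config hash, the root seed and the methodological
choices in force), so two runs with equal manifests produce byte-identical
result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .mediation import bootstrap_mediation
from .phase import BoldTimeSeries, bandpass, instantaneous_phase, network_metrics
from .stats import fdr_bh, group_ttest, normalize_fibers, partial_correlation, pc1

logger = logging.getLogger(__name__)

#: Methodological choices recorded in every run manifest.
DECISIONS_IN_FORCE = {
    "metastability_sd_denominator": "L-1 (sample SD)",
    "phase_convention": "four-quadrant angle of the analytic signal, demeaned input",
    "bandpass_filter": "second-order Butterworth, zero-phase (filtfilt)",
    "two_sample_test": "Welch (unequal variance) on residualized metrics",
    "bootstrap_variant": "bias-corrected (BC) percentile",
    "pc_sign": "sum of loadings positive",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    timeseries_dir: str
    parcellation: str
    phenotype: str
    out_dir: str
    tr: float = 2.0
    band: tuple[float, float] | None = (0.01, 0.1)
    trim: int = 0
    covariates: tuple[str, ...] = ("age", "gender", "handedness", "education", "fd", "tiv")
    score_column: str = "score"
    group_column: str = "group"
    fdr_q: float = 0.05
    n_boot: int = 2000
    seed: int = 0
    connectivity: str | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.band is not None:
            self.band = tuple(float(b) for b in self.band)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariates" in raw and isinstance(raw["covariates"], str):
            raw["covariates"] = tuple(s for s in raw["covariates"].split(",") if s)
        if raw.get("band") in ("none", "None", False):
            raw["band"] = None
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subject_files(config: RunConfig) -> dict[str, Path]:
    directory = Path(config.timeseries_dir)
    return {p.stem: p for p in sorted(directory.glob("*.tsv"))}


def validate_inputs(config: RunConfig) -> list[dict]:
    """Check input files for shape, finiteness and coverage problems.

    Returns a machine-readable list of issues; an empty list means the
    bundle is clean.  This is a reporting operation: it never raises for
    data problems, only collects them.
    """
    issues: list[dict] = []

    directory = Path(config.timeseries_dir)
    if not directory.is_dir():
        return [{"stage": "inputs", "issue": f"timeseries directory missing: {directory}"}]
    files = _subject_files(config)
    if not files:
        issues.append({"stage": "inputs", "issue": f"no .tsv time-series files in {directory}"})

    try:
        pheno = psio.read_phenotype(config.phenotype)
    except Exception as exc:  # noqa: BLE001 - reporting operation
        return issues + [{"stage": "phenotype", "issue": str(exc)}]
    try:
        parcellation = psio.read_parcellation(config.parcellation)
    except Exception as exc:  # noqa: BLE001
        return issues + [{"stage": "parcellation", "issue": str(exc)}]

    for sid in pheno["subject_id"]:
        if sid not in files:
            issues.append({"stage": "timeseries", "subject": sid, "issue": "time-series file missing"})

    shapes = set()
    for sid, path in files.items():
        raw = pd.read_csv(path, sep="\t", index_col="parcel_id")
        values = raw.to_numpy(dtype=float)
        shapes.add(values.shape)
        if not np.isfinite(values).all():
            rows = np.flatnonzero(~np.isfinite(values).all(axis=1))
            regions = [str(raw.index[r]) for r in rows[:5]]
            issues.append(
                {
                    "stage": "timeseries",
                    "subject": sid,
                    "issue": f"non-finite values in region(s): {', '.join(regions)}",
                }
            )
            continue
        mapped = sum(parcellation.network_of(str(r)) is not None for r in raw.index)
        if mapped == 0:
            issues.append(
                {"stage": "parcellation", "subject": sid, "issue": "no parcel overlaps the parcellation"}
            )
    if len(shapes) > 1:
        issues.append({"stage": "timeseries", "issue": f"inconsistent matrix shapes: {sorted(shapes)}"})

    missing_cols = [
        c
        for c in (config.group_column, config.score_column, *config.covariates)
        if c not in pheno.columns
    ]
    if missing_cols:
        issues.append({"stage": "phenotype", "issue": f"missing column(s): {', '.join(missing_cols)}"})
    elif pheno[list(config.covariates)].isna().any().any():
        issues.append({"stage": "phenotype", "issue": "NaN in covariate column(s)"})

    return issues


def compute_metrics(config: RunConfig) -> pd.DataFrame:
    """Per-subject global and per-network synchronization/metastability."""
    parcellation = psio.read_parcellation(config.parcellation)
    files = _subject_files(config)
    if not files:
        raise FileNotFoundError(f"no time-series files in {config.timeseries_dir}")
    records = []
    for sid, path in files.items():
        try:
            ts = psio.read_timeseries(path, tr=config.tr)
            if config.band is not None:
                ts = bandpass(ts, *config.band)
            phases = instantaneous_phase(ts)
            for metric in network_metrics(phases, parcellation, trim=config.trim):
                records.append(
                    {
                        "subject_id": sid,
                        "scope_label": metric.scope_label,
                        "synchronization": metric.synchronization,
                        "metastability": metric.metastability,
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'compute' failed for subject {sid}: {exc}") from exc
    return pd.DataFrame.from_records(records)


def compare_groups(
    metrics: pd.DataFrame,
    pheno: pd.DataFrame,
    config: RunConfig,
    value_column: str,
) -> pd.DataFrame:
    """Welch t-tests per scope on residualized metrics, FDR within the scope family."""
    merged = metrics.merge(pheno, on="subject_id", validate="many_to_one")
    rows = []
    for scope, sub in merged.groupby("scope_label", sort=False):
        cov = sub[list(config.covariates)] if config.covariates else None
        t, p, df = group_ttest(sub[value_column], sub[config.group_column], cov)
        g0 = sub.loc[sub[config.group_column] == 0, value_column].mean()
        g1 = sub.loc[sub[config.group_column] == 1, value_column].mean()
        rows.append(
            {
                "scope_label": scope,
                "metric": value_column,
                "mean_group0": g0,
                "mean_group1": g1,
                "t": t,
                "p": p,
                "df": df,
            }
        )
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(out["p"], q=config.fdr_q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


def correlate_scores(
    metrics: pd.DataFrame,
    pheno: pd.DataFrame,
    config: RunConfig,
    group: int = 1,
) -> pd.DataFrame:
    """Partial correlations of each metric with the score, within one group."""
    merged = metrics.merge(pheno, on="subject_id", validate="many_to_one")
    merged = merged[merged[config.group_column] == group]
    rows = []
    for scope, sub in merged.groupby("scope_label", sort=False):
        cov = sub[list(config.covariates)] if config.covariates else None
        for metric_name in ("synchronization", "metastability"):
            r, p = partial_correlation(sub[metric_name], sub[config.score_column], cov)
            rows.append({"scope_label": scope, "metric": metric_name, "r": r, "p": p})
    out = pd.DataFrame(rows)
    for metric_name, sub in out.groupby("metric"):
        reject, p_adj = fdr_bh(sub["p"], q=config.fdr_q)
        out.loc[sub.index, "p_fdr"] = p_adj
        out.loc[sub.index, "significant"] = reject
    return out


def run_end_to_end(config: RunConfig) -> dict:
    """Execute every stage and write the results bundle to ``config.out_dir``.

    Stages: per-subject metrics -> group comparisons (FDR per metric over
    scopes) -> metric-score partial correlations -> mediation models
    (group -> global metric -> score) -> optional connectivity PCA with
    PC1-metric correlations.  Returns a dict of the in-memory results and
    writes CSV/JSON files plus ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pheno = psio.read_phenotype(config.phenotype)

    metrics = compute_metrics(config)
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    comparisons = pd.concat(
        [
            compare_groups(metrics, pheno, config, "synchronization"),
            compare_groups(metrics, pheno, config, "metastability"),
        ],
        ignore_index=True,
    )
    comparisons.to_csv(out_dir / "group_comparison.csv", index=False)

    correlations = correlate_scores(metrics, pheno, config)
    correlations.to_csv(out_dir / "correlations.csv", index=False)

    glob = metrics[metrics["scope_label"] == "global"].merge(
        pheno, on="subject_id", validate="one_to_one"
    )
    cov = glob[list(config.covariates)] if config.covariates else None
    mediation_results = {}
    for mediator in ("synchronization", "metastability"):
        res = bootstrap_mediation(
            glob[config.group_column],
            glob[mediator],
            glob[config.score_column],
            cov,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        mediation_results[mediator] = {
            "estimates": res.estimates,
            "ci": {k: list(v) for k, v in res.ci.items()},
            "p_values": res.p_values,
            "level": res.level,
            "n_boot": res.n_boot,
            "n_redraws": res.n_redraws,
        }
    with open(out_dir / "mediation.json", "w") as fh:
        json.dump(mediation_results, fh, indent=2, sort_keys=True)

    pca_result = None
    if config.connectivity:
        conn = psio.read_connectivity(config.connectivity)
        conn = normalize_fibers(conn)
        pc = pc1(conn)
        pc_df = pd.DataFrame({"subject_id": conn.subject_ids, "pc1": pc.scores})
        merged = pc_df.merge(glob, on="subject_id", validate="one_to_one")
        pc_rows = []
        for metric_name in ("synchronization", "metastability"):
            r, p = partial_correlation(
                merged["pc1"],
                merged[metric_name],
                merged[list(config.covariates)] if config.covariates else None,
            )
            pc_rows.append({"metric": metric_name, "r": r, "p": p})
        pc_df.to_csv(out_dir / "pc1_scores.csv", index=False)
        pca_result = {
            "variance_explained": pc.variance_explained,
            "correlations": pc_rows,
        }
        with open(out_dir / "pca.json", "w") as fh:
            json.dump(pca_result, fh, indent=2, sort_keys=True)

    from . import __version__

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_subjects": int(pheno.shape[0]),
        "decisions": DECISIONS_IN_FORCE,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "metrics": metrics,
        "comparisons": comparisons,
        "correlations": correlations,
        "mediation": mediation_results,
        "pca": pca_result,
        "manifest": manifest,
    }
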