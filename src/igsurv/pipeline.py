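"""End-to-end analysis orchestration.

``run_full_analysis`` ties the stages together: load and validate the input
tables, normalize expression if needed, filter mutation calls and assign the
twelve subgroups, compute isotype metrics, run the median-split survival
screen (log-rank + univariate Cox, Bonferroni-adjusted, with an optional
covariate-adjusted Cox fit per cell), compute repertoire clonality, the
IgG1 V-J usage signature, and the burden correlation, and write a
deterministic TSV/JSON report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort as cio
from . import isotypes, repertoire, survival

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger(__name__)

DEFAULT_METRICS = [
    "IGH", "CD19", "IGHG4",
    "IGHG1_over_IGH", "IGHG4_over_IGH", "IgA_over_IGH", "IGH_over_MS4A1",
]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage of the analysis failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    expression_path: str
    clinical_path: str
    mutations_path: str
    clonotype_dir: str | None = None
    output_dir: str = "igsurv_out"
    expression_units: str = "TPM"
    metrics: list = field(default_factory=lambda: list(DEFAULT_METRICS))
    subgroups: list = field(default_factory=lambda: ["ALL"] + list(cio.SUBGROUPS))
    median_scope: str = "subgroup"          # or "cohort"
    min_reads: int = 500
    n_downsample: int = 500
    clonality_replicates: int = 10
    seed: int = 0
    bonferroni_m: int = 12
    adjusted_cox: bool = True
    signature_isotype: str = "IgG1"
    signature_subgroup: str = "ALL"
    signature_components: int = 5
    clonality_isotypes: list = field(default_factory=lambda: ["IgG1", "IgA"])

    def digest(self) -> str:
        fields = asdict(self)
        fields.pop("output_dir", None)  # destination does not change the analysis
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


@_stage("load")
def _load_inputs(config: AnalysisConfig):
    expression = cio.read_expression(config.expression_path, units=config.expression_units)
    if expression.units == "FPKM":
        expression = cio.fpkm_to_tpm(expression)
    patients = cio.read_clinical(config.clinical_path)
    calls = cio.read_mutations(config.mutations_path)
    missing = [s for s in patients["patient_id"] if s not in expression.values.columns]
    if missing:
        raise ValueError(f"patients without expression columns: {missing[:5]}...")
    return expression, patients, calls


@_stage("subgroups")
def _subgroups(config, patients, calls, expression) -> pd.DataFrame:
    retained = cio.filter_mutation_calls(calls)
    flags = cio.assign_subgroups(patients, retained, expression)
    flags.insert(0, "ALL", True)
    return flags


@_stage("metrics")
def _metrics(config, expression, patients) -> pd.DataFrame:
    prof = isotypes.compute_profiles(expression)
    prof = prof.reindex(patients["patient_id"])
    prof.index.name = "sample_id"
    return prof


def _adjusted_covariates(patients: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Stage/gender/smoking/age plus log2(CD45 TPM + 1) infiltration."""
    cov = pd.DataFrame(index=patients.index)
    stage = patients["stage"].astype(str).str.replace(r"[ab]$", "", regex=True)
    cov["stage_ord"] = stage.map({"I": 1, "II": 2, "III": 3, "IV": 4})
    cov["male"] = (patients["gender"].astype(str).str.lower()
                   .isin(["male", "m"])).astype(float)
    cov["ever_smoker"] = (patients["smoking"].astype(str).str.lower()
                          != "never").astype(float)
    cov["age"] = patients["age"].astype(float)
    cov["infiltration"] = np.log2(
        profiles["PTPRC"].reindex(patients["patient_id"]).to_numpy() + 1.0
    )
    return cov


@_stage("survival_screen")
def _survival_screen(config, patients, profiles, flags) -> pd.DataFrame:
    rows = []
    times = patients.set_index("patient_id")["os_days"]
    events = patients.set_index("patient_id")["event"]
    covariates = _adjusted_covariates(patients, profiles).set_index(
        patients["patient_id"]
    )
    for subgroup in config.subgroups:
        member_ids = flags.index[flags[subgroup]]
        for metric in config.metrics:
            values = profiles[metric]
            scope = member_ids if config.median_scope == "subgroup" else None
            row = {"subgroup": subgroup, "metric": metric}
            try:
                labels = isotypes.median_split(values, subgroup=scope)
                if config.median_scope == "cohort":
                    labels[~labels.index.isin(member_ids)] = "excluded"
                comp = survival.compare_survival(
                    labels, times, events, family_size=config.bonferroni_m
                )
            except ValueError as exc:
                logger.warning("skipping %s x %s: %s", subgroup, metric, exc)
                rows.append(row)
                continue
            row.update(
                n_high=comp.n_high, n_low=comp.n_low,
                hazard_ratio=comp.hazard_ratio,
                ci_lower=comp.ci_lower, ci_upper=comp.ci_upper,
                logrank_chi2=comp.chi2, p=comp.p, adjusted_p=comp.adjusted_p,
            )
            if config.adjusted_cox:
                try:
                    keep = labels.isin(["high", "low"])
                    X = covariates.loc[labels.index[keep]].copy()
                    X["high"] = (labels[keep] == "high").astype(float)
                    fit = survival.cox_fit(
                        X, times.loc[X.index], events.loc[X.index]
                    )
                    row.update(
                        adj_cox_hr=float(fit.hazard_ratios["high"]),
                        adj_cox_p=float(fit.p_values["high"]),
                    )
                except Exception as exc:  # small strata may not converge
                    logger.warning("adjusted Cox failed for %s x %s: %s",
                                   subgroup, metric, exc)
            rows.append(row)
    return pd.DataFrame(rows)


@_stage("clonality")
def _clonality(config, patients) -> pd.DataFrame:
    if config.clonotype_dir is None:
        return pd.DataFrame()
    repdir = Path(config.clonotype_dir)
    rows = []
    for pid in patients["patient_id"]:
        path = repdir / f"{pid}.tsv"
        if not path.exists():
            continue
        table = repertoire.read_clonotype_table(path, sample_id=pid)
        for isotype in config.clonality_isotypes:
            total = table.isotype_total(isotype)
            passed = repertoire.coverage_filter(table, isotype, config.min_reads)
            row = {"patient_id": pid, "isotype": isotype,
                   "reads": total, "passed": int(passed)}
            if passed:
                mean, sd = repertoire.sample_clonality(
                    table, isotype,
                    n=config.n_downsample,
                    replicates=config.clonality_replicates,
                    seed=config.seed,
                )
                row.update(clonality_mean=mean, clonality_sd=sd)
            rows.append(row)
    return pd.DataFrame(rows)


@_stage("signature")
def _signature(config, patients, flags) -> pd.DataFrame:
    if config.clonotype_dir is None:
        return pd.DataFrame()
    repdir = Path(config.clonotype_dir)
    cohort_ids = set(flags.index[flags[config.signature_subgroup]])
    tables = []
    for pid in patients["patient_id"]:
        if pid not in cohort_ids:
            continue
        path = repdir / f"{pid}.tsv"
        if not path.exists():
            continue
        table = repertoire.read_clonotype_table(path, sample_id=pid)
        if repertoire.coverage_filter(table, config.signature_isotype, config.min_reads):
            tables.append(table)
    if len(tables) < 3:
        logger.warning("signature skipped: only %d samples pass coverage", len(tables))
        return pd.DataFrame()
    usage = repertoire.vj_usage_matrix(tables, config.signature_isotype)
    labels = repertoire.survival_group_labels(
        patients.loc[patients.index.isin(usage.index)]
    )
    result = repertoire.signature_pca(
        usage, labels, n_components=min(config.signature_components,
                                        usage.shape[0] - 1, usage.shape[1])
    )
    out = result.to_frame()
    out.index.name = "feature"
    return out.reset_index()


@_stage("correlation")
def _burden_correlation(config, patients, profiles, flags) -> pd.DataFrame:
    rows = []
    burden = patients.set_index("patient_id")["mutation_burden"]
    ratio = profiles["IGHG1_over_IGH"]
    for subgroup in config.subgroups:
        ids = flags.index[flags[subgroup]]
        x = ratio.reindex(ids)
        y = burden.reindex(ids)
        row = {"subgroup": subgroup, "n": int((~(x.isna() | y.isna())).sum())}
        try:
            rho, p = survival.spearman_corr(x, y)
            row.update(spearman_rho=rho, p=p)
        except ValueError as exc:
            logger.warning("correlation skipped for %s: %s", subgroup, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle; returns the tables.

    Identical config and inputs produce byte-identical outputs.  Any stage
    failure aborts with a stage-named error and no partial bundle is left
    behind.
    """
    expression, patients, calls = _load_inputs(config)
    flags = _subgroups(config, patients, calls, expression)
    profiles = _metrics(config, expression, patients)
    results = {
        "metrics": profiles.reset_index(),
        "subgroups": flags.astype(int).reset_index(),
        "survival": _survival_screen(config, patients, profiles, flags),
        "clonality": _clonality(config, patients),
        "signature": _signature(config, patients, flags),
        "burden_correlation": _burden_correlation(config, patients, profiles, flags),
    }
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for name, df in results.items():
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
            written.append(path)
        manifest = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "n_patients": int(len(patients)),
            "tables": sorted(f"{n}.tsv" for n in results),
        }
        mpath = outdir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(mpath)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage 'write' failed: {exc}") from exc
    results["manifest"] = manifest
    return results
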