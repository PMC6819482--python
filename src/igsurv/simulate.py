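"""Synthetic cohorts with known ground truth.

Generates everything the analysis consumes — clinical records, driver-gene
mutation calls, a 14-gene (plus decoys) TPM expression matrix, non-silent
mutation burden, and per-sample clonotype tables — from an explicit seed.
The generative model mirrors the quantities the analysis estimates:

* per-patient isotype composition ~ Dirichlet; constant-gene TPM is the
  composition times a log-normal total-IGH expression, so IGHG1/IGH etc.
  are exact functions of the latent fractions;
* driver genotypes ~ independent Bernoulli at the observed cohort
  frequencies (KRAS 122/442, TP53 220/442, STK11 73/442, EGFR 57/442);
* mutation burden is coupled to IGHG1/IGH through a Gaussian copula
  calibrated to a target Spearman correlation;
* survival is exponential with a log-hazard shifted by planted hazard
  ratios on median-split indicators within chosen subgroups (default:
  HR 0.36 for IGHG1/IGH-high inside the KRAS-mutant stratum), under
  independent uniform administrative censoring;
* repertoires draw clone sizes from a power law, reads from a negative
  binomial depth, and V/J labels from realistic usage, with an optional
  V-J enrichment planted in long-surviving KRAS-mutant samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .cohort import ExpressionMatrix, write_expression
from .isotypes import CONSTANT_GENES, MARKER_GENES, compute_profiles
from .repertoire import ClonotypeTable, clonality, write_clonotype_table

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_repertoires",
    "simulate_usage_repertoire",
    "write_bundle",
]

#: Mean isotype composition of intratumoral IGH expression (fractions of
#: total); IgA and IgG1 dominate, IgD/IgE are trace.
DEFAULT_ISOTYPE_MEANS = {
    "IGHA1": 0.26, "IGHA2": 0.07, "IGHG1": 0.26, "IGHG2": 0.12,
    "IGHG3": 0.07, "IGHG4": 0.03, "IGHM": 0.16, "IGHD": 0.02, "IGHE": 0.01,
}

#: log-TPM (natural log) location/scale for the marker genes.
DEFAULT_MARKER_PARAMS = {
    "MS4A1": (3.4, 1.0),   # CD20
    "CD19": (2.7, 1.0),
    "SDC1": (4.4, 0.8),    # CD138
    "CD274": (1.6, 1.0),   # PD-L1; sigma 1.0 puts ~11.5% of samples > 2x mean
    "PTPRC": (5.7, 0.8),   # CD45
}

DEFAULT_V_FAMILY_FREQS = {
    "IGHV1": 0.16, "IGHV2": 0.03, "IGHV3": 0.42, "IGHV4": 0.24,
    "IGHV5": 0.08, "IGHV6": 0.02, "IGHV7": 0.05,
}

DEFAULT_J_GENE_FREQS = {
    "IGHJ1": 0.03, "IGHJ2": 0.05, "IGHJ3": 0.10, "IGHJ4": 0.50,
    "IGHJ5": 0.12, "IGHJ6": 0.20,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults reproduce the study conditions."""

    n_patients: int = 442
    genotype_freqs: dict = field(default_factory=lambda: {
        "KRAS": 122 / 442, "TP53": 220 / 442,
        "STK11": 73 / 442, "EGFR": 57 / 442,
    })
    subtype_freqs: dict = field(default_factory=lambda: {
        "PI": 65 / 442, "PP": 51 / 442, "TRU": 68 / 442,
    })
    #: Dirichlet concentration = means * total_concentration.
    isotype_means: dict = field(default_factory=lambda: dict(DEFAULT_ISOTYPE_MEANS))
    isotype_concentration: float = 10.0
    igh_log_mean: float = 7.6      # ln TPM of total IGH (median ~2000 TPM)
    igh_log_sd: float = 1.2
    marker_params: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PARAMS))
    n_decoy_genes: int = 50
    decoy_log_mean: float = 3.0
    decoy_log_sd: float = 1.5
    #: target Spearman correlation between IGHG1/IGH and mutation burden
    burden_rho: float = 0.48
    burden_log_mean: float = 1.8   # ln mutations/Mb (median ~6/Mb)
    burden_log_sd: float = 1.2
    #: planted hazard ratios on (subgroup, metric) median-split indicators
    planted_hr: dict = field(default_factory=lambda: {
        ("KRASmut", "IGHG1_over_IGH"): 0.36,
    })
    continuous_effect: bool = False
    baseline_hazard: float = 1 / 900.0   # per day; exponential survival
    censor_max_days: float = 3400.0      # uniform administrative censoring; ~30% censored
    # repertoire generation
    isotypes: tuple = ("IgG1", "IgA")
    n_clones: int | None = 150
    powerlaw_exponent: float = 2.0
    read_depth_mean: float = 2000.0
    read_depth_dispersion: float = 1.5   # negative-binomial size parameter
    v_family_freqs: dict = field(default_factory=lambda: dict(DEFAULT_V_FAMILY_FREQS))
    j_gene_freqs: dict = field(default_factory=lambda: dict(DEFAULT_J_GENE_FREQS))
    #: extra (V family, J gene) probability mass in enriched samples' IgG1
    signature_shift: dict = field(default_factory=lambda: {
        ("IGHV6", "IGHJ4"): 0.15, ("IGHV4", "IGHJ3"): 0.10,
    })
    signature_enabled: bool = True

    def validate(self) -> None:
        for g, f in self.genotype_freqs.items():
            if not 0 <= f <= 1:
                raise ValueError(f"genotype frequency out of [0,1] for {g}: {f}")
        if sum(self.subtype_freqs.values()) > 1 + 1e-9:
            raise ValueError("subtype frequencies sum above 1")
        if any(v <= 0 for v in self.isotype_means.values()):
            raise ValueError("Dirichlet concentrations must be positive")
        if abs(self.burden_rho) >= 1:
            raise ValueError(f"infeasible copula correlation: {self.burden_rho}")
        if self.n_clones is None and self.powerlaw_exponent <= 1:
            raise ValueError(
                "power-law exponent <= 1 needs a bounded clone count "
                "(normalization diverges otherwise)"
            )


@dataclass
class SimulatedCohort:
    patients: pd.DataFrame            # clinical columns + <GENE>_mut flags
    expression: ExpressionMatrix      # TPM
    mutation_calls: pd.DataFrame
    ground_truth: dict


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson r giving Spearman rho_s (r = 2 sin(pi rho_s / 6))."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Draw a full synthetic cohort; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_patients
    ids = [f"SIM-{i:04d}" for i in range(n)]

    # genotypes and clinical covariates
    genotypes = {
        g: rng.random(n) < f for g, f in config.genotype_freqs.items()
    }
    subtype_labels = list(config.subtype_freqs) + ["unknown"]
    subtype_p = list(config.subtype_freqs.values())
    subtype_p.append(1.0 - sum(subtype_p))
    subtype = rng.choice(subtype_labels, size=n, p=subtype_p)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.52, 0.25, 0.17, 0.06])
    gender = rng.choice(["female", "male"], size=n, p=[0.54, 0.46])
    age = np.clip(rng.normal(65, 9, size=n).round(1), 33, 90)
    smoking = rng.choice(["ever", "never"], size=n, p=[0.85, 0.15])

    # expression: isotype composition x total IGH, markers, decoys
    iso_genes = list(config.isotype_means)
    alpha = np.array([config.isotype_means[g] for g in iso_genes])
    alpha = alpha / alpha.sum() * config.isotype_concentration
    fractions = rng.dirichlet(alpha, size=n)                     # n x 9
    igh_total = rng.lognormal(config.igh_log_mean, config.igh_log_sd, size=n)
    expr = {g: fractions[:, k] * igh_total for k, g in enumerate(iso_genes)}
    for g, (mu, sd) in config.marker_params.items():
        expr[g] = rng.lognormal(mu, sd, size=n)
    for k in range(config.n_decoy_genes):
        expr[f"DECOY{k:03d}"] = rng.lognormal(
            config.decoy_log_mean, config.decoy_log_sd, size=n
        )
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=ids).T.astype(float), units="TPM"
    )

    # mutation burden coupled to IGHG1/IGH via a Gaussian copula
    ighg1_ratio = fractions[:, iso_genes.index("IGHG1")]
    r = _spearman_to_pearson(config.burden_rho)
    z = _st.norm.ppf((_st.rankdata(ighg1_ratio) - 0.5) / n)
    w = r * z + np.sqrt(1 - r * r) * rng.standard_normal(n)
    burden = np.exp(config.burden_log_mean + config.burden_log_sd * w)

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "os_days": np.nan,
            "event": False,
            "stage": stage,
            "gender": gender,
            "age": age,
            "smoking": smoking,
            "subtype": subtype,
            "mutation_burden": burden.round(4),
        },
        index=pd.Index(ids, name=None),
    )
    for g, flags in genotypes.items():
        patients[f"{g}_mut"] = flags

    # survival: exponential hazard with planted median-split effects
    profiles = compute_profiles(expression)
    log_hazard = np.full(n, np.log(config.baseline_hazard))
    indicators = {}
    for (subgroup, metric), hr in config.planted_hr.items():
        members = _subgroup_mask(patients, subgroup)
        vals = profiles[metric].reindex(ids).to_numpy()
        member_vals = vals[members]
        med = np.nanmedian(member_vals)
        if config.continuous_effect:
            centered = np.where(members, vals - np.nanmedian(member_vals), 0.0)
            log_hazard += np.log(hr) * 2 * np.nan_to_num(centered) / max(
                1e-12, np.nanstd(member_vals)
            )
            ind = members & (vals > med)
        else:
            ind = members & (vals > med)
            log_hazard += np.log(hr) * ind
        indicators[f"{subgroup}:{metric}"] = ind
    t_event = rng.exponential(1.0 / np.exp(log_hazard))
    t_censor = rng.uniform(0.0, config.censor_max_days, size=n)
    patients["os_days"] = np.minimum(t_event, t_censor).round(2)
    patients["event"] = t_event <= t_censor

    mutation_calls = _simulate_mutation_calls(rng, patients, genotypes)

    ground_truth = {
        "seed": int(seed),
        "planted_hr": {f"{s}:{m}": hr for (s, m), hr in config.planted_hr.items()},
        "planted_log_hr": {
            f"{s}:{m}": float(np.log(hr)) for (s, m), hr in config.planted_hr.items()
        },
        "burden_rho_target": config.burden_rho,
        "genotype_counts": {g: int(f.sum()) for g, f in genotypes.items()},
        "censoring_fraction": float(1 - patients["event"].mean()),
        "signature_features": [
            f"{v}|{j}" for (v, j) in config.signature_shift
        ] if config.signature_enabled else [],
        "n_effect_carriers": {k: int(v.sum()) for k, v in indicators.items()},
    }
    return SimulatedCohort(
        patients=patients,
        expression=expression,
        mutation_calls=mutation_calls,
        ground_truth=ground_truth,
    )


def _subgroup_mask(patients: pd.DataFrame, subgroup: str) -> np.ndarray:
    """Membership mask for planted effects, from simulation-time truth."""
    if subgroup == "ALL":
        return np.ones(len(patients), dtype=bool)
    if subgroup.endswith("mut"):
        return patients[f"{subgroup[:-3]}_mut"].to_numpy()
    if subgroup.endswith("wt"):
        return ~patients[f"{subgroup[:-2]}_mut"].to_numpy()
    if subgroup in ("PI", "PP", "TRU"):
        return (patients["subtype"] == subgroup).to_numpy()
    raise ValueError(f"unknown subgroup for planted effect: {subgroup!r}")


def _simulate_mutation_calls(rng, patients, genotypes) -> pd.DataFrame:
    """Driver calls consistent with the genotypes, plus filterable noise.

    Every mutant patient gets one retained-class call (HIGH/MODERATE impact,
    or LOW rescued by SIFT/PolyPhen); wild-type patients may carry LOW-impact
    tolerated/benign calls that the filter must remove.
    """
    rows = []
    ids = patients["patient_id"].to_numpy()
    n = len(ids)
    for gene, flags in genotypes.items():
        for pid in ids[flags]:
            kind = rng.random()
            if kind < 0.35:
                rows.append((pid, gene, "HIGH", "", ""))
            elif kind < 0.9:
                rows.append((pid, gene, "MODERATE", "deleterious", "probably_damaging"))
            else:  # low impact rescued by annotation
                rows.append((pid, gene, "LOW", "deleterious", ""))
        # passenger noise the filter must drop
        for pid in ids[rng.random(n) < 0.10]:
            rows.append((pid, gene, "LOW", "tolerated", "benign"))
        for pid in ids[rng.random(n) < 0.05]:
            rows.append((pid, gene, "MODIFIER", "", ""))
    return pd.DataFrame(
        rows, columns=["patient_id", "gene", "vep_impact", "sift", "polyphen"]
    )


def simulate_usage_repertoire(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    enriched: bool = False,
    depth: int | None = None,
) -> tuple[ClonotypeTable, dict]:
    """One sample's clonotype table; returns (table, per-isotype true clonality).

    Clone relative abundances follow a rank-frequency power law p_k ~
    k^-exponent over ``n_clones`` clones; reads are multinomial at a
    negative-binomial depth; V families and J genes are drawn independently
    from the configured usage, except that in ``enriched`` samples the
    planted (V, J) pairs receive their extra probability mass in the IgG1
    repertoire.
    """
    frames = []
    truth = {}
    v_names = list(config.v_family_freqs)
    v_p = np.array(list(config.v_family_freqs.values()), dtype=float)
    v_p /= v_p.sum()
    j_names = list(config.j_gene_freqs)
    j_p = np.array(list(config.j_gene_freqs.values()), dtype=float)
    j_p /= j_p.sum()
    planted = list(config.signature_shift.items())
    shift_total = sum(config.signature_shift.values())

    for isotype in config.isotypes:
        s = config.n_clones
        ranks = np.arange(1, s + 1, dtype=float)
        p = ranks ** (-config.powerlaw_exponent)
        p /= p.sum()
        truth[isotype] = clonality(p)
        if depth is None:
            mean, r = config.read_depth_mean, config.read_depth_dispersion
            d = int(rng.negative_binomial(r, r / (r + mean)))
        else:
            d = int(depth)
        if d == 0:
            continue
        counts = rng.multinomial(d, p)
        keep = counts > 0
        counts = counts[keep]
        k = counts.size
        v_idx = rng.choice(len(v_names), size=k, p=v_p)
        j_idx = rng.choice(len(j_names), size=k, p=j_p)
        v = np.array([v_names[i] + "-1" for i in v_idx], dtype=object)
        j = np.array([j_names[i] for i in j_idx], dtype=object)
        if enriched and isotype == "IgG1" and planted:
            u = rng.random(k)
            edge = 0.0
            for (vf, jg), mass in planted:
                sel = (u >= edge) & (u < edge + mass)
                v[sel] = vf + "-1"
                j[sel] = jg
                edge += mass
        aa_len = rng.integers(10, 21, size=k)
        cdr3aa = ["C" + "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=m - 2))
                  + "W" for m in aa_len]
        cdr3nt = ["".join(rng.choice(list("ACGT"), size=3 * m)) for m in aa_len]
        frames.append(pd.DataFrame({
            "count": counts,
            "freq": counts / counts.sum(),
            "cdr3nt": cdr3nt,
            "cdr3aa": cdr3aa,
            "v": v,
            "d": ".",
            "j": j,
            "isotype": isotype,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j", "isotype"]
    )
    if df.empty:
        df = df.astype({"count": int})
    return ClonotypeTable(sample_id=sample_id, clonotypes=df), truth


def simulate_repertoires(
    config: SimulationConfig, patients: pd.DataFrame, seed: int
) -> tuple[dict, dict]:
    """Clonotype tables for every patient; returns (tables, true clonality).

    When the planted V-J signature is enabled, long-surviving KRAS-mutant
    patients (overall survival above the cohort median) carry the enriched
    IgG1 usage.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    med = patients["os_days"].median()
    long_surv = (patients["os_days"] > med).to_numpy()
    kras = patients["KRAS_mut"].to_numpy() if "KRAS_mut" in patients else np.zeros(
        len(patients), dtype=bool
    )
    tables, truths = {}, {}
    for i, pid in enumerate(patients["patient_id"]):
        enriched = bool(config.signature_enabled and kras[i] and long_surv[i])
        table, truth = simulate_usage_repertoire(config, rng, pid, enriched=enriched)
        tables[pid] = table
        truths[pid] = truth
    return tables, truths


def write_bundle(
    outdir,
    cohort: SimulatedCohort,
    repertoires: dict | None = None,
    true_clonality: dict | None = None,
) -> None:
    """Write the full input bundle in the analysis' on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, outdir / "expression.tsv")
    clinical_cols = ["patient_id", "os_days", "event", "stage", "gender",
                     "age", "smoking", "subtype", "mutation_burden"]
    clin = cohort.patients[clinical_cols].copy()
    clin["event"] = clin["event"].astype(int)
    clin["subtype"] = clin["subtype"].replace("unknown", "")
    clin.to_csv(outdir / "clinical.tsv", sep="\t", index=False, float_format="%.6g")
    cohort.mutation_calls.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    truth = dict(cohort.ground_truth)
    if repertoires is not None:
        repdir = outdir / "clonotypes"
        repdir.mkdir(exist_ok=True)
        for pid, table in repertoires.items():
            write_clonotype_table(table, repdir / f"{pid}.tsv")
    if true_clonality is not None:
        truth["true_clonality"] = true_clonality
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
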