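"""Cohort input tables: expression, clinical records, mutation calls, subgroups.

The analysis operates on a "general cohort" of primary-tumor samples, one per
patient: a gene-level expression matrix (FPKM or TPM), a clinical table with
overall survival, and a table of annotated somatic mutation calls.  Patients
are assigned to twelve partially overlapping subgroups: mutant/wild-type
status for KRAS, TP53 and STK11, EGFR-mutant, PD-L1 high/low by CD274
expression, and three transcriptional subtypes (proximal inflammatory,
proximal proliferative, terminal respiratory unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SUBGROUPS",
    "GENOTYPE_GENES",
    "read_expression",
    "write_expression",
    "read_clinical",
    "read_mutations",
    "fpkm_to_tpm",
    "filter_mutation_calls",
    "assign_subgroups",
]

#: Subgroup columns, in reporting order.
SUBGROUPS = [
    "KRASmut", "KRASwt", "EGFRmut",
    "TP53mut", "TP53wt", "STK11mut", "STK11wt",
    "PDL1high", "PDL1low",
    "PI", "PP", "TRU",
]

#: Driver genes whose mutant/wild-type status defines genotype subgroups.
GENOTYPE_GENES = ["KRAS", "TP53", "STK11", "EGFR"]

VALID_IMPACTS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}

#: SIFT / PolyPhen categories treated as evidence of functional impact.
DAMAGING_SIFT = {"deleterious", "deleterious_low_confidence"}
DAMAGING_POLYPHEN = {"probably_damaging", "possibly_damaging"}

CLINICAL_COLUMNS = [
    "patient_id", "os_days", "event", "stage", "gender", "age",
    "smoking", "subtype", "mutation_burden",
]

TRANSCRIPTIONAL_SUBTYPES = {"PI", "PP", "TRU"}


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a units tag.

    ``values`` is a DataFrame indexed by gene symbol with one column per
    sample; entries are non-negative FPKM or TPM.
    """

    values: pd.DataFrame
    units: str = "TPM"

    def __post_init__(self) -> None:
        if self.units not in ("FPKM", "TPM"):
            raise ValueError(f"units must be 'FPKM' or 'TPM', got {self.units!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def gene(self, symbol: str) -> pd.Series:
        """Per-sample expression of one gene; KeyError names the gene."""
        if symbol not in self.values.index:
            raise KeyError(f"gene {symbol!r} absent from expression matrix")
        return self.values.loc[symbol]


def read_expression(path, units: str = "TPM") -> ExpressionMatrix:
    """Read a TSV with gene symbols in the first column, samples as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, units=units)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table; exactly one row per patient.

    Columns: patient_id, os_days, event (0/1), stage, gender, age, smoking,
    subtype (PI/PP/TRU/unknown), mutation_burden (may be empty).  Sample-level
    filtering (FFPE/normal/metastatic removal, one aliquot per patient) is
    assumed done upstream; duplicate patient rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
    if dupes:
        raise ValueError(
            f"duplicate patient rows (one aliquot per patient expected): {dupes}"
        )
    if (df["os_days"] <= 0).any():
        bad = df.loc[df["os_days"] <= 0, "patient_id"].tolist()
        raise ValueError(f"non-positive survival times for patients: {bad}")
    df["event"] = df["event"].astype(bool)
    df["subtype"] = df["subtype"].fillna("unknown")
    bad_subtype = set(df["subtype"]) - TRANSCRIPTIONAL_SUBTYPES - {"unknown"}
    if bad_subtype:
        raise ValueError(f"unknown transcriptional subtype labels: {sorted(bad_subtype)}")
    return df.set_index("patient_id", drop=False)


def read_mutations(path) -> pd.DataFrame:
    """Read mutation calls (MAF-compatible subset).

    Columns: patient_id, gene, vep_impact, sift, polyphen; sift/polyphen may
    be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("patient_id", "gene", "vep_impact") if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    for col in ("sift", "polyphen"):
        if col not in df.columns:
            df[col] = pd.NA
    return df


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by per-sample renormalization to 1e6.

    TPM(g, s) = FPKM(g, s) / sum_g FPKM(g, s) * 1e6.  Refuses already-TPM
    input so the normalization is never silently applied twice.
    """
    if matrix.units != "FPKM":
        raise ValueError(
            f"fpkm_to_tpm requires FPKM input, got units={matrix.units!r}"
        )
    colsums = matrix.values.sum(axis=0)
    zero = colsums.index[colsums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero expression for sample(s): {zero}")
    tpm = matrix.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=tpm, units="TPM")


def filter_mutation_calls(
    calls: pd.DataFrame,
    damaging_sift: set[str] = DAMAGING_SIFT,
    damaging_polyphen: set[str] = DAMAGING_POLYPHEN,
) -> pd.DataFrame:
    """Drop low-impact calls lacking SIFT/PolyPhen support.

    A call is retained iff its VEP impact is HIGH or MODERATE, or SIFT calls
    it deleterious, or PolyPhen calls it (probably/possibly) damaging.
    """
    impact = calls["vep_impact"].astype(str)
    unknown = calls.loc[~impact.isin(VALID_IMPACTS)]
    if len(unknown):
        raise ValueError(
            "unknown vep_impact value(s) in rows:\n"
            + unknown.to_string(max_rows=10)
        )
    sift = calls["sift"].fillna("").astype(str).str.lower()
    polyphen = calls["polyphen"].fillna("").astype(str).str.lower()
    keep = (
        impact.isin({"HIGH", "MODERATE"})
        | sift.isin(damaging_sift)
        | polyphen.isin(damaging_polyphen)
    )
    return calls.loc[keep].reset_index(drop=True)


def assign_subgroups(
    patients: pd.DataFrame,
    filtered_calls: pd.DataFrame,
    expression: ExpressionMatrix,
    pdl1_gene: str = "CD274",
    pdl1_mean_multiple: float = 2.0,
) -> pd.DataFrame:
    """Boolean membership table (patients x the twelve subgroups).

    Genotype flags come from retained mutation calls; PD-L1 high means CD274
    TPM strictly above ``pdl1_mean_multiple`` times the cohort arithmetic
    mean; transcriptional subtype flags are copied from the clinical labels.
    """
    if expression.units != "TPM":
        raise ValueError("assign_subgroups requires TPM expression")
    ids = patients["patient_id"]
    out = pd.DataFrame(False, index=ids, columns=SUBGROUPS)

    mutated = filtered_calls.groupby("gene")["patient_id"].agg(set).to_dict()
    for gene in GENOTYPE_GENES:
        has_mut = ids.isin(mutated.get(gene, set())).to_numpy()
        if f"{gene}mut" in out.columns:
            out[f"{gene}mut"] = has_mut
        if f"{gene}wt" in out.columns:
            out[f"{gene}wt"] = ~has_mut

    pdl1 = expression.gene(pdl1_gene).reindex(ids)
    if pdl1.isna().any():
        missing = pdl1.index[pdl1.isna()].tolist()
        raise ValueError(f"no {pdl1_gene} expression for patients: {missing}")
    threshold = pdl1_mean_multiple * pdl1.mean()
    out["PDL1high"] = (pdl1 > threshold).to_numpy()
    out["PDL1low"] = ~out["PDL1high"]

    subtype = patients.set_index("patient_id")["subtype"].reindex(ids)
    for label in TRANSCRIPTIONAL_SUBTYPES:
        out[label] = (subtype == label).to_numpy()
    return out
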