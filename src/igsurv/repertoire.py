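"""BCR repertoire statistics: clonality, V-J usage matrices, usage signature.

Clonotype tables are per-sample TSVs in VDJtools-style columns (count, freq,
cdr3nt, cdr3aa, v, d, j) plus an isotype column.  Clonality of an isotype
repertoire is 1 minus the normalized Shannon-Wiener index, computed after
downsampling the repertoire to a fixed number of reads (default 500) so that
samples with different sequencing depths are comparable; only samples with
strictly more than 500 reads covering that isotype's CDR3 enter the analysis.

For the usage signature, V genes are collapsed to families (IGHV3-11 ->
IGHV3), J genes kept at gene level, and the per-sample (V family, J gene)
read-frequency matrix is decomposed by PCA; features are additionally ranked
by the difference in mean frequency between long- and short-survival samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ClonotypeTable",
    "SignatureResult",
    "read_clonotype_table",
    "write_clonotype_table",
    "coverage_filter",
    "downsample_reads",
    "clonality",
    "sample_clonality",
    "collapse_v_family",
    "j_gene",
    "vj_usage_matrix",
    "signature_pca",
    "survival_group_labels",
]

_CLONOTYPE_COLUMNS = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j", "isotype"]

_V_FAMILY_RE = re.compile(r"^(IGHV\d+)(?:[-/].*)?$")


@dataclass
class ClonotypeTable:
    """One sample's clonotypes: a DataFrame in VDJtools-style columns."""

    sample_id: str
    clonotypes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CLONOTYPE_COLUMNS if c not in self.clonotypes.columns
                   and c != "d"]
        if missing:
            raise ValueError(f"clonotype table missing columns: {missing}")
        if "d" not in self.clonotypes.columns:
            self.clonotypes = self.clonotypes.assign(d=".")
        if (self.clonotypes["count"] < 1).any():
            raise ValueError("clonotype read counts must be >= 1")

    def isotype_total(self, isotype: str) -> int:
        """Total reads covering CDR3s of one isotype."""
        mask = self.clonotypes["isotype"] == isotype
        return int(self.clonotypes.loc[mask, "count"].sum())

    def subset(self, isotype: str) -> pd.DataFrame:
        return self.clonotypes.loc[self.clonotypes["isotype"] == isotype]


def read_clonotype_table(path, sample_id: str | None = None) -> ClonotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"cdr3nt": str, "cdr3aa": str})
    if sample_id is None:
        sample_id = str(path).rsplit("/", 1)[-1].removesuffix(".tsv")
    df["count"] = df["count"].astype(int)
    return ClonotypeTable(sample_id=sample_id, clonotypes=df)


def write_clonotype_table(table: ClonotypeTable, path) -> None:
    out = table.clonotypes.copy()
    total = out["count"].sum()
    out["freq"] = out["count"] / total
    out[_CLONOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def coverage_filter(table: ClonotypeTable, isotype: str, min_reads: int = 500) -> bool:
    """True iff the sample has strictly more than ``min_reads`` reads of the isotype."""
    return table.isotype_total(isotype) > min_reads


def downsample_reads(
    table: ClonotypeTable,
    isotype: str,
    n: int = 500,
    seed: int | np.random.Generator = 0,
) -> ClonotypeTable:
    """Downsample one isotype's repertoire to exactly ``n`` reads.

    Reads are drawn uniformly without replacement from the pooled reads
    (multivariate hypergeometric on the clonotype counts); clonotypes drawn
    to zero are dropped.  Deterministic given the seed.
    """
    sub = table.subset(isotype)
    total = int(sub["count"].sum())
    if total < n:
        raise ValueError(
            f"sample {table.sample_id}: {total} {isotype} reads < {n}; "
            "apply coverage_filter first"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(sub["count"].to_numpy(), n)
    out = sub.assign(count=new_counts)
    out = out.loc[out["count"] > 0].copy()
    out["freq"] = out["count"] / n
    return ClonotypeTable(sample_id=table.sample_id, clonotypes=out.reset_index(drop=True))


def clonality(counts) -> float:
    """1 minus the normalized Shannon-Wiener index of clone counts.

    With p_i = count_i / total and S clones, H = -sum p_i ln p_i and
    clonality = 1 - H / ln S: 0 for a perfectly even repertoire, 1 for a
    single dominant clone.  A single-clonotype repertoire is defined as
    maximally clonal (clonality 1), the limit of complete dominance.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("clonality of an empty repertoire is undefined")
    if (counts <= 0).any():
        raise ValueError("clone counts must be positive")
    if counts.size == 1:
        return 1.0
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(1.0 - h / np.log(counts.size))


def _clone_key(df: pd.DataFrame, identity: str = "nt") -> pd.Series:
    cdr3 = df["cdr3nt"] if identity == "nt" else df["cdr3aa"]
    return cdr3 + "|" + df["v"].map(collapse_v_family) + "|" + df["j"].map(j_gene)


def sample_clonality(
    table: ClonotypeTable,
    isotype: str,
    n: int = 500,
    replicates: int = 10,
    seed: int = 0,
    identity: str = "nt",
) -> tuple[float, float]:
    """Mean and SD of downsampled clonality over seeded replicates.

    Clonotype identity is CDR3 nucleotide sequence + V family + J gene
    (``identity='aa'`` switches to the amino-acid sequence).  Reported as
    the mean over ``replicates`` independent downsamplings; ``replicates=1``
    reproduces a single-draw estimate.
    """
    sub = table.subset(isotype)
    grouped = sub.groupby(_clone_key(sub, identity))["count"].sum()
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(replicates):
        down = rng.multivariate_hypergeometric(grouped.to_numpy(), n)
        vals.append(clonality(down[down > 0]))
    return float(np.mean(vals)), float(np.std(vals))


def collapse_v_family(v_call: str) -> str:
    """IGHV gene/allele name -> family, e.g. IGHV3-11 -> IGHV3."""
    m = _V_FAMILY_RE.match(str(v_call).split("*")[0])
    if m is None:
        raise ValueError(f"not an IGHV gene name: {v_call!r}")
    return m.group(1)


def j_gene(j_call: str) -> str:
    """IGHJ allele -> gene, e.g. IGHJ4*02 -> IGHJ4."""
    name = str(j_call).split("*")[0]
    if not name.startswith("IGHJ"):
        raise ValueError(f"not an IGHJ gene name: {j_call!r}")
    return name


def vj_usage_matrix(tables: list[ClonotypeTable], isotype: str) -> pd.DataFrame:
    """Samples x (V family, J gene) read-frequency matrix; rows sum to 1.

    Frequencies are read-count weighted within each sample's repertoire of
    the given isotype.  Callers should pre-apply :func:`coverage_filter`.
    """
    rows = {}
    for table in tables:
        sub = table.subset(isotype)
        if sub.empty:
            raise ValueError(f"sample {table.sample_id}: no {isotype} clonotypes")
        feat = sub["v"].map(collapse_v_family) + "|" + sub["j"].map(j_gene)
        counts = sub.groupby(feat.to_numpy())["count"].sum()
        rows[table.sample_id] = counts / counts.sum()
    mat = pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)
    if mat.shape[1] == 0:
        raise ValueError("empty V-J feature set")
    mat.index.name = "sample_id"
    return mat


@dataclass
class SignatureResult:
    """PCA of the usage matrix plus per-feature survival-group contrast."""

    loadings: pd.DataFrame            # features x components, unit-norm columns
    scores: pd.DataFrame              # samples x components
    explained_variance_ratio: np.ndarray
    group_difference: pd.Series       # mean freq (high survival) - mean freq (low)

    def to_frame(self) -> pd.DataFrame:
        out = self.loadings.copy()
        out["group_mean_difference"] = self.group_difference
        return out


def signature_pca(
    usage: pd.DataFrame,
    survival_labels: pd.Series,
    n_components: int | None = None,
) -> SignatureResult:
    """Principal components of V-J usage and the high-vs-low survival contrast.

    Columns are mean-centered (no unit-variance scaling); components are
    ordered by explained variance, and each component's sign is fixed so its
    largest-magnitude loading is positive.  ``group_difference`` is the mean
    frequency in high-survival samples minus the mean in low-survival
    samples, per feature; ``excluded`` samples contribute to the PCA but not
    to the contrast.
    """
    if usage.shape[0] < 3:
        raise ValueError("signature PCA needs at least 3 samples")
    if np.allclose(usage.to_numpy().var(axis=0), 0):
        raise ValueError("zero-variance usage matrix")
    k = n_components or min(usage.shape[0] - 1, usage.shape[1], 10)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(usage.to_numpy())
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, c]))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    labels = survival_labels.reindex(usage.index).fillna("excluded")
    high = usage.loc[labels == "high"]
    low = usage.loc[labels == "low"]
    diff = high.mean() - low.mean() if len(high) and len(low) else pd.Series(
        np.nan, index=usage.columns
    )
    return SignatureResult(
        loadings=pd.DataFrame(loadings, index=usage.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=usage.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        group_difference=diff,
    )


def survival_group_labels(patients: pd.DataFrame, cohort=None) -> pd.Series:
    """Long/short overall-survival labels relative to the cohort median.

    The median is taken over observed follow-up times of the cohort.  A
    patient is ``high`` if still under observation past the median (death or
    censoring after it), ``low`` if dead at or before the median, and
    ``excluded`` if censored at or before the median (fate at the median
    unknown).
    """
    sub = patients if cohort is None else patients.loc[patients.index.isin(cohort)]
    med = sub["os_days"].median()
    labels = pd.Series("excluded", index=sub.index, dtype=object)
    labels[sub["os_days"] > med] = "high"
    labels[(sub["os_days"] <= med) & sub["event"]] = "low"
    return labels
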