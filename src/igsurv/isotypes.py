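"""Per-sample immunoglobulin isotype composites, ratios, and median splits.

Total intratumoral antibody expression (IGH) is the sum of the nine heavy-
chain constant-region genes (IGHA1, IGHA2, IGHG1..IGHG4, IGHM, IGHD, IGHE);
IgA is IGHA1 + IGHA2.  Each isotype's proportion of IGH and its ratio to
MS4A1 (CD20, non-plasma B cells) are the metrics the survival analysis
dichotomizes at the cohort or subgroup median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix

__all__ = [
    "CONSTANT_GENES",
    "MARKER_GENES",
    "REQUIRED_GENES",
    "compute_profile",
    "compute_profiles",
    "median_split",
]

#: The nine IGH constant-region genes summed into total antibody expression.
CONSTANT_GENES = [
    "IGHA1", "IGHA2", "IGHG1", "IGHG2", "IGHG3", "IGHG4",
    "IGHM", "IGHD", "IGHE",
]

#: CD20, CD19, CD138, PD-L1 and CD45 marker genes.
MARKER_GENES = ["MS4A1", "CD19", "SDC1", "CD274", "PTPRC"]

REQUIRED_GENES = CONSTANT_GENES + MARKER_GENES

#: (metric name, numerator column, denominator column)
_RATIOS = [
    ("IGHG1_over_IGH", "IGHG1", "IGH"),
    ("IGHG4_over_IGH", "IGHG4", "IGH"),
    ("IgA_over_IGH", "IgA", "IGH"),
    ("IGH_over_MS4A1", "IGH", "MS4A1"),
    ("IGHG1_over_MS4A1", "IGHG1", "MS4A1"),
    ("IGHG4_over_MS4A1", "IGHG4", "MS4A1"),
    ("IgA_over_MS4A1", "IgA", "MS4A1"),
]


def compute_profiles(expression: ExpressionMatrix) -> pd.DataFrame:
    """Isotype profile table, one row per sample.

    Columns: the nine constant genes, the five markers, IGH and IgA sums,
    and the derived ratios.  A ratio whose denominator is zero is NaN — the
    sample drops out of that metric only, never of the whole analysis.
    """
    for g in REQUIRED_GENES:
        if g not in expression.values.index:
            raise ValueError(f"required gene {g!r} absent from expression matrix")
    prof = expression.values.loc[REQUIRED_GENES].T.copy()
    prof["IGH"] = prof[CONSTANT_GENES].sum(axis=1)
    prof["IgA"] = prof["IGHA1"] + prof["IGHA2"]
    for name, num, den in _RATIOS:
        den_vals = prof[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = prof[num].to_numpy(dtype=float) / den_vals
        ratio[den_vals == 0] = np.nan
        prof[name] = ratio
    prof.index.name = "sample_id"
    return prof


def compute_profile(sample_id: str, expression: ExpressionMatrix) -> pd.Series:
    """Single-sample isotype profile (see :func:`compute_profiles`)."""
    if sample_id not in expression.values.columns:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    sub = ExpressionMatrix(expression.values[[sample_id]], units=expression.units)
    return compute_profiles(sub).loc[sample_id]


def median_split(
    values: pd.Series,
    subgroup: pd.Index | list | None = None,
    min_size: int = 4,
) -> pd.Series:
    """Dichotomize a metric at the median within a subgroup.

    Returns labels ``high`` (strictly above the median), ``low`` (at or
    below), or ``excluded`` (missing value, or outside the subgroup).  The
    median is computed over the non-missing values of the subgroup members;
    ties at the median fall in the low group.
    """
    labels = pd.Series("excluded", index=values.index, dtype=object)
    member = values.index if subgroup is None else pd.Index(subgroup)
    in_group = values.loc[values.index.intersection(member)]
    observed = in_group.dropna()
    if len(observed) < min_size:
        raise ValueError(
            f"median split needs >= {min_size} non-missing values, got {len(observed)}"
        )
    if observed.nunique() == 1:
        raise ValueError("degenerate median split: all values identical")
    med = observed.median()
    labels.loc[observed.index[observed > med]] = "high"
    labels.loc[observed.index[observed <= med]] = "low"
    return labels
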