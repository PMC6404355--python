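"""qPCR relative quantification and the 2-fold / P<0.01 DEG filter.

Relative mRNA levels are quantified with the comparative-Ct (2^-ddCt) method
against an 18S rRNA internal control: per sample dCt = Ct_gene - Ct_ref, and
the treated-vs-control fold change is 2^-(mean dCt_treated - mean dCt_control).

Differential expression on log2 intensity matrices uses a per-gene Welch
two-sample t-test; a gene is selected iff |log2 FC| >= 1 (i.e. at least a
2-fold change, boundary inclusive) and p < 0.01, with no multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

REFERENCE_GENE = "18S"
CT_COLUMNS = ["sample", "group", "gene", "ct"]
GROUP_CONTROL = "control"
GROUP_TREATED = "treated"

__all__ = [
    "REFERENCE_GENE",
    "CT_COLUMNS",
    "GROUP_CONTROL",
    "GROUP_TREATED",
    "DdctResult",
    "ddct_fold_change",
    "deg_filter",
    "read_ct_csv",
]


@dataclass(frozen=True)
class DdctResult:
    """Fold change of one gene by the comparative-Ct method."""

    gene: str
    reference: str
    ddct: float  # mean dCt(treated) - mean dCt(control)
    fold: float  # 2^-ddct, group-level estimate
    per_sample: pd.Series  # fold per treated sample (vs mean control dCt)


def _delta_ct(ct: pd.DataFrame, group: str, gene: str, reference: str) -> pd.Series:
    sub = ct[ct["group"] == group]
    tgt = sub[sub["gene"] == gene].set_index("sample")["ct"]
    ref = sub[sub["gene"] == reference].set_index("sample")["ct"]
    if tgt.empty:
        raise InvalidParameterError(f"gene {gene!r} missing in group {group!r}")
    if not tgt.index.isin(ref.index).all():
        raise InvalidParameterError(
            f"reference gene {reference!r} missing for some samples in {group!r}"
        )
    return tgt - ref.reindex(tgt.index)


def ddct_fold_change(
    ct: pd.DataFrame, gene: str, reference: str = REFERENCE_GENE
) -> DdctResult:
    """2^-ddCt fold change of ``gene`` (treated vs control) against ``reference``.

    ``ct`` is a long table with columns sample, group, gene, ct; groups are
    "control" and "treated".  Adding a constant to all Ct values of a sample
    leaves the result unchanged (reference subtraction).
    """
    if not np.isfinite(ct["ct"]).all():
        raise InvalidParameterError("Ct values must be finite")
    dct_c = _delta_ct(ct, GROUP_CONTROL, gene, reference)
    dct_t = _delta_ct(ct, GROUP_TREATED, gene, reference)
    ddct = float(dct_t.mean() - dct_c.mean())
    per_sample = np.power(2.0, -(dct_t - dct_c.mean())).rename("fold")
    return DdctResult(gene, reference, ddct, float(2.0**-ddct), per_sample)


def deg_filter(
    mat: pd.DataFrame,
    groups,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Differentially expressed genes by fold change and Welch t-test.

    Parameters
    ----------
    mat
        genes x samples of log2 intensity (no missing values).
    groups
        per-column labels, "control" / "treated", >= 2 samples each.
    fc_threshold
        linear-scale fold threshold; selection requires
        ``|log2 FC| >= log2(fc_threshold)`` (inclusive).
    p_threshold
        selection requires ``p < p_threshold`` (exclusive); no multiplicity
        correction is applied.

    Returns a DataFrame indexed by gene with columns log2fc, p, selected.
    """
    groups = np.asarray(groups)
    if groups.size != mat.shape[1]:
        raise InvalidParameterError("groups length must match the sample count")
    if mat.isna().any().any():
        raise InvalidParameterError("expression matrix contains missing values")
    t_idx = groups == GROUP_TREATED
    c_idx = groups == GROUP_CONTROL
    if t_idx.sum() < 2 or c_idx.sum() < 2:
        raise InvalidParameterError("each group needs >= 2 samples")
    treated = mat.loc[:, t_idx].to_numpy(dtype=float)
    control = mat.loc[:, c_idx].to_numpy(dtype=float)
    log2fc = treated.mean(axis=1) - control.mean(axis=1)
    _, pvals = stats.ttest_ind(treated, control, axis=1, equal_var=False)
    selected = (np.abs(log2fc) >= np.log2(fc_threshold)) & (pvals < p_threshold)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "selected": selected}, index=mat.index
    )


def read_ct_csv(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample,group,gene,ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"Ct CSV missing columns: {missing}")
    return df
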