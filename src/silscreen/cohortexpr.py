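"""Tumor-vs-normal expression relevance from a log2 cohort matrix:
anti-log group means, fold-change, two-tailed t-test, and the
fold-change / p-value selection rule.

No multiple-testing correction is applied here by design: selection
uses the raw p < alpha rule together with the fold-change floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _groups(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(matrix.columns, pd.MultiIndex) or \
            "group" not in (matrix.columns.names or []):
        raise ValueError(
            "cohort matrix needs MultiIndex columns (sample_id, group)")
    labels = matrix.columns.get_level_values("group").to_numpy()
    tumor = labels == "tumor"
    normal = labels == "normal"
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("need >= 2 samples in each of tumor and normal")
    unknown = set(labels) - {"tumor", "normal"}
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    return tumor, normal


def group_fold_change(matrix: pd.DataFrame,
                      equal_var: bool = True) -> pd.DataFrame:
    """Per-probe fold-change of anti-logged means (tumor / normal) with a
    two-tailed t-test on the anti-logged values.

    ``matrix`` holds log2 expression, probes x samples, with column
    levels (sample_id, group). ``equal_var=False`` switches to Welch.
    Zero-variance probes get p = NaN and are listed in
    ``attrs["undefined_t"]``.
    """
    if matrix.isna().any().any():
        raise ValueError("missing expression values are not accepted")
    tumor, normal = _groups(matrix)
    antilog = np.power(2.0, matrix.to_numpy(dtype=float))
    t_vals = antilog[:, tumor]
    n_vals = antilog[:, normal]
    fc = t_vals.mean(axis=1) / n_vals.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(t_vals, n_vals, axis=1, equal_var=equal_var).pvalue
    undefined = [str(matrix.index[i]) for i in np.where(np.isnan(p))[0]]
    out = pd.DataFrame({
        "probe": matrix.index.to_numpy(),
        "mean_tumor": t_vals.mean(axis=1),
        "mean_normal": n_vals.mean(axis=1),
        "fold_change": fc,
        "p": p,
    })
    out.attrs["undefined_t"] = undefined
    return out


def select_overexpressed(results: pd.DataFrame, fc_min: float = 1.5,
                         alpha: float = 0.05) -> list[str]:
    """Probes with fold_change >= fc_min (inclusive) and p < alpha
    (strict), input order preserved."""
    keep = results[(results["fold_change"] >= fc_min)
                   & (results["p"] < alpha)]
    return list(keep["probe"])


def gene_level(results: pd.DataFrame,
               probe_to_gene: dict | None = None) -> pd.DataFrame:
    """Collapse a per-probe table to genes, keeping each gene's
    max-fold-change probe. With no mapping, probes are genes."""
    tab = results.copy()
    tab["gene_id"] = (tab["probe"].map(probe_to_gene) if probe_to_gene
                      else tab["probe"])
    idx = tab.groupby("gene_id")["fold_change"].idxmax()
    return tab.loc[idx].reset_index(drop=True)


def write_cohort_tsv(matrix: pd.DataFrame, path) -> None:
    """Probes x samples TSV with a two-line header (sample id, group)."""
    matrix.to_csv(path, sep="\t")


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    df.columns = df.columns.set_names(["sample_id", "group"])
    return df
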