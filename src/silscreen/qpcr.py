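"""Relative-quantification (ddCt) knockdown arithmetic and filtering.

Replicate Ct wells are averaged on the Ct scale before any delta is
taken. Negative knockdown (expression increase) is reported as a
negative percent, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REFERENCE_TARGET = "PPIA"
TREATED = "treated"
CONTROL = "GL2"


@dataclass
class KnockdownResult:
    gene_id: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    mrna_remaining: float
    knockdown_pct: float
    passes: bool


def knockdown_percent(ct_records: pd.DataFrame, gene: str,
                      reference: str = REFERENCE_TARGET,
                      min_pct: float = 70.0) -> KnockdownResult:
    """Compute ddCt knockdown for one gene from its Ct records.

    Requires all four (condition x target) Ct groups: the gene and the
    reference in both the siRNA-treated and GL2-treated conditions.
    mRNA remaining is 2^-ddCt; knockdown% is (1 - 2^-ddCt) * 100.
    """
    sub = ct_records
    if "gene_id" in sub.columns:
        sub = sub[sub["gene_id"] == gene]
    means = sub.groupby(["condition", "target"])["ct"].mean()

    def _get(cond: str, target: str) -> float:
        try:
            return float(means.loc[(cond, target)])
        except KeyError:
            raise ValueError(
                f"{gene}: missing Ct for condition={cond!r}, target={target!r}"
            ) from None

    d_treated = _get(TREATED, gene) - _get(TREATED, reference)
    d_control = _get(CONTROL, gene) - _get(CONTROL, reference)
    ddct = d_treated - d_control
    remaining = 2.0 ** (-ddct)
    pct = (1.0 - remaining) * 100.0
    return KnockdownResult(
        gene_id=gene, delta_ct_treated=d_treated, delta_ct_control=d_control,
        delta_delta_ct=ddct, mrna_remaining=remaining, knockdown_pct=pct,
        passes=pct >= min_pct,
    )


def knockdown_table(ct_records: pd.DataFrame,
                    min_pct: float = 70.0) -> pd.DataFrame:
    """Per-gene knockdown results for every gene in a Ct table."""
    genes = [g for g in ct_records["gene_id"].unique()]
    rows = [knockdown_percent(ct_records, g, min_pct=min_pct).__dict__
            for g in genes]
    return pd.DataFrame(rows)


def filter_knockdown(results: pd.DataFrame,
                     min_pct: float = 70.0) -> list[str]:
    """Genes at or above the knockdown threshold, input order preserved."""
    if results["gene_id"].duplicated().any():
        raise ValueError("expected one knockdown result per gene")
    keep = results[results["knockdown_pct"] >= min_pct]
    return list(keep["gene_id"])
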