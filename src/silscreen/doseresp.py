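"""Four-parameter logistic dose-response fitting and the
expression-sensitivity rank correlation across a cell-line panel.

Model (GraphPad parameterization):

    Y(X) = bottom + (top - bottom) / (1 + 10^((log_ic50 - X) * hill_slope))

with X = log10(dose). A decreasing viability curve has hill_slope < 0
under this convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def four_pl(x, bottom, top, log_ic50, hill_slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


@dataclass
class DoseResponseFit:
    cell_line: str
    bottom: float
    top: float
    log_ic50: float
    hill_slope: float
    rss: float
    converged: bool
    dose_range: tuple = (np.nan, np.nan)  # (min, max) molar doses fitted

    def predict(self, dose):
        return four_pl(np.log10(dose), self.bottom, self.top,
                       self.log_ic50, self.hill_slope)


def fit_4pl(doses, viability, cell_line: str = "") -> DoseResponseFit:
    """Nonlinear least squares on (log10 dose, mean viability%) with
    multi-start initialization; replicate viabilities at the same dose
    are averaged first.
    """
    doses = np.asarray(doses, float)
    viability = np.asarray(viability, float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    if not np.isfinite(viability).all():
        raise ValueError("viabilities must be finite")
    tab = pd.DataFrame({"d": doses, "v": viability}).groupby("d")["v"].mean()
    if len(tab) < 5:
        raise ValueError(f"need >= 5 distinct doses, got {len(tab)}")
    x = np.log10(tab.index.to_numpy())
    y = tab.to_numpy()

    best = None
    for hill0 in (-1.0, 1.0):
        p0 = (y.min(), y.max(), float(np.median(x)), hill0)
        try:
            popt, _ = optimize.curve_fit(four_pl, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return DoseResponseFit(cell_line, np.nan, np.nan, np.nan, np.nan,
                               np.nan, converged=False,
                               dose_range=(tab.index.min(), tab.index.max()))
    popt, rss = best
    if popt[0] > popt[1]:
        # (bottom, top, l, h) and (top, bottom, l, -h) trace the same
        # curve; report the canonical orientation with top >= bottom
        popt = (popt[1], popt[0], popt[2], -popt[3])
    return DoseResponseFit(cell_line, *map(float, popt), rss=rss,
                           converged=True,
                           dose_range=(float(tab.index.min()),
                                       float(tab.index.max())))


def viability_at(fit: DoseResponseFit, dose: float) -> tuple[float, bool]:
    """Model viability at ``dose`` (molar); the second value flags
    extrapolation beyond the fitted dose range."""
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if not fit.converged:
        raise ValueError(f"fit for {fit.cell_line!r} did not converge")
    lo, hi = fit.dose_range
    extrapolated = not (lo <= dose <= hi)
    return float(fit.predict(dose)), extrapolated


def fit_panel(dose_response: pd.DataFrame,
              reference_dose: float) -> pd.Series:
    """Fit each cell line's curve and read viability% at the reference
    dose; returns a Series indexed by cell line."""
    out = {}
    for line, grp in dose_response.groupby("cell_line", sort=True):
        fit = fit_4pl(grp["dose_molar"], grp["viability_pct"], cell_line=line)
        out[line], _ = viability_at(fit, reference_dose)
    return pd.Series(out, name="viability_pct")


# ---------------------------------------------------------------------------
# Spearman correlation across the panel
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = rx[perms]  # (n!, n)
    ry_c = ry - ry.mean()
    px_c = permuted - rx.mean()
    denom = math.sqrt((px_c[0] ** 2).sum() * (ry_c ** 2).sum())
    rhos = (px_c @ ry_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties; two-sided p by exact
    permutation for n <= 9, t-approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= 9:
        p = _spearman_exact_p(x, y, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def spearman_panel(delta_ct: pd.DataFrame,
                   sensitivity: pd.Series) -> pd.DataFrame:
    """Correlate each gene's per-line delta-Ct against viability% at the
    reference dose. Genes with a constant vector are reported with NaN
    rho and listed in ``attrs["undefined"]``.
    """
    rows, undefined = [], []
    for gene, grp in delta_ct.groupby("gene_id", sort=True):
        merged = grp.set_index("cell_line")["delta_ct"].to_frame().join(
            sensitivity.rename("viability"), how="inner").dropna()
        if len(merged) < 4:
            raise ValueError(f"{gene}: < 4 cell lines with both values")
        try:
            rho, p = spearman_correlation(merged["delta_ct"],
                                          merged["viability"])
        except ValueError:
            rows.append({"gene_id": gene, "rho": np.nan, "p": np.nan,
                         "n": len(merged)})
            undefined.append(gene)
            continue
        rows.append({"gene_id": gene, "rho": rho, "p": p, "n": len(merged)})
    out = pd.DataFrame(rows)
    out.attrs["undefined"] = undefined
    return out


def select_predictive(correlations: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Genes with p < alpha, annotated with the association sign.

    Sign convention: delta-Ct is inversely related to expression and
    viability inversely related to sensitivity, so rho(delta-Ct,
    viability) < 0 means expression is *inversely* correlated with drug
    sensitivity (low expression -> more sensitive) — the actionable
    direction for a second-site target.
    """
    if correlations["p"].isna().any():
        raise ValueError("p missing for some genes")
    sel = correlations[correlations["p"] < alpha].copy()
    sel["sign"] = np.where(sel["rho"] < 0, "inverse", "direct")
    return sel.reset_index(drop=True)
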