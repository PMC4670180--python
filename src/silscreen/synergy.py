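"""Chou-Talalay median-effect / combination-index analysis for
constant-ratio drug combinations, plus the Bliss additivity expectation
for percent-scale fold-change readouts.

Median-effect model: fa/fu = (D/Dm)^m, fit by least squares on
log10(fa/fu) vs log10(D). The combination index uses the
mutually-exclusive (two-term) form by default:

    CI = d_a/Dx_a(fa) + d_b/Dx_b(fa),   Dx_i = Dm_i * (fa/fu)^(1/m_i)

CI < 1 synergy, = 1 additivity, > 1 antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: fa values outside this open interval are excluded from the
#: median-effect regression (log(fa/fu) diverges at the boundaries).
FA_BOUNDS = (0.01, 0.99)


@dataclass
class MedianEffectFit:
    agent_id: str
    dm: float
    m: float
    r2: float
    n_points_used: int
    n_points_excluded: int = 0

    def fa_at(self, dose: float) -> float:
        """Fraction affected predicted at ``dose``."""
        return 1.0 / (1.0 + (self.dm / dose) ** self.m)

    def dose_at(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` (the Dx of the CI)."""
        if not 0.0 < fa < 1.0:
            raise ValueError("fa must be in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class CIResult:
    ratio_label: str
    points: pd.DataFrame  # columns: dose_a, dose_b, fa, ci
    mean_ci: float
    sem_ci: float
    verdict: str
    ci_at_ed: dict = field(default_factory=dict)  # fa level -> CI


def median_effect_fit(doses, viability, agent_id: str = "") -> MedianEffectFit:
    """Fit Dm and m from (dose, fractional viability) pairs.

    fa = 1 - viability; points with fa outside ``FA_BOUNDS`` are
    excluded (and counted), and at least 3 usable points are required.
    """
    doses = np.asarray(doses, float)
    v = np.asarray(viability, float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    fa = 1.0 - v
    usable = (fa > FA_BOUNDS[0]) & (fa < FA_BOUNDS[1])
    if usable.sum() < 3:
        excluded = [(float(d), float(f)) for d, f in
                    zip(doses[~usable], fa[~usable])]
        raise ValueError(
            f"median-effect fit needs >= 3 points with fa in {FA_BOUNDS}; "
            f"excluded points (dose, fa): {excluded}"
        )
    d_u, fa_u = doses[usable], fa[usable]
    x = np.log10(d_u)
    y = np.log10(fa_u / (1.0 - fa_u))
    res = stats.linregress(x, y)
    m = float(res.slope)
    dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(agent_id=agent_id, dm=dm, m=m,
                           r2=float(res.rvalue ** 2),
                           n_points_used=int(usable.sum()),
                           n_points_excluded=int((~usable).sum()))


def ci_at_point(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                dose_a: float, dose_b: float, fa_observed: float,
                exclusive: bool = True) -> float:
    """Combination index of the pair (dose_a, dose_b) producing
    ``fa_observed``. The non-exclusive variant adds the cross term."""
    if not 0.0 < fa_observed < 1.0:
        raise ValueError("fa_observed must be in (0, 1)")
    dx_a = fit_a.dose_at(fa_observed)
    dx_b = fit_b.dose_at(fa_observed)
    ci = dose_a / dx_a + dose_b / dx_b
    if not exclusive:
        ci += (dose_a * dose_b) / (dx_a * dx_b)
    return float(ci)


def verdict_from_ci(mean_ci: float) -> str:
    if mean_ci < 1.0:
        return "synergistic"
    if mean_ci == 1.0:
        return "additive"
    return "antagonistic"


def constant_ratio_ci(single_a: pd.DataFrame, single_b: pd.DataFrame,
                      combo: pd.DataFrame, ratio: float,
                      ratio_label: str = "", exclusive: bool = True,
                      ed_levels=(0.50, 0.75, 0.90)) -> CIResult:
    """CI analysis of a constant-molar-ratio combination series.

    Inputs are (dose_molar, viability) tables; ``combo`` doses are
    *total* molar doses that decompose as total * (R/(R+1), 1/(R+1))
    with R = ``ratio`` (agent a : agent b). Per-point CIs use each
    observed combo point's own fa; ED-level CIs come from the combo's
    fitted median-effect curve.
    """
    def _fit(df: pd.DataFrame, name: str) -> MedianEffectFit:
        tab = df.groupby("dose_molar")["viability"].mean()
        try:
            return median_effect_fit(tab.index.to_numpy(), tab.to_numpy(),
                                     agent_id=name)
        except ValueError as err:
            raise ValueError(f"median-effect fit failed at stage "
                             f"{name!r}: {err}") from err

    fit_a = _fit(single_a, "agent_a")
    fit_b = _fit(single_b, "agent_b")
    fit_c = _fit(combo, "combination")

    frac_a = ratio / (ratio + 1.0)
    frac_b = 1.0 / (ratio + 1.0)
    tab = combo.groupby("dose_molar")["viability"].mean()
    rows = []
    for total, viab in tab.items():
        fa = 1.0 - viab
        if not FA_BOUNDS[0] < fa < FA_BOUNDS[1]:
            continue
        da, db = total * frac_a, total * frac_b
        rows.append({"dose_a": da, "dose_b": db, "fa": fa,
                     "ci": ci_at_point(fit_a, fit_b, da, db, fa,
                                       exclusive=exclusive)})
    points = pd.DataFrame(rows)
    if len(points) == 0:
        raise ValueError("no usable combination points (all fa out of bounds)")
    mean_ci = float(points["ci"].mean())
    sem_ci = (float(points["ci"].std(ddof=1) / math.sqrt(len(points)))
              if len(points) > 1 else 0.0)
    ci_at_ed = {}
    for fa in ed_levels:
        total = fit_c.dose_at(fa)
        ci_at_ed[fa] = ci_at_point(fit_a, fit_b, total * frac_a,
                                   total * frac_b, fa, exclusive=exclusive)
    return CIResult(ratio_label=ratio_label or f"{ratio:g}:1",
                    points=points, mean_ci=mean_ci, sem_ci=sem_ci,
                    verdict=verdict_from_ci(mean_ci), ci_at_ed=ci_at_ed)


def bliss_additivity(fc_a: float, fc_b: float) -> float:
    """Expected combined value on the percent-like fold-change scale:
    fc_a + fc_b * (100 - fc_a) / 100.

    Implemented literally on this scale (the convention of the
    flow-cytometry fold-change readout), not re-derived from classical
    Bliss probabilities. An observed combination value larger than this
    expectation indicates synergy.
    """
    if not (np.isfinite(fc_a) and np.isfinite(fc_b)):
        raise ValueError("fold-change inputs must be finite")
    return float(fc_a + fc_b * (100.0 - fc_a) / 100.0)


def is_bliss_synergistic(observed: float, fc_a: float, fc_b: float) -> bool:
    return observed > bliss_additivity(fc_a, fc_b)


def fold_change(treated: float, vehicle: float) -> float:
    """treated / vehicle; vehicle must be > 0."""
    if vehicle <= 0:
        raise ValueError("vehicle measurement must be > 0")
    return float(treated) / float(vehicle)
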