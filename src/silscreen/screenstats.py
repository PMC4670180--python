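"""Screen statistics: viability normalization, sensitization index,
empirical-Bayes moderated testing, BH FDR, hit selection, deconvolution
validation, specificity filtering, and plate QC.

Definitions
-----------
V   well FI divided by the mean FI of the same plate/arm/replicate's
    GL2 (negative-control) wells.
SI  mean V across drug-arm replicates divided by mean V across
    vehicle-arm replicates (ratio of means).

The moderated test follows the standard gene-wise hierarchical-variance
approach: per-gene residual variances are shrunk toward a common prior
estimated by matching the first two moments of log s^2 to its scaled-F
theory (digamma/trigamma inversion); the moderated t then has
d0 + d_g degrees of freedom. Testing is done on log2 V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


class HyperparameterError(RuntimeError):
    """Empirical-Bayes hyper-parameter estimation failed."""


# ---------------------------------------------------------------------------
# normalization and SI
# ---------------------------------------------------------------------------

def normalize_viability(measurements: pd.DataFrame,
                        library) -> pd.DataFrame:
    """Score every well against the GL2 mean of its own
    (plate, arm, replicate) group.

    ``measurements`` is a tidy FI table; ``library`` a
    :class:`~silscreen.screenio.SiRNALibrary`. Control wells are scored
    too. Returns the joined table with a ``V`` column.
    """
    platemap = library.platemap()
    joined = measurements.merge(platemap, on=["plate_id", "well_id"], how="inner")
    gl2 = joined[(joined["payload_type"] == "control")
                 & (joined["payload_id"] == "GL2")]
    keys = ["plate_id", "arm", "replicate"]
    counts = gl2.groupby(keys).size()
    if (counts < 2).any() or len(counts) < joined.groupby(keys).ngroups:
        raise ValueError("every (plate, arm, replicate) needs >= 2 GL2 wells")
    ref = gl2.groupby(keys)["fi"].mean().rename("gl2_mean")
    if (ref <= 0).any():
        raise ValueError("non-positive GL2 mean fluorescence")
    out = joined.merge(ref.reset_index(), on=keys)
    out["V"] = out["fi"] / out["gl2_mean"]
    out["gene_id"] = out["payload_id"].where(out["payload_type"] == "library")
    return out


def compute_si(v_table: pd.DataFrame, drug_arm: str, vehicle_arm: str,
               by: str = "gene_id") -> pd.DataFrame:
    """Per-unit SI: (mean V under drug) / (mean V under vehicle).

    ``by`` is "gene_id" for pooled designs or "sirna_ids" for
    deconvolution data. Units present in only one arm are excluded and
    listed in ``result.attrs["missing"]``.
    """
    lib = v_table[v_table["payload_type"] == "library"]
    means = (lib.groupby([by, "arm"])["V"].mean().unstack("arm"))
    for arm in (drug_arm, vehicle_arm):
        if arm not in means.columns:
            raise ValueError(f"arm {arm!r} absent from viability table")
    missing = means.index[means[[drug_arm, vehicle_arm]].isna().any(axis=1)]
    means = means.drop(index=missing)
    if (means[vehicle_arm] <= 0).any():
        raise ValueError("non-positive mean vehicle viability")
    out = pd.DataFrame({
        by: means.index,
        "v_drug": means[drug_arm].to_numpy(),
        "v_vehicle": means[vehicle_arm].to_numpy(),
        "SI": (means[drug_arm] / means[vehicle_arm]).to_numpy(),
    }).reset_index(drop=True)
    out.attrs["missing"] = list(missing)
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderated test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0_sq) from gene-wise variances by moment matching
    of log s^2 against its theoretical scaled-F distribution.

    Returns d0 = inf with the bias-corrected geometric-mean variance when
    the observed spread of log s^2 is no wider than sampling alone
    explains (complete shrinkage).
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        raise HyperparameterError(
            "all gene-wise variances are zero; cannot estimate the "
            "variance prior (is the input noiseless or degenerate?)"
        )
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise HyperparameterError("need >= 2 genes with positive variance")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # spread of log s^2 fully explained by sampling: complete pooling,
        # for which the arithmetic mean of s^2 is the efficient estimator
        d0 = np.inf
        s0_sq = s2.mean()
    return float(d0), float(s0_sq)


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame
    d0: float
    s0_sq: float


def moderated_test(logv: pd.DataFrame, drug_arm: str, vehicle_arm: str,
                   value: str = "logV", by: str = "gene_id",
                   prior_df: float | None = None) -> ModeratedTestResult:
    """Two-arm moderated t-test per gene on replicate log2 viabilities.

    ``logv`` has columns (by, arm, replicate, value). ``prior_df``
    overrides the estimated d0 (0 gives the ordinary two-sample t;
    numpy.inf gives complete pooling to s0^2).
    """
    sub = logv[logv["arm"].isin([drug_arm, vehicle_arm])]
    genes, eff, s2s, dfs, n1s, n2s = [], [], [], [], [], []
    for gene, grp in sub.groupby(by, sort=True):
        a = grp.loc[grp["arm"] == drug_arm, value].to_numpy(float)
        b = grp.loc[grp["arm"] == vehicle_arm, value].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{gene}: need >= 2 replicates per arm")
        n1, n2 = len(a), len(b)
        df_g = n1 + n2 - 2
        pooled = (a.var(ddof=1) * (n1 - 1) + b.var(ddof=1) * (n2 - 1)) / df_g
        genes.append(gene)
        eff.append(a.mean() - b.mean())
        s2s.append(pooled)
        dfs.append(df_g)
        n1s.append(n1)
        n2s.append(n2)
    if len(genes) < 2:
        raise ValueError("moderated test needs a gene ensemble (>= 2 genes)")

    eff = np.array(eff)
    s2 = np.array(s2s, float)
    df_g = np.array(dfs, float)
    n1 = np.array(n1s, float)
    n2 = np.array(n2s, float)

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_g)
    else:
        d0 = float(prior_df)
        if d0 == 0:
            s0_sq = np.nan  # unused: no shrinkage
        elif np.isinf(d0):
            s0_sq = float(s2.mean())  # complete pooling
        else:
            s0_sq = estimate_variance_prior(s2, df_g)[1]

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.full_like(df_g, np.inf)
    elif d0 == 0:
        s2_tilde = s2
        df_total = df_g
    else:
        s2_tilde = (d0 * s0_sq + df_g * s2) / (d0 + df_g)
        df_total = d0 + df_g
    if d0 > 0:
        # cap at the ensemble's total residual df (no information beyond it)
        df_total = np.minimum(df_total, df_g.sum())

    with np.errstate(divide="ignore"):
        t_mod = eff / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame({
        by: genes, "log_effect": eff, "s2": s2, "df": df_g,
        "s2_tilde": s2_tilde, "t_mod": t_mod, "p": p,
    })
    table["q"] = bh_fdr(table["p"].to_numpy())
    return ModeratedTestResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# sensitization analysis (SI + moderated test combined)
# ---------------------------------------------------------------------------

def sensitization_analysis(v_table: pd.DataFrame, drug_arm: str,
                           vehicle_arm: str, by: str = "gene_id",
                           prior_df: float | None = None) -> ModeratedTestResult:
    """SI plus moderated statistics per gene from a normalized V table."""
    si = compute_si(v_table, drug_arm, vehicle_arm, by=by)
    lib = v_table[v_table["payload_type"] == "library"].copy()
    lib["logV"] = np.log2(lib["V"])
    res = moderated_test(lib, drug_arm, vehicle_arm, value="logV", by=by,
                         prior_df=prior_df)
    res.table = si.merge(res.table, on=by)
    return res


def select_primary_hits(results: pd.DataFrame, si_max: float = 0.85,
                        fdr_max: float = 0.10) -> list[str]:
    """Genes with SI <= si_max and q < fdr_max, sorted by SI ascending."""
    needed = {"gene_id", "SI", "q"}
    if not needed.issubset(results.columns):
        raise ValueError(f"results must carry columns {sorted(needed)}")
    hits = results[(results["SI"] <= si_max) & (results["q"] < fdr_max)]
    return list(hits.sort_values(["SI", "gene_id"], kind="stable")["gene_id"])


# ---------------------------------------------------------------------------
# deconvolution and specificity
# ---------------------------------------------------------------------------

def per_sirna_si(v_table: pd.DataFrame, drug_arm: str,
                 vehicle_arm: str) -> pd.DataFrame:
    """Average SI per individual siRNA across biological replicates.

    Each siRNA's SI is the ratio of its mean V across the drug-arm
    replicates to its mean V across the vehicle-arm replicates.
    """
    si = compute_si(v_table, drug_arm, vehicle_arm, by="sirna_ids")
    anno = (v_table[v_table["payload_type"] == "library"]
            [["sirna_ids", "gene_id"]].drop_duplicates())
    return si.merge(anno, on="sirna_ids").rename(columns={"sirna_ids": "sirna_id"})


def deconv_validate(per_sirna: pd.DataFrame, si_max: float = 0.85,
                    min_active: int = 2,
                    singles_per_gene: int = 4) -> pd.DataFrame:
    """Apply the >= min_active-of-singles rule and pick each gene's two
    lowest-SI siRNAs.

    Returns one row per gene: gene_id, n_active, validated, best_two
    (tuple of sirna_ids, empty for invalid genes), plus
    ``attrs["incomplete"]`` naming genes with missing siRNA values
    (missing siRNAs count as inactive).
    """
    rows, incomplete = [], []
    for gene, grp in per_sirna.groupby("gene_id", sort=True):
        grp = grp.dropna(subset=["SI"])
        if len(grp) == 0:
            rows.append({"gene_id": gene, "n_active": 0, "validated": False,
                         "best_two": ()})
            incomplete.append(gene)
            continue
        if len(grp) < singles_per_gene:
            incomplete.append(gene)
        n_active = int((grp["SI"] <= si_max).sum())
        validated = n_active >= min_active
        best = (grp.sort_values(["SI", "sirna_id"], kind="stable")
                .head(2)["sirna_id"])
        rows.append({"gene_id": gene, "n_active": n_active,
                     "validated": validated,
                     "best_two": tuple(best) if validated else ()})
    out = pd.DataFrame(rows)
    out.attrs["incomplete"] = incomplete
    return out


def specificity_filter(target_hits: list[str], counter_si: pd.DataFrame,
                       si_max: float = 0.85) -> tuple[list[str], list[str]]:
    """Split hits into (specific, common) by counter-drug SI <= si_max."""
    si_map = dict(zip(counter_si["gene_id"], counter_si["SI"]))
    missing = [g for g in target_hits if g not in si_map]
    if missing:
        raise ValueError(
            f"hits missing a counter-drug SI: {', '.join(missing)}")
    common = [g for g in target_hits if si_map[g] <= si_max]
    specific = [g for g in target_hits if g not in set(common)]
    return specific, common


# ---------------------------------------------------------------------------
# plate QC
# ---------------------------------------------------------------------------

def zprime(v_table: pd.DataFrame, positive: str = "PLK1",
           negative: str = "GL2") -> pd.DataFrame:
    """Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| per
    (plate, arm, replicate); identical control means yield NaN and
    passed=False."""
    ctl = v_table[v_table["payload_type"] == "control"]
    keys = ["plate_id", "arm", "replicate"]
    rows = []
    for key, grp in ctl.groupby(keys):
        pos = grp.loc[grp["payload_id"] == positive, "V"]
        neg = grp.loc[grp["payload_id"] == negative, "V"]
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError(
                f"{dict(zip(keys, key))}: need >= 2 wells per control")
        sep = abs(pos.mean() - neg.mean())
        if sep == 0:
            z = np.nan
        else:
            z = 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep
        rows.append(dict(zip(keys, key)) | {"zprime": z,
                                            "passed": bool(z == z and z > 0)})
    return pd.DataFrame(rows)
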