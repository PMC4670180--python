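"""End-to-end funnel orchestration: synthetic screen -> primary hits ->
deconvolution -> knockdown confirmation -> counter-drug specificity ->
expression-sensitivity correlation -> cohort overexpression -> final
candidates.

Final-candidate rule (a documented interpretation of the narrative
selection): (cohort-overexpressed specific hits minus the configured
direct-drug-target exclusion list) union (inverse-correlated
panel-predictive genes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from . import __version__, cohortexpr, doseresp, qpcr, screenstats, simdata
from .simdata import DASATINIB, IMATINIB, VEHICLE, FunnelFixture

log = logging.getLogger(__name__)

# per-stage RNG seed offsets from the master seed
_STAGE_SEEDS = {"primary": 0, "deconv": 1, "qpcr": 2, "pair": 3,
                "panel_dr": 4, "panel_expr": 5, "cohort": 6}


@dataclass
class FunnelConfig:
    fixture: str = "funnel_default"
    seed: int = simdata.DEFAULT_SEED
    si_max: float = 0.85
    fdr_max: float = 0.10
    min_active_sirnas: int = 2
    min_knockdown_pct: float = 70.0
    alpha_correlation: float = 0.05
    cohort_fc_min: float = 1.5
    cohort_alpha: float = 0.05
    primary_replicates: int = 2
    deconv_replicates: int = 3
    pair_replicates: int = 3
    exclusions: list = field(default_factory=list)  # empty -> fixture default
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        import yaml

        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
        return cls(**raw)


@dataclass
class FunnelReport:
    counts: dict
    primary_hits: list
    validated: list
    confirmed: list
    specific: list
    common: list
    predictive: list       # (gene, sign) pairs
    overexpressed: list
    final_candidates: list
    evidence: dict         # gene -> list of evidence flags
    exclusions_applied: list
    config: dict
    seed: int
    version: str = __version__
    candidate_rule: str = (
        "(cohort-overexpressed specific hits minus direct-drug-target "
        "exclusions) union inverse-correlated predictive genes "
        "[documented interpretation]"
    )

    def validate_monotone(self) -> None:
        c = self.counts
        chain = [c["library"], c["primary_hits"], c["validated"],
                 c["confirmed"], c["specific"]]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise AssertionError(f"funnel counts not non-increasing: {chain}")
        for gene in self.final_candidates:
            if not self.evidence.get(gene):
                raise AssertionError(f"candidate {gene} carries no evidence")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Funnel report", "",
                 f"seed: {self.seed}  |  version: {self.version}", "",
                 "| stage | genes |", "|---|---|"]
        for stage, n in self.counts.items():
            lines.append(f"| {stage} | {n} |")
        lines += ["", f"Final candidates: {', '.join(self.final_candidates)}",
                  f"Excluded as direct drug targets: "
                  f"{', '.join(self.exclusions_applied) or 'none'}",
                  "", f"Candidate rule: {self.candidate_rule}"]
        return "\n".join(lines) + "\n"


def _stage_noise(fixture: FunnelFixture, stage: str) -> simdata.NoiseModel:
    return dataclasses.replace(
        fixture.noise, seed=fixture.noise.seed * 101 + _STAGE_SEEDS[stage])


def _sirna_index(sirna_id: str) -> int:
    return int(sirna_id.rsplit("_s", 1)[1]) - 1


def run_funnel(config: FunnelConfig) -> FunnelReport:
    """Run the whole funnel on a packaged fixture; returns the report and
    (if ``config.out_dir`` is set) writes all intermediate tables."""
    fixture = simdata.funnel_fixture(config.fixture)
    fixture = fixture.with_seed(config.seed)
    exclusions = config.exclusions or fixture.direct_target_exclusions
    out_dir = pathlib.Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}

    # --- stage 1: primary pooled screen ------------------------------------
    library = simdata.build_library(fixture.library_spec, fixture.gene_names)
    meas = simdata.simulate_screen(
        library, fixture.truth, [VEHICLE, DASATINIB],
        replicates_per_arm=config.primary_replicates,
        noise=_stage_noise(fixture, "primary"))
    v = screenstats.normalize_viability(meas, library)
    primary = screenstats.sensitization_analysis(v, DASATINIB, VEHICLE)
    hits = screenstats.select_primary_hits(primary.table, config.si_max,
                                           config.fdr_max)
    tables["primary_results"] = primary.table
    tables["plate_qc"] = screenstats.zprime(v)
    log.info("primary screen: %d/%d genes pass SI<=%.2f & FDR<%.2f",
             len(hits), len(fixture.gene_names), config.si_max, config.fdr_max)

    validated: list[str] = []
    confirmed: list[str] = []
    specific: list[str] = []
    common: list[str] = []
    predictive = pd.DataFrame(columns=["gene_id", "rho", "p", "n", "sign"])
    overexpressed: list[str] = []
    best_two: dict[str, tuple[int, int]] = {}

    # --- stage 2: deconvolution -------------------------------------------
    if hits:
        deconv_lib = simdata.build_deconv_library(hits, fixture.library_spec)
        meas_d = simdata.simulate_screen(
            deconv_lib, fixture.truth, [VEHICLE, DASATINIB],
            replicates_per_arm=config.deconv_replicates,
            noise=_stage_noise(fixture, "deconv"))
        v_d = screenstats.normalize_viability(meas_d, deconv_lib)
        per_sirna = screenstats.per_sirna_si(v_d, DASATINIB, VEHICLE)
        deconv = screenstats.deconv_validate(
            per_sirna, config.si_max, config.min_active_sirnas,
            fixture.library_spec.singles_per_gene)
        validated = sorted(deconv.loc[deconv["validated"], "gene_id"])
        best_two = {
            row["gene_id"]: tuple(_sirna_index(s) for s in row["best_two"])
            for _, row in deconv.iterrows() if row["validated"]
        }
        tables["deconvolution"] = deconv.drop(columns="best_two").assign(
            best_two=[";".join(b) for b in deconv["best_two"]])
        log.info("deconvolution: %d validated, %d removed",
                 len(validated), len(hits) - len(validated))

    # --- stage 3: knockdown confirmation ----------------------------------
    if validated:
        qc = fixture.qpcr_config
        ct = simdata.simulate_qpcr(
            validated, fixture.truth, ct_ref=qc["ct_ref"],
            noise_sd=qc["noise_sd"],
            n_replicate_wells=qc["n_replicate_wells"],
            seed=fixture.noise.seed * 101 + _STAGE_SEEDS["qpcr"])
        kd = qpcr.knockdown_table(ct, min_pct=config.min_knockdown_pct)
        confirmed = qpcr.filter_knockdown(kd, config.min_knockdown_pct)
        tables["knockdown"] = kd
        log.info("knockdown filter: %d/%d genes >= %.0f%%",
                 len(confirmed), len(validated), config.min_knockdown_pct)

    # --- stage 4: counter-drug specificity ---------------------------------
    if confirmed:
        pair_lib = simdata.build_pair_library(
            {g: best_two[g] for g in confirmed}, fixture.library_spec)
        meas_p = simdata.simulate_screen(
            pair_lib, fixture.truth, [VEHICLE, DASATINIB, IMATINIB],
            replicates_per_arm=config.pair_replicates,
            noise=_stage_noise(fixture, "pair"))
        v_p = screenstats.normalize_viability(meas_p, pair_lib)
        si_das = screenstats.compute_si(v_p, DASATINIB, VEHICLE)
        si_ima = screenstats.compute_si(v_p, IMATINIB, VEHICLE)
        specific, common = screenstats.specificity_filter(
            confirmed, si_ima.rename(columns={"gene_id": "gene_id"}),
            config.si_max)
        tables["specificity"] = si_das.merge(
            si_ima, on="gene_id", suffixes=("_dasatinib", "_imatinib"))
        log.info("specificity: %d common with counter-drug, %d specific",
                 len(common), len(specific))

    # --- stage 5: expression-sensitivity panel -----------------------------
    if specific:
        dr = simdata.simulate_dose_response(
            list(fixture.panel_params), fixture.panel_params,
            fixture.panel_dose_series, replicate_count=3, noise_sd=2.0,
            seed=fixture.noise.seed * 101 + _STAGE_SEEDS["panel_dr"])
        sensitivity = doseresp.fit_panel(dr, fixture.reference_dose)
        expr = simdata.simulate_expression_panel(
            specific, fixture.truth, sensitivity,
            seed=fixture.noise.seed * 101 + _STAGE_SEEDS["panel_expr"])
        correlations = doseresp.spearman_panel(expr, sensitivity)
        predictive = doseresp.select_predictive(correlations,
                                                config.alpha_correlation)
        tables["panel_correlations"] = correlations
        log.info("panel: %d predictive genes (p < %.2f)",
                 len(predictive), config.alpha_correlation)

    # --- stage 6: cohort overexpression ------------------------------------
    if specific:
        cc = fixture.cohort_config
        matrix = simdata.simulate_cohort(
            specific, fixture.truth, seed=fixture.noise.seed * 101
            + _STAGE_SEEDS["cohort"], **cc)
        cohort = cohortexpr.group_fold_change(matrix)
        overexpressed = cohortexpr.select_overexpressed(
            cohort, config.cohort_fc_min, config.cohort_alpha)
        tables["cohort"] = cohort
        log.info("cohort: %d overexpressed (fc >= %.1f, p < %.2f)",
                 len(overexpressed), config.cohort_fc_min, config.cohort_alpha)

    # --- final candidates ---------------------------------------------------
    inverse = list(predictive.loc[predictive["sign"] == "inverse", "gene_id"])
    excluded = sorted(set(overexpressed) & set(exclusions))
    final = sorted((set(overexpressed) - set(exclusions)) | set(inverse))
    evidence: dict[str, list] = {}
    for g in final:
        flags = []
        if g in overexpressed:
            flags.append("cohort-overexpressed")
        if g in inverse:
            flags.append("inverse-predictive")
        evidence[g] = flags

    report = FunnelReport(
        counts={
            "library": len(fixture.gene_names),
            "primary_hits": len(hits),
            "deconv_removed": len(hits) - len(validated),
            "validated": len(validated),
            "confirmed": len(confirmed),
            "counter_drug_common": len(common),
            "specific": len(specific),
            "panel_predictive": len(predictive),
            "cohort_overexpressed": len(overexpressed),
            "final_candidates": len(final),
        },
        primary_hits=hits, validated=validated, confirmed=confirmed,
        specific=specific, common=common,
        predictive=list(zip(predictive["gene_id"], predictive["sign"])),
        overexpressed=overexpressed, final_candidates=final,
        evidence=evidence, exclusions_applied=excluded,
        config=dataclasses.asdict(config), seed=config.seed,
    )
    report.validate_monotone()

    if out_dir:
        from .screenio import write_results

        for name, tab in tables.items():
            if len(tab):
                write_results(tab, out_dir / f"{name}.csv")
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.md").write_text(report.to_markdown())
    return report
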