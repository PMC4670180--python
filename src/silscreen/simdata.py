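"""Synthetic screen, qPCR, dose-response, and cohort-expression generators.

Every generator plants a known :class:`GroundTruth` and is deterministic
for a fixed seed. The fluorescence model is multiplicative:

    FI = baseline * plate_effect * lethality(payload) * drug_factor * noise

where the drug factor of a library well under drug is the uniform
sub-lethal base effect times the planted per-gene sensitization effect,
so the base effect cancels out of the sensitization index downstream.
One RNG stream is derived per plate from the master seed, so editing one
plate's layout never perturbs another plate's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import screenio
from .doseresp import four_pl
from .screenio import SiRNALibrary, inner_wells, outer_wells

VEHICLE = "vehicle"
DASATINIB = "dasatinib"
IMATINIB = "imatinib"
KNOWN_ARMS = (VEHICLE, DASATINIB, IMATINIB)

#: Viability factor the sub-lethal drug dose exerts on control cells
#: (IC10-15 range); applied uniformly so it cancels out of the SI.
DRUG_BASE_EFFECT = 0.88
#: Residual viability of the strong-kill positive-control wells.
PLK1_LETHALITY = 0.05


@dataclass(frozen=True)
class LibrarySpec:
    """Layout parameters for an arrayed 96-well siRNA library."""

    n_genes: int
    duplexes_per_gene_pooled: int = 2
    singles_per_gene: int = 4
    library_wells_per_plate: int = 60
    controls_per_plate: dict = field(
        default_factory=lambda: {"GL2": 4, "PLK1": 4}
    )

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        n_ctl = sum(self.controls_per_plate.values())
        if not 1 <= self.library_wells_per_plate <= 96 - n_ctl:
            raise ValueError(
                f"library_wells_per_plate must be in [1, {96 - n_ctl}] "
                f"given {n_ctl} control wells per plate"
            )
        if n_ctl > 36:
            raise ValueError("control wells exceed the 36 border wells")


@dataclass
class GeneTruth:
    """Planted effects for one gene. All si_* values are viability ratios
    under drug relative to vehicle (1.0 = no sensitization)."""

    si_true_pooled: float = 1.0
    si_true_singles: tuple = (1.0, 1.0, 1.0, 1.0)
    off_target_pool_only: bool = False
    knockdown_fraction: float = 0.0
    imatinib_si_true: float = 1.0
    expression_sensitivity_rho: int = 0  # sign: -1 inverse, +1 direct, 0 null
    cohort_log2_shift: float = 0.0

    def __post_init__(self):
        if self.si_true_pooled <= 0 or any(s <= 0 for s in self.si_true_singles):
            raise ValueError("si_true values must be > 0")
        if not 0.0 <= self.knockdown_fraction <= 1.0:
            raise ValueError("knockdown_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Mapping gene -> planted effects, JSON round-trippable."""

    genes: dict  # gene_id -> GeneTruth

    def __getitem__(self, gene: str) -> GeneTruth:
        return self.genes[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def to_json(self) -> str:
        payload = {g: asdict(t) for g, t in self.genes.items()}
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(genes={
            g: GeneTruth(**{**d, "si_true_singles": tuple(d["si_true_singles"])})
            for g, d in raw.items()
        })


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise settings for the plate simulator."""

    fi_baseline: float = 40_000.0
    plate_effect_sd: float = 0.05
    well_cv: float = 0.03
    edge_effect: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.plate_effect_sd < 0 or self.well_cv < 0:
            raise ValueError("noise sigmas must be >= 0")


# ---------------------------------------------------------------------------
# library construction
# ---------------------------------------------------------------------------

def _assign_controls(spec: LibrarySpec, plate_ids: list[int]) -> pd.DataFrame:
    """Fixed control positions in the border wells, identical on every plate."""
    border = outer_wells()
    rows = []
    cursor = 0
    for name, count in spec.controls_per_plate.items():
        wells = border[cursor:cursor + count]
        cursor += count
        for p in plate_ids:
            rows += [{"control_name": name, "plate_id": p, "well_id": w}
                     for w in wells]
    return pd.DataFrame(rows, columns=["control_name", "plate_id", "well_id"])


def _layout(n_wells_needed: int, spec: LibrarySpec):
    """Deterministic (plate, well) sequence filling the inner wells in order."""
    per_plate = spec.library_wells_per_plate
    inner = inner_wells()[:per_plate]
    n_plates = math.ceil(n_wells_needed / per_plate)
    for i in range(n_wells_needed):
        yield i // per_plate + 1, inner[i % per_plate]
    # caller recomputes n_plates; generator kept simple
    return n_plates


def build_library(spec: LibrarySpec, gene_names: list[str]) -> SiRNALibrary:
    """Arrange one pooled well per gene (``duplexes_per_gene_pooled``
    duplexes each) into consecutive plates."""
    if len(gene_names) != spec.n_genes:
        raise ValueError(
            f"gene_names has {len(gene_names)} entries, spec.n_genes={spec.n_genes}"
        )
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("gene-name collision in library input")
    n_plates = math.ceil(spec.n_genes / spec.library_wells_per_plate)
    placements = _layout(spec.n_genes, spec)
    rows = []
    for gene, (plate, well) in zip(gene_names, placements):
        sirnas = ";".join(
            f"{gene}_s{i + 1}" for i in range(spec.duplexes_per_gene_pooled)
        )
        rows.append({"gene_id": gene, "sirna_ids": sirnas, "plate_id": plate,
                     "well_id": well, "pooled": True, "si_key": "pooled"})
    wells = pd.DataFrame(rows)
    controls = _assign_controls(spec, list(range(1, n_plates + 1)))
    return SiRNALibrary(wells=wells, controls=controls, n_plates=n_plates,
                        meta={"design": "primary-pooled"})


def build_deconv_library(hit_genes: list[str], spec: LibrarySpec) -> SiRNALibrary:
    """One well per individual siRNA (``singles_per_gene`` per gene)."""
    if not hit_genes:
        raise ValueError("hit_genes must be nonempty")
    if len(set(hit_genes)) != len(hit_genes):
        raise ValueError("duplicate hit genes in deconvolution input")
    k = spec.singles_per_gene
    n_wells = len(hit_genes) * k
    n_plates = math.ceil(n_wells / spec.library_wells_per_plate)
    placements = _layout(n_wells, spec)
    rows = []
    for gene in hit_genes:
        for i in range(k):
            plate, well = next(placements)
            rows.append({"gene_id": gene, "sirna_ids": f"{gene}_s{i + 1}",
                         "plate_id": plate, "well_id": well, "pooled": False,
                         "si_key": f"single:{i}"})
    wells = pd.DataFrame(rows)
    controls = _assign_controls(spec, list(range(1, n_plates + 1)))
    return SiRNALibrary(wells=wells, controls=controls, n_plates=n_plates,
                        meta={"design": "deconvolution-singles"})


def build_pair_library(best_two: dict, spec: LibrarySpec) -> SiRNALibrary:
    """Best-two pooled wells: ``best_two`` maps gene -> (i, j) zero-based
    indices of its two selected individual siRNAs."""
    if not best_two:
        raise ValueError("best_two must be nonempty")
    genes = list(best_two)
    n_plates = math.ceil(len(genes) / spec.library_wells_per_plate)
    placements = _layout(len(genes), spec)
    rows = []
    for gene, (plate, well) in zip(genes, placements):
        i, j = sorted(best_two[gene])
        rows.append({"gene_id": gene,
                     "sirna_ids": f"{gene}_s{i + 1};{gene}_s{j + 1}",
                     "plate_id": plate, "well_id": well, "pooled": True,
                     "si_key": f"pair:{i},{j}"})
    wells = pd.DataFrame(rows)
    controls = _assign_controls(spec, list(range(1, n_plates + 1)))
    return SiRNALibrary(wells=wells, controls=controls, n_plates=n_plates,
                        meta={"design": "best-two-pool"})


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

def _si_factor(truth: GroundTruth, gene: str, si_key: str, arm: str) -> float:
    if arm == VEHICLE:
        return 1.0
    t = truth[gene]
    if arm == IMATINIB:
        return t.imatinib_si_true
    if si_key == "pooled":
        return t.si_true_pooled
    if si_key.startswith("single:"):
        return t.si_true_singles[int(si_key.split(":")[1])]
    if si_key.startswith("pair:"):
        i, j = (int(x) for x in si_key.split(":")[1].split(","))
        return (t.si_true_singles[i] + t.si_true_singles[j]) / 2.0
    raise ValueError(f"unknown si_key {si_key!r}")


def simulate_screen(
    library: SiRNALibrary,
    truth: GroundTruth,
    arms: list[str],
    replicates_per_arm: int,
    noise: NoiseModel,
    drug_base_effect: float = DRUG_BASE_EFFECT,
    plk1_lethality: float = PLK1_LETHALITY,
) -> pd.DataFrame:
    """Simulate plate fluorescence for every (arm, replicate) copy.

    Returns a tidy measurement table (plate_id, well_id, arm, replicate,
    fi) with the ground truth withheld.
    """
    bad = [a for a in arms if a not in KNOWN_ARMS]
    if bad:
        raise ValueError(f"unknown treatment arm(s): {bad}; known: {KNOWN_ARMS}")
    if replicates_per_arm < 1:
        raise ValueError("replicates_per_arm must be >= 1")
    missing = [g for g in library.genes if g not in truth]
    if missing:
        raise ValueError(f"genes missing from ground truth: {missing[:5]}")

    platemap = library.platemap()
    out_rows = []
    for plate_idx, plate_id in enumerate(sorted(platemap["plate_id"].unique())):
        rng = np.random.default_rng([int(noise.seed), int(plate_idx)])
        pw = platemap[platemap["plate_id"] == plate_id].sort_values("well_id")
        for arm in arms:
            for rep in range(1, replicates_per_arm + 1):
                plate_effect = (
                    rng.lognormal(0.0, noise.plate_effect_sd)
                    if noise.plate_effect_sd > 0 else 1.0
                )
                n = len(pw)
                well_noise = (
                    rng.lognormal(0.0, noise.well_cv, size=n)
                    if noise.well_cv > 0 else np.ones(n)
                )
                for (_, row), wn in zip(pw.iterrows(), well_noise):
                    if row["payload_type"] == "library":
                        lethality = 1.0
                        si = _si_factor(truth, row["payload_id"],
                                        row["si_key"], arm)
                    else:  # control or empty (untransfected) well
                        lethality = (plk1_lethality
                                     if row["payload_id"] == "PLK1" else 1.0)
                        si = 1.0
                    drug = 1.0 if arm == VEHICLE else drug_base_effect * si
                    fi = noise.fi_baseline * plate_effect * lethality * drug * wn
                    if noise.edge_effect != 1.0 and screenio.is_edge_well(row["well_id"]):
                        fi *= noise.edge_effect
                    out_rows.append((plate_id, row["well_id"], arm, rep, fi))
    return pd.DataFrame(out_rows, columns=screenio.MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    genes: list[str],
    truth: GroundTruth,
    ct_ref: float = 25.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_replicate_wells: int = 3,
    ct_ppia: float = 20.0,
) -> pd.DataFrame:
    """Generate Ct records so that E[2^-ddCt] matches the planted
    remaining-mRNA fraction (1 - knockdown_fraction) per gene.

    Returns rows (gene_id, sample_id, condition, target, ct) with
    conditions "treated" (gene-siRNA) and "GL2" and targets the gene
    itself plus the "PPIA" reference.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        kd = truth[gene].knockdown_fraction
        if kd >= 1.0:
            raise ValueError(
                f"{gene}: knockdown_fraction=1 implies infinite Ct")
        ddct = -math.log2(1.0 - kd)
        means = {
            ("treated", gene): ct_ref + ddct,
            ("treated", "PPIA"): ct_ppia,
            ("GL2", gene): ct_ref,
            ("GL2", "PPIA"): ct_ppia,
        }
        for (cond, target), mu in means.items():
            for w in range(1, n_replicate_wells + 1):
                ct = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append({"gene_id": gene, "sample_id": f"{gene}_{cond}_w{w}",
                             "condition": cond, "target": target, "ct": ct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose-response simulation
# ---------------------------------------------------------------------------

def default_dose_series(top_dose: float = 1e-6, n: int = 8,
                        fold: float = 2.5) -> np.ndarray:
    """Serial dilution series, highest dose first."""
    return top_dose / fold ** np.arange(n)


def simulate_dose_response(
    cell_lines: list[str],
    fit_params: dict,
    dose_series,
    replicate_count: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent-viability wells around each line's 4PL curve.

    ``fit_params`` maps cell line -> (bottom, top, log_ic50, hill_slope).
    """
    doses = np.asarray(dose_series, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    if len(np.unique(doses)) != len(doses):
        raise ValueError("doses must be distinct")
    rng = np.random.default_rng(seed)
    rows = []
    for line in cell_lines:
        bottom, top, log_ic50, hill = fit_params[line]
        mu = four_pl(np.log10(doses), bottom, top, log_ic50, hill)
        for dose, m in zip(doses, mu):
            for rep in range(1, replicate_count + 1):
                v = m + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append({"cell_line": line, "dose_molar": dose,
                             "replicate": rep, "viability_pct": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression panel simulation (delta-Ct vs sensitivity)
# ---------------------------------------------------------------------------

#: Fixed low-correlation rank pattern used for unplanted genes; its
#: Spearman rho against the sensitivity order is ~0.21 (p ~ 0.66, n=7).
_NULL_PATTERN = np.array([4, 1, 6, 3, 7, 2, 5], dtype=float)


def simulate_expression_panel(
    genes: list[str],
    truth: GroundTruth,
    sensitivity: "pd.Series",
    noise_sd: float = 0.05,
    seed: int = 0,
    step: float = 0.5,
) -> pd.DataFrame:
    """Per-gene delta-Ct values over a cell-line panel.

    ``sensitivity`` is viability%-at-reference-dose indexed by cell line.
    A gene planted with expression_sensitivity_rho = -1 gets delta-Ct
    perfectly anti-monotone in viability (low expression in the most
    sensitive lines), +1 perfectly monotone, and 0 a fixed scrambled
    pattern whose rank correlation is small. Noise is small relative to
    ``step`` so ranks are stable across seeds.
    """
    rng = np.random.default_rng(seed)
    lines = list(sensitivity.index)
    viab_rank = sensitivity.rank().to_numpy()
    rows = []
    for gene in genes:
        sign = truth[gene].expression_sensitivity_rho
        if sign > 0:
            base = 10.0 + step * viab_rank
        elif sign < 0:
            base = 10.0 - step * viab_rank
        else:
            pattern = _NULL_PATTERN[np.argsort(viab_rank)] if len(lines) == 7 \
                else rng.permutation(len(lines)) + 1.0
            base = 10.0 + step * pattern
        noise = rng.normal(0.0, noise_sd, size=len(lines)) if noise_sd > 0 else 0.0
        for line, dct in zip(lines, base + noise):
            rows.append({"gene_id": gene, "cell_line": line, "delta_ct": dct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort expression simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    probes: list[str],
    truth: GroundTruth,
    n_tumor: int = 518,
    n_normal: int = 8,
    base_mean_log2: float = 8.0,
    sd_log2: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Log2 expression matrix (probes x samples) with planted tumor
    shifts; columns carry a two-level index (sample_id, group)."""
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 2 samples per group")
    if sd_log2 < 0:
        raise ValueError("sd_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    samples = [(f"T{i + 1:03d}", "tumor") for i in range(n_tumor)] + \
              [(f"N{i + 1:03d}", "normal") for i in range(n_normal)]
    cols = pd.MultiIndex.from_tuples(samples, names=["sample_id", "group"])
    data = np.empty((len(probes), len(samples)))
    for r, probe in enumerate(probes):
        shift = truth[probe].cohort_log2_shift if probe in truth else 0.0
        mu = np.where([g == "tumor" for _, g in samples],
                      base_mean_log2 + shift, base_mean_log2)
        data[r] = mu + rng.normal(0.0, sd_log2, size=len(samples))
    return pd.DataFrame(data, index=pd.Index(probes, name="probe"), columns=cols)


# ---------------------------------------------------------------------------
# funnel fixtures
# ---------------------------------------------------------------------------

@dataclass
class FunnelFixture:
    """Everything needed to run the full analysis funnel on synthetic data."""

    name: str
    library_spec: LibrarySpec
    gene_names: list[str]
    truth: GroundTruth
    noise: NoiseModel
    panel_params: dict          # cell line -> 4PL params
    panel_dose_series: np.ndarray
    reference_dose: float       # molar dose at which sensitivity is read
    cohort_config: dict
    qpcr_config: dict
    direct_target_exclusions: list[str]

    def with_seed(self, seed: int) -> "FunnelFixture":
        return replace(self, noise=replace(self.noise, seed=seed))


#: Default master seed for packaged fixtures.
DEFAULT_SEED = 20151

_PANEL_LINES = ["L1", "L2", "L3", "L4", "L5", "L6", "L7"]


def _panel_params() -> dict:
    # log IC50 spread gives well-separated viability at the 1 uM read dose
    log_ic50s = [-7.4, -7.0, -6.7, -6.4, -6.1, -5.8, -5.5]
    return {line: (15.0, 100.0, l, -1.0)
            for line, l in zip(_PANEL_LINES, log_ic50s)}


def _funnel_default_truth(genes: list[str]) -> GroundTruth:
    """Planted effects reproducing the packaged funnel's stage structure.

    Stage design (gene indices are 1-based within ``genes``):
      1-84    pooled sensitizers (si 0.60)
      1-40    validated: two of four singles active
      41-84   off-target: pool effect only, all singles null
      1-31    strong knockdown (0.85); 32-40 weak (0.55)
      30-31   imatinib-common sensitizers
      1,6     inverse expression-sensitivity association; 7,8 direct
      1-5     cohort-overexpressed (~2-fold); gene 5 is the planted
              direct-drug-target analog excluded from candidacy
    """
    truth = {}
    for idx, gene in enumerate(genes, start=1):
        t = GeneTruth()
        if idx <= 84:
            t.si_true_pooled = 0.60
            if idx <= 40:
                t.si_true_singles = (0.60, 0.68, 1.0, 1.0)
            else:
                t.si_true_singles = (1.0, 1.0, 1.0, 1.0)
                t.off_target_pool_only = True
            t.knockdown_fraction = 0.85 if idx <= 31 else 0.55
            if idx in (30, 31):
                t.imatinib_si_true = 0.60
            if idx in (1, 6):
                t.expression_sensitivity_rho = -1
            elif idx in (7, 8):
                t.expression_sensitivity_rho = +1
            if idx <= 5:
                t.cohort_log2_shift = 1.0
        truth[gene] = t
    return GroundTruth(genes=truth)


def funnel_fixture(name: str) -> FunnelFixture:
    """Packaged fixtures: ``funnel_default``, ``null_screen``, ``noiseless``."""
    known = ("funnel_default", "null_screen", "noiseless")
    if name not in known:
        raise ValueError(f"unknown fixture {name!r}; known fixtures: {known}")

    spec = LibrarySpec(n_genes=638)
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]

    if name == "funnel_default":
        truth = _funnel_default_truth(genes)
        noise = NoiseModel(seed=DEFAULT_SEED)
    elif name == "null_screen":
        truth = GroundTruth(genes={g: GeneTruth() for g in genes})
        noise = NoiseModel(seed=DEFAULT_SEED)
    else:  # noiseless
        truth = _funnel_default_truth(genes)
        noise = NoiseModel(plate_effect_sd=0.0, well_cv=0.0, seed=DEFAULT_SEED)

    qpcr_noise = 0.0 if name == "noiseless" else 0.05
    return FunnelFixture(
        name=name,
        library_spec=spec,
        gene_names=genes,
        truth=truth,
        noise=noise,
        panel_params=_panel_params(),
        panel_dose_series=default_dose_series(top_dose=5e-6, n=8, fold=2.5),
        reference_dose=1e-6,
        cohort_config={"n_tumor": 518, "n_normal": 8,
                       "base_mean_log2": 8.0, "sd_log2": 0.3},
        qpcr_config={"ct_ref": 25.0, "noise_sd": qpcr_noise,
                     "n_replicate_wells": 3},
        direct_target_exclusions=["G0005"],
    )


def write_fixture(fixture: FunnelFixture, out_dir) -> dict:
    """Write plate map, measurements, ground truth, and config to disk."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = build_library(fixture.library_spec, fixture.gene_names)
    meas = simulate_screen(library, fixture.truth, [VEHICLE, DASATINIB],
                           replicates_per_arm=2, noise=fixture.noise)
    paths = {
        "platemap": out / "platemap.csv",
        "measurements": out / "measurements.csv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.yaml",
    }
    library.platemap().to_csv(paths["platemap"], index=False)
    meas.to_csv(paths["measurements"], index=False)
    paths["ground_truth"].write_text(fixture.truth.to_json())
    cfg = {"fixture": fixture.name, "seed": fixture.noise.seed,
           "n_genes": fixture.library_spec.n_genes}
    paths["config"].write_text(yaml.safe_dump(cfg))
    return {k: str(v) for k, v in paths.items()}
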