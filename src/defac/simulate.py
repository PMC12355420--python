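"""Seeded synthetic-data generators.

Each generator emulates the statistical structure one analysis stage assumes —
log-normal fluorescence populations with a transfected subpopulation spanning
several decades, a mixture-distributed 1968-drug plate, noisy single-
exponential decay, multinomial litters — so the whole pipeline is exercisable
without any external data.  Seeds are required arguments and every generator
is bit-reproducible given (spec, seed).

``reference_plate`` builds a deterministic synthetic stand-in for the study's
raw screening table with exactly the published stage composition
(346 toxic / 129 GAG reducers / 52 stabilizers / 18 dual hits / 7 category
exclusions / 4 second-stage exclusions among 1968 drugs); measurement noise
is kept well inside the threshold margins, so the triage recomputes the
printed funnel from raw signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cytometry import GateConfig, N_LEVELS
from .io import DecayCourse, EventTable, GenotypeCounts, ScreenRecord

__all__ = [
    "DefacSimSpec",
    "ScreenSimSpec",
    "LitterSimSpec",
    "gen_defac_events",
    "gen_screen_table",
    "reference_plate",
    "gen_decay_course",
    "gen_litters",
    "DEFAULT_GATE",
]

LN2 = math.log(2.0)

# Gate used by the default simulation specs: Level 0 tops out at the upper
# edge of cellular autofluorescence; Levels 1-4 are equal log-width bins
# spanning the transfected construct's dynamic range.
DEFAULT_GATE = GateConfig(
    viability_threshold=1000.0,
    gfp_boundaries=(200.0, 1000.0, 5000.0, 25000.0),
    min_events_per_level=100,
)


# ---------------------------------------------------------------------------
# DEFAC event generator
# ---------------------------------------------------------------------------

@dataclass
class DefacSimSpec:
    """Simulation parameters for a paired untreated/BafA1 cytometry run.

    The BafA1 arm carries the full (arrested) LC3 signal; in the untreated
    arm the lysosome has degraded ``true_flux_by_level`` percent of it, so
    flux acts as a per-level multiplicative removal on the untreated arm —
    algebraically equivalent, for the geometric-mean ratio, to modeling
    accumulation in the inhibited arm.
    """

    seed: int
    n_events: int = 20000
    transfected_fraction: float = 0.6
    gfp_lognormal: tuple[float, float] = (math.log(3000.0), 1.5)  # construct expression
    autofluor_lognormal: tuple[float, float] = (math.log(50.0), 0.4)  # GFP-negative cells
    lc3_baseline_lognormal: tuple[float, float] = (math.log(1000.0), 0.5)
    lc3_noise_sigma: float = 0.25  # per-arm multiplicative measurement noise (log-SD)
    true_flux_by_level: tuple[float, ...] = (0.0, 40.0, 60.0, 60.0, 60.0)
    dead_fraction: float = 0.1
    viability_live_lognormal: tuple[float, float] = (math.log(100.0), 0.3)
    viability_dead_lognormal: tuple[float, float] = (math.log(5000.0), 0.3)
    n_replicates: int = 3
    gate: GateConfig = field(default_factory=lambda: DEFAULT_GATE)
    construct: str = "WT"

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must be in [0, 1]")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if len(self.true_flux_by_level) != N_LEVELS:
            raise ValueError(f"true_flux_by_level needs {N_LEVELS} entries")
        if any(f > 100.0 for f in self.true_flux_by_level):
            raise ValueError("flux cannot exceed 100%")
        for name in ("gfp_lognormal", "autofluor_lognormal", "lc3_baseline_lognormal"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} sigma must be > 0")


def _one_arm(spec: DefacSimSpec, rng: np.random.Generator, treatment: str, replicate: int) -> EventTable:
    n = spec.n_events
    transfected = rng.random(n) < spec.transfected_fraction
    gfp = np.where(
        transfected,
        rng.lognormal(*spec.gfp_lognormal, size=n),
        rng.lognormal(*spec.autofluor_lognormal, size=n),
    )
    level = np.searchsorted(np.asarray(spec.gate.gfp_boundaries), gfp, side="right")
    baseline = rng.lognormal(*spec.lc3_baseline_lognormal, size=n)
    noise = rng.lognormal(0.0, spec.lc3_noise_sigma, size=n)
    flux = np.asarray(spec.true_flux_by_level, dtype=float)[level]
    if treatment == "untreated":
        lc3 = baseline * (1.0 - flux / 100.0) * noise
    else:
        lc3 = baseline * noise
    lc3 = np.maximum(lc3, 1e-6)
    dead = rng.random(n) < spec.dead_fraction
    viability = np.where(
        dead,
        rng.lognormal(*spec.viability_dead_lognormal, size=n),
        rng.lognormal(*spec.viability_live_lognormal, size=n),
    )
    return EventTable(
        events=pd.DataFrame({"gfp": gfp, "lc3": lc3, "viability": viability}),
        sample_id=f"{spec.construct}_{treatment}_r{replicate}",
        construct=spec.construct,
        treatment=treatment,
        replicate=replicate,
        metadata={"simulated": True, "seed": spec.seed},
    )


def gen_defac_events(spec: DefacSimSpec) -> list[tuple[EventTable, EventTable]]:
    """Generate (untreated, bafa1) EventTable pairs, one per replicate."""
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for rep in range(1, spec.n_replicates + 1):
        untreated = _one_arm(spec, rng, "untreated", rep)
        bafa1 = _one_arm(spec, rng, "bafa1", rep)
        pairs.append((untreated, bafa1))
    return pairs


# ---------------------------------------------------------------------------
# screening-plate generators
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimSpec:
    """Mixture model for a drug-library plate run.

    Default fractions are calibrated so the expected triage stage counts
    match the published proportions: 346/1968 toxic; among survivors
    129/1622 GAG reducers, 52/1622 stabilizers, 18/1622 dual (the dual
    fraction exceeds the independent product — GAG and stabilization effects
    are positively correlated in the mixture, as observed).
    """

    seed: int
    n_drugs: int = 1968
    toxic_fraction: float = 346.0 / 1968.0
    dual_fraction: float = 18.0 / 1622.0  # of non-toxic drugs
    gag_only_fraction: float = 111.0 / 1622.0
    stab_only_fraction: float = 34.0 / 1622.0
    toxic_effect: tuple[float, float] = (math.log(0.30), 0.15)  # lognormal viability effect
    gag_effect: tuple[float, float] = (math.log(0.28), 0.15)
    stab_effect: tuple[float, float] = (math.log(3.2), 0.15)
    measurement_sigma: float = 0.08  # lognormal CV of each raw signal
    drugs_per_plate: int = 80
    vehicle_wells_per_plate: int = 8
    vehicle_means: tuple[float, float, float] = (10000.0, 8000.0, 5000.0)  # cellmask, sdc1, nluc
    tagged_fraction_of_dual: float = 7.0 / 18.0  # carry an excluded category tag

    def __post_init__(self) -> None:
        for name in ("toxic_fraction", "dual_fraction", "gag_only_fraction", "stab_only_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")


def _make_records(
    spec: ScreenSimSpec,
    rng: np.random.Generator,
    toxic: np.ndarray,
    gag: np.ndarray,
    stab: np.ndarray,
    tagged: np.ndarray,
    names: Sequence[str] | None = None,
) -> list[ScreenRecord]:
    n = spec.n_drugs
    sig = spec.measurement_sigma
    viab_eff = np.where(toxic, rng.lognormal(*spec.toxic_effect, size=n), 1.0)
    gag_eff = np.where(gag, rng.lognormal(*spec.gag_effect, size=n), 1.0)
    stab_eff = np.where(stab, rng.lognormal(*spec.stab_effect, size=n), 1.0)
    cm_mean, sdc1_mean, nluc_mean = spec.vehicle_means
    # fewer cells -> proportionally less total SDC1 signal; the cell-number
    # adjustment in the triage divides this back out
    cellmask = cm_mean * viab_eff * rng.lognormal(0.0, sig, size=n)
    sdc1 = sdc1_mean * viab_eff * gag_eff * rng.lognormal(0.0, sig, size=n)
    nluc = nluc_mean * stab_eff * rng.lognormal(0.0, sig, size=n)

    records: list[ScreenRecord] = []
    per_plate = spec.drugs_per_plate
    n_plates = math.ceil(n / per_plate)
    for p in range(n_plates):
        plate = f"P{p + 1:02d}"
        for w in range(spec.vehicle_wells_per_plate):
            records.append(
                ScreenRecord(
                    drug_id=f"DMSO_{plate}_{w + 1}",
                    drug_name="DMSO",
                    well=f"V{w + 1}",
                    plate=plate,
                    is_vehicle=True,
                    cellmask_raw=cm_mean * rng.lognormal(0.0, sig),
                    sdc1_raw=sdc1_mean * rng.lognormal(0.0, sig),
                    nluc_raw=nluc_mean * rng.lognormal(0.0, sig),
                )
            )
    for i in range(n):
        plate = f"P{i // per_plate + 1:02d}"
        tags = frozenset({"anticancer"} if tagged[i] and i % 2 == 0 else {"topical"}) if tagged[i] else frozenset()
        records.append(
            ScreenRecord(
                drug_id=f"D{i + 1:04d}",
                drug_name=names[i] if names is not None else f"drug-{i + 1}",
                well=f"W{i % per_plate + 1}",
                plate=plate,
                is_vehicle=False,
                category_tags=tags,
                cellmask_raw=float(cellmask[i]),
                sdc1_raw=float(sdc1[i]),
                nluc_raw=float(nluc[i]),
            )
        )
    return records


def gen_screen_table(spec: ScreenSimSpec) -> list[ScreenRecord]:
    """Stochastic library draw: per-drug latent effects from the mixture."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_drugs
    toxic = rng.random(n) < spec.toxic_fraction
    u = rng.random(n)
    dual = u < spec.dual_fraction
    gag_only = (u >= spec.dual_fraction) & (u < spec.dual_fraction + spec.gag_only_fraction)
    stab_only = (
        (u >= spec.dual_fraction + spec.gag_only_fraction)
        & (u < spec.dual_fraction + spec.gag_only_fraction + spec.stab_only_fraction)
    )
    gag = dual | gag_only
    stab = dual | stab_only
    tagged = dual & (rng.random(n) < spec.tagged_fraction_of_dual)
    return _make_records(spec, rng, toxic, gag, stab, tagged)


# Names printed for the study's second-stage (patient-cell toxicity) and
# final candidate sets; used only to label the synthetic reference plate.
SECOND_STAGE_TOXIC_NAMES = (
    "Andrographolide",
    "Apigenin",
    "Berberine sulfate",
    "Harmine hydrochloride",
)
FINAL_CANDIDATE_NAMES = (
    "Acitretin",
    "Dimethyl fumarate",
    "Entacapone",
    "Nifedipine",
    "Rifaximin",
    "Triclabendazole",
    "Vitamin A",
)


def reference_plate(seed: int = 0) -> tuple[list[ScreenRecord], dict[str, tuple[float, float]]]:
    """Deterministic synthetic stand-in for the raw screening table.

    Exactly 346 of 1968 drugs are cytotoxic; among the 1622 survivors exactly
    129 reduce the adjusted GAG reporter below 0.5, 52 keep the stability
    reporter above 2-fold, and 18 do both.  Of the 18 dual hits, 7 carry an
    anticancer/topical category tag and 4 of the remaining 11 are toxic to
    both patient cell types in the second stage, leaving 7 candidates.
    Effect sizes sit far from every threshold relative to the measurement
    noise, so the composition survives the noisy signal model; the triage
    still recomputes every count from raw signals.

    Returns (records, patient_viability) where ``patient_viability`` maps
    drug_id -> (fibroblast, LCL) viability ratios for the second stage.
    """
    # tighter effect spread than the stochastic generator: every latent effect
    # sits > 7 sigma from its threshold, so the composition is noise-proof
    spec = ScreenSimSpec(
        seed=seed,
        toxic_effect=(math.log(0.25), 0.05),
        gag_effect=(math.log(0.25), 0.05),
        stab_effect=(math.log(4.0), 0.05),
    )
    rng = np.random.default_rng(seed)
    n = spec.n_drugs
    toxic = np.zeros(n, dtype=bool)
    gag = np.zeros(n, dtype=bool)
    stab = np.zeros(n, dtype=bool)
    tagged = np.zeros(n, dtype=bool)

    order = rng.permutation(n)
    toxic[order[:346]] = True
    survivors = order[346:]
    gag[survivors[:111]] = True  # GAG-only
    stab[survivors[111:145]] = True  # stabilizer-only (34)
    dual_idx = survivors[145:163]  # 18 dual hits
    gag[dual_idx] = True
    stab[dual_idx] = True
    tagged[dual_idx[:7]] = True

    names = [f"drug-{i + 1}" for i in range(n)]
    second_stage_idx = dual_idx[7:11]
    for j, idx in enumerate(second_stage_idx):
        names[idx] = SECOND_STAGE_TOXIC_NAMES[j]
    for j, idx in enumerate(dual_idx[11:18]):
        names[idx] = FINAL_CANDIDATE_NAMES[j]

    records = _make_records(spec, rng, toxic, gag, stab, tagged, names=names)

    patient_viability: dict[str, tuple[float, float]] = {}
    for idx in dual_idx:
        drug_id = f"D{idx + 1:04d}"
        if idx in set(second_stage_idx):
            patient_viability[drug_id] = (
                float(rng.uniform(0.1, 0.4)),
                float(rng.uniform(0.1, 0.4)),
            )
        else:
            patient_viability[drug_id] = (
                float(rng.uniform(0.7, 1.1)),
                float(rng.uniform(0.7, 1.1)),
            )
    return records, patient_viability


# ---------------------------------------------------------------------------
# decay-course generator
# ---------------------------------------------------------------------------

def gen_decay_course(
    true_half_life_h: float,
    timepoints: Sequence[float] = (0.0, 6.0, 12.0, 24.0, 48.0),
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    series_id: str = "sim",
) -> DecayCourse:
    """Noisy single-exponential chase: 100 * exp(-ln2 t / t_half) * lognormal(cv).

    The pre (t = 0) point is exact 100 % — it is the normalization anchor,
    not a measurement.
    """
    if true_half_life_h <= 0:
        raise ValueError("half-life must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    k = LN2 / true_half_life_h
    rows = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            true_val = 100.0 * math.exp(-k * t)
            val = 100.0 if t == 0 else true_val * rng.lognormal(0.0, cv)
            rows.append({"time_h": float(t), "value": float(val), "replicate": rep})
    return DecayCourse(data=pd.DataFrame(rows), series_id=series_id)


# ---------------------------------------------------------------------------
# litter generator
# ---------------------------------------------------------------------------

@dataclass
class LitterSimSpec:
    """Heterozygote-cross litters with selectable homozygote embryonic survival."""

    seed: int
    n_dams: int = 6
    litter_size_mean: float = 8.0
    litter_size_dist: str = "poisson"  # or "fixed"
    hom_survival_prob: float = 1.0
    group_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.hom_survival_prob <= 1.0:
            raise ValueError("hom_survival_prob must be in [0, 1]")
        if self.litter_size_dist not in ("poisson", "fixed"):
            raise ValueError("litter_size_dist must be 'poisson' or 'fixed'")
        if self.n_dams < 1:
            raise ValueError("n_dams must be >= 1")


def gen_litters(spec: LitterSimSpec) -> GenotypeCounts:
    """Pooled genotype counts across dams.

    Each conceptus draws its genotype from the Mendelian 1:2:1 null;
    homozygotes are observed only with probability ``hom_survival_prob``
    (embryonic death removes them from the tally).
    """
    rng = np.random.default_rng(spec.seed)
    n_wt = n_het = n_hom = 0
    for _ in range(spec.n_dams):
        if spec.litter_size_dist == "poisson":
            size = int(rng.poisson(spec.litter_size_mean))
        else:
            size = int(round(spec.litter_size_mean))
        wt, het, hom = rng.multinomial(size, [0.25, 0.5, 0.25])
        surviving_hom = int(rng.binomial(hom, spec.hom_survival_prob)) if hom else 0
        n_wt += int(wt)
        n_het += int(het)
        n_hom += surviving_hom
    return GenotypeCounts(n_wt=n_wt, n_het=n_het, n_hom=n_hom, group_label=spec.group_label)
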