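"""FDA-library screening triage.

The screen treats reporter cells with each library drug and reads three
signals per well: CellMask (whole-cell stain, a proxy for cell number /
viability), an In-Cell-Western signal for the tagged GAG core protein SDC1,
and NanoLuc luminescence from a luciferase-tagged mutant VPS33A (protein
stability reporter).  Triage proceeds in fixed order:

1. vehicle (DMSO) normalization per plate — each signal divided by the plate's
   mean vehicle signal, so DMSO sits at ratio 1;
2. toxicity filter — drop drugs whose CellMask ratio is below 0.5
   (strict: exactly 0.5 is retained);
3. cell-number adjustment — SDC1 ratio divided by the CellMask ratio, so GAG
   loss explained by cell loss does not count;
4. dual-criterion quadrant — hits reduce adjusted GAG below 0.5 AND keep the
   mutant VPS33A reporter above 2-fold (both strict);
5. category exclusions (anticancer / topical, config-supplied) and, for the
   second stage, drugs toxic to BOTH patient fibroblasts and lymphoblastoid
   cells.

Every stage records retained/excluded id lists in a FunnelReport whose
conservation invariant (retained + excluded = input, chained stage to stage)
is enforced on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FunnelReport, FunnelStage, ScreenRecord, logger

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "normalize_to_vehicle",
    "cell_normalize_sdc1",
    "viability_filter",
    "quadrant_select",
    "apply_exclusions",
    "second_stage_filter",
    "run_funnel",
]


@dataclass
class ScreenConfig:
    """Triage thresholds.  Defaults are the study's printed criteria."""

    viability_min: float = 0.5
    gag_max: float = 0.5
    vps33a_min: float = 2.0
    excluded_categories: frozenset = frozenset({"anticancer", "topical"})
    named_exclusions: frozenset = frozenset()
    second_stage_viability_min: float = 0.5
    adjust_sdc1_by_cellmask: bool = True

    def __post_init__(self) -> None:
        for name in ("viability_min", "gag_max", "vps33a_min", "second_stage_viability_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.excluded_categories = frozenset(self.excluded_categories)
        self.named_exclusions = frozenset(self.named_exclusions)


@dataclass
class ScreenResult:
    drug_id: str
    drug_name: str = ""
    category_tags: frozenset = frozenset()
    viability_ratio: float = np.nan
    sdc1_ratio: float = np.nan  # cell-number adjusted when config says so
    sdc1_ratio_raw: float = np.nan
    vps33a_ratio: float = np.nan
    flags: dict = field(default_factory=dict)


def normalize_to_vehicle(records: Sequence[ScreenRecord], signal: str) -> dict[str, float]:
    """Per-drug ratio of a raw signal to the mean vehicle signal of its plate."""
    attr = {"cellmask": "cellmask_raw", "sdc1": "sdc1_raw", "nluc": "nluc_raw"}[signal]
    plates: dict[str, list[float]] = {}
    for rec in records:
        if rec.is_vehicle:
            v = getattr(rec, attr)
            if np.isfinite(v):
                plates.setdefault(rec.plate, []).append(v)
    ratios: dict[str, float] = {}
    for rec in records:
        if rec.is_vehicle:
            continue
        if rec.plate not in plates or not plates[rec.plate]:
            raise ValueError(f"no vehicle wells with {signal!r} signal on plate {rec.plate!r}")
        vmean = float(np.mean(plates[rec.plate]))
        if vmean <= 0:
            raise ValueError(f"vehicle mean for {signal!r} is not positive on plate {rec.plate!r}")
        raw = getattr(rec, attr)
        ratios[rec.drug_id] = raw / vmean if np.isfinite(raw) else np.nan
    return ratios


def cell_normalize_sdc1(sdc1_ratio: float, viability_ratio: float) -> float:
    """Adjust the GAG-reporter ratio for cell number: sdc1_ratio / viability_ratio."""
    if not viability_ratio > 0:
        raise ValueError(f"viability ratio must be positive, got {viability_ratio}")
    return sdc1_ratio / viability_ratio


def normalize_records(records: Sequence[ScreenRecord], config: ScreenConfig) -> list[ScreenResult]:
    """Vehicle-normalize all three signals and build per-drug results."""
    viab = normalize_to_vehicle(records, "cellmask")
    sdc1 = normalize_to_vehicle(records, "sdc1")
    has_nluc = any(np.isfinite(r.nluc_raw) for r in records if r.is_vehicle)
    nluc = normalize_to_vehicle(records, "nluc") if has_nluc else {}
    results = []
    for rec in records:
        if rec.is_vehicle:
            continue
        v = viab[rec.drug_id]
        s_raw = sdc1[rec.drug_id]
        s_adj = cell_normalize_sdc1(s_raw, v) if config.adjust_sdc1_by_cellmask else s_raw
        results.append(
            ScreenResult(
                drug_id=rec.drug_id,
                drug_name=rec.drug_name,
                category_tags=rec.category_tags,
                viability_ratio=v,
                sdc1_ratio=s_adj,
                sdc1_ratio_raw=s_raw,
                vps33a_ratio=nluc.get(rec.drug_id, np.nan),
            )
        )
    return results


def viability_filter(
    results: Sequence[ScreenResult], min_ratio: float = 0.5
) -> tuple[list[ScreenResult], list[ScreenResult]]:
    """Split into (retained, excluded-as-toxic).

    Exclusion is strict: a drug is dropped iff its CellMask ratio is *below*
    ``min_ratio``; a ratio exactly at the threshold is retained.
    """
    retained, excluded = [], []
    for r in results:
        if r.viability_ratio < min_ratio:
            r.flags["toxic"] = True
            excluded.append(r)
        else:
            r.flags["toxic"] = False
            retained.append(r)
    return retained, excluded


def quadrant_select(
    results: Sequence[ScreenResult], gag_max: float = 0.5, vps33a_min: float = 2.0
) -> tuple[list[ScreenResult], list[ScreenResult], list[ScreenResult]]:
    """Dual-criterion hit call on the (VPS33A, GAG) plane.

    Returns (dual_hits, gag_hits, stabilizers); dual hits satisfy BOTH
    adjusted GAG < gag_max and VPS33A reporter > vps33a_min, strict on both
    sides, so the vehicle point (1, 1) can never be a hit.  Drugs lacking the
    luminescence reporter are flagged unevaluable and never hits.
    """
    dual, gag_hits, stabilizers = [], [], []
    for r in results:
        evaluable = np.isfinite(r.vps33a_ratio)
        r.flags["unevaluable"] = not evaluable
        is_gag = np.isfinite(r.sdc1_ratio) and r.sdc1_ratio < gag_max
        is_stab = evaluable and r.vps33a_ratio > vps33a_min
        r.flags["gag_hit"] = bool(is_gag)
        r.flags["stabilizer"] = bool(is_stab)
        r.flags["dual_hit"] = bool(is_gag and is_stab)
        if is_gag:
            gag_hits.append(r)
        if is_stab:
            stabilizers.append(r)
        if is_gag and is_stab:
            dual.append(r)
    return dual, gag_hits, stabilizers


def apply_exclusions(
    hits: Sequence[ScreenResult],
    excluded_categories: Iterable[str] = (),
    named_exclusions: Iterable[str] = (),
) -> tuple[list[ScreenResult], list[tuple[ScreenResult, str]]]:
    """Remove hits by annotation category or by explicit drug name/id.

    Returns (candidates, removed) where each removed entry carries its
    reason.  The exclusion sets are pure config input — the study's own
    choice of which categories to drop was explicitly a judgment call, so
    nothing is hard-coded here.
    """
    cats = {c.lower() for c in excluded_categories}
    names = {n.lower() for n in named_exclusions}
    candidates, removed = [], []
    for r in hits:
        tag_hit = {t.lower() for t in r.category_tags} & cats
        if tag_hit:
            r.flags["excluded_by_category"] = True
            removed.append((r, f"category: {', '.join(sorted(tag_hit))}"))
        elif r.drug_name.lower() in names or r.drug_id.lower() in names:
            r.flags["excluded_by_name"] = True
            removed.append((r, "named exclusion"))
        else:
            candidates.append(r)
    return candidates, removed


def second_stage_filter(
    candidates: Sequence[ScreenResult],
    patient_viability: Mapping[str, tuple[float, float]],
    min_ratio: float = 0.5,
) -> tuple[list[ScreenResult], list[ScreenResult]]:
    """Patient-cell toxicity filter for the second screening stage.

    ``patient_viability`` maps drug_id -> (fibroblast ratio, LCL ratio).  A
    candidate is excluded only when viability is below ``min_ratio`` in BOTH
    cell types (conjunction); missing entries are retained.
    """
    retained, excluded = [], []
    for r in candidates:
        fib, lcl = patient_viability.get(r.drug_id, (np.nan, np.nan))
        toxic_both = np.isfinite(fib) and np.isfinite(lcl) and fib < min_ratio and lcl < min_ratio
        r.flags["second_stage_toxic"] = bool(toxic_both)
        (excluded if toxic_both else retained).append(r)
    return retained, excluded


def _stage(name: str, kept: Sequence[ScreenResult], dropped: Sequence[ScreenResult]) -> FunnelStage:
    return FunnelStage(
        stage_name=name,
        n_in=len(kept) + len(dropped),
        n_retained=len(kept),
        n_excluded=len(dropped),
        retained_ids=[r.drug_id for r in kept],
        excluded_ids=[r.drug_id for r in dropped],
    )


def run_funnel(
    records: Sequence[ScreenRecord],
    config: ScreenConfig | None = None,
    patient_viability: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[FunnelReport, list[ScreenResult]]:
    """Execute the whole triage in fixed order and account for every drug.

    Order is load-bearing: the toxicity filter precedes the quadrant, because
    the adjusted GAG ratio of a dying well divides a small CellMask ratio and
    would otherwise flood the hit quadrant with cytotoxic artifacts.

    Returns the FunnelReport plus every normalized ScreenResult (flags set).
    """
    config = config or ScreenConfig()
    results = normalize_records(records, config)
    stages: list[FunnelStage] = []

    viable, toxic = viability_filter(results, config.viability_min)
    stages.append(_stage("viability_filter", viable, toxic))

    dual, gag_hits, stabilizers = quadrant_select(viable, config.gag_max, config.vps33a_min)
    not_dual = [r for r in viable if not r.flags["dual_hit"]]
    stages.append(_stage("quadrant_select", dual, not_dual))

    candidates, removed = apply_exclusions(dual, config.excluded_categories, config.named_exclusions)
    stages.append(_stage("category_exclusions", candidates, [r for r, _ in removed]))

    if patient_viability is not None:
        final, second_toxic = second_stage_filter(
            candidates, patient_viability, config.second_stage_viability_min
        )
        stages.append(_stage("second_stage_viability", final, second_toxic))

    report = FunnelReport(stages=stages)
    report.validate()
    logger.info(
        "funnel: %s; single-criterion sets: %d GAG, %d stabilizer",
        " -> ".join(f"{s.stage_name}:{s.n_retained}" for s in stages),
        len(gag_hits),
        len(stabilizers),
    )
    report_meta = {"n_gag_hits": len(gag_hits), "n_stabilizers": len(stabilizers)}
    for r in results:
        r.flags.setdefault("toxic", False)
    # stash single-criterion counts on the report object for downstream summaries
    report.single_criterion = report_meta  # type: ignore[attr-defined]
    return report, results


def results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flat per-drug table of ratios and flags (the hits.tsv payload)."""
    rows = []
    for r in results:
        row = {
            "drug_id": r.drug_id,
            "drug_name": r.drug_name,
            "viability_ratio": r.viability_ratio,
            "sdc1_ratio": r.sdc1_ratio,
            "vps33a_ratio": r.vps33a_ratio,
        }
        row.update({k: v for k, v in r.flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)
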