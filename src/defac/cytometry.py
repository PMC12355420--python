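"""Per-expression-level autophagic-flux analysis (DEFAC).

The analysis rescues a knock-out line with a GFP-tagged construct, bins viable
cells into five expression levels by GFP intensity (Level 0 = GFP-negative,
Levels 1-4 spanning the transfected range), and quantifies autophagy within
each level as LC3 flux: the fractional difference of the geometric-mean LC3
signal between the lysosome-inhibited (Bafilomycin A1) arm and the untreated
arm,

    flux = (MFI_BafA1 - MFI_untreated) / MFI_BafA1 x 100  (%)

i.e. the percentage of LC3 that the lysosome would have degraded, relative to
the arrested (BafA1) amount.  The same formula applies unchanged to LC3-II
western-blot densitometry pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventTable, logger

N_LEVELS = 5

__all__ = [
    "GateConfig",
    "LevelFluxTable",
    "exclude_dead",
    "assign_levels",
    "geometric_mfi",
    "compute_flux",
    "defac_analysis",
    "quench_control",
    "compare_levels",
    "default_gfp_boundaries",
    "significance_stars",
]


@dataclass
class GateConfig:
    """Gating parameters: viability cut, GFP level boundaries, minimum bin size.

    ``gfp_boundaries`` are 4 strictly increasing intensities defining Levels
    0-4 with left-closed right-open bins (an event exactly on a boundary goes
    to the higher level).  The viability threshold is instrument-dependent and
    therefore required, never defaulted.
    """

    viability_threshold: float
    gfp_boundaries: Sequence[float]
    min_events_per_level: int = 100

    def __post_init__(self) -> None:
        b = np.asarray(self.gfp_boundaries, dtype=float)
        if b.size != N_LEVELS - 1:
            raise ValueError(f"need {N_LEVELS - 1} GFP boundaries, got {b.size}")
        if not np.all(np.diff(b) > 0):
            raise ValueError("GFP boundaries must be strictly increasing")
        if self.min_events_per_level < 1:
            raise ValueError("min_events_per_level must be >= 1")
        self.gfp_boundaries = tuple(float(x) for x in b)


@dataclass
class LevelFluxTable:
    """Per-level flux summary.

    ``summary`` has one row per level with event counts, the two geometric
    MFIs, the pooled flux, and mean/SD across replicates; ``per_replicate``
    holds one flux value per (level, replicate).  ``baseline_lc3`` is the mean
    LC3 of the GFP-negative (Level 0) untreated population — the dashed-line
    reference of the dot plot.
    """

    summary: pd.DataFrame
    per_replicate: pd.DataFrame
    baseline_lc3: float
    construct: str = ""
    metadata: dict = field(default_factory=dict)

    def flux(self, level: int) -> float:
        return float(self.summary.loc[self.summary["level"] == level, "flux_pct"].iloc[0])

    def replicate_fluxes(self, level: int) -> np.ndarray:
        mask = self.per_replicate["level"] == level
        return self.per_replicate.loc[mask, "flux_pct"].to_numpy(dtype=float)


def exclude_dead(events: EventTable, threshold: float) -> EventTable:
    """Drop dead cells: events with viability-dye intensity at/above threshold.

    The viability dye (7-AAD) enters only membrane-compromised cells, so
    dye-positive events are excluded as the dead-cell population.
    """
    if "viability" not in events.events.columns:
        raise KeyError("viability channel required for dead-cell exclusion")
    keep = events.events["viability"].to_numpy(dtype=float) < threshold
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no viable events after dead-cell exclusion")
    logger.info("excluded %d/%d dead events (%s)", n_removed, len(events), events.sample_id)
    return events.with_events(events.events.loc[keep].reset_index(drop=True))


def assign_levels(events: EventTable, gate: GateConfig) -> np.ndarray:
    """Label each event with its GFP expression level (0-4).

    The label is the number of boundaries at or below the event's GFP
    intensity; bins are left-closed right-open, so a boundary-valued event
    falls in the higher level.
    """
    gfp = events.events["gfp"].to_numpy(dtype=float)
    bounds = np.asarray(gate.gfp_boundaries, dtype=float)
    return np.searchsorted(bounds, gfp, side="right").astype(int)


def geometric_mfi(intensities: Sequence[float]) -> float:
    """Geometric mean fluorescence intensity: exp(mean(log x)).

    Returns NaN for empty input (flagged undefined rather than raising, so a
    sparse level degrades gracefully).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        return float("nan")
    if np.any(x <= 0):
        raise ValueError(
            "geometric MFI requires strictly positive intensities; apply a "
            "floor or arcsinh transform policy upstream"
        )
    return float(np.exp(np.mean(np.log(x))))


def arithmetic_mfi(intensities: Sequence[float]) -> float:
    x = np.asarray(intensities, dtype=float)
    return float(np.mean(x)) if x.size else float("nan")


def compute_flux(mfi_bafa1: float, mfi_untreated: float) -> float:
    """LC3 flux in percent: (MFI_BafA1 - MFI_untreated) / MFI_BafA1 x 100.

    Bounded above by 100 (complete degradation); negative values are possible
    when accumulation noise exceeds degradation and are reported, not clipped.
    """
    if not mfi_bafa1 > 0:
        raise ValueError(f"BafA1 MFI must be positive, got {mfi_bafa1}")
    return (mfi_bafa1 - mfi_untreated) / mfi_bafa1 * 100.0


def default_gfp_boundaries(reference: EventTable, n_decades: float | None = None) -> tuple[float, ...]:
    """Data-driven default gates from a mock/untransfected reference sample.

    Level 0's upper bound is the 99.5th percentile of the reference GFP
    channel (the GFP-negative gate); Levels 1-4 split the range up to the
    brightest observed events into equal log-width bins.
    """
    gfp = reference.events["gfp"].to_numpy(dtype=float)
    low = float(np.percentile(gfp, 99.5))
    high = float(gfp.max()) * 10.0 if n_decades is None else low * 10.0 ** n_decades
    if high <= low:
        high = low * 1e4
    edges = np.exp(np.linspace(np.log(low), np.log(high), N_LEVELS))
    return tuple(float(x) for x in edges[:-1])


def _level_mfis(table: EventTable, gate: GateConfig, statistic) -> tuple[np.ndarray, np.ndarray]:
    levels = assign_levels(table, gate)
    lc3 = table.events["lc3"].to_numpy(dtype=float)
    mfis = np.full(N_LEVELS, np.nan)
    counts = np.zeros(N_LEVELS, dtype=int)
    for lv in range(N_LEVELS):
        sel = lc3[levels == lv]
        counts[lv] = sel.size
        if sel.size:
            mfis[lv] = statistic(sel)
    return mfis, counts


def defac_analysis(
    untreated: Sequence[EventTable] | EventTable,
    bafa1: Sequence[EventTable] | EventTable,
    gate: GateConfig,
    use_arithmetic_mean: bool = False,
) -> LevelFluxTable:
    """Full per-level flux pipeline for paired untreated / BafA1 samples.

    Accepts one table per arm or matched replicate sequences.  Per replicate:
    dead-cell exclusion, level assignment with the shared gate, geometric LC3
    MFI per level per arm, flux per level.  Replicate fluxes are aggregated to
    mean +/- SD; the pooled (all replicates) flux is also reported.  Levels
    with fewer than ``gate.min_events_per_level`` events in either arm are
    flagged (``flux_defined = False``) rather than silently reported.
    """
    unt = [untreated] if isinstance(untreated, EventTable) else list(untreated)
    baf = [bafa1] if isinstance(bafa1, EventTable) else list(bafa1)
    if len(unt) != len(baf):
        raise ValueError(f"replicate mismatch: {len(unt)} untreated vs {len(baf)} bafa1 tables")
    reps_u = [t.replicate for t in unt]
    reps_b = [t.replicate for t in baf]
    if sorted(reps_u) != sorted(reps_b):
        raise ValueError(f"replicate labels differ between arms: {reps_u} vs {reps_b}")
    baf = [baf[reps_b.index(r)] for r in reps_u]  # align pairing by label

    statistic = arithmetic_mfi if use_arithmetic_mean else geometric_mfi

    per_rep_rows = []
    n_u_tot = np.zeros(N_LEVELS, dtype=int)
    n_b_tot = np.zeros(N_LEVELS, dtype=int)
    lc3_u_pool: list[list[np.ndarray]] = [[] for _ in range(N_LEVELS)]
    lc3_b_pool: list[list[np.ndarray]] = [[] for _ in range(N_LEVELS)]
    baseline_vals: list[np.ndarray] = []

    for tu, tb in zip(unt, baf):
        vu = exclude_dead(tu, gate.viability_threshold)
        vb = exclude_dead(tb, gate.viability_threshold)
        lev_u = assign_levels(vu, gate)
        lev_b = assign_levels(vb, gate)
        lc3_u = vu.events["lc3"].to_numpy(dtype=float)
        lc3_b = vb.events["lc3"].to_numpy(dtype=float)
        baseline_vals.append(lc3_u[lev_u == 0])
        for lv in range(N_LEVELS):
            su = lc3_u[lev_u == lv]
            sb = lc3_b[lev_b == lv]
            lc3_u_pool[lv].append(su)
            lc3_b_pool[lv].append(sb)
            n_u_tot[lv] += su.size
            n_b_tot[lv] += sb.size
            ok = su.size >= gate.min_events_per_level and sb.size >= gate.min_events_per_level
            mfi_u = statistic(su) if su.size else np.nan
            mfi_b = statistic(sb) if sb.size else np.nan
            flux = compute_flux(mfi_b, mfi_u) if ok and mfi_b > 0 else np.nan
            per_rep_rows.append(
                {
                    "level": lv,
                    "replicate": tu.replicate,
                    "n_untreated": su.size,
                    "n_bafa1": sb.size,
                    "mfi_lc3_untreated": mfi_u,
                    "mfi_lc3_bafa1": mfi_b,
                    "flux_pct": flux,
                    "flux_defined": ok,
                }
            )

    per_replicate = pd.DataFrame(per_rep_rows)
    summary_rows = []
    for lv in range(N_LEVELS):
        su = np.concatenate(lc3_u_pool[lv]) if lc3_u_pool[lv] else np.array([])
        sb = np.concatenate(lc3_b_pool[lv]) if lc3_b_pool[lv] else np.array([])
        ok = su.size >= gate.min_events_per_level and sb.size >= gate.min_events_per_level
        mfi_u = statistic(su) if su.size else np.nan
        mfi_b = statistic(sb) if sb.size else np.nan
        pooled_flux = compute_flux(mfi_b, mfi_u) if ok and mfi_b > 0 else np.nan
        rep_flux = per_replicate.loc[
            (per_replicate["level"] == lv) & per_replicate["flux_defined"], "flux_pct"
        ].to_numpy(dtype=float)
        summary_rows.append(
            {
                "level": lv,
                "n_untreated": int(n_u_tot[lv]),
                "n_bafa1": int(n_b_tot[lv]),
                "mfi_lc3_untreated": mfi_u,
                "mfi_lc3_bafa1": mfi_b,
                "flux_pct": pooled_flux,
                "flux_mean": float(np.mean(rep_flux)) if rep_flux.size else np.nan,
                "flux_sd": float(np.std(rep_flux, ddof=1)) if rep_flux.size > 1 else np.nan,
                "flux_defined": ok,
            }
        )
    summary = pd.DataFrame(summary_rows)
    baseline = float(np.mean(np.concatenate(baseline_vals))) if baseline_vals else float("nan")
    return LevelFluxTable(
        summary=summary,
        per_replicate=per_replicate,
        baseline_lc3=baseline,
        construct=unt[0].construct,
        metadata={"n_replicates": len(unt), "statistic": "arithmetic" if use_arithmetic_mean else "geometric"},
    )


def quench_control(untreated: EventTable, bafa1: EventTable, tolerance: float = 0.1) -> tuple[bool, float]:
    """Check that BafA1 does not alter gross GFP fluorescence (no quenching).

    Returns (pass, ratio) where ratio = GM(GFP, BafA1) / GM(GFP, untreated);
    the check passes iff |ratio - 1| <= tolerance.  A failing control would
    invalidate level assignment, since levels must mean the same expression
    in both arms.
    """
    if len(untreated) == 0 or len(bafa1) == 0:
        raise ValueError("quench control requires non-empty tables")
    gm_u = geometric_mfi(untreated.events["gfp"])
    gm_b = geometric_mfi(bafa1.events["gfp"])
    ratio = gm_b / gm_u
    return abs(ratio - 1.0) <= tolerance, float(ratio)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_levels(table_a: LevelFluxTable, table_b: LevelFluxTable, adjust: str = "none") -> pd.DataFrame:
    """Per-level two-sided Student's t-test on replicate flux values.

    p-values are reported unadjusted by default (each level is its own
    comparison against the reference construct); Holm adjustment across the
    level family is available via ``adjust='holm'``.  Levels with fewer than
    two replicate values on either side are flagged untestable.
    """
    rows = []
    for lv in range(N_LEVELS):
        a = table_a.replicate_fluxes(lv)
        b = table_b.replicate_fluxes(lv)
        if a.size < 2 or b.size < 2:
            rows.append({"level": lv, "t": np.nan, "p": np.nan, "testable": False, "stars": "na"})
            continue
        if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"level": lv, "t": float(t_stat), "p": float(p), "testable": True, "stars": ""})
    df = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        mask = df["testable"].to_numpy()
        if mask.any():
            adj = multipletests(df.loc[mask, "p"], method="holm")[1]
            df.loc[mask, "p"] = adj
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    df["stars"] = [significance_stars(p) if ok else "na" for p, ok in zip(df["p"], df["testable"])]
    return df
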