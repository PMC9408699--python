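"""Passive-stress decomposition of skinned fiber bundles.

Each bundle is stretched passively (sarcomere length 2.6 -> 3.0 um at
0.04 um/s) and held isometrically for 60 s; the steady-state stress is the
mean force over the tail of the hold divided by the bundle's cross-sectional
area (cylindrical assumption). Serial extraction — trypsin (degrades titin,
preferentially its lysine-rich PEVK region), then KCl + KI (depolymerises
the thick and thin filaments, removing titin's anchors) — leaves a residual
stress attributed to collagen; the titin-based stress is the control stress
minus that residual, so titin + collagen = total by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("control", "trypsin", "trypsin_kcl_ki")

SL_START_UM = 2.6
SL_END_UM = 3.0
RAMP_RATE_UM_S = 0.04
HOLD_S = 60.0

DEFAULT_WINDOW_S = 5.0
DEFAULT_SL_TOL_UM = 0.01


@dataclass(frozen=True)
class PassiveStressResult:
    bundle_id: str
    treatment_state: str
    steady_state_stress: float  # mN/mm^2
    cross_sectional_area: float  # mm^2

    def __post_init__(self) -> None:
        if self.cross_sectional_area <= 0:
            raise ValueError("area must be positive")


@dataclass(frozen=True)
class StressDecomposition:
    """Titin/collagen partition of one bundle's passive stress.

    ``monotonic`` is False when stress increased along the extraction
    sequence (flagged, never clipped); components may then be negative.
    """

    bundle_id: str
    total_stress: float
    trypsin_drop: float
    collagen_based: float
    titin_based: float
    monotonic: bool


def cross_sectional_area(diameter_um: float) -> float:
    """Cross-sectional area (mm^2) of a cylindrical bundle of given diameter (um)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * (diameter_um / 2.0) ** 2 * 1e-6


def steady_state_stress(
    trace: pd.DataFrame,
    area_mm2: float,
    window_s: float = DEFAULT_WINDOW_S,
    sl_end_um: float = SL_END_UM,
    sl_tol_um: float = DEFAULT_SL_TOL_UM,
) -> float:
    """Mean stress (mN/mm^2) over the final ``window_s`` of the isometric hold.

    ``trace`` has columns time_s, force_mN, sl_um with strictly increasing
    time. The hold phase is the trailing run of samples with
    |sl - sl_end| <= sl_tol; its absence, or a window longer than the hold,
    is an error.
    """
    t = trace["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    at_end = np.abs(trace["sl_um"].to_numpy(dtype=float) - sl_end_um) <= sl_tol_um
    if not at_end.any():
        raise ValueError("no hold phase detected (sarcomere length never "
                         f"reaches {sl_end_um} +/- {sl_tol_um} um)")
    # trailing contiguous hold
    last_false = np.flatnonzero(~at_end)
    start = 0 if last_false.size == 0 else last_false[-1] + 1
    if start >= len(t):
        raise ValueError("no hold phase detected at trace end")
    hold_t = t[start:]
    hold_duration = hold_t[-1] - hold_t[0]
    if window_s > hold_duration:
        raise ValueError(
            f"window {window_s} s exceeds hold duration {hold_duration:.3g} s"
        )
    sel = hold_t >= hold_t[-1] - window_s
    force = trace["force_mN"].to_numpy(dtype=float)[start:][sel]
    return float(force.mean() / area_mm2)


def decompose(results: dict[str, PassiveStressResult] | list[PassiveStressResult]
              ) -> StressDecomposition:
    """Partition one bundle's stress given all three treatment states."""
    if not isinstance(results, dict):
        results = {r.treatment_state: r for r in results}
    missing = [s for s in TREATMENTS if s not in results]
    if missing:
        raise ValueError(f"missing treatment states: {missing}")
    bundle_ids = {r.bundle_id for r in results.values()}
    if len(bundle_ids) != 1:
        raise ValueError(f"results mix bundles: {sorted(bundle_ids)}")
    total = results["control"].steady_state_stress
    post_trypsin = results["trypsin"].steady_state_stress
    collagen = results["trypsin_kcl_ki"].steady_state_stress
    return StressDecomposition(
        bundle_id=next(iter(bundle_ids)),
        total_stress=total,
        trypsin_drop=total - post_trypsin,
        collagen_based=collagen,
        titin_based=total - collagen,
        monotonic=total >= post_trypsin >= collagen,
    )


COMPONENTS = ("total_stress", "trypsin_drop", "collagen_based", "titin_based")


def group_summary(
    decompositions: "list[StressDecomposition] | pd.DataFrame",
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype mean +/- SD of each stress component, with Welch tests.

    ``metadata`` maps bundle_id -> genotype (index or column). Returns
    (summary, tests); ``tests`` is empty when fewer than two genotypes have
    >= 2 bundles. The Welch two-sample t-test is used as the between-genotype
    comparison.
    """
    if not isinstance(decompositions, pd.DataFrame):
        decompositions = pd.DataFrame([vars(d) for d in decompositions])
    if "bundle_id" in metadata.columns:
        metadata = metadata.set_index("bundle_id")
    df = decompositions.merge(metadata[["genotype"]], left_on="bundle_id",
                              right_index=True)
    summary = (
        df.groupby("genotype")[list(COMPONENTS)]
        .agg(["count", "mean", "std"])
        .rename(columns={"count": "n", "std": "sd"})
    )
    genotypes = sorted(df["genotype"].unique())
    tests = []
    if len(genotypes) == 2:
        a = df[df["genotype"] == genotypes[0]]
        b = df[df["genotype"] == genotypes[1]]
        if len(a) >= 2 and len(b) >= 2:
            for comp in COMPONENTS:
                t, p = stats.ttest_ind(a[comp], b[comp], equal_var=False)
                tests.append({"component": comp, "group_a": genotypes[0],
                              "group_b": genotypes[1], "t": float(t),
                              "p_value": float(p)})
    return summary, pd.DataFrame(tests)


def analyze_bundles(
    traces: pd.DataFrame,
    bundles: pd.DataFrame,
    window_s: float = DEFAULT_WINDOW_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline: traces -> steady stresses -> decompositions.

    ``traces`` is long-form (bundle_id, treatment_state, time_s, force_mN,
    sl_um); ``bundles`` has bundle_id, genotype, diameter_um (muscle_id
    optional). Returns (per-condition stresses, per-bundle decompositions).
    """
    if "bundle_id" in bundles.columns:
        bundles = bundles.set_index("bundle_id")
    stress_rows = []
    decomp_rows = []
    for bundle_id, per_bundle in traces.groupby("bundle_id", sort=True):
        area = cross_sectional_area(float(bundles.loc[bundle_id, "diameter_um"]))
        results = {}
        for state, tr in per_bundle.groupby("treatment_state"):
            sigma = steady_state_stress(tr.sort_values("time_s"), area, window_s)
            results[state] = PassiveStressResult(str(bundle_id), str(state),
                                                 sigma, area)
            stress_rows.append({
                "bundle_id": bundle_id, "treatment_state": state,
                "steady_state_stress": sigma, "cross_sectional_area": area,
            })
        decomp_rows.append(vars(decompose(results)))
    return pd.DataFrame(stress_rows), pd.DataFrame(decomp_rows)
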