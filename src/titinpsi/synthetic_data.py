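"""Synthetic splicing counts and fiber-bundle mechanics traces.

The generators emulate the statistical structure the analysis assumes so the
whole pipeline is testable without raw sequencing or rig data:

* splicing — per bin and sample the number of junction-informative reads is
  Poisson(coverage) and the inclusion count is beta-binomial around the true
  PSI (binomial at overdispersion 0). The default truth profile reproduces
  the qualitative group structure of the *mdm* mouse: PEVK exons shifted
  down, Z-repeat and Mex5 exons shifted up in the fast muscles.
* mechanics — per bundle a total steady stress is drawn per genotype; the
  collagen share, trypsin-resistant titin share and relaxation kinetics
  render ramp-and-hold force traces for the control, post-trypsin and
  post-trypsin+KCl+KI states. Group defaults are calibrated to published
  soleus fiber-bundle statistics (mdm 27.0 +/- 0.97, WT 13.0 +/- 2.14
  mN/mm^2 total, collagen residuals 6.7 and 2.6 mN/mm^2).

Every config carries a mandatory seed; identical configs produce identical
output, and truth tables always accompany the data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mechanics as mech
from .gene_model import GeneModel
from .psi_quant import BinCounts

GENOTYPES = ("WT", "mdm")
MUSCLES = ("EDL", "psoas", "soleus")
FAST_MUSCLES = ("EDL", "psoas")

#: mdm-downshifted PEVK exons and mdm-upshifted (fast-muscle) exons.
PEVK_DOWN_EXONS = (124, 125, 126, 127, 133, 134, 138, 139, 140, 141, 142,
                   143, 144, 145)
ZR_UP_EXONS = (12, 13)
MEX5_EXON = 346

#: Mex5 PSI by (genotype, muscle), matching the published group means.
MEX5_PSI = {
    ("WT", "EDL"): 0.63, ("WT", "psoas"): 0.58, ("WT", "soleus"): 0.97,
    ("mdm", "EDL"): 0.88, ("mdm", "psoas"): 0.93, ("mdm", "soleus"): 0.97,
}


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------

@dataclass
class SpliceSimConfig:
    model: GeneModel
    true_psi: dict[tuple[str, str, str], float]  # (bin_id, genotype, muscle)
    junction_coverage: float = 500.0
    overdispersion: float = 0.01
    n_samples: int = 4  # per genotype x muscle group
    seed: int = 0

    def __post_init__(self) -> None:
        if self.junction_coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must be in [0, 1)")
        for key, psi in self.true_psi.items():
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"true PSI for {key} outside [0, 1]")


def default_true_psi(
    model: GeneModel,
    genotypes: tuple[str, ...] = GENOTYPES,
    muscles: tuple[str, ...] = MUSCLES,
    baseline: float = 0.9,
) -> dict[tuple[str, str, str], float]:
    """Truth profile emulating the mdm splicing phenotype on a gene model.

    PEVK hotspot exons drop from 0.8 (WT) to 0.45 (mdm); Z-repeat exons 12-13
    rise from 0.3 to 0.7 in mdm fast muscles; Mex5 takes the published group
    means. All other bins sit at ``baseline`` in every group. Values are
    generator inputs, not claims about any real dataset.
    """
    truth: dict[tuple[str, str, str], float] = {}
    for b in model.bins:
        exon = b.parent_exon
        for g in genotypes:
            for m in muscles:
                psi = baseline
                if exon in PEVK_DOWN_EXONS:
                    psi = 0.45 if g == "mdm" else 0.80
                elif exon in ZR_UP_EXONS:
                    psi = 0.70 if (g == "mdm" and m in FAST_MUSCLES) else 0.30
                elif exon == MEX5_EXON:
                    psi = MEX5_PSI.get((g, m), baseline)
                truth[(b.bin_id, g, m)] = psi
    return truth


def simulate_splice_counts(
    config: SpliceSimConfig,
) -> tuple[list[BinCounts], pd.DataFrame, pd.DataFrame]:
    """Draw per-sample bin counts; returns (counts, metadata, truth).

    Sample ids are ``{genotype}_{muscle}_{k}``. Counts use unit position
    denominators (the simulation operates at the junction-count level, where
    both evidence classes have a single placement each). ``truth`` is a long
    table (bin_id, genotype, muscle, true_psi).
    """
    rng = np.random.default_rng(config.seed)
    groups = sorted({(g, m) for (_, g, m) in config.true_psi})
    counts: list[BinCounts] = []
    meta_rows = []
    for genotype, muscle in groups:
        for k in range(1, config.n_samples + 1):
            sample_id = f"{genotype}_{muscle}_{k}"
            meta_rows.append({"sample_id": sample_id, "genotype": genotype,
                              "muscle": muscle})
            for b in config.model.bins:
                psi = config.true_psi.get((b.bin_id, genotype, muscle))
                if psi is None:
                    continue
                total = int(rng.poisson(config.junction_coverage))
                inc = _beta_binomial(rng, total, psi, config.overdispersion)
                counts.append(BinCounts(sample_id, b.bin_id, inc, total - inc))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(
        [{"bin_id": b, "genotype": g, "muscle": m, "true_psi": v}
         for (b, g, m), v in sorted(config.true_psi.items())]
    )
    return counts, meta, truth


def _beta_binomial(rng: np.random.Generator, n: int, psi: float, rho: float) -> int:
    if n == 0:
        return 0
    if psi <= 0.0:
        return 0
    if psi >= 1.0:
        return n
    if rho == 0.0:
        return int(rng.binomial(n, psi))
    conc = 1.0 / rho - 1.0
    p = rng.beta(psi * conc, (1.0 - psi) * conc)
    return int(rng.binomial(n, p))


def write_splice_sim(
    config: SpliceSimConfig, out_dir: str | os.PathLike
) -> dict[str, str]:
    """Simulate and write counts.tsv, metadata.tsv and truth.tsv."""
    from .psi_quant import counts_to_tsv

    os.makedirs(out_dir, exist_ok=True)
    counts, meta, truth = simulate_splice_counts(config)
    paths = {name: os.path.join(os.fspath(out_dir), f"{name}.tsv")
             for name in ("counts", "metadata", "truth")}
    counts_to_tsv(counts, paths["counts"])
    meta.reset_index().to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------

@dataclass
class MechSimConfig:
    """Fiber-bundle simulation settings, calibrated to soleus group statistics.

    ``titin_fraction`` and ``trypsin_resistant_titin_fraction`` follow from
    the published group means: collagen = total x (1 - titin_fraction) and
    post-trypsin = collagen + titin x resistant_fraction.
    """

    total_mean: dict[str, float] = field(
        default_factory=lambda: {"mdm": 27.0, "WT": 13.0})
    total_sd: dict[str, float] = field(
        default_factory=lambda: {"mdm": 0.97, "WT": 2.14})
    titin_fraction: dict[str, float] = field(
        default_factory=lambda: {"mdm": 1.0 - 6.7 / 27.0, "WT": 1.0 - 2.6 / 13.0})
    trypsin_resistant_titin_fraction: dict[str, float] = field(
        default_factory=lambda: {"mdm": (16.1 - 6.7) / (27.0 - 6.7),
                                 "WT": (8.3 - 2.6) / (13.0 - 2.6)})
    n_bundles: dict[str, int] = field(
        default_factory=lambda: {"mdm": 20, "WT": 21})
    relaxation_tau_s: float = 5.0
    peak_overshoot: float = 0.25  # peak stress = steady x (1 + overshoot)
    noise_sd: float = 0.2  # mN/mm^2 on the rendered stress
    sampling_rate_hz: float = 25.0
    diameter_range_um: tuple[float, float] = (120.0, 220.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.titin_fraction, self.trypsin_resistant_titin_fraction):
            if any(not 0.0 <= f <= 1.0 for f in d.values()):
                raise ValueError("fractions must lie in [0, 1]")
        if any(s < 0 for s in self.total_sd.values()):
            raise ValueError("sd must be non-negative")


def simulate_fiber_bundles(
    config: MechSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render ramp-and-hold traces for every bundle and treatment state.

    Returns (traces, bundles, truth): ``traces`` is long-form (bundle_id,
    treatment_state, time_s, force_mN, sl_um); ``bundles`` has bundle_id,
    muscle_id, genotype, diameter_um; ``truth`` records each bundle's drawn
    steady stresses and titin fraction.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate_hz
    ramp_s = (mech.SL_END_UM - mech.SL_START_UM) / mech.RAMP_RATE_UM_S
    t = np.arange(0.0, ramp_s + mech.HOLD_S + dt / 2, dt)
    on_ramp = t < ramp_s
    sl = np.where(on_ramp, mech.SL_START_UM + mech.RAMP_RATE_UM_S * t,
                  mech.SL_END_UM)
    frac = np.clip(t / ramp_s, 0.0, 1.0)

    trace_frames = []
    bundle_rows, truth_rows = [], []
    for genotype in sorted(config.n_bundles):
        for k in range(1, config.n_bundles[genotype] + 1):
            bundle_id = f"{genotype}_b{k:02d}"
            diameter = rng.uniform(*config.diameter_range_um)
            area = mech.cross_sectional_area(diameter)
            total = max(rng.normal(config.total_mean[genotype],
                                   config.total_sd[genotype]), 0.0)
            tf = config.titin_fraction[genotype]
            resist = config.trypsin_resistant_titin_fraction[genotype]
            collagen = total * (1.0 - tf)
            titin = total * tf
            steady = {
                "control": total,
                "trypsin": collagen + titin * resist,
                "trypsin_kcl_ki": collagen,
            }
            for state, sigma_ss in steady.items():
                peak = sigma_ss * (1.0 + config.peak_overshoot)
                stress = np.where(
                    on_ramp,
                    peak * frac ** 2,  # toe-region rise during the stretch
                    sigma_ss + (peak - sigma_ss)
                    * np.exp(-(t - ramp_s) / config.relaxation_tau_s),
                )
                stress = stress + rng.normal(0.0, config.noise_sd, t.size)
                trace_frames.append(pd.DataFrame({
                    "bundle_id": bundle_id, "treatment_state": state,
                    "time_s": t, "force_mN": stress * area, "sl_um": sl,
                }))
            bundle_rows.append({
                "bundle_id": bundle_id, "muscle_id": "soleus",
                "genotype": genotype, "diameter_um": diameter,
            })
            truth_rows.append({
                "bundle_id": bundle_id, "genotype": genotype,
                "total_stress": total, "titin_fraction": tf,
                "steady_control": steady["control"],
                "steady_trypsin": steady["trypsin"],
                "steady_trypsin_kcl_ki": steady["trypsin_kcl_ki"],
            })
    traces = pd.concat(trace_frames, ignore_index=True)
    return traces, pd.DataFrame(bundle_rows), pd.DataFrame(truth_rows)


def write_mech_sim(
    config: MechSimConfig, out_dir: str | os.PathLike
) -> dict[str, str]:
    """Simulate and write traces.csv, bundles.tsv and truth.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    traces, bundles, truth = simulate_fiber_bundles(config)
    paths = {
        "traces": os.path.join(os.fspath(out_dir), "traces.csv"),
        "bundles": os.path.join(os.fspath(out_dir), "bundles.tsv"),
        "truth": os.path.join(os.fspath(out_dir), "truth.tsv"),
    }
    traces.to_csv(paths["traces"], index=False)
    bundles.to_csv(paths["bundles"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
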