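"""End-to-end orchestration of the 20-configuration sweep.

For every (vertex diameter, separation, delivery mode) the pipeline runs
geometry -> dose simulation -> prescription normalization -> directional
VPDR (3 directions x 9 profiles) -> uniformity statistics ->
normal-tissue metrics, and collects tidy report tables keyed by
(mode, diameter_cm, separation_cm).  Everything is deterministic given
the sweep seed: each configuration draws its noise seed from a
``numpy.random.SeedSequence`` spawned from (seed, mode, diameter,
separation), so single configurations can be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import normal_tissue as nt
from .geometry import (LatticeSpec, PhantomSpec, build_avoid_masks,
                       build_eval_normal_mask, build_phantom_mask,
                       build_vertex_masks)
from .grids import GridSpec
from .simulate import DeliveryMode, SimParams, normalize_prescription, simulate_dose
from .stats import DIRECTIONS, PAIRS, directional_cv, pairwise_ttests
from .vpdr import directional_vpdr, find_peaks

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "write_reports",
           "compare_tables"]

log = logging.getLogger("latticedose.sweep")

#: report schema version (bump on any column change)
REPORT_SCHEMA = "1"


@dataclass(frozen=True)
class SweepConfig:
    """Parameter grid and simulation settings for one sweep.

    Defaults reproduce the study grid: 4 vertex diameters x 5 separations
    (20 configurations) in both delivery modes on a 2 mm voxel grid.
    """

    diameters_cm: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    separations_cm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    modes: tuple[str, ...] = ("coplanar", "noncoplanar")
    spacing_mm: float = 2.0
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if not (self.diameters_cm and self.separations_cm and self.modes):
            raise ValueError("diameters, separations and modes must be non-empty")


@dataclass
class SweepResult:
    """Tidy report tables from one sweep."""

    values: pd.DataFrame    # per-profile VPDR values
    summary: pd.DataFrame   # per-direction mean/SD
    stats: pd.DataFrame     # CV + pairwise p-values per configuration
    tissue: pd.DataFrame    # normal-tissue metrics per configuration


def _config_seed(base_seed: int, mode_i: int, d_i: int, s_i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed,
                                  spawn_key=(mode_i, d_i, s_i))


def run_configuration(diameter_cm: float, separation_cm: float, mode: str,
                      seed_seq, spacing_mm: float = 2.0,
                      sim_overrides: dict | None = None,
                      phantom: PhantomSpec | None = None) -> dict:
    """Run the full pipeline for a single configuration.

    Returns a dict with the lattice, dose, VPDR results per direction,
    uniformity statistics, and normal-tissue metrics.
    """
    phantom = phantom or PhantomSpec()
    noise_seed = int(np.random.default_rng(seed_seq).integers(2 ** 31))
    params = DeliveryMode.params(mode, seed=noise_seed,
                                 **(sim_overrides or {}))
    grid = GridSpec.for_phantom(phantom.radius_cm, phantom.length_cm,
                                spacing_mm)
    lattice = LatticeSpec(diameter_cm, separation_cm)

    phantom_mask = build_phantom_mask(phantom, grid)
    vertex_masks = build_vertex_masks(lattice, grid)
    avoid = build_avoid_masks(lattice, vertex_masks, grid, phantom_mask)
    eval_normal = build_eval_normal_mask(phantom_mask, avoid, vertex_masks)

    raw = simulate_dose(lattice, params, grid, phantom)
    dose, factor = normalize_prescription(raw, vertex_masks)

    peaks = find_peaks(dose, vertex_masks)
    results = {d: directional_vpdr(dose, lattice, vertex_masks, d, peaks=peaks)
               for d in DIRECTIONS}
    samples = {d: r.values for d, r in results.items()}
    cv = directional_cv([results[d].mean for d in DIRECTIONS])
    pvals = pairwise_ttests(samples)
    metrics = nt.evaluate(dose, eval_normal)
    return {
        "lattice": lattice,
        "params": params,
        "dose": dose,
        "scale_factor": factor,
        "vpdr": results,
        "cv_pct": cv,
        "pvalues": pvals,
        "tissue": metrics,
    }


def run_sweep(config: SweepConfig) -> SweepResult:
    """Run every configuration of the sweep; failures are logged and skipped."""
    rows_v, rows_s, rows_t, rows_p = [], [], [], []
    for mode_i, mode in enumerate(config.modes):
        for d_i, d in enumerate(config.diameters_cm):
            for s_i, s in enumerate(config.separations_cm):
                key = {"mode": mode, "diameter_cm": d, "separation_cm": s}
                log.info("running %s seed=%s spacing=%.1f mm", key,
                         config.seed, config.spacing_mm)
                try:
                    out = run_configuration(
                        d, s, mode,
                        _config_seed(config.seed, mode_i, d_i, s_i),
                        config.spacing_mm, config.sim_overrides,
                        config.phantom)
                except Exception:  # pragma: no cover - defensive
                    log.exception("configuration %s failed; skipped", key)
                    continue
                for direction, res in out["vpdr"].items():
                    for p_i, v in enumerate(res.values):
                        rows_v.append({**key, "direction": direction,
                                       "profile_index": p_i, "vpdr_pct": v})
                    rows_s.append({**key, "direction": direction,
                                   "mean_pct": res.mean, "sd_pct": res.sd})
                rows_p.append({**key, "cv_pct": out["cv_pct"],
                               **{f"p_{a}_{b}": p
                                  for (a, b), p in out["pvalues"].items()}})
                rows_t.append({**key,
                               "mean_dose_cgy": out["tissue"].mean_dose_cgy,
                               "intersecting_volume_cm3":
                                   out["tissue"].intersecting_volume_cm3})
    return SweepResult(values=pd.DataFrame(rows_v),
                       summary=pd.DataFrame(rows_s),
                       stats=pd.DataFrame(rows_p),
                       tissue=pd.DataFrame(rows_t))


def write_reports(result: SweepResult, out_dir) -> list:
    """Write the four report tables as CSV with stable float formatting,
    so same-seed reruns are byte-identical.  Returns the paths written."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("vpdr_values", result.values),
                     ("vpdr_summary", result.summary),
                     ("directional_stats", result.stats),
                     ("normal_tissue", result.tissue)):
        path = out / f"sweep_{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# schema_version={REPORT_SCHEMA}\n")
            df.to_csv(fh, index=False, float_format="%.10g",
                      lineterminator="\n")
        paths.append(path)
    return paths


def compare_tables(a: pd.DataFrame, b: pd.DataFrame,
                   keys: tuple[str, ...] = ("diameter_cm", "separation_cm"),
                   value_col: str = "mean_pct") -> pd.DataFrame:
    """Per-configuration directional change report between two summary tables.

    ``a`` is the reference (e.g. coplanar), ``b`` the comparison (e.g.
    non-coplanar); both are tidy with one row per (configuration,
    direction).  Returns per-direction percent change and fold change of
    ``b`` relative to ``a`` plus the directional CV of each table.
    """
    keys = list(keys)
    merged = a.merge(b, on=keys + ["direction"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("tables share no configuration keys")
    va, vb = f"{value_col}_a", f"{value_col}_b"
    merged["percent_change"] = 100.0 * (merged[vb] - merged[va]) / merged[va]
    merged["fold_change"] = merged[vb] / merged[va]

    cv_a = a.groupby(keys)[value_col].apply(directional_cv).rename("cv_a_pct")
    cv_b = b.groupby(keys)[value_col].apply(directional_cv).rename("cv_b_pct")
    merged = merged.merge(cv_a, on=keys).merge(cv_b, on=keys)
    return merged
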