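"""Loaders for the packaged reference tables.

The study's raw dose grids are not deposited, so the published summary
tables ship with the package as plain CSV (under ``latticedose/data``)
and feed the statistics layer directly: directional VPDR means/SDs for
all 20 non-coplanar configurations, the coplanar vs non-coplanar
comparison at 2.0 cm separation, normal-tissue metrics, and per-plan MU /
modulation-complexity values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .plan_metrics import ARC_GEOMETRY, ArcSpec, PlanSummary

__all__ = [
    "load_vpdr_table",
    "load_coplanar_comparison",
    "load_normal_tissue_table",
    "load_plan_table",
    "plans_from_table",
]

_MU_COLUMNS = ("mu_couch0", "mu_couch315", "mu_couch45", "mu_couch90")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("latticedose.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_vpdr_table() -> pd.DataFrame:
    """Directional VPDR means/SDs (%) for the 20 non-coplanar configurations.

    Tidy: diameter_cm, separation_cm, direction, mean_pct, sd_pct.
    """
    return _read("reference_vpdr_noncoplanar.csv")


def load_coplanar_comparison() -> pd.DataFrame:
    """Coplanar vs non-coplanar directional VPDR at 2.0 cm separation."""
    return _read("reference_vpdr_coplanar_vs_noncoplanar.csv")


def load_normal_tissue_table() -> pd.DataFrame:
    """Eval_Normal mean dose (cGy) and intersecting volume (cm^3) per config."""
    return _read("reference_normal_tissue.csv")


def load_plan_table() -> pd.DataFrame:
    """Total MU, per-arc MU (couch 0/315/45/90), and MCS per configuration."""
    return _read("reference_plan_mu.csv")


def plans_from_table(table: pd.DataFrame | None = None) -> list[PlanSummary]:
    """Materialize :class:`PlanSummary` objects (MU only, no MLC sequences)
    from the reference plan table, for cohort MU statistics."""
    if table is None:
        table = load_plan_table()
    plans = []
    for _, row in table.iterrows():
        arcs = tuple(
            ArcSpec(geom[0], geom[1], geom[2], geom[3], float(row[col]))
            for geom, col in zip(ARC_GEOMETRY, _MU_COLUMNS)
        )
        plans.append(PlanSummary(
            f"D{row.diameter_cm:g}_S{row.separation_cm:g}", arcs))
    return plans
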