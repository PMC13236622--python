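"""Directional VPDR uniformity and change statistics.

Covers the statistical layer of the study: the coefficient of variation
across the three directional mean VPDRs, pairwise independent-samples
t-tests between directions with Bonferroni correction (alpha = 0.05 / 60
for 3 pairs x 20 configurations), threshold classification of
configurations, and percent/fold-change comparisons against reference
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DIRECTIONS",
    "PAIRS",
    "directional_cv",
    "pairwise_ttests",
    "bonferroni_threshold",
    "count_configs_below",
    "percent_increase",
    "fold_change",
    "significance_counts",
    "estimate_corridor_amplitudes",
    "recovered_si_transverse_ordering",
]

DIRECTIONS = ("AP", "LAT", "SI")
PAIRS = (("AP", "LAT"), ("AP", "SI"), ("LAT", "SI"))


def directional_cv(means) -> float:
    """Coefficient of variation (%) across the three directional means.

    100 * sample SD (n-1 denominator) / mean of the directional mean
    VPDRs; quantifies directional uniformity (lower = more uniform).
    """
    means = np.asarray(means, dtype=float)
    m = means.mean()
    if m <= 0:
        raise ValueError("mean of directional means must be > 0")
    if means.size < 2:
        raise ValueError("need >= 2 directional means")
    return float(100.0 * means.std(ddof=1) / m)


def pairwise_ttests(samples: dict[str, np.ndarray],
                    equal_var: bool = True) -> dict[tuple[str, str], float]:
    """Two-sided independent two-sample t-tests between direction pairs.

    ``samples`` maps direction labels to the per-profile VPDR values.
    The classical pooled-variance test is the default; ``equal_var=False``
    selects Welch's test.  Degenerate zero-variance input follows the
    convention p = 1 for equal means and p = 0 (with a warning) otherwise.
    """
    out: dict[tuple[str, str], float] = {}
    for a, b in PAIRS:
        if a not in samples or b not in samples:
            continue
        xa = np.asarray(samples[a], dtype=float)
        xb = np.asarray(samples[b], dtype=float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError("each sample set needs >= 2 values")
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            if xa.mean() == xb.mean():
                out[(a, b)] = 1.0
            else:
                warnings.warn(f"{a} vs {b}: zero variance with unequal "
                              "means; p set to 0")
                out[(a, b)] = 0.0
            continue
        out[(a, b)] = float(sps.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
    return out


def bonferroni_threshold(alpha: float = 0.05, m: int = 60) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def count_configs_below(summary: pd.DataFrame, threshold: float,
                        value_col: str = "mean_pct") -> int:
    """Configurations whose AP, LAT and SI mean VPDRs are all below threshold.

    ``summary`` is tidy with one row per (configuration, direction); the
    configuration key is every column except ``direction`` and the value
    column.  Comparison is strict (<).
    """
    keys = [c for c in summary.columns if c not in ("direction", value_col)]
    wide = summary.pivot_table(index=keys, columns="direction",
                               values=value_col)
    return int((wide < threshold).all(axis=1).sum())


def percent_increase(old: float, new: float) -> float:
    """Relative change 100 * (new - old) / old (%)."""
    if old <= 0:
        raise ValueError("reference value must be > 0")
    return 100.0 * (new - old) / old


def fold_change(a: float, b: float) -> float:
    """Ratio b / a."""
    if a == 0:
        raise ValueError("denominator must be nonzero")
    return b / a


def significance_counts(pvalues: pd.DataFrame, alpha_corrected: float
                        ) -> dict[tuple[str, str], int]:
    """Count configurations with p < alpha per direction pair.

    ``pvalues`` carries columns ``p_AP_LAT``, ``p_AP_SI``, ``p_LAT_SI``
    (one row per configuration).
    """
    return {
        pair: int((pvalues[f"p_{pair[0]}_{pair[1]}"] < alpha_corrected).sum())
        for pair in PAIRS
    }


# ----------------------------------------------------------------------
# anisotropy recovery: invert measured VPDRs back to corridor amplitudes
# ----------------------------------------------------------------------

def estimate_corridor_amplitudes(means_pct: dict[str, float],
                                 bath_fraction: float) -> dict[str, float]:
    """Invert directional mean VPDRs to per-direction corridor amplitudes.

    In the synthetic field model the valley dose is ~ (A + f) * peak and
    the peak (1 + f) * peak, with f the bath fraction of the peak, so
    ``A ~ VPDR/100 * (1 + f) - f``.  Used to check that the generating
    anisotropy ordering is recoverable from measurements alone.
    """
    return {
        d: (v / 100.0) * (1.0 + bath_fraction) - bath_fraction
        for d, v in means_pct.items()
    }


def recovered_si_transverse_ordering(means_pct: dict[str, float],
                                     bath_fraction: float) -> str:
    """Classify the SI vs transverse corridor anisotropy from measured VPDRs.

    Returns ``"si_low"`` if the recovered SI amplitude is below the mean
    transverse amplitude, ``"si_high"`` if above, ``"balanced"`` if within
    10% of it.
    """
    amps = estimate_corridor_amplitudes(means_pct, bath_fraction)
    transverse = 0.5 * (amps["AP"] + amps["LAT"])
    if transverse <= 0:
        return "balanced"
    ratio = amps["SI"] / transverse
    if ratio < 0.9:
        return "si_low"
    if ratio > 1.1:
        return "si_high"
    return "balanced"
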