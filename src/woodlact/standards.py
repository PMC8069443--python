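"""Yield standardization and the ICAR test-interval total.

Two official conventions used by milk recording schemes:

* fat-corrected milk (FCM) at a 3.5% fat reference, so yields of
  differing fat concentration are comparable;
* the ICAR test-interval method, which credits each interval between two
  controls with the mean of its bounding daily productions times the
  interval length — a trapezoid rule on the recording grid.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fcm_3_5", "constituent_daily_yield", "icar_total"]

#: coefficients of the 3.5% fat-correction formula
#: FCM = DMY * (0.634 + 0.1046 * fat%)
FCM_INTERCEPT = 0.634
FCM_FAT_COEF = 0.1046


def fcm_3_5(dmy, fat_pct):
    """Fat-corrected daily milk yield (g/day) at the 3.5% fat reference.

    ``FCM = DMY * (0.634 + 0.1046 * FY)`` with DMY the daily milk yield
    (g/day) and FY the fat content (%).  Vectorized over arrays.
    """
    dmy = np.asarray(dmy, dtype=float)
    fat_pct = np.asarray(fat_pct, dtype=float)
    if np.any(dmy < 0) or np.any(fat_pct < 0):
        raise ValueError("milk yield and fat content must be non-negative")
    out = dmy * (FCM_INTERCEPT + FCM_FAT_COEF * fat_pct)
    return float(out) if out.ndim == 0 else out


def constituent_daily_yield(dmy, pct):
    """Constituent (fat or protein) daily yield g/day from milk and content %."""
    dmy = np.asarray(dmy, dtype=float)
    pct = np.asarray(pct, dtype=float)
    if np.any(dmy < 0):
        raise ValueError("milk yield must be non-negative")
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("content percentage must lie in [0, 100]")
    out = dmy * pct / 100.0
    return float(out) if out.ndim == 0 else out


def icar_total(
    dims,
    productions,
    start_dim: float = 3,
    end_dim: float = 210,
    edges: str = "include",
) -> float:
    """ICAR test-interval total yield (kg) from a monthly control series.

    Each interval between consecutive controls contributes
    ``(P_n + P_{n-1}) / 2 * d`` with ``d`` the days between them.  With
    ``edges="include"`` (ICAR practice) the days before the first control
    and after the last one are credited at constant extrapolation,
    ``P_first * (dim_1 - start_dim)`` and ``P_last * (end_dim - dim_last)``;
    ``edges="between_only"`` restricts to the between-control intervals.

    dims must be strictly increasing; productions in g/day.
    """
    dims = np.asarray(dims, dtype=float)
    prods = np.asarray(productions, dtype=float)
    if dims.shape != prods.shape or dims.ndim != 1 or dims.size < 1:
        raise ValueError("dims and productions must be equal-length 1-d, non-empty")
    if np.any(np.diff(dims) <= 0):
        raise ValueError("control dims must be strictly increasing (no duplicates)")
    if edges not in ("include", "between_only"):
        raise ValueError(f"unknown edges mode {edges!r}")
    if edges == "include":
        if not (start_dim <= dims[0] and end_dim >= dims[-1]):
            raise ValueError("period [start_dim, end_dim] must cover the controls")

    grams = float(np.trapezoid(prods, dims)) if dims.size > 1 else 0.0
    if edges == "include":
        grams += prods[0] * (dims[0] - start_dim)
        grams += prods[-1] * (end_dim - dims[-1])
    return grams / 1000.0
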