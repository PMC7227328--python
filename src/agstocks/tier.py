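"""Tier 1 conversion-coefficient error analysis.

Carbon accounting without local trait data converts biomass density to carbon
density with a fixed coefficient — 0.47 (the IPCC Tier 1 default) or 0.5 (a
common alternative).  Against in-situ data, the error of a coefficient c for
a class whose effective (biomass-weighted) carbon fraction is f is

    error(c) = 100 · (c / f − 1)   [percent; positive = overestimate]

which ties the two coefficients together exactly:

    error(0.47) = 100 · (0.94 · (1 + error(0.5)/100) − 1)

so a published pair of percentages can be checked for internal consistency,
and the effective fraction can be recovered from either error alone.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "effective_fraction",
    "coefficient_error",
    "invert_error",
    "paired_error",
    "check_pair_consistency",
    "tier_report",
    "tier_report_from_published",
]

TIER1_COEFFICIENT = 0.47
COMMON_COEFFICIENT = 0.50


def effective_fraction(carbon_kg, biomass_kg) -> float:
    """Biomass-weighted carbon fraction of a class: Σ carbon / Σ biomass.

    Accepts totals or per-tree arrays; this (not the tree-averaged fraction)
    is the fraction a fixed coefficient competes with, because mean carbon
    density is a biomass-weighted quantity.
    """
    c = float(np.sum(carbon_kg))
    b = float(np.sum(biomass_kg))
    if b <= 0:
        raise ValueError("total biomass must be positive")
    return c / b


def coefficient_error(fraction: float, coefficient: float) -> float:
    """Percent error of a fixed coefficient against an effective fraction."""
    if fraction <= 0:
        raise ValueError("effective fraction must be positive")
    return 100.0 * (coefficient / fraction - 1.0)


def invert_error(coefficient: float, error_pct: float) -> float:
    """Effective fraction implied by a coefficient and its percent error."""
    if error_pct <= -100:
        raise ValueError("error must exceed -100%")
    return coefficient / (1.0 + error_pct / 100.0)


def paired_error(error_050_pct: float, coefficient: float = TIER1_COEFFICIENT) -> float:
    """Error of *coefficient* implied by the 0.5-coefficient error."""
    return coefficient_error(invert_error(COMMON_COEFFICIENT, error_050_pct), coefficient)


def check_pair_consistency(
    error_050_pct: float, error_047_pct: float, tol: float = 0.02
) -> bool:
    """Whether a published (0.5-error, 0.47-error) pair obeys the identity.

    *tol* is in percentage points; the default absorbs two-decimal rounding
    of both printed figures.  Signs matter: the printed 0.47 figures are
    magnitudes, so pass them signed (negative for underestimates).
    """
    return abs(paired_error(error_050_pct) - error_047_pct) <= tol


def tier_report(tree_stocks: pd.DataFrame, by: str = "lulc") -> pd.DataFrame:
    """Per-class effective fraction and fixed-coefficient errors.

    Expects the output of :func:`agstocks.accounting.compute_tree_stocks`
    with a class column (merge the plot register's ``lulc`` in beforehand if
    needed).
    """
    if by not in tree_stocks.columns:
        raise ValueError(f"column {by!r} not in tree stocks")
    rows = []
    for lulc, sub in tree_stocks.groupby(by, sort=False):
        f = effective_fraction(sub["carbon_kg"], sub["biomass_kg"])
        rows.append({
            "lulc": lulc,
            "effective_fraction": f,
            "error_050_pct": coefficient_error(f, COMMON_COEFFICIENT),
            "error_047_pct": coefficient_error(f, TIER1_COEFFICIENT),
        })
    return pd.DataFrame(rows)


def tier_report_from_published(pairs: pd.DataFrame, tol: float = 0.02) -> pd.DataFrame:
    """Audit published (0.5, 0.47) error pairs per class.

    ``pairs`` needs ``lulc, error_050_pct, error_047_pct`` (signed percent).
    Returns the implied effective fraction, the 0.47 error recomputed from
    the 0.5 error, and a ``consistent`` flag for the algebraic identity.
    """
    out = pairs.copy()
    out["effective_fraction"] = [
        invert_error(COMMON_COEFFICIENT, e) for e in out["error_050_pct"]
    ]
    out["implied_error_047_pct"] = [paired_error(e) for e in out["error_050_pct"]]
    out["consistent"] = [
        check_pair_consistency(e50, e47, tol=tol)
        for e50, e47 in zip(out["error_050_pct"], out["error_047_pct"])
    ]
    return out
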