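"""Tracer mass-balance partitioning of soil excess 13C into net rhizodeposition.

The approach assumes (i) homogeneous 13C enrichment within the root system and
(ii) equal enrichment of roots and rhizodeposits.  Under these assumptions the
share of the labelled belowground carbon found in the soil pool,

    %CdfR = mE_soil / (mE_soil + mE_root) * 100,

equals the rhizodeposit share of belowground carbon, and the quantity of
carbon derived from rhizodeposition follows from the layer's corrected root C:

    qCdfR = %CdfR * RC_s / (100 - %CdfR).

Net rhizodeposition is operationally everything labelled in the < 0.5 mm soil
fraction, which includes fine root fragments below that size.  Allocation
coefficients express grain, straw, root and rhizodeposition C as proportions
of whole-plant assimilated C.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingGroupError, UndefinedPartitionError

logger = logging.getLogger(__name__)

__all__ = [
    "percent_cdfr",
    "q_cdfr",
    "relative_rhizodeposition",
    "allocation_coefficients",
    "carbon_ratios",
    "treatment_summary",
]


def percent_cdfr(soil_excess_mass, root_excess_mass):
    """Percent of belowground tracer recovered in the soil pool, in [0, 100).

    Both excess masses are g 13C m-2 for one plot and soil layer (root excess
    summed over the root classes present in that layer).  A zero total is
    undefined: the plot/layer must be flagged and excluded upstream.
    """
    soil = np.asarray(soil_excess_mass, dtype=float)
    root = np.asarray(root_excess_mass, dtype=float)
    total = soil + root
    if np.any(total <= 0):
        raise UndefinedPartitionError(
            "soil + root excess mass must be positive to partition the tracer"
        )
    out = soil / total * 100.0
    return out if out.ndim else float(out)


def q_cdfr(pct, root_carbon):
    """Quantity of C derived from rhizodeposition (g C m-2).

    qCdfR = pct * RC / (100 - pct) with RC the layer's corrected root C.
    Satisfies the identity qCdfR / (qCdfR + RC) = pct / 100 exactly.
    """
    pct = np.asarray(pct, dtype=float)
    rc = np.asarray(root_carbon, dtype=float)
    if np.any((pct < 0) | (pct >= 100.0)):
        raise UndefinedPartitionError("%CdfR must lie in [0, 100) for a finite qCdfR")
    if np.any(rc < 0):
        raise ValueError("root carbon must be non-negative")
    out = pct * rc / (100.0 - pct)
    return out if out.ndim else float(out)


def relative_rhizodeposition(q, root_carbon):
    """Rhizodeposition C as a fraction of total belowground C: q / (q + RC)."""
    q = np.asarray(q, dtype=float)
    rc = np.asarray(root_carbon, dtype=float)
    total = q + rc
    if np.any(total <= 0):
        raise UndefinedPartitionError("q + root carbon must be positive")
    out = q / total
    return out if out.ndim else float(out)


def allocation_coefficients(grain_c, straw_c, root_c, rhizo_c):
    """Proportions of whole-plant C in grain, straw, root and rhizodeposition.

    Returns the four fractions in input order; they sum to 1 by construction.
    """
    parts = np.stack(
        [np.asarray(v, dtype=float) for v in (grain_c, straw_c, root_c, rhizo_c)]
    )
    if np.any(parts < 0):
        raise ValueError("carbon pools must be non-negative")
    total = parts.sum(axis=0)
    if np.any(total <= 0):
        raise UndefinedPartitionError("total plant C must be positive")
    coeffs = parts / total
    if coeffs.ndim == 1:
        return tuple(float(c) for c in coeffs)
    return tuple(coeffs)


def carbon_ratios(grain_c, straw_c, root_c, rhizo_c):
    """(root-to-shoot, belowground-to-aboveground) carbon ratios.

    root:shoot = root C / straw C; below:above = (root C + rhizodeposition C)
    / (straw C + grain C).  Both are scale-invariant.
    """
    grain = np.asarray(grain_c, dtype=float)
    straw = np.asarray(straw_c, dtype=float)
    root = np.asarray(root_c, dtype=float)
    rhizo = np.asarray(rhizo_c, dtype=float)
    if np.any(straw <= 0) or np.any(grain + straw <= 0):
        raise UndefinedPartitionError("straw C and aboveground C must be positive")
    rs = root / straw
    ba = (root + rhizo) / (straw + grain)
    if rs.ndim == 0:
        return float(rs), float(ba)
    return rs, ba


def treatment_summary(
    results: pd.DataFrame,
    value_cols: Sequence[str],
    *,
    system_col: str = "system",
    regime_col: str = "regime",
    control: str = "control",
    drought: str = "drought",
) -> pd.DataFrame:
    """Group means, standard errors and drought-vs-control percent change.

    Summarises per-plot results by cropping system x water regime and pooled
    across systems (``system == 'all'``).  SE = sd / sqrt(n) over plot
    replicates; for single-plot groups the SE is reported missing (logged).
    Percent change = (mean_drought - mean_control) / mean_control * 100 per
    system and pooled, attached to the drought rows.

    Returns a long frame with columns ``system, regime, variable, n, mean,
    se, pct_change_vs_control``.
    """
    if results.empty:
        raise MissingGroupError("no plot results to summarise")
    frames = [results]
    pooled = results.copy()
    pooled[system_col] = "all"
    frames.append(pooled)
    stacked = pd.concat(frames, ignore_index=True)

    long = stacked.melt(
        id_vars=[system_col, regime_col],
        value_vars=list(value_cols),
        var_name="variable",
        value_name="value",
    ).dropna(subset=["value"])
    if long.empty:
        raise MissingGroupError("all requested variables are missing")

    grp = long.groupby([system_col, regime_col, "variable"], as_index=False)["value"].agg(
        n="count", mean="mean", sd=lambda v: v.std(ddof=1)
    )
    grp["se"] = grp["sd"] / np.sqrt(grp["n"])
    singles = grp[grp["n"] < 2]
    if len(singles):
        logger.warning(
            "standard error undefined for single-plot group(s): %s",
            singles[[system_col, regime_col, "variable"]].to_dict("records"),
        )
    grp = grp.drop(columns="sd")

    wide = grp.pivot_table(
        index=[system_col, "variable"], columns=regime_col, values="mean"
    )
    if control in wide.columns and drought in wide.columns:
        change = (wide[drought] - wide[control]) / wide[control] * 100.0
        change.name = "pct_change_vs_control"
        grp = grp.merge(change.reset_index(), on=[system_col, "variable"], how="left")
        grp.loc[grp[regime_col] != drought, "pct_change_vs_control"] = np.nan
    else:
        grp["pct_change_vs_control"] = np.nan

    return grp.rename(columns={system_col: "system", regime_col: "regime"}).sort_values(
        ["system", "variable", "regime"]
    ).reset_index(drop=True)
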