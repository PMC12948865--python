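"""Root carbon pools: EOM correction, area scaling, and design aggregation.

Washed fine-root samples from the topsoil carry extraneous organic matter
(EOM — residues of organic amendments, litter, soil fauna, preceding crops).
Because EOM carries no tracer, a two-pool isotope mixing model separates root
carbon from EOM carbon using the atom-excess fractions of the bulk sample, a
clean-root endmember and the EOM endmember.  Mass-based root C (g C per kg dry
soil) from cores is scaled to area with layer bulk density and thickness, and
samples are aggregated following the field design: crown and coarse roots of
the topsoil are summed, within-row and between-row cores of the deeper layers
are averaged per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateMixingError, IncompleteDesignError, InvalidIsotopeRatioError
from .isotopes import AtomExcess

logger = logging.getLogger(__name__)

__all__ = [
    "LayerGeometry",
    "EomReference",
    "eom_root_fraction",
    "area_scale",
    "aggregate_roots",
    "TOPSOIL",
    "SUBSOIL_POSITIONS",
]

#: Canonical layer labels (m below surface); the first is the only one that
#: receives crown roots and the EOM correction.
TOPSOIL = "0-0.25"
SUBSOIL_POSITIONS = ("within_row", "between_row")


@dataclass(frozen=True)
class LayerGeometry:
    """Thickness (m) and dry bulk density (kg m-3) of one sampled soil layer."""

    layer: str
    thickness_m: float
    bulk_density_kg_m3: float

    def __post_init__(self) -> None:
        if self.thickness_m <= 0:
            raise ValueError(f"layer thickness must be positive, got {self.thickness_m}")
        if not (800.0 <= self.bulk_density_kg_m3 <= 2000.0):
            raise ValueError(
                f"bulk density {self.bulk_density_kg_m3} kg m-3 outside plausible range [800, 2000]"
            )


@dataclass(frozen=True)
class EomReference:
    """delta-13C of extraneous organic matter; default −29.3 permil."""

    delta13c_permil: float = -29.3

    def __post_init__(self) -> None:
        if not (-35.0 < self.delta13c_permil < -20.0):
            raise InvalidIsotopeRatioError(
                f"EOM delta13C {self.delta13c_permil} outside the natural-abundance range (-35, -20)"
            )


def eom_root_fraction(sample_excess, clean_root_excess, eom_excess, *, clamp: bool = True):
    """Root-C mass fraction f_RBC of a fine-root sample from two-pool mixing.

    f_RBC = (xE_sample − xE_EOM) / (xE_root − xE_EOM).  Equals 1 for a pure
    clean-root sample and 0 for pure EOM; linear in between.  Invariant under
    a common shift of all three excess values (only differences enter).

    Raw values outside [0, 1] arise from measurement noise pushing the sample
    outside its endmembers; they are clamped with a warning (the unclamped
    value is logged) unless ``clamp=False``.
    """
    xs = sample_excess.value if isinstance(sample_excess, AtomExcess) else sample_excess
    xr = clean_root_excess.value if isinstance(clean_root_excess, AtomExcess) else clean_root_excess
    xe = eom_excess.value if isinstance(eom_excess, AtomExcess) else eom_excess
    denom = xr - xe
    if np.any(np.asarray(denom) == 0.0):
        raise DegenerateMixingError(
            "clean-root and EOM endmembers have identical atom excess; mixing fraction undefined"
        )
    f = (np.asarray(xs, dtype=float) - xe) / denom
    raw = f if np.ndim(f) else float(f)
    if clamp:
        out_of_range = (np.asarray(f) < 0.0) | (np.asarray(f) > 1.0)
        if np.any(out_of_range):
            logger.warning(
                "f_RBC outside [0, 1] clamped; raw value(s): %s",
                np.asarray(raw)[np.atleast_1d(out_of_range)]
                if np.ndim(raw)
                else raw,
            )
        f = np.clip(f, 0.0, 1.0)
    return f if np.ndim(f) else float(f)


def area_scale(mass_based_c, geometry: LayerGeometry):
    """Scale mass-related root C (g C per kg dry soil) to area (g C m-2).

    RC_S = RC_M * rho * z, with rho the layer bulk density (kg m-3) and z the
    layer thickness (m).
    """
    mass_based_c = np.asarray(mass_based_c, dtype=float)
    if np.any(mass_based_c < 0):
        raise ValueError("mass-based root C must be non-negative")
    out = mass_based_c * geometry.bulk_density_kg_m3 * geometry.thickness_m
    return out if out.ndim else float(out)


def aggregate_roots(
    samples: pd.DataFrame,
    value_cols: Sequence[str] = ("carbon_g_m2",),
    *,
    f_rbc: Mapping[str, float] | None = None,
    carbon_col: str = "carbon_g_m2",
    topsoil: str = TOPSOIL,
) -> pd.DataFrame:
    """Aggregate per-sample root values to one row per plot, layer and class.

    Expects a tidy frame with columns ``plot_id, layer, root_class, position``
    plus the ``value_cols`` (already in g m-2).  Applies the field design:

    * within-row and between-row cores in the sub-topsoil layers are averaged
      per plot, layer and root class (both positions must be present);
    * in the topsoil, crown-root values are added to the coarse class;
    * the topsoil fine-root *carbon* is multiplied by the plot's EOM
      correction factor ``f_rbc`` (if given) before aggregation.  Other value
      columns (e.g. excess mass) pass through uncorrected.

    Returns a frame with columns ``plot_id, layer, root_class`` and the value
    columns; topsoil class sums conserve the (corrected) input mass.
    """
    required = {"plot_id", "layer", "root_class", "position", *value_cols}
    missing = required - set(samples.columns)
    if missing:
        raise KeyError(f"aggregate_roots input missing columns: {sorted(missing)}")
    df = samples.copy()

    if f_rbc is not None:
        mask = (df["layer"] == topsoil) & (df["root_class"] == "fine")
        factors = df.loc[mask, "plot_id"].map(f_rbc)
        if factors.isna().any():
            absent = sorted(df.loc[mask, "plot_id"][factors.isna()].unique())
            raise KeyError(f"no f_RBC correction factor for plots: {absent}")
        df.loc[mask, carbon_col] = df.loc[mask, carbon_col] * factors.to_numpy()

    # positions in the deeper layers must come in within/between pairs
    deep = df[df["layer"] != topsoil]
    pos_counts = deep.groupby(["plot_id", "layer", "root_class"])["position"].agg(
        lambda p: frozenset(p)
    )
    incomplete = pos_counts[pos_counts != frozenset(SUBSOIL_POSITIONS)]
    if len(incomplete):
        raise IncompleteDesignError(
            "missing within/between-row partner for: "
            + ", ".join(map(str, incomplete.index.tolist()[:5]))
        )

    # average positions (topsoil rows are single-position; mean is identity)
    agg = (
        df.groupby(["plot_id", "layer", "root_class"], as_index=False)[list(value_cols)]
        .mean()
    )

    # crown roots of the topsoil are summed into the coarse class
    crown = agg["root_class"] == "crown"
    if (crown & (agg["layer"] != topsoil)).any():
        raise IncompleteDesignError("crown roots are only sampled in the topsoil layer")
    agg.loc[crown, "root_class"] = "coarse"
    agg = agg.groupby(["plot_id", "layer", "root_class"], as_index=False)[list(value_cols)].sum()
    return agg.sort_values(["plot_id", "layer", "root_class"]).reset_index(drop=True)
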