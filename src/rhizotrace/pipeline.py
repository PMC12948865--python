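"""End-to-end tracer mass-balance pipeline.

Chains the calculation stages in their natural order: atom excess against
treatment/layer-matched natural-abundance references → excess-13C masses →
EOM-corrected, area-scaled, design-aggregated root C → per-layer tracer
partitioning (%CdfR, qCdfR) → profile totals, allocation coefficients and
ratios → treatment summaries.  :func:`analyze` is the in-memory core;
:func:`run_pipeline` adds file I/O, configuration and a run log recording
every reference pairing problem, clamp and exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as rio
from .errors import ConfigurationError, IncompleteDesignError, ReferencePairingError
from .isotopes import VPDB, IsotopeConstants, delta_to_atom_fraction, excess_mass
from .rhizo import allocation_coefficients, carbon_ratios, treatment_summary
from .roots import TOPSOIL, aggregate_roots, eom_root_fraction

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze", "run_pipeline"]

PROFILE_VALUE_COLS = (
    "grain_c_g_m2", "straw_c_g_m2", "root_c_g_m2", "rhizo_c_g_m2",
    "pct_cdfr_profile", "relative_rhizodeposition",
    "alloc_grain", "alloc_straw", "alloc_root", "alloc_rhizo",
    "root_to_shoot", "below_to_above",
)


@dataclass
class PipelineResult:
    """Tables produced by one pipeline run, plus the event log."""

    layer_table: pd.DataFrame
    profile_table: pd.DataFrame
    summary: pd.DataFrame
    f_rbc: pd.DataFrame
    events: List[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.layer_table.to_csv(out / "plot_layer_results.csv", index=False)
        self.profile_table.to_csv(out / "plot_profile_results.csv", index=False)
        self.summary.to_csv(out / "treatment_summary.csv", index=False)
        self.f_rbc.to_csv(out / "f_rbc.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(self.events) + "\n")


class RunConfig(BaseModel):
    """Paths and options for a file-based pipeline run."""

    model_config = ConfigDict(frozen=True)

    measurements: str
    references: str
    geometry: str
    output_dir: Optional[str] = None
    delta_eom: float = -29.3
    r_vpdb: float = VPDB.r_vpdb
    topsoil_layer: str = TOPSOIL
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _pair_references(
    measurements: pd.DataFrame, references: pd.DataFrame
) -> pd.DataFrame:
    m = measurements.copy()
    m["material"] = np.where(m["compartment"] == "soil", "soil", "plant")
    refs = references.rename(columns={"delta13C_permil": "ref_delta13C_permil"})
    merged = m.merge(refs, on=["system", "regime", "layer", "material"], how="left")
    missing = merged["ref_delta13C_permil"].isna()
    if missing.any():
        combos = (
            merged.loc[missing, ["system", "regime", "layer", "material"]]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ReferencePairingError(
            f"no natural-abundance reference for treatment x layer combination(s): {combos}"
        )
    merged["reference_id"] = (
        merged["system"] + "/" + merged["regime"] + "/"
        + merged["layer"] + "/" + merged["material"]
    )
    return merged


def _carbon_per_area(merged: pd.DataFrame, geometry: pd.DataFrame) -> pd.Series:
    geo = geometry.set_index("layer")
    soil_based = merged["mass_basis"] == "soil"
    uncovered = set(merged.loc[soil_based, "layer"]) - set(geo.index)
    if uncovered:
        raise ConfigurationError(
            f"geometry table lacks layer(s) required by soil-based masses: {sorted(uncovered)}"
        )
    carbon = merged["mass_value"] * merged["c_concentration"]
    rho = merged["layer"].map(geo["bulk_density_kg_m3"])
    z = merged["layer"].map(geo["thickness_m"])
    return carbon.where(~soil_based, carbon * rho * z)


def _eom_factors(
    merged: pd.DataFrame,
    delta_eom: float,
    constants: IsotopeConstants,
    topsoil: str,
    events: List[str],
) -> pd.DataFrame:
    """Per-plot EOM correction factor from the two-pool mixing model.

    The bulk topsoil fine-root sample is the mixture; the plot's topsoil
    coarse-root atom excess serves as the clean-root endmember (under the
    homogeneous-root-enrichment assumption all root classes share one
    enrichment); the EOM endmember converts the EOM delta against the same
    plant reference.
    """
    x_eom = delta_to_atom_fraction(delta_eom, constants).x13
    top = merged[merged["layer"] == topsoil]
    fine = top[top["compartment"] == "fine_root"].set_index("plot_id")
    coarse = top[top["compartment"] == "coarse_root"].set_index("plot_id")
    rows = []
    for plot_id, sample in fine.iterrows():
        if plot_id not in coarse.index:
            raise IncompleteDesignError(
                f"plot {plot_id}: topsoil fine-root sample has no coarse-root "
                "clean-root endmember"
            )
        clean = coarse.loc[plot_id]
        x_ref = delta_to_atom_fraction(
            float(sample["ref_delta13C_permil"]), constants
        ).x13
        eom_excess = x_eom - x_ref
        raw = eom_root_fraction(
            float(sample["excess_x"]), float(clean["excess_x"]), eom_excess, clamp=False
        )
        f = min(max(raw, 0.0), 1.0)
        if raw != f:
            events.append(f"f_RBC clamp: plot {plot_id} raw={raw:.6f} -> {f:.1f}")
        rows.append({"plot_id": plot_id, "f_rbc_raw": raw, "f_rbc": f})
    return pd.DataFrame(rows, columns=["plot_id", "f_rbc_raw", "f_rbc"])


def analyze(
    measurements: pd.DataFrame,
    references: pd.DataFrame,
    geometry: pd.DataFrame,
    *,
    delta_eom: float = -29.3,
    constants: IsotopeConstants = VPDB,
    topsoil: str = TOPSOIL,
) -> PipelineResult:
    """Run the full mass-balance analysis on in-memory tables.

    Deterministic for fixed inputs.  Returns per-plot-per-layer and per-plot
    profile tables, the treatment summary, the EOM correction factors and an
    event log of every clamp and exclusion.
    """
    events: List[str] = []
    merged = _pair_references(measurements, references)

    x_lab = delta_to_atom_fraction(merged["delta13C_permil"].to_numpy(), constants)
    x_ref = delta_to_atom_fraction(merged["ref_delta13C_permil"].to_numpy(), constants)
    merged["excess_x"] = x_lab.x13 - x_ref.x13
    merged["carbon_g_m2"] = _carbon_per_area(merged, geometry)
    merged["excess_g_m2"] = excess_mass(
        merged["excess_x"].to_numpy(), merged["carbon_g_m2"].to_numpy(),
        x_lab.x13, constants,
    )
    n_neg = int((merged["excess_g_m2"] < 0).sum())
    if n_neg:
        events.append(f"{n_neg} measurement(s) with negative excess mass (below reference)")
        logger.info("%d negative excess-mass measurements retained at isotope stage", n_neg)

    f_rbc = _eom_factors(merged, delta_eom, constants, topsoil, events)
    f_map = dict(zip(f_rbc["plot_id"], f_rbc["f_rbc"]))

    roots = merged[merged["compartment"].str.endswith("_root")].copy()
    roots["root_class"] = roots["compartment"].str.removesuffix("_root")
    agg = aggregate_roots(
        roots[["plot_id", "layer", "root_class", "position", "carbon_g_m2", "excess_g_m2"]],
        value_cols=("carbon_g_m2", "excess_g_m2"),
        f_rbc=f_map if f_map else None,
        topsoil=topsoil,
    )
    layer_roots = (
        agg.groupby(["plot_id", "layer"], as_index=False)[["carbon_g_m2", "excess_g_m2"]]
        .sum()
        .rename(columns={"carbon_g_m2": "root_carbon_g_m2",
                         "excess_g_m2": "root_excess_g_m2"})
    )
    soil = merged[merged["compartment"] == "soil"][
        ["plot_id", "system", "regime", "layer", "excess_g_m2"]
    ].rename(columns={"excess_g_m2": "soil_excess_g_m2"})
    bundles = soil.merge(layer_roots, on=["plot_id", "layer"], how="inner")

    for col in ("soil_excess_g_m2", "root_excess_g_m2"):
        neg = bundles[col] < 0
        if neg.any():
            events.append(
                f"{int(neg.sum())} negative {col} value(s) clamped to 0 entering layer bundles"
            )
            bundles.loc[neg, col] = 0.0

    total_excess = bundles["soil_excess_g_m2"] + bundles["root_excess_g_m2"]
    undefined = total_excess <= 0
    singular = (bundles["root_excess_g_m2"] <= 0) & (bundles["soil_excess_g_m2"] > 0)
    bundles["excluded"] = undefined | singular
    for _, row in bundles[bundles["excluded"]].iterrows():
        events.append(
            f"excluded plot {row['plot_id']} layer {row['layer']}: "
            + ("no excess in soil or roots" if row["soil_excess_g_m2"] <= 0
               else "zero root excess with positive soil excess (singular partition)")
        )
    ok = ~bundles["excluded"]
    bundles["pct_cdfr"] = np.nan
    bundles.loc[ok, "pct_cdfr"] = (
        bundles.loc[ok, "soil_excess_g_m2"] / total_excess[ok] * 100.0
    )
    bundles["q_cdfr_g_m2"] = (
        bundles["pct_cdfr"] * bundles["root_carbon_g_m2"] / (100.0 - bundles["pct_cdfr"])
    )
    denom = bundles["q_cdfr_g_m2"] + bundles["root_carbon_g_m2"]
    bundles["relative_rhizodeposition"] = bundles["q_cdfr_g_m2"] / denom
    layer_table = bundles[
        ["plot_id", "system", "regime", "layer", "root_carbon_g_m2",
         "root_excess_g_m2", "soil_excess_g_m2", "pct_cdfr", "q_cdfr_g_m2",
         "relative_rhizodeposition", "excluded"]
    ].sort_values(["plot_id", "layer"]).reset_index(drop=True)

    # whole-profile totals: excess masses summed, %CdfR recomputed from the
    # sums (mass balance is additive), qCdfR summed over layers
    valid = bundles[ok]
    prof = valid.groupby(["plot_id", "system", "regime"], as_index=False).agg(
        root_c_g_m2=("root_carbon_g_m2", "sum"),
        root_excess_g_m2=("root_excess_g_m2", "sum"),
        soil_excess_g_m2=("soil_excess_g_m2", "sum"),
        rhizo_c_g_m2=("q_cdfr_g_m2", "sum"),
        n_layers=("layer", "count"),
    )
    prof["pct_cdfr_profile"] = (
        prof["soil_excess_g_m2"]
        / (prof["soil_excess_g_m2"] + prof["root_excess_g_m2"]) * 100.0
    )
    prof["relative_rhizodeposition"] = prof["rhizo_c_g_m2"] / (
        prof["rhizo_c_g_m2"] + prof["root_c_g_m2"]
    )

    above = (
        merged[merged["compartment"].isin(("grain", "straw"))]
        .pivot_table(index="plot_id", columns="compartment",
                     values="carbon_g_m2", aggfunc="sum")
        .rename(columns={"grain": "grain_c_g_m2", "straw": "straw_c_g_m2"})
        .reset_index()
    )
    prof = prof.merge(above, on="plot_id", how="left")

    coeffs = allocation_coefficients(
        prof["grain_c_g_m2"].to_numpy(), prof["straw_c_g_m2"].to_numpy(),
        prof["root_c_g_m2"].to_numpy(), prof["rhizo_c_g_m2"].to_numpy(),
    )
    prof["alloc_grain"], prof["alloc_straw"], prof["alloc_root"], prof["alloc_rhizo"] = coeffs
    rs, ba = carbon_ratios(
        prof["grain_c_g_m2"].to_numpy(), prof["straw_c_g_m2"].to_numpy(),
        prof["root_c_g_m2"].to_numpy(), prof["rhizo_c_g_m2"].to_numpy(),
    )
    prof["root_to_shoot"] = rs
    prof["below_to_above"] = ba
    profile_table = prof.sort_values("plot_id").reset_index(drop=True)

    summary = treatment_summary(profile_table, PROFILE_VALUE_COLS)
    return PipelineResult(
        layer_table=layer_table,
        profile_table=profile_table,
        summary=summary,
        f_rbc=f_rbc,
        events=events,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run: read, validate, analyze, optionally write."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for path in (config.measurements, config.references, config.geometry):
        if not Path(path).exists():
            raise ConfigurationError(f"input file does not exist: {path}")
    measurements = rio.read_measurements(config.measurements)
    references = rio.read_references(config.references)
    geometry = rio.read_geometry(config.geometry)
    result = analyze(
        measurements, references, geometry,
        delta_eom=config.delta_eom,
        constants=IsotopeConstants(r_vpdb=config.r_vpdb),
        topsoil=config.topsoil_layer,
    )
    for event in result.events:
        logger.info("%s", event)
    if config.output_dir:
        result.write(config.output_dir)
    return result
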