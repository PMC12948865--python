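"""Stable carbon isotope arithmetic: delta notation, atom fractions, atom excess
and excess-:sup:`13`\\ C mass.

All conversions assume a binary isotope system (only :sup:`12`\\ C and
:sup:`13`\\ C), which is the standard treatment for tracer mass balances at
natural to moderately enriched :sup:`13`\\ C levels.  Delta values are per mil
versus the VPDB standard.

Functions accept scalars or numpy arrays and are the single place in the
package where isotope symbols live; every other module works with the derived
quantities (atom-excess fractions and excess masses in g :sup:`13`\\ C m\\
:sup:`-2`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidIsotopeRatioError

__all__ = [
    "IsotopeConstants",
    "VPDB",
    "AtomFractions",
    "AtomExcess",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "atom_excess",
    "excess_mass",
    "atom_fraction_for_excess",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Molar masses of the two carbon isotopes and the VPDB isotope ratio.

    The single source of truth for conversions.  ``r_vpdb`` defaults to
    0.0111802, the :sup:`13`\\ C/:sup:`12`\\ C ratio of the VPDB standard in
    the Coplen framework; the molar masses are CODATA values.  Overriding
    ``r_vpdb`` (e.g. with the truncated 0.011180) changes downstream results
    reproducibly in the fifth significant figure.
    """

    m12: float = 12.0
    m13: float = 13.0033548
    r_vpdb: float = 0.0111802

    def __post_init__(self) -> None:
        if not (self.m13 > self.m12 > 0):
            raise InvalidIsotopeRatioError(
                f"molar masses must satisfy m13 > m12 > 0, got m12={self.m12}, m13={self.m13}"
            )
        if not (0 < self.r_vpdb < 1):
            raise InvalidIsotopeRatioError(f"r_vpdb must lie in (0, 1), got {self.r_vpdb}")

    def mean_atomic_mass(self, x13):
        """Mean atomic mass of carbon with a given 13C atom fraction (g mol-1)."""
        x13 = np.asarray(x13, dtype=float)
        return (1.0 - x13) * self.m12 + x13 * self.m13


#: Default constants used throughout the package.
VPDB = IsotopeConstants()


class AtomFractions(NamedTuple):
    """13C and 12C atom fractions of a sample; ``x13 + x12 == 1`` by construction."""

    x13: float
    x12: float


class AtomExcess(NamedTuple):
    """Atom-excess fraction (labelled minus natural-abundance reference).

    ``reference_id`` records which natural-abundance record was subtracted so
    that every derived excess is traceable to its reference pairing.
    """

    value: float
    reference_id: str


def delta_to_atom_fraction(delta, constants: IsotopeConstants = VPDB) -> AtomFractions:
    """Convert delta-13C (per mil vs VPDB) to atom fractions.

    Uses R = R_VPDB * (delta/1000 + 1) and x13 = R / (1 + R).  Strictly
    increasing in delta.  delta <= -1000 per mil would imply a sample with no
    13C at all and is rejected.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise InvalidIsotopeRatioError(
            "delta13C <= -1000 permil implies a non-positive 13C/12C ratio"
        )
    r = constants.r_vpdb * (delta / 1000.0 + 1.0)
    x13 = r / (1.0 + r)
    if not x13.ndim:
        x13 = float(x13)
    return AtomFractions(x13=x13, x12=1.0 - x13)


def atom_fraction_to_delta(x13, constants: IsotopeConstants = VPDB):
    """Convert a 13C atom fraction back to delta-13C (per mil vs VPDB).

    Inverse of :func:`delta_to_atom_fraction`: delta = 1000 * (R/R_VPDB - 1)
    with R = x13 / (1 - x13).
    """
    x13 = np.asarray(x13, dtype=float)
    if np.any((x13 <= 0.0) | (x13 >= 1.0)):
        raise InvalidIsotopeRatioError("atom fraction x13 must lie strictly in (0, 1)")
    r = x13 / (1.0 - x13)
    delta = 1000.0 * (r / constants.r_vpdb - 1.0)
    return delta if delta.ndim else float(delta)


def atom_excess(labelled, reference, reference_id: str = "") -> AtomExcess:
    """Atom-excess fraction: labelled x13 minus natural-abundance reference x13.

    Accepts :class:`AtomFractions` tuples or bare x13 values.  Negative excess
    (sample below its reference) is representable on purpose — clipping would
    bias downstream mass sums; callers decide how to handle it.
    """
    x_lab = labelled.x13 if isinstance(labelled, AtomFractions) else labelled
    x_ref = reference.x13 if isinstance(reference, AtomFractions) else reference
    value = np.asarray(x_lab, dtype=float) - np.asarray(x_ref, dtype=float)
    return AtomExcess(value=value if value.ndim else float(value), reference_id=reference_id)


def excess_mass(excess, carbon_mass, labelled_x13, constants: IsotopeConstants = VPDB):
    """Mass of recovered excess 13C (g 13C m-2) in a carbon pool.

    m_E = xE * m(C) * M13 / (x12 * M12 + x13 * M13), with x12/x13 the atom
    fractions of the *measured* (labelled) sample.  The denominator is the mean
    atomic mass of the sample's carbon, so m(C)/denominator is moles of C and
    the product is grams of tracer-derived 13C.  Linear in both xE and m(C).
    """
    xe = excess.value if isinstance(excess, AtomExcess) else excess
    xe = np.asarray(xe, dtype=float)
    x13 = labelled_x13.x13 if isinstance(labelled_x13, AtomFractions) else labelled_x13
    carbon_mass = np.asarray(carbon_mass, dtype=float)
    if np.any(carbon_mass < 0):
        raise ValueError("carbon_mass must be non-negative")
    out = xe * carbon_mass * constants.m13 / constants.mean_atomic_mass(x13)
    return out if out.ndim else float(out)


def atom_fraction_for_excess(
    target_excess_mass,
    carbon_mass,
    reference_x13,
    constants: IsotopeConstants = VPDB,
):
    """Labelled x13 that yields a given excess 13C mass against a reference.

    Exact algebraic inverse of :func:`excess_mass` in x13 (the denominator's
    dependence on the labelled fractions makes this a linear solve rather than
    a plain division).  Used by the forward simulator so that synthetic delta
    values reproduce target excess masses to machine precision.
    """
    e = np.asarray(target_excess_mass, dtype=float)
    m = np.asarray(carbon_mass, dtype=float)
    x_ref = np.asarray(reference_x13, dtype=float)
    if np.any(m <= 0):
        raise ValueError("carbon_mass must be positive to invert for an atom fraction")
    dm = constants.m13 - constants.m12
    # e * (m12 + x*dm) = (x - x_ref) * m * m13  ->  solve for x
    x = (e * constants.m12 + x_ref * m * constants.m13) / (m * constants.m13 - e * dm)
    return x if x.ndim else float(x)
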