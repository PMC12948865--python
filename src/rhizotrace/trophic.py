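"""Copiotroph/oligotroph classification of prokaryotic taxa by rrn copy number.

Fast-growing copiotrophs tend to carry many rRNA operon (rrn) copies per
genome, slow-growing oligotrophs few; the conventional cut is five copies at
the lowest assigned taxonomic rank (>= 5 copiotroph, < 5 oligotroph).  Taxa
without a copy-number match stay unclassified and are excluded from ratios.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["classify_trophic", "trophic_ratio", "classify_table", "sample_summary"]

COPIOTROPH = "copiotroph"
OLIGOTROPH = "oligotroph"
UNCLASSIFIED = "unclassified"

#: rrn copies per genome at and above which a taxon counts as copiotrophic.
DEFAULT_THRESHOLD = 5.0


def classify_trophic(rrn_copy_number, threshold: float = DEFAULT_THRESHOLD):
    """Classify a taxon (or array of taxa) by mean rrn copies per genome.

    Copiotroph iff copy number >= threshold; oligotroph below; missing copy
    numbers yield ``"unclassified"`` (logged).  Non-positive copy numbers are
    invalid.
    """
    cn = np.asarray(rrn_copy_number, dtype=float)
    missing = np.isnan(cn)
    if np.any(cn[~missing] <= 0):
        raise ValueError("rrn copy number must be positive")
    out = np.where(cn >= threshold, COPIOTROPH, OLIGOTROPH)
    if np.any(missing):
        logger.warning("%d taxa lack an rrn copy number; left unclassified", missing.sum())
        out = np.where(missing, UNCLASSIFIED, out)
    if out.ndim == 0:
        return out.item()
    return out


def classify_table(
    taxa: pd.DataFrame,
    *,
    copy_col: str = "rrn_copy_number",
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Return ``taxa`` with a ``trophic`` label column appended."""
    out = taxa.copy()
    out["trophic"] = classify_trophic(out[copy_col].to_numpy(dtype=float), threshold)
    return out


def trophic_ratio(labels, read_counts, *, orientation: str = "oligo_to_copio"):
    """Read-count ratio between the two trophic classes for one sample.

    ``orientation`` selects ``"oligo_to_copio"`` or ``"copio_to_oligo"``.
    Unclassified taxa are excluded from both numerator and denominator.  A
    zero denominator gives NaN (missing, logged), not an exception — such
    samples are real but carry no finite ratio.  The ratio is invariant to a
    uniform rescaling of read counts.
    """
    labels = np.asarray(labels)
    reads = np.asarray(read_counts, dtype=float)
    if np.any(reads < 0):
        raise ValueError("read counts must be non-negative")
    oligo = reads[labels == OLIGOTROPH].sum()
    copio = reads[labels == COPIOTROPH].sum()
    if orientation == "oligo_to_copio":
        num, den = oligo, copio
    elif orientation == "copio_to_oligo":
        num, den = copio, oligo
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if den == 0:
        logger.warning("zero %s reads; trophic ratio reported missing", orientation.split("_")[-1])
        return float("nan")
    return float(num / den)


def sample_summary(
    taxa: pd.DataFrame,
    sample_cols: Sequence[str],
    *,
    copy_col: str = "rrn_copy_number",
    threshold: float = DEFAULT_THRESHOLD,
    weight: str = "reads",
) -> pd.DataFrame:
    """Per-sample trophic composition from a taxon x sample read-count table.

    ``weight="reads"`` sums read counts per class; ``weight="asv"`` counts
    taxa with at least one read instead.  Returns one row per sample with the
    class totals, both ratio orientations, and the number of unclassified
    taxa carrying reads.
    """
    if weight not in ("reads", "asv"):
        raise ValueError("weight must be 'reads' or 'asv'")
    labelled = classify_table(taxa, copy_col=copy_col, threshold=threshold)
    rows = []
    for sample in sample_cols:
        reads = labelled[sample].to_numpy(dtype=float)
        w = reads if weight == "reads" else (reads > 0).astype(float)
        lab = labelled["trophic"].to_numpy()
        rows.append(
            {
                "sample": sample,
                "oligotroph": w[lab == OLIGOTROPH].sum(),
                "copiotroph": w[lab == COPIOTROPH].sum(),
                "unclassified": w[lab == UNCLASSIFIED].sum(),
                "oligo_to_copio": trophic_ratio(lab, w),
                "copio_to_oligo": trophic_ratio(lab, w, orientation="copio_to_oligo"),
            }
        )
    return pd.DataFrame(rows)
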