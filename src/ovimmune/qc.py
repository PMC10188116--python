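"""Cell-level quality filters and LogNormalize-style normalization.

A cell is kept when its detected-gene count lies in [min_features,
max_features] and its mitochondrial count proportion is at most max_mito
(strict inequalities remove: fewer than 200 features, more than 2500, or
more than 10% mitochondrial counts, by default). "Features" means genes
with a nonzero raw count; the mito proportion is computed on raw counts
over all genes.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCReport:
    """Removal tally; each removed cell is attributed to its first failing rule
    in the order (low features, high features, high mito)."""

    n_input_cells: int
    n_removed_low_features: int
    n_removed_high_features: int
    n_removed_mito: int
    n_retained: int

    def to_dict(self) -> dict:
        return asdict(self)


def qc_filter(
    m: CountMatrix,
    min_features: int = 200,
    max_features: int = 2500,
    max_mito: float = 0.10,
) -> tuple[CountMatrix, QCReport]:
    """Apply the three cell-quality rules and report the removals."""
    if m.n_cells == 0:
        raise ValueError("qc_filter requires a nonempty matrix")
    if not (0 <= min_features <= max_features):
        raise ValueError("need 0 <= min_features <= max_features")
    if not (0 <= max_mito <= 1):
        raise ValueError("max_mito must lie in [0, 1]")

    feats = m.features_per_cell()
    mito = m.mito_fraction_per_cell()
    low = feats < min_features
    high = feats > max_features
    hi_mito = mito > max_mito
    fail = low | high | hi_mito

    report = QCReport(
        n_input_cells=m.n_cells,
        n_removed_low_features=int(low.sum()),
        n_removed_high_features=int((high & ~low).sum()),
        n_removed_mito=int((hi_mito & ~low & ~high).sum()),
        n_retained=int((~fail).sum()),
    )
    logger.info(
        "QC %s: %d cells in, %d removed (low=%d high=%d mito=%d), %d retained",
        m.sample_label, report.n_input_cells,
        report.n_input_cells - report.n_retained,
        report.n_removed_low_features, report.n_removed_high_features,
        report.n_removed_mito, report.n_retained,
    )
    if report.n_retained == 0:
        logger.warning("QC removed every cell of sample %s", m.sample_label)
    return m.subset_cells(~fail), report


def log_normalize(m: CountMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    """Per-cell scaling to a fixed total followed by natural log(1 + x).

    value(g, i) = ln(1 + scale * count(g, i) / total(i)); zeros map to zeros,
    so a normalized value is 0 iff the raw count is 0.
    """
    totals = m.totals_per_cell().astype(float)
    if (totals == 0).any():
        bad = m.barcodes[totals == 0]
        raise ValueError(
            f"cells with zero total counts cannot be normalized: {list(bad[:5])}"
        )
    scaled = m.counts.multiply(scale / totals[None, :]).tocsr()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        genes=m.genes,
        barcodes=m.barcodes,
        values=scaled,
        sample_label=m.sample_label,
    )
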