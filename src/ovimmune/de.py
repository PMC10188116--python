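"""Per-cluster old-vs-young differential expression.

A gene is a DEG within a cell type when the old/young fold change of its
mean normalized expression is at least twofold (either direction), the
two-tailed pooled-variance t-test gives p <= 0.05, and the Storey q-value
(FDR) is <= 0.1. A tail-restricted variant additionally flags genes in
the extreme 2.5% tails of the cell type's empirical fold-change
distribution, guarding against calls that merely ride a global shift.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def _values(m):
    """Expression values of a NormalizedMatrix or CountMatrix."""
    return m.values if hasattr(m, "values") else m.counts


def _group_matrix(norm, cells: pd.DataFrame, cell_type: str,
                  age_group: str) -> np.ndarray:
    info = cells.set_index("barcode")
    mask = (
        (info.loc[norm.barcodes, "cell_type"] == cell_type)
        & (info.loc[norm.barcodes, "age_group"] == age_group)
    ).to_numpy()
    return np.asarray(_values(norm)[:, np.flatnonzero(mask)].todense())


def fold_change(
    norm,
    cells: pd.DataFrame,
    cell_type: str,
    pseudocount: float = 1e-9,
) -> pd.Series:
    """Old/young ratio of mean expression per gene.

    Operates on normalized expression by default; passing a CountMatrix
    computes the ratio of raw mean counts instead (parameter-recovery
    checks use the raw scale, where a planted fold is the estimand). The
    pseudocount guards zero denominators and is negligible relative to
    any detected mean.
    """
    old = _group_matrix(norm, cells, cell_type, "old")
    young = _group_matrix(norm, cells, cell_type, "young")
    if old.shape[1] < 2 or young.shape[1] < 2:
        raise ValueError(f"cell type {cell_type!r} needs >= 2 cells per age group")
    fc = (old.mean(axis=1) + pseudocount) / (young.mean(axis=1) + pseudocount)
    return pd.Series(fc, index=norm.genes, name="fc")


def t_test(
    norm: NormalizedMatrix, cells: pd.DataFrame, cell_type: str
) -> pd.Series:
    """Two-tailed Student (pooled-variance) t-test, old vs young, per gene.

    Genes with zero variance in both groups get p = 1 (logged).
    """
    old = _group_matrix(norm, cells, cell_type, "old")
    young = _group_matrix(norm, cells, cell_type, "young")
    if old.shape[1] < 2 or young.shape[1] < 2:
        raise ValueError(f"cell type {cell_type!r} needs >= 2 cells per age group")
    res = stats.ttest_ind(old, young, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (old.var(axis=1) == 0) & (young.var(axis=1) == 0)
    if degenerate.any():
        logger.info(
            "%s: %d genes with zero variance in both groups get p=1",
            cell_type, int(degenerate.sum()),
        )
    p[degenerate | np.isnan(p)] = 1.0
    return pd.Series(p, index=norm.genes, name="p")


def estimate_pi0(p, lambda_grid=None) -> float:
    """Smoother-free Storey null-proportion estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)), averaged over the
    lambda grid and clipped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    m = p.size
    est = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    pi0 = float(est.mean())
    return min(max(pi0, 1.0 / m), 1.0)


def storey_q(p, lambda_grid=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q(i) = min over p(j) >= p(i) of pi0 * m * p(j) / rank(j).

    With fewer than 10 p-values the pi0 estimate is unstable, so pi0
    falls back to 1 (the Benjamini-Hochberg limit, logged). q is clipped
    to [0, 1] and is monotone nondecreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if p.size < 10:
            logger.info("fewer than 10 p-values: pi0 fixed at 1 (BH limit)")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_degs(
    fc: pd.Series,
    p: pd.Series,
    q,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Apply the conjunction of fold, p and q thresholds gene-by-gene."""
    if not fc.index.equals(p.index):
        raise ValueError("fc and p must be indexed by the same genes")
    q = np.asarray(q, dtype=float)
    fc_v = fc.to_numpy(dtype=float)
    direction = np.where(
        fc_v >= fc_threshold, "up", np.where(fc_v <= 1.0 / fc_threshold, "down", "none")
    )
    is_deg = (direction != "none") & (p.to_numpy() <= p_threshold) & (q <= q_threshold)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc_v)
    return pd.DataFrame(
        {
            "gene": fc.index,
            "fc": fc_v,
            "log2fc": log2fc,
            "p": p.to_numpy(),
            "q": q,
            "direction": direction,
            "is_deg": is_deg,
        }
    )


def tail_restricted_degs(records: pd.DataFrame, tail_mass: float = 0.025) -> pd.DataFrame:
    """Flag genes in the extreme fold-change tails of one cell type.

    ``in_tail`` is true for genes at or below the ``tail_mass`` quantile
    or at or above the ``1 - tail_mass`` quantile of the empirical fc
    distribution. A degenerate distribution (no strict tails) flags none.
    """
    if not 0 < tail_mass < 0.5:
        raise ValueError("tail_mass must lie in (0, 0.5)")
    out = records.copy()
    fc = out["fc"].to_numpy(dtype=float)
    lo = np.quantile(fc, tail_mass)
    hi = np.quantile(fc, 1.0 - tail_mass)
    if lo >= hi:
        out["in_tail"] = False
    else:
        out["in_tail"] = (fc <= lo) | (fc >= hi)
    return out


def genes_tested(
    norm: NormalizedMatrix, cells: pd.DataFrame, cell_type: str, min_cells: int = 3
) -> np.ndarray:
    """Detection filter: genes with a nonzero value in >= min_cells cells of
    the type, across both ages (normalized values are 0 iff raw counts are)."""
    info = cells.set_index("barcode")
    mask = (info.loc[norm.barcodes, "cell_type"] == cell_type).to_numpy()
    sub = norm.values[:, np.flatnonzero(mask)]
    detected = np.asarray((sub > 0).sum(axis=1)).ravel()
    return detected >= min_cells


def differential_expression(
    norm: NormalizedMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.1,
    pseudocount: float = 1e-9,
    tail_mass: float = 0.025,
    min_cells_detected: int = 3,
) -> pd.DataFrame:
    """Full DEG stack for one cell type: filter, fc, t-test, Storey q, calls."""
    tested = genes_tested(norm, cells, cell_type, min_cells_detected)
    sub = NormalizedMatrix(
        genes=norm.genes[tested],
        barcodes=norm.barcodes,
        values=norm.values[np.flatnonzero(tested)],
        sample_label=norm.sample_label,
    )
    fc = fold_change(sub, cells, cell_type, pseudocount)
    p = t_test(sub, cells, cell_type)
    q = storey_q(p.to_numpy())
    records = call_degs(fc, p, q, fc_threshold, p_threshold, q_threshold)
    records.insert(1, "cell_type", cell_type)
    return tail_restricted_degs(records, tail_mass)


def classify_terms(lists: pd.DataFrame) -> pd.DataFrame:
    """Label enrichment terms global (>= 2 cell types) or specific (1).

    ``lists`` has columns (cell_type, term, direction); counting is per
    (term, direction) over distinct cell types.
    """
    if lists.empty:
        return pd.DataFrame(columns=["term", "direction", "n_cell_types", "label"])
    counts = (
        lists.drop_duplicates()
        .groupby(["term", "direction"])["cell_type"]
        .nunique()
        .reset_index(name="n_cell_types")
    )
    counts["label"] = np.where(counts["n_cell_types"] >= 2, "global", "specific")
    return counts
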