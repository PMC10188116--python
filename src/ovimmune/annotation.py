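"""Marker-score computation and cluster identity assignment.

The normalized expression score of marker gene g in cell i of cluster c is

    S_{g,i,c} = (E_{g,i} - m_g) / (M_g - m_g) * N_{g,c} / N_c

where E is the raw count, M_g/m_g are the max/min of g across all cells of
the sample, N_c is the cluster size and N_{g,c} the number of cluster cells
expressing g (raw count above the expression threshold, 0 by default).
Scores lie in [0, 1]. Cluster identity is called from the marker evidence
(mean score of each candidate type's markers over the cluster's cells);
an optional external per-cell reference label yields a cluster-majority
call recorded alongside, with disagreements surfaced rather than resolved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

UNRESOLVED = "unresolved"


def marker_score(
    raw: CountMatrix,
    cells: pd.DataFrame,
    panel: pd.DataFrame,
    expressed_threshold: int = 0,
) -> pd.DataFrame:
    """Score every panel marker in every cell of ``raw``.

    ``cells`` must assign a cluster_id to each barcode of the matrix.
    Panel genes absent from the matrix score 0 everywhere (with a warning),
    as do genes constant across the sample (degenerate M_g = m_g).
    Returns a long table (gene, candidate cell_type, barcode, cluster_id,
    score).
    """
    cell_info = cells.set_index("barcode")
    missing_bc = [b for b in raw.barcodes if b not in cell_info.index]
    if missing_bc:
        raise ValueError(f"cells table lacks {len(missing_bc)} matrix barcodes")
    clusters = cell_info.loc[raw.barcodes, "cluster_id"].to_numpy()
    cluster_ids, cluster_pos = np.unique(clusters, return_inverse=True)
    n_per_cluster = np.bincount(cluster_pos)

    gidx = raw.gene_index()
    frames = []
    for cell_type, gene in panel.itertuples(index=False):
        if gene not in gidx:
            logger.warning("marker %s (%s) absent from matrix; scored 0", gene, cell_type)
            score = np.zeros(raw.n_cells)
        else:
            row = np.asarray(raw.counts[gidx[gene]].todense()).ravel().astype(float)
            m_g, big_m = row.min(), row.max()
            if big_m == m_g:
                logger.warning("marker %s constant across sample; scored 0", gene)
                score = np.zeros(raw.n_cells)
            else:
                rel = (row - m_g) / (big_m - m_g)
                expressed = row > expressed_threshold
                n_gc = np.bincount(
                    cluster_pos, weights=expressed, minlength=len(cluster_ids)
                )
                frac = n_gc / n_per_cluster
                score = rel * frac[cluster_pos]
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "cell_type": cell_type,
                    "barcode": raw.barcodes,
                    "cluster_id": clusters,
                    "score": score,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def assign_clusters(
    scores: pd.DataFrame,
    panel: pd.DataFrame,
    reference_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call each cluster's identity from mean marker evidence.

    Evidence for (cluster, type) is the mean score of the type's markers
    over the cluster's cells. The call is the argmax (lexicographic
    tie-break, logged); clusters with zero evidence for every type are
    ``unresolved``. When per-cell ``reference_labels`` (barcode, cell_type)
    are given, each cluster's modal reference label is recorded and an
    agreement flag set; disagreements are logged for manual review.
    """
    types = sorted(panel["cell_type"].unique())
    evidence = (
        scores.groupby(["cluster_id", "cell_type"])["score"].mean().unstack()
        .reindex(columns=types)
        .fillna(0.0)
    )

    ref_majority = None
    if reference_labels is not None:
        ref = reference_labels.set_index("barcode")["cell_type"]
        per_cell = scores[["barcode", "cluster_id"]].drop_duplicates()
        per_cell = per_cell[per_cell["barcode"].isin(ref.index)]
        per_cell["ref"] = ref.loc[per_cell["barcode"]].to_numpy()
        ref_majority = (
            per_cell.groupby("cluster_id")["ref"]
            .agg(lambda s: s.value_counts().sort_index().idxmax())
        )

    rows = []
    for cluster_id, ev in evidence.iterrows():
        if (ev == 0).all():
            call = UNRESOLVED
        else:
            best = ev.max()
            ties = sorted(ev.index[ev == best])
            call = ties[0]
            if len(ties) > 1:
                logger.warning(
                    "cluster %s: tied marker evidence %s; chose %s", cluster_id, ties, call
                )
        row = {"cluster_id": cluster_id, "cell_type": call}
        for t in types:
            row[f"score_{t}"] = ev[t]
        if ref_majority is not None:
            ref_call = ref_majority.get(cluster_id)
            row["reference_majority"] = ref_call
            row["agreement"] = bool(ref_call == call)
            if ref_call is not None and ref_call != call:
                logger.warning(
                    "cluster %s: marker call %s disagrees with reference majority %s",
                    cluster_id, call, ref_call,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def apply_assignments(cells: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Copy cluster-level type calls onto the per-cell table."""
    mapping = assignments.set_index("cluster_id")["cell_type"]
    out = cells.copy()
    out["cell_type"] = out["cluster_id"].map(mapping).fillna(UNRESOLVED)
    return out
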