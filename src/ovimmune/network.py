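"""Ligand-receptor interaction network edge analysis.

An edge of the cytokine/chemokine interaction map is flagged in a given
direction when both of its nodes changed significantly that way: the
ligand is a DEG with that direction in at least one cell type AND the
receptor is a DEG with the same direction in at least one cell type
(possibly the same one). The chord summary counts flagged edges per
(ligand cell type, receptor cell type) pair, an edge contributing to the
full cross-product of its endpoint type lists.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import pandas as pd

logger = logging.getLogger(__name__)


def _deg_types_by_gene(degs: Mapping[str, pd.DataFrame], direction: str) -> dict:
    """gene -> sorted list of cell types where it is a DEG in ``direction``."""
    out: dict[str, list] = {}
    for cell_type, table in degs.items():
        hits = table.loc[table["is_deg"] & (table["direction"] == direction), "gene"]
        for g in hits:
            out.setdefault(g, []).append(cell_type)
    return {g: sorted(ts) for g, ts in out.items()}


def flag_edges(
    pairs: pd.DataFrame,
    degs: Mapping[str, pd.DataFrame],
    direction: str,
) -> pd.DataFrame:
    """Evaluate the both-nodes-significant rule for every ligand→receptor pair.

    ``degs`` maps cell type -> DEG table (gene, direction, is_deg, ...).
    Returns one row per pair with the qualifying endpoint cell types
    (comma-joined, sorted) and the flag.
    """
    if pairs.empty:
        raise ValueError("ligand-receptor pair table is empty")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    by_gene = _deg_types_by_gene(degs, direction)
    rows = []
    for ligand, receptor in pairs[["ligand", "receptor"]].itertuples(index=False):
        lt = by_gene.get(ligand, [])
        rt = by_gene.get(receptor, [])
        rows.append(
            {
                "ligand": ligand,
                "receptor": receptor,
                "direction": direction,
                "ligand_cell_types": ",".join(lt),
                "receptor_cell_types": ",".join(rt),
                "flagged": bool(lt and rt),
            }
        )
    flagged = sum(r["flagged"] for r in rows)
    logger.info("%d of %d edges flagged %s", flagged, len(rows), direction)
    return pd.DataFrame(rows)


def chord_summarize(edges: pd.DataFrame) -> pd.DataFrame:
    """Count flagged interactions per (source, target) cell-type pair."""
    counts: dict[tuple, int] = {}
    for row in edges.itertuples(index=False):
        if not row.flagged:
            continue
        for src in row.ligand_cell_types.split(","):
            for tgt in row.receptor_cell_types.split(","):
                key = (src, tgt, row.direction)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"source": s, "target": t, "direction": d, "n_flagged_interactions": n}
        for (s, t, d), n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "direction", "n_flagged_interactions"]
    )
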