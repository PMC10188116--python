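"""Sparse count-matrix containers and plain-text readers/writers.

On-disk formats are the 10x Genomics triplet layout (a MatrixMarket
coordinate file plus ``features`` and ``barcodes`` listings, optionally
gzipped) and tab-separated tables for every tabular input and result.
Genes are rows and cells are columns everywhere; indices are 0-based in
memory and 1-based in MatrixMarket files, per that format's convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Mouse mitochondrial genes are conventionally prefixed "mt-".
DEFAULT_MITO_PREFIX = "mt-"


class MatrixFormatError(ValueError):
    """A triplet directory (or matrix construction) is internally inconsistent."""


def _dedupe_names(names: list[str]) -> tuple[np.ndarray, int]:
    """Suffix repeated identifiers with .1, .2, ... so they stay unique."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    n_dup = sum(1 for v in seen.values() if v)
    return np.asarray(out, dtype=object), n_dup


def mito_flags_from_names(genes, prefix: str = DEFAULT_MITO_PREFIX) -> np.ndarray:
    """Case-insensitive gene-name prefix rule for mitochondrial genes."""
    p = prefix.lower()
    return np.asarray([str(g).lower().startswith(p) for g in genes], dtype=bool)


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells, with identifiers and mito flags.

    Invariants enforced on construction: unique gene identifiers, unique
    barcodes, integer nonnegative counts, mito_flags aligned to genes.
    """

    genes: np.ndarray
    barcodes: np.ndarray
    counts: sp.csr_matrix
    sample_label: str = ""
    mito_flags: np.ndarray | None = None

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.counts.eliminate_zeros()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise MatrixFormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        data = self.counts.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if not np.array_equal(data, np.round(data)):
                    raise ValueError("counts must be integers")
            if data.min() < 0:
                raise ValueError("counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)
        if self.mito_flags is None:
            self.mito_flags = mito_flags_from_names(self.genes)
        else:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
            if len(self.mito_flags) != len(self.genes):
                raise ValueError("mito_flags length must equal gene count")

    # -- derived per-cell statistics ------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def features_per_cell(self) -> np.ndarray:
        """Number of detected genes (count > 0) per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def totals_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)

    def mito_fraction_per_cell(self) -> np.ndarray:
        """Mitochondrial proportion of raw counts per cell (0 where total is 0)."""
        tot = self.totals_per_cell().astype(float)
        mito = np.asarray(self.counts[self.mito_flags].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / tot, 0.0)
        return frac

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            genes=self.genes,
            barcodes=self.barcodes[idx],
            counts=self.counts[:, idx],
            sample_label=self.sample_label,
            mito_flags=self.mito_flags,
        )

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the same axes as its source CountMatrix."""

    genes: np.ndarray
    barcodes: np.ndarray
    values: sp.csr_matrix
    sample_label: str = ""

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr().astype(np.float64)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise MatrixFormatError("normalized matrix shape mismatch")
        if self.values.data.size and self.values.data.min() < 0:
            raise ValueError("normalized values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset_cells(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            genes=self.genes,
            barcodes=self.barcodes[idx],
            values=self.values[:, idx],
            sample_label=self.sample_label,
        )

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass(frozen=True)
class GeneSet:
    """A named list of unique gene identifiers."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


def concat_cells(a, b, sample_label: str | None = None):
    """Column-concatenate two matrices sharing an identical gene axis."""
    if not np.array_equal(a.genes, b.genes):
        raise ValueError("matrices must share an identical gene axis; align first")
    barcodes = np.concatenate([a.barcodes, b.barcodes])
    label = sample_label if sample_label is not None else f"{a.sample_label}+{b.sample_label}"
    if isinstance(a, CountMatrix):
        return CountMatrix(
            genes=a.genes,
            barcodes=barcodes,
            counts=sp.hstack([a.counts, b.counts], format="csr"),
            sample_label=label,
            mito_flags=a.mito_flags,
        )
    return NormalizedMatrix(
        genes=a.genes,
        barcodes=barcodes,
        values=sp.hstack([a.values, b.values], format="csr"),
        sample_label=label,
    )


def align_genes(a: CountMatrix, b: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Restrict both matrices to their shared genes, in ``a``'s order."""
    shared = [g for g in a.genes if g in set(b.genes)]
    if not shared:
        raise ValueError("matrices share no genes")
    ia = [a.gene_index()[g] for g in shared]
    ib = [b.gene_index()[g] for g in shared]
    out = []
    for m, idx in ((a, ia), (b, ib)):
        out.append(
            CountMatrix(
                genes=m.genes[idx],
                barcodes=m.barcodes,
                counts=m.counts[idx],
                sample_label=m.sample_label,
                mito_flags=m.mito_flags[idx],
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# 10x triplet layout
# ---------------------------------------------------------------------------

def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(dir_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dir_path / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {dir_path}")


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_10x_triplet(
    dir_path,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    sample_label: str | None = None,
) -> CountMatrix:
    """Load a 10x triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, plain or gzipped. Gene symbols come from the second
    features column when present (Cell Ranger layout), else the first.
    Duplicate symbols are suffixed ``.1``, ``.2`` to keep identifiers unique.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, ("matrix.mtx",))
    feat_path = _find(dir_path, ("features.tsv", "genes.tsv"))
    bc_path = _find(dir_path, ("barcodes.tsv",))

    feat_rows = [line.split("\t") for line in _read_lines(feat_path)]
    symbols = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    barcodes = _read_lines(bc_path)

    with _open_text(mtx_path) as fh:
        banner = fh.readline()
        if "coordinate" not in banner:
            raise MatrixFormatError("expected a MatrixMarket coordinate file")
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        try:
            n_rows, n_cols, _ = (int(x) for x in line.split())
        except ValueError as exc:
            raise MatrixFormatError(f"bad MatrixMarket size line: {line!r}") from exc
    if n_rows != len(symbols):
        raise MatrixFormatError(
            f"matrix header declares {n_rows} genes but features lists {len(symbols)}"
        )
    if n_cols != len(barcodes):
        raise MatrixFormatError(
            f"matrix header declares {n_cols} cells but barcodes lists {len(barcodes)}"
        )

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)

    genes, n_dup = _dedupe_names(symbols)
    if n_dup:
        logger.warning("%d duplicated gene symbols disambiguated in %s", n_dup, feat_path)

    return CountMatrix(
        genes=genes,
        barcodes=np.asarray(barcodes, dtype=object),
        counts=mat.tocsr(),
        sample_label=sample_label if sample_label is not None else dir_path.name,
        mito_flags=mito_flags_from_names(genes, mito_prefix),
    )


def write_10x_triplet(m: CountMatrix, dir_path) -> None:
    """Write a CountMatrix as matrix.mtx + features.tsv + barcodes.tsv."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), m.counts.tocoo(), field="integer")
    with open(dir_path / "features.tsv", "w") as fh:
        for g in m.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")


# ---------------------------------------------------------------------------
# Tabular inputs / outputs
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path) -> None:
    """Write any result table as TSV with a header row.

    Fields containing tabs/newlines are quoted so the file round-trips
    losslessly through :func:`read_table`.
    """
    records.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Load a gene set from one-gene-per-line or two-column (set, gene) TSV.

    Duplicates are collapsed with a warning; an empty file is an error.
    """
    path = Path(path)
    rows = [line.split("\t") for line in _read_lines(path)]
    if not rows:
        raise ValueError(f"gene set file {path} is empty")
    if len(rows[0]) >= 2:
        set_name = name or rows[0][0]
        genes = [r[-1] for r in rows]
    else:
        set_name = name or path.stem
        genes = [r[0] for r in rows]
    unique = list(dict.fromkeys(genes))
    if len(unique) != len(genes):
        logger.warning(
            "gene set %s: %d duplicate entries collapsed", set_name, len(genes) - len(unique)
        )
    return GeneSet(name=set_name, genes=tuple(unique))


def write_gene_set(gs: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for g in gs.genes:
            fh.write(f"{g}\n")


def _read_two_column(path, columns: tuple[str, str]) -> pd.DataFrame:
    rows = [line.split("\t") for line in _read_lines(Path(path))]
    if not rows:
        raise ValueError(f"{path} is empty")
    if [c.lower() for c in rows[0][:2]] == list(columns):
        rows = rows[1:]
    if any(len(r) < 2 for r in rows):
        raise ValueError(f"{path}: expected two tab-separated columns")
    return pd.DataFrame([r[:2] for r in rows], columns=list(columns))


def read_lr_pairs(path) -> pd.DataFrame:
    """Load a directed ligand→receptor pair table (two-column TSV).

    Self-pairs are rejected; duplicated pairs are dropped with a warning.
    """
    df = _read_two_column(path, ("ligand", "receptor"))
    if (df["ligand"] == df["receptor"]).any():
        bad = df.loc[df["ligand"] == df["receptor"], "ligand"].tolist()
        raise ValueError(f"self-pairs not allowed in ligand-receptor table: {bad}")
    n0 = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) != n0:
        logger.warning("%d duplicate ligand-receptor pairs dropped", n0 - len(df))
    return df


def read_marker_panel(path) -> pd.DataFrame:
    """Load a (cell_type, marker gene) panel; (type, gene) pairs must be unique."""
    df = _read_two_column(path, ("cell_type", "gene"))
    if df.duplicated().any():
        raise ValueError("marker panel contains duplicated (cell_type, gene) pairs")
    return df


def read_cell_clusters(path) -> pd.DataFrame:
    df = _read_two_column(path, ("barcode", "cluster_id"))
    df["cluster_id"] = df["cluster_id"].astype(int)
    if (df["cluster_id"] < 0).any():
        raise ValueError("cluster_id must be >= 0")
    if df["barcode"].duplicated().any():
        raise ValueError("each barcode may appear only once in the cluster table")
    return df


def packaged_lr_pairs() -> pd.DataFrame:
    """The shipped curated mouse chemokine/cytokine ligand→receptor snapshot."""
    with resources.as_file(resources.files("ovimmune") / "data" / "lr_pairs.tsv") as p:
        return read_lr_pairs(p)


def packaged_sasp_receptors() -> GeneSet:
    """The shipped synthetic stand-in list of 24 SASP-factor receptors.

    A constructed list (see file name): receptors named in the aging-ovary
    literature plus canonical receptors of well-known SASP factors.
    """
    with resources.as_file(
        resources.files("ovimmune") / "data" / "sasp_receptors_synthetic.tsv"
    ) as p:
        return read_gene_set(p, name="sasp_receptors")
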