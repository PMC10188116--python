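"""Synthetic scRNA-seq generator with planted structure.

Emulates the statistical structure the downstream analysis assumes:
negative-binomial counts per cell type with elevated marker genes,
mitochondrial genes with a controlled per-cell count proportion, an
age-dependent composition shift (innate-dominated young sample, a
DNT-dominated old sample), planted per-cluster differential expression
at set fold changes, a coordinated downregulation of the chemokine and
cytokine gene sets, and an old-age elevation of the expressed fraction
of the SASP-receptor set in macrophages.

The generative model is the package's own (the analysis implies none):
counts ~ NB(mean mu, dispersion theta) with P(X=0) = (theta/(theta+mu))^theta.
Expressed-fraction plantings are zero-inflated on top of the NB mean:
count = Bernoulli(f) * (1 + NB(mu, theta)), so the detection probability
is exactly f while the conditional expression level tracks mu. Where a
(cell_type, gene) appears in both ``de_spec`` and ``fraction_spec``, the
fraction planting takes precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSet, packaged_lr_pairs, packaged_sasp_receptors

logger = logging.getLogger(__name__)

#: The 13 protein-coding mouse mitochondrial genes.
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

_AGE_OFFSET = {"young": 0, "old": 1}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-sample (young/old) experiment."""

    n_cell_types: int
    cells_per_type_young: tuple
    cells_per_type_old: tuple
    n_genes: int = 2000
    markers_per_type: int = 3
    marker_fold: float = 8.0
    baseline_mean: float = 0.3
    dispersion: float = 2.0
    de_spec: tuple = ()  # (cell_type, gene, fold_change applied to old mean)
    fraction_spec: tuple = ()  # (cell_type, gene, frac_young, frac_old)
    mito_fraction_range: tuple = (0.01, 0.04)
    seed: int = 0
    cell_type_names: tuple = ()
    extra_genes: tuple = ()  # named genes (e.g. ligand/receptor symbols) to include

    def __post_init__(self):
        names = self.cell_type_names or tuple(
            f"CT{i:02d}" for i in range(self.n_cell_types)
        )
        object.__setattr__(self, "cell_type_names", names)
        if len(names) != self.n_cell_types:
            raise ValueError("cell_type_names length must equal n_cell_types")
        for vec in (self.cells_per_type_young, self.cells_per_type_old):
            if len(vec) != self.n_cell_types:
                raise ValueError("composition vectors must have length n_cell_types")
            if any(n < 0 for n in vec):
                raise ValueError("cell counts must be nonnegative")
        if self.baseline_mean < 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean must be >= 0 and dispersion > 0")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be > 0")
        for _, _, fold in self.de_spec:
            if fold <= 0:
                raise ValueError("planted fold changes must be > 0")
        for _, _, fy, fo in self.fraction_spec:
            if not (0 <= fy <= 1 and 0 <= fo <= 1):
                raise ValueError("expressed fractions must lie in [0, 1]")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.n_genes < self._n_named_genes():
            raise ValueError(
                f"n_genes={self.n_genes} too small for "
                f"{self._n_named_genes()} named genes"
            )

    def _n_named_genes(self) -> int:
        return (
            len(MITO_GENES)
            + self.n_cell_types * self.markers_per_type
            + len(self.extra_genes)
        )

    # -- gene layout ----------------------------------------------------
    def marker_genes(self, cell_type: str) -> tuple:
        t = self.cell_type_names.index(cell_type)
        return tuple(f"{cell_type}-mk{j + 1}" for j in range(self.markers_per_type))

    def gene_names(self) -> np.ndarray:
        names = list(MITO_GENES)
        for ct in self.cell_type_names:
            names.extend(self.marker_genes(ct))
        names.extend(self.extra_genes)
        n_fill = self.n_genes - len(names)
        names.extend(f"G{i:05d}" for i in range(n_fill))
        return np.asarray(names, dtype=object)


def marker_panel(config: SimConfig) -> pd.DataFrame:
    """The (cell_type, gene) marker panel matching the generator's plantings."""
    rows = [
        (ct, g) for ct in config.cell_type_names for g in config.marker_genes(ct)
    ]
    return pd.DataFrame(rows, columns=["cell_type", "gene"])


def expected_means(config: SimConfig, age_group: str) -> pd.DataFrame:
    """Generating NB means per gene (rows) per cell type (columns).

    Mitochondrial rows report the mean implied by the midpoint of the
    per-cell mito-fraction sampling range. Fraction-planted entries report
    the zero-inflated mean f * (1 + mu).
    """
    genes = config.gene_names()
    gidx = {g: i for i, g in enumerate(genes)}
    n_mito = len(MITO_GENES)
    mu = np.full((config.n_genes, config.n_cell_types), config.baseline_mean)
    mu[:n_mito] = 0.0
    for t, ct in enumerate(config.cell_type_names):
        for g in config.marker_genes(ct):
            mu[gidx[g], t] *= config.marker_fold
    if age_group == "old":
        for ct, g, fold in config.de_spec:
            mu[gidx[g], config.cell_type_names.index(ct)] *= fold
    for ct, g, fy, fo in config.fraction_spec:
        f = fy if age_group == "young" else fo
        t = config.cell_type_names.index(ct)
        base = config.baseline_mean
        mu[gidx[g], t] = f * (1.0 + base)
    p_mid = float(np.mean(config.mito_fraction_range))
    nonmito_total = mu[n_mito:].sum(axis=0)
    mu[:n_mito] = p_mid / (1.0 - p_mid) * nonmito_total / n_mito
    return pd.DataFrame(mu, index=genes, columns=list(config.cell_type_names))


def _nb_draw(rng: np.random.Generator, mu, theta: float, size) -> np.ndarray:
    """NB with mean mu and dispersion theta; mu may broadcast over ``size``."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    out = np.zeros(size, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = theta / (theta + mu[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def _simulate_sample(config: SimConfig, age_group: str):
    rng = np.random.default_rng((config.seed, _AGE_OFFSET[age_group]))
    genes = config.gene_names()
    gidx = {g: i for i, g in enumerate(genes)}
    n_mito = len(MITO_GENES)
    comp = (
        config.cells_per_type_young
        if age_group == "young"
        else config.cells_per_type_old
    )
    if sum(comp) == 0:
        raise ValueError(f"composition for age group {age_group!r} sums to zero")

    frac_by_type: dict[str, list] = {}
    for ct, g, fy, fo in config.fraction_spec:
        frac_by_type.setdefault(ct, []).append((g, fy if age_group == "young" else fo))

    blocks = []
    rows = []
    for t, ct in enumerate(config.cell_type_names):
        n_cells = int(comp[t])
        if n_cells == 0:
            continue
        mu = np.full(config.n_genes, config.baseline_mean)
        mu[:n_mito] = 0.0
        for g in config.marker_genes(ct):
            mu[gidx[g]] *= config.marker_fold
        if age_group == "old":
            for ct2, g, fold in config.de_spec:
                if ct2 == ct:
                    mu[gidx[g]] *= fold
        block = _nb_draw(
            rng, mu[:, None], config.dispersion, (config.n_genes, n_cells)
        )
        # mito counts: per-cell target proportion drawn from the config range
        lo, hi = config.mito_fraction_range
        p_cell = rng.uniform(lo, hi, size=n_cells)
        nonmito_total = mu[n_mito:].sum()
        mito_mu = p_cell / (1.0 - p_cell) * nonmito_total / n_mito
        block[:n_mito] = _nb_draw(
            rng, mito_mu[None, :], config.dispersion, (n_mito, n_cells)
        )
        # fraction plantings override the NB draw for their (type, gene)
        for g, f in frac_by_type.get(ct, ()):  # order fixed by fraction_spec
            expressed = rng.random(n_cells) < f
            level = 1 + _nb_draw(
                rng, config.baseline_mean, config.dispersion, (n_cells,)
            )
            block[gidx[g]] = np.where(expressed, level, 0)
        blocks.append(block)
        prefix = "Y" if age_group == "young" else "O"
        start = len(rows)
        for j in range(n_cells):
            rows.append(
                {
                    "barcode": f"{prefix}{start + j:05d}-1",
                    "age_group": age_group,
                    "cluster_id": t,
                    "cell_type": ct,
                }
            )
    counts = np.concatenate(blocks, axis=1)
    cells = pd.DataFrame(rows)
    matrix = CountMatrix(
        genes=genes,
        barcodes=cells["barcode"].to_numpy(dtype=object),
        counts=sp.csr_matrix(counts),
        sample_label=age_group,
    )
    return matrix, cells


def simulate_counts(config: SimConfig):
    """Draw the young and old samples plus the ground-truth cell table.

    Returns ``(young, old, cells)``. Each sample uses its own RNG stream
    seeded from ``(config.seed, per-sample offset)``, so young and old
    draws are independent but the whole call is bit-reproducible.
    """
    young, cells_y = _simulate_sample(config, "young")
    old, cells_o = _simulate_sample(config, "old")
    cells = pd.concat([cells_y, cells_o], ignore_index=True)
    return young, old, cells


def simulate_qc_violators(
    config: SimConfig, n_low: int, n_high: int, n_mito: int
):
    """Append cells violating each QC rule to a clean young sample.

    Returns ``(matrix, manifest)`` where the manifest lists one row per
    appended cell with its planted violation (``low_features``,
    ``high_features`` or ``high_mito``). Clean cells generated by the
    config are expected to pass default QC.
    """
    if min(n_low, n_high, n_mito) < 0:
        raise ValueError("violator counts must be nonnegative")
    if n_high > 0 and config.n_genes < 2501:
        raise ValueError(
            f"cannot plant >2500 detected genes with n_genes={config.n_genes}"
        )
    base, _ = _simulate_sample(config, "young")
    if n_low + n_high + n_mito == 0:
        return base, pd.DataFrame(columns=["barcode", "violation"])

    rng = np.random.default_rng((config.seed, 97))
    n_mito_genes = len(MITO_GENES)
    cols = []
    manifest = []

    def _add(tag, col):
        bc = f"V{len(manifest):04d}-{tag}"
        manifest.append({"barcode": bc, "violation": tag})
        cols.append((bc, col))

    for _ in range(n_low):
        col = np.zeros(config.n_genes, dtype=np.int64)
        picks = rng.choice(
            np.arange(n_mito_genes, config.n_genes), size=50, replace=False
        )
        col[picks] = 1
        _add("low_features", col)
    for _ in range(n_high):
        col = np.zeros(config.n_genes, dtype=np.int64)
        col[:2501] = 1  # includes the mito genes: ~0.5% mito, well under 10%
        _add("high_features", col)
    for _ in range(n_mito):
        col = np.zeros(config.n_genes, dtype=np.int64)
        picks = rng.choice(
            np.arange(n_mito_genes, config.n_genes), size=300, replace=False
        )
        col[picks] = 1
        col[:n_mito_genes] = 8  # 104 mito of 404 total counts: ~26% mito
        _add("high_mito", col)

    extra = np.stack([c for _, c in cols], axis=1)
    matrix = CountMatrix(
        genes=base.genes,
        barcodes=np.concatenate([base.barcodes, [b for b, _ in cols]]),
        counts=sp.hstack([base.counts, sp.csr_matrix(extra)], format="csr"),
        sample_label=base.sample_label,
        mito_flags=base.mito_flags,
    )
    return matrix, pd.DataFrame(manifest)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

_TYPES = ("ILC1", "Mph", "NT", "NK", "DC", "DNT")
_YOUNG = (1171, 728, 562, 324, 331, 191)   # 3307 cells; ILC1 35.4%, NK 9.8%
_OLD = (1203, 766, 656, 383, 500, 1960)    # 5468 cells; DNT 35.8%
_INNATE = ("ILC1", "NT", "DC")             # types carrying the mediator down-shift
#: focal strongly-affected interactions mirroring the reported network pattern
_FOCAL_DOWN = (
    ("ILC1", ("Ccl3", "Ccl4", "Ccl5", "Ccl8", "Ccr5", "Cxcl2", "Ccrl2")),
    ("DC", ("Ccl2", "Ccl7", "Ccl12", "Ccr5", "Cxcl2")),
    ("NT", ("Ccr2", "Cxcl2", "Il1a", "Il1b", "Il1rn", "Il1r1", "Il1r2",
            "Tnf", "Tnfrsf1b", "Inhba", "Acvr2a")),
)


def chemokine_cytokine_sets(pairs: pd.DataFrame | None = None):
    """Partition an LR pair table's genes into chemokine and cytokine sets.

    Chemokines follow the systematic Ccl/Cxcl ligand and Ccr/Cxcr/Ccrl
    receptor nomenclature; everything else in the table is a cytokine or
    cytokine receptor.
    """
    if pairs is None:
        pairs = packaged_lr_pairs()
    genes = list(
        dict.fromkeys(pairs["ligand"].tolist() + pairs["receptor"].tolist())
    )
    chemo_prefixes = ("Ccl", "Cxcl", "Ccr", "Cxcr", "Ccrl", "Ackr")
    chemo = [g for g in genes if g.startswith(chemo_prefixes)]
    cyto = [g for g in genes if g not in chemo]
    return (
        GeneSet(name="chemokines", genes=tuple(chemo)),
        GeneSet(name="cytokines", genes=tuple(cyto)),
    )


def default_config(seed: int = 0, n_genes: int = 2000) -> SimConfig:
    """The default synthetic study conditions.

    Composition mirrors the measured samples (3307 young / 5468 old cells;
    young dominated by innate types with ILC1 at 35.4% and DNT at ~6%, old
    dominated by DNT at ~36% with every innate fraction reduced). The
    chemokine and cytokine sets are coordinately halved in the innate
    types at old age, a focal subset of ligand-receptor genes is cut to
    0.25x so the twofold network rule engages, control genes are planted
    at 4x / 0.25x per type, and the 24 SASP receptors gain +0.2 detection
    probability in old macrophages.
    """
    pairs = packaged_lr_pairs()
    chemo, cyto = chemokine_cytokine_sets(pairs)
    sasp = packaged_sasp_receptors()
    extra = tuple(
        dict.fromkeys(list(chemo.genes) + list(cyto.genes) + list(sasp.genes))
    )

    de: list[tuple] = []
    for ct in _INNATE:
        for g in chemo.genes + cyto.genes:
            de.append((ct, g, 0.5))
    focal = {(ct, g) for ct, gs in _FOCAL_DOWN for g in gs}
    de = [(ct, g, 0.25 if (ct, g) in focal else f) for ct, g, f in de]
    # per-type planted control DEGs on filler genes (4x up / 0.25x down)
    n_fill_start = 13 + len(_TYPES) * 3 + len(extra)
    fillers = [f"G{i:05d}" for i in range(n_genes - n_fill_start)]
    k = 0
    for ct in _TYPES:
        for _ in range(8):
            de.append((ct, fillers[k], 4.0))
            k += 1
        for _ in range(8):
            de.append((ct, fillers[k], 0.25))
            k += 1

    frac = tuple(("Mph", g, 0.30, 0.50) for g in sasp.genes)

    return SimConfig(
        n_cell_types=len(_TYPES),
        cells_per_type_young=_YOUNG,
        cells_per_type_old=_OLD,
        n_genes=n_genes,
        markers_per_type=3,
        marker_fold=8.0,
        baseline_mean=0.3,
        dispersion=2.0,
        de_spec=tuple(de),
        fraction_spec=frac,
        mito_fraction_range=(0.01, 0.04),
        seed=seed,
        cell_type_names=_TYPES,
        extra_genes=extra,
    )


def planted_expectations(config: SimConfig) -> dict:
    """Ground truth for end-to-end recovery checks."""
    de_by_type: dict[str, dict[str, float]] = {}
    for ct, g, fold in config.de_spec:
        de_by_type.setdefault(ct, {})[g] = fold
    frac_by_type: dict[str, dict[str, tuple]] = {}
    for ct, g, fy, fo in config.fraction_spec:
        frac_by_type.setdefault(ct, {})[g] = (fy, fo)
        # fraction plantings supersede DE plantings for the same entry
        de_by_type.get(ct, {}).pop(g, None)
    return {"de": de_by_type, "fractions": frac_by_type}
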