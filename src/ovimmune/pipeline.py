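"""End-to-end orchestration: config validation, staged execution, run report.

Every stage writes plain TSV/JSON into the run's output directory so any
stage can be re-run and inspected in isolation; there is no opaque binary
state. One global seed deterministically derives every stage seed, and
wall-clock timings live in a separate file (timings.json) so all other
outputs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, de, geneset, network, qc, sasp, simulate
from . import io as ovio

logger = logging.getLogger(__name__)

STAGES = ("qc", "normalize", "annotate", "de", "setshift", "network", "sasp",
          "composition")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    young_dir: str
    old_dir: str
    clusters_young: str
    clusters_old: str
    marker_panel: str
    lr_pairs: str
    chemokine_set: str
    cytokine_set: str
    sasp_set: str
    out_dir: str
    min_features: int = 200
    max_features: int = 2500
    max_mito: float = 0.10
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    q_threshold: float = 0.1
    alpha: float = 0.01
    n_resample: int = 10000
    pseudocount: float = 1e-9
    tail_mass: float = 0.025
    mito_prefix: str = "mt-"
    seed: int = 0

_PATH_KEYS = ("young_dir", "old_dir", "clusters_young", "clusters_old",
              "marker_panel", "lr_pairs", "chemokine_set", "cytokine_set",
              "sasp_set")


def validate_config(path) -> RunConfig:
    """Parse, default, and range-check a YAML run config; reject unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of config keys")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = [k for k in _PATH_KEYS + ("out_dir",) if k not in raw]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    cfg = RunConfig(**raw)
    base = Path(path).parent
    for key in _PATH_KEYS:
        p = Path(getattr(cfg, key))
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigError(f"{key}: path does not exist: {p}")
        setattr(cfg, key, str(p))
    out = Path(cfg.out_dir)
    if not out.is_absolute():
        out = base / out
    cfg.out_dir = str(out)
    if not (0 <= cfg.min_features <= cfg.max_features):
        raise ConfigError("need 0 <= min_features <= max_features")
    if not (0 <= cfg.max_mito <= 1):
        raise ConfigError("max_mito must lie in [0, 1]")
    for key in ("p_threshold", "q_threshold", "alpha", "tail_mass"):
        v = getattr(cfg, key)
        if not (0 < v < 1):
            raise ConfigError(f"{key} must lie in (0, 1)")
    if cfg.fc_threshold < 1:
        raise ConfigError("fc_threshold must be >= 1")
    if cfg.n_resample < 1:
        raise ConfigError("n_resample must be >= 1")
    return cfg


def derive_seed(base_seed: int, *tags: int) -> int:
    """Deterministically derive a sub-2^31 stage seed from the global seed."""
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(t) for t in tags))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# stages (each reads its on-disk inputs and writes its outputs)
# ---------------------------------------------------------------------------

def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


_RAW_CACHE: dict = {}


def _load_raw(config: RunConfig, age: str) -> ovio.CountMatrix:
    d = config.young_dir if age == "young" else config.old_dir
    key = (d, config.mito_prefix, age)
    if key not in _RAW_CACHE:
        if len(_RAW_CACHE) > 6:
            _RAW_CACHE.clear()
        _RAW_CACHE[key] = ovio.read_10x_triplet(
            d, mito_prefix=config.mito_prefix, sample_label=age
        )
    return _RAW_CACHE[key]


def _load_filtered(config: RunConfig, age: str) -> ovio.CountMatrix:
    m = _load_raw(config, age)
    keep_path = _out(config) / f"retained_barcodes_{age}.txt"
    keep = set(keep_path.read_text().split())
    mask = np.asarray([b in keep for b in m.barcodes])
    return m.subset_cells(mask)


def stage_qc(config: RunConfig) -> dict:
    out = _out(config)
    reports = {}
    for age in ("young", "old"):
        m = _load_raw(config, age)
        filtered, report = qc.qc_filter(
            m, config.min_features, config.max_features, config.max_mito
        )
        (out / f"retained_barcodes_{age}.txt").write_text(
            "\n".join(map(str, filtered.barcodes)) + "\n"
        )
        reports[age] = report
    table = pd.DataFrame(
        [{"sample": age, **rep.to_dict()} for age, rep in reports.items()]
    )
    ovio.write_table(table, out / "qc_report.tsv")
    return {age: rep.to_dict() for age, rep in reports.items()}


def stage_normalize(config: RunConfig) -> dict:
    """Validate that both filtered samples normalize cleanly."""
    info = {}
    for age in ("young", "old"):
        m = _load_filtered(config, age)
        if m.n_cells == 0:
            raise ValueError(f"no cells left in {age} sample after QC")
        qc.log_normalize(m)
        info[age] = m.n_cells
    return info


def stage_annotate(config: RunConfig) -> dict:
    out = _out(config)
    panel = ovio.read_marker_panel(config.marker_panel)
    all_cells = []
    info = {}
    for age in ("young", "old"):
        m = _load_filtered(config, age)
        clusters = ovio.read_cell_clusters(
            config.clusters_young if age == "young" else config.clusters_old
        )
        clusters = clusters[clusters["barcode"].isin(set(m.barcodes))]
        scores = annotation.marker_score(m, clusters, panel)
        assignments = annotation.assign_clusters(scores, panel)
        ovio.write_table(assignments, out / f"cluster_assignments_{age}.tsv")
        cells = annotation.apply_assignments(clusters, assignments)
        cells.insert(1, "age_group", age)
        all_cells.append(cells)
        info[age] = {
            "n_clusters": int(assignments.shape[0]),
            "types": sorted(assignments["cell_type"].unique()),
        }
    combined = pd.concat(all_cells, ignore_index=True)
    ovio.write_table(combined, out / "cells.tsv")
    return info


def _load_cells(config: RunConfig) -> pd.DataFrame:
    df = ovio.read_table(_out(config) / "cells.tsv")
    df["barcode"] = df["barcode"].astype(str)
    return df


def _combined_norm(config: RunConfig):
    young = _load_filtered(config, "young")
    old = _load_filtered(config, "old")
    young, old = ovio.align_genes(young, old)
    combined = ovio.concat_cells(young, old)
    return qc.log_normalize(combined), combined


def _usable_types(cells: pd.DataFrame) -> list:
    counts = cells.groupby(["cell_type", "age_group"]).size().unstack(fill_value=0)
    usable = []
    for ct, row in counts.iterrows():
        if ct == annotation.UNRESOLVED:
            continue
        if row.get("young", 0) >= 2 and row.get("old", 0) >= 2:
            usable.append(ct)
        else:
            logger.warning("cell type %s lacks cells in one age group; skipped", ct)
    return sorted(usable)


def stage_de(config: RunConfig) -> dict:
    out = _out(config)
    norm, _ = _combined_norm(config)
    cells = _load_cells(config)
    info = {}
    for ct in _usable_types(cells):
        table = de.differential_expression(
            norm, cells, ct,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            q_threshold=config.q_threshold,
            pseudocount=config.pseudocount,
            tail_mass=config.tail_mass,
        )
        ovio.write_table(table, out / f"deg_{ct}.tsv")
        info[ct] = {
            "n_tested": int(table.shape[0]),
            "n_deg": int(table["is_deg"].sum()),
            "n_down": int((table["is_deg"] & (table["direction"] == "down")).sum()),
            "n_up": int((table["is_deg"] & (table["direction"] == "up")).sum()),
        }
    return info


def _load_deg_tables(config: RunConfig) -> dict:
    out = _out(config)
    tables = {}
    for p in sorted(out.glob("deg_*.tsv")):
        tables[p.stem.removeprefix("deg_")] = ovio.read_table(p)
    if not tables:
        raise ValueError("no DEG tables found; run the de stage first")
    return tables


def stage_setshift(config: RunConfig) -> dict:
    out = _out(config)
    degs = _load_deg_tables(config)
    sets = [
        ovio.read_gene_set(config.chemokine_set, name="chemokines"),
        ovio.read_gene_set(config.cytokine_set, name="cytokines"),
    ]
    rows = []
    curves = []
    for si, gs in enumerate(sets):
        for ti, (ct, table) in enumerate(sorted(degs.items())):
            fc = table.set_index("gene")["fc"]
            seed = derive_seed(config.seed, 1, si, ti)
            res = geneset.set_shift_test(fc, gs, config.n_resample, seed)
            rows.append({"cell_type": ct, **res.to_dict()})
            present = [g for g in gs.genes if g in fc.index]
            curves.append(
                geneset.ecdf_table(fc.loc[present], f"{gs.name}|{ct}|set")
            )
            curves.append(
                geneset.ecdf_table(fc, f"{gs.name}|{ct}|all_genes", n_points=200)
            )
    ovio.write_table(pd.DataFrame(rows), out / "set_shift.tsv")
    ovio.write_table(pd.concat(curves, ignore_index=True), out / "set_shift_ecdf.tsv")
    return {
        "n_significant": int(sum(r["ks_p"] < config.alpha for r in rows)),
        "n_tests": len(rows),
    }


def stage_network(config: RunConfig) -> dict:
    out = _out(config)
    degs = _load_deg_tables(config)
    pairs = ovio.read_lr_pairs(config.lr_pairs)
    edge_frames = []
    chord_frames = []
    for direction in ("down", "up"):
        edges = network.flag_edges(pairs, degs, direction)
        edge_frames.append(edges)
        chord_frames.append(network.chord_summarize(edges))
    edges = pd.concat(edge_frames, ignore_index=True)
    chords = pd.concat(chord_frames, ignore_index=True)
    ovio.write_table(edges, out / "network_edges.tsv")
    ovio.write_table(chords, out / "network_chord.tsv")
    return {
        "n_flagged_down": int(
            (edges["flagged"] & (edges["direction"] == "down")).sum()
        ),
        "n_flagged_up": int((edges["flagged"] & (edges["direction"] == "up")).sum()),
    }


def stage_sasp(config: RunConfig) -> dict:
    out = _out(config)
    young = _load_filtered(config, "young")
    old = _load_filtered(config, "old")
    young, old = ovio.align_genes(young, old)
    combined = ovio.concat_cells(young, old)
    cells = _load_cells(config)
    gs = ovio.read_gene_set(config.sasp_set, name="sasp_receptors")

    frac_frames = []
    shift_rows = []
    fwer_rows = []
    for ti, ct in enumerate(_usable_types(cells)):
        fracs = sasp.expressed_fraction(combined, cells, ct, gs)
        fracs = sasp.fraction_test(fracs, alpha=config.alpha)
        frac_frames.append(fracs)
        diffs = sasp.all_gene_fraction_diffs(combined, cells, ct)
        seed = derive_seed(config.seed, 2, ti)
        res = sasp.fraction_set_cdf(diffs, gs, config.n_resample, seed)
        shift_rows.append({"cell_type": ct, **res.to_dict()})
        k = int((fracs["significant"] & (fracs["diff"] > 0)).sum())
        fwer_rows.append(
            sasp.analytic_fwer(k, len(gs), config.alpha, cell_type=ct).to_dict()
        )
    ovio.write_table(pd.concat(frac_frames, ignore_index=True),
                     out / "sasp_fractions.tsv")
    ovio.write_table(pd.DataFrame(shift_rows), out / "sasp_shift.tsv")
    ovio.write_table(pd.DataFrame(fwer_rows), out / "sasp_fwer.tsv")
    return {r["cell_type"]: r["k_significant"] for r in fwer_rows}


def stage_composition(config: RunConfig) -> dict:
    out = _out(config)
    cells = _load_cells(config)
    table = geneset.composition_fractions(cells)
    ovio.write_table(table, out / "composition.tsv")
    return {"n_rows": int(table.shape[0])}


_STAGE_FNS = {
    "qc": stage_qc,
    "normalize": stage_normalize,
    "annotate": stage_annotate,
    "de": stage_de,
    "setshift": stage_setshift,
    "network": stage_network,
    "sasp": stage_sasp,
    "composition": stage_composition,
}


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; abort naming the stage on failure.

    Returns the run report (also written as report.json); wall-clock
    timings go to timings.json so the report stays deterministic.
    """
    out = _out(config)
    report: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    timings = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            report["stages"][stage] = _STAGE_FNS[stage](config)
        except Exception as exc:
            report["failed_stage"] = stage
            report["error"] = str(exc)
            (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
            raise StageError(stage, str(exc)) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# synthetic input bundles
# ---------------------------------------------------------------------------

def write_synthetic_inputs(
    input_dir,
    seed: int = 0,
    config: simulate.SimConfig | None = None,
    with_qc_violators: tuple[tuple[int, int, int], tuple[int, int, int]] | None = (
        (280, 0, 106),   # young: 3693 loaded barcodes, 3307 clean
        (136, 0, 40),    # old: 5644 loaded barcodes, 5468 clean
    ),
) -> Path:
    """Materialize a complete synthetic input bundle plus run_config.yaml.

    Writes young/ and old/ 10x triplet directories, per-cell cluster
    tables, the marker panel, the LR pair table, the chemokine/cytokine/
    SASP gene sets, and a ready-to-run YAML config pointing at them.
    ``with_qc_violators`` appends (n_low, n_high, n_mito) QC-failing cells
    per sample so the QC stage has work to do; pass None for clean samples.
    """
    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else simulate.default_config(seed=seed)

    young, old, cells = simulate.simulate_counts(cfg)
    matrices = {"young": young, "old": old}
    if with_qc_violators is not None:
        for age, spec in zip(("young", "old"), with_qc_violators):
            n_low, n_high, n_mito = spec
            if n_low + n_high + n_mito == 0:
                continue
            base = matrices[age]
            vcfg = dataclasses.replace(
                cfg,
                cells_per_type_young=(1,) * cfg.n_cell_types,
                cells_per_type_old=(1,) * cfg.n_cell_types,
                seed=derive_seed(cfg.seed, 9, 0 if age == "young" else 1),
            )
            extra, manifest = simulate.simulate_qc_violators(
                vcfg, n_low, n_high, n_mito
            )
            viol = extra.subset_cells(np.arange(cfg.n_cell_types, extra.n_cells))
            viol_barcodes = np.asarray(
                [f"{age[0].upper()}{b}" for b in viol.barcodes], dtype=object
            )
            viol = ovio.CountMatrix(
                genes=viol.genes, barcodes=viol_barcodes, counts=viol.counts,
                sample_label=age, mito_flags=viol.mito_flags,
            )
            matrices[age] = ovio.concat_cells(base, viol, sample_label=age)
            viol_cells = pd.DataFrame(
                {
                    "barcode": viol_barcodes,
                    "age_group": age,
                    "cluster_id": 0,
                    "cell_type": cfg.cell_type_names[0],
                }
            )
            cells = pd.concat([cells, viol_cells], ignore_index=True)

    for age, m in matrices.items():
        ovio.write_10x_triplet(m, input_dir / age)
        sub = cells[cells["age_group"] == age]
        ovio.write_table(
            sub[["barcode", "cluster_id"]], input_dir / f"clusters_{age}.tsv"
        )
    ovio.write_table(cells, input_dir / "true_cells.tsv")
    ovio.write_table(simulate.marker_panel(cfg), input_dir / "marker_panel.tsv")

    pairs = ovio.packaged_lr_pairs()
    ovio.write_table(pairs, input_dir / "lr_pairs.tsv")
    chemo, cyto = simulate.chemokine_cytokine_sets(pairs)
    ovio.write_gene_set(chemo, input_dir / "chemokine_set.tsv")
    ovio.write_gene_set(cyto, input_dir / "cytokine_set.tsv")
    ovio.write_gene_set(ovio.packaged_sasp_receptors(), input_dir / "sasp_set.tsv")

    config_yaml = {
        "young_dir": "young",
        "old_dir": "old",
        "clusters_young": "clusters_young.tsv",
        "clusters_old": "clusters_old.tsv",
        "marker_panel": "marker_panel.tsv",
        "lr_pairs": "lr_pairs.tsv",
        "chemokine_set": "chemokine_set.tsv",
        "cytokine_set": "cytokine_set.tsv",
        "sasp_set": "sasp_set.tsv",
        "out_dir": "results",
        "seed": int(seed),
    }
    cfg_path = input_dir / "run_config.yaml"
    cfg_path.write_text(yaml.safe_dump(config_yaml, sort_keys=True))
    return cfg_path
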