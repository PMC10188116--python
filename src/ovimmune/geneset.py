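"""Gene-set distribution-shift tests and composition summaries.

A gene set's fold-change (or any per-gene statistic's) distribution is
compared against the all-gene background by a two-sample KS test, and
against a resampling null of random same-size gene sets drawn without
replacement from the tested-gene universe: the observed set's median is
ranked among the resampled medians.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftResult:
    set_name: str
    n_set: int
    ks_D: float
    ks_p: float
    null_percentile: float
    n_resample: int
    seed: int
    median_set: float
    median_all: float

    def to_dict(self) -> dict:
        return asdict(self)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_x - ECDF_y|.

    The p-value is exact when both samples have at most 25 observations,
    asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if max(x.size, y.size) <= 25 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def _resampled_medians(values: np.ndarray, k: int, n_resample: int,
                       rng: np.random.Generator) -> np.ndarray:
    m = values.size
    out = np.empty(n_resample)
    for i in range(n_resample):
        out[i] = np.median(values[rng.choice(m, size=k, replace=False)])
    return out


def set_shift_test(
    fc: pd.Series,
    gene_set: GeneSet,
    n_resample: int = 10000,
    seed: int = 0,
) -> ShiftResult:
    """Test whether a gene set's values are shifted relative to all genes.

    ``fc`` maps every tested gene to its statistic (fold change here, a
    fraction difference elsewhere). The KS test compares the set's values
    to all genes' values; the resampling null draws ``n_resample`` random
    same-size sets without replacement from the tested genes and reports
    the percentile of the observed set median among the resampled medians
    (ties counted half).
    """
    present = [g for g in gene_set.genes if g in fc.index]
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with fc")
    if len(present) < len(gene_set) / 2:
        logger.warning(
            "gene set %s: only %d of %d genes among tested genes",
            gene_set.name, len(present), len(gene_set),
        )
    obs = fc.loc[present].to_numpy(dtype=float)
    all_values = fc.to_numpy(dtype=float)
    d, p = ks_two_sample(obs, all_values)
    rng = np.random.default_rng(seed)
    null = _resampled_medians(all_values, len(present), n_resample, rng)
    med = float(np.median(obs))
    percentile = float(
        ((null < med).sum() + 0.5 * (null == med).sum()) / n_resample
    )
    return ShiftResult(
        set_name=gene_set.name,
        n_set=len(present),
        ks_D=d,
        ks_p=p,
        null_percentile=percentile,
        n_resample=n_resample,
        seed=seed,
        median_set=med,
        median_all=float(np.median(all_values)),
    )


def ecdf_table(values, label: str, n_points: int | None = None) -> pd.DataFrame:
    """Empirical CDF as a (label, x, y) table for export/plotting."""
    v = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, v.size + 1) / v.size
    if n_points is not None and v.size > n_points:
        idx = np.linspace(0, v.size - 1, n_points).astype(int)
        v, y = v[idx], y[idx]
    return pd.DataFrame({"curve": label, "x": v, "y": y})


def composition_fractions(cells: pd.DataFrame, conf_level: float = 0.95,
                          method: str = "wilson") -> pd.DataFrame:
    """Per-age cell-type fractions with binomial confidence intervals.

    Wilson score intervals by default. Fractions within an age sum to 1.
    """
    rows = []
    for age, group in cells.groupby("age_group"):
        n_total = len(group)
        for cell_type, n in group["cell_type"].value_counts().sort_index().items():
            lo, hi = proportion_confint(n, n_total, alpha=1 - conf_level, method=method)
            rows.append(
                {
                    "age_group": age,
                    "cell_type": cell_type,
                    "n": int(n),
                    "n_total": n_total,
                    "fraction": n / n_total,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
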