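"""Population mean-fitness trajectory from intergenic super-barcodes.

As selected lineages change frequency, the population mean fitness
xbar_t drifts away from zero and discounts every lineage's apparent
log-slope.  Neutral (intergenic) barcodes measure exactly this discount:
their frequency decays as exp(-xbar_t t).  Summing ~100 random intergenic
barcodes into "super-barcodes" beats down counting noise, and the median
across super-barcodes resists contamination by the occasional selected
intergenic insertion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountTable, MeanFitnessSeries
from .error_model import MAD_TO_SD

__all__ = ["build_superbarcodes", "estimate_mean_fitness", "mean_fitness_series"]

log = logging.getLogger(__name__)


def build_superbarcodes(
    intergenic: CountTable,
    size: int = 100,
    rmax: int = 500,
    keep_leftover: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sum disjoint random groups of intergenic barcodes into super-barcodes.

    Only barcodes with r < ``rmax`` at every timepoint are eligible
    (high-count barcodes are more likely to carry secondary selected
    mutations).  Leftover barcodes after grouping form one final smaller
    group when ``keep_leftover`` (set False to discard them).
    """
    r = intergenic.counts
    eligible = r.index[(r.to_numpy() < rmax).all(axis=1)]
    if len(eligible) < 2 * size:
        raise ValueError(
            f"need at least {2 * size} eligible intergenic barcodes, "
            f"found {len(eligible)}"
        )
    if rng is None:
        rng = np.random.default_rng()
    perm = rng.permutation(len(eligible))
    groups = [perm[i : i + size] for i in range(0, len(perm), size)]
    if len(groups[-1]) < size and not keep_leftover:
        groups = groups[:-1]
    rows = [r.loc[eligible[g]].sum(axis=0) for g in groups]
    out = pd.DataFrame(rows, index=[f"sb{i:04d}" for i in range(len(rows))])
    out.index.name = "superbarcode"
    return out


def estimate_mean_fitness(
    superbarcodes: pd.DataFrame, meta: pd.DataFrame, t_index: int
) -> tuple[float, float]:
    """Mean fitness between time 0 and timepoint ``t_index`` (positional).

    Each super-barcode contributes the negative per-generation log-slope
    of its frequency, -(1/t)[log(r_t/R_t) - log(r_0/R_0)]; the estimate
    is the median across super-barcodes and the standard error is the
    Gaussian-rescaled MAD divided by sqrt(n).  Super-barcodes extinct at
    either endpoint are excluded with a warning.
    """
    t = float(meta["generations"].iloc[t_index])
    if t <= 0:
        raise ValueError("mean fitness is defined for t > 0 generations")
    R = meta["total_reads"].to_numpy(float)
    r0 = superbarcodes.iloc[:, 0].to_numpy(float)
    rt = superbarcodes.iloc[:, t_index].to_numpy(float)
    ok = (r0 > 0) & (rt > 0)
    if not ok.all():
        log.warning(
            "excluding %d extinct super-barcodes at t=%.2f", (~ok).sum(), t
        )
    if ok.sum() == 0:
        raise ValueError("all super-barcodes extinct at this timepoint")
    x = -(np.log(rt[ok] / R[t_index]) - np.log(r0[ok] / R[0])) / t
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    se = (mad / MAD_TO_SD) / np.sqrt(ok.sum())
    return med, se


def mean_fitness_series(
    intergenic: CountTable,
    size: int = 100,
    rmax: int = 500,
    rng: np.random.Generator | None = None,
) -> MeanFitnessSeries:
    """xbar_t at every timepoint (xbar_0 = 0 by construction)."""
    sb = build_superbarcodes(intergenic, size=size, rmax=rmax, rng=rng)
    T = len(intergenic.meta)
    xbar = np.zeros(T)
    se = np.zeros(T)
    for k in range(1, T):
        xbar[k], se[k] = estimate_mean_fitness(sb, intergenic.meta, k)
    return MeanFitnessSeries(
        intergenic.generations, xbar, se, n_superbarcodes=len(sb)
    )
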