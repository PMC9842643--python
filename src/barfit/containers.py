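"""Core data containers shared across the pipeline.

The pipeline moves read-count tables (barcode x timepoint) through a chain
of cleaning, error-calibration and likelihood-inference stages.  The
containers here are thin wrappers around pandas DataFrames so that every
stage can be driven either from files (TSV) or in memory.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "GeneBarcodeSet",
    "MeanFitnessSeries",
    "serial_dilution_timepoints",
    "generations_per_cycle",
    "read_pool",
    "write_pool",
]

#: metadata columns every CountTable carries, one row per timepoint
META_COLUMNS = ("timepoint", "generations", "transfer_index", "total_reads")


def generations_per_cycle(dilution: float = 100.0) -> float:
    """Generations elapsed in one serial-dilution growth cycle.

    Under serial transfer at a fixed dilution factor D, the culture must
    double log2(D) times to return to saturation, independent of growth
    rate; a 1:100 cycle is log2(100) ~ 6.64 generations.
    """
    if dilution <= 1:
        raise ValueError("dilution factor must exceed 1")
    return math.log2(dilution)


def serial_dilution_timepoints(
    n_cycles: int,
    dilution: float = 100.0,
    total_reads: int | np.ndarray = 10_000_000,
) -> pd.DataFrame:
    """Build the timepoint metadata table for a serial-dilution experiment.

    Returns one row per observation: time 0 plus the end of each of
    ``n_cycles`` growth cycles.  ``generations`` accumulates
    log2(dilution) per cycle; ``transfer_index`` counts transfers.
    """
    gpc = generations_per_cycle(dilution)
    idx = np.arange(n_cycles + 1)
    reads = np.broadcast_to(np.asarray(total_reads), idx.shape).astype(np.int64)
    return pd.DataFrame(
        {
            "timepoint": [f"t{i}" for i in idx],
            "generations": gpc * idx,
            "transfer_index": idx,
            "total_reads": reads,
        }
    )


@dataclass
class CountTable:
    """Barcode read counts over timepoints, with per-timepoint metadata.

    Attributes
    ----------
    counts:
        DataFrame indexed by barcode, one integer column per timepoint
        (column names match ``meta['timepoint']``).
    meta:
        DataFrame with columns ``timepoint, generations, transfer_index,
        total_reads``.  ``total_reads`` is the library sequencing depth
        R_t, which may exceed the column sum (unmapped reads).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"timepoint metadata missing column {col!r}")
        if not (self.meta["total_reads"] > 0).all():
            raise ValueError("total_reads must be positive at every timepoint")
        gens = self.meta["generations"].to_numpy(float)
        order = self.meta["transfer_index"].to_numpy()
        if len(gens) > 1 and not (np.diff(gens[np.argsort(order)]) > 0).all():
            raise ValueError("generations must increase with transfer_index")
        self.counts = self.counts[list(self.meta["timepoint"])]
        self.counts.columns.name = None
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")

    @property
    def generations(self) -> np.ndarray:
        return self.meta["generations"].to_numpy(float)

    @property
    def total_reads(self) -> np.ndarray:
        return self.meta["total_reads"].to_numpy(float)

    @property
    def transfer_index(self) -> np.ndarray:
        return self.meta["transfer_index"].to_numpy(int)

    def frequencies(self) -> pd.DataFrame:
        """Observed barcode frequencies r_{t,i} / R_t."""
        return self.counts / self.total_reads

    def subset(self, barcodes) -> "CountTable":
        return CountTable(self.counts.loc[list(barcodes)].copy(), self.meta.copy())

    # ---- I/O -----------------------------------------------------------
    def write(self, counts_path: str | Path, meta_path: str | Path) -> None:
        out = self.counts.reset_index()
        out.columns = ["barcode"] + list(self.counts.columns)
        out.to_csv(counts_path, sep="\t", index=False)
        self.meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, meta_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t").set_index("barcode")
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(counts, meta)


@dataclass
class GeneBarcodeSet:
    """The clean barcode trajectories assigned to one gene.

    ``masks`` holds one boolean retained-timepoint vector per barcode
    (extinct tails trimmed); counts outside the mask are ignored by the
    likelihood.
    """

    gene: str
    counts: pd.DataFrame  # barcode x timepoint
    masks: dict = field(default_factory=dict)  # barcode -> bool array

    def __post_init__(self) -> None:
        T = self.counts.shape[1]
        for bc in self.counts.index:
            if bc not in self.masks:
                self.masks[bc] = np.ones(T, dtype=bool)

    @property
    def n_barcodes(self) -> int:
        return len(self.counts)

    def drop(self, barcodes) -> "GeneBarcodeSet":
        keep = [b for b in self.counts.index if b not in set(barcodes)]
        return GeneBarcodeSet(
            self.gene,
            self.counts.loc[keep].copy(),
            {b: self.masks[b] for b in keep},
        )


@dataclass
class MeanFitnessSeries:
    """Population mean-fitness trajectory x̄_t (1/generation) with errors."""

    generations: np.ndarray
    xbar: np.ndarray
    se: np.ndarray
    n_superbarcodes: int = 0

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, float)
        self.xbar = np.asarray(self.xbar, float)
        self.se = np.asarray(self.se, float)
        if self.generations[0] == 0 and self.xbar[0] != 0:
            raise ValueError("mean fitness at t=0 must be 0 by construction")

    @classmethod
    def zero(cls, generations) -> "MeanFitnessSeries":
        g = np.asarray(generations, float)
        return cls(g, np.zeros_like(g), np.zeros_like(g))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generations": self.generations, "xbar": self.xbar, "se": self.se}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "MeanFitnessSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df["generations"], df["xbar"], df["se"])


# ---- insertion pool tables ----------------------------------------------

POOL_COLUMNS = ("barcode", "position", "gene", "frac_within_gene", "intergenic")


def read_pool(path: str | Path) -> pd.DataFrame:
    """Read a barcode->insertion pool table (TSV).

    Columns: barcode, position (1-based), gene (empty for intergenic),
    frac_within_gene in [0, 1] (NaN for intergenic), intergenic (0/1),
    optionally gc_content.
    """
    pool = pd.read_csv(path, sep="\t", dtype={"barcode": str, "gene": str})
    for col in POOL_COLUMNS:
        if col not in pool.columns:
            raise ValueError(f"pool table missing column {col!r}")
    pool["intergenic"] = pool["intergenic"].astype(bool)
    return pool


def write_pool(pool: pd.DataFrame, path: str | Path) -> None:
    pool.to_csv(path, sep="\t", index=False)
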