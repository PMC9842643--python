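"""Barcode count-table cleanup: sequencing-error merging, gene assignment,
count floors, extinct-tail trimming and gene-level filters.

The output of this module is the set of per-gene clean barcode
trajectories (:class:`~barfit.containers.GeneBarcodeSet`) consumed by the
likelihood machinery, plus the intergenic (putatively neutral) table used
to calibrate errors and mean fitness.
"""

from __future__ import annotations

import logging

import edlib
import numpy as np
import pandas as pd

from .containers import CountTable, GeneBarcodeSet

__all__ = [
    "merge_barcode_errors",
    "map_and_trim",
    "enforce_min_initial",
    "trim_extinct",
    "assemble_gene_sets",
    "process_experiment",
]

log = logging.getLogger(__name__)


def _edit_distance(a: str, b: str, k: int) -> int:
    """Levenshtein distance, or k+1 if it exceeds the cutoff k."""
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    return d if d >= 0 else k + 1


def _merge_pass(counts: pd.DataFrame, totals: pd.Series, max_edit: int):
    """One merge pass: each minority barcode is absorbed by the unique
    higher-count barcode at minimum edit distance <= max_edit, if any.

    Minority/majority ranking uses total counts summed over timepoints;
    ties are broken lexicographically so the result is independent of
    input row order.  Returns (counts, totals, n_merged).
    """
    # descending count; lexicographic tie-break -> deterministic ranking
    order = sorted(counts.index, key=lambda bc: (-totals[bc], bc))
    lengths = {bc: len(bc) for bc in order}
    absorbed: dict[str, str] = {}
    for i in range(len(order) - 1, 0, -1):
        minority = order[i]
        best_d = max_edit + 1
        best = None
        ambiguous = False
        for majority in order[:i]:
            # a true minority has strictly fewer counts than its parent
            if totals[majority] <= totals[minority]:
                continue
            if abs(lengths[majority] - lengths[minority]) > max_edit:
                continue
            d = _edit_distance(minority, majority, max_edit)
            if d < best_d:
                best_d, best, ambiguous = d, majority, False
            elif d == best_d and d <= max_edit:
                ambiguous = True
        if best is not None and best_d <= max_edit and not ambiguous:
            absorbed[minority] = best
    if not absorbed:
        return counts, totals, 0
    # follow chains in case the target was itself absorbed this pass
    def _root(bc: str) -> str:
        while bc in absorbed:
            bc = absorbed[bc]
        return bc

    out = counts.copy()
    for minority, majority in absorbed.items():
        out.loc[_root(minority)] += counts.loc[minority]
    out = out.drop(index=list(absorbed))
    return out, out.sum(axis=1), len(absorbed)


def merge_barcode_errors(table: CountTable, max_edit: int = 4) -> CountTable:
    """Merge read counts of likely PCR/sequencing-error barcodes.

    Two passes: first off-by-one neighbors (edit distance 1), then the
    general pass at edit distance <= ``max_edit``.  A minority barcode is
    merged only when it maps to a *unique* majority barcode at its
    minimum edit distance; ambiguous minorities are left untouched.
    Total read counts are conserved.
    """
    counts = table.counts.copy()
    totals = counts.sum(axis=1)
    counts, totals, n1 = _merge_pass(counts, totals, 1)
    counts, totals, n2 = _merge_pass(counts, totals, max_edit)
    if n1 or n2:
        log.info("merged %d off-by-one and %d distant error barcodes", n1, n2)
    return CountTable(counts, table.meta.copy())


def map_and_trim(
    table: CountTable,
    pool: pd.DataFrame,
    edge_frac: float = 0.05,
    unmapped_warn_frac: float = 0.10,
) -> tuple[pd.DataFrame, CountTable]:
    """Assign barcodes to genes via the insertion pool; split off neutrals.

    Insertions in the first or last ``edge_frac`` of a gene are discarded
    (they may not disrupt the gene product); the closed interval
    [edge_frac, 1 - edge_frac] is retained.  Barcodes absent from the
    pool are dropped with a logged count; a warning fires when the
    unmapped read fraction exceeds ``unmapped_warn_frac``.

    Returns
    -------
    gene_assignment : DataFrame (barcode, gene) for retained gene barcodes
    intergenic : CountTable of the putatively neutral barcodes
    """
    pool = pool.set_index("barcode")
    known = table.counts.index.intersection(pool.index)
    n_dropped = len(table.counts.index) - len(known)
    unmapped_reads = table.counts.drop(index=known).to_numpy().sum()
    frac = unmapped_reads / max(table.counts.to_numpy().sum(), 1)
    if n_dropped:
        log.info("dropped %d barcodes absent from the pool", n_dropped)
    if frac > unmapped_warn_frac:
        log.warning("%.1f%% of reads map to no pool barcode", 100 * frac)

    sub = pool.loc[known]
    inter_bcs = known[sub["intergenic"].to_numpy().astype(bool)]
    genic = sub[~sub["intergenic"].astype(bool)]
    frac_pos = genic["frac_within_gene"].to_numpy(float)
    keep = (frac_pos >= edge_frac) & (frac_pos <= 1 - edge_frac)
    gene_assignment = (
        genic[keep].reset_index()[["barcode", "gene"]].copy()
    )
    return gene_assignment, table.subset(inter_bcs)


def enforce_min_initial(counts: pd.DataFrame, r0_min: int = 80) -> pd.DataFrame:
    """Merge low-initial-count barcodes within a gene until min r0 >= r0_min.

    Iteratively sums the lowest-r0 barcode into the next-lowest (across
    all timepoints) until every remaining barcode starts at >= ``r0_min``
    reads or a single barcode remains.  Ties on r0 break
    lexicographically.  Total counts are conserved.
    """
    counts = counts.copy()
    t0 = counts.columns[0]
    while len(counts) > 1 and counts[t0].min() < r0_min:
        order = sorted(counts.index, key=lambda bc: (counts.at[bc, t0], bc))
        lowest, nxt = order[0], order[1]
        counts.loc[nxt] += counts.loc[lowest]
        counts = counts.drop(index=lowest)
    return counts


def trim_extinct(trajectory: np.ndarray) -> np.ndarray | None:
    """Trim an extinct tail to a single terminal zero.

    Returns a boolean retained-timepoint mask, or None if the barcode
    went extinct after just one timepoint (such barcodes are dropped).
    A zero followed by a nonzero count is an observation, not extinction.
    """
    r = np.asarray(trajectory)
    T = len(r)
    nz = np.nonzero(r)[0]
    if len(nz) == 0 or nz[-1] == 0:
        return None  # zero from the second timepoint onward
    t_ext = nz[-1] + 1  # first timepoint of the trailing zero run, if any
    mask = np.zeros(T, dtype=bool)
    mask[: min(t_ext + 1, T)] = True
    return mask


def assemble_gene_sets(
    table: CountTable,
    gene_assignment: pd.DataFrame,
    min_barcodes: int = 4,
    r0_min: int = 80,
) -> dict[str, GeneBarcodeSet]:
    """Build clean per-gene barcode sets.

    Applies, per gene: the initial-count floor merge, extinct-tail
    trimming (dropping immediately-extinct barcodes) and the minimum
    barcode-count filter.  Genes failing the filter are excluded and
    logged.
    """
    out: dict[str, GeneBarcodeSet] = {}
    n_excluded = 0
    for gene, grp in gene_assignment.groupby("gene"):
        bcs = [b for b in grp["barcode"] if b in table.counts.index]
        if not bcs:
            continue
        counts = enforce_min_initial(table.counts.loc[bcs], r0_min=r0_min)
        masks: dict[str, np.ndarray] = {}
        keep = []
        for bc in counts.index:
            mask = trim_extinct(counts.loc[bc].to_numpy())
            if mask is not None:
                masks[bc] = mask
                keep.append(bc)
        if len(keep) < min_barcodes:
            n_excluded += 1
            continue
        out[gene] = GeneBarcodeSet(gene, counts.loc[keep], masks)
    if n_excluded:
        log.info("excluded %d genes with <%d clean barcodes", n_excluded, min_barcodes)
    return out


def process_experiment(
    table: CountTable,
    pool: pd.DataFrame,
    max_edit: int = 4,
    edge_frac: float = 0.05,
    r0_min: int = 80,
    min_barcodes: int = 4,
    merge_errors: bool = True,
) -> tuple[dict[str, GeneBarcodeSet], CountTable]:
    """Full cleanup chain: error-merge, map, floor, trim, filter.

    Returns (gene sets, intergenic CountTable).  ``merge_errors=False``
    skips the edit-distance pass, which is the identity on libraries with
    no sequencing errors and is quadratic in barcode count.
    """
    if merge_errors:
        table = merge_barcode_errors(table, max_edit=max_edit)
    gene_assignment, intergenic = map_and_trim(table, pool, edge_frac=edge_frac)
    genes = assemble_gene_sets(
        table, gene_assignment, min_barcodes=min_barcodes, r0_min=r0_min
    )
    return genes, intergenic
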