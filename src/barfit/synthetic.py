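"""Synthetic BarSeq experiment generator.

Emulates the generative process the inference pipeline assumes: lineage
frequencies follow a selection + genetic-drift diffusion,

    df/dt = s f + sqrt(f / N_e) eta(t),        f << 1,

observed through sqrt-scale Gaussian technical noise and discrete read
sampling.  Drift is applied once per transfer (variance 1/(4 N_e) on the
sqrt-frequency scale per transfer), with deterministic exponential growth
within a transfer — the same timebase the error model fits.  Technical
noise of variance zeta_t on the sqrt-frequency scale corresponds to a
count overdispersion c_t = 4 zeta_t R_t, with Poisson sampling (c = 1) as
the floor; the generator folds measurement noise and read sampling into a
single negative-binomial draw so that the variance decomposition

    var(phi_j - phi_k) = zeta_j + zeta_k + |j - k| / (4 N_e)

holds exactly by construction for neutral lineages.

Every lineage's ground truth (gene, fitness, outlier status, realized
initial frequency) is emitted alongside the count tables, so each
downstream stage can be verified without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, serial_dilution_timepoints

__all__ = [
    "SimConfig",
    "simulate_lineage_frequencies",
    "add_measurement_noise",
    "sample_read_counts",
    "build_experiment",
    "build_outlier_benchmark",
]

_BASES = np.array(list("ACGT"))


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct random DNA barcodes (random 20-mers are far apart in edit
    distance with overwhelming probability)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


@dataclass
class SimConfig:
    """Parameters of one synthetic BarSeq experiment.

    Defaults mirror the operating regime of a typical RB-TnSeq fitness
    assay on a serial 1:100 dilution: sequencing depth ~2e7 reads,
    initial lineage frequencies ~2e-5 (so ~400 reads at t0), effective
    population size 1e8 per transfer, sqrt-scale technical variance 2e-8
    per timepoint, observations at the end of each of 4 daily cycles
    (~6.64 generations each).
    """

    n_genes: int = 50
    barcodes_per_gene: int = 20
    n_intergenic: int = 10000
    s_values: np.ndarray | None = None  # per-gene fitness, 1/generation
    #: gene index -> (number of outlier barcodes, their secondary fitness)
    outlier_spec: dict = field(default_factory=dict)
    Ne: float = 1e8  # effective population size per transfer
    zeta: float | np.ndarray = 2e-8  # technical variance, sqrt-freq scale
    depths: float | np.ndarray = 2e7  # reads per timepoint R_t
    n_cycles: int = 4
    dilution: float = 100.0
    f0_scale: float = 2e-5  # typical initial genic-lineage frequency
    #: the intergenic neutral class sits at lower abundance, as in real
    #: libraries where genic barcodes must clear the r0 floor while the
    #: many intergenic insertions need only populate the 50 < r < 500
    #: error-calibration window
    f0_scale_intergenic: float = 5e-6
    f0_spread: float = 3.0  # log-uniform f0 in [scale/spread, scale*spread]
    n_replicates: int = 1
    barcode_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_values is None:
            self.s_values = np.zeros(self.n_genes)
        self.s_values = np.asarray(self.s_values, float)
        if len(self.s_values) != self.n_genes:
            raise ValueError("s_values must have one entry per gene")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if np.any(np.asarray(self.zeta) < 0):
            raise ValueError("zeta must be nonnegative")
        if np.any(np.asarray(self.depths) <= 0):
            raise ValueError("depths must be positive")
        n_genic = self.n_genes * self.barcodes_per_gene
        if self.f0_scale * n_genic + self.f0_scale_intergenic * self.n_intergenic > 1:
            raise ValueError("total initial library frequency budget exceeds 1")

    @property
    def n_lineages(self) -> int:
        return self.n_genes * self.barcodes_per_gene + self.n_intergenic

    def timepoints(self) -> pd.DataFrame:
        return serial_dilution_timepoints(
            self.n_cycles, self.dilution, total_reads=self.depths
        )


def simulate_lineage_frequencies(
    s: float,
    f0: float,
    Ne: float,
    generations: np.ndarray,
    transfer_index: np.ndarray,
    mean_fitness: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one lineage's frequency trajectory at the observation times.

    The trajectory starts at ``f0`` at the first timepoint.  Between
    observations the expectation follows f0 * exp((s - xbar_t) t); drift
    adds Gaussian variance Delta_transfers/(4 Ne) on the sqrt-frequency
    scale.  Zero is absorbing.

    Parameters
    ----------
    mean_fitness:
        Cumulative population mean fitness xbar_t (1/generation) at each
        observation, entering through the exponent (s - xbar_t) t.  None
        means a static population (xbar = 0).
    Ne:
        Effective population size per transfer; ``np.inf`` switches
        drift off.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie strictly between 0 and 1")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    gens = np.asarray(generations, float)
    trans = np.asarray(transfer_index, int)
    if mean_fitness is None:
        mean_fitness = np.zeros_like(gens)
    xbar = np.asarray(mean_fitness, float)
    if rng is None:
        rng = np.random.default_rng()

    # log of the systematic growth factor between consecutive observations
    log_mu = (s * gens - xbar * gens)
    traj = np.empty_like(gens)
    traj[0] = f0
    drift_sd = 0.0 if math.isinf(Ne) else 1.0
    for k in range(1, len(gens)):
        f_prev = traj[k - 1]
        if f_prev == 0.0:
            traj[k] = 0.0
            continue
        f_det = f_prev * math.exp(log_mu[k] - log_mu[k - 1])
        n_transfers = trans[k] - trans[k - 1]
        if drift_sd == 0.0 or n_transfers == 0:
            traj[k] = f_det
        else:
            var = n_transfers / (4.0 * Ne)
            phi = math.sqrt(f_det) + rng.normal(0.0, math.sqrt(var))
            # subtract the kick variance so the frequency stays a
            # martingale (E[(phi+eps)^2] = phi^2 + var would otherwise
            # inflate the mean by var per transfer)
            traj[k] = max(phi * phi - var, 0.0)
    return traj


def add_measurement_noise(
    f: np.ndarray, zeta: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Observe sqrt-frequencies through Gaussian technical noise.

    phi_obs | f ~ N(sqrt(f), zeta) with ``zeta`` a *variance* on the
    sqrt-frequency scale (so that zeta terms add with the drift variance
    in the error model); negative draws are truncated to 0.
    """
    if zeta < 0:
        raise ValueError("zeta must be nonnegative")
    f = np.asarray(f, float)
    phi = np.sqrt(f)
    if zeta == 0:
        return phi
    if rng is None:
        rng = np.random.default_rng()
    return np.maximum(phi + rng.normal(0.0, math.sqrt(zeta), size=phi.shape), 0.0)


def sample_read_counts(
    freqs: np.ndarray,
    R: float,
    c: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw integer read counts with mean R*f and variance c*R*f.

    ``c = 1`` is Poisson sampling; ``c > 1`` uses a negative binomial
    with the same mean-variance relation.  Zero frequency always yields
    zero counts.
    """
    if c < 1:
        raise ValueError("count variance parameter c must be >= 1")
    if R <= 0:
        raise ValueError("depth R must be positive")
    freqs = np.asarray(freqs, float)
    if rng is None:
        rng = np.random.default_rng()
    mu = R * freqs
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if c <= 1 + 1e-9:
        out[pos] = rng.poisson(mu[pos])
    else:
        # NB(n, p) with n = mu/(c-1), p = 1/c has mean mu, variance c*mu
        n = mu[pos] / (c - 1.0)
        out[pos] = rng.negative_binomial(n, 1.0 / c)
    return out


def _draw_f0(
    n: int, scale: float, spread: float, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = math.log(scale / spread), math.log(scale * spread)
    return np.exp(rng.uniform(lo, hi, size=n))


def _truth_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign lineages to genes/intergenic, fitness values and f0."""
    records = []
    barcodes = _random_barcodes(cfg.n_lineages, cfg.barcode_length, rng)
    i = 0
    for g in range(cfg.n_genes):
        n_out, s_out = cfg.outlier_spec.get(g, (0, 0.0))
        if n_out > cfg.barcodes_per_gene:
            raise ValueError("more outliers than barcodes in gene")
        for b in range(cfg.barcodes_per_gene):
            is_out = b < n_out
            records.append(
                {
                    "barcode": barcodes[i],
                    "gene": f"g{g:04d}",
                    "s_true": s_out if is_out else cfg.s_values[g],
                    "outlier": is_out,
                    "intergenic": False,
                }
            )
            i += 1
    for _ in range(cfg.n_intergenic):
        records.append(
            {
                "barcode": barcodes[i],
                "gene": "",
                "s_true": 0.0,
                "outlier": False,
                "intergenic": True,
            }
        )
        i += 1
    truth = pd.DataFrame.from_records(records)
    inter = truth["intergenic"].to_numpy()
    f0 = np.where(
        inter,
        _draw_f0(len(truth), cfg.f0_scale_intergenic, cfg.f0_spread, rng),
        _draw_f0(len(truth), cfg.f0_scale, cfg.f0_spread, rng),
    )
    truth["f0"] = f0
    if truth["f0"].sum() > 1:
        raise ValueError("total initial library frequency exceeds 1")
    return truth


def _mean_fitness_series(truth: pd.DataFrame, gens: np.ndarray) -> np.ndarray:
    """Deterministic population mean fitness xbar_t implied by the truth.

    xbar_t * t = log( sum_i f0_i e^{s_i t} / sum_i f0_i ), the log of the
    population-wide growth factor relative to neutrality.
    """
    f0 = truth["f0"].to_numpy()
    s = truth["s_true"].to_numpy()
    xbar = np.zeros_like(gens)
    for k, t in enumerate(gens):
        if t > 0:
            xbar[k] = math.log(np.sum(f0 * np.exp(s * t)) / f0.sum()) / t
    return xbar


def pool_table(truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Build an insertion-pool table consistent with a truth table.

    Positions are arbitrary; gene insertions land at fractional position
    0.5 so that no synthetic barcode is lost to the edge filter.
    """
    n = len(truth)
    pool = pd.DataFrame(
        {
            "barcode": truth["barcode"].to_numpy(),
            "position": rng.permutation(n) * 997 + 1,
            "gene": truth["gene"].to_numpy(),
            "frac_within_gene": np.where(truth["intergenic"], np.nan, 0.5),
            "intergenic": truth["intergenic"].to_numpy().astype(int),
        }
    )
    pool["gc_content"] = [
        (bc.count("G") + bc.count("C")) / len(bc) for bc in pool["barcode"]
    ]
    return pool


def build_experiment(cfg: SimConfig):
    """Generate a full synthetic experiment.

    Returns
    -------
    tables : list[CountTable]
        One count table per replicate.  Replicates share lineage
        identities and initial frequencies but have independent drift,
        noise and sampling realizations (including at t=0: replicate
        cultures are sequenced separately).
    truth : pandas.DataFrame
        Columns barcode, gene, s_true, outlier, intergenic, f0.
    pool : pandas.DataFrame
        Matching insertion-pool table.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_truth, ss_pool, *ss_reps = root.spawn(2 + cfg.n_replicates)
    rng_truth = np.random.default_rng(ss_truth)
    truth = _truth_table(cfg, rng_truth)
    pool = pool_table(truth, np.random.default_rng(ss_pool))

    meta = cfg.timepoints()
    gens = meta["generations"].to_numpy(float)
    trans = meta["transfer_index"].to_numpy(int)
    R = meta["total_reads"].to_numpy(float)
    zeta = np.broadcast_to(np.asarray(cfg.zeta, float), gens.shape)
    # fold technical noise + read sampling into one NB draw per timepoint
    c_t = np.maximum(4.0 * zeta * R, 1.0)
    xbar = _mean_fitness_series(truth, gens)

    tables = []
    for ss_rep in ss_reps:
        rng = np.random.default_rng(ss_rep)
        freqs = np.empty((len(truth), len(gens)))
        for i, row in enumerate(truth.itertuples()):
            freqs[i] = simulate_lineage_frequencies(
                row.s_true, row.f0, cfg.Ne, gens, trans, xbar, rng
            )
        counts = np.empty_like(freqs, dtype=np.int64)
        for k in range(len(gens)):
            counts[:, k] = sample_read_counts(freqs[:, k], R[k], c_t[k], rng)
        df = pd.DataFrame(
            counts, index=pd.Index(truth["barcode"], name="barcode"),
            columns=meta["timepoint"],
        )
        tables.append(CountTable(df, meta.copy()))
    return tables, truth, pool


def build_outlier_benchmark(
    seed: int = 0,
    n_genes: int = 500,
    lineages_per_gene: int = 20,
    n_outliers: tuple[int, ...] = (1, 2, 3),
    s_outlier: float = 0.02,
    Ne: float = 1e8,
    zeta: float = 2e-8,
    n_days: int = 4,
    depth: float = 2e7,
    f0_scale: float = 2e-5,
    f0_spread: float = 3.0,
):
    """Benchmark for the outlier detector's operating characteristics.

    Genes of ``lineages_per_gene`` neutral lineages carry n in
    ``n_outliers`` planted lineages with secondary fitness +/-
    ``s_outlier`` per generation (one sign per gene, alternating across
    genes; n cycles across genes).  Trajectories diffuse with effective
    population size ``Ne`` per day and are observed at t=0 and at the
    end of each of ``n_days`` days (~6.64 generations per day) through
    sqrt-scale Gaussian noise of variance ``zeta``, then converted to
    integer counts at depth ``depth`` by deterministic rounding — the
    rounding contributes negligible variance, so the count-level
    overdispersion seen by the likelihood is c_t = (4 zeta + 1/Ne) R_t.

    Returns ``(table, truth)``: a CountTable over all lineages and a
    truth table (barcode, gene, s_true, outlier, f0).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    meta = serial_dilution_timepoints(n_days, 100.0, total_reads=int(depth))
    gens = meta["generations"].to_numpy(float)
    trans = meta["transfer_index"].to_numpy(int)

    records = []
    all_counts = []
    lo, hi = math.log(f0_scale / f0_spread), math.log(f0_scale * f0_spread)
    for g in range(n_genes):
        n_out = n_outliers[g % len(n_outliers)]
        sign = 1.0 if (g // len(n_outliers)) % 2 == 0 else -1.0
        for b in range(lineages_per_gene):
            is_out = b < n_out
            s = sign * s_outlier if is_out else 0.0
            f0 = math.exp(rng.uniform(lo, hi))
            f = simulate_lineage_frequencies(s, f0, Ne, gens, trans, None, rng)
            phi_obs = add_measurement_noise(f, zeta, rng)
            counts = np.rint(depth * phi_obs**2).astype(np.int64)
            records.append(
                {
                    "barcode": f"g{g:04d}_b{b:02d}",
                    "gene": f"g{g:04d}",
                    "s_true": s,
                    "outlier": is_out,
                    "f0": f0,
                }
            )
            all_counts.append(counts)
    truth = pd.DataFrame.from_records(records)
    df = pd.DataFrame(
        np.vstack(all_counts),
        index=pd.Index(truth["barcode"], name="barcode"),
        columns=meta["timepoint"],
    )
    return CountTable(df, meta), truth


def planted_fitness_matrix(
    n_blocks: int = 4,
    genes_per_block: int = 8,
    n_envs: int = 10,
    effect_scale: float = 0.03,
    se: float = 0.003,
    n_neutral: int = 0,
    seed: int = 0,
):
    """Synthetic gene x environment fitness tables with planted structure.

    Genes within a block share a latent environment-response profile
    (drawn N(0, effect_scale^2) per environment) observed through
    independent Gaussian measurement noise of standard deviation ``se``;
    ``n_neutral`` additional genes have zero true effect everywhere.
    Returns (tables, block_assignment): per-environment DataFrames in the
    fitness-table layout (s_hat, se, p, q, n_barcodes, significant) and
    the true block label per gene (-1 for neutral fillers).

    Used to verify that the cofitness network machinery recovers known
    correlation structure; not a model of any particular dataset.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.normal(0.0, effect_scale, size=(n_blocks, n_envs))
    genes, blocks, s_rows = [], {}, []
    for b in range(n_blocks):
        for g in range(genes_per_block):
            name = f"blk{b}_g{g}"
            genes.append(name)
            blocks[name] = b
            s_rows.append(profiles[b] + rng.normal(0.0, se, size=n_envs))
    for g in range(n_neutral):
        name = f"neutral_g{g}"
        genes.append(name)
        blocks[name] = -1
        s_rows.append(rng.normal(0.0, se, size=n_envs))
    S = np.asarray(s_rows)
    tables = {}
    for k in range(n_envs):
        z = np.abs(S[:, k]) / se
        # crude but monotone neutrality p-value; block genes are far from
        # 0 in most environments, fillers are not
        p = np.clip(2.0 * (1.0 - 0.5 * (1 + np.vectorize(math.erf)(z / math.sqrt(2)))), 1e-300, 1.0)
        tables[f"env{k:02d}"] = pd.DataFrame(
            {
                "s_hat": S[:, k],
                "se": se,
                "p": p,
                "q": p,
                "n_barcodes": 10,
                "significant": p < 0.05,
            },
            index=pd.Index(genes, name="gene"),
        )
    return tables, pd.Series(blocks)
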