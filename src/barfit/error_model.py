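"""Calibration of technical noise and genetic drift from neutral barcodes.

Barcode read counts carry two noise sources: technical noise from library
prep/sequencing (variance ``zeta_t`` per timepoint on the sqrt-frequency
scale, uncorrelated in time) and genetic drift (variance accumulating as
``|j - k| / (4 N_e)`` per transfer on the same scale).  On the
variance-stabilized scale phi = sqrt(f), the variance of neutral-barcode
increments between two timepoints decomposes additively:

    kappa_{j,k} = var(phi_j - phi_k) = zeta_j + zeta_k + |j - k| / (4 N_e)

kappa is estimated robustly (MAD, rescaled to a Gaussian-consistent
variance) from intergenic barcodes with intermediate counts, and the
decomposition is fit by weighted least squares under the physical
constraint zeta_t >= 1/(4 R_t) (technical noise cannot undercut read
sampling).  The count-level overdispersion used by the likelihood follows
as c_t = (4 zeta_t + 1/N_e) R_t.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .containers import CountTable

__all__ = [
    "MAD_TO_SD",
    "NoiseModel",
    "vst",
    "estimate_kappa",
    "kappa_matrix",
    "decompose_noise",
    "stratified_kappa",
    "fit_noise_model",
]

#: Phi^-1(3/4): MAD of a Gaussian equals MAD_TO_SD times its SD
MAD_TO_SD = 0.67449


def vst(f):
    """Variance-stabilizing transformation phi = sqrt(f) for count-derived
    frequencies (variance proportional to mean becomes constant)."""
    f = np.asarray(f, float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    return np.sqrt(f)


def _mad_variance(psi: np.ndarray) -> float:
    med = np.median(psi)
    mad = np.median(np.abs(psi - med))
    return (mad / MAD_TO_SD) ** 2


def estimate_kappa(
    neutral: CountTable,
    j: int,
    k: int,
    rmin: int = 50,
    rmax: int = 500,
    n_boot: int = 500,
    min_barcodes: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Robust variance of neutral sqrt-frequency increments between
    timepoints ``j`` and ``k`` (positional indices).

    Only barcodes with ``rmin < r < rmax`` at *both* timepoints enter
    (enough counts for the CLT, low enough frequency that secondary
    selection is unlikely).  The estimate is the squared rescaled MAD of
    psi_i = phi_{i,j} - phi_{i,k}; its variance comes from a barcode
    bootstrap.

    Returns (kappa_hat, var_kappa_hat).
    """
    if j == k:
        return 0.0, 0.0
    r = neutral.counts.to_numpy(float)
    R = neutral.total_reads
    ok = (
        (r[:, j] > rmin) & (r[:, j] < rmax) & (r[:, k] > rmin) & (r[:, k] < rmax)
    )
    n = int(ok.sum())
    if n < min_barcodes:
        raise ValueError(
            f"only {n} neutral barcodes with {rmin}<r<{rmax} at timepoints "
            f"{j},{k}; need >={min_barcodes} for a reliable kappa"
        )
    psi = np.sqrt(r[ok, j] / R[j]) - np.sqrt(r[ok, k] / R[k])
    kappa = _mad_variance(psi)
    if rng is None:
        rng = np.random.default_rng()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _mad_variance(psi[rng.integers(0, n, size=n)])
    return kappa, float(np.var(boots, ddof=1))


def kappa_matrix(
    neutral: CountTable,
    rmin: int = 50,
    rmax: int = 500,
    n_boot: int = 500,
    min_barcodes: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kappa_hat and its bootstrap variance for every timepoint pair."""
    T = len(neutral.meta)
    labels = list(neutral.meta["timepoint"])
    K = np.zeros((T, T))
    V = np.zeros((T, T))
    for j in range(T):
        for k in range(j + 1, T):
            K[j, k], V[j, k] = estimate_kappa(
                neutral, j, k, rmin, rmax, n_boot, min_barcodes, rng
            )
            K[k, j], V[k, j] = K[j, k], V[j, k]
    return (
        pd.DataFrame(K, index=labels, columns=labels),
        pd.DataFrame(V, index=labels, columns=labels),
    )


@dataclass
class NoiseModel:
    """Fitted per-timepoint noise parameters.

    zeta: technical variance per timepoint (sqrt-frequency scale).
    Ne: effective population size per transfer.
    c: count overdispersion per timepoint, c_t = (4 zeta_t + 1/Ne) R_t.
    """

    zeta: np.ndarray
    Ne: float
    R: np.ndarray
    transfer_index: np.ndarray
    kappa: pd.DataFrame | None = None
    kappa_var: pd.DataFrame | None = None
    boundary_active: bool = False

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, float)
        self.R = np.asarray(self.R, float)
        self.transfer_index = np.asarray(self.transfer_index, int)
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if np.any(self.zeta < 1.0 / (4.0 * self.R) - 1e-15):
            raise ValueError("zeta_t must be at least the sampling floor 1/(4 R_t)")

    @property
    def c(self) -> np.ndarray:
        return (4.0 * self.zeta + 1.0 / self.Ne) * self.R

    @classmethod
    def from_parameters(cls, zeta, Ne, R, transfer_index=None) -> "NoiseModel":
        R = np.asarray(R, float)
        zeta = np.broadcast_to(np.asarray(zeta, float), R.shape).copy()
        if transfer_index is None:
            transfer_index = np.arange(len(R))
        return cls(zeta, Ne, R, transfer_index)

    def predicted_kappa(self) -> pd.DataFrame:
        t = self.transfer_index
        z = self.zeta
        K = z[:, None] + z[None, :] + np.abs(t[:, None] - t[None, :]) / (4 * self.Ne)
        np.fill_diagonal(K, 0.0)
        labels = self.kappa.index if self.kappa is not None else range(len(z))
        return pd.DataFrame(K, index=labels, columns=labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transfer_index": self.transfer_index,
                "R": self.R,
                "zeta": self.zeta,
                "c": self.c,
                "Ne": self.Ne,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "NoiseModel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["zeta"].to_numpy(),
            float(df["Ne"].iloc[0]),
            df["R"].to_numpy(),
            df["transfer_index"].to_numpy(),
        )


def decompose_noise(
    kappa: pd.DataFrame,
    kappa_var: pd.DataFrame,
    R: np.ndarray,
    transfer_index: np.ndarray,
) -> NoiseModel:
    """Split the kappa matrix into technical noise and drift.

    Minimizes the inverse-variance-weighted squared residuals of the
    additive decomposition over (zeta_1..zeta_T, 1/Ne), box-constrained
    to zeta_t >= 1/(4 R_t) and 1/Ne >= 0.  Zero-variance entries (an
    exactly specified kappa) get unit weights.
    """
    K = kappa.to_numpy(float)
    V = kappa_var.to_numpy(float)
    R = np.asarray(R, float)
    trans = np.asarray(transfer_index, int)
    T = len(R)
    pairs = [(j, k) for j in range(T) for k in range(j + 1, T)]
    kvals = np.array([K[j, k] for j, k in pairs])
    w = np.array([V[j, k] for j, k in pairs])
    w = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 1.0)
    dt = np.array([abs(trans[k] - trans[j]) for j, k in pairs], float)
    A = np.zeros((len(pairs), T + 1))
    for m, (j, k) in enumerate(pairs):
        A[m, j] = 1.0
        A[m, k] = 1.0
        A[m, T] = dt[m] / 4.0
    floor = 1.0 / (4.0 * R)

    # bounded weighted linear least squares; the problem is normalized to
    # O(1) (kappa values are ~1e-8, weights ~1e18) so the solver's
    # tolerances behave
    scale = max(np.abs(kvals).max(), np.abs(floor).max(), 1e-300)
    sw = np.sqrt(w * scale**2 / np.mean(w * scale**2))
    res = lsq_linear(
        A * sw[:, None],
        (kvals / scale) * sw,
        bounds=(np.concatenate([floor, [0.0]]) / scale, np.inf),
        tol=1e-14,
    )
    if not res.success:
        raise RuntimeError("noise decomposition did not converge")
    theta = res.x * scale
    zeta = np.maximum(theta[:T], floor)
    inv_ne = max(theta[T], 0.0)
    Ne = 1.0 / inv_ne if inv_ne > 0 else np.inf
    if np.isinf(Ne):  # drift indistinguishable from zero; keep c finite
        Ne = 1e300
    model = NoiseModel(
        zeta,
        Ne,
        R,
        trans,
        kappa=kappa,
        kappa_var=kappa_var,
        boundary_active=bool(np.all(zeta <= floor * (1 + 1e-9))),
    )
    return model


def stratified_kappa(
    neutral: CountTable,
    grouping: pd.Series,
    rmin: int = 50,
    rmax: int = 500,
    n_boot: int = 500,
    min_barcodes: int = 100,
    rng: np.random.Generator | None = None,
) -> dict:
    """kappa matrices per barcode stratum (e.g. GC-content or position
    bins) — a diagnostic for frequency biases, which would show up as
    strata with inconsistent apparent drift/noise.

    ``grouping`` maps barcode -> stratum label over all neutral barcodes.
    Strata where any pair lacks ``min_barcodes`` eligible barcodes are
    reported as None (missing).
    """
    out = {}
    for label, bcs in grouping.groupby(grouping):
        sub = neutral.subset(bcs.index)
        try:
            out[label] = kappa_matrix(sub, rmin, rmax, n_boot, min_barcodes, rng)
        except ValueError:
            out[label] = None
    return out


def fit_noise_model(
    neutral: CountTable,
    rmin: int = 50,
    rmax: int = 500,
    n_boot: int = 500,
    min_barcodes: int = 100,
    rng: np.random.Generator | None = None,
) -> NoiseModel:
    """Convenience: kappa matrix + decomposition in one call."""
    K, V = kappa_matrix(neutral, rmin, rmax, n_boot, min_barcodes, rng)
    return decompose_noise(K, V, neutral.total_reads, neutral.transfer_index)
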