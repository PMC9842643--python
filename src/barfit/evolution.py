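"""Relating knockout fitness effects to evolutionary outcomes.

Genes are classified from one environment's fitness column into
putatively neutral (|s| below a small band *and* not significantly
non-neutral), significantly beneficial, or significantly deleterious;
everything else is excluded.  Fitness is normalized by the median of the
modeled non-neutral class, so regression slopes read as the change in
outcome between a neutral knockout and the "typical" beneficial (or
deleterious) knockout.  Outcomes supported: mutation establishment
(logistic model, with a permutation test for slope differences between
time intervals) and expression change (weighted least squares), plus
rank-based comparisons of expression change between fitness classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

from .inference import fdr_correct

__all__ = [
    "classify_and_normalize",
    "establishment_logit",
    "slope_permutation_test",
    "expression_wls",
    "rank_compare",
    "RegressionResult",
]

NEUTRAL, BENEFICIAL, DELETERIOUS, EXCLUDED = (
    "neutral",
    "beneficial",
    "deleterious",
    "excluded",
)


def classify_fitness(
    s: pd.Series, significant: pd.Series, neutral_band: float = 0.005
) -> pd.Series:
    """Assign genes to fitness classes.

    Neutral requires *both* |s| < ``neutral_band`` and no significance
    call; significant genes split by sign; the remainder (small-but-
    uncalled effects outside the band) are excluded from the models.
    """
    out = pd.Series(EXCLUDED, index=s.index)
    out[(s.abs() < neutral_band) & ~significant] = NEUTRAL
    out[significant & (s > 0)] = BENEFICIAL
    out[significant & (s < 0)] = DELETERIOUS
    return out


def classify_and_normalize(
    s: pd.Series,
    significant: pd.Series,
    target_class: str,
    neutral_band: float = 0.005,
) -> tuple[pd.Series, pd.Series]:
    """Classes plus normalized fitness s~ for one model.

    s~_i = s_i / median(s over the ``target_class``), computed for the
    target-class genes and the neutral genes entering that model
    (neutral genes keep their small normalized values).  Raises when the
    target class is empty (normalization undefined; model skipped).
    """
    classes = classify_fitness(s, significant, neutral_band)
    members = classes == target_class
    if members.sum() == 0:
        raise ValueError(f"no genes in class {target_class!r}")
    med = float(s[members].median())
    keep = members | (classes == NEUTRAL)
    return classes, (s[keep] / med)


@dataclass
class RegressionResult:
    """One fitted outcome model (per fitness class)."""

    target_class: str
    beta: float
    beta_se: float
    beta_p: float
    intercept: float
    n_class: int
    n_neutral: int
    beta_q: float = np.nan
    flags: tuple = ()
    model: object = field(default=None, repr=False)


def _logit_fit(y: np.ndarray, x: np.ndarray):
    X = sm.add_constant(x)
    flags: list[str] = []
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or not np.all(
            np.isfinite(res.bse)
        ):
            raise ValueError("logit did not converge")
    except Exception:
        # complete/quasi-separation: small-ridge fallback, Wald errors
        # from the penalized Hessian; flagged so callers can discount it
        flags.append("separation")
        res = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=1e-4, disp=0, trim_mode="off"
        )
    return res, flags


def establishment_logit(
    s: pd.Series,
    significant: pd.Series,
    mutated: pd.Series,
    neutral_band: float = 0.005,
    pooled_fdr: bool = True,
) -> list[RegressionResult]:
    """Logistic models of mutation establishment versus fitness.

    Fits log p/(1-p) = s~ beta + beta0 separately for the beneficial and
    deleterious classes, each pooled with the neutral class.  Classes
    with no members, or with a constant response, are skipped.  The
    slope p-values are BH-corrected, pooled over the fitted classes.
    """
    results: list[RegressionResult] = []
    for target in (BENEFICIAL, DELETERIOUS):
        try:
            classes, s_tilde = classify_and_normalize(
                s, significant, target, neutral_band
            )
        except ValueError:
            continue
        y = mutated.loc[s_tilde.index].astype(float).to_numpy()
        if len(np.unique(y)) < 2:
            results.append(
                RegressionResult(
                    target, np.nan, np.nan, np.nan, np.nan,
                    int((classes == target).sum()),
                    int((classes == NEUTRAL).sum()),
                    flags=("degenerate-response",),
                )
            )
            continue
        res, flags = _logit_fit(y, s_tilde.to_numpy())
        results.append(
            RegressionResult(
                target,
                float(res.params[1]),
                float(res.bse[1]) if np.all(np.isfinite(res.bse)) else np.nan,
                float(res.pvalues[1]) if np.all(np.isfinite(res.bse)) else np.nan,
                float(res.params[0]),
                int((classes == target).sum()),
                int((classes == NEUTRAL).sum()),
                flags=tuple(flags),
                model=res,
            )
        )
    if pooled_fdr:
        _pool_fdr(results)
    return results


def _pool_fdr(results: list[RegressionResult]) -> None:
    ok = [r for r in results if np.isfinite(r.beta_p)]
    if ok:
        q, _ = fdr_correct([r.beta_p for r in ok])
        for r, qv in zip(ok, q):
            r.beta_q = float(qv)


def expression_wls(
    s: pd.Series,
    significant: pd.Series,
    delta_e: pd.Series,
    var_delta_e: pd.Series,
    neutral_band: float = 0.005,
    pooled_fdr: bool = True,
) -> list[RegressionResult]:
    """Weighted-least-squares models of expression change versus fitness.

    Delta E_i = s~_i beta + beta0 + eps, weights proportional to
    1/var(Delta E_i); fitted separately for beneficial and deleterious
    classes pooled with neutrals, with BH correction pooled over slopes.
    """
    if np.any(var_delta_e.dropna() <= 0):
        raise ValueError("expression-change variances must be positive")
    results: list[RegressionResult] = []
    for target in (BENEFICIAL, DELETERIOUS):
        try:
            classes, s_tilde = classify_and_normalize(
                s, significant, target, neutral_band
            )
        except ValueError:
            continue
        idx = s_tilde.index.intersection(delta_e.dropna().index)
        if len(idx) < 3:
            continue
        X = sm.add_constant(s_tilde.loc[idx].to_numpy())
        res = sm.WLS(
            delta_e.loc[idx].to_numpy(),
            X,
            weights=1.0 / var_delta_e.loc[idx].to_numpy(),
        ).fit()
        results.append(
            RegressionResult(
                target,
                float(res.params[1]),
                float(res.bse[1]),
                float(res.pvalues[1]),
                float(res.params[0]),
                int((classes == target).sum()),
                int((classes == NEUTRAL).sum()),
                model=res,
            )
        )
    if pooled_fdr:
        _pool_fdr(results)
    return results


def slope_permutation_test(
    s: pd.Series,
    significant: pd.Series,
    mutated_a: pd.Series,
    mutated_b: pd.Series,
    target_class: str = BENEFICIAL,
    neutral_band: float = 0.005,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test for a slope difference between two time intervals.

    The null shuffles, independently per gene, which interval its
    establishment flag belongs to, and refits both logistic models
    ``n_perm`` times; p is the plus-one-corrected two-sided tail
    probability of the observed slope difference.

    Returns (observed difference beta_a - beta_b, p).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    _, s_tilde = classify_and_normalize(s, significant, target_class, neutral_band)
    idx = s_tilde.index
    x = s_tilde.to_numpy()
    ya = mutated_a.loc[idx].astype(float).to_numpy()
    yb = mutated_b.loc[idx].astype(float).to_numpy()

    def slope_diff(a, b) -> float:
        ra, _ = _logit_fit(a, x)
        rb, _ = _logit_fit(b, x)
        return float(ra.params[1] - rb.params[1])

    obs = slope_diff(ya, yb)
    if rng is None:
        rng = np.random.default_rng()
    exceed = 0
    for _ in range(n_perm):
        swap = rng.random(len(idx)) < 0.5
        pa = np.where(swap, yb, ya)
        pb = np.where(swap, ya, yb)
        if abs(slope_diff(pa, pb)) >= abs(obs):
            exceed += 1
    return obs, (exceed + 1) / (n_perm + 1)


def rank_compare(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests between outcome distributions.

    ``groups`` maps class label -> array of outcome values (e.g.
    expression log-fold changes per fitness class).  Groups with fewer
    than 2 members are skipped; p-values are BH-corrected across pairs.
    """
    labels = [k for k, v in groups.items() if len(v) >= 2]
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            stat, p = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "U": stat, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"], df["significant"] = fdr_correct(df["p"])
    return df


def split_by_median(s: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split genes at the median fitness into lower/upper halves
    (sizes differing by at most one)."""
    order = s.sort_values(kind="stable").index
    half = len(order) // 2
    return order[:half], order[half:]


def mutated_status(
    clone_mutations: pd.DataFrame,
    genes: pd.Index | list,
    clones: list[str] | None = None,
    exclude_synonymous: bool = True,
    preexisting: set | None = None,
) -> pd.Series:
    """Gene-level mutated flags from a clone mutation table.

    ``clone_mutations`` has one row per observed mutation with columns
    ``gene``, ``clone`` and ``mutation_type``.  A gene is flagged mutated
    when any retained mutation hits it: restricted to ``clones`` (e.g.
    the clones of one sublineage) when given, excluding synonymous SNPs
    (type ``"synonymous"``) by default, and excluding genes in
    ``preexisting`` (mutations already present in the assayed clone's
    ancestor).  Returns a 0/1 Series over ``genes``.
    """
    df = clone_mutations
    if clones is not None:
        df = df[df["clone"].isin(clones)]
    if exclude_synonymous and "mutation_type" in df.columns:
        df = df[df["mutation_type"] != "synonymous"]
    hit = set(df["gene"]) - (preexisting or set())
    return pd.Series([int(g in hit) for g in genes], index=pd.Index(genes))
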