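"""Reactant identification by multinomial logistic regression on jump events.

For a mass-action jump process observed at reaction events, the embedded
chain's conditional law over stoichiometric categories,
P(Y = k | X) = a_k(X) / sum_j a_j(X), is *exactly* of multinomial-logit form
in log molecular counts whenever reactant multiplicities are 0/1: taking a
constant-rate (pure-birth) reaction r as the reference,

    log P(Y=k|X) / P(Y=r|X) = log(kappa_k / kappa_r) + sum_i nu_ik log X_i.

Fitting the multinomial logit to (pre-jump state, jump category) pairs
therefore recovers the reactant sets — including catalysts, which are
invisible to stoichiometry — as the significantly positive slopes, and rate
ratios kappa_k / kappa_r as exponentiated intercepts.

The fitter is a weighted Newton solver on the aggregated multinomial
likelihood with a tiny ridge on the slopes (default 1e-6) so that
quasi-separated categories (a category that only ever fires at positive
counts of some species) remain numerically benign.  Events sharing a
pre-jump state are aggregated into category counts first, which makes the
fit cheap even on multi-million-event datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr
from scipy.stats import norm

from .ssa_sim import EventDataset

__all__ = [
    "ReactionCategory",
    "DesignMatrix",
    "CoefTable",
    "ReactantCallMatrix",
    "infer_categories",
    "category_label",
    "build_design",
    "fit_multinomial",
    "call_reactants",
    "recover_orders",
    "rate_ratios",
    "z_threshold",
    "identify",
]

DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_ZERO_FLOOR = 0.0
DEFAULT_RIDGE = 1e-6


def z_threshold(p: float = DEFAULT_P_THRESHOLD) -> float:
    """Z-score cutoff for a one-sided upper-tail test at level ``p``.

    At the default p = 0.001 this is 3.09 (to two decimals).
    """
    return float(norm.isf(p))


@dataclass(frozen=True)
class ReactionCategory:
    """A stoichiometric category: one distinct observed jump vector."""

    jump: tuple[int, ...]
    label: str
    index: int


def category_label(jump: Sequence[int], species: Sequence[str]) -> str:
    """Canonical label for a jump vector, e.g. (+1, -1) -> '+A1-A2'."""
    parts = []
    for d, sp in zip(jump, species):
        if d == 0:
            continue
        sign = "+" if d > 0 else "-"
        mult = "" if abs(d) == 1 else str(abs(d))
        parts.append(f"{sign}{mult}{sp}")
    return "".join(parts) if parts else "0"


def infer_categories(ds: EventDataset) -> list[ReactionCategory]:
    """One category per distinct observed jump vector, in lexicographic order.

    Reactions that never fired are absent by construction; reactions sharing
    a jump vector are merged into a single category.
    """
    if ds.n_events == 0:
        raise ValueError("empty event dataset")
    uniq = np.unique(ds.jumps, axis=0)  # lexicographic row order
    return [
        ReactionCategory(jump=tuple(int(v) for v in row),
                         label=category_label(row, ds.species), index=i)
        for i, row in enumerate(uniq)
    ]


@dataclass
class DesignMatrix:
    """Transformed pre-jump covariates plus the event's category response.

    ``Z`` has one row per event (covariates z(X_1)..z(X_s)); ``y`` holds the
    category index of each event's jump; ``categories`` fixes the index
    order.  Under the log transform, z(x) = log x for x >= 1 and
    z(0) = ``zero_floor``.

    The default floor is 0, i.e. z = log max(x, 1), which keeps zero-count
    states inside the hull of the observed covariates.  Deeply negative
    floors make zero-count states linearly separable from positive-count
    states, which quasi-separates any category that only fires while some
    species is present — exactly the situation in strongly intermittent
    regimes — and inflates its standard errors until nothing is called.
    """

    Z: np.ndarray
    y: np.ndarray
    categories: list[ReactionCategory]
    species: list[str]
    transform: str
    zero_floor: float


def build_design(
    ds: EventDataset,
    transform: str = "log",
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> DesignMatrix:
    """Build the regression design from pooled jump events.

    Covariates are computed from PRE-jump counts only.  ``transform`` is
    ``"log"`` (canonical; makes the embedded-chain likelihood exactly
    multinomial-logit for 0/1 reactant multiplicities) or ``"identity"``.
    """
    if transform not in ("log", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    categories = infer_categories(ds)
    lookup = {cat.jump: cat.index for cat in categories}
    y = np.array([lookup[tuple(int(v) for v in row)] for row in ds.jumps], dtype=np.int64)
    X = ds.pre_states.astype(np.float64)
    if transform == "log":
        Z = np.where(X >= 1, np.log(np.maximum(X, 1.0)), zero_floor)
    else:
        Z = X
    return DesignMatrix(Z=Z, y=y, categories=categories, species=list(ds.species),
                        transform=transform, zero_floor=zero_floor)


@dataclass
class CoefTable:
    """Fitted multinomial-logit coefficients with one-sided inference.

    ``table`` is tidy: one row per (non-reference category, term) with
    columns ``category``, ``species`` ("(intercept)" for the intercept),
    ``estimate``, ``std_error``, ``z``, ``p_one_sided`` (upper tail).
    The reference category is the baseline: all its coefficients are zero by
    definition and it has no rows.
    """

    table: pd.DataFrame
    categories: list[ReactionCategory]
    reference: ReactionCategory
    species: list[str]
    converged: bool
    n_events: int
    log_likelihood: float

    def slopes(self) -> pd.DataFrame:
        """(category x species) matrix of slope estimates."""
        sub = self.table[self.table["species"] != "(intercept)"]
        return sub.pivot(index="category", columns="species", values="estimate")

    def intercepts(self) -> pd.Series:
        sub = self.table[self.table["species"] == "(intercept)"]
        return sub.set_index("category")["estimate"]

    def _pivot(self, col: str) -> pd.DataFrame:
        sub = self.table[self.table["species"] != "(intercept)"]
        return sub.pivot(index="category", columns="species", values=col)


def _default_reference(categories: Sequence[ReactionCategory]) -> ReactionCategory:
    """Pure-birth category with the lexicographically smallest jump vector."""
    births = [c for c in categories
              if sum(c.jump) == 1 and all(v in (0, 1) for v in c.jump)]
    if not births:
        raise ValueError(
            "no pure-birth category observed; pass an explicit reference"
        )
    return min(births, key=lambda c: c.jump)


def _aggregate(Z: np.ndarray, y: np.ndarray, m: int):
    """Collapse events sharing a covariate row into per-category counts."""
    uniq, inv = np.unique(Z, axis=0, return_inverse=True)
    counts = np.zeros((uniq.shape[0], m), dtype=np.float64)
    np.add.at(counts, (inv, y), 1.0)
    return uniq, counts


def fit_multinomial(
    design: DesignMatrix,
    reference: ReactionCategory | str | None = None,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CoefTable:
    """Maximum-likelihood fit of the multinomial logit by Newton's method.

    Parameters
    ----------
    reference
        Reference category (object or label).  Defaults to the pure-birth
        category with the lexicographically smallest jump vector, mirroring
        the convention of taking a production reaction as baseline.
    ridge
        L2 penalty on slopes only (intercepts unpenalized).  The default
        1e-6 leaves well-conditioned estimates untouched to ~4 decimals but
        guarantees convergence under quasi-separation.

    Standard errors come from the inverse observed information; Z-scores are
    estimate/SE and P-values are one-sided upper tail, P = 1 - Phi(Z).
    """
    cats = design.categories
    m = len(cats)
    if isinstance(reference, str):
        match = [c for c in cats if c.label == reference]
        if not match:
            raise ValueError(f"reference category {reference!r} not present in data")
        reference = match[0]
    elif reference is None:
        reference = _default_reference(cats)
    elif reference.jump not in {c.jump for c in cats}:
        raise ValueError("reference category not present in data")

    non_ref = [c for c in cats if c.jump != reference.jump]
    order = [c.index for c in non_ref] + [reference.index]
    # columns of counts reordered so the reference is last
    Zu, counts_all = _aggregate(design.Z, design.y, m)
    counts = counts_all[:, order]
    n_states, s = Zu.shape
    K = m - 1                      # free categories
    p = s + 1                      # intercept + slopes
    X = np.hstack([np.ones((n_states, 1)), Zu])   # (n_states, p)
    N = counts.sum(axis=1)                         # events per state

    B = np.zeros((K, p))
    pen = np.zeros(K * p)
    pen[np.arange(K * p) % p != 0] = ridge         # slopes only

    def _probs(B):
        eta = X @ B.T                              # (n_states, K)
        eta_full = np.hstack([eta, np.zeros((n_states, 1))])
        lse = logsumexp(eta_full, axis=1, keepdims=True)
        return np.exp(eta_full - lse), lse

    def _loglik(B):
        P, _ = _probs(B)
        ll = float(np.sum(counts * np.log(np.maximum(P, 1e-300))))
        return ll - 0.5 * float(pen @ (B.ravel() ** 2))

    ll = _loglik(B)
    converged = False
    for _ in range(max_iter):
        P, _ = _probs(B)
        Pk = P[:, :K]
        # gradient: per category X^T (counts_k - N * P_k), minus penalty
        G = ((counts[:, :K] - N[:, None] * Pk).T @ X).ravel() - pen * B.ravel()
        # observed information (negative Hessian), block (k, l):
        # X^T diag(N * (P_k delta_kl - P_k P_l)) X
        H = np.empty((K * p, K * p))
        for k in range(K):
            for l in range(k, K):
                w = N * (Pk[:, k] * ((k == l) - Pk[:, l]))
                block = X.T @ (w[:, None] * X)
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = block
                if l != k:
                    H[l * p:(l + 1) * p, k * p:(k + 1) * p] = block.T
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, G)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, G, rcond=None)[0]
        # damped Newton: halve until the objective improves
        scale = 1.0
        for _half in range(30):
            B_new = B + scale * step.reshape(K, p)
            ll_new = _loglik(B_new)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if not np.isfinite(ll_new):
            raise RuntimeError("multinomial fit diverged")
        delta = ll_new - ll
        B, ll = B_new, ll_new
        if abs(delta) < tol * (1.0 + abs(ll)) and np.max(np.abs(G)) < 1e-6 * (1 + design.Z.shape[0]):
            converged = True
            break
    if not converged:
        # accept a stationary enough point; flag otherwise
        P, _ = _probs(B)
        Pk = P[:, :K]
        G = ((counts[:, :K] - N[:, None] * Pk).T @ X).ravel() - pen * B.ravel()
        converged = bool(np.max(np.abs(G)) < 1e-3 * (1 + design.Z.shape[0]))
        if not converged:
            raise RuntimeError("multinomial fit did not converge")

    # standard errors from the inverse observed information at the optimum
    P, _ = _probs(B)
    Pk = P[:, :K]
    H = np.empty((K * p, K * p))
    for k in range(K):
        for l in range(k, K):
            w = N * (Pk[:, k] * ((k == l) - Pk[:, l]))
            block = X.T @ (w[:, None] * X)
            H[k * p:(k + 1) * p, l * p:(l + 1) * p] = block
            if l != k:
                H[l * p:(l + 1) * p, k * p:(k + 1) * p] = block.T
    H[np.diag_indices_from(H)] += pen
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(K, p)

    rows = []
    terms = ["(intercept)"] + design.species
    for k, cat in enumerate(non_ref):
        for j, term in enumerate(terms):
            est = B[k, j]
            s_e = se[k, j]
            z = est / s_e if s_e > 0 else np.nan
            rows.append({
                "category": cat.label,
                "species": term,
                "estimate": est,
                "std_error": s_e,
                "z": z,
                "p_one_sided": float(1.0 - ndtr(z)) if np.isfinite(z) else np.nan,
            })
    table = pd.DataFrame(rows)
    return CoefTable(
        table=table,
        categories=list(cats),
        reference=reference,
        species=list(design.species),
        converged=converged,
        n_events=int(design.y.shape[0]),
        log_likelihood=ll,
    )


@dataclass
class ReactantCallMatrix:
    """Significance calls per (category, species).

    ``calls`` holds "+" for significant-positive coefficients (the reactant
    call), "-" for significant-negative ones (reported for interpretation,
    never treated as a reactant), and "" otherwise.  ``jumps`` carries each
    category's net-change vector.
    """

    calls: pd.DataFrame              # (categories x species) of "+", "-", ""
    positive: pd.DataFrame           # boolean "+" indicator
    negative: pd.DataFrame           # boolean significant-negative indicator
    jumps: pd.DataFrame              # (categories x species) net changes
    reference: str
    p_threshold: float

    def call_sets(self) -> dict[str, frozenset[str]]:
        """Map category label -> set of species called '+'."""
        return {
            lab: frozenset(sp for sp in self.calls.columns if self.calls.loc[lab, sp] == "+")
            for lab in self.calls.index
        }


def call_reactants(coefs: CoefTable, p_threshold: float = DEFAULT_P_THRESHOLD) -> ReactantCallMatrix:
    """Call reactants: '+' where the slope is positive with one-sided
    P < ``p_threshold`` (default 0.001, i.e. Z >= 3.09).

    Significant negative slopes (lower-tail P < threshold) are reported in a
    separate channel: they mean the *reference* reaction becomes more likely
    as that species grows, and are never called as reactants.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    est = coefs._pivot("estimate")
    z = coefs._pivot("z")
    zcrit = z_threshold(p_threshold)
    pos = (est > 0) & (z >= zcrit)
    neg = (est < 0) & (z <= -zcrit)
    calls = pos.map(lambda b: "+" if b else "")
    calls = calls.where(~neg, "-")
    labels = [c.label for c in coefs.categories if c.jump != coefs.reference.jump]
    order = [lab for lab in labels if lab in calls.index]
    calls = calls.loc[order, coefs.species]
    jump_by_label = {c.label: c.jump for c in coefs.categories}
    jumps = pd.DataFrame([jump_by_label[lab] for lab in order],
                         index=order, columns=coefs.species)
    return ReactantCallMatrix(
        calls=calls,
        positive=pos.loc[order, coefs.species],
        negative=neg.loc[order, coefs.species],
        jumps=jumps,
        reference=coefs.reference.label,
        p_threshold=p_threshold,
    )


def recover_orders(coefs: CoefTable, p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Estimated reactant multiplicities nu_ik from fitted log-count slopes.

    Under the log transform the slope on species i for category k recovers
    the power of X_i in the propensity, i.e. the consumed multiplicity.
    Significant positive slopes are rounded to the nearest nonnegative
    integer; everything else is 0.
    """
    est = coefs._pivot("estimate")
    z = coefs._pivot("z")
    sig = (est > 0) & (z >= z_threshold(p_threshold))
    orders = np.where(sig, np.maximum(np.rint(est), 0), 0).astype(int)
    return pd.DataFrame(orders, index=est.index, columns=est.columns)


def rate_ratios(coefs: CoefTable, reference_rate: float | None = None) -> pd.Series:
    """Rate-constant estimates from intercepts: kappa_k / kappa_r = exp(alpha_k).

    If ``reference_rate`` (kappa_r) is supplied, absolute kappa_k are
    returned instead of ratios.
    """
    ratios = np.exp(coefs.intercepts())
    ratios.name = "rate_ratio" if reference_rate is None else "rate"
    return ratios * reference_rate if reference_rate is not None else ratios


def identify(
    ds: EventDataset,
    reference: str | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    transform: str = "log",
    zero_floor: float = DEFAULT_ZERO_FLOOR,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[CoefTable, ReactantCallMatrix]:
    """End-to-end identification: design, fit, and reactant calls."""
    design = build_design(ds, transform=transform, zero_floor=zero_floor)
    coefs = fit_multinomial(design, reference=reference, ridge=ridge)
    return coefs, call_reactants(coefs, p_threshold=p_threshold)
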