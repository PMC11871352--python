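"""Site-heterogeneous codon models (M0, M1a, M2a, M7, M8) with LRTs.

All models share the GY94 substitution process with F3x4 codon
frequencies; they differ only in how the nonsynonymous/synonymous rate
ratio ω varies over codons:

* M0 — a single ω for all sites;
* M1a (nearly neutral) — classes (p0, ω0≤1) and (p1, ω1=1);
* M2a (positive selection) — M1a plus a class (p2, ω2≥1);
* M7 (beta) — ω ~ Beta(p, q) on (0,1), discretized into K=10
  equal-probability categories (quantile midpoints);
* M8 (beta & ω) — p0·Beta(p, q) plus an extra class (p1, ωs≥1).

Likelihoods are computed by Felsenstein pruning over an unrooted tree,
summing the site likelihood over ω classes; κ, branch lengths and model
parameters are maximized numerically (bounded quasi-Newton on log/logit
transforms, with seeded random restarts).  Positive-selection evidence
comes from the 2Δℓ likelihood-ratio tests M1a–M2a and M7–M8 (χ², df=2)
and from naive empirical Bayes (NEB) posteriors P(ω>1) per codon —
posterior class weights evaluated at the MLEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ..genetic_code import VERTEBRATE_MITO
from .alignment import CodonAlignment
from .gy94 import decompose, f3x4_frequencies, rate_matrix, structure
from .trees import UnrootedTree

MODELS = ("M0", "M1a", "M2a", "M7", "M8")
N_BETA_CATEGORIES = 10
OMEGA_MIN, OMEGA_MAX = 1e-4, 999.0
_LOGIT_BOUND = 8.0  # keeps proportions/omega0 off exact 0/1


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def beta_categories(p: float, q: float, k: int = N_BETA_CATEGORIES) -> np.ndarray:
    """K equal-probability ω categories of Beta(p, q): quantile midpoints."""
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    return np.clip(stats.beta.ppf(quantiles, p, q), 1e-9, 1 - 1e-9)


@dataclass
class SiteModelFit:
    """A fitted site model: ℓ, MLEs, and the pieces needed for NEB."""

    model: str
    lnL: float
    kappa: float
    params: dict[str, float]
    branch_lengths: np.ndarray
    class_weights: np.ndarray
    class_omegas: np.ndarray
    converged: bool
    boundary: list[str] = field(default_factory=list)
    n_free_params: int = 0
    # private state for site_posteriors
    _class_site_lik: np.ndarray | None = None  # (n_class, n_patterns)
    _column_pattern: np.ndarray | None = None
    _kept_columns: np.ndarray | None = None


@dataclass
class LrtResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# model parameterizations (unconstrained vector <-> class structure)

def _model_spec(model: str):
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return {
        "M0": 1, "M1a": 2, "M2a": 4, "M7": 2, "M8": 4,
    }[model]


def _default_theta(model: str) -> np.ndarray:
    return {
        "M0": np.array([np.log(0.3)]),
        "M1a": np.array([_logit(0.8), _logit(0.1)]),
        "M2a": np.array([_logit(0.8), _logit(0.8), _logit(0.1), np.log(0.5)]),
        "M7": np.array([np.log(0.5), np.log(1.5)]),
        "M8": np.array([_logit(0.9), np.log(0.5), np.log(1.5), np.log(0.5)]),
    }[model]


def _theta_bounds(model: str) -> list[tuple[float, float]]:
    lb, ub = -_LOGIT_BOUND, _LOGIT_BOUND
    logw = (np.log(OMEGA_MIN), np.log(OMEGA_MAX))
    logbeta = (np.log(5e-3), np.log(99.0))
    logex = (np.log(1e-6), np.log(OMEGA_MAX - 1.0))  # omega_extra = 1 + e^x
    return {
        "M0": [logw],
        "M1a": [(lb, ub), (lb, ub)],
        "M2a": [(lb, ub), (lb, ub), (lb, ub), logex],
        "M7": [logbeta, logbeta],
        "M8": [(lb, ub), logbeta, logbeta, logex],
    }[model]


def _classes_from_theta(model: str, theta: np.ndarray):
    """(weights, omegas, named params) for a model's parameter vector."""
    if model == "M0":
        w = float(np.exp(theta[0]))
        return np.array([1.0]), np.array([w]), {"omega": w}
    if model == "M1a":
        p0 = float(_sigmoid(theta[0]))
        w0 = float(_sigmoid(theta[1]))
        return (
            np.array([p0, 1 - p0]), np.array([w0, 1.0]),
            {"p0": p0, "p1": 1 - p0, "omega0": w0},
        )
    if model == "M2a":
        p0 = float(_sigmoid(theta[0]))
        p1 = float((1 - p0) * _sigmoid(theta[1]))
        p2 = 1 - p0 - p1
        w0 = float(_sigmoid(theta[2]))
        w2 = float(1.0 + np.exp(theta[3]))
        return (
            np.array([p0, p1, p2]), np.array([w0, 1.0, w2]),
            {"p0": p0, "p1": p1, "p2": p2, "omega0": w0, "omega2": w2},
        )
    if model == "M7":
        p, q = np.exp(theta)
        return (
            np.full(N_BETA_CATEGORIES, 1 / N_BETA_CATEGORIES),
            beta_categories(p, q),
            {"p": float(p), "q": float(q)},
        )
    if model == "M8":
        p0 = float(_sigmoid(theta[0]))
        p, q = np.exp(theta[1:3])
        ws = float(1.0 + np.exp(theta[3]))
        weights = np.append(
            np.full(N_BETA_CATEGORIES, p0 / N_BETA_CATEGORIES), 1 - p0
        )
        omegas = np.append(beta_categories(p, q), ws)
        return weights, omegas, {
            "p0": p0, "p1": 1 - p0, "p": float(p), "q": float(q),
            "omega": ws,
        }
    raise ValueError(model)


# ---------------------------------------------------------------------------
# likelihood engine

def _per_class_site_likelihoods(
    patterns: np.ndarray,
    tree: UnrootedTree,
    branch_lengths: np.ndarray,
    kappa: float,
    weights: np.ndarray,
    omegas: np.ndarray,
    pi: np.ndarray,
    st,
) -> np.ndarray:
    """Site likelihood per ω class: (n_class, n_patterns)."""
    n_states = len(pi)
    npat = patterns.shape[1]
    # mixture-averaged rate normalization (branch length = expected
    # substitutions per codon averaged over classes)
    Qs, rates = [], []
    for om in omegas:
        Q, r = rate_matrix(kappa, float(om), pi, st)
        Qs.append(Q)
        rates.append(r)
    scale = float(np.dot(weights, rates))
    if scale <= 0 or not np.isfinite(scale):
        return np.full((len(omegas), npat), 1e-300)
    out = np.empty((len(omegas), npat))
    for k, Q in enumerate(Qs):
        eig = decompose(Q / scale, pi)
        Ps = [eig.transition_matrix(t) for t in branch_lengths]
        partial: dict[int, np.ndarray] = {}
        for node, parent, edge in tree.postorder:
            P = Ps[edge]
            if node < tree.n_leaves:
                msg = P[:, patterns[node]]
            else:
                msg = P @ partial.pop(node)
            if parent in partial:
                partial[parent] *= msg
            else:
                partial[parent] = msg.copy() if node < tree.n_leaves else msg
        out[k] = pi @ partial[tree.root]
    return np.clip(out, 1e-300, None)


def codon_log_likelihood(
    aln: CodonAlignment,
    tree: UnrootedTree,
    branch_lengths: np.ndarray,
    kappa: float,
    weights: np.ndarray,
    omegas: np.ndarray,
    pi: np.ndarray | None = None,
) -> float:
    """Mixture log-likelihood at fixed parameters (no optimization)."""
    _check_tree_taxa(aln, tree)
    patterns, counts, _ = _aligned_patterns(aln, tree)
    if pi is None:
        pi = f3x4_frequencies(list(aln.sequences), aln.code)
    st = structure(aln.code)
    cls = _per_class_site_likelihoods(
        patterns, tree, np.asarray(branch_lengths, float), kappa,
        np.asarray(weights, float), np.asarray(omegas, float), pi, st,
    )
    site = np.asarray(weights, float) @ cls
    return float(np.dot(counts, np.log(site)))


def _check_tree_taxa(aln: CodonAlignment, tree: UnrootedTree) -> None:
    if set(tree.taxa) != set(aln.taxa):
        raise ValueError(
            f"tree taxa {sorted(tree.taxa)} != alignment taxa "
            f"{sorted(aln.taxa)}"
        )


def _aligned_patterns(aln: CodonAlignment, tree: UnrootedTree):
    """Pattern matrix with rows ordered to match the tree's leaf ids."""
    patterns, counts, col_pattern = aln.encode_complete_deletion()
    order = [aln.taxa.index(t) for t in tree.taxa]
    return patterns[order], counts, col_pattern


def fit_site_model(
    aln: CodonAlignment,
    tree: UnrootedTree,
    model: str = "M0",
    n_restarts: int = 2,
    seed: int = 0,
    maxiter: int = 400,
) -> SiteModelFit:
    """Maximum-likelihood fit of one site model.

    Branch lengths, κ and the model's ω-distribution parameters are
    optimized jointly (L-BFGS-B on transformed coordinates); the best of
    `n_restarts` seeded starts is returned.  Non-convergence and
    parameter-boundary hits are flagged on the result, never silent.
    """
    _check_tree_taxa(aln, tree)
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    _model_spec(model)
    patterns, counts, col_pattern = _aligned_patterns(aln, tree)
    pi = f3x4_frequencies(list(aln.sequences), aln.code)
    st = structure(aln.code)
    n_edges = tree.n_edges
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray):
        kappa = float(np.exp(x[0]))
        bl = np.exp(x[1: 1 + n_edges])
        weights, omegas, named = _classes_from_theta(model, x[1 + n_edges:])
        return kappa, bl, weights, omegas, named

    def negloglik(x: np.ndarray) -> float:
        kappa, bl, weights, omegas, _ = unpack(x)
        cls = _per_class_site_likelihoods(
            patterns, tree, bl, kappa, weights, omegas, pi, st
        )
        site = weights @ cls
        val = -float(np.dot(counts, np.log(site)))
        return val if np.isfinite(val) else 1e12

    bl0 = np.clip(tree.branch_lengths, 1e-4, 20.0)
    base = np.concatenate([[np.log(2.0)], np.log(bl0), _default_theta(model)])
    bounds = (
        [(np.log(0.05), np.log(100.0))]
        + [(np.log(1e-8), np.log(50.0))] * n_edges
        + _theta_bounds(model)
    )

    best = None
    for r in range(max(1, n_restarts)):
        x0 = base.copy()
        if r > 0:  # seeded jitter around the deterministic start
            x0 = x0 + rng.normal(0.0, 0.4, size=x0.shape)
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    kappa, bl, weights, omegas, named = unpack(best.x)
    boundary = []
    for i, (lo, hi) in enumerate(bounds):
        if best.x[i] <= lo + 1e-6 or best.x[i] >= hi - 1e-6:
            if i == 0:
                boundary.append("kappa")
            elif i <= n_edges:
                pass  # branch length at 0 is ordinary, not pathological
            else:
                boundary.append(f"theta[{i - 1 - n_edges}]")
    if not best.success and "ABNORMAL" in str(best.message):
        warnings.warn(f"{model}: optimizer did not converge cleanly "
                      f"({best.message})", stacklevel=2)

    cls = _per_class_site_likelihoods(
        patterns, tree, bl, kappa, weights, omegas, pi, st
    )
    fit = SiteModelFit(
        model=model,
        lnL=-float(best.fun),
        kappa=kappa,
        params=named,
        branch_lengths=bl,
        class_weights=weights,
        class_omegas=omegas,
        converged=bool(best.success),
        boundary=boundary,
        n_free_params=1 + n_edges + len(_default_theta(model)),
        _class_site_lik=cls,
        _column_pattern=col_pattern,
        _kept_columns=aln.kept_columns(),
    )
    return fit


_NESTED_DF = {("M1a", "M2a"): 2, ("M7", "M8"): 2}


def lrt(null: SiteModelFit, alt: SiteModelFit, df: int | None = None) -> LrtResult:
    """Likelihood-ratio test between nested site models.

    The statistic 2(ℓ_alt − ℓ_null) is clipped at zero (an optimizer can
    leave the richer model a hair below its nested null); p-values use
    χ² with df=2 for the canonical M1a–M2a and M7–M8 pairs, or an
    explicit `df` for other nestings.
    """
    if df is None:
        df = _NESTED_DF.get((null.model, alt.model))
        if df is None:
            raise ValueError(
                f"{null.model} vs {alt.model} is not a canonical nested "
                "pair; pass df explicitly"
            )
    statistic = max(0.0, 2.0 * (alt.lnL - null.lnL))
    return LrtResult(
        null_model=null.model, alt_model=alt.model, statistic=statistic,
        df=df, p_value=float(stats.chi2.sf(statistic, df)),
    )


def site_posteriors(fit: SiteModelFit) -> dict:
    """Naive empirical Bayes class posteriors per retained codon column.

    P(class k | site) ∝ p_k · L(site | ω_k) at the MLEs.  Returns the
    full class-posterior matrix, the per-column P(ω>1), and the columns
    ranked by that probability (1-based positions in the original
    alignment frame).
    """
    if fit._class_site_lik is None:
        raise ValueError("fit carries no site likelihoods")
    w = fit.class_weights[:, None] * fit._class_site_lik
    post = w / w.sum(axis=0, keepdims=True)          # (n_class, n_pat)
    per_col = post[:, fit._column_pattern]            # (n_class, n_cols)
    positive = fit.class_omegas > 1.0
    p_pos = per_col[positive].sum(axis=0) if positive.any() else np.zeros(
        per_col.shape[1]
    )
    cols = fit._kept_columns + 1
    order = np.argsort(-p_pos, kind="stable")
    return {
        "columns": cols,
        "class_posteriors": per_col,
        "p_positive": p_pos,
        "ranked": [(int(cols[i]), float(p_pos[i])) for i in order],
    }


def fit_models(
    aln: CodonAlignment,
    tree: UnrootedTree,
    models: tuple[str, ...] = MODELS,
    seed: int = 0,
    n_restarts: int = 2,
) -> dict[str, SiteModelFit]:
    """Fit several site models and return them keyed by model code."""
    return {
        m: fit_site_model(
            aln, tree, m, n_restarts=n_restarts, seed=seed + 17 * i
        )
        for i, m in enumerate(models)
    }
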