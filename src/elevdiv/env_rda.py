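"""Environmental RDA: collinearity handling, selection, partitioning.

The soil organic-matter block (SOM, TOC, TON, WC) is near-perfectly
collinear (VIF >> 10), so it is collapsed to the first axis of a
correlation-matrix PCA (OM_pc1) before modelling.  Community composition
(Hellinger-transformed relative abundances) is then regressed on the
standardized predictors by redundancy analysis; parsimonious models come
from forward selection with a permutation test and a double stopping rule
(term significance and the full-model adjusted-R-squared ceiling) followed
by backward elimination.  Hierarchical partitioning decomposes the
full-model adjusted R-squared into per-predictor individual contributions
(order-averaged incremental gains over all predictor subsets) and reports
unique contributions (leave-one-out losses); negative shared variance can
make unique exceed individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_data import OM_BLOCK, EnvTable

logger = logging.getLogger(__name__)

__all__ = [
    "vif",
    "OmCollapse",
    "collapse_om_block",
    "RdaFit",
    "rda",
    "SelectionResult",
    "select_predictors",
    "hierarchical_partition",
    "rda_over_bootstrap",
    "build_design",
]


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column, 1 / (1 - R2_j).

    R2_j comes from regressing column j (with intercept) on the remaining
    columns.  Exact collinearity is reported as inf, not an error.
    """
    X = predictors.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("VIF needs at least 2 columns")
    if n <= m:
        raise ValueError("need more rows than columns")
    out = {}
    for j, name in enumerate(predictors.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class OmCollapse:
    scores: pd.Series
    variance_share: float
    loadings: pd.Series


def collapse_om_block(env: EnvTable | pd.DataFrame, block=OM_BLOCK) -> OmCollapse:
    """First principal component of the standardized organic-matter block.

    Correlation-matrix PCA (columns standardized to unit variance because
    the block mixes %, fractions and mg/g); PC1 is sign-fixed to correlate
    positively with SOM.
    """
    frame = env.frame if isinstance(env, EnvTable) else env
    missing = [c for c in block if c not in frame.columns]
    if missing:
        raise ValueError(f"missing block columns: {missing}")
    X = frame[list(block)].to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(block, sd) if s == 0]
        raise ValueError(f"zero-variance column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=len(block))
    scores = pca.fit_transform(Z)
    pc1 = scores[:, 0]
    load = pca.components_[0]
    if np.corrcoef(pc1, Z[:, list(block).index("SOM")])[0, 1] < 0:
        pc1, load = -pc1, -load
    return OmCollapse(
        scores=pd.Series(pc1, index=frame.index, name="OM_pc1"),
        variance_share=float(pca.explained_variance_ratio_[0]),
        loadings=pd.Series(load, index=list(block)),
    )


def build_design(env: EnvTable, meta_frame: pd.DataFrame) -> pd.DataFrame:
    """Standard candidate predictor set: OM_pc1, elevation, pH, C_N, P, N_P."""
    om = collapse_om_block(env)
    if om.variance_share < 0.5:
        logger.warning("OM_pc1 explains only %.0f%% of its block", 100 * om.variance_share)
    design = pd.DataFrame(
        {
            "OM_pc1": om.scores,
            "elevation": meta_frame.loc[om.scores.index, "elevation_m"],
            "pH": env.frame["pH"],
            "C_N": env.frame["C_N"],
            "P": env.frame["P"],
            "N_P": env.frame["N_P"],
        }
    )
    return design


# ---------------------------------------------------------------------------
# RDA core


@dataclass(frozen=True)
class RdaFit:
    r_squared: float
    adj_r_squared: float
    n: int
    n_predictors: int


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance predictor")
    return (X - X.mean(axis=0)) / sd


def _prepare_response(Y) -> np.ndarray:
    """Centre the response; compress wide responses to their row-space.

    R2 depends on the response only through inner products between samples,
    so a samples x species matrix can be replaced exactly by its SVD scores
    U*s (at most n columns) — a large constant-factor saving when the
    selection loop runs over many bootstrap datasets.
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    if Yc.shape[1] > Yc.shape[0]:
        u, s, _ = np.linalg.svd(Yc, full_matrices=False)
        Yc = u * s
    return Yc


def _q_basis(X: np.ndarray | None) -> np.ndarray | None:
    """Orthonormal basis of the centred column space of X (rank-robust)."""
    if X is None or X.shape[1] == 0:
        return None
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-10 * s[0] if s[0] > 0 else slice(0, 0)
    return u[:, keep]


def _r2(Yc: np.ndarray, X: np.ndarray | None) -> float:
    """Fraction of total response variance captured by the projection on X."""
    q = _q_basis(X)
    if q is None:
        return 0.0
    ss_tot = float(np.sum(Yc**2))
    return float(np.sum((q.T @ Yc) ** 2)) / ss_tot


def _adjust(r2: float, n: int, m: int) -> float:
    if m == 0:
        return 0.0
    if n - m - 1 <= 0:
        raise ValueError("too few samples for the number of predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda(response, design: pd.DataFrame) -> RdaFit:
    """Redundancy analysis R2 and Ezekiel-adjusted R2.

    The response (typically Hellinger-transformed abundances) is centred
    column-wise; predictors are standardized; R2 is the fraction of total
    response sum of squares captured by the least-squares projection onto
    the predictor space.
    """
    Yc = _prepare_response(response)
    X = design.to_numpy(dtype=float)
    n, m = X.shape
    if n != Yc.shape[0]:
        raise ValueError("response and design have different sample counts")
    if n <= m + 1:
        raise ValueError("need n > number of predictors + 1")
    Xs = _standardize(X)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xs]))
    if rank < m + 1:
        v = vif(design)
        bad = list(v.index[np.isinf(v)])
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(design.columns)}")
    r2 = _r2(Yc, Xs)
    return RdaFit(r_squared=r2, adj_r_squared=_adjust(r2, n, m), n=n, n_predictors=m)


def _subset_adj_r2_factory(Yc: np.ndarray, Xs: pd.DataFrame, adjusted: bool = True):
    """Memoised (adjusted) R2 over predictor subsets (shared by selection/HP).

    The adjustment penalises by the effective rank of the subset design, so
    duplicated or collinear candidates do not inflate the penalty.
    """
    n = Yc.shape[0]
    cache: dict[frozenset, float] = {frozenset(): 0.0}
    mat = Xs.to_numpy(dtype=float)
    idx = {c: i for i, c in enumerate(Xs.columns)}

    def adj(subset) -> float:
        key = frozenset(subset)
        if key not in cache:
            cols = [idx[c] for c in sorted(key)]
            x = mat[:, cols]
            r2 = _r2(Yc, x)
            if not adjusted:
                cache[key] = r2
            else:
                q = _q_basis(x)
                rank = 0 if q is None else q.shape[1]
                cache[key] = _adjust(r2, n, rank)
        return cache[key]

    return adj


# ---------------------------------------------------------------------------
# Stepwise selection


@dataclass
class SelectionResult:
    selected: list[str]
    adj_r_squared: float
    path: list[dict] = field(default_factory=list)


def _perm_p(Yc, X_red, X_full, n_perm, rng) -> float:
    """Permutation p for the added terms (Freedman-Lane residual permutation)."""
    n = Yc.shape[0]
    m_red = 0 if X_red is None else X_red.shape[1]
    m_full = X_full.shape[1]
    df_gain = m_full - m_red
    df_res = n - 1 - m_full
    if df_res <= 0:
        raise ValueError("too few samples for the permutation test")
    q_red = _q_basis(X_red)
    q_full = _q_basis(X_full)

    def partial_f(y: np.ndarray) -> float:
        ss_tot = float(np.sum(y**2))
        r_full = float(np.sum((q_full.T @ y) ** 2)) / ss_tot
        r_red = float(np.sum((q_red.T @ y) ** 2)) / ss_tot if q_red is not None else 0.0
        den = 1.0 - r_full
        if den <= 0:
            return np.inf
        return ((r_full - r_red) / df_gain) / (den / df_res)

    f_obs = partial_f(Yc)
    fitted_red = q_red @ (q_red.T @ Yc) if q_red is not None else np.zeros_like(Yc)
    resid_red = Yc - fitted_red
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ystar = fitted_red + resid_red[perm]
        ystar = ystar - ystar.mean(axis=0)
        if partial_f(ystar) >= f_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def select_predictors(
    response,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed=None,
) -> SelectionResult:
    """Forward + backward stepwise RDA model selection.

    Forward phase: at each step the candidate with the largest adjusted-R2
    gain (ties broken by name) is tested with a permutation partial-F test;
    it enters only if p <= alpha and the model's adjusted R2 stays at or
    below the all-candidate (full-model) adjusted R2.  Backward phase: terms
    whose removal is not significant at alpha are dropped, least significant
    first.  An empty selection is a valid outcome.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    Yc = _prepare_response(response)
    Xs = pd.DataFrame(
        _standardize(candidates.to_numpy(dtype=float)),
        index=candidates.index,
        columns=candidates.columns,
    )
    rng = np.random.default_rng(seed)
    adj = _subset_adj_r2_factory(Yc, Xs)
    names = list(Xs.columns)
    # ceiling = adjusted R2 of the model holding every candidate (lstsq
    # tolerates rank deficiency); disabled when n is too small to fit it
    try:
        full_model_adj = adj(frozenset(names))
    except ValueError:
        full_model_adj = np.inf

    selected: list[str] = []
    path: list[dict] = []

    def cols(subset):
        return Xs[sorted(subset)].to_numpy() if subset else None

    while True:
        remaining = [c for c in names if c not in selected]
        if not remaining:
            break
        gains = sorted(
            ((adj(frozenset([*selected, c])), c) for c in remaining),
            key=lambda t: (-t[0], t[1]),
        )
        best_adj, best = gains[0]
        if best_adj <= adj(frozenset(selected)) + 1e-12:
            path.append({"step": "stop", "reason": "no adjusted-R2 gain", "candidate": best})
            break
        if best_adj > full_model_adj + 1e-9:
            path.append({"step": "stop", "reason": "adjusted-R2 ceiling", "candidate": best})
            break
        p = _perm_p(Yc, cols(selected), Xs[sorted([*selected, best])].to_numpy(), n_perm, rng)
        path.append({"step": "forward", "candidate": best, "adj_r2": best_adj, "p": p})
        if p > alpha:
            path.append({"step": "stop", "reason": f"p={p:.4f} > alpha", "candidate": best})
            break
        selected.append(best)

    # backward elimination
    changed = True
    while changed and len(selected) > 1:
        changed = False
        tests = []
        for term in sorted(selected):
            reduced = [c for c in selected if c != term]
            p = _perm_p(Yc, cols(reduced), Xs[sorted(selected)].to_numpy(), n_perm, rng)
            tests.append((p, term))
        p_worst, term_worst = max(tests)
        if p_worst > alpha:
            selected.remove(term_worst)
            path.append({"step": "backward-drop", "candidate": term_worst, "p": p_worst})
            changed = True

    if not selected:
        logger.warning("select_predictors: no predictor met the criteria")
    return SelectionResult(
        selected=sorted(selected, key=names.index),
        adj_r_squared=adj(frozenset(selected)),
        path=path,
    )


# ---------------------------------------------------------------------------
# Hierarchical partitioning


def hierarchical_partition(response, design: pd.DataFrame, adjusted: bool = True) -> pd.DataFrame:
    """Individual and unique adjusted-R2 contributions per predictor.

    individual_j averages the incremental adjusted R2 of adding j over all
    predictor orderings (computed by subset enumeration with hierarchy
    weights s!(m-s-1)!/m!); the individual contributions sum exactly to the
    full-model adjusted R2.  unique_j is the loss from dropping j from the
    full model.  With ``adjusted=False`` the decomposition runs on raw R2,
    where orthogonal predictors have individual exactly equal to unique
    (the small-sample penalty otherwise shifts the order-averaged terms).
    """
    m = design.shape[1]
    if m > 8:
        raise ValueError("hierarchical partitioning limited to 8 predictors")
    Yc = _prepare_response(response)
    Xs = pd.DataFrame(
        _standardize(design.to_numpy(dtype=float)),
        index=design.index,
        columns=design.columns,
    )
    adj = _subset_adj_r2_factory(Yc, Xs, adjusted=adjusted)
    names = list(Xs.columns)
    full = adj(frozenset(names))
    rows = []
    for j in names:
        rest = [c for c in names if c != j]
        unique = full - adj(frozenset(rest))
        individual = 0.0
        for s in range(m):
            w = factorial(s) * factorial(m - s - 1) / factorial(m)
            for sub in combinations(rest, s):
                individual += w * (adj(frozenset([*sub, j])) - adj(frozenset(sub)))
        rows.append((j, individual, unique))
    out = pd.DataFrame(rows, columns=["predictor", "individual", "unique"]).set_index("predictor")
    out.attrs["full_adj_r2"] = full
    return out


# ---------------------------------------------------------------------------
# Bootstrap selection frequencies


def rda_over_bootstrap(
    datasets,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run stepwise RDA selection over bootstrap datasets and tally sets.

    ``datasets`` yields (response, candidate-design) pairs, one per transect
    combination.  Returns (summary, records): summary lists each selected
    variable set with its frequency (descending) and mean adjusted R2;
    records holds the per-dataset outcome.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, (resp, cand) in enumerate(datasets):
        child = ss.spawn(1)[0]
        res = select_predictors(resp, cand, alpha=alpha, n_perm=n_perm, seed=child)
        label = " + ".join(res.selected) if res.selected else "(none)"
        rows.append((i, label, res.adj_r_squared))
    records = pd.DataFrame(rows, columns=["dataset", "selected_set", "adj_r2"])
    summary = (
        records.groupby("selected_set")
        .agg(frequency=("dataset", "size"), mean_adj_r2=("adj_r2", "mean"))
        .sort_values("frequency", ascending=False)
        .reset_index()
    )
    return summary, records
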