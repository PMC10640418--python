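"""Beta diversity: Bray-Curtis, PCoA, PERMANOVA, and elevation decay.

Dissimilarities are Bray-Curtis on Hellinger-transformed relative
abundances.  PERMANOVA follows the McArdle-Anderson trace formulation on
the Gower-centred matrix with sequential (Type-I) sums of squares for the
fixed formula elevation + habitat + elevation x habitat, elevation entering
as a continuous covariate; p-values come from free permutation of samples.
The elevation-decay analysis regresses pairwise dissimilarity on elevation
separation within a habitat and contrasts each elevation-interval class
against the within-band (0 m) class with ANOVA + Tukey HSD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, tukey_hsd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core_data import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "bray_curtis",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "DecayResult",
    "elevation_decay",
]


def bray_curtis(matrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d(x, y) = sum|x-y| / sum(x+y)."""
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(x.shape[0])]
    if (x < 0).any():
        raise ValueError("negative entries")
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("two all-zero rows make Bray-Curtis undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=ids)


def pcoa(dm: DistanceMatrix):
    """Principal coordinate analysis (Gower double-centring + eigh).

    Returns the scikit-bio ordination result restricted to axes with
    positive eigenvalues; any negative eigenvalues are kept in
    ``result.eigvals`` and logged (no Lingoes/Cailliez correction).
    """
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh")
    neg = res.eigvals[res.eigvals < -1e-10]
    if len(neg):
        logger.info("pcoa: %d negative eigenvalues, most negative %.3g", len(neg), neg.min())
    keep = res.eigvals.index[res.eigvals > 1e-10]
    res.samples = res.samples[keep]
    return res


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table (terms + residual + total)."""

    table: pd.DataFrame
    n_permutations: int

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _design_terms(meta: SampleMeta, ids) -> tuple[list[str], list[np.ndarray]]:
    f = meta.frame.loc[list(ids)]
    elev = f["elevation_m"].to_numpy(dtype=float)
    elev = (elev - elev.mean()) / elev.std()
    levels = sorted(f["habitat"].unique())
    if len(levels) < 2:
        raise ValueError("habitat term requires two habitat levels")
    hab = (f["habitat"] == levels[1]).to_numpy(dtype=float)
    return (
        ["elevation", "habitat", "elevation:habitat"],
        [elev[:, None], hab[:, None], (elev * hab)[:, None]],
    )


def permanova(
    dm: DistanceMatrix,
    meta: SampleMeta,
    n_perm: int = 999,
    seed=None,
    exact: bool = False,
) -> PermanovaResult:
    """PERMANOVA of a dissimilarity matrix on elevation * habitat.

    Sequential SS in the order elevation, habitat, interaction; pseudo-F per
    term; p by free permutation of sample identities (``exact`` enumerates
    all n! permutations, feasible only for small n).
    """
    d = dm.data
    ids = dm.ids
    n = d.shape[0]
    g = _gower_center(d)
    names, cols = _design_terms(meta, ids)
    n_terms = len(cols)

    intercept = np.ones((n, 1))
    hats = []
    x = intercept
    for c in cols:
        x = np.hstack([x, c])
        hats.append(_hat(x))
    h_prev = _hat(intercept)

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        prev = np.vdot(h_prev, gmat)
        out = np.empty(n_terms)
        for k, h in enumerate(hats):
            cur = np.vdot(h, gmat)
            out[k] = cur - prev
            prev = cur
        return out

    ss_total = float(np.trace(g))
    ss_terms = term_ss(g)
    ss_res = ss_total - ss_terms.sum()
    df_terms = np.ones(n_terms)
    df_res = n - 1 - n_terms
    if df_res <= 0:
        raise ValueError("not enough samples for the model")
    f_obs = (ss_terms / df_terms) / (ss_res / df_res)

    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        perms = np.array(list(iter_permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    g_perm = g[perms[:, :, None], perms[:, None, :]]
    prev = np.einsum("ij,pij->p", h_prev, g_perm)
    ss_p = np.empty((len(perms), n_terms))
    for k, h in enumerate(hats):
        cur = np.einsum("ij,pij->p", h, g_perm)
        ss_p[:, k] = cur - prev
        prev = cur
    res_p = ss_total - ss_p.sum(axis=1)
    f_p = (ss_p / df_terms) / (res_p / df_res)[:, None]

    # ties (e.g. permutations fixing replicate samples within a band) must
    # count as hits; F is O(1)-O(100), so 1e-8 absolute marks a genuine tie
    if exact:
        pvals = (f_p >= f_obs - 1e-8).mean(axis=0)
        n_used = len(perms)
    else:
        pvals = ((f_p >= f_obs - 1e-8).sum(axis=0) + 1) / (n_perm + 1)
        n_used = n_perm

    rows = []
    for k, name in enumerate(names):
        rows.append((name, 1, ss_terms[k], f_obs[k], ss_terms[k] / ss_total, pvals[k]))
    rows.append(("Residual", df_res, ss_res, np.nan, ss_res / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "F", "R2", "p"]).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_used)


# ---------------------------------------------------------------------------
# Elevation decay


@dataclass
class DecayResult:
    habitat: str
    pairs: pd.DataFrame  # delta_elevation, dissimilarity, interval_class
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    anova_f: float
    anova_p: float
    class_means: pd.Series
    tukey_vs_within: pd.DataFrame | None


def elevation_decay(dm: DistanceMatrix, meta: SampleMeta, habitat: str) -> DecayResult:
    """Distance-decay of dissimilarity with elevation separation in one habitat.

    All within-habitat sample pairs contribute (delta elevation,
    dissimilarity); an OLS line is fitted and pairs are binned by their
    nominal band-elevation interval.  One-way ANOVA across interval classes
    plus Tukey HSD contrasts each class against the 0-m within-band class.
    Pairs share samples, so the class tests inherit that non-independence
    from the design.
    """
    f = meta.frame
    sub = [sid for sid in dm.ids if f.loc[sid, "habitat"] == habitat]
    if len(set(f.loc[sub, "band_id"])) < 2:
        raise ValueError(f"habitat {habitat!r} has fewer than 2 bands")
    d = dm.filter(sub).data
    elev = f.loc[sub, "elevation_m"].to_numpy(dtype=float)

    rows = []
    for i, j in combinations(range(len(sub)), 2):
        rows.append((abs(elev[i] - elev[j]), d[i, j]))
    pairs = pd.DataFrame(rows, columns=["delta_elevation", "dissimilarity"])
    pairs["interval_class"] = pairs["delta_elevation"].round(6)

    X = sm.add_constant(pairs["delta_elevation"].to_numpy())
    fit = sm.OLS(pairs["dissimilarity"].to_numpy(), X).fit()

    groups = {c: g["dissimilarity"].to_numpy() for c, g in pairs.groupby("interval_class")}
    classes = sorted(groups)
    usable = [c for c in classes if len(groups[c]) >= 2]
    if len(usable) >= 2 and pairs["dissimilarity"].var() > 1e-20:
        anova_f, anova_p = f_oneway(*[groups[c] for c in usable])
    elif len(usable) >= 2:
        anova_f, anova_p = 0.0, 1.0  # constant dissimilarities: nothing to explain
    else:
        anova_f, anova_p = math.nan, math.nan

    tukey = None
    if (
        0.0 in groups
        and len(groups[0.0]) >= 2
        and len(usable) >= 2
        and pairs["dissimilarity"].var() > 1e-20
    ):
        res = tukey_hsd(*[groups[c] for c in usable])
        i0 = usable.index(0.0)
        rows = []
        for k, c in enumerate(usable):
            if c == 0.0:
                continue
            rows.append(
                (c, float(np.mean(groups[c]) - np.mean(groups[0.0])), float(res.pvalue[i0, k]))
            )
        tukey = pd.DataFrame(rows, columns=["interval_class", "mean_diff_vs_within", "p"])
    else:
        logger.warning("elevation_decay(%s): no within-band pairs; Tukey contrasts skipped", habitat)

    return DecayResult(
        habitat=habitat,
        pairs=pairs,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        class_means=pairs.groupby("interval_class")["dissimilarity"].mean(),
        tukey_vs_within=tukey,
    )
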