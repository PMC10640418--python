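"""Hill numbers with size-based rarefaction and extrapolation.

Alpha diversity uses abundance data: a sample of n sequences is interpolated
(exactly, via hypergeometric expectations) or extrapolated (anchored on the
singleton/doubleton counts f1, f2 through the Chao1-type estimate of
undetected richness) to a common size m, by default twice the minimum
sequencing depth.  Gamma diversity uses incidence data: ASV occurrences
across T sampling units, interpolated exactly and extrapolated via the
Chao2-type estimate from Q1, Q2.  Extrapolation is considered reliable up to
twice the reference size and is capped there by default.

The Hill number of order q,

    qD = (sum_i p_i^q)^(1/(1-q)),   q >= 0, q != 1,

is the effective number of equally abundant species: q = 0 is richness,
q = 1 the exponential of Shannon entropy (the q -> 1 limit), q = 2 the
inverse Simpson concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, digamma
from scipy.stats import hypergeom

from .core_data import AsvTable

__all__ = [
    "HillEstimate",
    "RarefactionCurve",
    "hill_number",
    "rarefy_abundance",
    "alpha_profile",
    "rarefy_incidence",
    "incidence_curve",
    "gamma_curves",
]


@dataclass(frozen=True)
class HillEstimate:
    """A single rarefied/extrapolated Hill number."""

    q: float
    m: int
    estimate: float
    method: str  # 'interpolated' | 'observed' | 'extrapolated'


@dataclass
class RarefactionCurve:
    """A rarefaction/extrapolation curve on a grid of sizes."""

    mode: str  # 'abundance' | 'incidence'
    q: float
    sizes: np.ndarray
    estimates: np.ndarray
    reference_size: int

    def as_frame(self) -> pd.DataFrame:
        method = np.where(
            self.sizes < self.reference_size, "interpolated",
            np.where(self.sizes == self.reference_size, "observed", "extrapolated"),
        )
        return pd.DataFrame(
            {"size": self.sizes, "estimate": self.estimates, "method": method}
        )


def hill_number(p: np.ndarray, q: float) -> float:
    """Hill number of order q for a probability vector ``p``.

    The q = 1 limit is handled explicitly as exp(Shannon entropy).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    total = p.sum()
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"probabilities sum to {total}, not 1")
    p = p[p > 0]
    if q < 0:
        raise ValueError("q must be >= 0")
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _lchoose(a, b):
    """log C(a, b), -inf where b > a; vectorised."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where(b > a, -np.inf, out)


def _f0_hat(f1: float, f2: float, n: int) -> float:
    """Bias-corrected Chao1 estimate of undetected richness."""
    k = (n - 1) / n
    if f2 > 0:
        return k * f1 * f1 / (2.0 * f2)
    return k * f1 * (f1 - 1) / 2.0


def _interp_richness(x: np.ndarray, n: int, m: int) -> float:
    # E[S_m] = sum_i [1 - C(n - x_i, m) / C(n, m)]
    with np.errstate(invalid="ignore"):
        logratio = _lchoose(n - x, m) - _lchoose(n, m)
    terms = 1.0 - np.where(np.isneginf(logratio), 0.0, np.exp(logratio))
    terms[n - x < m] = 1.0
    return float(terms.sum())


def _interp_shannon(x: np.ndarray, n: int, m: int) -> float:
    """Exact expected Shannon entropy of a size-m subsample.

    X_i,m is hypergeometric; E[H_m] = -sum_i E[(X/m) ln(X/m)] computed
    termwise over the support, grouped by distinct count values.
    """
    h = 0.0
    j_cache: dict[int, np.ndarray] = {}
    vals, mult = np.unique(x, return_counts=True)
    for xv, k in zip(vals, mult):
        hi = min(int(xv), m)
        lo = max(1, m - (n - int(xv)))
        j = j_cache.get((lo, hi))
        if j is None:
            j = np.arange(lo, hi + 1)
            j_cache[(lo, hi)] = j
        pmf = hypergeom.pmf(j, n, int(xv), m)
        frac = j / m
        h -= k * float(np.sum(pmf * frac * np.log(frac)))
    return h


def _shannon_asymptotic(x: np.ndarray, n: int) -> float:
    """Chao-Wang-Jost asymptotic (sample-size-free) Shannon entropy."""
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    part = float(np.sum((x / n) * (digamma(n) - digamma(x))))
    if f1 == 0:
        return part
    if f2 > 0:
        A = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    elif f1 > 1:
        A = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        A = 1.0
    if A >= 1.0:
        return part
    r = np.arange(1, n)
    series = float(np.sum((1.0 / r) * (1.0 - A) ** r))
    part += (f1 / n) * (1.0 - A) ** (1 - n) * (-np.log(A) - series)
    return part


def rarefy_abundance(counts, m: int, q: float = 0, strict: bool = True) -> HillEstimate:
    """Hill number of order q in {0, 1, 2} at sequence count ``m``.

    Interpolation (m < n) is exact under hypergeometric subsampling;
    extrapolation (m > n) is anchored on f1/f2.  With ``strict`` the 2n
    reliability cap on extrapolation is enforced.
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample")
    n = int(x.sum())
    m = int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    if strict and m > 2 * n:
        raise ValueError(f"extrapolation target {m} exceeds 2x reference size {2 * n}")
    if q not in (0, 1, 2):
        raise ValueError("pipeline estimators support q in {0, 1, 2}")

    if m == n:
        method = "observed"
    elif m < n:
        method = "interpolated"
    else:
        method = "extrapolated"

    if q == 2:
        # one unbiased formula covers interpolation, the observed point and
        # extrapolation; at m = n it reduces to the observed inverse Simpson
        s2 = float(np.sum(x * (x - 1.0)) / (n * (n - 1.0))) if n > 1 else 0.0
        denom = 1.0 / m + (1.0 - 1.0 / m) * s2
        est = 1.0 / denom
    elif q == 1:
        if m < n:
            est = float(np.exp(_interp_shannon(x, n, m)))
        else:
            h_obs = float(-np.sum((x / n) * np.log(x / n)))
            if m == n:
                est = float(np.exp(h_obs))
            else:
                h_inf = _shannon_asymptotic(x, n)
                mstar = m - n
                est = float(np.exp((n / m) * h_obs + (mstar / m) * max(h_inf, h_obs)))
    else:  # q == 0
        if m < n:
            est = _interp_richness(x, n, m)
        else:
            s_obs = float(x.size)
            if m == n:
                est = s_obs
            else:
                f1 = int((x == 1).sum())
                f2 = int((x == 2).sum())
                f0 = _f0_hat(f1, f2, n)
                if f0 <= 0 or f1 == 0:
                    est = s_obs
                else:
                    mstar = m - n
                    est = s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar)
    return HillEstimate(q=float(q), m=m, estimate=est, method=method)


def alpha_profile(
    table: AsvTable,
    m: int | None = None,
    qs=(0, 1, 2),
    strict: bool = True,
) -> pd.DataFrame:
    """Per-sample Hill estimates at a common size m (default 2x min depth).

    Returns a tidy frame with columns sample_id, q, m, estimate, method.
    """
    if table.n_samples == 0:
        raise ValueError("empty table")
    if m is None:
        m = int(2 * table.depths.min())
    rows = []
    counts = table.counts.to_numpy()
    for i, sid in enumerate(table.sample_ids):
        for q in qs:
            est = rarefy_abundance(counts[i], m, q=q, strict=strict)
            rows.append((sid, est.q, est.m, est.estimate, est.method))
    return pd.DataFrame(rows, columns=["sample_id", "q", "m", "estimate", "method"])


def rarefy_incidence(occurrence, t: int, strict: bool = True) -> HillEstimate:
    """Sample-based richness (q = 0) at ``t`` sampling units.

    ``occurrence`` is a samples x ASVs 0/1 matrix (T sampling units).
    Interpolation is exact; extrapolation beyond T uses the Chao2-type
    estimate of undetected richness from Q1, Q2.
    """
    occ = np.asarray(occurrence)
    if occ.ndim != 2:
        raise ValueError("occurrence must be a samples x ASVs matrix")
    occ = (occ > 0).astype(np.int64)
    T = occ.shape[0]
    y = occ.sum(axis=0)
    y = y[y > 0]
    t = int(t)
    if t < 1:
        raise ValueError("t must be >= 1")
    if strict and t > 2 * T:
        raise ValueError(f"extrapolation target {t} exceeds 2x sampling units {2 * T}")
    s_obs = float(y.size)
    if t == T:
        return HillEstimate(0.0, t, s_obs, "observed")
    if t < T:
        with np.errstate(invalid="ignore"):
            logratio = _lchoose(T - y, t) - _lchoose(T, t)
        terms = 1.0 - np.where(np.isneginf(logratio), 0.0, np.exp(logratio))
        terms[T - y < t] = 1.0
        return HillEstimate(0.0, t, float(terms.sum()), "interpolated")
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    k = (T - 1) / T
    q0 = k * q1 * q1 / (2.0 * q2) if q2 > 0 else k * q1 * (q1 - 1) / 2.0
    if q0 <= 0 or q1 == 0:
        est = s_obs
    else:
        tstar = t - T
        est = s_obs + q0 * (1.0 - (1.0 - q1 / (T * q0 + q1)) ** tstar)
    return HillEstimate(0.0, t, est, "extrapolated")


def incidence_curve(occurrence, t_grid=None, extrapolate_factor: int = 2) -> RarefactionCurve:
    """Occurrence-based rarefaction/extrapolation curve for richness."""
    occ = np.asarray(occurrence)
    T = occ.shape[0]
    if t_grid is None:
        t_grid = np.arange(1, extrapolate_factor * T + 1)
    t_grid = np.asarray(t_grid, dtype=int)
    est = np.array([rarefy_incidence(occ, int(t)).estimate for t in t_grid])
    return RarefactionCurve("incidence", 0.0, t_grid, est, T)


def gamma_curves(
    table: AsvTable,
    replicate_ids,
    transect_id_sets,
    extrapolate_factor: int = 2,
) -> tuple[RarefactionCurve, RarefactionCurve]:
    """Gamma rarefaction for the replicate pool and the averaged transect sets.

    The replicate curve accumulates its full sample pool (t up to 2x its
    size); each transect combination is rarefied on a common grid and the
    curves averaged pointwise, mirroring an averaged bootstrap curve.
    """
    replicate_ids = list(replicate_ids)
    transect_id_sets = [list(s) for s in transect_id_sets]
    if not transect_id_sets:
        raise ValueError("no transect datasets given")
    sizes = {len(s) for s in transect_id_sets}
    if len(sizes) != 1:
        raise ValueError(f"transect datasets differ in size: {sorted(sizes)}")
    known = set(table.sample_ids)
    for s in transect_id_sets + [replicate_ids]:
        missing = set(s) - known
        if missing:
            raise ValueError(f"sample ids not in table: {sorted(missing)}")

    occ_all = table.occurrence()
    rep_curve = incidence_curve(occ_all.loc[replicate_ids].to_numpy(), None, extrapolate_factor)

    t_len = sizes.pop()
    grid = np.arange(1, extrapolate_factor * t_len + 1)
    acc = np.zeros(grid.size)
    for ids in transect_id_sets:
        acc += incidence_curve(occ_all.loc[ids].to_numpy(), grid).estimates
    mean_curve = RarefactionCurve(
        "incidence", 0.0, grid, acc / len(transect_id_sets), t_len
    )
    return rep_curve, mean_curve
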