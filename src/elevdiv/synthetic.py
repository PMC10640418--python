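"""Synthetic elevation-gradient communities with known ground truth.

The generator emulates the sampling design the pipeline targets: 16
elevation bands between 400 and 2260 m a.s.l., six of them (500, 900, 1300,
1620, 1940, 2260 m) carrying five replicate plots each, the rest a single
plot — 40 samples in total.  Communities follow a coenocline: each species
in the pool has an elevation optimum and a Gaussian response curve, so
composition turns over deterministically along the gradient while replicate
plots within a band differ only by lognormal overdispersion.  Realised
expected richness follows a configured linear decline with elevation, read
counts are multinomial draws at lognormal depths with a fixed floor, and the
environment table carries a four-variable organic-matter block driven by a
single elevation-linked latent factor (pairwise correlations calibrated
above a target), plus pH and P on separate latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_data import AsvTable, EnvTable, SampleMeta

__all__ = ["SimulationConfig", "GroundTruth", "simulate_community", "simulate_env_block"]

STUDY_BAND_ELEVATIONS = (
    400, 500, 600, 700, 800, 900, 1000, 1100, 1200, 1300,
    1460, 1620, 1780, 1940, 2100, 2260,
)
STUDY_REPLICATED_BANDS = (500, 900, 1300, 1620, 1940, 2260)


@dataclass
class SimulationConfig:
    """Study-design and generative parameters.

    Defaults reproduce the two-strategy elevational design: replicate
    strategy = 5 plots x 6 bands, transect strategy = 1 plot x 16 bands,
    sharing samples at the replicated bands.
    """

    band_elevations_m: tuple = STUDY_BAND_ELEVATIONS
    replicated_bands: tuple = STUDY_REPLICATED_BANDS
    n_replicates: int = 5
    treeline_m: float = 1400.0
    #: true expected richness at elevation e is intercept + slope * e
    richness_intercept: float = 450.0
    richness_slope: float = -0.12
    #: sd (m) of the Gaussian species response along elevation
    niche_breadth_m: float = 300.0
    #: concentration of replicate plots around the band expectation;
    #: log-abundance jitter sd = 1/sqrt(concentration); inf = no jitter
    within_band_dispersion: float = 6.0
    #: lognormal sequencing depth; floor mirrors a minimum usable depth
    depth_log_mean: float = 9.2
    depth_log_sd: float = 0.45
    min_depth: int = 3834
    n_species_pool: int = 3000
    #: per-species lognormal commonness spread (0 = perfectly even pool)
    commonness_sd: float = 0.3
    env_block_correlation: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.env_block_correlation < 1):
            raise ValueError("env_block_correlation must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if not np.isfinite(self.richness_slope) or not np.isfinite(self.niche_breadth_m):
            raise ValueError("slope and niche breadth must be finite")
        need = max(
            self.true_richness(e) for e in self.band_elevations_m
        )
        if self.n_species_pool < need:
            raise ValueError("species pool smaller than max expected richness")
        missing = set(self.replicated_bands) - set(self.band_elevations_m)
        if missing:
            raise ValueError(f"replicated bands not in band list: {sorted(missing)}")

    def true_richness(self, elevation_m: float) -> int:
        return max(5, int(round(self.richness_intercept + self.richness_slope * elevation_m)))


@dataclass
class GroundTruth:
    """Generative parameters recorded for parameter-recovery tests."""

    richness_intercept: float
    richness_slope: float
    niche_breadth_m: float
    #: initial rate of expected Bray-Curtis increase per metre of elevation
    #: separation, measured on the noise-free band expectations
    turnover_per_m: float
    env_coefficients: dict = field(default_factory=dict)
    species_optima: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("species_optima")
        return d


# Table-style scales (mean, sd) for the organic-matter block and the other
# soil variables; units as in a soil physicochemistry table: WC fraction,
# SOM %, TON/TOC/P mg per g.
_OM_SCALES = {"SOM": (55.0, 28.0), "TOC": (2.8, 1.5), "TON": (0.13, 0.065), "WC": (0.055, 0.025)}


def simulate_env_block(
    n: int,
    target_r: float,
    seed,
    latent: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Four collinear organic-matter variables from one shared latent.

    Each column is an affine transform of the latent plus independent noise.
    The noise sd is calibrated so the population pairwise correlation is
    target_r + 0.3*(1 - target_r), leaving finite-sample correlations above
    target_r - 0.02 at n >= 30.  ``noise_sd`` overrides the calibration.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if not (0 < target_r < 1):
        raise ValueError("target correlation must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if latent is None:
        latent = rng.standard_normal(n)
    latent = np.asarray(latent, dtype=float)
    z = (latent - latent.mean()) / latent.std()
    if noise_sd is None:
        r_pop = target_r + 0.3 * (1.0 - target_r)
        noise_sd = float(np.sqrt(1.0 / r_pop - 1.0))
    cols = {}
    for name, (mu, sd) in _OM_SCALES.items():
        obs = z + noise_sd * rng.standard_normal(n)
        cols[name] = mu + sd * obs
    return pd.DataFrame(cols), latent


def _om_latent(elev: np.ndarray, treeline: float) -> np.ndarray:
    # organic matter high through the forest, collapsing above the treeline
    return 1.0 / (1.0 + np.exp((elev - (treeline + 150.0)) / 130.0))


def _band_expectation(cfg: SimulationConfig, optima: np.ndarray,
                      commonness: np.ndarray, elevation: float) -> np.ndarray:
    """Expected relative abundances at one band (coenocline + thinning)."""
    w = np.exp(-((elevation - optima) ** 2) / (2.0 * cfg.niche_breadth_m**2))
    s_target = cfg.true_richness(elevation)
    keep = np.argsort(w)[::-1][:s_target]
    p = np.zeros_like(w)
    p[keep] = w[keep] * commonness[keep]
    return p / p.sum()


def _expected_bray_curtis(pa: np.ndarray, pb: np.ndarray) -> float:
    return float(np.abs(pa - pb).sum() / (pa + pb).sum())


def simulate_community(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[AsvTable, SampleMeta, EnvTable, GroundTruth]:
    """Draw one full synthetic dataset (counts, metadata, environment, truth)."""
    cfg = config or SimulationConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    elevs = np.array(sorted(cfg.band_elevations_m), dtype=float)
    sigma = cfg.niche_breadth_m
    lo, hi = elevs.min() - 2 * sigma, elevs.max() + 2 * sigma
    optima = np.linspace(lo, hi, cfg.n_species_pool)
    optima = optima + rng.uniform(-0.4, 0.4, cfg.n_species_pool) * (optima[1] - optima[0])
    commonness = np.exp(cfg.commonness_sd * rng.standard_normal(cfg.n_species_pool))

    band_p = {e: _band_expectation(cfg, optima, commonness, e) for e in elevs}

    if np.isinf(cfg.within_band_dispersion):
        jitter_sd = 0.0
    else:
        jitter_sd = 1.0 / np.sqrt(cfg.within_band_dispersion)

    sample_rows = []
    meta_rows = []
    for e in elevs:
        n_rep = cfg.n_replicates if e in set(map(float, cfg.replicated_bands)) else 1
        band = f"B{int(e)}"
        for r in range(n_rep):
            sid = f"{band}_r{r + 1}" if n_rep > 1 else band
            p = band_p[e].copy()
            if jitter_sd > 0:
                mask = p > 0
                logp = np.log(p[mask]) + jitter_sd * rng.standard_normal(mask.sum())
                p[mask] = np.exp(logp)
                p /= p.sum()
            depth = max(cfg.min_depth, int(round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))))
            counts = rng.multinomial(depth, p)
            sample_rows.append((sid, counts))
            meta_rows.append((sid, e, band))

    sids = [r[0] for r in sample_rows]
    mat = np.vstack([r[1] for r in sample_rows])
    present = mat.sum(axis=0) > 0
    asv_ids = [f"ASV{i:05d}" for i in np.flatnonzero(present)]
    counts = pd.DataFrame(mat[:, present], index=sids, columns=asv_ids)
    table = AsvTable(counts)

    meta = SampleMeta(
        pd.DataFrame(
            {"elevation_m": [r[1] for r in meta_rows], "band_id": [r[2] for r in meta_rows]},
            index=pd.Index(sids, name="sample_id"),
        ),
        treeline_m=cfg.treeline_m,
    )

    # --- environment ------------------------------------------------------
    sample_elev = np.array([r[1] for r in meta_rows])
    om_latent = _om_latent(sample_elev, cfg.treeline_m)
    om_latent = om_latent + 0.03 * rng.standard_normal(om_latent.size)
    om_block, _ = simulate_env_block(
        len(sids), cfg.env_block_correlation, rng, latent=om_latent
    )
    om_block.index = pd.Index(sids, name="sample_id")
    # keep the block physically plausible without breaking correlations much
    om_block["WC"] = om_block["WC"].clip(lower=0.004)
    om_block["SOM"] = om_block["SOM"].clip(lower=1.0)
    om_block["TOC"] = om_block["TOC"].clip(lower=0.05)
    om_block["TON"] = om_block["TON"].clip(lower=0.005)

    ph_coef = {"base": 4.1, "amp": 1.9, "scale": 750.0, "noise": 0.18}
    ph = (
        ph_coef["base"]
        + ph_coef["amp"] * np.exp(-sample_elev / ph_coef["scale"])
        + ph_coef["noise"] * rng.standard_normal(len(sids))
    )
    p_coef = {"log_mean": np.log(0.022), "elev_slope": -2.2e-4, "log_sd": 0.5}
    p_var = np.exp(
        p_coef["log_mean"]
        + p_coef["elev_slope"] * (sample_elev - 400.0)
        + p_coef["log_sd"] * rng.standard_normal(len(sids))
    )

    env = pd.DataFrame(
        {
            "WC": om_block["WC"],
            "SOM": om_block["SOM"],
            "pH": np.clip(ph, 3.0, 8.5),
            "TON": om_block["TON"],
            "TOC": om_block["TOC"],
            "C_N": om_block["TOC"] / om_block["TON"],
            "P": p_var,
            "N_P": om_block["TON"] / p_var,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    env_table = EnvTable(env)

    # --- ground truth -----------------------------------------------------
    adjacent = [
        _expected_bray_curtis(band_p[a], band_p[b]) / (b - a)
        for a, b in zip(elevs[:-1], elevs[1:])
    ]
    truth = GroundTruth(
        richness_intercept=cfg.richness_intercept,
        richness_slope=cfg.richness_slope,
        niche_breadth_m=cfg.niche_breadth_m,
        turnover_per_m=float(np.mean(adjacent)),
        env_coefficients={
            "om_target_r": cfg.env_block_correlation,
            "pH": ph_coef,
            "P": p_coef,
        },
        species_optima=optima,
    )
    return table, meta, env_table, truth
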