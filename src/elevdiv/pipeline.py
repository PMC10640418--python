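"""End-to-end orchestration of the strategy-comparison analysis.

``run_full`` executes: data loading (or simulation) -> micro-eukaryote
filtering -> Hill-number alpha diversity at a common rarefaction target ->
elevational regressions for the replicate strategy and the bootstrap of
transect combinations (with ANCOVA slope comparison) -> gamma rarefaction
curves for both strategies -> Bray-Curtis beta diversity (PCoA, PERMANOVA
per strategy, elevation decay per habitat) -> environmental RDA with
stepwise selection, hierarchical partitioning and bootstrap selection
frequencies.  Every output is written as TSV/JSON into ``out_dir`` together
with a manifest that records config and seeds, sufficient to reproduce the
bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha_regression import compare_slopes_ancova, fit_elevation_trend
from .beta import bray_curtis, elevation_decay, pcoa, permanova
from .bootstrap import aggregate, draw_combinations
from .core_data import (
    DEFAULT_EXCLUDE_LINEAGES,
    AsvTable,
    EnvTable,
    SampleMeta,
    filter_microeukaryotes,
    hellinger,
    read_asv_table,
    read_env_table,
    read_sample_meta,
    to_relative,
    write_asv_table,
    write_env_table,
    write_sample_meta,
)
from .env_rda import build_design, hierarchical_partition, rda_over_bootstrap, select_predictors, vif
from .hill import alpha_profile, gamma_curves
from .synthetic import SimulationConfig, simulate_community

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full"]

_STAGES = ("simulate", "combinations", "permanova", "rda", "rda_bootstrap")


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    meta_path: str | None = None
    env_path: str | None = None
    simulate: SimulationConfig | None = None
    out_dir: str = "elevdiv_run"
    n_boot: int = 1000
    qs: tuple = (0, 1, 2)
    #: sequences per sample for alpha rarefaction; None = 2x min depth
    rarefaction_target: int | None = None
    n_perm: int = 999
    #: cheaper permutation count inside the per-combination selection loop
    n_perm_selection: int = 199
    alpha: float = 0.05
    seed: int = 0
    bh_correct: bool = True
    treeline_m: float = 1400.0
    exclude_lineages: tuple = DEFAULT_EXCLUDE_LINEAGES

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.rarefaction_target is not None and self.rarefaction_target < 1:
            raise ValueError("rarefaction target must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            )
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the master seed."""
        idx = _STAGES.index(stage)
        return int(
            np.random.SeedSequence([int(self.seed), idx]).generate_state(1)[0] % (2**31)
        )


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        table, meta, env, truth = simulate_community(cfg.simulate, seed=cfg.stage_seed("simulate"))
        return table, meta, env, truth
    if cfg.counts_path is None or cfg.meta_path is None:
        raise ValueError("either counts_path+meta_path or a simulate block is required")
    table = read_asv_table(cfg.counts_path)
    meta = read_sample_meta(cfg.meta_path, cfg.treeline_m)
    env = read_env_table(cfg.env_path) if cfg.env_path else None
    return table, meta, env, None


def _alpha_stage(cfg, table, meta, combos, out):
    prof = alpha_profile(table, m=cfg.rarefaction_target, qs=cfg.qs)
    prof.to_csv(out / "alpha_estimates.tsv", sep="\t", index=False)

    rep_ids = list(meta.frame.index[meta.frame["is_replicated_band"]])
    elev = meta.frame["elevation_m"]
    table2_rows = []
    for q in cfg.qs:
        est = prof[prof["q"] == q].set_index("sample_id")["estimate"]
        rep_fit = fit_elevation_trend(est.loc[rep_ids], meta, q=q, strategy="replicate")
        records = []
        for combo in combos:
            ids = list(combo.sample_ids)
            tr_fit = fit_elevation_trend(est.loc[ids], meta, q=q, strategy="transect")
            anc = compare_slopes_ancova(
                (elev.loc[rep_ids].to_numpy(), est.loc[rep_ids].to_numpy()),
                (elev.loc[ids].to_numpy(), est.loc[ids].to_numpy()),
            )
            records.append(
                {"slope": tr_fit.slope, "p": tr_fit.p_value, "ancova_p": anc}
            )
        records = pd.DataFrame(records)
        if cfg.bh_correct:
            summ = aggregate(records, p_fields=("p", "ancova_p"), coef_fields=("slope",))
            tr_p, anc_p = summ.p_corrected_mean["p"], summ.p_corrected_mean["ancova_p"]
        else:
            summ = aggregate(records, coef_fields=("slope",))
            tr_p, anc_p = float(records["p"].mean()), float(records["ancova_p"].mean())
        table2_rows.append(
            {
                "q": q,
                "replicate_slope": rep_fit.slope,
                "replicate_slope_se": rep_fit.slope_se,
                "replicate_p": rep_fit.p_value,
                "transect_slope_mean": summ.coef_mean["slope"],
                "transect_slope_sd": summ.coef_sd["slope"],
                "transect_p": tr_p,
                "ancova_p": anc_p,
            }
        )
    table2 = pd.DataFrame(table2_rows)
    table2.to_csv(out / "alpha_slopes.tsv", sep="\t", index=False)
    return prof, table2


def _beta_stage(cfg, table, meta, combos, out):
    hel = hellinger(to_relative(table))
    dm = bray_curtis(hel)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "bray_curtis.tsv", sep="\t", index_label="sample_id"
    )

    ord_res = pcoa(dm)
    ord_res.samples.to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
    ord_res.eigvals.to_frame("eigenvalue").to_csv(out / "pcoa_eigenvalues.tsv", sep="\t")

    rep_ids = list(meta.frame.index[meta.frame["is_replicated_band"]])
    seed = cfg.stage_seed("permanova")
    perm_rep = permanova(dm.filter(rep_ids), meta, n_perm=cfg.n_perm, seed=seed)
    perm_rep.table.to_csv(out / "permanova_replicate.tsv", sep="\t")

    terms = ["elevation", "habitat", "elevation:habitat"]
    recs = []
    ss = np.random.SeedSequence([seed, 1])
    children = ss.generate_state(len(combos)) % (2**31)
    for combo, child in zip(combos, children):
        res = permanova(dm.filter(list(combo.sample_ids)), meta, n_perm=cfg.n_perm, seed=int(child))
        recs.append(
            {
                f"{which}_{t}": res.table.loc[t, col]
                for t in terms
                for which, col in (("R2", "R2"), ("F", "F"), ("p", "p"))
            }
        )
    recs = pd.DataFrame(recs)
    p_fields = tuple(f"p_{t}" for t in terms)
    coef_fields = tuple(f"{w}_{t}" for t in terms for w in ("R2", "F"))
    summ = aggregate(recs, p_fields=p_fields if cfg.bh_correct else (), coef_fields=coef_fields)
    rows = []
    for t in terms:
        rows.append(
            {
                "term": t,
                "R2_mean": summ.coef_mean[f"R2_{t}"],
                "R2_sd": summ.coef_sd[f"R2_{t}"],
                "F_mean": summ.coef_mean[f"F_{t}"],
                "p_corrected_mean": summ.p_corrected_mean.get(f"p_{t}", float(recs[f"p_{t}"].mean())),
            }
        )
    perm_tr = pd.DataFrame(rows).set_index("term")
    perm_tr.to_csv(out / "permanova_transect_mean.tsv", sep="\t")

    decays = {}
    for habitat in ("forest", "alpine"):
        try:
            res = elevation_decay(dm, meta, habitat)
        except ValueError as exc:
            logger.warning("elevation decay skipped for %s: %s", habitat, exc)
            continue
        res.pairs.to_csv(out / f"decay_pairs_{habitat}.tsv", sep="\t", index=False)
        if res.tukey_vs_within is not None:
            res.tukey_vs_within.to_csv(out / f"decay_tukey_{habitat}.tsv", sep="\t", index=False)
        decays[habitat] = res
    return hel, dm, perm_rep, perm_tr, decays


def _gamma_stage(cfg, table, meta, combos, out):
    rep_ids = list(meta.frame.index[meta.frame["is_replicated_band"]])
    rep_curve, tr_curve = gamma_curves(
        table, rep_ids, [list(c.sample_ids) for c in combos]
    )
    frames = []
    for label, curve in (("replicate", rep_curve), ("transect_mean", tr_curve)):
        f = curve.as_frame()
        f.insert(0, "strategy", label)
        frames.append(f)
    gamma = pd.concat(frames, ignore_index=True)
    gamma.to_csv(out / "gamma_curves.tsv", sep="\t", index=False)
    return rep_curve, tr_curve


def _env_stage(cfg, hel, meta, env, combos, out):
    vif_table = vif(env.frame)
    vif_table.to_frame("VIF").to_csv(out / "vif.tsv", sep="\t")
    design = build_design(env, meta.frame)
    design.to_csv(out / "env_design.tsv", sep="\t", index_label="sample_id")

    seed = cfg.stage_seed("rda")
    rep_ids = list(meta.frame.index[meta.frame["is_replicated_band"]])
    sel = select_predictors(
        hel.loc[rep_ids], design.loc[rep_ids], alpha=cfg.alpha, n_perm=cfg.n_perm, seed=seed
    )
    rep_result = {
        "selected": sel.selected,
        "adj_r2": sel.adj_r_squared,
        "path": sel.path,
    }
    if sel.selected:
        hp = hierarchical_partition(hel.loc[rep_ids], design.loc[rep_ids, sel.selected])
        hp.to_csv(out / "hp_replicate.tsv", sep="\t")
        rep_result["full_adj_r2"] = hp.attrs["full_adj_r2"]
    with open(out / "rda_replicate.json", "w") as fh:
        json.dump(rep_result, fh, indent=2, sort_keys=True)

    datasets = (
        (hel.loc[list(c.sample_ids)], design.loc[list(c.sample_ids)]) for c in combos
    )
    summary, records = rda_over_bootstrap(
        datasets, alpha=cfg.alpha, n_perm=cfg.n_perm_selection,
        seed=cfg.stage_seed("rda_bootstrap"),
    )
    summary.to_csv(out / "rda_transect_frequencies.tsv", sep="\t", index=False)
    records.to_csv(out / "rda_transect_records.tsv", sep="\t", index=False)
    return rep_result, summary


def run_full(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, meta, env, truth = _load_inputs(cfg)
    if table.taxonomy is not None and cfg.exclude_lineages:
        table = filter_microeukaryotes(table, cfg.exclude_lineages)
    if cfg.simulate is not None:
        write_asv_table(table, out / "counts.tsv")
        write_sample_meta(meta, out / "metadata.tsv")
        if env is not None:
            write_env_table(env, out / "environment.tsv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)

    combos = draw_combinations(meta, cfg.n_boot, cfg.stage_seed("combinations"))

    prof, table2 = _alpha_stage(cfg, table, meta, combos, out)
    rep_curve, tr_curve = _gamma_stage(cfg, table, meta, combos, out)
    hel, dm, perm_rep, perm_tr, decays = _beta_stage(cfg, table, meta, combos, out)

    rda_rep = rda_freq = None
    if env is not None:
        rda_rep, rda_freq = _env_stage(cfg, hel, meta, env, combos, out)
    else:
        logger.warning("no environment table: env RDA stage skipped")

    manifest = {
        "package_version": __version__,
        # out_dir is where the bundle lands, not part of the analysis: two
        # runs into different directories must produce identical bundles
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k != "out_dir"
        },
        "stage_seeds": {s: PipelineConfig.stage_seed(cfg, s) for s in _STAGES},
        "n_samples": table.n_samples,
        "n_asvs": table.n_asvs,
        "rarefaction_target": int(prof["m"].iloc[0]),
        "degenerate_sd": cfg.n_boot < 2,
    }
    blob = json.dumps(manifest, sort_keys=True, default=str)
    manifest["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "table": table,
        "meta": meta,
        "env": env,
        "truth": truth,
        "alpha_profile": prof,
        "alpha_slopes": table2,
        "gamma_replicate": rep_curve,
        "gamma_transect_mean": tr_curve,
        "distance_matrix": dm,
        "permanova_replicate": perm_rep,
        "permanova_transect_mean": perm_tr,
        "decays": decays,
        "rda_replicate": rda_rep,
        "rda_frequencies": rda_freq,
        "manifest": manifest,
    }
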