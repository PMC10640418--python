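"""Transect-strategy bootstrap: sample combinations and aggregation.

The replicate strategy observes several plots per replicated band; the
transect strategy keeps a single plot per band.  Because the replicated
bands offer a choice of plot, the single-plot design is realised many times
by randomly picking one replicate per replicated band (with replacement
across combinations) together with all singleton-band samples.  Any
per-dataset statistic can then be aggregated across combinations:
coefficients are averaged (+/- SD), p-values are Benjamini-Hochberg
corrected across the combinations of each named field and then averaged,
and categorical outcomes (e.g. selected variable sets) are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_data import SampleMeta

__all__ = ["StrategyCombination", "BootstrapSummary", "draw_combinations", "aggregate"]


@dataclass(frozen=True)
class StrategyCombination:
    """One single-plot-per-band realisation of the transect design."""

    index: int
    sample_ids: tuple[str, ...]


@dataclass
class BootstrapSummary:
    n_boot: int
    coef_mean: dict = field(default_factory=dict)
    coef_sd: dict = field(default_factory=dict)
    p_corrected_mean: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    #: provenance of the correction family: BH is applied across the n_boot
    #: values of each named p-field, then averaged
    bh_family: str = "per-field across combinations"


def draw_combinations(meta: SampleMeta, n_boot: int, seed) -> list[StrategyCombination]:
    """Draw ``n_boot`` transect combinations: one sample per band, uniformly.

    Bands appear in elevation order within each combination.  Drawing is
    with replacement across combinations (the product space is much larger
    than typical n_boot, so collisions are rare).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    bands = meta.band_samples()  # ordered by elevation
    for band, sids in bands.items():
        if not sids:
            raise ValueError(f"band {band} has no samples")
    combos = []
    for i in range(n_boot):
        chosen = tuple(
            sids[rng.integers(len(sids))] if len(sids) > 1 else sids[0]
            for sids in bands.values()
        )
        combos.append(StrategyCombination(index=i, sample_ids=chosen))
    return combos


def aggregate(
    records: pd.DataFrame,
    p_fields=(),
    coef_fields=(),
    categorical_fields=(),
) -> BootstrapSummary:
    """Summarise per-combination statistic records.

    coef fields -> mean and SD; each p field -> BH step-up correction across
    the records of that field, then arithmetic mean; categorical fields ->
    value counts (summing to the number of records).
    """
    missing = [f for f in (*p_fields, *coef_fields, *categorical_fields) if f not in records]
    if missing:
        raise KeyError(f"missing fields in records: {missing}")
    out = BootstrapSummary(n_boot=len(records))
    for f in coef_fields:
        vals = records[f].to_numpy(dtype=float)
        out.coef_mean[f] = float(vals.mean())
        out.coef_sd[f] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    for f in p_fields:
        vals = records[f].to_numpy(dtype=float)
        adj = multipletests(vals, method="fdr_bh")[1]
        out.p_corrected_mean[f] = float(adj.mean())
    for f in categorical_fields:
        out.frequencies[f] = records[f].value_counts().to_dict()
    return out
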