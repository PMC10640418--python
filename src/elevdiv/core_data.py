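"""Data model, file I/O, and community-matrix transformations.

The central object is the :class:`AsvTable`, a samples x ASVs matrix of
non-negative integer sequence counts in which amplicon sequence variants
(ASVs) stand in for species and read counts for abundances.  Sample-level
context lives in :class:`SampleMeta` (elevation, habitat, elevation band,
replication status) and :class:`EnvTable` (soil physicochemistry).

On disk, count tables follow the common amplicon convention of ASVs as rows
and samples as columns; in memory everything is oriented samples x ASVs so
that per-sample operations are row-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Elevation (m a.s.l.) separating forest from alpine habitat.
DEFAULT_TREELINE_M = 1400.0

#: Soil physicochemical variables expected in an environment table.
ENV_COLUMNS = ("WC", "SOM", "pH", "TON", "TOC", "C_N", "P", "N_P")

#: The collinear organic-matter block collapsed to one PCA axis downstream.
OM_BLOCK = ("SOM", "TOC", "TON", "WC")

#: Lineage prefixes removed by default when restricting to micro-eukaryotes:
#: multicellular animals and land plants.
DEFAULT_EXCLUDE_LINEAGES = ("Metazoa", "Embryophyceae", "Streptophyta")


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvTable:
    """Samples x ASVs count matrix with optional per-ASV taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per ASV id; entries
        are non-negative integers (read counts).
    taxonomy
        Optional Series indexed by ASV id giving a semicolon-separated
        lineage string per ASV.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise DataError("duplicate sample ids: %s" % sorted(c.index[c.index.duplicated()]))
        if c.columns.has_duplicates:
            raise DataError("duplicate ASV ids: %s" % sorted(c.columns[c.columns.duplicated()]))
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise DataError("counts must be integers")
            self.counts = c = c.astype(np.int64)
            values = c.to_numpy()
        if (values < 0).any():
            bad = c.index[(values < 0).any(axis=1)][0]
            raise DataError(f"negative count in sample {bad!r}")
        empties = c.index[values.sum(axis=1) == 0]
        if len(empties):
            raise DataError(f"sample(s) with zero total count: {list(empties)}")
        c.index.name = None
        c.columns.name = None
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Total sequence count per sample."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "AsvTable":
        """Restrict to ``sample_ids`` (order preserved), dropping ASVs absent everywhere."""
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise DataError(f"unknown sample ids: {missing}")
        sub = self.counts.loc[list(sample_ids)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        tax = self.taxonomy.loc[sub.columns] if self.taxonomy is not None else None
        return AsvTable(sub, tax)

    def occurrence(self) -> pd.DataFrame:
        """Presence/absence (0/1) view of the counts."""
        return (self.counts > 0).astype(np.int8)


@dataclass
class SampleMeta:
    """Per-sample design metadata.

    ``frame`` is indexed by sample id with columns ``elevation_m`` (float),
    ``habitat`` ('forest'/'alpine'), ``band_id`` (label shared by samples at
    one nominal elevation) and ``is_replicated_band`` (bool).  Habitat may be
    derived from elevation via the treeline or supplied explicitly (explicit
    labels win).
    """

    frame: pd.DataFrame
    treeline_m: float = DEFAULT_TREELINE_M

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise DataError("duplicate sample ids in metadata")
        required = {"elevation_m", "band_id"}
        if not required.issubset(f.columns):
            raise DataError(f"metadata must contain columns {sorted(required)}")
        f = f.copy()
        f["elevation_m"] = f["elevation_m"].astype(float)
        if "habitat" not in f.columns or f["habitat"].isna().all():
            f["habitat"] = np.where(f["elevation_m"] < self.treeline_m, "forest", "alpine")
        bad = set(f["habitat"]) - {"forest", "alpine"}
        if bad:
            raise DataError(f"unknown habitat labels: {sorted(bad)}")
        sizes = f.groupby("band_id").size()
        f["is_replicated_band"] = f["band_id"].map(sizes > 1)
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def band_samples(self) -> dict[str, list[str]]:
        """Sample ids per band, bands ordered by elevation."""
        f = self.frame.sort_values("elevation_m")
        out: dict[str, list[str]] = {}
        for sid, band in f["band_id"].items():
            out.setdefault(band, []).append(sid)
        return out

    def replicated_bands(self) -> list[str]:
        f = self.frame
        return sorted(
            f.loc[f["is_replicated_band"], "band_id"].unique(),
            key=lambda b: f.loc[f["band_id"] == b, "elevation_m"].iloc[0],
        )

    def band_elevation(self, band_id: str) -> float:
        return float(self.frame.loc[self.frame["band_id"] == band_id, "elevation_m"].iloc[0])

    def subset(self, sample_ids) -> "SampleMeta":
        return SampleMeta(self.frame.loc[list(sample_ids)].copy(), self.treeline_m)


@dataclass
class EnvTable:
    """Per-sample soil physicochemical variables.

    Columns: WC (water content, fraction), SOM (soil organic matter, %), pH,
    TON (total organic nitrogen, mg/g), TOC (total organic carbon, mg/g),
    C_N (carbon:nitrogen ratio), P (bioavailable phosphorus, mg/g),
    N_P (nitrogen:phosphorus ratio).
    """

    frame: pd.DataFrame
    ratio_rtol: float = field(default=0.05, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ENV_COLUMNS if c not in f.columns]
        if missing:
            raise DataError(f"environment table missing columns: {missing}")
        f = f[list(ENV_COLUMNS)].astype(float)
        if not np.isfinite(f.to_numpy()).all():
            raise DataError("non-finite value in environment table")
        if ((f["pH"] <= 0) | (f["pH"] >= 14)).any():
            raise DataError("pH out of (0, 14)")
        self.frame = f

    def check_ratio_consistency(self) -> bool:
        """True if C_N ~ TOC/TON and N_P ~ TON/P within relative tolerance."""
        f = self.frame
        ok_cn = np.allclose(f["C_N"], f["TOC"] / f["TON"], rtol=self.ratio_rtol)
        ok_np = np.allclose(f["N_P"], f["TON"] / f["P"], rtol=self.ratio_rtol)
        return bool(ok_cn and ok_np)

    def subset(self, sample_ids) -> "EnvTable":
        return EnvTable(self.frame.loc[list(sample_ids)].copy(), self.ratio_rtol)


# ---------------------------------------------------------------------------
# I/O

def read_asv_table(path, taxonomy_column: str = "taxonomy") -> AsvTable:
    """Read a TSV count table (ASVs as rows, samples as columns).

    A trailing column named ``taxonomy`` (configurable) is split off as the
    per-ASV lineage.  Counts are validated against the AsvTable invariants.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None and df.shape[1] == 0:
        raise DataError(f"{path}: malformed header")
    taxonomy = None
    if taxonomy_column in df.columns:
        taxonomy = df.pop(taxonomy_column).astype(str)
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: non-numeric count ({exc})") from exc
    table = AsvTable(counts.T, taxonomy)
    logger.info("read_asv_table: %d samples x %d ASVs from %s",
                table.n_samples, table.n_asvs, path)
    return table


def write_asv_table(table: AsvTable, path) -> None:
    """Write a table in the same orientation ``read_asv_table`` expects."""
    out = table.counts.T
    if table.taxonomy is not None:
        out = out.assign(taxonomy=table.taxonomy)
    out.to_csv(path, sep="\t", index_label="asv_id")


def read_sample_meta(path, treeline_m: float = DEFAULT_TREELINE_M) -> SampleMeta:
    """Read a sample metadata TSV (columns sample_id, elevation_m, [habitat], band_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"band_id": str})
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing sample_id column")
    return SampleMeta(df.set_index("sample_id"), treeline_m)


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing sample_id column")
    return EnvTable(df.set_index("sample_id"))


def write_env_table(env: EnvTable, path) -> None:
    env.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Transformations

def filter_microeukaryotes(
    table: AsvTable,
    exclude_lineages: tuple[str, ...] = DEFAULT_EXCLUDE_LINEAGES,
) -> AsvTable:
    """Drop ASVs whose lineage contains any excluded taxon prefix.

    A lineage matches if any of its semicolon-separated components starts
    with one of the ``exclude_lineages`` prefixes.  The default removes
    multicellular animals and land plants, leaving micro-eukaryotes.
    """
    if not exclude_lineages:
        return table
    if table.taxonomy is None:
        raise DataError(
            "table has no taxonomy; skip filter_microeukaryotes or attach lineages"
        )

    def excluded(lineage: str) -> bool:
        parts = [p.strip() for p in str(lineage).split(";")]
        return any(p.startswith(pref) for p in parts for pref in exclude_lineages)

    mask = ~table.taxonomy.fillna("").map(excluded)
    kept = table.counts.loc[:, mask.to_numpy()]
    removed = table.n_asvs - kept.shape[1]
    logger.info("filter_microeukaryotes: kept %d ASVs, removed %d", kept.shape[1], removed)
    if kept.shape[1] == 0:
        raise DataError("all ASVs excluded by lineage filter")
    return AsvTable(kept, table.taxonomy[mask])


def to_relative(table: AsvTable) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise DataError("sample with zero total count")
    return pd.DataFrame(counts / totals, index=table.counts.index, columns=table.counts.columns)


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of row-normalised abundances.

    For each row i: y_ij = sqrt(x_ij / sum_j x_ij), so squared entries sum
    to 1 per row.  Applying it to proportions or to raw counts gives the
    same result.
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise DataError("negative entry passed to hellinger")
    rowsum = x.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise DataError("zero row passed to hellinger")
    out = np.sqrt(x / rowsum)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
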