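"""Data model and I/O: OTU tables, environment tables, networks, distance matrices.

Tables are thin dataclasses around pandas DataFrames with the validation the
downstream analyses rely on (unique ids, non-negative abundances, bounded
environmental variables).  Distance matrices use
:class:`skbio.stats.distance.DistanceMatrix`, which enforces symmetry, a zero
diagonal and unique ids.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

#: The environmental variables entering the "overall" environmental distance.
ENV_VARIABLES = ("GD", "GA", "GS", "NDVI", "elevation", "pH", "Cond",
                 "TN", "NO3", "NH4", "TP", "SRP", "DOC")
HYDRO_VARIABLES = ("GD", "GA", "GS")
NUTRIENT_VARIABLES = ("TN", "NO3", "NH4", "TP", "SRP")
VEGETATION_VARIABLES = ("NDVI",)
COORD_COLUMNS = ("lat", "lon")


def _check_unique(index: pd.Index, what: str) -> None:
    dup = index[index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what}: {sorted(set(dup.astype(str)))!r}")


def _check_numeric_nonneg(df: pd.DataFrame, row_what: str, col_what: str) -> None:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric value {df[col].iloc[i]!r} at {row_what} "
                f"{df.index[i]!r}, {col_what} {col!r}")
        if coerced.isna().any():
            i = int(np.argmax(coerced.isna().to_numpy()))
            raise ValueError(
                f"missing value at {row_what} {df.index[i]!r}, {col_what} {col!r}")
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = map(int, np.argwhere(arr < 0)[0])
        raise ValueError(
            f"negative value {arr[i, j]!r} at {row_what} {df.index[i]!r}, "
            f"{col_what} {df.columns[j]!r}")


@dataclass
class OtuTable:
    """OTU-by-sample abundance matrix (counts or relative abundances).

    Rows are OTUs, columns are samples — the common QIIME export
    orientation.  ``taxonomy`` optionally maps OTU ids to lineage strings;
    ``kind_label`` is a free community label such as ``"bacteria"``.
    """

    data: pd.DataFrame
    taxonomy: dict | None = None
    kind_label: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "OTU id")
        _check_unique(self.data.columns, "sample id")
        _check_numeric_nonneg(self.data, "OTU", "sample")
        self.data = self.data.astype(float).rename_axis(None).rename_axis(None, axis=1)
        if self.taxonomy:
            extra = set(self.taxonomy) - set(self.data.index)
            if extra:
                raise ValueError(f"taxonomy references unknown OTU ids: {sorted(extra)!r}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def restrict_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        tax = None
        if self.taxonomy is not None:
            tax = dict(self.taxonomy)
        return type(self)(self.data[list(sample_ids)].copy(), taxonomy=tax,
                          kind_label=self.kind_label)

    def restrict_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        keep = list(otu_ids)
        tax = None
        if self.taxonomy is not None:
            tax = {k: v for k, v in self.taxonomy.items() if k in set(keep)}
        return type(self)(self.data.loc[keep].copy(), taxonomy=tax,
                          kind_label=self.kind_label)


@dataclass
class EnvTable:
    """Per-sample environmental variables (rows = samples).

    Recognised variables are hydrology (GD km, GA and GS as fractions of
    glaciated area / glacier source water), vegetation (NDVI), elevation (m),
    pH, conductivity, nutrients (TN, NO3, NH4, TP, SRP), DOC, and decimal
    coordinates ``lat``/``lon``.  Optional columns may be absent; analyses
    that need them fail loudly.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.rename_axis(None).rename_axis(None, axis=1)
        _check_unique(self.data.index, "sample id")
        if self.data.index.isna().any() or (self.data.index.astype(str) == "").any():
            raise ValueError("missing sample id in environment table")
        for col, lo, hi in (("GA", 0.0, 1.0), ("GS", 0.0, 1.0),
                            ("NDVI", -1.0, 1.0), ("lat", -90.0, 90.0),
                            ("lon", -180.0, 180.0)):
            if col in self.data.columns:
                v = self.data[col].astype(float)
                bad = (v < lo) | (v > hi)
                if bad.any():
                    s = self.data.index[bad][0]
                    raise ValueError(
                        f"{col} out of range [{lo}, {hi}] for sample {s!r}: "
                        f"{float(v[bad].iloc[0])}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def absent_variables(self) -> list[str]:
        return [v for v in ENV_VARIABLES if v not in self.data.columns]

    def restrict_samples(self, sample_ids: Sequence[str]) -> "EnvTable":
        return EnvTable(self.data.loc[list(sample_ids)].copy())


def read_otu_table(path, format: str = "tsv", transpose: bool = False,
                   kind_label: str = "") -> OtuTable:
    """Read a tab-separated OTU table (first column OTU ids, header sample ids).

    A trailing column named ``taxonomy`` (case-insensitive) is split off into
    the taxonomy map.  ``transpose=True`` accepts sample-rows input.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        taxonomy = {str(k): str(v) for k, v in df[df.columns[-1]].items()
                    if pd.notna(v)}
        df = df.iloc[:, :-1]
    if transpose:
        df = df.T
    return OtuTable(df, taxonomy=taxonomy, kind_label=kind_label)


def read_env_table(path) -> EnvTable:
    """Read a tab-separated environment table (first column sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    _check_numeric = df.select_dtypes(exclude="number").columns
    if len(_check_numeric):
        col = _check_numeric[0]
        raise ValueError(f"non-numeric environment column {col!r}")
    env = EnvTable(df.astype(float))
    if env.absent_variables:
        logger.info("environment table lacks optional variables: %s",
                    env.absent_variables)
    return env


class AlignResult(NamedTuple):
    a: Union[OtuTable, EnvTable]
    b: Union[OtuTable, EnvTable]
    dropped: list[str]


def align_samples(a, b) -> AlignResult:
    """Restrict two tables to their shared samples, in ``a``'s order.

    Needed whenever a community is missing samples (e.g. one fungal library
    failing to amplify) before any cross-matrix comparison.  Fails if fewer
    than 3 samples are shared, below which distance-matrix tests are
    meaningless.
    """
    sa, sb = list(a.sample_ids), set(b.sample_ids)
    shared = [s for s in sa if s in sb]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples between tables; need >= 3")
    dropped = sorted((set(sa) | set(b.sample_ids)) - set(shared))
    if dropped:
        logger.info("align_samples dropped %d sample(s): %s", len(dropped), dropped)
    return AlignResult(a.restrict_samples(shared), b.restrict_samples(shared), dropped)


def write_otu_table(t: OtuTable, path) -> None:
    df = t.data.copy()
    if t.taxonomy is not None:
        df["taxonomy"] = [t.taxonomy.get(o, "") for o in t.otu_ids]
    df.to_csv(path, sep="\t", index_label="otu_id")


def write_env_table(e: EnvTable, path) -> None:
    e.data.to_csv(path, sep="\t", index_label="sample_id")


# --- network serialization ---------------------------------------------------

EDGE_COLUMNS = ("source", "target", "rho", "p", "sign")


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Serialize a co-occurrence network (edge TSV or GraphML).

    The edge TSV carries ``source, target, rho, p, sign`` per edge; GraphML
    carries the same attributes plus node annotations.  Both round-trip
    through :func:`read_network`.
    """
    path = Path(path)
    if format == "edge_tsv":
        rows = [{"source": u, "target": v, "rho": d["rho"], "p": d["p"],
                 "sign": d["sign"]}
                for u, v, d in sorted(net.edges(data=True))]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unsupported network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    path = Path(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=float(row.rho),
                       p=float(row.p), sign=str(row.sign))
        return g
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unsupported network format {format!r}")


# --- distance matrices -------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t", index_label="")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
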