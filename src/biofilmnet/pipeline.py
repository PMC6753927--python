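"""End-to-end orchestration: from OTU + environment tables to networks,
modules, distance matrices, Mantel/partial-Mantel grids and pairwise
PERMANOVA, with a manifest that fully determines the run.
"""
from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .config import AnalysisConfig
from .distance import ENV_BLOCKS, bray_curtis, env_distance, geographic_distance
from .inference import mantel, mantel_matrix, partial_mantel, pairwise_module_permanova
from .io import (EnvTable, align_samples, read_env_table, read_otu_table,
                 write_distance_matrix, write_network, write_otu_table)
from .modules import (detect_modules, major_modules, membership_frame,
                      module_names, module_subtable)
from .network import (build_network, pvalue_matrix, spearman_matrix,
                      topology_summary)
from .preprocess import (filter_by_relative_abundance, hellinger_transform,
                         normalize_env, to_relative_abundance)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

CONFIG_KEYS = ("abundance_threshold", "rho_threshold", "p_threshold",
               "major_module_min_nodes", "modular_structure_q",
               "n_permutations", "rng_seed", "pvalue_method",
               "env_normalize_margin", "filter_mode")


def env_correlation_report(e: EnvTable, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Spearman rho + p between environmental variables.

    Constant variables are masked (NaN) with a warning; ``significant``
    applies the p < alpha display mask without touching stored values.
    """
    cols = [c for c in e.data.columns if c not in ("lat", "lon")]
    if len(cols) < 2:
        raise ValueError("need >= 2 environmental variables")
    x = e.data[cols].to_numpy(dtype=float)
    n = x.shape[0]
    ranks = stats.rankdata(x, axis=0)
    const = ranks.std(axis=0) == 0
    if const.any():
        import warnings
        warnings.warn(f"constant environment variable(s): "
                      f"{[c for c, k in zip(cols, const) if k]}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rows = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        r = rho[i, j]
        if const[i] or const[j] or not np.isfinite(r):
            rows.append({"a": cols[i], "b": cols[j], "rho": np.nan,
                         "p": np.nan, "significant": False})
            continue
        from .network import correlation_pvalue
        p = correlation_pvalue(float(r), n)
        rows.append({"a": cols[i], "b": cols[j], "rho": float(r), "p": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows, columns=["a", "b", "rho", "p", "significant"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def analyze_community(otu, env: EnvTable, cfg: AnalysisConfig, prefix: str,
                      outdir: Path | None = None) -> dict:
    """Run the within-community stages and return their products.

    Stages: align -> relative abundance -> filter -> Hellinger -> Spearman +
    p -> network -> topology -> modules -> major modules -> module
    sub-tables -> Bray-Curtis (community + modules).
    """
    result: dict = {"prefix": prefix}
    otu_al, env_al, dropped = align_samples(otu, env)
    result["dropped_samples"] = dropped
    rel = to_relative_abundance(otu_al)
    filt = filter_by_relative_abundance(rel, cfg.abundance_threshold,
                                        mode=cfg.filter_mode)
    hel = hellinger_transform(filt)
    rho = spearman_matrix(hel)
    if cfg.pvalue_method == "t_approx":
        pvals = pvalue_matrix(hel, rho=rho, method="t_approx")
    else:
        pvals = pvalue_matrix(hel, rho=rho, method="exact_perm",
                              n_perm=cfg.n_permutations,
                              seed=cfg.substream_seed(f"{prefix}:pvalues"))
    net = build_network(rho, pvals, cfg, kind_label=otu.kind_label,
                        taxonomy=filt.taxonomy)
    result["filtered"] = filt
    result["network"] = net
    if net.number_of_edges() > 0:
        partition = detect_modules(net, seed=cfg.substream_seed(f"{prefix}:modules"))
    else:
        partition = None
    result["partition"] = partition
    result["topology"] = topology_summary(net, partition)
    dms = {f"{prefix}C": bray_curtis(filt)}
    if partition is not None:
        names = module_names(partition, cfg, prefix=prefix)
        for mid, name in names.items():
            sub = module_subtable(filt, partition, mid)
            dms[name] = bray_curtis(sub)
    result["distance_matrices"] = dms
    logger.info("[%s] %d OTUs retained, %d nodes, %d edges, %d modules, "
                "%d major", prefix, filt.shape[0], net.number_of_nodes(),
                net.number_of_edges(),
                0 if partition is None else len(partition.module_sizes),
                0 if partition is None else len(major_modules(partition, cfg)))
    if outdir is not None:
        write_otu_table(filt, outdir / f"{prefix}_filtered_relabund.tsv")
        write_network(net, outdir / f"{prefix}_network_edges.tsv", "edge_tsv")
        write_network(net, outdir / f"{prefix}_network.graphml", "graphml")
        _write_tsv(result["topology"].to_frame(),
                   outdir / f"{prefix}_topology.tsv")
        if partition is not None:
            _write_tsv(membership_frame(partition, cfg, prefix=prefix,
                                        taxonomy=filt.taxonomy),
                       outdir / f"{prefix}_modules.tsv")
        for name, dm in dms.items():
            write_distance_matrix(dm, outdir / f"dm_{name}.tsv")
    return result


def environmental_distances(env: EnvTable, cfg: AnalysisConfig) -> dict:
    """Normalized env-block distances plus geographic distance."""
    norm = normalize_env(env, margin=cfg.env_normalize_margin)
    dms = {block: env_distance(norm, block) for block in ENV_BLOCKS
           if not [c for c in ENV_BLOCKS[block] if c not in env.data.columns]}
    if {"lat", "lon"} <= set(env.data.columns):
        dms["geographic"] = geographic_distance(env)
    return dms


def env_mantel_table(env_dms: dict, cfg: AnalysisConfig) -> pd.DataFrame:
    """Mantel grid among environmental/geographic distances, plus partial
    Mantel (controlling nutrient dissimilarity) for the non-nutrient pairs."""
    grid = mantel_matrix(env_dms, n_perm=cfg.n_permutations,
                         seed=cfg.substream_seed("env_mantel"))
    grid["partial_r"] = np.nan
    grid["partial_p"] = np.nan
    if "nutrient" in env_dms:
        for idx, row in grid.iterrows():
            if "nutrient" in (row["a"], row["b"]):
                continue
            res = partial_mantel(env_dms[row["a"]], env_dms[row["b"]],
                                 env_dms["nutrient"],
                                 n_perm=cfg.n_permutations,
                                 seed=cfg.substream_seed(
                                     f"env_pmantel:{row['a']}:{row['b']}"))
            grid.loc[idx, "partial_r"] = res.r
            grid.loc[idx, "partial_p"] = res.p
    return grid


def community_env_mantel_table(comm_dms: dict, env_dms: dict,
                               cfg: AnalysisConfig) -> pd.DataFrame:
    """Mantel of every community/module Bray-Curtis matrix against every
    environmental/geographic distance."""
    rows = []
    for cname, cdm in comm_dms.items():
        for ename, edm in env_dms.items():
            res = mantel(cdm, edm, n_perm=cfg.n_permutations,
                         seed=cfg.substream_seed(f"mantel:{cname}:{ename}"))
            rows.append({"community": cname, "environment": ename,
                         "r": res.r, "p": res.p, "n": res.n_obs,
                         "significant": res.p < 0.05})
    return pd.DataFrame(rows, columns=["community", "environment", "r", "p",
                                       "n", "significant"])


def run_pipeline(config_path) -> Path:
    """Execute the full analysis described by a YAML config file.

    The config names one or more OTU tables and an environment table::

        otu_tables: {bacteria: b.tsv, fungi: f.tsv}
        env_table: env.tsv
        outdir: results/run1
        rng_seed: 1
        # plus any AnalysisConfig field

    Outputs (all TSV/GraphML/JSON) land in ``outdir``; a manifest records
    config, input hashes, seed and per-stage counts.
    """
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text())
    cfg = AnalysisConfig(**{k: raw[k] for k in CONFIG_KEYS if k in raw})
    outdir = Path(raw.get("outdir", "biofilmnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    env_path = Path(raw["env_table"])
    env = read_env_table(env_path)
    manifest = {
        "config": {**cfg.to_dict(), "otu_tables": {k: str(v) for k, v in
                                                   raw["otu_tables"].items()},
                   "env_table": str(env_path)},
        "input_sha256": {str(env_path): _sha256(env_path)},
        "seed": cfg.rng_seed,
        "version": __version__,
        "stages": {},
    }

    all_comm_dms: dict = {}
    partitions = {}
    filtered = {}
    for label, path in raw["otu_tables"].items():
        path = Path(path)
        manifest["input_sha256"][str(path)] = _sha256(path)
        otu = read_otu_table(path, kind_label=label)
        prefix = label[:1].upper()
        try:
            res = analyze_community(otu, env, cfg, prefix, outdir=outdir)
        except Exception as exc:
            raise RuntimeError(f"stage 'community:{label}' failed: {exc}") from exc
        all_comm_dms.update(res["distance_matrices"])
        partitions[label] = (res["partition"], prefix)
        filtered[label] = res["filtered"]
        manifest["stages"][label] = {
            "otus_retained": res["filtered"].shape[0],
            "nodes": res["network"].number_of_nodes(),
            "edges": res["network"].number_of_edges(),
            "modules": (0 if res["partition"] is None
                        else len(res["partition"].module_sizes)),
            "major_modules": (0 if res["partition"] is None
                              else len(major_modules(res["partition"], cfg))),
            "modularity": (None if res["partition"] is None
                           else res["partition"].q),
            "dropped_samples": res["dropped_samples"],
        }

    env_dms = environmental_distances(env, cfg)
    _write_tsv(env_correlation_report(env), outdir / "env_correlations.tsv")
    _write_tsv(env_mantel_table(env_dms, cfg), outdir / "env_mantel.tsv")
    _write_tsv(community_env_mantel_table(all_comm_dms, env_dms, cfg),
               outdir / "community_env_mantel.tsv")
    if len(all_comm_dms) >= 2:
        _write_tsv(mantel_matrix(all_comm_dms, n_perm=cfg.n_permutations,
                                 seed=cfg.substream_seed("community_mantel")),
                   outdir / "community_mantel_matrix.tsv")
    for label, (partition, prefix) in partitions.items():
        if partition is None or len(major_modules(partition, cfg)) < 2:
            continue
        _write_tsv(pairwise_module_permanova(filtered[label], partition, cfg,
                                             prefix=prefix),
                   outdir / f"{prefix}_module_permanova.tsv")

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
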