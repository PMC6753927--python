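#!/usr/bin/env python
"""Construct every distance matrix the inference stage needs: Bray-Curtis
for each community and each major module, Euclidean environmental blocks
(overall / hydrological / nutrient / vegetation) on normalized variables,
and geographic (great-circle) distance.  Also writes the pairwise Spearman
correlation table of the raw environmental variables.

Outputs under results/distances/.
"""
import argparse
from pathlib import Path

import pandas as pd

import biofilmnet as bn
from biofilmnet.distance import ENV_BLOCKS, env_distance, geographic_distance
from biofilmnet.io import read_env_table, read_otu_table, write_distance_matrix
from biofilmnet.modules import ModulePartition, major_modules, module_names, module_subtable
from biofilmnet.pipeline import env_correlation_report
from biofilmnet.preprocess import RelAbundTable, normalize_env


def load_partition(path):
    df = pd.read_csv(path, sep="\t")
    return ModulePartition(
        assignment=dict(zip(df.otu_id.astype(str), df.module_id)), q=float("nan"))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--netdir", type=Path, default=Path("results/networks"))
    ap.add_argument("--moddir", type=Path, default=Path("results/modules"))
    ap.add_argument("--outdir", type=Path, default=Path("results/distances"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    env = read_env_table(args.datadir / "env.tsv")
    norm = normalize_env(env)
    for block in ENV_BLOCKS:
        write_distance_matrix(env_distance(norm, block),
                              args.outdir / f"dm_env_{block}.tsv")
    write_distance_matrix(geographic_distance(env),
                          args.outdir / "dm_geographic.tsv")
    env_correlation_report(env).to_csv(args.outdir / "env_correlations.tsv",
                                       sep="\t", index=False)

    for label, prefix in (("bacteria", "B"), ("fungi", "F")):
        filt = RelAbundTable(read_otu_table(
            args.netdir / f"{label}_filtered_relabund.tsv").data)
        part = load_partition(args.moddir / f"{label}_module_membership.tsv")
        write_distance_matrix(bn.bray_curtis(filt),
                              args.outdir / f"dm_{prefix}C.tsv")
        names = module_names(part, prefix=prefix)
        for mid, name in names.items():
            sub = module_subtable(filt, part, mid)
            write_distance_matrix(bn.bray_curtis(sub),
                                  args.outdir / f"dm_{name}.tsv")
        print(f"{label}: community + {len(names)} major-module "
              f"Bray-Curtis matrices written")
    print(f"environmental blocks + geographic distances -> {args.outdir}")


if __name__ == "__main__":
    main()
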