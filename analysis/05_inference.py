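#!/usr/bin/env python
"""Permutation inference over the distance matrices: the environmental
Mantel/partial-Mantel grid, every community/module vs every environmental
block, the all-vs-all community/module Mantel grid, and pairwise PERMANOVA
between major modules.

Writes long-format result tables under results/inference/ and prints the
qualitative outcome (which matrices track the gradient).
"""
import argparse
from pathlib import Path

import pandas as pd

from biofilmnet.config import AnalysisConfig
from biofilmnet.inference import mantel_matrix, pairwise_module_permanova
from biofilmnet.io import read_distance_matrix, read_otu_table
from biofilmnet.pipeline import community_env_mantel_table, env_mantel_table
from biofilmnet.preprocess import RelAbundTable

ENV_NAMES = ("overall", "hydrological", "nutrient", "vegetation")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--netdir", type=Path, default=Path("results/networks"))
    ap.add_argument("--moddir", type=Path, default=Path("results/modules"))
    ap.add_argument("--dmdir", type=Path, default=Path("results/distances"))
    ap.add_argument("--outdir", type=Path, default=Path("results/inference"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=999)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = AnalysisConfig(rng_seed=args.seed, n_permutations=args.n_perm)

    env_dms = {b: read_distance_matrix(args.dmdir / f"dm_env_{b}.tsv")
               for b in ENV_NAMES}
    env_dms["geographic"] = read_distance_matrix(args.dmdir / "dm_geographic.tsv")
    comm_dms = {p.stem[3:]: read_distance_matrix(p)
                for p in sorted(args.dmdir.glob("dm_[BF]*.tsv"))}

    env_grid = env_mantel_table(env_dms, cfg)
    env_grid.to_csv(args.outdir / "env_mantel.tsv", sep="\t", index=False)

    grid = community_env_mantel_table(comm_dms, env_dms, cfg)
    grid.to_csv(args.outdir / "community_env_mantel.tsv", sep="\t", index=False)
    sig = grid[grid.significant]
    print("community/module x environment Mantel (p < 0.05):")
    for _, row in sig.iterrows():
        print(f"  {row.community:5s} ~ {row.environment:12s} "
              f"r = {row.r:.2f}, p = {row.p:.3f}")
    quiet = sorted(set(grid.community) - set(sig.community))
    print(f"no environmental association: {', '.join(quiet) or 'none'}")

    cross = mantel_matrix(comm_dms, n_perm=cfg.n_permutations,
                          seed=cfg.substream_seed("community_mantel"))
    cross.to_csv(args.outdir / "community_mantel_matrix.tsv", sep="\t",
                 index=False)
    n_sig = int(cross.significant.sum())
    print(f"community/module Mantel grid: {n_sig} of {len(cross)} pairs "
          "significant at 0.05")

    from biofilmnet.modules import ModulePartition
    for label, prefix in (("bacteria", "B"), ("fungi", "F")):
        mem = pd.read_csv(args.moddir / f"{label}_module_membership.tsv",
                          sep="\t")
        part = ModulePartition(
            assignment=dict(zip(mem.otu_id.astype(str), mem.module_id)),
            q=0.0)
        filt = RelAbundTable(read_otu_table(
            args.netdir / f"{label}_filtered_relabund.tsv").data)
        table = pairwise_module_permanova(filt, part, cfg, prefix=prefix)
        table.to_csv(args.outdir / f"{prefix}_module_permanova.tsv",
                     sep="\t", index=False)
        print(f"{label}: pairwise module PERMANOVA, "
              f"{int((table.p < 0.05).sum())}/{len(table)} pairs "
              "compositionally distinct (p < 0.05)")


if __name__ == "__main__":
    main()
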