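#!/usr/bin/env python
"""Build the co-occurrence networks: relative abundance -> >0.01% filter ->
Hellinger -> Spearman (+ t-approximation p) -> |rho| > 0.7 & p < 0.01 edges.

Writes the filtered tables, edge lists and a side-by-side topology summary
(the whole-network descriptors) under results/networks/.
"""
import argparse
import warnings
from pathlib import Path

import pandas as pd

import biofilmnet as bn
from biofilmnet.io import read_env_table, read_otu_table, write_network, write_otu_table
from biofilmnet.modules import detect_modules
from biofilmnet.network import topology_summary


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/networks"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    env = read_env_table(args.datadir / "env.tsv")
    summaries = {}
    for label in ("bacteria", "fungi"):
        otu = read_otu_table(args.datadir / f"{label}_otu.tsv",
                             kind_label=label)
        otu, _, dropped = bn.align_samples(otu, env)
        rel = bn.to_relative_abundance(otu)
        filt = bn.filter_by_relative_abundance(rel)
        hel = bn.hellinger_transform(filt)
        rho = bn.spearman_matrix(hel)
        p = bn.pvalue_matrix(hel, rho=rho)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = bn.build_network(rho, p, kind_label=label,
                                   taxonomy=filt.taxonomy)
        part = detect_modules(net, seed=args.seed)
        ts = topology_summary(net, part)
        summaries[label] = ts.to_frame().set_index("parameter")["value"]
        write_otu_table(filt, args.outdir / f"{label}_filtered_relabund.tsv")
        write_network(net, args.outdir / f"{label}_network_edges.tsv")
        print(f"{label}: {filt.shape[0]} OTUs kept "
              f"(dropped samples: {dropped or 'none'}); network "
              f"{net.number_of_nodes()} nodes / {net.number_of_edges()} edges, "
              f"Q = {part.q:.3f}")

    table = pd.DataFrame(summaries)
    table.to_csv(args.outdir / "topology_summary.tsv", sep="\t")
    print("\nTopology summary (bacteria vs fungi):")
    print(table.to_string())


if __name__ == "__main__":
    main()
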