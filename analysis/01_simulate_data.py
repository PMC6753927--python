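#!/usr/bin/env python
"""Generate the two synthetic communities (bacteria-like and fungi-like)
plus the shared environment table, and write them under results/data/.

The bacteria-like community has four gradient-responsive planted modules of
five; the fungi-like community has exactly one responsive module of six and
is missing one sample (a failed library).  The planted truth is written
alongside so later steps can be checked against it.
"""
import argparse
from pathlib import Path

from biofilmnet.io import write_env_table, write_otu_table
from biofilmnet.simulate import end_to_end_fixture


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    b_otu, env, b_truth = end_to_end_fixture("bacteria_like", seed=args.seed)
    f_otu, _, f_truth = end_to_end_fixture("fungi_like", seed=args.seed + 1)

    write_otu_table(b_otu, args.outdir / "bacteria_otu.tsv")
    write_otu_table(f_otu, args.outdir / "fungi_otu.tsv")
    write_env_table(env, args.outdir / "env.tsv")
    b_truth.to_frame().to_csv(args.outdir / "bacteria_truth.tsv",
                              sep="\t", index=False)
    f_truth.to_frame().to_csv(args.outdir / "fungi_truth.tsv",
                              sep="\t", index=False)
    print(f"bacteria: {b_otu.shape[0]} OTUs x {b_otu.shape[1]} samples "
          f"({len(b_truth.responsive_modules)} responsive modules)")
    print(f"fungi:    {f_otu.shape[0]} OTUs x {f_otu.shape[1]} samples "
          f"({len(f_truth.responsive_modules)} responsive module)")
    print(f"environment: {len(env.sample_ids)} samples -> {args.outdir}")


if __name__ == "__main__":
    main()
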