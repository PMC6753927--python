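"""Relative abundance, abundance filtering, Hellinger transform, env scaling.

The pipeline order is fixed as: relative abundance -> abundance filter ->
Hellinger.  Filtering and transforming do not commute once columns are
renormalized, so the Hellinger step always uses the totals of the table it
is handed (no renormalization happens in between).
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import ENV_VARIABLES, EnvTable, OtuTable


class RelAbundTable(OtuTable):
    """OTU table on the relative-abundance scale.

    Column sums are 1 for non-empty samples at creation; subsetting rows
    (abundance filter, module sub-tables) keeps the scale but lowers the
    sums, so the invariant enforced here is values in [0, 1] and column sums
    <= 1.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.data.to_numpy()
        if arr.size and arr.max() > 1 + 1e-9:
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=0)
        if arr.size and (sums > 1 + 1e-9).any():
            raise ValueError("relative-abundance column sums must be <= 1")


def to_relative_abundance(t: OtuTable) -> RelAbundTable:
    """Divide each sample column by its total; empty samples stay zero."""
    arr = t.values
    sums = arr.sum(axis=0)
    empty = sums == 0
    if empty.any():
        warnings.warn(
            f"all-zero sample column(s): {list(np.array(t.sample_ids)[empty])}",
            stacklevel=2)
    out = np.divide(arr, np.where(empty, 1.0, sums)[None, :])
    df = pd.DataFrame(out, index=t.otu_ids, columns=t.sample_ids)
    return RelAbundTable(df, taxonomy=dict(t.taxonomy) if t.taxonomy else None,
                         kind_label=t.kind_label)


def filter_by_relative_abundance(t: RelAbundTable, threshold: float = 1e-4,
                                 mode: str = "mean_across_samples") -> RelAbundTable:
    """Keep OTUs whose relative abundance exceeds ``threshold`` (strict >).

    ``mean_across_samples`` (default) compares each OTU's mean relative
    abundance across samples to the threshold; ``overall`` compares the
    OTU's share of the pooled table.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold!r}")
    arr = t.values
    if mode == "mean_across_samples":
        score = arr.mean(axis=1)
    elif mode == "overall":
        total = arr.sum()
        score = arr.sum(axis=1) / total if total > 0 else np.zeros(len(arr))
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    keep = score > threshold
    if not keep.any():
        raise ValueError(
            f"abundance filter at {threshold} removed every OTU ({len(arr)} rows)")
    kept = [o for o, k in zip(t.otu_ids, keep) if k]
    logging.getLogger(__name__).info(
        "abundance filter (> %g, %s): retained %d of %d OTUs",
        threshold, mode, len(kept), len(arr))
    return t.restrict_otus(kept)


def hellinger_transform(t: OtuTable) -> OtuTable:
    """Square root of the within-sample relative abundance.

    Each cell becomes sqrt(value / column total), so every non-empty sample
    has unit sum of squares; this makes abundance data amenable to
    correlation and Euclidean-type analysis.
    """
    arr = t.values
    sums = arr.sum(axis=0)
    out = np.sqrt(np.divide(arr, np.where(sums == 0, 1.0, sums)[None, :]))
    df = pd.DataFrame(out, index=t.otu_ids, columns=t.sample_ids)
    return OtuTable(df, taxonomy=dict(t.taxonomy) if t.taxonomy else None,
                    kind_label=t.kind_label)


def normalize_env(e: EnvTable, margin: str = "per_sample",
                  variables: tuple[str, ...] | None = None) -> EnvTable:
    """Scale environmental variables to unit Euclidean norm.

    ``per_sample`` scales each sample's variable vector (the default of the
    classic ``decostand(..., "normalize")`` convention); ``per_variable``
    scales each variable across samples.  Coordinates and any column not in
    ``variables`` are left untouched; zero vectors stay zero.
    """
    if variables is None:
        variables = tuple(v for v in ENV_VARIABLES if v in e.data.columns)
    missing = [v for v in variables if v not in e.data.columns]
    if missing:
        raise ValueError(f"environment table lacks variable(s) {missing!r}")
    block = e.data[list(variables)].to_numpy(dtype=float)
    axis = 1 if margin == "per_sample" else 0
    if margin not in ("per_sample", "per_variable"):
        raise ValueError(f"unknown margin {margin!r}")
    norms = np.sqrt((block ** 2).sum(axis=axis, keepdims=True))
    scaled = np.divide(block, np.where(norms == 0, 1.0, norms))
    out = e.data.copy()
    out[list(variables)] = scaled
    return EnvTable(out)
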