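"""Distance matrices: Bray-Curtis, Euclidean environmental blocks, geographic
great-circle distance, and the NDVI utility.

All outputs are :class:`skbio.stats.distance.DistanceMatrix` (symmetric,
hollow, labeled) — the common currency of the Mantel/PERMANOVA stage.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .io import (ENV_VARIABLES, HYDRO_VARIABLES, NUTRIENT_VARIABLES,
                 VEGETATION_VARIABLES, EnvTable, OtuTable)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

ENV_BLOCKS = {
    "overall": tuple(ENV_VARIABLES),
    "hydrological": tuple(HYDRO_VARIABLES),
    "nutrient": tuple(NUTRIENT_VARIABLES),
    "vegetation": tuple(VEGETATION_VARIABLES),
}


def bray_curtis(t: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y).

    A pair of all-zero samples has an undefined distance; it is set to 0
    with a warning.
    """
    if t.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = t.values.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("Bray-Curtis undefined for all-zero sample pair(s); set to 0",
                      stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, ids=t.sample_ids)


def otu_profile_bray_curtis(t: OtuTable) -> DistanceMatrix:
    """Bray-Curtis between OTU across-sample abundance profiles (rows)."""
    if t.shape[0] < 2:
        raise ValueError("need >= 2 OTUs")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(t.values, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("Bray-Curtis undefined for all-zero OTU pair(s); set to 0",
                      stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, ids=t.otu_ids)


def env_distance(e: EnvTable, block: str = "overall") -> DistanceMatrix:
    """Euclidean distance over one block of (normalized) env variables.

    Blocks: overall (all 13 analysis variables), hydrological (GD, GA, GS),
    nutrient (TN, NO3, NH4, TP, SRP), vegetation (NDVI).
    """
    if block not in ENV_BLOCKS:
        raise ValueError(f"unknown block {block!r}; choose from {sorted(ENV_BLOCKS)}")
    cols = ENV_BLOCKS[block]
    missing = [c for c in cols if c not in e.data.columns]
    if missing:
        raise ValueError(f"environment table lacks variable(s) {missing!r} "
                         f"required by block {block!r}")
    x = e.data[list(cols)].to_numpy(dtype=float)
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(d, ids=e.sample_ids)


def geographic_distance(e: EnvTable) -> DistanceMatrix:
    """Great-circle (haversine) distance between sites in km."""
    for c in ("lat", "lon"):
        if c not in e.data.columns:
            raise ValueError(f"environment table lacks coordinate column {c!r}")
    lat = np.radians(e.data["lat"].to_numpy(dtype=float))
    lon = np.radians(e.data["lon"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # symmetrize away rounding noise
    return DistanceMatrix(d, ids=e.sample_ids)


def ndvi(nir, red, mask=None):
    """NDVI = (NIR - RED) / (NIR + RED), plus the masked mean.

    Pixels where NIR + RED = 0 are undefined (NaN) and excluded from the
    mean.  ``mask`` selects the sub-catchment pixels over which the mean is
    taken (all pixels if omitted).

    Returns
    -------
    (ndvi_array, masked_mean)
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise ValueError(f"NIR shape {nir.shape} != RED shape {red.shape}")
    if (nir < 0).any() or (red < 0).any():
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, (nir - red) / denom)
    if mask is None:
        mask = np.ones(nir.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != nir.shape:
            raise ValueError("mask shape does not match reflectance arrays")
        if not mask.any():
            raise ValueError("empty sub-catchment mask")
    sel = out[mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError("no defined NDVI pixel inside the mask")
    return out, float(sel.mean())
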