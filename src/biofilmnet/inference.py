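"""Permutation inference on distance matrices: Mantel, partial Mantel,
pairwise Mantel grids, and PERMANOVA.

All tests permute with an explicit integer seed and use the standard
(1 + #extreme) / (1 + n_perm) estimate, so p >= 1/(n_perm + 1) always.
Mantel statistics are Spearman correlations of the strict lower/upper
triangles; the tail is one-sided (greater), the convention of the vegan-style
ecosystem these analyses come from.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .config import AnalysisConfig
from .distance import otu_profile_bray_curtis
from .modules import ModulePartition, major_modules, module_names

_EPS = 1e-12


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_obs: int
    method: str = "spearman"
    tail: str = "one_sided_greater"


@dataclass
class PermanovaResult:
    f: float
    r2: float
    p: float
    n_perm: int
    n_obs: int
    n_groups: int


def _align(*dms: DistanceMatrix) -> list[DistanceMatrix]:
    ids = list(dms[0].ids)
    for dm in dms[1:]:
        present = set(dm.ids)
        ids = [i for i in ids if i in present]
    return [dm.filter(ids) for dm in dms]


def _triangle(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _permuted_triangles(m: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Strict upper triangles of m after joint row/column permutation."""
    n = m.shape[0]
    iu = np.triu_indices(n, 1)
    out = np.empty((len(perms), len(iu[0])))
    for k, pm in enumerate(perms):
        out[k] = m[np.ix_(pm, pm)][iu]
    return out


def _corr_with(xc: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with centered vector xc."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(xc)
    return rc @ xc / denom


def mantel(dx: DistanceMatrix, dy: DistanceMatrix, n_perm: int = 999,
           seed: int = 0) -> MantelResult:
    """Spearman Mantel test between two distance matrices.

    The matrices are aligned on shared ids (in ``dx``'s order); rows and
    columns of ``dy`` are permuted jointly; the p-value is one-sided
    (greater).
    """
    dx, dy = _align(dx, dy)
    n = dx.shape[0]
    if n < 4:
        raise ValueError(f"Mantel needs >= 4 shared observations, got {n}")
    x = stats.rankdata(_triangle(dx.data))
    y = stats.rankdata(_triangle(dy.data))
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Mantel undefined: a distance triangle has zero variance")
    xc = x - x.mean()
    r_obs = float((y - y.mean()) @ xc
                  / (np.linalg.norm(y - y.mean()) * np.linalg.norm(xc)))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ranks = _rank_rows(_permuted_triangles(dy.data, perms))
    r_perm = _corr_with(xc, ranks)
    p = float((1 + np.sum(r_perm >= r_obs - _EPS)) / (1 + n_perm))
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n_obs=n)


def partial_mantel(dx: DistanceMatrix, dy: DistanceMatrix, dz: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Partial Mantel: correlation of dx and dy controlling dz.

    Uses the first-order partial correlation of triangle Spearman
    correlations, permuting ``dy`` (dx and dz held fixed) and recomputing
    r_xy and r_yz for each permutation.
    """
    dx, dy, dz = _align(dx, dy, dz)
    n = dx.shape[0]
    if n < 5:
        raise ValueError(f"partial Mantel needs >= 5 shared observations, got {n}")
    x = stats.rankdata(_triangle(dx.data))
    y = stats.rankdata(_triangle(dy.data))
    z = stats.rankdata(_triangle(dz.data))
    for name, v in (("dx", x), ("dy", y), ("dz", z)):
        if v.std() == 0:
            raise ValueError(f"partial Mantel undefined: {name} triangle has "
                             "zero variance")
    xc, zc = x - x.mean(), z - z.mean()
    r_xz = float(zc @ xc / (np.linalg.norm(zc) * np.linalg.norm(xc)))
    if abs(r_xz) >= 1 - _EPS:
        raise ValueError("partial Mantel undefined: |r_xz| = 1")

    def _partial(r_xy, r_yz):
        denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
        return (r_xy - r_xz * r_yz) / denom

    yc = y - y.mean()
    r_xy = float(yc @ xc / (np.linalg.norm(yc) * np.linalg.norm(xc)))
    r_yz = float(yc @ zc / (np.linalg.norm(yc) * np.linalg.norm(zc)))
    if abs(r_yz) >= 1 - _EPS:
        raise ValueError("partial Mantel undefined: |r_yz| = 1")
    r_obs = float(_partial(r_xy, r_yz))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ranks = _rank_rows(_permuted_triangles(dy.data, perms))
    r_xy_p = _corr_with(xc, ranks)
    r_yz_p = _corr_with(zc, ranks)
    ok = np.abs(r_yz_p) < 1 - _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        r_p = _partial(r_xy_p[ok], r_yz_p[ok])
    p = float((1 + np.sum(r_p >= r_obs - _EPS)) / (1 + n_perm))
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, n_obs=n)


def mantel_matrix(mats: dict, n_perm: int = 999, seed: int = 0,
                  alpha: float = 0.05) -> pd.DataFrame:
    """All unordered pairwise Mantel tests among named distance matrices.

    Each pair is aligned on its own shared samples.  ``significant`` applies
    the p < alpha display mask (0.05 mirrors the usual correlation-grid
    figures); the stored r and p are unaffected by the mask.
    """
    names = list(mats)
    if len(names) < 2:
        raise ValueError("need >= 2 matrices")
    ss = np.random.SeedSequence(seed)
    rows = []
    pair_seeds = ss.generate_state(len(names) * (len(names) - 1) // 2) % (2**31 - 1)
    for k, (a, b) in enumerate(itertools.combinations(names, 2)):
        res = mantel(mats[a], mats[b], n_perm=n_perm, seed=int(pair_seeds[k]))
        rows.append({"a": a, "b": b, "r": res.r, "p": res.p,
                     "n": res.n_obs, "significant": res.p < alpha})
    return pd.DataFrame(rows, columns=["a", "b", "r", "p", "n", "significant"])


def permanova(d: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within pools within-group squared
    distances scaled by group size; F = (SS_between/(a-1)) / (SS_within/(N-a));
    the p-value permutes group labels.
    """
    if isinstance(grouping, dict):
        labels = np.array([grouping[i] for i in d.ids])
    else:
        labels = np.asarray(grouping)
        if len(labels) != d.shape[0]:
            raise ValueError("grouping length does not match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"singleton group(s) not allowed: {list(small)!r}")
    n = d.shape[0]
    a = len(uniq)
    d2 = d.data ** 2
    sst = float(_triangle(d2).sum()) / n

    group_masks = np.array([labels == g for g in uniq])  # a x n booleans

    def _ssw(masks: np.ndarray) -> np.ndarray:
        # masks: (n_reps, a, n) -> SS_within per replicate
        out = np.zeros(masks.shape[0])
        for gi in range(a):
            mg = masks[:, gi, :].astype(float)
            out += np.einsum("ri,ij,rj->r", mg, d2, mg) / (2.0 * counts[gi])
        return out

    ssw_obs = float(_ssw(group_masks[None, :, :])[0])
    ssb = sst - ssw_obs
    with np.errstate(divide="ignore"):
        # ssw = 0 (perfect separation) gives F = inf, R2 = 1
        f_obs = float(np.divide(ssb / (a - 1), ssw_obs / (n - a)))
    r2 = ssb / sst
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_masks = group_masks[:, perms]          # a x n_perm x n
    perm_masks = np.swapaxes(perm_masks, 0, 1)  # n_perm x a x n
    ssw_p = _ssw(perm_masks)
    ssb_p = sst - ssw_p
    with np.errstate(divide="ignore", invalid="ignore"):
        f_p = (ssb_p / (a - 1)) / (ssw_p / (n - a))
    p = float((1 + np.sum(f_p >= f_obs - _EPS)) / (1 + n_perm))
    return PermanovaResult(f=float(f_obs), r2=float(r2), p=p, n_perm=n_perm,
                           n_obs=n, n_groups=a)


def pairwise_module_permanova(t, p: ModulePartition,
                              cfg: AnalysisConfig | None = None,
                              prefix: str = "M") -> pd.DataFrame:
    """Pairwise PERMANOVA of taxonomic composition among major modules.

    Observations are OTUs (each OTU's across-sample relative-abundance
    profile), distances are Bray-Curtis between OTU profiles, and the
    grouping is module membership; one test per unordered pair of major
    modules.
    """
    cfg = cfg or AnalysisConfig()
    major = major_modules(p, cfg)
    if len(major) < 2:
        raise ValueError("need >= 2 major modules for pairwise tests")
    names = module_names(p, cfg, prefix=prefix)
    present = set(t.otu_ids)
    rows = []
    ss = np.random.SeedSequence(cfg.substream_seed("pairwise_permanova"))
    pair_seeds = ss.generate_state(len(major) * (len(major) - 1) // 2) % (2**31 - 1)
    for k, (ma, mb) in enumerate(itertools.combinations(major, 2)):
        otus = [o for o in t.otu_ids
                if o in present and p.assignment.get(o) in (ma, mb)]
        sub = t.restrict_otus(otus)
        dm = otu_profile_bray_curtis(sub)
        grouping = {o: p.assignment[o] for o in otus}
        res = permanova(dm, grouping, n_perm=cfg.n_permutations,
                        seed=int(pair_seeds[k]))
        rows.append({"module_a": names.get(ma, str(ma)),
                     "module_b": names.get(mb, str(mb)),
                     "F": res.f, "R2": res.r2, "p": res.p,
                     "n_otus": res.n_obs})
    return pd.DataFrame(rows, columns=["module_a", "module_b", "F", "R2",
                                       "p", "n_otus"])
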