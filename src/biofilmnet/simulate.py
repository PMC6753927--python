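"""Synthetic communities with planted module structure and known
environment responsiveness.

The generator emulates the processed data layer of a glacier-fed stream
survey: a handful of samples (11 by default) ordered along a latent
glacier-influence gradient g, an environment table whose hydrological
(GD, GA, GS) and vegetation/elevation variables track g while nutrient
variables are decoupled noise, and OTU count tables whose OTUs belong to
planted modules.  Each module has a shared latent profile across samples:

    f_m(s) = effect_size * dir_m * g_s  (responsive modules only)
             + idiosyncratic component w_m(s)

where w_m is a module-specific standardized random walk *shuffled across
samples* so it is exchangeable with respect to g (keeping non-responsive
modules truly null for gradient tests while still binding module members
together).  OTU expected abundances are lognormal around exp(a_i + f_m),
and counts are drawn multinomially per sample at a fixed depth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EnvTable, OtuTable

#: idiosyncratic (module-binding) profile weight for responsive / noise modules
IDIO_WEIGHT_RESPONSIVE = 1.0
IDIO_WEIGHT_NOISE = 1.5
#: relative gradient sensitivity of successive responsive modules; modules
#: differ in how strongly they track the gradient (and alternate direction),
#: which keeps same-direction responders from collapsing into one block
RESPONSIVENESS_MULTIPLIERS = (1.2, 1.0, 0.8, 0.9)
#: per-OTU lognormal noise (log scale)
OTU_NOISE_SD = 0.75
#: spread of baseline log-abundances a_i
BASE_ABUNDANCE_SD = 1.2

DEFAULT_EFFECT_SIZE = 1.2
DEFAULT_DEPTH = 20000
DEFAULT_N_SAMPLES = 11

_BACTERIAL_PHYLA = ("Proteobacteria", "Bacteroidetes", "Cyanobacteria",
                    "Actinobacteria", "Firmicutes", "Verrucomicrobia",
                    "Planctomycetes", "Acidobacteria")
_FUNGAL_PHYLA = ("Ascomycota", "Basidiomycota", "Chytridiomycota",
                 "Mucoromycota", "Cryptomycota")

PRESETS = {
    # Many OTUs, most modules gradient-responsive: a dense, connected,
    # environment-driven community.  Community-level power comes from
    # aggregating four responsive modules, so each module's own gradient
    # weight is modest and the module-binding idiosyncratic weight strong
    # (keeps between-module correlations below the edge threshold).
    "bacteria_like": dict(
        n_otus=400,
        module_fractions=(0.30, 0.25, 0.20, 0.15, 0.10),
        responsive=(True, True, True, True, False),
        effect_size=1.25,
        idio_responsive=1.3,
        idio_noise=1.5,
        depth=DEFAULT_DEPTH,
        phyla=_BACTERIAL_PHYLA,
        kind_label="bacteria",
        drop_sample=None,
    ),
    # Fewer OTUs, exactly one responsive module (the "FM3 analogue");
    # one sample is dropped, mirroring a library that failed to amplify.
    # The single responsive module carries a strong gradient share so its
    # own dissimilarity tracks hydrology while the community's does not.
    "fungi_like": dict(
        n_otus=150,
        module_fractions=(0.26, 0.21, 0.15, 0.15, 0.125, 0.105),
        responsive=(False, False, True, False, False, False),
        effect_size=1.6,
        idio_responsive=0.55,
        idio_noise=2.1,
        depth=DEFAULT_DEPTH,
        phyla=_FUNGAL_PHYLA,
        kind_label="fungi",
        drop_sample=1,
    ),
}


@dataclass
class SyntheticTruth:
    """Ground truth of a planted community."""

    module_of: dict
    responsive: dict
    gradient: np.ndarray
    effect_size: float
    seed: int

    @property
    def n_otus(self) -> int:
        return len(self.module_of)

    @property
    def responsive_modules(self) -> list[int]:
        return sorted(m for m, r in self.responsive.items() if r)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"otu_id": o, "module": m, "responsive": self.responsive[m]}
                for o, m in sorted(self.module_of.items())]
        return pd.DataFrame(rows, columns=["otu_id", "module", "responsive"])


def _latent_gradient(n_samples: int, rng: np.random.Generator,
                     jitter: float = 0.03) -> np.ndarray:
    g = np.linspace(0.0, 1.0, n_samples) + rng.normal(0.0, jitter, n_samples)
    return g


def generate_env(n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0,
                 gradient: np.ndarray | None = None) -> EnvTable:
    """Environment table driven by a latent glacier-influence gradient.

    GD, NDVI, pH, Cond and DOC increase downstream (with g); GA, GS and
    elevation decrease — a tightly correlated block.  The five nutrient
    variables are independent noise, decoupled from the gradient.
    Coordinates lie along a line so geographic distance tracks sample order.
    """
    if n_samples < 6:
        raise ValueError("need >= 6 samples")
    rng = np.random.default_rng(seed)
    g = _latent_gradient(n_samples, rng) if gradient is None else np.asarray(gradient)
    n = len(g)
    e = rng.normal

    data = {
        "GD": np.clip(2.0 + 28.0 * g + e(0, 1.5, n), 0.0, None),
        "GA": np.clip(0.75 - 0.70 * g + e(0, 0.04, n), 0.0, 1.0),
        "GS": np.clip(0.85 - 0.75 * g + e(0, 0.04, n), 0.0, 1.0),
        "NDVI": np.clip(-0.05 + 0.60 * g + e(0, 0.03, n), -1.0, 1.0),
        "elevation": 3800.0 - 1150.0 * g + e(0, 50.0, n),
        "pH": 7.6 + 0.9 * g + e(0, 0.15, n),
        "Cond": np.clip(120.0 + 180.0 * g + e(0, 25.0, n), 1.0, None),
        "TN": np.clip(0.55 + e(0, 0.18, n), 0.02, None),
        "NO3": np.clip(0.30 + e(0, 0.10, n), 0.01, None),
        "NH4": np.clip(0.08 + e(0, 0.03, n), 0.005, None),
        "TP": np.clip(0.05 + e(0, 0.02, n), 0.002, None),
        "SRP": np.clip(0.02 + e(0, 0.008, n), 0.001, None),
        "DOC": np.clip(0.9 + 2.2 * g + e(0, 0.45, n), 0.05, None),
        "lat": 43.05 + e(0, 0.002, n),
        "lon": 86.75 + 0.012 * np.arange(n) + e(0, 0.0008, n),
    }
    ids = [f"S{i + 1:02d}" for i in range(n)]
    return EnvTable(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))


def make_truth(n_otus: int, module_fractions, responsive, gradient,
               effect_size: float = DEFAULT_EFFECT_SIZE,
               seed: int = 0) -> SyntheticTruth:
    """Assign OTUs to planted modules with the given size fractions."""
    fr = np.asarray(module_fractions, dtype=float)
    fr = fr / fr.sum()
    sizes = np.floor(fr * n_otus).astype(int)
    sizes[0] += n_otus - sizes.sum()
    module_of = {}
    k = 0
    for m, s in enumerate(sizes):
        for _ in range(s):
            module_of[f"OTU{k + 1:04d}"] = m
            k += 1
    return SyntheticTruth(module_of=module_of,
                          responsive={m: bool(r) for m, r in enumerate(responsive)},
                          gradient=np.asarray(gradient, dtype=float),
                          effect_size=float(effect_size), seed=seed)


def _module_profiles(truth: SyntheticTruth, rng: np.random.Generator,
                     idio_responsive: float = IDIO_WEIGHT_RESPONSIVE,
                     idio_noise: float = IDIO_WEIGHT_NOISE) -> dict:
    g = truth.gradient
    gz = (g - g.mean()) / g.std()
    n = len(g)
    profiles = {}
    k = 0
    for m in sorted(truth.responsive):
        walk = np.cumsum(rng.standard_normal(n))
        walk = (walk - walk.mean()) / max(walk.std(), 1e-9)
        walk = walk[rng.permutation(n)]  # exchangeable w.r.t. the gradient
        if truth.responsive[m]:
            mult = RESPONSIVENESS_MULTIPLIERS[k % len(RESPONSIVENESS_MULTIPLIERS)]
            direction = 1 if k % 2 == 0 else -1  # up/down-stream responders
            profiles[m] = truth.effect_size * mult * direction * gz \
                + idio_responsive * walk
            k += 1
        else:
            profiles[m] = idio_noise * walk
    return profiles


def generate_community(truth: SyntheticTruth,
                       n_samples: int | None = None,
                       depth: int = DEFAULT_DEPTH, seed: int = 0,
                       kind_label: str = "", phyla=None,
                       idio_responsive: float = IDIO_WEIGHT_RESPONSIVE,
                       idio_noise: float = IDIO_WEIGHT_NOISE,
                       otu_noise_sd: float = OTU_NOISE_SD) -> OtuTable:
    """Multinomial OTU count table realizing the planted truth.

    Expected abundance of OTU i in sample s is proportional to
    exp(a_i + f_m(s) + noise); every sample column sums to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    n = len(truth.gradient)
    if n_samples is not None and n_samples != n:
        raise ValueError("n_samples must match the truth gradient length")
    rng = np.random.default_rng(seed)
    profiles = _module_profiles(truth, rng, idio_responsive=idio_responsive,
                                idio_noise=idio_noise)
    otus = sorted(truth.module_of)
    n_otus = len(otus)
    a = rng.normal(0.0, BASE_ABUNDANCE_SD, n_otus)
    log_lam = np.empty((n_otus, n))
    for i, otu in enumerate(otus):
        f = profiles[truth.module_of[otu]]
        log_lam[i] = a[i] + f + rng.normal(0.0, otu_noise_sd, n)
    w = np.exp(log_lam)
    counts = np.empty((n_otus, n), dtype=int)
    for s in range(n):
        counts[:, s] = rng.multinomial(depth, w[:, s] / w[:, s].sum())
    ids = [f"S{i + 1:02d}" for i in range(n)]
    taxonomy = None
    if phyla is not None:
        domain = "Fungi" if kind_label == "fungi" else "Bacteria"
        # phylum loosely follows module membership, with some mixing
        module_phylum = {m: phyla[m % len(phyla)] for m in profiles}
        taxonomy = {}
        for otu in otus:
            if rng.random() < 0.7:
                ph = module_phylum[truth.module_of[otu]]
            else:
                ph = phyla[rng.integers(len(phyla))]
            taxonomy[otu] = f"{domain};{ph};genus_{rng.integers(100):02d}"
    df = pd.DataFrame(counts, index=pd.Index(otus, name="otu_id"), columns=ids)
    return OtuTable(df.astype(float), taxonomy=taxonomy, kind_label=kind_label)


def end_to_end_fixture(preset: str = "bacteria_like", seed: int = 0,
                       n_samples: int = DEFAULT_N_SAMPLES,
                       effect_size: float | None = None):
    """A ready-to-run (OtuTable, EnvTable, SyntheticTruth) triple.

    ``bacteria_like``: many OTUs, most modules responsive — the community-
    level composition tracks the hydrological gradient.  ``fungi_like``:
    fewer OTUs, exactly one responsive module, and one dropped sample —
    only that module's dissimilarity should track the gradient.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[preset]
    if effect_size is None:
        effect_size = spec["effect_size"]
    ss = np.random.SeedSequence(seed)
    s_env, s_truth, s_comm = (int(x) for x in ss.generate_state(3) % (2**31 - 1))
    rng = np.random.default_rng(s_env)
    g = _latent_gradient(n_samples, rng)
    env = generate_env(n_samples, seed=s_env, gradient=g)
    truth = make_truth(spec["n_otus"], spec["module_fractions"],
                       spec["responsive"], g, effect_size=effect_size,
                       seed=s_truth)
    otu = generate_community(truth, depth=spec["depth"], seed=s_comm,
                             kind_label=spec["kind_label"], phyla=spec["phyla"],
                             idio_responsive=spec["idio_responsive"],
                             idio_noise=spec["idio_noise"])
    if spec["drop_sample"] is not None:
        keep = [s for k, s in enumerate(otu.sample_ids) if k != spec["drop_sample"]]
        otu = otu.restrict_samples(keep)
    return otu, env, truth
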