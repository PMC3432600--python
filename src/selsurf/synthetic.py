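"""Synthetic tadpole collections with known trait–fitness structure.

Real surveys of *Spea multiplicata* tadpoles record, for each individual,
snout–vent length (SVL), orbitohyoideus jaw-muscle width (OH), an ordinal
mouthpart score (MP, 1 = most omnivore-like … 5 = most carnivore-like) and a
denticle-row count (DR), grouped into pond collections.  No such raw data are
redistributable, so this module generates collections with the statistical
structure the downstream analysis assumes:

* a latent trophic morph ``z*`` per tadpole, drawn from a symmetric
  two-component Gaussian mixture (omnivore vs carnivore ecomorphs) and
  standardized to unit total SD;
* observable traits driven by ``z*``: MP rises with it, DR falls with it
  (carnivores have fewer denticle rows), and OH scales allometrically with
  SVL plus a morph effect;
* ln SVL — the fitness proxy — following a configurable quadratic function of
  ``z*``, so the true linear (``beta_true``) and quadratic (``gamma_true``)
  selection effects are known exactly.  A positive ``gamma_true`` creates
  disruptive selection (fitness minimum at intermediate morphs), a negative
  one stabilizing selection.

Pond-level ecological covariates (ordinal conspecific density, fairy-shrimp
density, fractional vegetative cover) can be generated with a configurable
monotone link to each pond's true quadratic effect, emulating the field
pattern that disruptive selection concentrates where per-capita resources
are scarce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["GeneratorConfig", "generate_pond", "generate_ponds", "generate_ecology"]

# Offset separating the ecology RNG stream from the per-pond streams
# (pond i uses seed + i, so streams stay disjoint for any n_ponds <= offset).
_ECOLOGY_SEED_OFFSET = 100003


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic survey.

    Parameters
    ----------
    n_ponds : int
        Number of pond collections.
    n_per_pond : int or sequence of int
        Tadpoles per pond (single value or one per pond).  Must be >= 10.
    bimodality : float
        Separation of the two morph-mixture components in units of the
        component SD (0 = unimodal; >= 3 gives visibly bimodal morphology).
    beta_true : float
        Linear effect of the latent morph on ln SVL, per SD of morph.
    gamma_true : float
        Quadratic effect on ln SVL per SD^2; + disruptive, - stabilizing.
    noise_sd : float
        Residual SD of ln SVL (dimensionless, log scale).  Default 0.15
        corresponds to ~15% individual size variation, typical of larval
        anuran cohorts.
    allometry_slope : float
        Slope of ln OH on ln SVL (jaw muscle scales slightly negatively
        allometric with body length).
    seed : int
        Base RNG seed; pond ``i`` uses ``seed + i``.
    baseline_ln_svl : float
        Mean ln SVL (mm) of an average morph; default ln(25 mm) ~= 3.22.
    oh_intercept : float
        Intercept of the ln OH allometry.
    morph_oh_effect : float
        Additive effect of the latent morph on ln OH (carnivores have
        larger jaw muscles at a given body size).
    oh_noise_sd : float
        Residual SD of ln OH.
    ecology_link : float in [0, 1]
        Strength of the monotone association between a pond's true
        quadratic effect and its ecological covariates (0 = independent).
    """

    n_ponds: int = 22
    n_per_pond: int | tuple[int, ...] = 130
    bimodality: float = 3.0
    beta_true: float = 0.05
    gamma_true: float = 0.1
    noise_sd: float = 0.15
    allometry_slope: float = 0.8
    seed: int = 0
    baseline_ln_svl: float = 3.22
    oh_intercept: float = -1.6
    morph_oh_effect: float = 0.12
    oh_noise_sd: float = 0.05
    ecology_link: float = 0.8
    year: int = 2006

    def __post_init__(self) -> None:
        if self.n_ponds < 1:
            raise ValueError("n_ponds must be a positive integer")
        for n in self.pond_sizes():
            if n < 10:
                raise ValueError("n_per_pond must be >= 10 for every pond")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.bimodality < 0:
            raise ValueError("bimodality must be >= 0")
        if not 0.0 <= self.ecology_link <= 1.0:
            raise ValueError("ecology_link must lie in [0, 1]")

    def pond_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_pond, int):
            return (self.n_per_pond,) * self.n_ponds
        sizes = tuple(int(n) for n in self.n_per_pond)
        if len(sizes) != self.n_ponds:
            raise ValueError("n_per_pond list must have one entry per pond")
        return sizes


def _mixture_quantiles(bimodality: float, probs: np.ndarray) -> np.ndarray:
    """Quantiles of the standardized symmetric two-component normal mixture."""
    scale = np.sqrt(1.0 + bimodality**2 / 4.0)
    mu = bimodality / 2.0

    def cdf(x: float) -> float:
        xs = x * scale
        return 0.5 * (norm.cdf(xs - mu) + norm.cdf(xs + mu))

    lo, hi = -10.0, 10.0
    return np.array([brentq(lambda x, p=p: cdf(x) - p, lo, hi) for p in probs])


def _draw_latent_morph(rng: np.random.Generator, n: int, bimodality: float) -> np.ndarray:
    """Latent morph z*: mixture components at +-b/2 (unit component SD),
    standardized so the total SD is exactly 1 for any b >= 0."""
    component = rng.choice([-1.0, 1.0], size=n)
    z = component * bimodality / 2.0 + rng.standard_normal(n)
    return z / np.sqrt(1.0 + bimodality**2 / 4.0)


def _mouthpart_scores(z: np.ndarray, bimodality: float) -> np.ndarray:
    # Equal-probability quintile cut points of the mixture keep all five
    # ordinal levels populated regardless of the separation parameter.
    cuts = _mixture_quantiles(bimodality, np.array([0.2, 0.4, 0.6, 0.8]))
    return (np.searchsorted(cuts, z) + 1).astype(int)


def generate_pond(config: GeneratorConfig, pond_index: int) -> pd.DataFrame:
    """Generate one pond collection of tadpole records.

    Returns a DataFrame with columns ``pond_id, year, SVL_mm, OH_mm, MP, DR``
    plus the ground-truth latent morph ``z_true`` (for validation; drop it to
    mimic field data).  Identical ``(config.seed, pond_index)`` gives
    bit-identical output.
    """
    sizes = config.pond_sizes()
    if not 0 <= pond_index < config.n_ponds:
        raise ValueError(f"pond_index {pond_index} outside 0..{config.n_ponds - 1}")
    n = sizes[pond_index]
    if n <= 0:
        raise ValueError("degenerate pond: non-positive sample size")

    rng = np.random.default_rng(config.seed + pond_index)
    z = _draw_latent_morph(rng, n, config.bimodality)

    mp = _mouthpart_scores(z, config.bimodality)
    # Carnivore-like tadpoles have fewer denticle rows.
    dr = np.maximum(0, np.rint(6.0 - 2.0 * z)).astype(int)

    ln_svl = (
        config.baseline_ln_svl
        + config.beta_true * z
        + (config.gamma_true / 2.0) * z**2
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    ln_oh = (
        config.oh_intercept
        + config.allometry_slope * ln_svl
        + config.morph_oh_effect * z
        + rng.normal(0.0, config.oh_noise_sd, size=n)
    )

    return pd.DataFrame(
        {
            "pond_id": f"P{pond_index:02d}",
            "year": config.year,
            "SVL_mm": np.exp(ln_svl),
            "OH_mm": np.exp(ln_oh),
            "MP": mp,
            "DR": dr,
            "z_true": z,
        }
    )


def generate_ponds(
    config: GeneratorConfig, gamma_true_by_pond: "list[float] | None" = None
) -> pd.DataFrame:
    """All pond collections, optionally with a distinct true quadratic effect
    per pond, concatenated into one tadpole table."""
    frames = []
    for i in range(config.n_ponds):
        cfg = config
        if gamma_true_by_pond is not None:
            if len(gamma_true_by_pond) != config.n_ponds:
                raise ValueError("need one gamma_true per pond")
            cfg = _with_gamma(config, float(gamma_true_by_pond[i]))
        frames.append(generate_pond(cfg, i))
    return pd.concat(frames, ignore_index=True)


def _with_gamma(config: GeneratorConfig, gamma: float) -> GeneratorConfig:
    from dataclasses import replace

    return replace(config, gamma_true=gamma)


def generate_ecology(
    config: GeneratorConfig, gamma_true_by_pond: "list[float]"
) -> pd.DataFrame:
    """Pond-level ecological covariates with a monotone link to selection.

    With ``config.ecology_link = L``, ordinal tadpole density (1-3) increases
    in the pond's true quadratic effect and resource abundance (fairy-shrimp
    category and vegetative cover, a proxy for detritus) decreases in it, so
    per-capita resource availability falls as disruptive selection rises —
    the association the competition hypothesis predicts.  ``L = 0`` makes the
    covariates independent of selection; ``L = 1`` makes the latent ordering
    deterministic (ordinal ties aside).
    """
    gammas = np.asarray(gamma_true_by_pond, dtype=float)
    if gammas.shape[0] != config.n_ponds:
        raise ValueError("need one gamma_true per pond")
    rng = np.random.default_rng(config.seed + _ECOLOGY_SEED_OFFSET)
    k = config.n_ponds
    L = config.ecology_link

    # Rank-normalized gamma in (0, 1); midranks for ties.
    order = pd.Series(gammas).rank(method="average").to_numpy()
    r = order / (k + 1.0)

    dens_latent = L * r + (1.0 - L) * rng.uniform(size=k)
    res_latent = L * (1.0 - r) + (1.0 - L) * rng.uniform(size=k)
    cover_latent = L * (1.0 - r) + (1.0 - L) * rng.uniform(size=k)

    density = np.digitize(dens_latent, [1.0 / 3.0, 2.0 / 3.0]) + 1
    shrimp = np.digitize(res_latent, [1.0 / 3.0, 2.0 / 3.0]) + 1
    cover = np.clip(cover_latent, 1e-6, 1.0)

    sizes = config.pond_sizes()
    return pd.DataFrame(
        {
            "pond_id": [f"P{i:02d}" for i in range(k)],
            "tadpole_density": density.astype(int),
            "shrimp_density": shrimp.astype(int),
            "cover": cover,
            "n": sizes,
        }
    )
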