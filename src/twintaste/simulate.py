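"""Twin-structured synthetic data with known genetic/environmental ground truth.

Two layers are generated:

1. **Latent twin traits.** For ``k`` traits, per-component covariance
   matrices ``Sigma_A`` (additive genetic), ``Sigma_C`` (shared
   environment), ``Sigma_D`` (dominance) and ``Sigma_E`` (unique
   environment) define a classical twin model: monozygotic (MZ) co-twins
   share their A (and D) draws, dizygotic (DZ) co-twins' A draws correlate
   0.5 and D draws 0.25, C is shared within every family and E is
   independent.  The expected co-twin covariance is therefore
   ``Sigma_A + Sigma_C + Sigma_D`` for MZ and
   ``0.5 Sigma_A + 0.25 Sigma_D + Sigma_C`` for DZ.

2. **Image ratings.** Per visual domain, each rating decomposes additively
   (before optional clipping) into a grand mean, an image value, the
   individual's evaluation bias, a typicality-weighted image value, an
   individual-by-image idiosyncrasy, an exposure (presentation) effect and
   residual noise.  The bias offset and the typicality weight are
   deterministic linear functions of the latent twin traits, so the
   downstream evaluation-bias and taste-typicality metrics inherit the
   configured A/C/D/E structure.

Counts and rating-layer scales default to the discovery-sample study
conditions (558 MZ + 216 DZ same-sex pairs, 65 images of which 15 are shown
twice, 1-7 rating scale, ages 21-68).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DomainConfig",
    "SimulationConfig",
    "simulate_twin_traits",
    "simulate_ratings",
    "simulate_control_scores",
    "write_simulation",
    "trait_only_config",
    "univariate_config",
    "bivariate_ae_config",
    "bias_dominant_config",
]


@dataclass(frozen=True)
class DomainConfig:
    """Rating-layer parameters for one visual domain.

    Standard deviations are on the rating scale.  ``typicality_scale`` and
    ``bias_scale`` map the standardized latent traits onto the individual's
    weight on the shared image values (weight = 1 + scale * trait) and onto
    the individual rating offset, respectively.
    """

    name: str
    n_images: int = 65
    n_repeats: int = 15
    image_sd: float = 1.0
    taste_sd: float = 0.7
    exposure_sd: float = 0.1
    residual_sd: float = 0.6
    typicality_scale: float = 0.4
    bias_scale: float = 0.5

    def __post_init__(self):
        if self.n_repeats > self.n_images:
            raise ValueError("n_repeats cannot exceed n_images")
        for attr in ("image_sd", "taste_sd", "exposure_sd", "residual_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")


def _as_cov(mat, k: int, name: str) -> np.ndarray:
    m = np.zeros((k, k)) if mat is None else np.atleast_2d(np.asarray(mat, dtype=float))
    if m.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(m)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {eig.min():.3g})")
    return m


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification for a twin-rating simulation.

    ``trait_names`` orders the latent traits; when ``domains`` are present
    the convention is ``(typicality_<domain>, bias_<domain>)`` per domain.
    The four component matrices are trait x trait covariances in trait
    units squared (traits are typically standardized, so shares of 1).
    """

    n_mz_pairs: int
    n_dz_pairs: int
    trait_names: tuple[str, ...]
    sigma_a: np.ndarray = None
    sigma_c: np.ndarray = None
    sigma_d: np.ndarray = None
    sigma_e: np.ndarray = None
    domains: tuple[DomainConfig, ...] = ()
    grand_mean: float = 4.0
    rating_scale: tuple[float, float] = (1.0, 7.0)
    clip_ratings: bool = False
    round_ratings: bool = False
    sex_ratio: float = 0.76
    age_range: tuple[float, float] = (21.0, 68.0)
    seed: int = 0

    def __post_init__(self):
        k = len(self.trait_names)
        if k == 0:
            raise ValueError("at least one trait is required")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0 or self.n_mz_pairs + self.n_dz_pairs == 0:
            raise ValueError("need a positive number of twin pairs")
        if not self.rating_scale[0] < self.rating_scale[1]:
            raise ValueError("rating_scale lower bound must be below upper bound")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        for comp in ("sigma_a", "sigma_c", "sigma_d", "sigma_e"):
            object.__setattr__(self, comp, _as_cov(getattr(self, comp), k, comp))
        total = np.diag(self.sigma_a + self.sigma_c + self.sigma_d + self.sigma_e)
        if np.any(total <= 0):
            bad = [self.trait_names[i] for i in np.flatnonzero(total <= 0)]
            raise ValueError(f"total variance must be > 0 for every trait; zero for {bad}")
        # The classical twin design cannot separate C from D within a trait.
        both = np.flatnonzero((np.diag(self.sigma_c) > 0) & (np.diag(self.sigma_d) > 0))
        if both.size:
            warnings.warn(
                "C and D are both nonzero for trait(s) "
                f"{[self.trait_names[i] for i in both]}; a classical twin design "
                "cannot identify both components",
                stacklevel=2,
            )
        if self.domains and k != 2 * len(self.domains):
            raise ValueError("expect two traits (typicality, bias) per domain")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_pairs(self) -> int:
        return self.n_mz_pairs + self.n_dz_pairs

    def ground_truth(self) -> dict:
        """All configured variances, for oracle tests and sidecar files."""
        return {
            "trait_names": list(self.trait_names),
            "sigma_a": self.sigma_a.tolist(),
            "sigma_c": self.sigma_c.tolist(),
            "sigma_d": self.sigma_d.tolist(),
            "sigma_e": self.sigma_e.tolist(),
            "domains": [vars(d).copy() for d in self.domains],
            "grand_mean": self.grand_mean,
            "seed": self.seed,
        }

    @classmethod
    def default(cls, n_mz_pairs: int = 558, n_dz_pairs: int = 216, seed: int = 0
                ) -> "SimulationConfig":
        """Two-domain (scenes, faces) study-like configuration.

        Trait variance components follow the final univariate AE models
        (typicality A = 0.36/0.33, bias A = 0.26/0.41) with cross-domain
        additive-genetic covariance 0.18 for typicality and a moderate
        genetic and environmental overlap for bias.
        """
        names = ("typicality_scenes", "bias_scenes", "typicality_faces", "bias_faces")
        a = np.array([
            [0.36, 0.00, 0.18, 0.00],
            [0.00, 0.26, 0.00, 0.17],
            [0.18, 0.00, 0.33, 0.00],
            [0.00, 0.17, 0.00, 0.41],
        ])
        e = np.array([
            [0.64, 0.00, 0.09, 0.00],
            [0.00, 0.74, 0.00, 0.25],
            [0.09, 0.00, 0.67, 0.00],
            [0.00, 0.25, 0.00, 0.59],
        ])
        return cls(
            n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs, trait_names=names,
            sigma_a=a, sigma_e=e,
            domains=(DomainConfig("scenes"), DomainConfig("faces")),
            seed=seed,
        )


def trait_only_config(sigma_a=None, sigma_c=None, sigma_d=None, sigma_e=None, *,
                      trait_names=("trait",), n_mz_pairs=558, n_dz_pairs=216,
                      seed=0, **kwargs) -> SimulationConfig:
    """Configuration for latent traits alone (no rating layer)."""
    return SimulationConfig(
        n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs, trait_names=tuple(trait_names),
        sigma_a=sigma_a, sigma_c=sigma_c, sigma_d=sigma_d, sigma_e=sigma_e, seed=seed,
        **kwargs,
    )


def univariate_config(a=0.0, c=0.0, d=0.0, e=1.0, *, n_mz_pairs=558, n_dz_pairs=216,
                      seed=0, trait_name="trait") -> SimulationConfig:
    """Single-trait twin configuration with scalar A/C/D/E variances."""
    return trait_only_config(
        sigma_a=[[a]], sigma_c=[[c]], sigma_d=[[d]], sigma_e=[[e]],
        trait_names=(trait_name,), n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs, seed=seed,
    )


def bivariate_ae_config(a1, a2, a12, e12=0.0, *, totals=(1.0, 1.0),
                        n_mz_pairs=1070, n_dz_pairs=430, seed=0,
                        trait_names=("trait1", "trait2")) -> SimulationConfig:
    """Bivariate AE configuration from A variances/covariance and E covariance.

    E variances are the complements making each trait's total equal
    ``totals`` (standardized traits by default).
    """
    sa = [[a1, a12], [a12, a2]]
    se = [[totals[0] - a1, e12], [e12, totals[1] - a2]]
    return trait_only_config(sigma_a=sa, sigma_e=se, trait_names=tuple(trait_names),
                             n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs, seed=seed)


def bias_dominant_config(n_mz_pairs=320, n_dz_pairs=200, seed=0) -> SimulationConfig:
    """One-domain scenario whose individual-level rating variance is
    dominated by evaluation-bias differences (used to check that the first
    principal axis of the rating matrix tracks evaluation-bias)."""
    names = ("typicality_abstract", "bias_abstract")
    return SimulationConfig(
        n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs, trait_names=names,
        sigma_a=np.diag([0.36, 0.32]), sigma_e=np.diag([0.64, 0.68]),
        domains=(DomainConfig("abstract", taste_sd=0.6, residual_sd=0.5,
                              typicality_scale=0.3, bias_scale=1.0),),
        seed=seed,
    )


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Draw from N(0, cov) robustly for singular PSD covariance."""
    k = cov.shape[0]
    if not np.any(cov):
        return np.zeros((size, k))
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return rng.standard_normal((size, k)) @ (v * np.sqrt(w)).T


def simulate_twin_traits(config: SimulationConfig) -> pd.DataFrame:
    """Generate latent twin traits honouring the configured A/C/D/E structure.

    Returns a long-format frame with one row per individual:
    ``family_id, individual_id, twin_order, zygosity, sex, age`` plus one
    column per trait.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    nm, nd, k = config.n_mz_pairs, config.n_dz_pairs, config.n_traits

    def _pair_block(n, rho_a, rho_d):
        # shared + unique split gives co-twin correlation rho for A and D
        a_sh = _mvn(rng, rho_a * config.sigma_a, n)
        a_un = [_mvn(rng, (1 - rho_a) * config.sigma_a, n) for _ in range(2)]
        d_sh = _mvn(rng, rho_d * config.sigma_d, n)
        d_un = [_mvn(rng, (1 - rho_d) * config.sigma_d, n) for _ in range(2)]
        c = _mvn(rng, config.sigma_c, n)
        e = [_mvn(rng, config.sigma_e, n) for _ in range(2)]
        return [a_sh + a_un[t] + d_sh + d_un[t] + c + e[t] for t in range(2)]

    mz = _pair_block(nm, 1.0, 1.0)
    dz = _pair_block(nd, 0.5, 0.25)

    n_fam = nm + nd
    sex = np.where(rng.random(n_fam) < config.sex_ratio, "F", "M")
    age = np.round(rng.uniform(*config.age_range, size=n_fam), 1)

    rows = []
    for t in range(2):
        values = np.vstack([mz[t], dz[t]])
        df = pd.DataFrame(values, columns=list(config.trait_names))
        df.insert(0, "family_id", np.arange(n_fam))
        df.insert(1, "individual_id", [f"I{f:05d}_{t + 1}" for f in range(n_fam)])
        df.insert(2, "twin_order", t + 1)
        df.insert(3, "zygosity", ["MZ"] * nm + ["DZ"] * nd)
        df.insert(4, "sex", sex)
        df.insert(5, "age", age)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["family_id", "twin_order"], ignore_index=True)


def simulate_ratings(config: SimulationConfig, traits: pd.DataFrame) -> pd.DataFrame:
    """Generate the per-presentation rating table implied by the latent traits.

    Each rating is ``grand_mean + weight * image + bias + idiosyncrasy +
    exposure + residual`` where ``weight = 1 + typicality_scale *
    typicality_trait`` and ``bias = bias_scale * bias_trait``; the
    ``n_repeats`` first images of each domain appear with presentation
    index 1 and 2.  Deterministic given config and traits.
    """
    if not config.domains:
        raise ValueError("config declares no rating domains")
    need = 2 * (config.n_mz_pairs + config.n_dz_pairs)
    if len(traits) != need:
        raise ValueError(f"traits/config mismatch: {len(traits)} individuals, expected {need}")
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.rating_scale
    frames = []
    n_ind = len(traits)
    for di, dc in enumerate(config.domains):
        typ = traits[config.trait_names[2 * di]].to_numpy()
        bias = traits[config.trait_names[2 * di + 1]].to_numpy()
        weight = 1.0 + dc.typicality_scale * typ
        offset = dc.bias_scale * bias

        img = rng.normal(0.0, dc.image_sd, size=dc.n_images)
        expo = rng.normal(0.0, dc.exposure_sd, size=2)
        idio = rng.normal(0.0, dc.taste_sd, size=(n_ind, dc.n_images))

        image_idx = np.concatenate([np.arange(dc.n_images), np.arange(dc.n_repeats)])
        pres = np.concatenate([np.ones(dc.n_images, int), np.full(dc.n_repeats, 2)])
        base = (weight[:, None] * img[image_idx][None, :]
                + offset[:, None]
                + idio[:, image_idx]
                + expo[pres - 1][None, :]
                + config.grand_mean)
        base = base + rng.normal(0.0, dc.residual_sd, size=base.shape)
        if config.round_ratings:
            base = np.round(base)
        if config.clip_ratings:
            base = np.clip(base, lo, hi)

        n_obs = base.shape[1]
        frame = pd.DataFrame({
            "family_id": np.repeat(traits["family_id"].to_numpy(), n_obs),
            "individual_id": np.repeat(traits["individual_id"].to_numpy(), n_obs),
            "twin_order": np.repeat(traits["twin_order"].to_numpy(), n_obs),
            "zygosity": np.repeat(traits["zygosity"].to_numpy(), n_obs),
            "sex": np.repeat(traits["sex"].to_numpy(), n_obs),
            "age": np.repeat(traits["age"].to_numpy(), n_obs),
            "domain": dc.name,
            "image_id": np.tile([f"{dc.name}_{i:03d}" for i in image_idx], n_ind),
            "presentation": np.tile(pres, n_ind),
            "rating": base.ravel(),
        })
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_control_scores(traits: pd.DataFrame, confound_loading: float, *,
                            typicality_col: str, bias_col: str,
                            seed: int = 0) -> pd.DataFrame:
    """Control-task typicality/bias scores correlated with the aesthetic traits.

    Each control score is ``loading * z(trait) + sqrt(1 - loading^2) * noise``
    so its population correlation with the aesthetic score equals the
    loading exactly.
    """
    if not 0 <= confound_loading <= 1:
        raise ValueError("confound_loading must be in [0, 1]")
    rng = np.random.default_rng([seed, 2])
    resid = np.sqrt(1.0 - confound_loading**2)
    out = {"individual_id": traits["individual_id"].to_numpy()}
    for name, col in (("control_typicality", typicality_col), ("control_bias", bias_col)):
        x = traits[col].to_numpy()
        sd = x.std(ddof=0)
        z = (x - x.mean()) / (sd if sd > 0 else 1.0)
        out[name] = confound_loading * z + resid * rng.standard_normal(len(x))
    return pd.DataFrame(out)


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the ratings CSV and a ground-truth JSON sidecar to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traits = simulate_twin_traits(config)
    ratings = simulate_ratings(config, traits)
    paths = {
        "ratings": out_dir / "ratings.csv",
        "truth": out_dir / "ground_truth.json",
        "traits": out_dir / "latent_traits.csv",
    }
    # %.17g keeps the CSV round trip bit-exact for float64 ratings
    ratings.to_csv(paths["ratings"], index=False, float_format="%.17g")
    traits.to_csv(paths["traits"], index=False, float_format="%.17g")
    paths["truth"].write_text(json.dumps(config.ground_truth(), indent=2))
    return paths
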