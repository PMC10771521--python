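"""Multivariate classical twin design: shared etiology across traits.

The multivariate CTD exploits cross-twin cross-trait covariances (trait
*i* of twin 1 with trait *j* of twin 2) to partition the phenotypic
covariance between traits into additive-genetic (A), shared-environmental
(C) and unique-environmental (E) covariance components.  Per-component
trait x trait covariance matrices ``Sigma_A``, ``Sigma_C``, ``Sigma_E``
are estimated directly (direct symmetric approach, entries unbounded), by
full-information ML over the stacked per-family Gaussian whose cross-twin
block is ``Sigma_A + Sigma_C`` for MZ and ``0.5 Sigma_A + Sigma_C`` for DZ
pairs.

Derived quantities:

* bivariate heritability ``h2_b = sigma_Aij / (sigma_Aij + sigma_Cij +
  sigma_Eij)`` - the share of the phenotypic covariance between traits i
  and j accounted for by additive genetics;
* genetic correlation ``rhoA = sigma_Aij / sqrt(sigma2_Ai * sigma2_Aj)``
  and the analogous environmental correlation ``rhoE``.

Per-trait component inclusion (e.g. A for two traits only, C for a third)
is expressed by zeroing the excluded trait's row/column of that component
matrix; the E block is always full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "make_multitrait_pairs",
    "MultivariateTwinModel",
    "MultivariateTwinResults",
    "fit_multivariate",
    "saturated_minus2ll",
    "bivariate_heritability",
    "genetic_correlation",
    "cross_twin_cross_trait_correlations",
]

_CROSS_WEIGHT = {"A": {"MZ": 1.0, "DZ": 0.5},
                 "C": {"MZ": 1.0, "DZ": 1.0},
                 "D": {"MZ": 1.0, "DZ": 0.25},
                 "E": {"MZ": 0.0, "DZ": 0.0}}


def bivariate_heritability(sigma_a_ij: float, sigma_c_ij: float = 0.0,
                           sigma_e_ij: float = 0.0, clip: bool = True) -> float:
    """Share of the phenotypic covariance between two traits due to A.

    ``h2_b = sigma_Aij / (sigma_Aij + sigma_Cij + sigma_Eij)``.  Values
    outside [0, 1] (possible with direct-symmetric estimates) are clipped
    with a warning unless ``clip`` is False.
    """
    total = sigma_a_ij + sigma_c_ij + sigma_e_ij
    if total == 0:
        raise ValueError("phenotypic covariance is zero; bivariate h2 undefined")
    h2b = sigma_a_ij / total
    if clip and not 0 <= h2b <= 1:
        warnings.warn(f"bivariate heritability {h2b:.3f} outside [0, 1]; clipped",
                      stacklevel=2)
        h2b = float(np.clip(h2b, 0.0, 1.0))
    return float(h2b)


def genetic_correlation(sigma_a_ij: float, sigma2_a_i: float, sigma2_a_j: float
                        ) -> float:
    """``rhoA = sigma_Aij / sqrt(sigma2_Ai * sigma2_Aj)``."""
    if sigma2_a_i <= 0 or sigma2_a_j <= 0:
        raise ValueError("genetic correlation undefined: nonpositive A variance")
    return float(sigma_a_ij / np.sqrt(sigma2_a_i * sigma2_a_j))


def make_multitrait_pairs(individuals: pd.DataFrame, value_cols: list[str]
                          ) -> pd.DataFrame:
    """Wide per-family table ``y_<trait>_<member>`` from per-individual rows.

    ``individuals`` needs family_id, twin_order, zygosity, sex, age plus
    one column per trait.
    """
    d = individuals.reset_index()
    wide = d.pivot(index="family_id", columns="twin_order", values=value_cols)
    meta = d.drop_duplicates("family_id").set_index("family_id")[["zygosity", "sex"]]
    out = {"zygosity": meta["zygosity"], "sex": meta["sex"]}
    for col in value_cols:
        for t in (1, 2):
            out[f"y_{col}_{t}"] = wide.get((col, t))
    return pd.DataFrame(out).reset_index()


def cross_twin_cross_trait_correlations(pairs: pd.DataFrame, traits: list[str]
                                        ) -> dict[str, pd.DataFrame]:
    """Empirical per-zygosity cross-twin cross-trait correlation matrices.

    Entry (i, j): Pearson correlation of twin 1's trait i with twin 2's
    trait j, symmetrized by averaging the two twin orderings.
    """
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs["zygosity"] == zyg]
        y1 = sub[[f"y_{t}_1" for t in traits]].to_numpy(dtype=float)
        y2 = sub[[f"y_{t}_2" for t in traits]].to_numpy(dtype=float)
        ok = np.isfinite(y1).all(axis=1) & np.isfinite(y2).all(axis=1)
        if ok.sum() < 20:
            raise ValueError(f"fewer than 20 complete {zyg} pairs")
        y1, y2 = y1[ok], y2[ok]
        k = len(traits)
        m = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                a = np.corrcoef(y1[:, i], y2[:, j])[0, 1]
                b = np.corrcoef(y1[:, j], y2[:, i])[0, 1]
                m[i, j] = 0.5 * (a + b)
        out[zyg] = pd.DataFrame(m, index=traits, columns=traits)
    return out


class MultivariateTwinModel:
    """Direct-symmetric multivariate CTD model.

    Parameters
    ----------
    pairs : wide per-family table from :func:`make_multitrait_pairs`.
    traits : ordered trait names.
    include : mapping component -> list of traits loading on it, e.g.
        ``{"A": ["scenes", "faces"], "C": ["abstract"], "E": None}``;
        ``None`` means all traits.  E is always full.  A cross-trait
        covariance is free exactly when both traits load on the component.
    standardize : z-scale each trait over all observed values first
        (component matrices then live on the correlation-like scale).
    """

    def __init__(self, pairs: pd.DataFrame, traits: list[str],
                 include: dict[str, list | None] | None = None,
                 standardize: bool = True):
        self.traits = list(traits)
        self.k = len(self.traits)
        if self.k < 2:
            raise ValueError("need at least two traits")
        include = dict(include or {"A": None, "C": None, "E": None})
        include["E"] = None  # E block always full
        for comp in include:
            if comp not in "ACDE":
                raise ValueError(f"unknown component {comp!r}")
        if "C" in include and "D" in include:
            raise ValueError("C and D cannot both be included")
        self.components = tuple(c for c in "ACDE" if c in include)
        self.loading = {}
        for comp in self.components:
            tr = include[comp]
            tr = self.traits if tr is None else list(tr)
            unknown = set(tr) - set(self.traits)
            if unknown:
                raise ValueError(f"component {comp} lists unknown traits {sorted(unknown)}")
            self.loading[comp] = [self.traits.index(t) for t in tr]
        self.standardize = standardize
        self._prepare(pairs)
        self._index_params()

    def _prepare(self, pairs: pd.DataFrame):
        cols = [f"y_{t}_{m}" for m in (1, 2) for t in self.traits]
        missing = [c for c in cols if c not in pairs.columns]
        if missing:
            raise ValueError(f"missing trait columns: {missing}")
        y = pairs[cols].to_numpy(dtype=float)
        if self.standardize:
            for j in range(self.k):
                vals = y[:, [j, self.k + j]]
                mu, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
                if sd == 0:
                    raise ValueError(f"trait {self.traits[j]} has zero variance")
                y[:, [j, self.k + j]] = (vals - mu) / sd
        zyg = pairs["zygosity"].to_numpy()
        obs = np.isfinite(y)
        keep = obs.any(axis=1)
        y, zyg, obs = y[keep], zyg[keep], obs[keep]
        self.n_families = len(y)
        self.n_obs_values = int(obs.sum())
        self._groups = []
        pat_ids = [tuple(row) for row in obs]
        frame = pd.DataFrame({"zyg": zyg, "pat": pat_ids})
        for (z, pat), idx in frame.groupby(["zyg", "pat"], sort=False).groups.items():
            mask = np.array(pat)
            self._groups.append((z, mask, y[np.asarray(idx)][:, mask]))
        self._complete = {z: int(((zyg == z) & obs.all(axis=1)).sum())
                          for z in ("MZ", "DZ")}
        self._y = y
        self._zyg = zyg
        self._last_mu = np.zeros(self.k)  # refreshed by each likelihood eval

    def _index_params(self):
        self.param_index = []
        for comp in self.components:
            tr = self.loading[comp]
            for a_i, a_j in [(i, j) for idx, i in enumerate(tr) for j in tr[idx:]]:
                self.param_index.append((comp, a_i, a_j))
        self.n_comp_params = len(self.param_index)
        self.n_params = self.n_comp_params + self.k  # + trait means

    def _matrices(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        mats = {c: np.zeros((self.k, self.k)) for c in self.components}
        for val, (comp, i, j) in zip(theta, self.param_index):
            mats[comp][i, j] = mats[comp][j, i] = val
        return mats

    def _sigma(self, mats: dict[str, np.ndarray], zyg: str) -> np.ndarray:
        sw = sum(mats.values())
        sb = sum(_CROSS_WEIGHT[c][zyg] * m for c, m in mats.items())
        return np.block([[sw, sb], [sb, sw]])

    def _neg2ll(self, theta: np.ndarray) -> float:
        mats = self._matrices(theta)
        sig = {z: self._sigma(mats, z) for z in ("MZ", "DZ")}
        # profile the k trait means by GLS, then accumulate -2LL
        x_full = np.vstack([np.eye(self.k), np.eye(self.k)])
        chols, xtwx, xtwy = {}, np.zeros((self.k, self.k)), np.zeros(self.k)
        for gi, (z, mask, yv) in enumerate(self._groups):
            s = sig[z][np.ix_(mask, mask)]
            try:
                ch = np.linalg.cholesky(s)
            except np.linalg.LinAlgError:
                return 1e10
            chols[gi] = ch
            sinv = np.linalg.inv(s)
            xp = x_full[mask]
            xtwx += len(yv) * xp.T @ sinv @ xp
            xtwy += xp.T @ sinv @ yv.sum(axis=0)
        try:
            mu_tr = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return 1e10
        self._last_mu = mu_tr
        total = 0.0
        log2pi = np.log(2 * np.pi)
        for gi, (z, mask, yv) in enumerate(self._groups):
            ch = chols[gi]
            logdet = 2 * np.sum(np.log(np.diag(ch)))
            r = yv - (x_full[mask] @ mu_tr)
            w = np.linalg.solve(ch, r.T)
            total += len(yv) * (mask.sum() * log2pi + logdet) + float((w ** 2).sum())
        return float(total)

    def _moment_start(self) -> np.ndarray:
        """Crude component matrices from empirical within/cross covariances."""
        cov_w, cov_b = {}, {}
        for z in ("MZ", "DZ"):
            sel = (self._zyg == z) & np.isfinite(self._y).all(axis=1)
            yv = self._y[sel]
            if len(yv) < self.k * 2 + 2:
                cov_w[z] = np.eye(self.k)
                cov_b[z] = 0.3 * np.eye(self.k)
                continue
            s = np.cov(yv.T)
            sw = 0.5 * (s[:self.k, :self.k] + s[self.k:, self.k:])
            sb = 0.5 * (s[:self.k, self.k:] + s[self.k:, :self.k].T)
            cov_w[z], cov_b[z] = sw, 0.5 * (sb + sb.T)
        a0 = 2 * (cov_b["MZ"] - cov_b["DZ"])
        c0 = 2 * cov_b["DZ"] - cov_b["MZ"]
        sw = 0.5 * (cov_w["MZ"] + cov_w["DZ"])
        guesses = {"A": a0, "C": c0, "D": a0 * 0.5,
                   "E": sw - a0 - (c0 if "C" in self.components else 0)}
        x0 = []
        for comp, i, j in self.param_index:
            g = guesses[comp][i, j]
            if i == j and comp == "E":
                g = max(g, 0.2 * sw[i, i])
            x0.append(g)
        return np.array(x0)

    def fit(self, restarts: int = 2, seed: int = 0) -> "MultivariateTwinResults":
        x0 = self._moment_start()
        rng = np.random.default_rng(seed)
        best = None
        for trial in range(restarts + 1):
            xs = x0 if trial == 0 else x0 * (1 + rng.normal(0, 0.2, size=len(x0)))
            res = optimize.minimize(self._neg2ll, xs, method="BFGS",
                                    options={"gtol": 1e-7, "maxiter": 3000})
            res = optimize.minimize(self._neg2ll, res.x, method="Nelder-Mead",
                                    options={"xatol": 1e-9, "fatol": 1e-9,
                                             "maxiter": 20000, "maxfev": 20000})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        m2ll = float(self._neg2ll(best.x))
        mats = self._matrices(best.x)
        return MultivariateTwinResults(
            model=self,
            sigma={c: pd.DataFrame(m, index=self.traits, columns=self.traits)
                   for c, m in mats.items()},
            trait_means=pd.Series(self._last_mu, index=self.traits),
            theta=np.asarray(best.x, dtype=float),
            minus2ll=m2ll, n_params=self.n_params, aic=m2ll + 2 * self.n_params,
            converged=bool(best.success or best.fun < 1e9),
            message=str(best.message))

    # -- constrained refits for profile CIs ---------------------------------

    def _min_m2ll_fixed_derived(self, kind: str, i: int, j: int, value: float,
                                x0_full: np.ndarray | None = None) -> float:
        """Refit with rhoA or h2_b between traits i and j held fixed.

        The A cross-covariance parameter is substituted by the expression
        implied by the fixed derived quantity, keeping the problem
        unconstrained.
        """
        sub_idx = self.param_index.index(("A", min(i, j), max(i, j)))
        free_idx = [t for t in range(self.n_comp_params) if t != sub_idx]
        ia = self.param_index.index(("A", i, i))
        ja = self.param_index.index(("A", j, j))

        def a12(theta_full):
            if kind == "rhoA":
                va_i, va_j = theta_full[ia], theta_full[ja]
                if va_i <= 0 or va_j <= 0:
                    return None
                return value * np.sqrt(va_i * va_j)
            # h2b: a12 = h2b/(1-h2b) * (c12 + e12)
            if abs(1 - value) < 1e-12:
                return None
            other = 0.0
            for comp in ("C", "E"):
                key = (comp, min(i, j), max(i, j))
                if key in self.param_index:
                    other += theta_full[self.param_index.index(key)]
            return value / (1 - value) * other

        def obj(theta_free):
            full = np.empty(self.n_comp_params)
            full[free_idx] = theta_free
            full[sub_idx] = 0.0
            sub = a12(full)
            if sub is None:
                return 1e10
            full[sub_idx] = sub
            return self._neg2ll(full)

        if x0_full is None:
            x0_full = self._moment_start()
        res = optimize.minimize(obj, x0_full[free_idx], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8,
                                         "maxiter": 20000, "maxfev": 20000})
        return float(res.fun)


@dataclass
class MultivariateTwinResults:
    """Fitted multivariate CTD model with derived genetic overlap measures."""

    model: MultivariateTwinModel
    sigma: dict[str, pd.DataFrame]
    trait_means: pd.Series
    theta: np.ndarray
    minus2ll: float
    n_params: int
    aic: float
    converged: bool
    message: str
    _ci_cache: dict = field(default_factory=dict, repr=False)

    def _idx(self, trait) -> int:
        return self.model.traits.index(trait) if isinstance(trait, str) else int(trait)

    @property
    def phenotypic_covariance(self) -> pd.DataFrame:
        """Model-implied within-person trait covariance (sum of components)."""
        total = sum(m.to_numpy() for m in self.sigma.values())
        return pd.DataFrame(total, index=self.model.traits, columns=self.model.traits)

    def bivariate_heritability(self, trait_i, trait_j, clip: bool = True) -> float:
        i, j = self._idx(trait_i), self._idx(trait_j)
        parts = {c: self.sigma[c].iloc[i, j] if c in self.sigma else 0.0
                 for c in ("A", "C", "E")}
        return bivariate_heritability(parts["A"], parts["C"], parts["E"], clip=clip)

    def genetic_correlation(self, trait_i, trait_j) -> float:
        i, j = self._idx(trait_i), self._idx(trait_j)
        sa = self.sigma["A"].to_numpy()
        return genetic_correlation(sa[i, j], sa[i, i], sa[j, j])

    def environmental_correlation(self, trait_i, trait_j) -> float:
        i, j = self._idx(trait_i), self._idx(trait_j)
        se = self.sigma["E"].to_numpy()
        if se[i, i] <= 0 or se[j, j] <= 0:
            raise ValueError("environmental correlation undefined: nonpositive E variance")
        return float(se[i, j] / np.sqrt(se[i, i] * se[j, j]))

    def correlation_matrix(self, component: str) -> pd.DataFrame:
        """Component correlation matrix (e.g. rhoA for 'A', rhoE for 'E')."""
        m = self.sigma[component].to_numpy()
        d = np.sqrt(np.diag(m))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = m / np.outer(d, d)
        return pd.DataFrame(r, index=self.model.traits, columns=self.model.traits)

    def profile_ci(self, kind: str, trait_i, trait_j, level: float = 0.95,
                   search: tuple[float, float] | None = None, tol: float = 1e-3
                   ) -> tuple[float, float]:
        """Profile-likelihood CI for rhoA ('rhoA') or bivariate h2 ('h2b')."""
        i, j = self._idx(trait_i), self._idx(trait_j)
        key = (kind, i, j, level)
        if key in self._ci_cache:
            return self._ci_cache[key]
        center = (self.genetic_correlation(i, j) if kind == "rhoA"
                  else self.bivariate_heritability(i, j, clip=False))
        if search is None:
            search = (-0.99, 0.99) if kind == "rhoA" else (center - 1.0, min(center + 1.0, 0.999))
        crit = self.minus2ll + sps.chi2.ppf(level, 1)

        def excess(v):
            return self.model._min_m2ll_fixed_derived(kind, i, j, v,
                                                      x0_full=self.theta) - crit

        bounds = []
        for edge in search:
            lo, hi = sorted((center, edge))
            if excess(edge) < 0:
                bounds.append(-np.inf if edge < center else np.inf)
                continue
            bounds.append(optimize.brentq(excess, lo, hi, xtol=tol))
        out = (min(bounds), max(bounds))
        self._ci_cache[key] = out
        return out

    def compare(self, reduced: "MultivariateTwinResults") -> dict:
        from .univariate import compare_models
        return compare_models(self, reduced)

    def summary(self) -> str:
        lines = [
            f"Multivariate CTD model ({''.join(self.model.components)}), "
            f"traits: {', '.join(self.model.traits)}",
            f"  complete pairs: MZ {self.model._complete['MZ']}, "
            f"DZ {self.model._complete['DZ']}",
            f"  -2LL {self.minus2ll:.3f}   AIC {self.aic:.3f}   "
            f"free parameters {self.n_params}",
        ]
        for comp, mat in self.sigma.items():
            lines.append(f"  Sigma_{comp}:")
            lines.append("    " + mat.round(3).to_string().replace("\n", "\n    "))
        for ti, tj in combinations(self.model.traits, 2):
            parts = []
            if "A" in self.sigma:
                sa = self.sigma["A"]
                if sa.loc[ti, ti] > 0 and sa.loc[tj, tj] > 0:
                    parts.append(f"rhoA = {self.genetic_correlation(ti, tj):.3f}")
                    parts.append(f"h2_b = {self.bivariate_heritability(ti, tj, clip=False):.3f}")
            parts.append(f"rhoE = {self.environmental_correlation(ti, tj):.3f}")
            lines.append(f"  {ti} ~ {tj}: " + ", ".join(parts))
        return "\n".join(lines)


def fit_multivariate(pairs: pd.DataFrame, traits: list[str],
                     include: dict | None = None, standardize: bool = True,
                     **fit_kw) -> MultivariateTwinResults:
    """Fit the multivariate CTD model (convenience wrapper)."""
    return MultivariateTwinModel(pairs, traits, include, standardize).fit(**fit_kw)


@dataclass
class MVSaturatedResult:
    """Reference fit for the multivariate model-comparison chain."""

    minus2ll: float
    n_params: int
    aic: float
    n_families: int
    model: None = None


def saturated_minus2ll(pairs: pd.DataFrame, traits: list[str],
                       standardize: bool = True) -> MVSaturatedResult:
    """Saturated multivariate reference fit by per-zygosity sample moments.

    Unstructured 2k-variate mean vector and covariance matrix per
    zygosity, maximum likelihood on complete pairs (incomplete pairs are
    excluded with a warning — use the structured models for FIML over
    missing patterns).  Returns -2LL and the free parameter count
    ``2 * (2k + k(2k+1))``.
    """
    model = MultivariateTwinModel(pairs, traits, standardize=standardize)
    k = model.k
    total = 0.0
    n_used = 0
    log2pi = np.log(2 * np.pi)
    for z in ("MZ", "DZ"):
        sel = (model._zyg == z) & np.isfinite(model._y).all(axis=1)
        yv = model._y[sel]
        if len(yv) < 2 * k + 2:
            raise ValueError(f"too few complete {z} pairs for a saturated fit")
        mu = yv.mean(axis=0)
        s = np.cov(yv.T, ddof=0)
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            raise ValueError(f"singular saturated covariance for {z}")
        # ML at the sample moments: quad form reduces to n * 2k
        total += len(yv) * (2 * k * log2pi + logdet + 2 * k)
        n_used += len(yv)
    if n_used < model.n_families:
        warnings.warn(
            f"{model.n_families - n_used} incomplete families excluded from "
            "the saturated fit", stacklevel=2)
    n_params = 2 * (2 * k + k * (2 * k + 1))
    return MVSaturatedResult(minus2ll=float(total), n_params=n_params,
                             aic=float(total) + 2 * n_params, n_families=n_used)
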