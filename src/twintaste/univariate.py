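"""Univariate classical twin design models by full-information ML.

The classical twin design (CTD) partitions trait variance into additive
genetic (A), shared/common environmental (C) or dominance genetic (D), and
unique environmental (E, including measurement error) components from the
contrast between monozygotic (MZ) and dizygotic (DZ) same-sex twin pairs.
Under the model, the expected co-twin covariance is ``A + C + D`` for MZ
and ``0.5 A + C + 0.25 D`` for DZ, and every twin's variance is
``A + C + D + E``.

Estimation uses the *direct symmetric* parameterization: variance
components enter the expected covariance matrices directly and are
unbounded in sign, which removes the boundary bias of path-coefficient
(Cholesky) parameterizations and keeps likelihood-ratio tests on the
standard chi-square reference.  Incomplete pairs contribute the marginal
univariate Gaussian likelihood of their observed member (FIML).  Mean
covariates (sex, age) enter the mean model only, with identical
coefficients for both twins.

Heritability is the standardized A share, ``h2 = A / (A + C|D + E)``;
likelihood-based (profile) confidence intervals are available for raw
components and standardized shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import pearson_ci

__all__ = [
    "PAIR_COLUMNS",
    "make_pair_table",
    "UnivariateTwinModel",
    "UnivariateTwinResults",
    "SaturatedTwinModel",
    "SaturatedTwinResults",
    "fit_univariate",
    "fit_saturated",
    "compare_models",
    "heritability",
]

PAIR_COLUMNS = ["family_id", "zygosity", "sex", "age1", "age2", "y1", "y2"]

_COTWIN_WEIGHT = {"A": {"MZ": 1.0, "DZ": 0.5},
                  "C": {"MZ": 1.0, "DZ": 1.0},
                  "D": {"MZ": 1.0, "DZ": 0.25},
                  "E": {"MZ": 0.0, "DZ": 0.0}}
_CHI2_95 = sps.chi2.ppf(0.95, 1)  # 3.841...


def make_pair_table(individuals: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Wide per-family pair table from a long per-individual metric table.

    ``individuals`` must carry family_id, twin_order, zygosity, sex, age
    and ``value_col``; missing co-twins yield NaN entries (incomplete
    pairs).
    """
    d = individuals.reset_index()
    wide = d.pivot(index="family_id", columns="twin_order",
                   values=[value_col, "age"])
    meta = d.drop_duplicates("family_id").set_index("family_id")[["zygosity", "sex"]]
    out = pd.DataFrame({
        "zygosity": meta["zygosity"],
        "sex": meta["sex"],
        "age1": wide.get(("age", 1)),
        "age2": wide.get(("age", 2)),
        "y1": wide.get((value_col, 1)),
        "y2": wide.get((value_col, 2)),
    })
    return out.reset_index()


def _validate_components(components: str) -> tuple[str, ...]:
    comps = tuple(components.upper())
    if sorted(set(comps)) != sorted(comps):
        raise ValueError("duplicate components")
    bad = set(comps) - set("ACDE")
    if bad:
        raise ValueError(f"unknown components: {sorted(bad)}")
    if "E" not in comps:
        raise ValueError("E must always be included")
    if "C" in comps and "D" in comps:
        raise ValueError("C and D cannot both be included (not identified in a CTD)")
    return comps


class UnivariateTwinModel:
    """One-trait CTD variance-component model.

    Parameters
    ----------
    pairs : pair table with columns ``family_id, zygosity, sex, age1,
        age2, y1, y2`` (either y may be missing).
    components : subset of "ACDE" as a string, e.g. "ACE", "ADE", "AE",
        "CE" or "E".  E is mandatory; C and D are mutually exclusive.
    covariates : subset of ("sex", "age") entering the mean model.
    standardize : z-scale the trait over all observed values before
        fitting (shares are unaffected; raw components become shares of 1).
    """

    def __init__(self, pairs: pd.DataFrame, components: str = "ACE",
                 covariates: tuple[str, ...] = (), standardize: bool = False):
        self.components = _validate_components(components)
        self.covariates = tuple(covariates)
        bad = set(self.covariates) - {"sex", "age"}
        if bad:
            raise ValueError(f"unsupported covariates: {sorted(bad)}")
        self.pairs = pairs.reset_index(drop=True)
        if not self.pairs["zygosity"].isin(["MZ", "DZ"]).all():
            raise ValueError("zygosity must be MZ or DZ")
        self.standardize = standardize
        self._prepare()

    # -- data layout --------------------------------------------------------

    def _design_row(self, sex, age, age_center):
        row = [1.0]
        for cov in self.covariates:
            if cov == "sex":
                row.append(1.0 if sex == "F" else 0.0)
            else:
                row.append(0.0 if pd.isna(age) else age - age_center)
        return row

    def _prepare(self):
        d = self.pairs
        y = d[["y1", "y2"]].to_numpy(dtype=float)
        obs = np.isfinite(y)
        if not obs.any(axis=1).all():
            d = d[obs.any(axis=1)].reset_index(drop=True)
            y = d[["y1", "y2"]].to_numpy(dtype=float)
            obs = np.isfinite(y)
        if self.standardize:
            vals = y[obs]
            y = (y - vals.mean()) / vals.std(ddof=1)
        ages = d[["age1", "age2"]].to_numpy(dtype=float)
        age_center = np.nanmean(ages[obs]) if np.isfinite(ages[obs]).any() else 0.0
        self.p = 1 + len(self.covariates)
        self.n_obs_values = int(obs.sum())

        self._groups = {}
        for zyg in ("MZ", "DZ"):
            zmask = (d["zygosity"] == zyg).to_numpy()
            comp = zmask & obs[:, 0] & obs[:, 1]
            if comp.any():
                idx = np.flatnonzero(comp)
                x = np.array([[self._design_row(d.loc[i, "sex"], ages[i, t], age_center)
                               for t in range(2)] for i in idx])
                self._groups[(zyg, "pair")] = (y[idx], x)
            for t in range(2):
                single = zmask & obs[:, t] & ~obs[:, 1 - t]
                if single.any():
                    idx = np.flatnonzero(single)
                    x = np.array([self._design_row(d.loc[i, "sex"], ages[i, t], age_center)
                                  for i in idx])
                    self._groups[(zyg, f"single{t + 1}")] = (y[idx, t], x)
        self._n_complete = {z: self._groups.get((z, "pair"), (np.empty((0, 2)), None))[0].shape[0]
                            for z in ("MZ", "DZ")}

    # -- likelihood ---------------------------------------------------------

    def _sigma(self, comp_vals: dict[str, float], zyg: str) -> tuple[float, float]:
        v = sum(comp_vals.values())
        c = sum(val * _COTWIN_WEIGHT[k][zyg] for k, val in comp_vals.items())
        return v, c

    def minus2ll(self, comp_vals: dict[str, float], beta: np.ndarray) -> float:
        """-2 log likelihood at the given components and mean coefficients."""
        total = 0.0
        log2pi = np.log(2 * np.pi)
        for (zyg, kind), (yv, xv) in self._groups.items():
            v, c = self._sigma(comp_vals, zyg)
            if kind == "pair":
                det = v * v - c * c
                if v <= 0 or det <= 0:
                    return np.inf
                mu = xv @ beta
                r = yv - mu
                i11 = v / det
                i12 = -c / det
                quad = i11 * (r[:, 0] ** 2 + r[:, 1] ** 2) + 2 * i12 * r[:, 0] * r[:, 1]
                total += len(yv) * (2 * log2pi + np.log(det)) + quad.sum()
            else:
                if v <= 0:
                    return np.inf
                r = yv - xv @ beta
                total += len(yv) * (log2pi + np.log(v)) + (r ** 2).sum() / v
        return float(total)

    def _profiled_beta(self, comp_vals: dict[str, float]) -> np.ndarray | None:
        """GLS mean coefficients at fixed components (exact profile)."""
        xtwx = np.zeros((self.p, self.p))
        xtwy = np.zeros(self.p)
        for (zyg, kind), (yv, xv) in self._groups.items():
            v, c = self._sigma(comp_vals, zyg)
            if kind == "pair":
                det = v * v - c * c
                if v <= 0 or det <= 0:
                    return None
                sinv = np.array([[v, -c], [-c, v]]) / det
                xtwx += np.einsum("nip,ij,njq->pq", xv, sinv, xv)
                xtwy += np.einsum("nip,ij,nj->p", xv, sinv, yv)
            else:
                if v <= 0:
                    return None
                xtwx += xv.T @ xv / v
                xtwy += xv.T @ yv / v
        try:
            return np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return None

    def _objective(self, theta: np.ndarray, free: tuple[str, ...],
                   fixed: dict[str, float]) -> float:
        comp_vals = dict(zip(free, theta))
        comp_vals.update(fixed)
        comp_vals = {k: comp_vals[k] for k in self.components}
        beta = self._profiled_beta(comp_vals)
        if beta is None:
            return 1e10
        val = self.minus2ll(comp_vals, beta)
        return 1e10 if not np.isfinite(val) else val

    # -- fitting ------------------------------------------------------------

    def _moment_start(self) -> dict[str, float]:
        """Crude component starts from observed MZ/DZ covariances."""
        cov = {}
        var = []
        for zyg in ("MZ", "DZ"):
            g = self._groups.get((zyg, "pair"))
            if g is not None and len(g[0]) > 2:
                yv = g[0]
                s = np.cov(yv.T)
                cov[zyg] = float(s[0, 1])
                var.append(float(s[0, 0] + s[1, 1]) / 2)
        v = np.mean(var) if var else 1.0
        cmz, cdz = cov.get("MZ", 0.3 * v), cov.get("DZ", 0.15 * v)
        start = {}
        if "A" in self.components and "C" in self.components:
            start["A"], start["C"] = 2 * (cmz - cdz), 2 * cdz - cmz
        elif "A" in self.components and "D" in self.components:
            start["A"], start["D"] = 4 * cdz - cmz, 2 * cmz - 4 * cdz
        elif "A" in self.components:
            start["A"] = cmz
        elif "C" in self.components:
            start["C"] = (cmz + cdz) / 2
        elif "D" in self.components:
            start["D"] = cmz
        start["E"] = max(v - sum(start.values()), 0.1 * v)
        return start

    def fit(self, restarts: int = 5, seed: int = 0) -> "UnivariateTwinResults":
        free = self.components
        start = self._moment_start()
        x0 = np.array([start[k] for k in free])
        scale = max(abs(x0).max(), 0.1)
        rng = np.random.default_rng(seed)
        best = None
        for trial in range(restarts + 1):
            xs = x0 if trial == 0 else x0 + rng.normal(0, 0.3 * scale, size=len(free))
            res = optimize.minimize(
                self._objective, xs, args=(free, {}), method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        comp_vals = dict(zip(free, best.x))
        beta = self._profiled_beta({k: comp_vals[k] for k in self.components})
        k_free = len(free) + self.p
        m2ll = float(best.fun)
        return UnivariateTwinResults(
            model=self, components={k: float(v) for k, v in comp_vals.items()},
            beta=np.asarray(beta), minus2ll=m2ll, n_params=k_free,
            aic=m2ll + 2 * k_free, converged=bool(best.success),
            message=str(best.message))

    # constrained refits used by profile CIs ---------------------------------

    def _min_m2ll_fixed_component(self, comp: str, value: float) -> float:
        free = tuple(k for k in self.components if k != comp)
        if not free:
            return self._objective(np.array([]), free, {comp: value})
        start = self._moment_start()
        x0 = np.array([start[k] for k in free])
        res = optimize.minimize(self._objective, x0, args=(free, {comp: value}),
                                method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        return float(res.fun)

    def _min_m2ll_fixed_share(self, comp: str, share: float) -> float:
        """Refit with the standardized share of ``comp`` held fixed.

        Parameterized by the total variance and the remaining free shares,
        so the constraint is enforced exactly without Lagrangian machinery.
        """
        others = [k for k in self.components if k != comp]
        free_shares = others[:-1]  # the last share is 1 - sum(others)

        def obj(theta):
            log_t = theta[0]
            if not -20 < log_t < 20:
                return 1e10
            t = np.exp(log_t)
            shares = {comp: share}
            shares.update(dict(zip(free_shares, theta[1:])))
            shares[others[-1]] = 1.0 - sum(shares.values())
            comp_vals = {k: shares[k] * t for k in self.components}
            beta = self._profiled_beta(comp_vals)
            if beta is None:
                return 1e10
            val = self.minus2ll(comp_vals, beta)
            return 1e10 if not np.isfinite(val) else val

        start = self._moment_start()
        total = max(sum(start.values()), 1e-3)
        x0 = [np.log(total)] + [start[k] / total for k in free_shares]
        res = optimize.minimize(obj, np.array(x0), method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        return float(res.fun)


@dataclass
class UnivariateTwinResults:
    """Fitted univariate CTD model."""

    model: UnivariateTwinModel
    components: dict[str, float]
    beta: np.ndarray
    minus2ll: float
    n_params: int
    aic: float
    converged: bool
    message: str
    _ci_cache: dict = field(default_factory=dict, repr=False)

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()))

    def standardized_shares(self) -> dict[str, float]:
        """Component shares of the total phenotypic variance (sum to 1)."""
        t = self.total_variance
        if t <= 0:
            raise ValueError("total phenotypic variance is not positive")
        return {k: v / t for k, v in self.components.items()}

    @property
    def heritability(self) -> float:
        """h2 = A / (A + C|D + E); zero when A is not in the model."""
        return self.standardized_shares().get("A", 0.0)

    def profile_ci(self, param: str, level: float = 0.95,
                   search_halfwidth: float = 1.5, tol: float = 1e-4
                   ) -> tuple[float, float]:
        """Likelihood-based CI: the set where the profiled -2LL stays within
        the chi-square(1) quantile of its minimum.

        ``param`` is a raw component ("A", "C", "D", "E") or a
        standardized share ("A_share"/"h2", "C_share", "D_share",
        "E_share").  Bounds that run off the search range are returned as
        +/-inf (open-ended).
        """
        key = (param, level)
        if key in self._ci_cache:
            return self._ci_cache[key]
        crit = self.minus2ll + sps.chi2.ppf(level, 1)

        if param in ("h2", "A_share", "C_share", "D_share", "E_share"):
            comp = "A" if param == "h2" else param[0]
            if comp not in self.components:
                raise ValueError(f"component {comp} not in model")
            center = self.standardized_shares()[comp]
            profile = lambda v: self.model._min_m2ll_fixed_share(comp, v)
        else:
            comp = param
            if comp not in self.components:
                raise ValueError(f"component {comp} not in model")
            center = self.components[comp]
            profile = lambda v: self.model._min_m2ll_fixed_component(comp, v)
            search_halfwidth = max(search_halfwidth, 3 * abs(center) + 1)

        def excess(v):
            return profile(v) - crit

        bounds = []
        for sign in (-1, 1):
            lo, hi = center, center + sign * search_halfwidth
            if excess(hi) < 0:
                bounds.append(sign * np.inf)
                continue
            b = optimize.brentq(excess, min(lo, hi), max(lo, hi), xtol=tol)
            bounds.append(b)
        out = (min(bounds), max(bounds))
        self._ci_cache[key] = out
        return out

    def compare(self, reduced: "UnivariateTwinResults") -> dict:
        """LRT of this (full) model against a nested reduced model."""
        return compare_models(self, reduced)

    def summary(self) -> str:
        shares = self.standardized_shares()
        lines = [
            f"Univariate CTD model: {''.join(self.model.components)}"
            + (f"  (covariates: {', '.join(self.model.covariates)})"
               if self.model.covariates else ""),
            f"  complete pairs: MZ {self.model._n_complete['MZ']}, "
            f"DZ {self.model._n_complete['DZ']}; observed values "
            f"{self.model.n_obs_values}",
            f"  -2LL {self.minus2ll:.3f}   AIC {self.aic:.3f}   "
            f"free parameters {self.n_params}",
        ]
        for k in self.model.components:
            lines.append(f"  {k}: {self.components[k]:8.4f}   share {shares[k]:6.3f}")
        lines.append(f"  h2 = {self.heritability:.3f}")
        if not self.converged:
            lines.append(f"  WARNING: optimizer reported non-convergence: {self.message}")
        return "\n".join(lines)


def fit_univariate(pairs: pd.DataFrame, components: str = "ACE",
                   covariates: tuple[str, ...] = (), standardize: bool = False,
                   **fit_kw) -> UnivariateTwinResults:
    """Fit a univariate CTD model (convenience wrapper)."""
    return UnivariateTwinModel(pairs, components, covariates, standardize).fit(**fit_kw)


def compare_models(full, reduced) -> dict:
    """Likelihood-ratio test of a reduced model nested in a full model.

    ``chi2 = minus2LL_reduced - minus2LL_full`` on ``delta_df`` degrees of
    freedom (difference in free parameter counts); also reports the AIC
    difference (reduced - full).
    """
    if reduced.n_params > full.n_params:
        raise ValueError("reduced model has more parameters than the full model")
    full_comps = getattr(full.model, "components", None)
    red_comps = getattr(reduced.model, "components", None)
    if full_comps is not None and red_comps is not None:
        if not set(red_comps) <= set(full_comps):
            raise ValueError(
                f"{''.join(red_comps)} is not nested in {''.join(full_comps)}")
    chi2 = reduced.minus2ll - full.minus2ll
    if chi2 < -1e-6:
        warnings.warn(
            f"reduced model fits better than full (chi2 = {chi2:.3g}); "
            "likely a convergence failure", stacklevel=2)
    chi2 = max(chi2, 0.0)
    delta_df = full.n_params - reduced.n_params
    p = float(sps.chi2.sf(chi2, delta_df)) if delta_df > 0 else 1.0
    return {"chi2": float(chi2), "delta_df": int(delta_df), "p": p,
            "delta_aic": float(reduced.aic - full.aic)}


def heritability(fit: UnivariateTwinResults, ci: bool = False, level: float = 0.95
                 ) -> dict:
    """Standardized shares (including h2) and optional profile CIs."""
    shares = fit.standardized_shares()
    out = {"h2": fit.heritability, "shares": shares}
    if ci:
        out["ci"] = {k: fit.profile_ci(f"{k}_share", level=level) for k in shares}
    return out


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------

class SaturatedTwinModel:
    """Unstructured per-zygosity means and covariances, for assumption tests.

    Free parameters: a mean per (zygosity, twin order) cell, a variance per
    cell and a covariance per zygosity (10 without covariates), plus shared
    covariate coefficients.  ``equate_means`` / ``equate_variances`` in
    {"none", "order", "all"} tie parameters across twin order, or across
    both order and zygosity, for the homogeneity submodels.
    """

    def __init__(self, pairs: pd.DataFrame, covariates: tuple[str, ...] = (),
                 equate_means: str = "none", equate_variances: str = "none",
                 standardize: bool = False):
        for name, v in (("equate_means", equate_means),
                        ("equate_variances", equate_variances)):
            if v not in ("none", "order", "all"):
                raise ValueError(f"{name} must be 'none', 'order' or 'all'")
        self.equate_means = equate_means
        self.equate_variances = equate_variances
        # reuse the data layout of the structured model
        self._base = UnivariateTwinModel(pairs, "ACE", covariates, standardize)
        for zyg in ("MZ", "DZ"):
            if self._base._n_complete[zyg] < 20:
                warnings.warn(f"fewer than 20 complete {zyg} pairs", stacklevel=2)
        self._index_params()

    def _cell_label(self, kind: str, zyg: str, order: int, tying: str) -> str:
        if tying == "all":
            return kind
        if tying == "order":
            return f"{kind}_{zyg}"
        return f"{kind}_{zyg}{order}"

    def _index_params(self):
        labels = []
        for zyg in ("MZ", "DZ"):
            for order in (1, 2):
                for kind, tying in (("mu", self.equate_means),
                                    ("logv", self.equate_variances)):
                    lab = self._cell_label(kind, zyg, order, tying)
                    if lab not in labels:
                        labels.append(lab)
            labels.append(f"rho_{zyg}")
        for cov in self._base.covariates:
            labels.append(f"beta_{cov}")
        self.param_labels = labels
        self.n_params = len(labels)

    def _unpack(self, theta):
        p = dict(zip(self.param_labels, theta))
        mu, var, cov = {}, {}, {}
        for zyg in ("MZ", "DZ"):
            for order in (1, 2):
                mu[(zyg, order)] = p[self._cell_label("mu", zyg, order, self.equate_means)]
                var[(zyg, order)] = np.exp(
                    p[self._cell_label("logv", zyg, order, self.equate_variances)])
            cov[zyg] = np.tanh(p[f"rho_{zyg}"]) * np.sqrt(var[(zyg, 1)] * var[(zyg, 2)])
        betas = np.array([p[f"beta_{c}"] for c in self._base.covariates])
        return mu, var, cov, betas

    def minus2ll(self, theta) -> float:
        mu, var, cov, betas = self._unpack(theta)
        total = 0.0
        log2pi = np.log(2 * np.pi)
        for (zyg, kind), (yv, xv) in self._base._groups.items():
            if kind == "pair":
                v1, v2, c = var[(zyg, 1)], var[(zyg, 2)], cov[zyg]
                det = v1 * v2 - c * c
                if det <= 0:
                    return 1e10
                m = np.stack([
                    mu[(zyg, 1)] + xv[:, 0, 1:] @ betas,
                    mu[(zyg, 2)] + xv[:, 1, 1:] @ betas], axis=1)
                r = yv - m
                quad = (v2 * r[:, 0] ** 2 + v1 * r[:, 1] ** 2
                        - 2 * c * r[:, 0] * r[:, 1]) / det
                total += len(yv) * (2 * log2pi + np.log(det)) + quad.sum()
            else:
                order = int(kind[-1])
                v = var[(zyg, order)]
                m = mu[(zyg, order)] + xv[:, 1:] @ betas
                r = yv - m
                total += len(yv) * (log2pi + np.log(v)) + (r ** 2).sum() / v
        return float(total)

    def _start(self) -> np.ndarray:
        stats = {}
        for zyg in ("MZ", "DZ"):
            g = self._base._groups.get((zyg, "pair"))
            if g is not None and len(g[0]) > 2:
                yv = g[0]
                s = np.cov(yv.T)
                stats[zyg] = (yv.mean(axis=0), np.diag(s),
                              s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))
            else:
                stats[zyg] = (np.zeros(2), np.ones(2), 0.3)
        x0 = []
        for lab in self.param_labels:
            if lab.startswith("mu"):
                zyg = lab[3:5] if len(lab) > 2 else "MZ"
                order = int(lab[5]) if len(lab) > 5 else 1
                x0.append(stats.get(zyg, stats["MZ"])[0][order - 1]
                          if lab != "mu" else np.mean([stats[z][0].mean() for z in stats]))
            elif lab.startswith("logv"):
                zyg = lab[5:7] if len(lab) > 4 else "MZ"
                order = int(lab[7]) if len(lab) > 7 else 1
                v = (stats.get(zyg, stats["MZ"])[1][order - 1]
                     if lab != "logv" else np.mean([stats[z][1].mean() for z in stats]))
                x0.append(np.log(max(v, 1e-3)))
            elif lab.startswith("rho"):
                x0.append(np.arctanh(np.clip(stats[lab[4:]][2], -0.95, 0.95)))
            else:
                x0.append(0.0)
        return np.array(x0)

    def fit(self) -> "SaturatedTwinResults":
        res = optimize.minimize(self.minus2ll, self._start(), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-9,
                                         "maxiter": 20000, "maxfev": 20000})
        res = optimize.minimize(self.minus2ll, res.x, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 2000})
        mu, var, cov, betas = self._unpack(res.x)
        corr = {z: float(cov[z] / np.sqrt(var[(z, 1)] * var[(z, 2)]))
                for z in ("MZ", "DZ")}
        ci = {}
        for z in ("MZ", "DZ"):
            n = self._base._n_complete[z]
            ci[z] = pearson_ci(corr[z], n) if n >= 4 else (np.nan, np.nan)
        m2ll = float(res.fun)
        return SaturatedTwinResults(
            model=self, means=mu, variances=var, covariances=cov,
            beta=betas, twin_correlations=corr, correlation_ci=ci,
            minus2ll=m2ll, n_params=self.n_params,
            aic=m2ll + 2 * self.n_params, converged=True, message=str(res.message))


@dataclass
class SaturatedTwinResults:
    model: SaturatedTwinModel
    means: dict
    variances: dict
    covariances: dict
    beta: np.ndarray
    twin_correlations: dict[str, float]
    correlation_ci: dict[str, tuple[float, float]]
    minus2ll: float
    n_params: int
    aic: float
    converged: bool
    message: str

    def homogeneity_tests(self) -> pd.DataFrame:
        """LRTs of equated-means/variances submodels against this model."""
        base = self.model._base
        rows = []
        specs = [("equal means across order", dict(equate_means="order")),
                 ("equal means across order and zygosity", dict(equate_means="all")),
                 ("equal variances across order", dict(equate_variances="order")),
                 ("equal variances across order and zygosity",
                  dict(equate_variances="all"))]
        for label, kw in specs:
            sub = SaturatedTwinModel(base.pairs, base.covariates, **kw).fit()
            lrt = compare_models(self, sub)
            rows.append({"submodel": label, **lrt})
        return pd.DataFrame(rows).set_index("submodel")

    def summary(self) -> str:
        lines = ["Saturated twin model",
                 f"  -2LL {self.minus2ll:.3f}   AIC {self.aic:.3f}   "
                 f"free parameters {self.n_params}"]
        for z in ("MZ", "DZ"):
            lo, hi = self.correlation_ci[z]
            lines.append(
                f"  r_{z} = {self.twin_correlations[z]:.3f} "
                f"95% CI [{lo:.3f}, {hi:.3f}]  "
                f"(n complete = {self.model._base._n_complete[z]})")
        return "\n".join(lines)


def fit_saturated(pairs: pd.DataFrame, covariates: tuple[str, ...] = (),
                  standardize: bool = False, **kw) -> SaturatedTwinResults:
    """Fit the saturated (unstructured) two-group twin model."""
    return SaturatedTwinModel(pairs, covariates, standardize=standardize, **kw).fit()
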