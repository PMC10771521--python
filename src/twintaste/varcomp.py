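"""Crossed random-effects variance components of image ratings.

The rating of individual *j* for image *i* at presentation (exposure) *p*
is modelled as a Gaussian random-intercept model crossed in individual,
image and exposure:

    rating = mu + ind_j + img_i + (ind:img)_ij + exp_p + (ind:exp)_jp
             + (img:exp)_ip + residual

All effects are independent zero-mean Gaussians.  Estimation maximizes the
restricted likelihood (REML), profiled over the residual variance and
log-parameterized in the variance ratios so every component is
nonnegative.  The linear algebra goes through Henderson's mixed-model
equations with a sparse LU factorization, which keeps each likelihood
evaluation linear-ish in the number of random-effect levels.

The individual:image interaction is identifiable only through repeated
presentations; with no repeats the exposure terms and the interaction are
dropped (merged into the residual) with a warning.  For balanced designs a
closed-form ANOVA (method-of-moments) estimator is provided as an
independent path.

Variance partitioning coefficients (VPC) are each component's share of the
summed components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse

__all__ = [
    "CrossedVarianceModel",
    "CrossedVarianceResults",
    "fit_crossed_vc",
    "vpc",
]

FULL_TERMS = ("ind", "img", "ind:img", "exp", "ind:exp", "img:exp")
COMPONENT_NAMES = {
    "ind": "sigma2_ind", "img": "sigma2_img", "ind:img": "sigma2_img_ind",
    "exp": "sigma2_exp", "ind:exp": "sigma2_ind_exp", "img:exp": "sigma2_img_exp",
}


def _codes(values) -> tuple[np.ndarray, int]:
    c = pd.Categorical(values)
    return c.codes.astype(np.int64), len(c.categories)


def _onehot(codes: np.ndarray, q: int) -> sparse.csc_matrix:
    n = len(codes)
    return sparse.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q))


@dataclass
class CrossedVarianceResults:
    """Estimated variance components with convergence diagnostics."""

    components: dict[str, float]      # named sigma2_* including sigma2_res
    terms: tuple[str, ...]            # random terms actually fitted
    method: str
    converged: bool
    message: str
    reml_criterion: float | None = None
    n_obs: int = 0

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()))

    def vpc(self) -> dict[str, float]:
        return vpc(self.components)

    def summary(self) -> str:
        lines = [f"Crossed variance components ({self.method}, n={self.n_obs})"]
        shares = self.vpc()
        for name, val in self.components.items():
            lines.append(f"  {name:16s} {val:10.5f}   VPC {shares[name]:6.3f}")
        lines.append(f"  total            {self.total_variance:10.5f}")
        if self.reml_criterion is not None:
            lines.append(f"  REML -2 logLik   {self.reml_criterion:10.3f}")
        lines.append(f"  converged: {self.converged} ({self.message})")
        return "\n".join(lines)


def vpc(components: dict[str, float]) -> dict[str, float]:
    """Variance partitioning coefficients: each component over the total."""
    vals = np.array(list(components.values()), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("components must be finite")
    total = vals.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    return {k: float(v / total) for k, v in components.items()}


class CrossedVarianceModel:
    """Crossed random-intercept model for one domain's long rating table.

    Parameters
    ----------
    table : DataFrame with columns individual_id, image_id, presentation,
        rating.  Restrict to one twin per pair upstream to avoid familial
        confounding.
    """

    def __init__(self, table: pd.DataFrame):
        need = {"individual_id", "image_id", "presentation", "rating"}
        missing = need - set(table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.y = self.table["rating"].to_numpy(dtype=float)
        self.n = len(self.y)
        has_repeats = self.table.duplicated(
            subset=["individual_id", "image_id"], keep=False).any()
        if has_repeats:
            self.terms = FULL_TERMS
        else:
            warnings.warn(
                "no repeated presentations: exposure terms are inestimable and "
                "the individual:image interaction is confounded with the "
                "residual; dropping those terms", stacklevel=2)
            self.terms = ("ind", "img")
        self._build_design()

    def _build_design(self):
        t = self.table
        ind, n_ind = _codes(t["individual_id"])
        img, n_img = _codes(t["image_id"])
        exp_, n_exp = _codes(t["presentation"])
        pieces, sizes = {}, {}
        for term in self.terms:
            if term == "ind":
                codes, q = ind, n_ind
            elif term == "img":
                codes, q = img, n_img
            elif term == "exp":
                codes, q = exp_, n_exp
            elif term == "ind:img":
                codes, q = _codes(ind.astype(np.int64) * n_img + img)
            elif term == "ind:exp":
                codes, q = _codes(ind * n_exp + exp_)
            elif term == "img:exp":
                codes, q = _codes(img * n_exp + exp_)
            pieces[term] = _onehot(codes, q)
            sizes[term] = q
        # the individual:image block is by far the largest but its
        # normal-equations block is diagonal, so it is eliminated by a
        # Schur complement instead of entering the factorization
        self.cell_term = "ind:img" if "ind:img" in self.terms else None
        self.small_terms = tuple(tm for tm in self.terms if tm != self.cell_term)
        self.q_small = np.array([sizes[tm] for tm in self.small_terms])
        self.p = 1
        x = sparse.csc_matrix(np.ones((self.n, 1)))
        w1 = sparse.hstack([x] + [pieces[tm] for tm in self.small_terms], format="csc")
        self.w1tw1 = np.asarray((w1.T @ w1).todense())
        self.w1ty = w1.T @ self.y
        self.yty = float(self.y @ self.y)
        if self.cell_term is not None:
            z2 = pieces[self.cell_term]
            self.q_cell = sizes[self.cell_term]
            self.n_cell = np.asarray(z2.sum(axis=0)).ravel()
            self.m12 = (w1.T @ z2).tocsr()
            self.z2ty = z2.T @ self.y
        else:
            self.q_cell = 0

    # -- REML ---------------------------------------------------------------

    def _criterion(self, log_gamma: np.ndarray) -> tuple[float, float]:
        """Profiled REML criterion (up to constants)."""
        lg = dict(zip(self.terms, log_gamma))
        gamma_small = np.exp([lg[tm] for tm in self.small_terms])
        ginv = np.concatenate(
            [np.zeros(self.p)] + [np.full(q, 1.0 / g)
                                  for q, g in zip(self.q_small, gamma_small)])
        m11 = self.w1tw1 + np.diag(ginv)
        rhs1 = self.w1ty.copy()
        logdet_cells = 0.0
        if self.cell_term is not None:
            g_c = np.exp(lg[self.cell_term])
            m22 = self.n_cell + 1.0 / g_c
            logdet_cells = float(np.sum(np.log(m22)))
            inv22 = 1.0 / m22
            scaled = self.m12.multiply(inv22)
            m11 = m11 - np.asarray((scaled @ self.m12.T).todense())
            rhs1 = rhs1 - scaled @ self.z2ty
        try:
            chol = np.linalg.cholesky(m11)
        except np.linalg.LinAlgError:
            return 1e12, np.nan
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol)))) + logdet_cells
        a = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs1))
        ypy = self.yty - float(self.w1ty @ a)
        if self.cell_term is not None:
            b = inv22 * (self.z2ty - self.m12.T @ a)
            ypy -= float(self.z2ty @ b)
        if not np.isfinite(ypy) or ypy <= 0:
            return 1e12, np.nan
        log_g = float(np.dot(self.q_small, [lg[tm] for tm in self.small_terms]))
        if self.cell_term is not None:
            log_g += self.q_cell * lg[self.cell_term]
        crit = log_g + logdet + (self.n - self.p) * np.log(ypy)
        return crit, ypy

    def fit(self, method: str = "reml", restarts: int = 2) -> CrossedVarianceResults:
        if method == "moments":
            return self._fit_moments()
        if method != "reml":
            raise ValueError("method must be 'reml' or 'moments'")

        n_t = len(self.terms)
        bounds = [(-15.0, 8.0)] * n_t
        starts = [np.full(n_t, np.log(0.3))]
        rng = np.random.default_rng(0)
        for _ in range(restarts):
            starts.append(np.log(0.3) + rng.normal(0, 1.5, size=n_t))

        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda lg: self._criterion(lg)[0], x0, method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 200, "ftol": 1e-10})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        crit, ypy = self._criterion(best.x)
        sigma2_res = ypy / (self.n - self.p)
        gamma = np.exp(best.x)
        comps = {}
        for term in FULL_TERMS:
            name = COMPONENT_NAMES[term]
            if term in self.terms:
                g = gamma[self.terms.index(term)]
                comps[name] = float(g * sigma2_res) if g > 2e-6 else 0.0
            else:
                comps[name] = 0.0
        comps["sigma2_res"] = float(sigma2_res)
        np_ = self.n - self.p
        full_crit = crit + np_ * (1 + np.log(2 * np.pi)) - np_ * np.log(np_)
        grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else np.nan
        return CrossedVarianceResults(
            components=comps, terms=self.terms, method="reml",
            converged=bool(best.success),
            message=f"{best.message} (|grad| = {grad_norm:.2e})",
            reml_criterion=float(full_crit), n_obs=self.n)

    # -- balanced-design ANOVA estimator ------------------------------------

    def _fit_moments(self) -> CrossedVarianceResults:
        """Closed-form ANOVA (expected-mean-squares) estimator.

        Requires a balanced complete crossed layout: either every
        individual rates every image once (two-way), or every individual
        rates every image at both presentations (three-way, one
        observation per cell).
        """
        t = self.table
        counts = t.groupby(["individual_id", "image_id"]).size()
        i_n = t["individual_id"].nunique()
        j_n = t["image_id"].nunique()
        if len(counts) != i_n * j_n or counts.nunique() != 1:
            raise ValueError("moments estimator requires a balanced complete design")
        k_n = int(counts.iloc[0])
        y = self.y
        grand = y.mean()
        cell = t.pivot_table(index="individual_id", columns="image_id",
                             values="rating", aggfunc="mean").to_numpy()
        mi = cell.mean(axis=1)
        mj = cell.mean(axis=0)

        if k_n == 1:
            # two-way main effects: y_ij = mu + a_i + b_j + e_ij
            ms_a = j_n * np.sum((mi - grand) ** 2) / (i_n - 1)
            ms_b = i_n * np.sum((mj - grand) ** 2) / (j_n - 1)
            resid = cell - mi[:, None] - mj[None, :] + grand
            ms_e = np.sum(resid ** 2) / ((i_n - 1) * (j_n - 1))
            s_res = ms_e
            comps = {name: 0.0 for name in COMPONENT_NAMES.values()}
            comps["sigma2_ind"] = max(0.0, (ms_a - ms_e) / j_n)
            comps["sigma2_img"] = max(0.0, (ms_b - ms_e) / i_n)
            comps["sigma2_res"] = float(s_res)
        elif k_n == 2 and t.groupby(["individual_id", "image_id"])["presentation"].nunique().eq(2).all():
            # three-way crossed, one obs per cell; 3-way interaction -> residual
            wide = t.pivot_table(index=["individual_id", "image_id"],
                                 columns="presentation", values="rating",
                                 aggfunc="first")
            arr = np.empty((i_n, j_n, 2))
            for kk, p in enumerate(sorted(t["presentation"].unique())):
                arr[:, :, kk] = wide[p].unstack().to_numpy()
            m = arr.mean()
            mi_ = arr.mean(axis=(1, 2))
            mj_ = arr.mean(axis=(0, 2))
            mk_ = arr.mean(axis=(0, 1))
            mij = arr.mean(axis=2)
            mik = arr.mean(axis=1)
            mjk = arr.mean(axis=0)
            i_, j_, k_ = i_n, j_n, 2
            ms = {
                "A": j_ * k_ * np.sum((mi_ - m) ** 2) / (i_ - 1),
                "B": i_ * k_ * np.sum((mj_ - m) ** 2) / (j_ - 1),
                "C": i_ * j_ * np.sum((mk_ - m) ** 2) / (k_ - 1),
                "AB": k_ * np.sum((mij - mi_[:, None] - mj_[None, :] + m) ** 2)
                      / ((i_ - 1) * (j_ - 1)),
                "AC": j_ * np.sum((mik - mi_[:, None] - mk_[None, :] + m) ** 2)
                      / ((i_ - 1) * (k_ - 1)),
                "BC": i_ * np.sum((mjk - mj_[:, None] - mk_[None, :] + m) ** 2)
                      / ((j_ - 1) * (k_ - 1)),
            }
            resid = (arr - mij[:, :, None] - mik[:, None, :] - mjk[None, :, :]
                     + mi_[:, None, None] + mj_[None, :, None] + mk_[None, None, :] - m)
            ms["E"] = np.sum(resid ** 2) / ((i_ - 1) * (j_ - 1) * (k_ - 1))
            s_e = ms["E"]
            s_ab = max(0.0, (ms["AB"] - s_e) / k_)
            s_ac = max(0.0, (ms["AC"] - s_e) / j_)
            s_bc = max(0.0, (ms["BC"] - s_e) / i_)
            s_a = max(0.0, (ms["A"] - s_e - k_ * s_ab - j_ * s_ac) / (j_ * k_))
            s_b = max(0.0, (ms["B"] - s_e - k_ * s_ab - i_ * s_bc) / (i_ * k_))
            s_c = max(0.0, (ms["C"] - s_e - j_ * s_ac - i_ * s_bc) / (i_ * j_))
            comps = {
                "sigma2_ind": float(s_a), "sigma2_img": float(s_b),
                "sigma2_img_ind": float(s_ab), "sigma2_exp": float(s_c),
                "sigma2_ind_exp": float(s_ac), "sigma2_img_exp": float(s_bc),
                "sigma2_res": float(s_e),
            }
        else:
            raise ValueError("moments estimator supports 1 or 2 complete presentations")
        return CrossedVarianceResults(
            components=comps, terms=self.terms, method="moments",
            converged=True, message="closed form", n_obs=self.n)


def fit_crossed_vc(table: pd.DataFrame, method: str = "reml") -> CrossedVarianceResults:
    """Convenience wrapper: fit the crossed variance-component model."""
    return CrossedVarianceModel(table).fit(method=method)
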