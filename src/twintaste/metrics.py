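"""The three aesthetic phenotypes and their supporting analyses.

* **Pairwise agreement** (``r_inter``): Pearson correlation of two
  individuals' repeat-averaged rating vectors over shared images, analysed
  on the Fisher-z scale across MZ, DZ and matched unrelated (UR) pairs.
* **Taste-typicality** (``mm2``): correlation of an individual's ratings
  with the average ratings of everyone else excluding their co-twin,
  Fisher-z transformed for analysis.
* **Evaluation-bias**: the individual's mean rating within a domain.

Also here: construction of sex- and age-matched unrelated pseudo-pairs,
principal axes of the rating matrix, and the 3 x 3 (pair class x domain)
type III ANOVA on z-transformed agreement with Bonferroni-corrected
marginal contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import RatingMatrix
from .stats import (
    cohens_d,
    cohens_d_ci,
    fisher_z,
    fisher_z_inverse,
    partial_eta_squared_ci,
    pearson_ci,
    was_clipped,
)

__all__ = [
    "PairRecord",
    "pairwise_agreement",
    "twin_pair_records",
    "make_unrelated_pairs",
    "taste_typicality_mm2",
    "evaluation_bias",
    "individual_metrics",
    "principal_axes",
    "PrincipalAxes",
    "agreement_anova",
    "AgreementAnovaResult",
]


@dataclass
class PairRecord:
    pair_class: str  # MZ | DZ | UR
    member1: str
    member2: str
    domain: str
    sex: str
    mean_age: float
    r_inter: float
    z_inter: float
    clipped: bool = False


def pairwise_agreement(matrix: RatingMatrix, member1, member2) -> PairRecord:
    """Inter-individual Pearson correlation of two rating vectors.

    Computed over the images both individuals rated (repeat-averaged).
    Raises for constant vectors, which leave the correlation undefined.
    """
    x = matrix.values.loc[member1]
    y = matrix.values.loc[member2]
    shared = x.notna() & y.notna()
    xv, yv = x[shared].to_numpy(), y[shared].to_numpy()
    if len(xv) < 3:
        raise ValueError("fewer than 3 shared images")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant rating vector; agreement undefined")
    r = float(np.corrcoef(xv, yv)[0, 1])
    meta = matrix.meta
    pc = meta.loc[member1, "zygosity"] if meta.loc[member1, "family_id"] == meta.loc[member2, "family_id"] else "UR"
    return PairRecord(
        pair_class=pc, member1=str(member1), member2=str(member2),
        domain=matrix.domain,
        sex=meta.loc[member1, "sex"] if meta.loc[member1, "sex"] == meta.loc[member2, "sex"] else "mixed",
        mean_age=float((meta.loc[member1, "age"] + meta.loc[member2, "age"]) / 2),
        r_inter=r, z_inter=fisher_z(r), clipped=was_clipped(r),
    )


def twin_pair_records(matrix: RatingMatrix) -> list[PairRecord]:
    """Pairwise agreement for every complete twin pair in the matrix."""
    meta = matrix.meta
    records = []
    for fam, grp in meta.groupby("family_id", sort=False):
        if len(grp) != 2:
            continue
        ids = grp.sort_values("twin_order").index
        try:
            records.append(pairwise_agreement(matrix, ids[0], ids[1]))
        except ValueError as err:
            warnings.warn(f"pair {fam} dropped: {err}", stacklevel=2)
    return records


def make_unrelated_pairs(matrix: RatingMatrix, seed: int = 0) -> tuple[list[PairRecord], list]:
    """Sex-matched, age-matched unrelated (UR) pseudo-pairs.

    Every twin-order-2 member is matched with a twin-order-1 member from a
    different family of the same sex, greedily choosing the smallest age
    difference; each individual is used at most once.  The pool order is
    shuffled deterministically from ``seed`` to break ties.  Returns the
    UR pair records and the ids left unpaired.
    """
    rng = np.random.default_rng([seed, 7])
    meta = matrix.meta
    records, unpaired = [], []
    for sex in sorted(meta["sex"].unique()):
        sub = meta[meta["sex"] == sex]
        seconds = sub[sub["twin_order"] == 2]
        firsts = sub[sub["twin_order"] == 1]
        order = seconds.index.to_numpy()[rng.permutation(len(seconds))]
        available = dict(zip(firsts.index, zip(firsts["age"], firsts["family_id"])))
        for sid in order:
            s_age, s_fam = meta.loc[sid, "age"], meta.loc[sid, "family_id"]
            candidates = [(abs(age - s_age), fid) for fid, (age, fam) in available.items()
                          if fam != s_fam]
            if not candidates:
                unpaired.append(sid)
                continue
            candidates.sort(key=lambda t: (t[0], str(t[1])))
            fid = candidates[0][1]
            del available[fid]
            try:
                records.append(pairwise_agreement(matrix, sid, fid))
            except ValueError as err:
                warnings.warn(f"UR pair ({sid}, {fid}) dropped: {err}", stacklevel=2)
        unpaired.extend(available.keys())
    return records, unpaired


def taste_typicality_mm2(matrix: RatingMatrix, individual_id) -> tuple[float, float]:
    """Taste-typicality: r (and Fisher z) of an individual's ratings with the
    mean ratings of every other individual excluding the co-twin ("mean
    minus two")."""
    meta = matrix.meta
    fam = meta.loc[individual_id, "family_id"]
    others = meta.index[meta["family_id"] != fam]
    if len(others) < 3:
        raise ValueError("need at least 3 individuals outside the family")
    ref = matrix.values.loc[others].mean(axis=0)
    row = matrix.values.loc[individual_id]
    ok = row.notna() & ref.notna()
    x, y = row[ok].to_numpy(), ref[ok].to_numpy()
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("constant reference or rating vector; mm2 undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, fisher_z(r)


def evaluation_bias(matrix: RatingMatrix, individual_id) -> float:
    """Evaluation-bias: the individual's mean (repeat-averaged) rating."""
    return float(matrix.values.loc[individual_id].mean())


def individual_metrics(matrix: RatingMatrix) -> pd.DataFrame:
    """Taste-typicality (r and z) and evaluation-bias for every individual."""
    rows = []
    for iid in matrix.individuals:
        try:
            r, z = taste_typicality_mm2(matrix, iid)
        except ValueError:
            r = z = np.nan
        rows.append({
            "individual_id": iid, "domain": matrix.domain,
            "taste_typicality_r": r, "taste_typicality_z": z,
            "evaluation_bias": evaluation_bias(matrix, iid),
        })
    out = pd.DataFrame(rows).set_index("individual_id")
    return out.join(matrix.meta)


@dataclass
class PrincipalAxes:
    """SVD principal axes of the column-centred (unscaled) rating matrix."""

    scores: pd.DataFrame          # individuals x axes
    loadings: pd.DataFrame        # images x axes
    explained_variance_ratio: np.ndarray


def principal_axes(matrix: RatingMatrix, n_axes: int = 2,
                   align_bias=None, align_typicality=None) -> PrincipalAxes:
    """Principal axes of the rating matrix via SVD of the centred data.

    Columns (images) are mean-centred, not scaled.  When alignment vectors
    are given, axis 1 is flipped so its scores correlate positively with
    evaluation-bias and axis 2 so it correlates positively with
    taste-typicality (z scale); remaining axes are left as returned.
    """
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    if np.isnan(x).any():
        raise ValueError("principal axes require a complete rating matrix")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_axes = min(n_axes, len(s))
    scores = u[:, :n_axes] * s[:n_axes]
    loads = vt[:n_axes].T
    with np.errstate(invalid="ignore"):
        evr = s**2 / np.sum(s**2)
    for axis, target in ((0, align_bias), (1, align_typicality)):
        if target is None or axis >= n_axes:
            continue
        t = np.asarray(target, dtype=float)
        c = np.corrcoef(scores[:, axis], t)[0, 1]
        if c < 0:
            scores[:, axis] *= -1
            loads[:, axis] *= -1
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    return PrincipalAxes(
        scores=pd.DataFrame(scores, index=matrix.individuals, columns=cols),
        loadings=pd.DataFrame(loads, index=matrix.images, columns=cols),
        explained_variance_ratio=evr[:n_axes],
    )


@dataclass
class AgreementAnovaResult:
    """Type III ANOVA of z-transformed agreement over pair class x domain."""

    anova_table: pd.DataFrame
    effect_sizes: pd.DataFrame          # partial eta^2 with CI per term
    marginal_means: pd.DataFrame        # per class and per class|domain, z and r
    contrasts: pd.DataFrame             # Bonferroni-adjusted pairwise contrasts

    def summary(self) -> str:
        parts = ["Pairwise agreement ANOVA (type III, z scale)", "",
                 self.anova_table.round(4).to_string(), "",
                 "Partial eta^2:", self.effect_sizes.round(4).to_string(), "",
                 "Marginal means (back-transformed r):",
                 self.marginal_means.round(4).to_string(), "",
                 "Contrasts (Bonferroni):", self.contrasts.round(4).to_string()]
        return "\n".join(parts)


def _marginal_z(params, classes, domains, cls=None, dom=None):
    """Model-implied marginal mean of z under sum-to-zero coding, averaging
    over the levels of any factor not fixed."""
    import itertools
    cells = [(c, d) for c in ([cls] if cls else classes)
             for d in ([dom] if dom else domains)]
    return float(np.mean([params[(c, d)] for c, d in cells]))


def agreement_anova(pair_records, alpha: float = 0.05) -> AgreementAnovaResult:
    """3 x 3 type III ANOVA of Fisher-z agreement with marginal contrasts.

    Pair-class and domain enter with sum-to-zero contrasts; marginal means
    are averaged on the z scale and reported back-transformed to r, per
    the analysis protocol.  Pairwise contrasts are Bonferroni corrected
    with multipliers 3 (class), 3 (domain) and 9 (class within domain).
    """
    import statsmodels.api as smapi
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    df = pd.DataFrame([vars(r) for r in pair_records]) if not isinstance(
        pair_records, pd.DataFrame) else pair_records.copy()
    classes = sorted(df["pair_class"].unique())
    domains = sorted(df["domain"].unique())
    counts = df.groupby(["pair_class", "domain"]).size()
    if len(counts) < len(classes) * len(domains):
        raise ValueError("empty cells in the pair-class x domain design")

    # drop degenerate (single-level) factors from the formula
    terms = [t for t, levels in (("C(pair_class, Sum)", classes),
                                 ("C(domain, Sum)", domains)) if len(levels) > 1]
    formula = "z_inter ~ " + (" * ".join(terms) if terms else "1")
    model = smf.ols(formula, data=df).fit()
    table = smapi.stats.anova_lm(model, typ=3)

    # partial eta^2 with noncentral-F CI per model term
    ss_res = table.loc["Residual", "sum_sq"]
    df_res = int(table.loc["Residual", "df"])
    eff_rows = []
    for term in table.index:
        if term in ("Intercept", "Residual"):
            continue
        ss, d1 = table.loc[term, "sum_sq"], int(table.loc[term, "df"])
        eta = ss / (ss + ss_res)
        lo, hi = partial_eta_squared_ci(table.loc[term, "F"], d1, df_res)
        eff_rows.append({"term": term, "partial_eta_sq": eta,
                         "ci_low": lo, "ci_high": hi})
    effects = pd.DataFrame(eff_rows).set_index("term")

    # cell means implied by the fitted model (equal to observed cell means)
    cell = {(c, d): float(model.predict(pd.DataFrame(
        {"pair_class": [c], "domain": [d]})).iloc[0])
        for c in classes for d in domains}
    mm_rows = []
    for c in classes:
        z = _marginal_z(cell, classes, domains, cls=c)
        mm_rows.append({"level": c, "scope": "pair_class", "z": z,
                        "r": fisher_z_inverse(z)})
    for d in domains:
        z = _marginal_z(cell, classes, domains, dom=d)
        mm_rows.append({"level": d, "scope": "domain", "z": z,
                        "r": fisher_z_inverse(z)})
    for c in classes:
        for d in domains:
            z = cell[(c, d)]
            mm_rows.append({"level": f"{c}|{d}", "scope": "cell", "z": z,
                            "r": fisher_z_inverse(z)})
    marginal = pd.DataFrame(mm_rows).set_index(["scope", "level"])

    # pairwise contrasts on observed z values with Bonferroni multipliers
    sigma2 = ss_res / df_res

    def _contrast(sub1, sub2, label, mult):
        z1, z2 = sub1["z_inter"].to_numpy(), sub2["z_inter"].to_numpy()
        diff = z1.mean() - z2.mean()
        se = np.sqrt(sigma2 * (1 / len(z1) + 1 / len(z2)))
        t = diff / se
        p = min(1.0, 2 * sps.t.sf(abs(t), df_res) * mult)
        d = cohens_d(z1, z2)
        dlo, dhi = cohens_d_ci(d, len(z1), len(z2))
        return {"contrast": label, "estimate_z": diff, "t": t,
                "p_bonferroni": p, "cohens_d": d, "d_ci_low": dlo, "d_ci_high": dhi}

    rows = []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            rows.append(_contrast(df[df.pair_class == c1], df[df.pair_class == c2],
                                  f"{c1} - {c2}", 3))
    for i, d1 in enumerate(domains):
        for d2 in domains[i + 1:]:
            rows.append(_contrast(df[df.domain == d1], df[df.domain == d2],
                                  f"{d1} - {d2}", 3))
    for dom in domains:
        sub = df[df.domain == dom]
        for i, c1 in enumerate(classes):
            for c2 in classes[i + 1:]:
                rows.append(_contrast(sub[sub.pair_class == c1],
                                      sub[sub.pair_class == c2],
                                      f"{c1} - {c2} | {dom}", 9))
    contrasts = pd.DataFrame(rows).set_index("contrast")
    return AgreementAnovaResult(table, effects, marginal, contrasts)
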