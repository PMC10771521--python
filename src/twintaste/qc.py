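"""Rating-table validation, reliability, exclusion rules and repeat averaging.

The long-format rating table has one row per individual x image x
presentation with pedigree metadata.  QC mirrors the study protocol:
per-domain exclusion of individuals with zero rating variance or with
intra-individual test-retest reliability below 0.5, and a 3 x IQR fence on
derived metrics.  Exclusions are applied per visual domain, so a pair may
survive in one domain as an incomplete pair after losing a member in
another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RATINGS_COLUMNS",
    "RatingMatrix",
    "QCReport",
    "read_ratings",
    "validate_ratings",
    "intra_individual_reliability",
    "intra_image_reliability",
    "apply_exclusions",
    "metric_outlier_filter",
    "average_repeats",
    "rating_matrices",
]

RATINGS_COLUMNS = [
    "family_id", "individual_id", "twin_order", "zygosity", "sex", "age",
    "domain", "image_id", "presentation", "rating",
]

_KEY = ["individual_id", "domain", "image_id", "presentation"]


def validate_ratings(table: pd.DataFrame, scale: tuple[float, float] | None = None
                     ) -> pd.DataFrame:
    """Validate a long-format rating table and return it.

    Checks the documented header, key uniqueness, two individuals per
    family, and (when a bounded ``scale`` is declared) rating bounds.
    Offending rows are reported by positional row number.
    """
    missing = [c for c in RATINGS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dup = table.duplicated(subset=_KEY)
    if dup.any():
        first = table.loc[dup.idxmax(), _KEY].to_dict()
        raise ValueError(
            f"{int(dup.sum())} duplicated (individual, domain, image, presentation) "
            f"key(s); first duplicate: {first}"
        )
    fam = table.groupby("family_id")["individual_id"].nunique()
    bad_fam = fam[fam > 2]
    if len(bad_fam):
        raise ValueError(f"families with more than two individuals: {list(bad_fam.index[:5])}")
    if not table["presentation"].isin([1, 2]).all():
        raise ValueError("presentation must be 1 or 2")
    if scale is not None:
        lo, hi = scale
        out = ~table["rating"].between(lo, hi)
        if out.any():
            rows = list(np.flatnonzero(out)[:5])
            raise ValueError(
                f"{int(out.sum())} rating(s) outside declared scale [{lo}, {hi}]; "
                f"first offending rows (0-based): {rows}"
            )
    return table


def read_ratings(path: str | Path, scale: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read and validate a rating CSV with the documented header."""
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_ratings(table, scale=scale)


def _repeat_vectors(sub: pd.DataFrame, by: str) -> pd.DataFrame | None:
    """Wide presentation-1 / presentation-2 values for repeated images."""
    wide = sub.pivot_table(index=by, columns="presentation", values="rating", aggfunc="first")
    if 1 not in wide.columns or 2 not in wide.columns:
        return None
    return wide.dropna(subset=[1, 2])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector is constant."""
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def intra_individual_reliability(table: pd.DataFrame, individual_id, domain: str) -> float:
    """Test-retest reliability of one individual's ratings within a domain.

    Pearson correlation of the presentation-1 vs presentation-2 rating
    vectors over the repeated images; NaN when either vector is constant.
    """
    sub = table[(table["individual_id"] == individual_id) & (table["domain"] == domain)]
    wide = _repeat_vectors(sub, "image_id")
    if wide is None or len(wide) < 3:
        raise ValueError(
            f"individual {individual_id!r} has fewer than 3 repeated images in {domain!r}"
        )
    return _pearson(wide[1].to_numpy(), wide[2].to_numpy())


def intra_image_reliability(table: pd.DataFrame, image_id, domain: str) -> float:
    """Across-individual reliability of a repeated image's two presentations."""
    sub = table[(table["image_id"] == image_id) & (table["domain"] == domain)]
    wide = _repeat_vectors(sub, "individual_id")
    if wide is None or len(wide) < 3:
        raise ValueError(f"image {image_id!r} lacks two presentations by >=3 raters in {domain!r}")
    return _pearson(wide[1].to_numpy(), wide[2].to_numpy())


def _all_intra_individual(table: pd.DataFrame) -> pd.DataFrame:
    """Per (individual, domain) reliability; NaN if constant, None-row skipped
    if no repeats."""
    rep = table[table.duplicated(subset=["individual_id", "domain", "image_id"], keep=False)]
    if rep.empty:
        return pd.DataFrame(columns=["individual_id", "domain", "r_intra"])
    wide = rep.pivot_table(index=["individual_id", "domain", "image_id"],
                           columns="presentation", values="rating", aggfunc="first")
    wide = wide.dropna()
    out = (wide.groupby(level=["individual_id", "domain"])
           .apply(lambda g: _pearson(g[1].to_numpy(), g[2].to_numpy())
                  if len(g) >= 3 else np.nan)
           .rename("r_intra").reset_index())
    return out


@dataclass
class QCReport:
    """Per-domain bookkeeping of exclusions.

    ``excluded`` maps domain -> rule -> list of individual ids;
    ``retained``/``input`` count individuals per domain; the two reconcile
    exactly.
    """

    input_counts: dict = field(default_factory=dict)
    retained_counts: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)
    r_intra: pd.DataFrame | None = None
    r_image: pd.DataFrame | None = None

    def excluded_counts(self) -> dict:
        return {d: {rule: len(ids) for rule, ids in rules.items()}
                for d, rules in self.excluded.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "input_counts": self.input_counts,
            "retained_counts": self.retained_counts,
            "excluded_counts": self.excluded_counts(),
            "excluded": {d: {r: sorted(map(str, ids)) for r, ids in rules.items()}
                         for d, rules in self.excluded.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def apply_exclusions(table: pd.DataFrame, r_intra_min: float = 0.5,
                     require_repeats: bool = False) -> tuple[pd.DataFrame, QCReport]:
    """Apply the zero-variance and low-reliability exclusion rules per domain.

    An individual is dropped from a domain when their rating sd is 0 there,
    or when their intra-individual reliability is undefined (constant
    repeat vector) or strictly below ``r_intra_min``.  Individuals without
    repeated images are only excludable under the sd rule unless
    ``require_repeats``.  The co-twin is retained (incomplete pair).
    """
    report = QCReport()
    rel = _all_intra_individual(table)
    report.r_intra = rel
    keep_masks = []
    for domain, sub in table.groupby("domain", sort=False):
        ind_sd = sub.groupby("individual_id")["rating"].std(ddof=0)
        zero_sd = set(ind_sd[ind_sd == 0].index)
        rel_d = rel[rel["domain"] == domain].set_index("individual_id")["r_intra"]
        low_rel = set(rel_d[(rel_d < r_intra_min) | rel_d.isna()].index)
        if require_repeats:
            low_rel |= set(ind_sd.index) - set(rel_d.index)
        low_rel -= zero_sd  # attribute each exclusion to a single rule
        report.input_counts[domain] = int(ind_sd.size)
        report.excluded[domain] = {
            "zero_sd": sorted(zero_sd),
            "low_reliability": sorted(low_rel),
        }
        drop = zero_sd | low_rel
        report.retained_counts[domain] = int(ind_sd.size - len(drop))
        keep_masks.append(~sub["individual_id"].isin(drop))
    keep = pd.concat(keep_masks).reindex(table.index, fill_value=False)
    return table[keep].copy(), report


def metric_outlier_filter(values, iqr_mult: float = 3.0, two_sided: bool = True
                          ) -> np.ndarray:
    """Retention mask under the Tukey fence with multiplier ``iqr_mult``.

    Values outside ``[Q1 - m*IQR, Q3 + m*IQR]`` are flagged for exclusion
    (only the upper fence when ``two_sided`` is False).  Quartiles use
    linear interpolation.  A zero IQR excludes nothing.  NaNs are retained
    (they carry no metric information to fence on).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values to place an IQR fence")
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.ones_like(v, dtype=bool)
    hi = v > q3 + iqr_mult * iqr
    lo = (v < q1 - iqr_mult * iqr) if two_sided else np.zeros_like(hi)
    return ~(hi | lo) | ~finite


@dataclass
class RatingMatrix:
    """Individuals x images matrix of repeat-averaged ratings for one domain.

    ``values`` is indexed by individual_id with image_id columns; ``meta``
    carries family/zygosity/sex/age/twin_order per individual.
    """

    domain: str
    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def individuals(self) -> pd.Index:
        return self.values.index

    @property
    def images(self) -> pd.Index:
        return self.values.columns

    def row(self, individual_id) -> np.ndarray:
        return self.values.loc[individual_id].to_numpy()

    def first_members(self) -> "RatingMatrix":
        ids = self.meta.index[self.meta["twin_order"] == 1]
        return RatingMatrix(self.domain, self.values.loc[ids], self.meta.loc[ids])


def average_repeats(table: pd.DataFrame, domain: str) -> RatingMatrix:
    """Repeat-averaged individuals x images matrix for one domain.

    Repeated presentations are averaged per individual; unrepeated images
    pass through unchanged.
    """
    sub = table[table["domain"] == domain]
    if sub.empty:
        raise ValueError(f"no ratings for domain {domain!r}")
    values = sub.pivot_table(index="individual_id", columns="image_id",
                             values="rating", aggfunc="mean")
    meta = (sub[["individual_id", "family_id", "twin_order", "zygosity", "sex", "age"]]
            .drop_duplicates("individual_id").set_index("individual_id"))
    return RatingMatrix(domain, values, meta.loc[values.index])


def rating_matrices(table: pd.DataFrame) -> dict[str, RatingMatrix]:
    """``average_repeats`` for every domain present in the table."""
    return {d: average_repeats(table, d) for d in table["domain"].unique()}
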