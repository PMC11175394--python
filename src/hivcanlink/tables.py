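"""Analytical outputs: origin–destination matrix, demographics, tests, ORs.

The central object is the origin–destination (OD) cross-tabulation of
province of cancer diagnosis (rows) against province of HIV care (columns,
the home-province proxy). Column percentages answer "where did province X's
HIV patients obtain their cancer diagnoses?"; the diagonal is within-
province care and the off-diagonal mass is cross-province travel.

Percentages are always re-derived from counts — never stored — and rounded
half away from zero to one decimal, the convention that reproduces every
checkable printed percentage of the source registry tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .provinces import PROVINCE_CENTROIDS, PROVINCES


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (printed-table convention), element-wise."""
    factor = 10.0 ** decimals
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# origin-destination matrix

@dataclass
class OriginDestinationMatrix:
    """9×9 counts: rows = province of cancer diagnosis, columns = province
    of HIV diagnosis and care (home)."""

    counts: pd.DataFrame

    @classmethod
    def from_cases(cls, cases: pd.DataFrame) -> "OriginDestinationMatrix":
        for col in ("diagnosis_province", "home_province"):
            bad = set(cases[col]) - set(PROVINCES)
            if bad:
                raise ValueError(f"unknown province code(s) in {col}: {sorted(bad)}")
        ct = pd.crosstab(cases["diagnosis_province"], cases["home_province"])
        ct = ct.reindex(index=list(PROVINCES), columns=list(PROVINCES),
                        fill_value=0)
        return cls(counts=ct.astype(int))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "OriginDestinationMatrix":
        ct = counts.reindex(index=list(PROVINCES), columns=list(PROVINCES))
        if ct.isna().any().any():
            raise ValueError("counts must cover all 9×9 province cells")
        if (ct.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        return cls(counts=ct.astype(int))

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def column_percentages(self) -> pd.DataFrame:
        """Cell percentage of its column's cell sum, half-away one decimal.

        Column sums are always the cell sums of this matrix, never an
        external total."""
        colsum = self.counts.sum(axis=0).astype(float)
        pct = 100.0 * self.counts / colsum
        return pd.DataFrame(round_half_away(pct.to_numpy(), 1),
                            index=self.counts.index,
                            columns=self.counts.columns)

    def off_diagonal_total(self) -> int:
        return self.total() - int(np.trace(self.counts.to_numpy()))

    def within_province_total(self) -> int:
        return int(np.trace(self.counts.to_numpy()))


def od_matrix(cases: pd.DataFrame) -> OriginDestinationMatrix:
    """Cross-tabulate analysis cases into the OD matrix."""
    return OriginDestinationMatrix.from_cases(cases)


def destination_shares(matrix: OriginDestinationMatrix) -> pd.Series:
    """Each diagnosis province's share of all out-of-home-province cases:
    off-diagonal row sum over total off-diagonal sum. All-diagonal input
    yields missing shares."""
    counts = matrix.counts.to_numpy().astype(float)
    off = counts.copy()
    np.fill_diagonal(off, 0.0)
    denom = off.sum()
    if denom == 0:
        return pd.Series(np.nan, index=matrix.counts.index)
    return pd.Series(off.sum(axis=1) / denom, index=matrix.counts.index)


# --------------------------------------------------------------------------
# demographics

def median_iqr(values) -> tuple[float, float, float]:
    """Median and inclusive quartiles (linear interpolation) of a sample."""
    arr = np.asarray([v for v in values if not pd.isna(v)], dtype=float)
    if arr.size == 0:
        return (math.nan,) * 3
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def _demo_rows(cases: pd.DataFrame):
    yield "total", "all", np.ones(len(cases), dtype=bool)
    for level in ("Female", "Male"):
        yield "gender", level, (cases["sex"] == ("F" if level == "Female" else "M")).to_numpy()
    for level in ("Black", "Coloured", "White", "Asian"):
        yield "ethnicity", level, (cases["race"] == level).to_numpy()
    yield "black_vs_nonblack", "Black", (cases["race"] == "Black").to_numpy()
    yield "black_vs_nonblack", "non-Black", (cases["race"] != "Black").to_numpy()


def demographics_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Demographic characteristics by location of cancer diagnosis.

    One row per characteristic level with outside/within-province counts,
    row totals and row percentages (half-away, one decimal). The returned
    frame's ``attrs['age']`` holds median/IQR of age at diagnosis overall
    and by location."""
    if cases.empty:
        raise ValueError("demographics_table requires a non-empty cohort")
    out_mask = cases["out_of_province"].to_numpy(dtype=bool)
    rows = []
    for char, level, mask in _demo_rows(cases):
        outside = int((mask & out_mask).sum())
        within = int((mask & ~out_mask).sum())
        rows.append((char, level, outside, within))
    table = _percentify(pd.DataFrame(
        rows, columns=["characteristic", "level", "outside", "within"]))
    ages = cases["age_at_diagnosis"]
    table.attrs["age"] = {
        "overall": median_iqr(ages),
        "outside": median_iqr(ages[out_mask]),
        "within": median_iqr(ages[~out_mask]),
    }
    return table


def demographics_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Row percentages recomputed from printed outside/within cell counts."""
    return _percentify(counts.copy())


def _percentify(table: pd.DataFrame) -> pd.DataFrame:
    table["total"] = table["outside"] + table["within"]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["pct_outside"] = round_half_away(
            100.0 * table["outside"] / table["total"], 1)
        table["pct_within"] = round_half_away(
            100.0 * table["within"] / table["total"], 1)
    return table


# --------------------------------------------------------------------------
# tests and regression

def chi_square(contingency) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, upper-tail p). Raises on a zero
    expected count.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    expected = scipy.stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError("chi-square undefined: zero expected count")
    stat, p, dof, _ = scipy.stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def logistic_fit(cases: pd.DataFrame,
                 covariates: tuple = ("age", "gender", "race", "cancer_type"),
                 cancer_reference: str | None = None) -> pd.DataFrame:
    """Logistic regression of out-of-province cancer diagnosis.

    Outcome: 1 when the province of cancer diagnosis differs from the home
    province. Age enters continuously (OR per year); gender is male vs
    female (reference Female); race is Black vs non-Black (reference
    non-Black); cancer type is dummy-coded against ``cancer_reference``
    (default: the most frequent type). Returns one row per term with the
    odds ratio, Wald 95% CI and p-value; reference levels and convergence
    are recorded in ``attrs``.
    """
    y = cases["out_of_province"].astype(int).to_numpy()
    X = pd.DataFrame(index=cases.index)
    refs = {}
    if "age" in covariates:
        X["age"] = pd.to_numeric(cases["age_at_diagnosis"], errors="coerce")
    if "gender" in covariates:
        X["male"] = (cases["sex"] == "M").astype(int)
        refs["gender"] = "Female"
    if "race" in covariates:
        X["black"] = (cases["race"] == "Black").astype(int)
        refs["race"] = "non-Black"
    if "cancer_type" in covariates:
        if cancer_reference is None:
            cancer_reference = cases["cancer_type"].value_counts().idxmax()
        refs["cancer_type"] = cancer_reference
        dummies = pd.get_dummies(cases["cancer_type"], prefix="cancer",
                                 dtype=int)
        dummies = dummies.drop(columns=f"cancer_{cancer_reference}")
        X = pd.concat([X, dummies], axis=1)
    keep = ~X.isna().any(axis=1)
    Xk = sm.add_constant(X[keep].astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            # convergence is checked explicitly below
            warnings.simplefilter("ignore")
            fit = sm.Logit(y[keep.to_numpy()], Xk).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation, singular design, ...
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge")
    params = fit.params.drop("const")
    conf = fit.conf_int(alpha=0.05).drop("const")
    result = pd.DataFrame({
        "term": params.index,
        "odds_ratio": np.exp(params.to_numpy()),
        "ci_low": np.exp(conf[0].to_numpy()),
        "ci_high": np.exp(conf[1].to_numpy()),
        "p_value": fit.pvalues.drop("const").to_numpy(),
    }).reset_index(drop=True)
    result.attrs["references"] = refs
    result.attrs["converged"] = True
    result.attrs["n"] = int(keep.sum())
    return result


# --------------------------------------------------------------------------
# flow export

def export_flows(matrix: OriginDestinationMatrix,
                 centroids: dict | None = None) -> dict:
    """GeoJSON FeatureCollection of cross-province diagnosis flows.

    One LineString feature per off-diagonal cell with a positive count,
    running from the home (HIV care) province centroid to the diagnosis
    province centroid, with origin, destination and count properties.
    """
    if centroids is None:
        centroids = PROVINCE_CENTROIDS
    features = []
    for dx in PROVINCES:
        for home in PROVINCES:
            if dx == home:
                continue
            count = int(matrix.counts.loc[dx, home])
            if count == 0:
                continue
            for p in (home, dx):
                if p not in centroids:
                    raise ValueError(f"missing centroid for province {p}")
            features.append({
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(centroids[home]), list(centroids[dx])],
                },
                "properties": {
                    "origin": home,
                    "destination": dx,
                    "count": count,
                },
            })
    return {"type": "FeatureCollection", "features": features}


def out_of_province_proportion(cases: pd.DataFrame) -> float:
    """Fraction of cases diagnosed outside the home province."""
    if cases.empty:
        raise ValueError("no cases")
    return float(cases["out_of_province"].mean())
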