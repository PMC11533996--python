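"""Cohort statistics for structure-quality tables.

The cohort side of the audit asks whether waterless depositions cluster,
which of them are outliers, and how they compare to the rest of the
archive.  The machinery — median imputation, 0–1 min–max scaling, Ward
agglomerative clustering via the Lance–Williams recurrence, the local
outlier factor with tie-inclusive k-neighbourhoods, correlation-matrix
PCA, regression-spline ratio curves and yearly box-plot summaries — is
implemented here directly, so every step is a deterministic, inspectable
computation (scipy/scikit-learn equivalents serve as cross-checks in the
test suite, not as the implementation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_structures import StructureMetadata

__all__ = [
    "QualityMatrix",
    "LinkageTree",
    "RatioCurve",
    "median_impute",
    "minmax_scale",
    "ward_linkage",
    "lof_scores",
    "pca_project",
    "fit_ratio_spline",
    "yearly_ratio_summary",
]


@dataclass
class QualityMatrix:
    """structures × quality-metrics table with explicit missingness.

    ``values`` is float with NaN marking missing cells; ``mask`` (True =
    missing) is derived from it and always consistent.
    """

    row_ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("values shape does not match row_ids × columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column names must be unique")

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "QualityMatrix":
        return cls(
            row_ids=[str(i) for i in df.index],
            columns=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)

    def complete_cases(self) -> "QualityMatrix":
        keep = ~self.mask.any(axis=1)
        return QualityMatrix(
            row_ids=[r for r, k in zip(self.row_ids, keep) if k],
            columns=list(self.columns),
            values=self.values[keep],
        )


@dataclass
class LinkageTree:
    """Agglomerative merge history: (cluster_a, cluster_b, height, size).

    Clusters 0..n−1 are the leaves; merge i creates cluster n+i, exactly
    as in the scipy linkage convention.
    """

    merges: np.ndarray  # (n-1, 4)
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("a tree over n leaves needs exactly n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class RatioCurve:
    """Least-squares cubic regression spline with pointwise 95% CI."""

    knots: np.ndarray          # interior knot positions
    coefficients: np.ndarray   # basis coefficients
    fit_range: tuple[float, float]
    covariance: np.ndarray     # coefficient covariance (sigma² (XᵀX)⁻¹)
    residual_sd: float

    def _basis(self, x: np.ndarray) -> np.ndarray:
        return _spline_basis(np.asarray(x, dtype=float), self.knots, self.fit_range)

    def __call__(self, x) -> np.ndarray:
        scalar = np.isscalar(x)
        out = self._basis(np.atleast_1d(x)) @ self.coefficients
        return float(out[0]) if scalar else out

    def confidence_band(self, x, level: float = 0.95) -> np.ndarray:
        """Half-width of the pointwise CI of the fitted mean at x."""
        from scipy.stats import norm

        basis = self._basis(np.atleast_1d(x))
        var = np.einsum("ij,jk,ik->i", basis, self.covariance, basis)
        z = norm.ppf(0.5 + level / 2)
        return z * np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def median_impute(m: QualityMatrix) -> QualityMatrix:
    """Replace missing cells with their column median (observed values only)."""
    values = m.values.copy()
    for j, col in enumerate(m.columns):
        observed = values[~np.isnan(values[:, j]), j]
        if observed.size == 0:
            raise ValueError(f"column {col!r} is fully missing; drop it before imputing")
        values[np.isnan(values[:, j]), j] = np.median(observed)
    return QualityMatrix(list(m.row_ids), list(m.columns), values)


def minmax_scale(m: QualityMatrix) -> QualityMatrix:
    """Map each column to [0, 1] via (x − min)/(max − min).

    Constant columns map to 0 with a warning (they carry no contrast).
    """
    if m.mask.any():
        raise ValueError("matrix has missing values: impute first")
    values = m.values.copy()
    for j, col in enumerate(m.columns):
        lo, hi = values[:, j].min(), values[:, j].max()
        if hi == lo:
            warnings.warn(f"column {col!r} is constant; scaled to 0", stacklevel=2)
            values[:, j] = 0.0
        else:
            values[:, j] = (values[:, j] - lo) / (hi - lo)
    return QualityMatrix(list(m.row_ids), list(m.columns), values)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_linkage(m: QualityMatrix) -> LinkageTree:
    """Agglomerative clustering under the Ward minimum-variance objective.

    Pairwise cluster distances start as Euclidean point distances and are
    updated with the Lance–Williams recurrence for Ward linkage; each step
    merges the globally closest pair (ties broken by the lowest index
    pair).  Heights follow the convention height² = 2·ΔSSE, so they match
    the familiar dendrogram scale of standard implementations.
    """
    if m.mask.any():
        raise ValueError("matrix has missing values: impute first")
    x = m.values
    n = len(x)
    if n < 2:
        raise ValueError("clustering needs at least 2 rows")
    # active cluster distances, sizes and ids (id >= n means merged cluster)
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(dist, np.inf)
    sizes = {i: 1 for i in range(n)}
    ids = list(range(n))
    merges = []
    next_id = n
    for _ in range(n - 1):
        k = len(ids)
        # lowest-index tie-break: flat argmin over the upper triangle picks
        # the row-major-first pair among exact ties
        upper = np.triu(np.ones((k, k), dtype=bool), 1)
        flat = np.where(upper, dist, np.inf).ravel()
        a, b = divmod(int(np.argmin(flat)), k)
        d_ab = dist[a, b]
        id_a, id_b = ids[a], ids[b]
        sa, sb = sizes[id_a], sizes[id_b]
        merges.append((min(id_a, id_b), max(id_a, id_b), d_ab, sa + sb))
        # Lance–Williams update for Ward: d(new, c)² weighted combination
        new_row = np.empty(k)
        for c in range(k):
            if c in (a, b):
                new_row[c] = np.inf
                continue
            sc = sizes[ids[c]]
            t = sa + sb + sc
            new_row[c] = math.sqrt(
                max(
                    ((sa + sc) * dist[a, c] ** 2 + (sb + sc) * dist[b, c] ** 2 - sc * d_ab**2)
                    / t,
                    0.0,
                )
            )
        # replace cluster a by the merge, delete b
        dist[a, :] = new_row
        dist[:, a] = new_row
        dist[a, a] = np.inf
        keep = [i for i in range(k) if i != b]
        dist = dist[np.ix_(keep, keep)]
        sizes[next_id] = sa + sb
        ids[a] = next_id
        del ids[b]
        next_id += 1
    return LinkageTree(merges=np.array(merges), n_leaves=n)


# ---------------------------------------------------------------------------
# local outlier factor
# ---------------------------------------------------------------------------

def lof_scores(m: QualityMatrix, k: int = 5) -> np.ndarray:
    """Local outlier factor per row, with tie-inclusive k-neighbourhoods.

    Follows the original definition: the k-distance of a point is the
    distance to its k-th nearest neighbour; the neighbourhood contains
    *all* points within that distance (ties included), the reachability
    distance is max(k-distance(b), d(a, b)), the local reachability
    density is the inverse mean reachability over the neighbourhood, and
    LOF(a) is the mean ratio lrd(b)/lrd(a) over the neighbours of a.
    Coincident duplicates share a k-distance, so no division by zero
    arises.  Scores near 1 mean inlier.
    """
    if m.mask.any():
        raise ValueError("matrix has missing values: impute first")
    x = m.values
    n = len(x)
    if n <= k:
        raise ValueError(f"LOF with k={k} needs more than {k} rows, got {n}")
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(dist, np.inf)
    kdist = np.sort(dist, axis=1)[:, k - 1]
    neighbors = [np.where(dist[i] <= kdist[i] + 1e-12)[0] for i in range(n)]
    lrd = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        reach = np.maximum(kdist[nb], dist[i, nb])
        # coincident duplicates share a zero k-distance; cap the density so
        # their neighbours get a huge-but-finite score instead of inf
        lrd[i] = 1.0 / max(reach.mean(), 1e-10)
    scores = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        scores[i] = (lrd[nb] / lrd[i]).mean()
    return scores


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_project(m: QualityMatrix) -> dict:
    """Correlation-matrix PCA of complete-case rows.

    Columns are standardized to mean 0 / variance 1; components are the
    eigenvectors of the correlation matrix sorted by decreasing
    eigenvalue, with the sign convention that each component's
    largest-magnitude loading is positive.  Returns loadings (p × p,
    columns are components), scores (n × p) and explained_variance
    (eigenvalues, summing to p).
    """
    if m.mask.any():
        raise ValueError("PCA needs complete cases; filter or impute first")
    x = m.values
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(m.columns, sd) if s == 0]
        raise ValueError(f"zero-variance columns {bad}: drop before PCA")
    z = (x - mu) / sd
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(p):
        imax = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[imax, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return {
        "loadings": eigvecs,
        "scores": z @ eigvecs,
        "explained_variance": eigvals,
        "columns": list(m.columns),
        "row_ids": list(m.row_ids),
    }


# ---------------------------------------------------------------------------
# regression splines
# ---------------------------------------------------------------------------

def _spline_basis(x: np.ndarray, knots: np.ndarray, fit_range) -> np.ndarray:
    """Truncated-power cubic regression-spline basis: 1, x, x², x³, (x−κ)₊³."""
    lo, hi = fit_range
    xc = np.clip(x, lo, hi)
    cols = [np.ones_like(xc), xc, xc**2, xc**3]
    for kn in knots:
        cols.append(np.where(xc > kn, (xc - kn) ** 3, 0.0))
    return np.column_stack(cols)


def fit_ratio_spline(
    x: Sequence[float],
    y: Sequence[float],
    knots: Sequence[float] | int = 4,
) -> RatioCurve:
    """Least-squares cubic regression spline with homoscedastic 95% CI.

    ``knots`` is either explicit interior knot positions or a count, in
    which case knots are placed at quantiles of x.  The curve is C²
    everywhere by construction of the truncated-power basis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(knots, int):
        qs = np.linspace(0, 1, knots + 2)[1:-1]
        knots = np.quantile(x, qs)
    knots = np.sort(np.asarray(knots, dtype=float))
    fit_range = (float(x.min()), float(x.max()))
    if np.any(knots <= fit_range[0]) or np.any(knots >= fit_range[1]):
        raise ValueError("knots must lie strictly inside the data range")
    basis = _spline_basis(x, knots, fit_range)
    n, p = basis.shape
    if n < p:
        raise ValueError(f"underdetermined fit: {n} points for {p} basis functions; use fewer knots")
    gram = basis.T @ basis
    if np.linalg.cond(gram) > 1e12:
        raise ValueError("ill-conditioned spline system; use fewer knots")
    coef = np.linalg.solve(gram, basis.T @ y)
    resid = y - basis @ coef
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(gram)
    return RatioCurve(
        knots=knots,
        coefficients=coef,
        fit_range=fit_range,
        covariance=cov,
        residual_sd=math.sqrt(sigma2),
    )


# ---------------------------------------------------------------------------
# yearly summaries
# ---------------------------------------------------------------------------

def yearly_ratio_summary(
    records: Sequence[StructureMetadata],
    ratios: Sequence[float] | None = None,
    pool_before: int = 1995,
) -> pd.DataFrame:
    """Per-release-year box-plot statistics of the water/residue ratio.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data point within 1.5·IQR of the box, and
    values beyond are listed as outliers.  Years before ``pool_before``
    are pooled into that year's row (early sparse years are accumulated).
    Also reports the waterless count and percentage per year.
    """
    rows = []
    for i, rec in enumerate(records):
        if rec.release_year is None:
            continue
        if ratios is not None:
            ratio = ratios[i]
        elif rec.n_waters is not None and rec.n_residues:
            ratio = rec.n_waters / rec.n_residues
        else:
            ratio = np.nan
        waterless = rec.n_waters == 0 if rec.n_waters is not None else np.isclose(ratio, 0)
        year = max(rec.release_year, pool_before)
        rows.append((year, ratio, waterless))
    if not rows:
        return pd.DataFrame(
            columns=["year", "n_released", "n_waterless", "pct_waterless",
                     "q1", "median", "q3", "whisker_low", "whisker_high", "outliers"]
        ).set_index("year")
    df = pd.DataFrame(rows, columns=["year", "ratio", "waterless"])
    out = []
    for year, grp in df.groupby("year"):
        vals = grp["ratio"].dropna().to_numpy()
        n_waterless = int(grp["waterless"].sum())
        entry = {
            "year": int(year),
            "n_released": len(grp),
            "n_waterless": n_waterless,
            "pct_waterless": 100.0 * n_waterless / len(grp),
        }
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            entry.update(
                q1=q1,
                median=med,
                q3=q3,
                whisker_low=float(inside.min()) if inside.size else np.nan,
                whisker_high=float(inside.max()) if inside.size else np.nan,
                outliers=sorted(vals[(vals < lo_fence) | (vals > hi_fence)].tolist()),
            )
        else:
            entry.update(q1=np.nan, median=np.nan, q3=np.nan,
                         whisker_low=np.nan, whisker_high=np.nan, outliers=[])
        out.append(entry)
    return pd.DataFrame(out).set_index("year").sort_index()
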