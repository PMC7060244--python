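"""Portable classification rule: FPCA scores + quadratic discriminant analysis.

The clustering of the training lakes is turned into a rule that classifies
any new lake from at least one year of temperature data.  Seasonal profiles
are reduced to two functional principal component (FPC) scores, and a
per-class Gaussian model on the scores (QDA) yields the posterior
probability of membership in each thermal region — the "confidence in
classification".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .curves import (DEFAULT_GRID, DEFAULT_LAMBDA, SeasonalCurve, SmoothFit,
                     apply_ice_rule, fit_saturated_bspline, seasonal_profile)
from .synthetic import OBS_PER_YEAR, LakeSeries


@dataclass
class FPCAModel:
    """Functional PCA of seasonal curves on a common within-year grid.

    Eigenfunctions are orthonormal under the stored quadrature rule
    (uniform weights 1/n_grid on the periodic day-of-year grid); scores are
    quadrature inner products of the centred curve with each eigenfunction.
    """

    grid: np.ndarray
    mean_curve: np.ndarray
    eigenfunctions: np.ndarray    # n_components x n_grid (all computed)
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    n_retained: int
    weights: np.ndarray

    @property
    def retained_explained(self) -> float:
        return float(self.explained_fraction[: self.n_retained].sum())


def fit_fpca(curves: list[SeasonalCurve], n_retained: int = 2) -> FPCAModel:
    """Fit FPCA to seasonal curves sharing one grid.

    Eigen-decomposes the quadrature-weighted sample covariance of the
    centred curves; components are sorted by decreasing eigenvalue.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 curves")
    grid = curves[0].grid
    y = np.vstack([c.values for c in curves])
    if any(c.grid.shape != grid.shape or not np.allclose(c.grid, grid)
           for c in curves[1:]):
        raise ValueError("curves must share a common grid")
    w = np.full(grid.size, 1.0 / grid.size)  # uniform quadrature on [0, 1)
    mean = y.mean(axis=0)
    yc = y - mean
    if np.allclose(yc, 0.0):
        raise ValueError("zero variance: all curves identical")
    # weighted covariance eigenproblem via the symmetrized matrix
    sw = np.sqrt(w)
    cov = (yc.T @ yc) / (len(curves) - 1)
    m = (cov * sw[None, :]) * sw[:, None]
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    phi = (evecs[:, order] / sw[:, None]).T   # orthonormal under quadrature
    total = evals.sum()
    return FPCAModel(
        grid=grid, mean_curve=mean, eigenfunctions=phi, eigenvalues=evals,
        explained_fraction=evals / total, n_retained=n_retained, weights=w,
    )


def project_scores(curve: SeasonalCurve, model: FPCAModel) -> np.ndarray:
    """FPC scores of a curve: quadrature inner products with eigenfunctions."""
    vals = curve.values
    if curve.grid.shape != model.grid.shape or not np.allclose(curve.grid, model.grid):
        if curve.grid.min() > model.grid.min() + 0.05 or \
           curve.grid.max() < model.grid.max() - 0.05:
            raise ValueError("curve grid does not cover the model grid")
        # periodic linear interpolation onto the model grid
        vals = np.interp(model.grid, curve.grid, curve.values,
                         period=1.0)
    yc = vals - model.mean_curve
    phi = model.eigenfunctions[: model.n_retained]
    return phi @ (model.weights * yc)


def reconstruct(scores: np.ndarray, model: FPCAModel) -> np.ndarray:
    """Curve implied by FPC scores (mean + sum of score * eigenfunction)."""
    k = len(scores)
    return model.mean_curve + scores @ model.eigenfunctions[:k]


@dataclass
class QDAModel:
    """Per-class Gaussian model on FPC scores with posterior probabilities.

    Class covariances are regularized by adding ``reg_eps`` to the diagonal;
    priors are proportional to class frequencies.
    """

    classes: list[str]
    means: np.ndarray          # n_classes x d
    covariances: np.ndarray    # n_classes x d x d
    priors: np.ndarray
    reg_eps: float

    def log_joint(self, x: np.ndarray) -> np.ndarray:
        """log prior + log Gaussian density per class, rows = samples."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = x.shape[1]
        out = np.empty((x.shape[0], len(self.classes)))
        for j in range(len(self.classes)):
            cov = self.covariances[j]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(f"class {self.classes[j]}: covariance not PD")
            diff = x - self.means[j]
            maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
            out[:, j] = (np.log(self.priors[j]) - 0.5 * logdet - 0.5 * maha
                         - 0.5 * d * np.log(2 * np.pi))
        return out

    def posterior(self, x: np.ndarray) -> np.ndarray:
        lj = self.log_joint(x)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> list[str]:
        return [self.classes[j] for j in np.argmax(self.log_joint(x), axis=1)]


def fit_qda(scores: np.ndarray, labels: list[str] | np.ndarray,
            reg_eps: float = 1e-6) -> QDAModel:
    """Fit per-class Gaussians to (scores, labels) with frequency priors."""
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    d = x.shape[1]
    means = np.empty((len(classes), d))
    covs = np.empty((len(classes), d, d))
    priors = np.empty(len(classes))
    for j, c in enumerate(classes):
        xi = x[labels == c]
        if xi.shape[0] < 2 and reg_eps == 0:
            raise ValueError(f"class {c!r} has {xi.shape[0]} member(s); "
                             "needs >= 2 or reg_eps > 0")
        means[j] = xi.mean(axis=0)
        if xi.shape[0] >= 2:
            covs[j] = np.cov(xi, rowvar=False).reshape(d, d)
        else:
            covs[j] = np.zeros((d, d))
        covs[j] += reg_eps * np.eye(d)
        priors[j] = xi.shape[0] / x.shape[0]
    return QDAModel(classes, means, covs, priors, reg_eps)


@dataclass
class ClassifierPipeline:
    """End-to-end rule: series -> smooth -> seasonal profile -> scores -> QDA.

    ``cluster_codes`` maps training cluster indices to region codes; the QDA
    classes are region codes.  Serializes to a single JSON document that is
    sufficient to classify new data with no retraining.
    """

    fpca: FPCAModel
    qda: QDAModel
    spline_lambda: float = DEFAULT_LAMBDA
    grid_points_per_year: int = DEFAULT_GRID
    provenance: dict = field(default_factory=dict)

    def classify_curve(self, curve: SeasonalCurve):
        s = project_scores(curve, self.fpca)
        post = self.qda.posterior(s)[0]
        order = np.argsort(post)[::-1]
        return (self.qda.classes[order[0]], post,
                self.qda.classes[order[1]] if len(post) > 1 else None)

    def classify_series(self, series: LakeSeries):
        """Classify a lake from >= 1 year of fortnightly observations.

        Returns (region code, posterior vector over classes, second-closest
        region code).
        """
        if series.values.size < OBS_PER_YEAR:
            raise ValueError("need at least 1 year (24 fortnightly observations) "
                             f"of data, got {series.values.size}")
        clean = apply_ice_rule(series)
        fit = fit_saturated_bspline(clean, lam=self.spline_lambda)
        prof = seasonal_profile(fit, self.grid_points_per_year)
        return self.classify_curve(prof)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "lakethermal-classifier",
            "version": 1,
            "grid": self.fpca.grid.tolist(),
            "mean_curve": self.fpca.mean_curve.tolist(),
            "eigenfunctions": self.fpca.eigenfunctions[: self.fpca.n_retained].tolist(),
            "eigenvalues": self.fpca.eigenvalues[: self.fpca.n_retained].tolist(),
            "explained_fraction": self.fpca.explained_fraction[: self.fpca.n_retained].tolist(),
            "n_retained": self.fpca.n_retained,
            "weights": self.fpca.weights.tolist(),
            "qda": {
                "classes": self.qda.classes,
                "means": self.qda.means.tolist(),
                "covariances": self.qda.covariances.tolist(),
                "priors": self.qda.priors.tolist(),
                "reg_eps": self.qda.reg_eps,
            },
            "spline_lambda": self.spline_lambda,
            "grid_points_per_year": self.grid_points_per_year,
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierPipeline":
        doc = json.loads(text)
        if doc.get("format") != "lakethermal-classifier":
            raise ValueError("not a lakethermal classifier document")
        n_ret = int(doc["n_retained"])
        evals = np.asarray(doc["eigenvalues"], dtype=float)
        fpca = FPCAModel(
            grid=np.asarray(doc["grid"], dtype=float),
            mean_curve=np.asarray(doc["mean_curve"], dtype=float),
            eigenfunctions=np.asarray(doc["eigenfunctions"], dtype=float),
            eigenvalues=evals,
            explained_fraction=np.asarray(doc["explained_fraction"], dtype=float),
            n_retained=n_ret,
            weights=np.asarray(doc["weights"], dtype=float),
        )
        q = doc["qda"]
        qda = QDAModel(
            classes=list(q["classes"]),
            means=np.asarray(q["means"], dtype=float),
            covariances=np.asarray(q["covariances"], dtype=float),
            priors=np.asarray(q["priors"], dtype=float),
            reg_eps=float(q["reg_eps"]),
        )
        return cls(fpca=fpca, qda=qda,
                   spline_lambda=float(doc["spline_lambda"]),
                   grid_points_per_year=int(doc["grid_points_per_year"]),
                   provenance=dict(doc.get("provenance", {})))


def train_pipeline(
    profiles: list[SeasonalCurve],
    region_labels: list[str] | np.ndarray,
    n_retained: int = 2,
    reg_eps: float = 1e-6,
    provenance: dict | None = None,
) -> ClassifierPipeline:
    """Train FPCA + QDA from seasonal profiles and region-code labels."""
    fpca = fit_fpca(profiles, n_retained=n_retained)
    scores = np.vstack([project_scores(c, fpca) for c in profiles])
    qda = fit_qda(scores, region_labels, reg_eps=reg_eps)
    return ClassifierPipeline(fpca=fpca, qda=qda,
                              provenance=provenance or {})


# ---------------------------------------------------------------------------
# Location-based classification on a 2-degree grid

@dataclass(frozen=True)
class LocationResult:
    region_code: str | None
    posterior: float | None
    reason: str = ""

    @property
    def is_lake_cell(self) -> bool:
        return self.region_code is not None


def cell_center(lat: float, lon: float) -> tuple[float, float]:
    """Center of the 2-degree cell containing (lat, lon).

    Cells are half-open boxes with south/west edges inclusive and centers
    at odd degrees; longitude wraps into [-180, 180).
    """
    if not -90 <= lat <= 90:
        raise ValueError(f"latitude {lat} out of range")
    lon = ((lon + 180.0) % 360.0) - 180.0
    clat = 2.0 * np.floor((min(lat, 89.999999) + 90.0) / 2.0) - 89.0
    clon = 2.0 * np.floor((lon + 180.0) / 2.0) - 179.0
    return float(clat), float(clon)


def classify_location(lat: float, lon: float, label_grid) -> LocationResult:
    """Look up the thermal region of the 2-degree cell containing a point.

    ``label_grid`` is a DataFrame with columns lat_center, lon_center,
    region_code and (optionally) posterior.  Cells absent from the table
    are "no lake" cells.
    """
    clat, clon = cell_center(lat, lon)
    hit = label_grid[(label_grid["lat_center"] == clat)
                     & (label_grid["lon_center"] == clon)]
    if hit.empty:
        return LocationResult(None, None, reason="no lake cell")
    row = hit.iloc[0]
    post = float(row["posterior"]) if "posterior" in hit.columns else None
    return LocationResult(str(row["region_code"]), post)
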