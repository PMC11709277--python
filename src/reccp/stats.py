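"""Double-angle descriptive statistics for astigmatism vectors.

Centroids, 95% error ellipses from variance–covariance matrices, mean
vector difference (MVD), mean squared prediction error (MSE), and the
mean/SD/median/quantile summary rows used in cohort tables.

The 95% ellipse assumes a bivariate normal cloud: the sample covariance is
eigen-decomposed and each semi-axis is ``sqrt(chi2_2(0.95) * lambda_i)``,
so the area is ``pi * chi2_2(0.95) * sqrt(det Sigma)``.  MSE is the mean
squared length of the 2D error vectors (dpt^2); MVD is the mean length
(dpt), so MSE >= MVD^2 by Jensen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CHI2_2_95",
    "ErrorEllipse",
    "centroid",
    "error_ellipse_95",
    "ellipse_from_cov",
    "ellipse_polygon",
    "mean_vector_difference",
    "mean_squared_error",
    "descriptive_summary",
    "EvaluationRow",
    "evaluate_predictions",
    "DegenerateEllipseError",
]

#: chi-square(2 dof) 0.95 quantile scaling the covariance eigenvalues
CHI2_2_95: float = float(sps.chi2.ppf(0.95, df=2))  # 5.991464547...


class DegenerateEllipseError(np.linalg.LinAlgError):
    """Raised when the sample covariance is singular (flat point cloud)."""


@dataclass(frozen=True)
class ErrorEllipse:
    """95% confidence ellipse of a bivariate normal (C0, C45) cloud."""

    centroid: tuple[float, float]  # dpt
    covariance: np.ndarray  # (2, 2), dpt^2
    semi_axes: tuple[float, float]  # major, minor; dpt
    orientation: float  # major-axis angle, degrees in [0, 180)
    area: float  # pi * a * b, dpt^2


def centroid(points: np.ndarray) -> tuple[float, float]:
    """Component-wise mean of an (n, 2) cloud of (C0, C45) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("centroid of an empty point set is undefined")
    mean = pts.mean(axis=0)
    return (float(mean[0]), float(mean[1]))


def ellipse_from_cov(
    mean: np.ndarray, cov: np.ndarray, scale: float = CHI2_2_95
) -> ErrorEllipse:
    """Build the confidence ellipse for a given mean and covariance."""
    cov = np.asarray(cov, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0:
        raise DegenerateEllipseError(
            f"covariance is singular (eigenvalues {eigvals.tolist()})"
        )
    a = float(np.sqrt(scale * eigvals[1]))
    b = float(np.sqrt(scale * eigvals[0]))
    major = eigvecs[:, 1]
    orientation = float(np.degrees(np.arctan2(major[1], major[0])) % 180.0)
    return ErrorEllipse(
        centroid=(float(mean[0]), float(mean[1])),
        covariance=cov,
        semi_axes=(a, b),
        orientation=orientation,
        area=float(np.pi * a * b),
    )


def error_ellipse_95(points: np.ndarray) -> ErrorEllipse:
    """95% error ellipse of an (n, 2) sample (n >= 3, n-1 covariance)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 points, got {pts.shape[0]}")
    return ellipse_from_cov(pts.mean(axis=0), np.cov(pts, rowvar=False, ddof=1))


def ellipse_polygon(ellipse: ErrorEllipse, n_vertices: int = 100) -> np.ndarray:
    """Vertices of the ellipse boundary, for double-angle plot export."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = ellipse.semi_axes
    phi = np.radians(ellipse.orientation)
    x = a * np.cos(t)
    y = b * np.sin(t)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return (np.column_stack([x, y]) @ rot.T) + np.asarray(ellipse.centroid)


def _paired(pred, actual) -> np.ndarray:
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.shape[0] < 1:
        raise ValueError("need at least one pair")
    return actual - pred


def mean_vector_difference(pred, actual) -> float:
    """Mean length of the 2D difference vectors, in dpt."""
    diff = _paired(pred, actual)
    return float(np.mean(np.hypot(diff[:, 0], diff[:, 1])))


def mean_squared_error(pred, actual) -> float:
    """Mean squared length of the 2D difference vectors, in dpt^2."""
    diff = _paired(pred, actual)
    return float(np.mean(np.sum(diff**2, axis=1)))


def descriptive_summary(values) -> dict[str, float]:
    """Mean, SD (n-1), median and 2.5%/97.5% quantiles of a series.

    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a summary row")
    q025, q975 = np.quantile(v, [0.025, 0.975])
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "median": float(np.median(v)),
        "q2.5": float(q025),
        "q97.5": float(q975),
    }


@dataclass(frozen=True)
class EvaluationRow:
    """One row of the evaluation table: prediction-error statistics for a
    (modality, model, split) combination."""

    centroid_x: float  # dpt
    centroid_y: float  # dpt
    ellipse_area: float  # dpt^2
    mvd: float  # dpt
    mse: float  # dpt^2


def evaluate_predictions(model, X: np.ndarray, Y: np.ndarray) -> EvaluationRow:
    """Prediction-error statistics of a model on a data split.

    Errors are ``Y - model.predict(X)`` (actual recCP minus predicted);
    reports their centroid, 95% error-ellipse area, MVD and MSE.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    pred = model.predict(X)
    errors = Y - pred
    cx, cy = centroid(errors)
    return EvaluationRow(
        centroid_x=cx,
        centroid_y=cy,
        ellipse_area=error_ellipse_95(errors).area,
        mvd=mean_vector_difference(pred, Y),
        mse=mean_squared_error(pred, Y),
    )
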