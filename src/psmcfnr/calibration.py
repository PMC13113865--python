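"""FNR sweep optimization and coverage -> FNR polynomial calibration.

The optimization step follows the pipeline's core protocol: a candidate
false-negative rate is swept from 0 (no correction) to 0.99 in steps of
0.01 (100 candidates), each candidate correction is applied to the
low-coverage query trajectory, both curves are projected onto the shared
logarithmic time grid, and the Hausdorff and discrete Frechet distances to
the high-coverage reference are recorded.  The optimal FNR per metric is
the argmin; discrete Frechet is the primary criterion because it preserves
temporal ordering.  SSE is evaluated at the Frechet optimum and at FNR=0
as an independent goodness-of-fit check only.

The calibration step regresses optimal FNR on mean sequencing coverage.
Samples at or above the anchor coverage (default 15x, where false-negative
losses are negligible) enter the regression as optimal FNR = 0.  Polynomial
degrees 1-3 are compared by R-squared with a parsimony rule: the lowest
degree within ``parsimony_tol`` of the best R-squared wins.  The fitted
polynomial predicts the FNR correction for further genomes of the same
population sequenced at other depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .curves import TimeGrid, apply_fnr_correction, project_onto_grid
from .distances import discrete_frechet, hausdorff, sum_squared_errors
from .psmc_io import ScaledTrajectory

__all__ = [
    "SweepResult",
    "CoverageObservation",
    "CalibrationModel",
    "FNRCalibrator",
    "sweep_fnr",
    "select_optimal_fnr",
    "assemble_observations",
    "observations_frame",
    "fit_polynomial",
    "select_degree",
    "predict_fnr",
]

ANCHOR_COVERAGE = 15.0
FNR_MAX = 0.99


def _fnr_candidates(fnr_min: float, fnr_max: float, step: float) -> np.ndarray:
    """Candidate grid generated by index, f_i = fnr_min + i*step.

    Values are rounded to 10 decimals so that decimal candidates such as
    0.30 are represented exactly (no cumulative float drift at 0.99).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0.0 <= fnr_min <= fnr_max < 1.0:
        raise ValueError("require 0 <= fnr_min <= fnr_max < 1")
    n = int(np.floor((fnr_max - fnr_min) / step + 0.5)) + 1
    return np.round(fnr_min + step * np.arange(n), 10)


@dataclass(frozen=True)
class SweepResult:
    """Distance records across the candidate FNR grid for one query.

    ``records`` has one row per candidate (columns ``fnr``, ``hausdorff``,
    ``frechet``, ``sse``), sorted by fnr.  ``sse_at_optimum`` is evaluated
    at the Frechet-optimal FNR, ``sse_uncorrected`` at FNR = 0.
    """

    records: pd.DataFrame
    optimal_fnr_frechet: float
    optimal_fnr_hausdorff: float
    sse_at_optimum: float
    sse_uncorrected: float
    grid: TimeGrid
    sample_id: str = ""
    coverage: float = float("nan")

    @property
    def log10_sse_reduction(self) -> float:
        """log10(SSE uncorrected) - log10(SSE at optimum); inf if SSE -> 0."""
        if self.sse_at_optimum == 0.0:
            return float("inf") if self.sse_uncorrected > 0 else 0.0
        return float(np.log10(self.sse_uncorrected) - np.log10(self.sse_at_optimum))


@dataclass(frozen=True)
class CoverageObservation:
    """One regression point: mean coverage (x) versus optimal FNR."""

    coverage: float
    optimal_fnr: float
    source: str = "swept"  # "swept" | "anchor"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.optimal_fnr <= FNR_MAX:
            raise ValueError("optimal_fnr must lie in [0, 0.99]")
        if self.source not in ("swept", "anchor"):
            raise ValueError("source must be 'swept' or 'anchor'")


def sweep_fnr(
    reference: ScaledTrajectory,
    query: ScaledTrajectory,
    grid: TimeGrid | None = None,
    fnr_min: float = 0.0,
    fnr_max: float = FNR_MAX,
    step: float = 0.01,
    y_scale: float = 1.0e4,
    log_y: bool = False,
) -> SweepResult:
    """Score every candidate FNR correction of ``query`` against ``reference``.

    Returns per-candidate Hausdorff/Frechet/SSE records and the per-metric
    optima (argmin; ties resolved toward the smallest FNR, i.e. the least
    correction).
    """
    grid = grid or TimeGrid()
    candidates = _fnr_candidates(fnr_min, fnr_max, step)
    ref_curve = project_onto_grid(reference, grid, y_scale=y_scale, log_y=log_y)

    rows = []
    for f in candidates:
        cand = project_onto_grid(
            apply_fnr_correction(query, float(f)), grid, y_scale=y_scale, log_y=log_y
        )
        rows.append(
            {
                "fnr": float(f),
                "hausdorff": hausdorff(ref_curve, cand),
                "frechet": discrete_frechet(ref_curve, cand),
                "sse": sum_squared_errors(ref_curve, cand),
            }
        )
    records = pd.DataFrame(rows, columns=["fnr", "hausdorff", "frechet", "sse"])

    # idxmin on an ascending-fnr frame breaks ties toward the smallest FNR.
    opt_frechet = float(records.loc[records["frechet"].idxmin(), "fnr"])
    opt_hausdorff = float(records.loc[records["hausdorff"].idxmin(), "fnr"])

    sse_at_opt = float(records.loc[records["fnr"] == opt_frechet, "sse"].iloc[0])
    zero_curve = project_onto_grid(
        apply_fnr_correction(query, 0.0), grid, y_scale=y_scale, log_y=log_y
    )
    sse_zero = sum_squared_errors(ref_curve, zero_curve)

    return SweepResult(
        records=records,
        optimal_fnr_frechet=opt_frechet,
        optimal_fnr_hausdorff=opt_hausdorff,
        sse_at_optimum=sse_at_opt,
        sse_uncorrected=sse_zero,
        grid=grid,
        sample_id=query.meta.sample_id,
        coverage=query.meta.mean_coverage,
    )


def select_optimal_fnr(result: SweepResult, metric: str = "frechet") -> float:
    """Optimal FNR under the chosen metric (default: discrete Frechet)."""
    if metric == "frechet":
        return result.optimal_fnr_frechet
    if metric == "hausdorff":
        return result.optimal_fnr_hausdorff
    raise ValueError(f"unknown metric {metric!r}; expected 'frechet' or 'hausdorff'")


def assemble_observations(
    sweep_results: Mapping[float, SweepResult],
    anchor_coverages: Iterable[float] = (),
    anchor_coverage: float = ANCHOR_COVERAGE,
    metric: str = "frechet",
) -> list[CoverageObservation]:
    """Build the coverage -> optimal-FNR regression points.

    Swept samples below the anchor threshold contribute their swept
    optimum; any sample at or above the threshold (swept or listed in
    ``anchor_coverages``, e.g. the high-coverage reference itself) enters
    as optimal FNR = 0, anchoring the fit where false-negative losses are
    negligible.  At least 3 points are required for the quadratic fit.
    """
    obs: list[CoverageObservation] = []
    for cov, res in sorted(sweep_results.items()):
        if cov >= anchor_coverage:
            obs.append(CoverageObservation(cov, 0.0, "anchor", res.sample_id))
        else:
            obs.append(
                CoverageObservation(cov, select_optimal_fnr(res, metric), "swept", res.sample_id)
            )
    for cov in anchor_coverages:
        if cov >= anchor_coverage:
            obs.append(CoverageObservation(float(cov), 0.0, "anchor"))
    if len(obs) < 3:
        raise ValueError(
            f"insufficient points for polynomial fit: {len(obs)} observations, need >= 3"
        )
    return obs


def observations_frame(observations: Sequence[CoverageObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": o.sample_id,
                "coverage": o.coverage,
                "optimal_fnr": o.optimal_fnr,
                "source": o.source,
            }
            for o in observations
        ]
    )


class FNRCalibrator(RegressorMixin, BaseEstimator):
    """Polynomial regression of optimal FNR on mean sequencing coverage.

    Parameters
    ----------
    degree : int or "auto", default "auto"
        Polynomial degree.  With "auto", every degree in ``degrees`` is
        fitted and the lowest degree whose R-squared is within
        ``parsimony_tol`` of the best is selected.
    degrees : tuple of int, default (1, 2, 3)
        Candidate degrees for automatic selection.
    parsimony_tol : float, default 0.005
        R-squared slack for preferring a lower degree.
    anchor_coverage : float, default 15.0
        Depth at and above which predictions clamp to 0 when the raw
        polynomial dips negative.
    clamp : tuple of float, default (0.0, 0.99)
        Predictions are clamped into this interval (the sweep domain).

    Attributes
    ----------
    degree_ : int
        Selected degree.
    coef_ : ndarray of shape (degree_ + 1,)
        Coefficients in ascending powers of coverage.
    r_squared_ : float
        1 - SS_res / SS_tot about the mean observed FNR (1.0 when both
        SS_tot and SS_res vanish, 0.0 when only SS_tot does).
    r_squared_by_degree_ : dict
        R-squared per candidate degree (auto mode only).

    Examples
    --------
    >>> import numpy as np
    >>> cov = np.arange(5.0, 16.0)
    >>> fnr = np.clip(0.6 * (15 - cov) ** 2 / 15**2, 0, None)
    >>> cal = FNRCalibrator().fit(cov[:, None], fnr)
    >>> cal.degree_
    2
    """

    def __init__(
        self,
        degree: int | str = "auto",
        degrees: tuple[int, ...] = (1, 2, 3),
        parsimony_tol: float = 0.005,
        anchor_coverage: float = ANCHOR_COVERAGE,
        clamp: tuple[float, float] = (0.0, FNR_MAX),
    ) -> None:
        self.degree = degree
        self.degrees = degrees
        self.parsimony_tol = parsimony_tol
        self.anchor_coverage = anchor_coverage
        self.clamp = clamp

    @staticmethod
    def _validate_xy(X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of mean coverages")
        if np.any(~np.isfinite(X)):
            raise ValueError("coverages must be finite")
        if y is None:
            return X
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        return X, y

    @staticmethod
    def _ols(cov: np.ndarray, fnr: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
        design = np.vander(cov, degree + 1, increasing=True)
        if np.linalg.matrix_rank(design) < degree + 1:
            raise ValueError(
                "rank-deficient design: need more distinct coverages than the "
                f"polynomial degree ({degree})"
            )
        coef, *_ = np.linalg.lstsq(design, fnr, rcond=None)
        resid = fnr - design @ coef
        ss_res = float(resid @ resid)
        centered = fnr - fnr.mean()
        ss_tot = float(centered @ centered)
        if ss_tot == 0.0:
            r2 = 1.0 if ss_res < 1e-24 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        return coef, r2

    def fit(self, X, y):
        """Fit the calibration polynomial.

        X is a (n, 1) array of mean coverages, y the optimal FNR values.
        """
        X, y = self._validate_xy(X, y)
        cov = X[:, 0]

        if self.degree == "auto":
            fits: dict[int, tuple[np.ndarray, float]] = {}
            for d in sorted(self.degrees):
                if cov.size >= d + 1:
                    fits[d] = self._ols(cov, y, d)
            if not fits:
                raise ValueError("not enough observations for any candidate degree")
            best_r2 = max(r2 for _, r2 in fits.values())
            chosen = min(d for d, (_, r2) in fits.items() if r2 >= best_r2 - self.parsimony_tol)
            self.coef_, self.r_squared_ = fits[chosen]
            self.degree_ = chosen
            self.r_squared_by_degree_ = {d: r2 for d, (_, r2) in fits.items()}
        else:
            d = int(self.degree)
            if cov.size < d + 1:
                raise ValueError(
                    f"need at least {d + 1} observations for a degree-{d} fit, got {cov.size}"
                )
            self.coef_, self.r_squared_ = self._ols(cov, y, d)
            self.degree_ = d
            self.r_squared_by_degree_ = {d: self.r_squared_}

        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted FNR per coverage, clamped into the sweep domain."""
        check_is_fitted(self, "coef_")
        X = self._validate_xy(X)
        cov = X[:, 0]
        raw = np.polynomial.polynomial.polyval(cov, self.coef_)
        out = np.clip(raw, self.clamp[0], self.clamp[1])
        # At anchor depth and above, a negative raw prediction means "no
        # correction needed", which the lower clamp already encodes; the
        # branch is explicit for readability.
        out[(cov >= self.anchor_coverage) & (raw < 0)] = 0.0
        return out

    def to_model(self, metric: str = "frechet", grid: TimeGrid | None = None) -> "CalibrationModel":
        check_is_fitted(self, "coef_")
        return CalibrationModel(
            degree=self.degree_,
            coefficients=tuple(float(c) for c in self.coef_),
            r_squared=float(self.r_squared_),
            metric=metric,
            grid=grid or TimeGrid(),
            anchor_coverage=self.anchor_coverage,
        )


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted coverage -> FNR polynomial, serializable as plain text."""

    degree: int
    coefficients: tuple[float, ...]  # ascending powers of coverage
    r_squared: float
    metric: str = "frechet"
    grid: TimeGrid = field(default_factory=TimeGrid)
    anchor_coverage: float = ANCHOR_COVERAGE

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count must equal degree + 1")

    def predict(self, coverage) -> np.ndarray:
        """Evaluate the polynomial, clamped into [0, 0.99]."""
        cov = np.atleast_1d(np.asarray(coverage, dtype=float))
        if np.any(cov <= 0):
            raise ValueError("coverage must be positive")
        raw = np.polynomial.polynomial.polyval(cov, np.asarray(self.coefficients))
        out = np.clip(raw, 0.0, FNR_MAX)
        out[(cov >= self.anchor_coverage) & (raw < 0)] = 0.0
        return out

    def write_report(self, path: str | Path) -> None:
        lines = [
            f"degree\t{self.degree}",
            "coefficients\t" + "\t".join("%.17g" % c for c in self.coefficients),
            f"r_squared\t{'%.17g' % self.r_squared}",
            f"metric\t{self.metric}",
            f"grid\t{self.grid.n_points}\t{'%.17g' % self.grid.t_min}\t{'%.17g' % self.grid.t_max}",
            f"anchor_coverage\t{'%.17g' % self.anchor_coverage}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_report(cls, path: str | Path) -> "CalibrationModel":
        kv: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            key, *vals = line.split("\t")
            kv[key] = vals
        try:
            return cls(
                degree=int(kv["degree"][0]),
                coefficients=tuple(float(v) for v in kv["coefficients"]),
                r_squared=float(kv["r_squared"][0]),
                metric=kv.get("metric", ["frechet"])[0],
                grid=TimeGrid(
                    int(kv["grid"][0]), float(kv["grid"][1]), float(kv["grid"][2])
                )
                if "grid" in kv
                else TimeGrid(),
                anchor_coverage=float(kv.get("anchor_coverage", ["15"])[0]),
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise ValueError(f"malformed calibration model report: {path}") from exc


def fit_polynomial(
    observations: Sequence[CoverageObservation], degree: int
) -> CalibrationModel:
    """Ordinary least-squares polynomial fit of fixed degree."""
    cov = np.array([o.coverage for o in observations])
    fnr = np.array([o.optimal_fnr for o in observations])
    cal = FNRCalibrator(degree=degree).fit(cov[:, None], fnr)
    return cal.to_model()


def select_degree(
    observations: Sequence[CoverageObservation],
    degrees: tuple[int, ...] = (1, 2, 3),
    parsimony_tol: float = 0.005,
) -> CalibrationModel:
    """Fit degrees 1-3 and keep the most parsimonious near-best model."""
    cov = np.array([o.coverage for o in observations])
    fnr = np.array([o.optimal_fnr for o in observations])
    cal = FNRCalibrator(degree="auto", degrees=degrees, parsimony_tol=parsimony_tol).fit(
        cov[:, None], fnr
    )
    return cal.to_model()


def predict_fnr(model: CalibrationModel, coverage) -> np.ndarray:
    """Predicted FNR correction for new coverage(s), clamped to [0, 0.99]."""
    return model.predict(coverage)
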