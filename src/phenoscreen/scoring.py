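"""Mahalanobis phenotypic scoring against a robust control hyper-ellipsoid.

The control cells of a plate define a multivariate reference: PCA of
their attribute covariance fits a hyper-ellipsoid whose principal axes
capture correlated attribute families.  Each cell's score is its
Mahalanobis distance

    D = sqrt( (x - mu)' Sigma^+ (x - mu) )

computed through the retained principal axes, which balances attribute
scales and correlations.  The fit is robust: points beyond a chi-square
distance quantile are iteratively trimmed before refitting, so bubbles,
debris and clumps do not inflate the reference ellipsoid.  Per-attribute
contributions decompose D^2 additively to rank which features a
treatment changed most, and wells aggregate to a robust (median) score.

Usage follows the model/results pattern::

    model = ControlModel(control_records)
    res = model.fit()
    distances = res.mahalanobis(treated_records)
    res.summary()
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plates import PlateLayout, WellAddress, ROLE_EMPTY
from .simulate import PROVENANCE_COLUMNS

__all__ = [
    "ControlModel",
    "ControlModelResults",
    "WellScore",
    "attribute_matrix",
    "fit_control_model",
    "mahalanobis_score",
    "attribute_contributions",
    "flag_outliers",
    "score_well",
    "score_plate",
    "plate_heatmap",
]

_NON_ATTRIBUTE = set(PROVENANCE_COLUMNS) | {"field", "outlier", "distance", "flagged"}


def attribute_matrix(records) -> tuple[np.ndarray, list[str]]:
    """Extract the numeric attribute block from a records table.

    Provenance columns (plate / well / cell / field) and any score
    bookkeeping columns are dropped; everything else is an attribute.
    """
    if isinstance(records, pd.DataFrame):
        cols = [c for c in records.columns if c not in _NON_ATTRIBUTE]
        return records[cols].to_numpy(dtype=float), list(cols)
    arr = np.atleast_2d(np.asarray(records, dtype=float))
    return arr, [f"attr_{i}" for i in range(arr.shape[1])]


class ControlModel:
    """Robust-PCA hyper-ellipsoid model of a control cell population.

    Parameters
    ----------
    controls : DataFrame or (n, p) array
        One row per control cell; non-attribute columns are ignored.
    trim_quantile : float
        Chi-square quantile beyond which points are trimmed during the
        robust fit (default 0.975).
    variance_floor : float
        Principal axes with variance below ``variance_floor`` times the
        mean eigenvalue are dropped from the retained set, absorbing
        rank deficiency (default 1e-6).
    max_iter : int
        Maximum trim/refit iterations (default 10).
    """

    def __init__(
        self,
        controls,
        attribute_names=None,
        trim_quantile: float = 0.975,
        variance_floor: float = 1e-6,
        max_iter: int = 10,
    ):
        X, names = attribute_matrix(controls)
        if attribute_names is not None:
            names = list(attribute_names)
        if X.shape[1] != len(names):
            raise ValueError("attribute_names length does not match data width")
        if not (0 < trim_quantile < 1):
            raise ValueError("trim_quantile must be in (0, 1)")
        self.X = X
        self.attribute_names = names
        self.trim_quantile = trim_quantile
        self.variance_floor = variance_floor
        self.max_iter = max_iter

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ControlModel":
        return cls(frame, **kwargs)

    @staticmethod
    def _consistency(d: int, q: float) -> float:
        """Trimming consistency factor: restricting a d-variate normal to
        its chi-square(q) ellipsoid shrinks the covariance by
        ``P(chi2_{d+2} <= chi2_{d,q}) / q``; dividing by this keeps the
        trimmed estimate unbiased under the null."""
        return stats.chi2.cdf(stats.chi2.ppf(q, d), d + 2) / q

    def _decompose(self, X: np.ndarray, trimmed: bool):
        mu = X.mean(axis=0)
        cov = np.cov(X - mu, rowvar=False, ddof=1)
        lam, V = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(lam)[::-1]
        lam, V = np.clip(lam[order], 0.0, None), V[:, order]
        floor = self.variance_floor * lam.mean()
        retained = int(np.sum(lam > floor))
        if trimmed and retained > 0:
            lam = lam / self._consistency(retained, self.trim_quantile)
        return mu, V, lam, retained

    def fit(self) -> "ControlModelResults":
        X = self.X
        n, p = X.shape
        if n <= p:
            raise ValueError(
                f"need more control cells than attributes: n={n}, p={p}"
            )
        mask = np.ones(n, dtype=bool)
        history: list[int] = []
        mu = V = lam = None
        retained = p
        for iteration in range(self.max_iter):
            if mask.sum() <= p:
                raise ValueError(
                    f"too few inliers after trimming ({int(mask.sum())} <= {p} attributes)"
                )
            mu, V, lam, retained = self._decompose(X[mask], trimmed=iteration > 0)
            if retained == 0:
                raise ValueError("all attributes have zero variance in the controls")
            d2 = _squared_distance(X, mu, V, lam, retained)
            new_mask = d2 <= stats.chi2.ppf(self.trim_quantile, retained)
            history.append(int((~new_mask).sum()))
            # converged when the inlier set repeats (allowing period-2
            # oscillation of boundary points under readmission); `mask`
            # stays the set the returned model was fitted on
            if np.array_equal(new_mask, mask) or (
                len(history) > 2 and np.array_equal(new_mask, prev_mask)
            ):
                break
            if iteration == self.max_iter - 1:
                break
            prev_mask = mask
            mask = new_mask
        return ControlModelResults(
            model=self,
            attribute_names=self.attribute_names,
            center=mu,
            axes=V,
            variances=lam,
            retained=retained,
            trim_quantile=self.trim_quantile,
            trim_iterations=len(history),
            trim_history=history,
            n_used=int(mask.sum()),
            n_trimmed=int(n - mask.sum()),
        )


def _squared_distance(X, mu, V, lam, retained) -> np.ndarray:
    Y = (np.atleast_2d(X) - mu) @ V[:, :retained]
    return np.sum(Y**2 / lam[:retained], axis=1)


@dataclass
class ControlModelResults:
    """Fitted control hyper-ellipsoid: center, principal axes, variances."""

    model: ControlModel | None
    attribute_names: list[str]
    center: np.ndarray
    axes: np.ndarray
    variances: np.ndarray
    retained: int
    trim_quantile: float
    trim_iterations: int
    trim_history: list[int]
    n_used: int
    n_trimmed: int

    # -- scoring -------------------------------------------------------

    def _validate(self, records) -> np.ndarray:
        if isinstance(records, pd.Series):
            records = records.to_frame().T
        if isinstance(records, pd.DataFrame):
            missing = [c for c in self.attribute_names if c not in records.columns]
            if missing:
                raise ValueError(f"records lack model attributes: {missing}")
            return records[self.attribute_names].to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(records, dtype=float))
        if arr.shape[1] != len(self.attribute_names):
            raise ValueError(
                f"expected {len(self.attribute_names)} attributes, got {arr.shape[1]}"
            )
        return arr

    def squared_mahalanobis(self, records) -> np.ndarray:
        X = self._validate(records)
        return _squared_distance(X, self.center, self.axes, self.variances, self.retained)

    def mahalanobis(self, records):
        """Mahalanobis distance of each record to the control center."""
        d = np.sqrt(self.squared_mahalanobis(records))
        if np.isscalar(records) or (
            isinstance(records, pd.Series) or np.asarray(records).ndim == 1
        ):
            return float(d[0])
        return d

    def pseudo_inverse(self) -> np.ndarray:
        """Covariance pseudo-inverse through the retained axes."""
        Vr = self.axes[:, : self.retained]
        return Vr @ np.diag(1.0 / self.variances[: self.retained]) @ Vr.T

    def contributions(self, record) -> pd.Series:
        """Signed per-attribute share of D^2; sums to 1.

        With ``g = Sigma^+ (x - mu)`` the share of attribute j is
        ``c_j = (x - mu)_j g_j / D^2``; the decomposition is exact and
        ranking |c_j| identifies the attributes a treatment changed
        most.  Undefined at the center (D = 0).
        """
        x = self._validate(record)[0]
        delta = x - self.center
        g = self.pseudo_inverse() @ delta
        d2 = float(delta @ g)
        if d2 <= 0:
            raise ValueError("contributions are undefined at zero distance")
        return pd.Series(delta * g / d2, index=self.attribute_names)

    def rank_contributions(self, record) -> pd.DataFrame:
        c = self.contributions(record)
        order = c.abs().sort_values(ascending=False).index
        return pd.DataFrame(
            {"attribute": order, "contribution": c[order].to_numpy()}
        ).reset_index(drop=True)

    def flag_outliers(self, records, quantile: float = 0.999) -> np.ndarray:
        """True where D^2 exceeds the chi-square(retained) quantile."""
        d2 = self.squared_mahalanobis(records)
        return d2 > stats.chi2.ppf(quantile, self.retained)

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Control hyper-ellipsoid (robust PCA)",
            "=" * 40,
            f"attributes:      {len(self.attribute_names)}",
            f"retained axes:   {self.retained}",
            f"cells used:      {self.n_used}  (trimmed {self.n_trimmed})",
            f"trim quantile:   {self.trim_quantile}",
            f"trim iterations: {self.trim_iterations}  history {self.trim_history}",
            "",
            "leading axis variances:",
        ]
        for k in range(min(5, self.retained)):
            lines.append(f"  axis {k + 1}: {self.variances[k]:.6g}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "attribute_names": self.attribute_names,
            "center": self.center.tolist(),
            "axes": self.axes.tolist(),
            "variances": self.variances.tolist(),
            "retained": self.retained,
            "trim_quantile": self.trim_quantile,
            "trim_iterations": self.trim_iterations,
            "trim_history": self.trim_history,
            "n_used": self.n_used,
            "n_trimmed": self.n_trimmed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ControlModelResults":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            model=None,
            attribute_names=p["attribute_names"],
            center=np.array(p["center"]),
            axes=np.array(p["axes"]),
            variances=np.array(p["variances"]),
            retained=p["retained"],
            trim_quantile=p["trim_quantile"],
            trim_iterations=p["trim_iterations"],
            trim_history=p["trim_history"],
            n_used=p["n_used"],
            n_trimmed=p["n_trimmed"],
        )


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def fit_control_model(
    controls,
    trim_quantile: float = 0.975,
    variance_floor: float = 1e-6,
    max_iter: int = 10,
) -> ControlModelResults:
    """Fit the robust control hyper-ellipsoid (see :class:`ControlModel`)."""
    return ControlModel(
        controls,
        trim_quantile=trim_quantile,
        variance_floor=variance_floor,
        max_iter=max_iter,
    ).fit()


def mahalanobis_score(record, model: ControlModelResults):
    return model.mahalanobis(record)


def attribute_contributions(record, model: ControlModelResults) -> pd.Series:
    return model.contributions(record)


def flag_outliers(records, model: ControlModelResults, quantile: float = 0.999):
    return model.flag_outliers(records, quantile=quantile)


@dataclass(frozen=True)
class WellScore:
    """Aggregated score for one well: robust location and spread."""

    well: str
    score: float          # median distance over non-outlier cells (NaN if empty)
    n_cells: int
    dispersion: float     # MAD of the distances
    n_outliers: int
    empty: bool = False


def score_well(
    records, model: ControlModelResults, outlier_quantile: float = 0.999,
    well: str = "",
) -> WellScore:
    """Median Mahalanobis distance over the well's non-artifact cells.

    Artifacts (bubbles, debris, clumps) are flagged against the well's
    OWN distance distribution — cells whose robust z-score (median/MAD
    of the distances) exceeds the two-sided normal quantile matching
    ``outlier_quantile`` — so a genuinely shifted treated population is
    not rejected for being far from the controls.
    """
    d = np.atleast_1d(model.mahalanobis(records))
    if d.size == 0:
        return WellScore(well, float("nan"), 0, float("nan"), 0, empty=True)
    med = np.median(d)
    mad = stats.median_abs_deviation(d, scale="normal")
    if mad > 0:
        out = np.abs(d - med) / mad > stats.norm.ppf((1 + outlier_quantile) / 2)
    else:
        out = np.zeros(d.size, dtype=bool)
    kept = d[~out]
    return WellScore(
        well=well,
        score=float(np.median(kept)),
        n_cells=int(d.size),
        dispersion=float(stats.median_abs_deviation(kept)),
        n_outliers=int(out.sum()),
    )


def score_plate(
    records: pd.DataFrame,
    layout: PlateLayout,
    trim_quantile: float = 0.975,
    variance_floor: float = 1e-6,
    max_iter: int = 10,
    outlier_quantile: float = 0.999,
) -> tuple[pd.DataFrame, ControlModelResults]:
    """Score every well of a plate against its own pooled controls.

    The control model is fitted on the cells of all layout wells with
    role ``control``; every non-empty well is then scored.  Returns a
    per-well table (well, role, drugs, doses, score, dispersion,
    counts) and the fitted control model.
    """
    if "well" not in records.columns:
        raise ValueError("records must carry a 'well' column")
    control_names = {str(w) for w in layout.control_wells}
    if not control_names:
        raise ValueError("layout defines no control wells")
    controls = records[records["well"].isin(control_names)]
    if controls.empty:
        raise ValueError("no cells found in the layout's control wells")
    model = fit_control_model(
        controls, trim_quantile=trim_quantile,
        variance_floor=variance_floor, max_iter=max_iter,
    )
    rows = []
    for well in sorted(layout.wells):
        a = layout.wells[well]
        if a.role == ROLE_EMPTY:
            continue
        cells = records[records["well"] == str(well)]
        if cells.empty:
            continue
        ws = score_well(cells, model, outlier_quantile=outlier_quantile, well=str(well))
        rows.append(
            {
                "well": str(well),
                "role": a.role,
                "drug_1": a.drugs[0] if len(a.drugs) > 0 else "",
                "conc_1": a.concentrations[0] if len(a.drugs) > 0 else float("nan"),
                "drug_2": a.drugs[1] if len(a.drugs) > 1 else "",
                "conc_2": a.concentrations[1] if len(a.drugs) > 1 else float("nan"),
                "replicate_group": a.replicate_group,
                "score": ws.score,
                "dispersion": ws.dispersion,
                "n_cells": ws.n_cells,
                "n_outliers": ws.n_outliers,
            }
        )
    return pd.DataFrame(rows), model


def plate_grid(well_scores: pd.DataFrame, layout: PlateLayout) -> np.ndarray:
    """Dense (n_rows, n_cols) score grid aligned to the physical plate."""
    grid = np.full((layout.n_rows, layout.n_cols), np.nan)
    for _, row in well_scores.iterrows():
        w = WellAddress.from_string(row["well"])
        grid[w.row_index, w.column - 1] = row["score"]
    return grid


def plate_heatmap(
    grid: np.ndarray, path, title: str = "Mahalanobis well scores",
    vmin: float | None = None, vmax: float | None = None,
) -> dict:
    """Write a spectral-colormap heatmap PNG of a plate score grid.

    Returns the color-scale bounds actually used so reports can record
    them alongside the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = grid[np.isfinite(grid)]
    vmin = float(finite.min()) if vmin is None and finite.size else (vmin or 0.0)
    vmax = float(finite.max()) if vmax is None and finite.size else (vmax or 1.0)
    fig, ax = plt.subplots(figsize=(10, 7))
    im = ax.imshow(grid, cmap="Spectral_r", vmin=vmin, vmax=vmax)
    ax.set_title(title)
    ax.set_xticks(range(grid.shape[1]), [str(c + 1) for c in range(grid.shape[1])],
                  fontsize=6)
    ax.set_yticks(range(grid.shape[0]),
                  [chr(ord("A") + r) for r in range(grid.shape[0])], fontsize=6)
    fig.colorbar(im, ax=ax, label="score")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return {"vmin": vmin, "vmax": vmax}
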