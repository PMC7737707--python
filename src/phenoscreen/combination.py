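"""Binary drug-combination analysis under Loewe additivity and Bliss
independence.

A combination experiment measures fractional effects on an ``n1 x n2``
dose-pair grid with single-drug edges.  Two null models predict the
combined effect from the single-drug median-effect parameters
(Dm1, s1, Dm2, s2):

* **Loewe additivity** — the drugs behave as dilutions of one another;
  the combined effect f solves

      D1 / (Dm1 * [f/(1-f)]**(1/s1)) + D2 / (Dm2 * [f/(1-f)]**(1/s2)) = 1

  (the denominators are the single-drug doses Dx_i producing effect f).
* **Bliss independence** — implemented as the product of the two
  single-drug effect fractions, f_comb = f1 * f2; the conventional
  inclusion-exclusion form f1 + f2 - f1*f2 is available via
  ``convention="inclusion-exclusion"``.

Departure from a null model (synergy/antagonism) is quantified by
residuals, the combination index CI = D1/Dx1 + D2/Dx2 (CI < 1 synergy,
> 1 antagonism), and a seeded randomization test on the mean residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dose_response import MedianEffectResults, fit_median_effect
from .simulate import fractional_effect

__all__ = [
    "CombinationParams",
    "CombinationMatrix",
    "CombinationModel",
    "CombinationResults",
    "SynergyReport",
    "bliss_predict",
    "loewe_predict",
    "combination_surface",
    "combination_index",
    "fit_single_drug_edges",
    "fit_combination_joint",
]


@dataclass(frozen=True)
class CombinationParams:
    """Per-drug median-effect parameters of a binary combination."""

    dm1: float
    s1: float
    dm2: float
    s2: float

    def __post_init__(self) -> None:
        if min(self.dm1, self.dm2) <= 0 or min(self.s1, self.s2) <= 0:
            raise ValueError("Dm and s parameters must all be positive")


def bliss_predict(D1, D2, params, convention: str = "product"):
    """Bliss-independence prediction from single-drug effect fractions.

    ``"product"`` is f1 * f2 (a zero dose zeroes the product);
    ``"inclusion-exclusion"`` is the conventional f1 + f2 - f1*f2.
    Vectorised over dose grids.
    """
    f1 = np.asarray(fractional_effect(D1, params.dm1, params.s1))
    f2 = np.asarray(fractional_effect(D2, params.dm2, params.s2))
    if convention == "product":
        out = f1 * f2
    elif convention == "inclusion-exclusion":
        out = f1 + f2 - f1 * f2
    else:
        raise ValueError(f"unknown Bliss convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def _loewe_condition(f, D1, D2, params):
    t = f / (1.0 - f)
    return (
        D1 / (params.dm1 * t ** (1.0 / params.s1))
        + D2 / (params.dm2 * t ** (1.0 / params.s2))
        - 1.0
    )


def loewe_predict(
    D1: float, D2: float, params, tol: float = 1e-8, max_iter: int = 200
) -> float:
    """Combined fractional effect under Loewe additivity.

    Solves the isobole condition for f by bisection on (0, 1); the
    left-hand side is strictly decreasing in f, so the root is unique.
    A zero partner dose reduces exactly to the single-drug curve.
    """
    if D1 < 0 or D2 < 0 or D1 + D2 <= 0:
        raise ValueError("need non-negative doses with D1 + D2 > 0")
    if D2 == 0:
        return float(fractional_effect(D1, params.dm1, params.s1))
    if D1 == 0:
        return float(fractional_effect(D2, params.dm2, params.s2))
    lo, hi = 1e-9, 1.0 - 1e-9
    g_lo, g_hi = _loewe_condition(lo, D1, D2, params), _loewe_condition(hi, D1, D2, params)
    if g_lo < 0 or g_hi > 0:
        raise ValueError(
            f"no sign change on the Loewe bracket (g(lo)={g_lo:.3g}, "
            f"g(hi)={g_hi:.3g}); degenerate parameters {params}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = _loewe_condition(mid, D1, D2, params)
        if abs(g) < tol:
            return mid
        if g > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def combination_surface(D1, D2, params, model: str, convention: str = "product"):
    """Model surface used for fitting: reduces to the single-drug curve
    whenever a partner dose is exactly zero (for either null model)."""
    if D1 == 0 and D2 == 0:
        return 0.0
    if D2 == 0:
        return float(fractional_effect(D1, params.dm1, params.s1))
    if D1 == 0:
        return float(fractional_effect(D2, params.dm2, params.s2))
    if model == "loewe":
        return loewe_predict(D1, D2, params)
    if model == "bliss":
        return float(bliss_predict(D1, D2, params, convention=convention))
    raise ValueError(f"unknown model {model!r}")


def combination_index(D1: float, D2: float, f_observed: float, params) -> float:
    """CI = D1/Dx1 + D2/Dx2 at observed effect f; 1 = Loewe-additive."""
    if not (0.0 < f_observed < 1.0):
        raise ValueError("combination index requires f strictly inside (0, 1)")
    t = f_observed / (1.0 - f_observed)
    dx1 = params.dm1 * t ** (1.0 / params.s1)
    dx2 = params.dm2 * t ** (1.0 / params.s2)
    return D1 / dx1 + D2 / dx2


# ---------------------------------------------------------------------------
# Combination matrices
# ---------------------------------------------------------------------------

@dataclass
class CombinationMatrix:
    """Duplicate-averaged fractional effects on a dose-pair grid.

    ``observed_f[i, j]`` is the effect at ``(doses_1[i], doses_2[j])``;
    ``edge_1`` / ``edge_2`` hold the single-agent effects along each
    drug's ladder.
    """

    drug_1: str
    drug_2: str
    doses_1: np.ndarray
    doses_2: np.ndarray
    observed_f: np.ndarray
    edge_1: np.ndarray | None = None
    edge_2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses_1 = np.asarray(self.doses_1, dtype=float)
        self.doses_2 = np.asarray(self.doses_2, dtype=float)
        self.observed_f = np.asarray(self.observed_f, dtype=float)
        if self.observed_f.shape != (len(self.doses_1), len(self.doses_2)):
            raise ValueError("observed_f shape must be (len(doses_1), len(doses_2))")
        if np.any(self.doses_1 <= 0) or np.any(self.doses_2 <= 0):
            raise ValueError("grid doses must be strictly positive")
        for edge, doses, name in (
            (self.edge_1, self.doses_1, "edge_1"),
            (self.edge_2, self.doses_2, "edge_2"),
        ):
            if edge is not None and len(edge) != len(doses):
                raise ValueError(f"{name} length must match its dose ladder")

    @classmethod
    def from_virtual_plate(
        cls,
        frame: pd.DataFrame,
        drug_1: str,
        drug_2: str,
        score_column: str = "score",
        amplitude: tuple[float, float] | None = None,
    ) -> "CombinationMatrix":
        """Build from a virtual-plate table (duplicate-averaged rows).

        Scores are normalized to fractional effects using ``amplitude =
        (A, B)``; when omitted, B is the mean control score (falling
        back to the plate minimum) and A spans to the maximum score.
        """
        is_pair = (frame["drug_1"] == drug_1) & (frame["drug_2"] == drug_2)
        only_1 = (frame["drug_1"] == drug_1) & (
            frame["drug_2"].fillna("").eq("")
        )
        only_2 = (
            frame["drug_1"].eq(drug_2) & frame["drug_2"].fillna("").eq("")
        )
        core = frame[is_pair]
        if core.empty:
            raise ValueError(f"no dose-pair rows for {drug_1} + {drug_2}")
        if amplitude is None:
            controls = frame[frame.get("role", "") == "control"][score_column]
            all_scores = frame[score_column].astype(float)
            B = float(controls.mean()) if len(controls) else float(all_scores.min())
            A = float(all_scores.max()) - B
            if A <= 0:
                raise ValueError("cannot normalize: score amplitude is not positive")
        else:
            A, B = amplitude
        doses_1 = np.sort(core["conc_1"].unique())
        doses_2 = np.sort(core["conc_2"].unique())
        grid = np.full((len(doses_1), len(doses_2)), np.nan)
        for _, row in core.iterrows():
            i = int(np.searchsorted(doses_1, row["conc_1"]))
            j = int(np.searchsorted(doses_2, row["conc_2"]))
            grid[i, j] = (row[score_column] - B) / A
        if np.isnan(grid).any():
            raise ValueError("dose-pair grid is incomplete")

        def _edge(sub: pd.DataFrame, doses: np.ndarray):
            if sub.empty:
                return None
            values = sub.set_index("conc_1")[score_column]
            if not set(np.round(doses, 15)).issubset(set(np.round(values.index, 15))):
                return None
            return ((values.reindex(doses).to_numpy() - B) / A)

        edge_1 = _edge(frame[only_1], doses_1)
        edge_2 = _edge(frame[only_2], doses_2)
        return cls(
            drug_1=drug_1, drug_2=drug_2,
            doses_1=doses_1, doses_2=doses_2,
            observed_f=np.clip(grid, 0.0, 1.0),
            edge_1=None if edge_1 is None else np.clip(edge_1, 0.0, 1.0),
            edge_2=None if edge_2 is None else np.clip(edge_2, 0.0, 1.0),
        )

    @classmethod
    def from_params(
        cls,
        params: CombinationParams,
        doses_1,
        doses_2,
        model: str = "bliss",
        convention: str = "product",
        drug_1: str = "drug1",
        drug_2: str = "drug2",
    ) -> "CombinationMatrix":
        """Model-generated matrix (used for tests and null calibration)."""
        doses_1 = np.asarray(doses_1, dtype=float)
        doses_2 = np.asarray(doses_2, dtype=float)
        grid = np.array(
            [
                [combination_surface(d1, d2, params, model, convention) for d2 in doses_2]
                for d1 in doses_1
            ]
        )
        return cls(
            drug_1=drug_1, drug_2=drug_2,
            doses_1=doses_1, doses_2=doses_2, observed_f=grid,
            edge_1=np.asarray(fractional_effect(doses_1, params.dm1, params.s1)),
            edge_2=np.asarray(fractional_effect(doses_2, params.dm2, params.s2)),
        )


def fit_single_drug_edges(
    matrix: CombinationMatrix,
) -> tuple[MedianEffectResults, MedianEffectResults]:
    """Median-effect fits of the two single-agent edges.

    The matrix carries fractional effects, so the fits are run with the
    amplitude pinned to (A, B) = (1, 0) and only (Dm, s) free.
    """
    if matrix.edge_1 is None or matrix.edge_2 is None:
        raise ValueError("combination matrix lacks single-drug edge data")
    fit1 = fit_median_effect(matrix.doses_1, matrix.edge_1, fixed_amplitude=(1.0, 0.0))
    fit2 = fit_median_effect(matrix.doses_2, matrix.edge_2, fixed_amplitude=(1.0, 0.0))
    return fit1, fit2


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class SynergyReport:
    """Residual summary of a combination matrix against a null model."""

    residuals: np.ndarray
    mean_residual: float
    max_abs_residual: float
    max_cell: tuple[int, int]
    ci_map: np.ndarray
    p_value: float
    n_randomizations: int
    seed: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Synergy report (observed - null prediction)",
                "=" * 44,
                f"mean residual:     {self.mean_residual:+.4g}",
                f"max |residual|:    {self.max_abs_residual:.4g} at cell {self.max_cell}",
                f"randomization p:   {self.p_value:.4g} "
                f"({self.n_randomizations} draws, seed {self.seed})",
                "interpretation: residual > 0 = stronger than the null "
                "(synergy); CI < 1 synergy, > 1 antagonism",
            ]
        )


@dataclass
class CombinationResults:
    """Joint fit of a combination matrix under one null model."""

    model_name: str
    params: CombinationParams
    rss: float
    converged: bool
    source: str                      # "edges" or "joint"
    matrix: CombinationMatrix
    convention: str = "product"
    edge_fits: tuple | None = None

    @property
    def predicted_f(self) -> np.ndarray:
        return np.array(
            [
                [
                    combination_surface(d1, d2, self.params, self.model_name, self.convention)
                    for d2 in self.matrix.doses_2
                ]
                for d1 in self.matrix.doses_1
            ]
        )

    @property
    def residuals(self) -> np.ndarray:
        return self.matrix.observed_f - self.predicted_f

    def combination_index_map(self) -> np.ndarray:
        """CI at each observed grid cell (NaN where f is at a bound)."""
        ci = np.full(self.matrix.observed_f.shape, np.nan)
        for i, d1 in enumerate(self.matrix.doses_1):
            for j, d2 in enumerate(self.matrix.doses_2):
                f = self.matrix.observed_f[i, j]
                if 0.0 < f < 1.0:
                    ci[i, j] = combination_index(d1, d2, f, self.params)
        return ci

    def synergy_report(
        self, n_randomizations: int = 1000, seed: int = 0
    ) -> SynergyReport:
        """Residual summary with a seeded sign-randomization test.

        Under the null the residuals are symmetric about zero, so the
        mean residual is compared with its distribution under random
        sign flips of the per-cell residuals.
        """
        r = self.residuals
        mean_r = float(r.mean())
        flat = r.ravel()
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_randomizations, flat.size))
        null_means = (signs * flat).mean(axis=1)
        p = float((np.abs(null_means) >= abs(mean_r)).mean())
        idx = int(np.argmax(np.abs(flat)))
        cell = np.unravel_index(idx, r.shape)
        return SynergyReport(
            residuals=r,
            mean_residual=mean_r,
            max_abs_residual=float(np.abs(flat[idx])),
            max_cell=(int(cell[0]), int(cell[1])),
            ci_map=self.combination_index_map(),
            p_value=p,
            n_randomizations=n_randomizations,
            seed=seed,
        )

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                f"Combination fit ({self.model_name}, {self.source})",
                "=" * 40,
                f"{self.matrix.drug_1}: Dm1 = {p.dm1:.6g}, s1 = {p.s1:.4g}",
                f"{self.matrix.drug_2}: Dm2 = {p.dm2:.6g}, s2 = {p.s2:.4g}",
                f"rss = {self.rss:.6g}   converged = {self.converged}",
            ]
        )

    def to_json(self, path) -> None:
        p = self.params
        payload = {
            "model": self.model_name,
            "drug_1": self.matrix.drug_1,
            "drug_2": self.matrix.drug_2,
            "Dm1": p.dm1, "s1": p.s1, "Dm2": p.dm2, "s2": p.s2,
            "rss": self.rss,
            "converged": self.converged,
            "source": self.source,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


class CombinationModel:
    """Fits (Dm1, Dm2, s1, s2) to a full combination matrix.

    The single-drug edges provide initial estimates; the joint fit then
    minimizes the squared deviation between observed fractional effects
    and the chosen null-model surface over every cell (core grid plus
    edges) simultaneously.
    """

    def __init__(
        self,
        matrix: CombinationMatrix,
        model: str = "loewe",
        convention: str = "product",
    ):
        if model not in ("loewe", "bliss"):
            raise ValueError(f"model must be 'loewe' or 'bliss', got {model!r}")
        self.matrix = matrix
        self.model_name = model
        self.convention = convention

    def _cells(self):
        m = self.matrix
        cells = [
            (d1, d2, m.observed_f[i, j])
            for i, d1 in enumerate(m.doses_1)
            for j, d2 in enumerate(m.doses_2)
        ]
        if m.edge_1 is not None:
            cells += [(d1, 0.0, f) for d1, f in zip(m.doses_1, m.edge_1)]
        if m.edge_2 is not None:
            cells += [(0.0, d2, f) for d2, f in zip(m.doses_2, m.edge_2)]
        return cells

    def fit(self) -> CombinationResults:
        cells = self._cells()
        if len(cells) < 8:
            raise ValueError(f"need >= 8 informative cells, have {len(cells)}")
        edge_fits = None
        try:
            f1, f2 = fit_single_drug_edges(self.matrix)
            edge_fits = (f1, f2)
            x0 = np.array([np.log(f1.Dm), f1.s, np.log(f2.Dm), f2.s])
        except ValueError:
            gm1 = float(np.exp(np.mean(np.log(self.matrix.doses_1))))
            gm2 = float(np.exp(np.mean(np.log(self.matrix.doses_2))))
            x0 = np.array([np.log(gm1), 1.0, np.log(gm2), 1.0])

        d_all = np.concatenate([self.matrix.doses_1, self.matrix.doses_2])
        log_lo, log_hi = np.log(d_all.min() / 100.0), np.log(d_all.max() * 100.0)
        lower = [log_lo, 0.1, log_lo, 0.1]
        upper = [log_hi, 10.0, log_hi, 10.0]
        x0 = np.clip(x0, lower, upper)

        def residuals(theta):
            params = CombinationParams(
                dm1=float(np.exp(theta[0])), s1=float(theta[1]),
                dm2=float(np.exp(theta[2])), s2=float(theta[3]),
            )
            return np.array(
                [
                    f_obs
                    - combination_surface(d1, d2, params, self.model_name, self.convention)
                    for d1, d2, f_obs in cells
                ]
            )

        sol = least_squares(
            residuals, x0, bounds=(lower, upper),
            method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
        )
        params = CombinationParams(
            dm1=float(np.exp(sol.x[0])), s1=float(sol.x[1]),
            dm2=float(np.exp(sol.x[2])), s2=float(sol.x[3]),
        )
        return CombinationResults(
            model_name=self.model_name,
            params=params,
            rss=float(np.sum(sol.fun**2)),
            converged=bool(sol.success),
            source="joint",
            matrix=self.matrix,
            convention=self.convention,
            edge_fits=edge_fits,
        )


def fit_combination_joint(
    matrix: CombinationMatrix, model: str = "loewe", convention: str = "product"
) -> CombinationResults:
    """Joint 4-parameter fit (see :class:`CombinationModel`)."""
    return CombinationModel(matrix, model=model, convention=convention).fit()
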