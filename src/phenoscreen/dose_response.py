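"""Median-effect (Chou) dose-response fitting of well-score curves.

The response of the well score to dose D is modelled as

    score(D) = A * f(D) + B,      f(D) = 1 / (1 + (Dm / D)**s)

where B is the baseline score at zero dose, A the score amplitude at
saturating dose, Dm the median-effect concentration (f = 0.5) and s the
Hill sigmoidicity.  Fitting proceeds in the classical two-step way:
A and B from the curve extremes, (Dm, s) from the linearization

    log(1/f - 1) = s * log(Dm / D)

and finally a damped (Levenberg-Marquardt-type) nonlinear least-squares
refinement of all four parameters.

    res = MedianEffectModel(doses, scores).fit()
    res.params, res.summary()
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import fractional_effect

__all__ = [
    "MedianEffectModel",
    "MedianEffectResults",
    "estimate_amplitude_baseline",
    "normalize_effect",
    "linearized_median_effect",
    "fit_median_effect",
    "CLIP_DELTA",
]

#: Clip bound keeping log(1/f - 1) finite during linearization.
CLIP_DELTA = 0.01


def estimate_amplitude_baseline(scores) -> tuple[float, float]:
    """(A, B) from the response-curve extremes: B = min, A = max - min.

    A constant curve yields A = 0, which downstream code treats as a
    non-responsive drug.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores to estimate amplitude/baseline")
    b = float(scores.min())
    return float(scores.max()) - b, b


def normalize_effect(
    scores, A: float, B: float, delta: float = CLIP_DELTA
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional effect f = (score - B) / A.

    Returns ``(clipped, raw)``: the clipped values (to [delta,
    1 - delta]) feed the linearization; the raw values are kept for the
    nonlinear fit.
    """
    if A <= 0:
        raise ValueError(f"amplitude must be positive to normalize, got A={A}")
    raw = (np.asarray(scores, dtype=float) - B) / A
    return np.clip(raw, delta, 1.0 - delta), raw


def linearized_median_effect(doses, f) -> tuple[float, float]:
    """(Dm, s) from the least-squares line of log(1/f - 1) on log D.

    The line has slope -s and intercept s*log(Dm); points with f at or
    beyond the clip bounds carry no information and must be excluded by
    the caller.
    """
    doses = np.asarray(doses, dtype=float)
    f = np.asarray(f, dtype=float)
    usable = (f > 0) & (f < 1) & (doses > 0)
    if usable.sum() < 2:
        raise ValueError(
            f"need >= 2 doses with f strictly inside (0, 1); have {int(usable.sum())}"
        )
    x = np.log(doses[usable])
    y = np.log(1.0 / f[usable] - 1.0)
    slope, intercept = np.polyfit(x, y, 1)
    s = -slope
    if s <= 0:
        # non-increasing response; return a weak positive slope so the
        # nonlinear step still has a starting point
        s = 0.1
    dm = float(np.exp(intercept / s))
    return dm, float(s)


@dataclass
class MedianEffectResults:
    """Fitted median-effect parameters with diagnostics."""

    A: float
    B: float
    Dm: float
    s: float
    rss: float
    converged: bool
    n_points: int
    responsive: bool = True
    low_confidence: bool = False
    doses: np.ndarray = field(default_factory=lambda: np.array([]))
    scores: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def params(self) -> dict:
        return {"A": self.A, "B": self.B, "Dm": self.Dm, "s": self.s}

    def fraction(self, doses):
        """Model fractional effect f(D)."""
        return fractional_effect(doses, self.Dm, self.s)

    def predict(self, doses):
        """Model score A*f(D) + B."""
        return self.A * np.asarray(self.fraction(doses)) + self.B

    def curve_frame(self, n: int = 100) -> pd.DataFrame:
        """Fitted curve sampled log-uniformly over the data's dose range."""
        doses = np.geomspace(self.doses.min(), self.doses.max(), n)
        return pd.DataFrame({"dose": doses, "score": self.predict(doses)})

    def summary(self) -> str:
        lines = [
            "Median-effect fit: score = A/[1+(Dm/D)^s] + B",
            "=" * 46,
            f"A  (amplitude):   {self.A:.6g}",
            f"B  (baseline):    {self.B:.6g}",
            f"Dm (median dose): {self.Dm:.6g}",
            f"s  (Hill):        {self.s:.6g}",
            f"rss:              {self.rss:.6g}   n = {self.n_points}",
            f"converged:        {self.converged}",
        ]
        if not self.responsive:
            lines.append("flag: non-responsive (zero amplitude)")
        if self.low_confidence:
            lines.append("flag: low confidence (few points or narrow dose span)")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            **{k: float(v) for k, v in self.params.items()},
            "rss": float(self.rss),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
            "responsive": bool(self.responsive),
            "low_confidence": bool(self.low_confidence),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


class MedianEffectModel:
    """Median-effect dose-response model for one drug / condition.

    Parameters
    ----------
    doses, scores : array-like
        Positive doses with their well scores.  Repeated doses
        (duplicate wells) are averaged before fitting.
    fixed_amplitude : (A, B), optional
        Pin the amplitude and baseline (used when the responses are
        already fractional effects, A=1, B=0) so only (Dm, s) are free.
    delta : float
        Clip bound for the linearized initialization.
    """

    #: bounds relative to the data: A in [0, 10*range], B within one range
    #: of the minimum, Dm within a factor 100 of the dose span, s in [0.1, 10]
    S_BOUNDS = (0.1, 10.0)

    def __init__(self, doses, scores, fixed_amplitude=None, delta: float = CLIP_DELTA):
        doses = np.asarray(doses, dtype=float)
        scores = np.asarray(scores, dtype=float)
        if doses.shape != scores.shape:
            raise ValueError("doses and scores must have equal length")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        # duplicate averaging, then sort by dose
        frame = (
            pd.DataFrame({"dose": doses, "score": scores})
            .groupby("dose", as_index=False)
            .mean()
            .sort_values("dose")
        )
        self.doses = frame["dose"].to_numpy()
        self.scores = frame["score"].to_numpy()
        self.fixed_amplitude = fixed_amplitude
        self.delta = delta

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, dose: str = "dose", score: str = "score", **kwargs
    ) -> "MedianEffectModel":
        return cls(frame[dose].to_numpy(), frame[score].to_numpy(), **kwargs)

    def _initialize(self):
        if self.fixed_amplitude is not None:
            A0, B0 = self.fixed_amplitude
        else:
            A0, B0 = estimate_amplitude_baseline(self.scores)
        if A0 <= 0:
            return A0, B0, None, None
        f_clip, _ = normalize_effect(self.scores, A0, B0, self.delta)
        interior = (f_clip > self.delta) & (f_clip < 1.0 - self.delta)
        try:
            dm0, s0 = linearized_median_effect(self.doses[interior], f_clip[interior])
        except ValueError:
            dm0, s0 = float(np.exp(np.mean(np.log(self.doses)))), 1.0
        return A0, B0, dm0, s0

    def _residuals(self, theta):
        if self.fixed_amplitude is not None:
            dm, s = np.exp(theta[0]), theta[1]
            A, B = self.fixed_amplitude
        else:
            A, B, dm, s = theta[0], theta[1], np.exp(theta[2]), theta[3]
        f = 1.0 / (1.0 + (dm / self.doses) ** s)
        return self.scores - (A * f + B)

    def fit(self) -> MedianEffectResults:
        n = len(self.doses)
        if n < 2:
            raise ValueError("need at least 2 distinct doses")
        span_decades = np.log10(self.doses.max() / self.doses.min())
        low_confidence = n < 4 or span_decades < 2.0

        A0, B0, dm0, s0 = self._initialize()
        if dm0 is None:
            # flat curve: nothing to fit
            return MedianEffectResults(
                A=0.0, B=B0, Dm=float("nan"), s=float("nan"),
                rss=float(np.sum((self.scores - self.scores.mean()) ** 2)),
                converged=True, n_points=n, responsive=False,
                low_confidence=low_confidence,
                doses=self.doses, scores=self.scores,
            )

        log_dm_lo = np.log(self.doses.min() / 100.0)
        log_dm_hi = np.log(self.doses.max() * 100.0)
        dm0 = float(np.clip(dm0, np.exp(log_dm_lo), np.exp(log_dm_hi)))
        s0 = float(np.clip(s0, *self.S_BOUNDS))

        if self.fixed_amplitude is not None:
            x0 = np.array([np.log(dm0), s0])
            lower = [log_dm_lo, self.S_BOUNDS[0]]
            upper = [log_dm_hi, self.S_BOUNDS[1]]
        else:
            rng_ = float(self.scores.max() - self.scores.min()) or 1.0
            x0 = np.array([A0, B0, np.log(dm0), s0])
            lower = [0.0, self.scores.min() - rng_, log_dm_lo, self.S_BOUNDS[0]]
            upper = [10.0 * rng_, self.scores.min() + rng_, log_dm_hi, self.S_BOUNDS[1]]

        rss0 = float(np.sum(self._residuals(x0) ** 2))
        sol = least_squares(
            self._residuals, x0, bounds=(lower, upper),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        rss = float(np.sum(sol.fun**2))
        theta = sol.x
        converged = bool(sol.success)
        if rss > rss0:  # refinement must never be worse than its start
            theta, rss, converged = x0, rss0, False

        if self.fixed_amplitude is not None:
            A, B = self.fixed_amplitude
            dm, s = float(np.exp(theta[0])), float(theta[1])
        else:
            A, B, dm, s = float(theta[0]), float(theta[1]), float(np.exp(theta[2])), float(theta[3])
        return MedianEffectResults(
            A=A, B=B, Dm=dm, s=s, rss=rss, converged=converged,
            n_points=n, low_confidence=low_confidence,
            doses=self.doses, scores=self.scores,
        )


def fit_median_effect(doses, scores, fixed_amplitude=None) -> MedianEffectResults:
    """Fit the median-effect model (see :class:`MedianEffectModel`)."""
    return MedianEffectModel(doses, scores, fixed_amplitude=fixed_amplitude).fit()
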