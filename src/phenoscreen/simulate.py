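"""Ground-truthed synthetic inputs for the scoring and fitting pipeline.

Two levels of simulation are provided:

* **Feature level** — correlated multivariate per-cell attribute
  populations.  Controls are multivariate normal; treatment shifts a
  chosen attribute subset by ``max_shift * f(D)`` where
  ``f(D) = 1 / (1 + (Dm/D)**s)`` is the median-effect (Hill) fractional
  effect, the same dose law the fitting module assumes.
* **Image level** — rendered three-channel fields (nucleus / actin /
  tubulin) of convex cells with bright nuclear disks and line-segment
  fibers on a noisy background, with exact per-cell masks and attribute
  ground truth for segmentation tests.

All generators are deterministic for a fixed seed; per-well seeds are
derived by a stable CRC32 hash of (seed, plate, well) so duplicate wells
receive independent but reproducible draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .plates import PlateLayout, ROLE_CONTROL, ROLE_TREATED

__all__ = [
    "ATTRIBUTE_NAMES",
    "FeatureSimSpec",
    "ImageSimSpec",
    "GroundTruth",
    "fractional_effect",
    "derive_well_seed",
    "simulate_control_population",
    "simulate_treated_population",
    "simulate_dose_response_plate",
    "render_synthetic_field",
]

#: The per-cell attribute vector computed by the imaging module.
ATTRIBUTE_NAMES = (
    "Cell_Area",
    "Cell_LongAxis",
    "Nuc_Area",
    "Nuc_TotInt",
    "Nuc_AvgInt",
    "Act_TotInt-Bck",
    "Act_AvgInt-Bck",
    "Act_CelInt-Bck",
    "Act_Fib_CelInt-Bck",
    "Act_Fib_Len",
    "Tub_TotInt-Bck",
    "Tub_AvgInt-Bck",
    "Tub_CelInt-Bck",
    "Tub_Fib_Len",
    "Tub_Texture",
    "Nuc_Cyto_Ratio",
)

PROVENANCE_COLUMNS = ("plate", "well", "cell")


def fractional_effect(dose, dm: float, s: float):
    """Median-effect fractional effect ``f = 1 / (1 + (dm/dose)**s)``.

    ``f(0) = 0``, ``f(dm) = 0.5`` and ``f -> 1`` as dose grows; ``s``
    controls sigmoidicity.  Vectorised over ``dose``.
    """
    from scipy.special import expit

    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    if dm <= 0 or s <= 0:
        raise ValueError("dm and s must be positive")
    f = np.zeros(dose.shape)
    pos = dose > 0
    # logistic form of 1/(1 + (dm/D)^s), stable at extreme dose ratios
    f[pos] = expit(s * (np.log(dose[pos]) - np.log(dm)))
    return f if f.ndim else float(f)


def derive_well_seed(seed: int, plate: str, well) -> int:
    """Stable per-well seed below 2**31 from the experiment seed."""
    return zlib.crc32(f"{seed}:{plate}:{well}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class GroundTruth:
    """Known truth accompanying a simulated dataset.

    Only the fields relevant to the generator that produced it are
    populated: feature simulations carry the fractional effect and
    attribute shift; rendered fields carry label masks and the per-cell
    geometry/intensity table.
    """

    fraction: float | None = None
    fractions: dict | None = None          # (plate, well) -> f for plate sims
    effect_shift: pd.Series | None = None  # attribute -> shift at this dose
    cell_table: pd.DataFrame | None = None
    cell_labels: np.ndarray | None = None
    nucleus_labels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Feature-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSimSpec:
    """Specification of a correlated per-cell attribute population.

    The control covariance is given in factor form,
    ``loadings @ loadings.T + diag(noise_sd**2)``, which is positive
    semidefinite by construction and mimics correlated attribute
    families (cell size with total intensities, fiber content across
    channels).  ``effect`` maps attribute name to its saturating shift in
    control-SD units; the realised shift at dose D is ``effect *
    f(D)`` with the median-effect law ``(dm_true, s_true)``.
    """

    attribute_names: tuple[str, ...]
    control_mean: np.ndarray
    loadings: np.ndarray
    noise_sd: np.ndarray
    effect: Mapping[str, float]
    dm_true: float = 1e-6       # molar; 1 uM is a typical screening AC50 scale
    s_true: float = 1.5
    well_noise_sd: float = 0.05  # lognormal sd of multiplicative well-level noise

    def __post_init__(self) -> None:
        n = len(self.attribute_names)
        if self.control_mean.shape != (n,):
            raise ValueError("control_mean length must match attribute_names")
        if self.loadings.shape[0] != n or self.noise_sd.shape != (n,):
            raise ValueError("loadings/noise_sd shapes must match attribute_names")
        unknown = set(self.effect) - set(self.attribute_names)
        if unknown:
            raise ValueError(f"effect names not in attribute set: {sorted(unknown)}")
        if self.dm_true <= 0 or self.s_true <= 0:
            raise ValueError("dm_true and s_true must be positive")

    @property
    def covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.noise_sd**2)

    @property
    def attribute_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def shift_vector(self, f: float) -> np.ndarray:
        """Mean shift (attribute units) at fractional effect ``f``."""
        shift = np.zeros(len(self.attribute_names))
        sd = self.attribute_sd
        for name, units in self.effect.items():
            i = self.attribute_names.index(name)
            shift[i] = units * sd[i] * f
        return shift

    @classmethod
    def from_covariance(
        cls,
        attribute_names,
        control_mean,
        covariance,
        effect: Mapping[str, float],
        **kwargs,
    ) -> "FeatureSimSpec":
        """Build from an explicit covariance matrix (must be symmetric PSD)."""
        cov = np.asarray(covariance, dtype=float)
        if cov.shape != (len(attribute_names),) * 2 or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric square matrix")
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-10 * max(w.max(), 1.0):
            raise ValueError("covariance is not positive semidefinite")
        loadings = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        return cls(
            attribute_names=tuple(attribute_names),
            control_mean=np.asarray(control_mean, dtype=float),
            loadings=loadings,
            noise_sd=np.zeros(len(attribute_names)),
            effect=dict(effect),
            **kwargs,
        )

    @classmethod
    def default(cls) -> "FeatureSimSpec":
        """A 16-attribute population emulating a tubulin-depolymerising drug.

        Two latent factors induce the familiar correlation families —
        cell size with total stain content, and fiber content across the
        actin and tubulin channels.  Treatment depletes the tubulin
        attributes (fiber length, intensities) and swells nuclear
        content, the phenotype of a microtubule poison.
        """
        names = ATTRIBUTE_NAMES
        n = len(names)
        mean = np.array(
            [900.0, 45.0, 180.0, 5.4e5, 3000.0, 2.4e5, 260.0, 2.1e5, 9.0e4,
             140.0, 2.2e5, 240.0, 1.9e5, 160.0, 0.35, 3.2],
        )
        # factor 1: size <-> total intensities; factor 2: fiber content
        size_load = np.array(
            [120.0, 4.0, 20.0, 6e4, 0.0, 3e4, 0.0, 2.5e4, 8e3, 6.0,
             2.8e4, 0.0, 2.3e4, 7.0, 0.0, 0.0]
        )
        fiber_load = np.array(
            [0.0, 0.0, 0.0, 0.0, 0.0, 6e3, 8.0, 5e3, 1.2e4, 18.0,
             5e3, 7.0, 4e3, 20.0, 0.03, 0.0]
        )
        loadings = np.column_stack([size_load, fiber_load])
        noise_sd = np.array(
            [80.0, 3.0, 18.0, 5e4, 280.0, 2e4, 24.0, 1.8e4, 9e3, 14.0,
             1.9e4, 22.0, 1.6e4, 16.0, 0.04, 0.3]
        )
        effect = {
            "Tub_Fib_Len": -4.0,
            "Tub_TotInt-Bck": -3.0,
            "Tub_CelInt-Bck": -2.5,
            "Tub_Texture": -2.0,
            "Nuc_TotInt": 2.0,
        }
        return cls(
            attribute_names=names,
            control_mean=mean,
            loadings=loadings,
            noise_sd=noise_sd,
            effect=effect,
        )


def _draw_population(
    spec: FeatureSimSpec, n: int, rng: np.random.Generator, mean_shift: np.ndarray
) -> np.ndarray:
    k = spec.loadings.shape[1]
    z = rng.standard_normal((n, k))
    eps = rng.standard_normal((n, len(spec.attribute_names)))
    return spec.control_mean + mean_shift + z @ spec.loadings.T + eps * spec.noise_sd


def _records_frame(spec, values, plate, well) -> pd.DataFrame:
    frame = pd.DataFrame(values, columns=list(spec.attribute_names))
    frame.insert(0, "plate", plate)
    frame.insert(1, "well", well)
    frame.insert(2, "cell", np.arange(1, len(frame) + 1))
    return frame


def simulate_control_population(
    spec: FeatureSimSpec, n: int, seed: int, plate: str = "sim", well: str = "A01"
) -> pd.DataFrame:
    """Draw ``n`` untreated cells from the control distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = _draw_population(spec, n, rng, np.zeros(len(spec.attribute_names)))
    return _records_frame(spec, values, plate, well)


def simulate_treated_population(
    spec: FeatureSimSpec,
    dose: float,
    n: int,
    seed: int,
    plate: str = "sim",
    well: str = "A01",
    shift_scale: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw ``n`` treated cells at ``dose``.

    Effect attributes are shifted by ``max_shift * f(dose)`` (times the
    optional ``shift_scale``, used for well-level noise); all other
    attributes and the covariance are unchanged.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    f = fractional_effect(dose, spec.dm_true, spec.s_true)
    shift = spec.shift_vector(f) * shift_scale
    rng = np.random.default_rng(seed)
    values = _draw_population(spec, n, rng, shift)
    truth = GroundTruth(
        fraction=f,
        effect_shift=pd.Series(shift, index=list(spec.attribute_names)),
    )
    return _records_frame(spec, values, plate, well), truth


def _combined_fraction(spec: FeatureSimSpec, concentrations) -> float:
    """Independent-action combination of per-dose fractional effects."""
    f = 1.0
    for c in concentrations:
        f *= 1.0 - fractional_effect(c, spec.dm_true, spec.s_true)
    return 1.0 - f


def simulate_dose_response_plate(
    spec: FeatureSimSpec,
    layout: PlateLayout,
    cells_per_well: int,
    seed: int,
    well_noise: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-cell records for every non-empty well of a layout.

    Control wells draw from the control distribution; treated wells from
    the shifted distribution at their layout dose (multi-drug wells
    combine doses by independent action).  Per-well seeds derive from
    ``(seed, plate, well)``, so duplicates get independent draws.  With
    ``well_noise=True`` each treated well's shift is scaled by a
    lognormal factor of sd ``spec.well_noise_sd``.
    """
    frames = []
    fractions: dict = {}
    for well in sorted(layout.wells):
        a = layout.wells[well]
        wseed = derive_well_seed(seed, layout.plate_id, well)
        if a.role == ROLE_CONTROL:
            frames.append(
                simulate_control_population(
                    spec, cells_per_well, wseed, plate=layout.plate_id, well=str(well)
                )
            )
            fractions[(layout.plate_id, str(well))] = 0.0
        elif a.role == ROLE_TREATED:
            if len(a.concentrations) == 1:
                dose = a.concentrations[0]
                f = fractional_effect(dose, spec.dm_true, spec.s_true)
            else:
                f = _combined_fraction(spec, a.concentrations)
                # map the combined fraction back to an equivalent dose
                f = min(f, 1.0 - 1e-12)
                dose = spec.dm_true * (f / (1.0 - f)) ** (1.0 / spec.s_true) if f > 0 else 0.0
            scale = 1.0
            if well_noise and spec.well_noise_sd > 0:
                noise_rng = np.random.default_rng(wseed + 1)
                scale = float(
                    np.exp(noise_rng.normal(0.0, spec.well_noise_sd))
                )
            frame, _ = simulate_treated_population(
                spec, dose, cells_per_well, wseed,
                plate=layout.plate_id, well=str(well), shift_scale=scale,
            )
            frames.append(frame)
            fractions[(layout.plate_id, str(well))] = f
    records = pd.concat(frames, ignore_index=True)
    return records, GroundTruth(fractions=fractions)


# ---------------------------------------------------------------------------
# Image-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimSpec:
    """Rendering parameters for a synthetic three-channel field.

    Cells are ellipses (eccentricity <= ``max_eccentricity``) with a
    concentric nuclear disk in the nucleus channel and random
    line-segment fibers in the cytoplasmic channels; intensities are in
    arbitrary camera units on a flat background with Gaussian noise.
    """

    field_size: tuple[int, int] = (512, 512)
    n_cells: int = 20
    cell_radius_range: tuple[float, float] = (14.0, 24.0)
    nucleus_radius_fraction: float = 0.45
    fiber_count_range: tuple[int, int] = (2, 5)
    channel_intensities: Mapping[str, float] = field(
        default_factory=lambda: {"nucleus": 3000.0, "actin": 900.0, "tubulin": 900.0}
    )
    fiber_gain: float = 2.0          # fiber brightness relative to the cell body
    background_level: float = 100.0
    noise_sd: float = 10.0
    max_eccentricity: float = 0.8
    margin: int = 3                  # empty pixels enforced between cells

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.channel_intensities.values()):
            raise ValueError("channel intensities must be non-negative")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be non-negative")
        if not (0 < self.nucleus_radius_fraction < 1):
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")


def _ellipse_mask(shape, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _segment_in_ellipse(rng, cy, cx, a, b, theta, shrink=0.92):
    """A random chord of the ellipse, shrunk so it stays interior."""
    phi = rng.uniform(0, np.pi)
    # random interior anchor in ellipse coordinates
    r = np.sqrt(rng.uniform(0, 0.5))
    alpha = rng.uniform(0, 2 * np.pi)
    pu, pv = a * r * np.cos(alpha), b * r * np.sin(alpha)
    du = np.cos(phi - theta)
    dv = np.sin(phi - theta)
    # solve ((pu + t du)/a)^2 + ((pv + t dv)/b)^2 = 1 for t
    qa = (du / a) ** 2 + (dv / b) ** 2
    qb = 2 * (pu * du / a**2 + pv * dv / b**2)
    qc = (pu / a) ** 2 + (pv / b) ** 2 - 1.0
    disc = qb**2 - 4 * qa * qc
    t1 = (-qb - np.sqrt(disc)) / (2 * qa) * shrink
    t2 = (-qb + np.sqrt(disc)) / (2 * qa) * shrink
    ends = []
    for t in (t1, t2):
        u, v = pu + t * du, pv + t * dv
        x = cx + u * np.cos(theta) - v * np.sin(theta)
        y = cy + u * np.sin(theta) + v * np.cos(theta)
        ends.append((y, x))
    return ends


def render_synthetic_field(
    spec: ImageSimSpec, seed: int
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render one field; returns channel rasters and exact ground truth.

    Ground truth carries the cell and nucleus label masks (disjoint, one
    label per cell) and a per-cell table of true area, long axis,
    per-channel signal sums and fiber lengths.
    """
    from skimage.draw import line as draw_line

    rng = np.random.default_rng(seed)
    h, w = spec.field_size
    channels = {
        name: np.full((h, w), spec.background_level, dtype=float)
        for name in ("nucleus", "actin", "tubulin")
    }
    cell_labels = np.zeros((h, w), dtype=int)
    nucleus_labels = np.zeros((h, w), dtype=int)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, outer radius)
    rows = []
    max_tries = 300 * max(spec.n_cells, 1)
    tries = 0
    label = 0
    while label < spec.n_cells:
        if tries > max_tries:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{h}x{w} after {max_tries} tries"
            )
        tries += 1
        a = rng.uniform(*spec.cell_radius_range)
        ecc = rng.uniform(0, spec.max_eccentricity)
        b = a * np.sqrt(1 - ecc**2)
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a + 1, h - a - 1)
        cx = rng.uniform(a + 1, w - a - 1)
        if any(
            np.hypot(cy - py, cx - px) < a + pr + spec.margin for py, px, pr in placed
        ):
            continue
        label += 1
        placed.append((cy, cx, a))
        body = _ellipse_mask((h, w), cy, cx, a, b, theta)
        nuc_r = spec.nucleus_radius_fraction * b
        nucleus = _ellipse_mask((h, w), cy, cx, nuc_r, nuc_r, 0.0)
        cell_labels[body] = label
        nucleus_labels[nucleus] = label

        channels["nucleus"][nucleus] += spec.channel_intensities["nucleus"]
        fiber_rows = {}
        for chan in ("actin", "tubulin"):
            amp = spec.channel_intensities[chan]
            channels[chan][body] += amp
            n_fib = rng.integers(spec.fiber_count_range[0], spec.fiber_count_range[1] + 1)
            total_len = 0.0
            for _ in range(n_fib):
                (y0, x0), (y1, x1) = _segment_in_ellipse(rng, cy, cx, a, b, theta)
                rr, cc = draw_line(
                    int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
                )
                keep = body[rr, cc]
                rr, cc = rr[keep], cc[keep]
                channels[chan][rr, cc] += amp * spec.fiber_gain
                total_len += np.hypot(y1 - y0, x1 - x0)
            fiber_rows[chan] = (n_fib, total_len)

        rows.append(
            {
                "cell": label,
                "center_y": cy,
                "center_x": cx,
                "area": int(body.sum()),
                "long_axis": 2 * a,
                "nucleus_area": int(nucleus.sum()),
                "actin_fiber_count": fiber_rows["actin"][0],
                "actin_fiber_length": fiber_rows["actin"][1],
                "tubulin_fiber_count": fiber_rows["tubulin"][0],
                "tubulin_fiber_length": fiber_rows["tubulin"][1],
            }
        )

    # exact noiseless signal sums per cell and channel (background excluded)
    for row in rows:
        cell = cell_labels == row["cell"]
        for chan in ("nucleus", "actin", "tubulin"):
            row[f"{chan}_signal"] = float(
                (channels[chan][cell] - spec.background_level).sum()
            )

    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0, spec.noise_sd, size=(h, w)), 0, None
            )

    truth = GroundTruth(
        cell_table=pd.DataFrame(rows),
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
    )
    return channels, truth
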