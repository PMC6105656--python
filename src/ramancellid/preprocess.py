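"""Spectral conditioning chain: despiking, baseline removal, smoothing,
normalization, derivatives, and ordered recipes over whole datasets.

The chain mirrors standard confocal Raman practice: cosmic-ray removal,
iterative order-5 polynomial baseline subtraction, Savitzky-Golay
smoothing (width 11, order 3), and either area or vector normalization.
For discriminant analysis a joint Savitzky-Golay second-derivative step
(which smooths and differentiates in one pass) plus mean centering is
used instead of plain smoothing.

Derivatives are taken with respect to the wavenumber coordinate (per
cm^-1), not per grid index, so results are invariant to the grid density.
Edges are handled by polynomial extrapolation of the edge window rather
than reflection padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectral_data import SpectralDataError, SpectralDataset, Spectrum

__all__ = [
    "PreprocessError",
    "Step",
    "PreprocessRecipe",
    "despike",
    "subtract_baseline",
    "savgol_smooth",
    "normalize_area",
    "normalize_vector",
    "second_derivative",
    "apply_recipe",
    "PLSDA_RECIPE",
    "PCA_RECIPE",
]


class PreprocessError(SpectralDataError):
    pass


_STEP_NAMES = {
    "despike", "baseline", "savgol", "area_norm", "vector_norm",
    "derivative", "mean_center",
}


@dataclass(frozen=True)
class Step:
    """One named preprocessing step with its parameters."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _STEP_NAMES:
            raise PreprocessError(f"unknown preprocessing step {self.name!r}")
        if self.name in ("savgol", "derivative"):
            width = self.params.get("width", 11)
            polyorder = self.params.get("polyorder", 3)
            if width % 2 == 0 or width <= polyorder:
                raise PreprocessError(
                    f"{self.name}: width must be odd and > polyorder "
                    f"(got width={width}, polyorder={polyorder})"
                )


@dataclass(frozen=True)
class PreprocessRecipe:
    """Ordered step list; applied row-wise except mean_center (dataset-level)."""

    steps: tuple[Step, ...] = ()

    @classmethod
    def from_config(cls, items: list) -> "PreprocessRecipe":
        """Build from config entries: strings or one-key {name: params} maps."""
        steps = []
        for item in items:
            if isinstance(item, str):
                steps.append(Step(item))
            elif isinstance(item, dict) and len(item) == 1:
                ((name, params),) = item.items()
                steps.append(Step(name, dict(params or {})))
            else:
                raise PreprocessError(f"cannot parse recipe entry {item!r}")
        return cls(tuple(steps))

    def to_config(self) -> list:
        return [
            s.name if not s.params else {s.name: dict(s.params)} for s in self.steps
        ]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.steps)


#: Recipe used ahead of PLS-DA: vector normalization, joint SG second
#: derivative with smoothing, then mean centering over the dataset.
PLSDA_RECIPE = PreprocessRecipe(
    (
        Step("vector_norm"),
        Step("derivative", {"order": 2, "width": 15, "polyorder": 3}),
        Step("mean_center"),
    )
)

#: Recipe used ahead of PCA: normalization to unit area.
PCA_RECIPE = PreprocessRecipe((Step("area_norm"),))


# ---------------------------------------------------------------------------
# Single-spectrum operations (array kernels + Spectrum wrappers)
# ---------------------------------------------------------------------------

def _runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Consecutive runs [start, stop] (inclusive) in a sorted index array."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [indices.size - 1]))
    return [(int(indices[a]), int(indices[b])) for a, b in zip(starts, stops)]


def _despike_row(
    y: np.ndarray, z_threshold: float, max_width: int
) -> tuple[np.ndarray, np.ndarray]:
    n = y.size
    d2 = np.diff(y, n=2)
    med = np.median(d2)
    mad = np.median(np.abs(d2 - med))
    if mad == 0:
        return y.copy(), np.array([], dtype=int)
    z = 0.6745 * (d2 - med) / mad
    hits = np.flatnonzero(np.abs(z) > z_threshold)
    sigma_est = mad / 0.6745 / np.sqrt(6.0)  # noise sd implied by d2 spread
    flagged = np.zeros(n, dtype=bool)
    for i0, i1 in _runs(hits):
        # a width-w spike perturbs at most w + 2 consecutive second
        # differences; longer runs are band curvature, not spikes
        if i1 - i0 + 1 > max_width + 2:
            continue
        w0, w1 = i0, min(i1 + 2, n - 1)  # d2 index i touches samples i..i+2
        left, right = w0 - 1, w1 + 1
        window = np.arange(w0, w1 + 1)
        # anchor on samples outside the window; at the spectrum ends only
        # one anchor exists and the local level is taken from it alone
        if left < 0:
            local = np.full(window.size, y[right]) if right < n else np.zeros(window.size)
        elif right > n - 1:
            local = np.full(window.size, y[left])
        else:
            local = np.interp(window, [left, right], [y[left], y[right]])
        dev = np.abs(y[window] - local)
        keep = (dev >= 0.25 * dev.max()) & (dev > 3.0 * sigma_est)
        order = np.argsort(dev)[::-1]
        chosen = [j for j in order if keep[j]][:max_width]
        if not chosen and dev.max() > 0:
            chosen = [int(order[0])]
        flagged[window[chosen]] = True
    out = y.copy()
    idx = np.flatnonzero(flagged)
    if idx.size:
        good = np.flatnonzero(~flagged)
        if good.size:
            out[idx] = np.interp(idx, good, y[good])
    return out, idx


def despike(
    s: Spectrum, z_threshold: float = 8.0, max_width: int = 3
) -> tuple[Spectrum, np.ndarray]:
    """Remove cosmic-ray spikes via a modified z-score on second differences.

    Points whose second difference has |modified z| above ``z_threshold``,
    in runs of at most ``max_width`` points, are replaced by linear
    interpolation of the flanking unflagged points (nearest-neighbour
    extrapolation at the spectrum ends).  All other points are returned
    bitwise unchanged.
    """
    if z_threshold <= 0:
        raise PreprocessError("z_threshold must be positive")
    if max_width not in (1, 2, 3):
        raise PreprocessError("max_width must be 1, 2 or 3")
    if len(s.axis) < 5:
        raise PreprocessError("despike needs at least 5 points")
    out, idx = _despike_row(s.intensities, z_threshold, max_width)
    return s.replace_intensities(out), idx


def _baseline_row(
    y: np.ndarray, design: np.ndarray, pinv: np.ndarray, max_iter: int, tol: float
) -> np.ndarray:
    work = y.copy()
    scale = float(np.max(np.abs(y))) or 1.0
    fit = design @ (pinv @ work)
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = design @ (pinv @ work)
        if np.max(np.abs(new_fit - fit)) < tol * scale:
            fit = new_fit
            break
        fit = new_fit
    return fit


def _poly_design(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    # scaled Vandermonde keeps order-5 fits well conditioned
    u = (x - x.mean()) / (np.ptp(x) / 2.0 if np.ptp(x) > 0 else 1.0)
    design = np.vander(u, order + 1, increasing=True)
    return design, np.linalg.pinv(design)


def subtract_baseline(
    s: Spectrum, order: int = 5, max_iter: int = 100, tol: float = 1e-6
) -> tuple[Spectrum, np.ndarray]:
    """Iterative clipped-polynomial (ModPoly-style) baseline removal.

    Repeatedly fits an order-``order`` polynomial and clips the working
    signal to the pointwise minimum of signal and fit, until the fit moves
    by less than ``tol`` (relative to the signal range) or ``max_iter`` is
    reached.  Returns the corrected spectrum and the baseline itself, so
    that corrected + baseline reconstructs the input bitwise.
    """
    if order < 0:
        raise PreprocessError("order must be >= 0")
    if len(s.axis) <= order + 1:
        raise PreprocessError(
            f"axis length {len(s.axis)} too short for order-{order} baseline"
        )
    design, pinv = _poly_design(s.axis.values, order)
    baseline = _baseline_row(s.intensities, design, pinv, max_iter, tol)
    return s.replace_intensities(s.intensities - baseline), baseline


def savgol_smooth(s: Spectrum, width: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; edge windows use polynomial extrapolation."""
    _check_savgol(s, width, polyorder)
    return s.replace_intensities(
        savgol_filter(s.intensities, width, polyorder, mode="interp")
    )


def second_derivative(s: Spectrum, width: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative per cm^-1 (grid-step aware)."""
    return _derivative(s, 2, width, polyorder)


def _derivative(s: Spectrum, order: int, width: int, polyorder: int) -> Spectrum:
    _check_savgol(s, width, polyorder)
    if order > polyorder:
        raise PreprocessError("derivative order must be <= polyorder")
    return s.replace_intensities(
        savgol_filter(
            s.intensities, width, polyorder, deriv=order,
            delta=s.axis.step, mode="interp",
        )
    )


def _check_savgol(s: Spectrum, width: int, polyorder: int) -> None:
    if width % 2 == 0:
        raise PreprocessError(f"width must be odd, got {width}")
    if width <= polyorder:
        raise PreprocessError("width must exceed polyorder")
    if len(s.axis) < width:
        raise PreprocessError(
            f"spectrum ({len(s.axis)} points) shorter than window ({width})"
        )


def normalize_area(s: Spectrum) -> Spectrum:
    """Scale so the trapezoidal area of |intensities| over the axis is 1."""
    area = float(np.trapezoid(np.abs(s.intensities), s.axis.values))
    if area <= 0:
        raise PreprocessError("cannot area-normalize a zero-area spectrum")
    return s.replace_intensities(s.intensities / area)


def normalize_vector(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0:
        raise PreprocessError("cannot vector-normalize a zero spectrum")
    return s.replace_intensities(s.intensities / norm)


# ---------------------------------------------------------------------------
# Dataset-level recipe application
# ---------------------------------------------------------------------------

def _apply_rowwise(d: SpectralDataset, step: Step) -> SpectralDataset:
    rows = []
    for i in range(d.n_spectra):
        s = Spectrum(d.axis, d.matrix[i])
        if step.name == "despike":
            s, _ = despike(s, **step.params)
        elif step.name == "baseline":
            s, _ = subtract_baseline(s, **step.params)
        elif step.name == "savgol":
            s = savgol_smooth(s, **step.params)
        elif step.name == "area_norm":
            s = normalize_area(s)
        elif step.name == "vector_norm":
            s = normalize_vector(s)
        elif step.name == "derivative":
            p = dict(step.params)
            order = p.pop("order", 2)
            s = _derivative(s, order, p.get("width", 11), p.get("polyorder", 3))
        rows.append(s.intensities)
    matrix = np.vstack(rows) if rows else d.matrix
    return d.with_matrix(matrix)


def apply_recipe(d: SpectralDataset, r: PreprocessRecipe) -> SpectralDataset:
    """Apply an ordered recipe to every spectrum of a dataset.

    All steps act row-wise except ``mean_center``, which subtracts the
    column means over the whole dataset and therefore requires more than
    one spectrum.
    """
    out = d
    for step in r.steps:
        if step.name == "mean_center":
            if out.n_spectra < 2:
                raise PreprocessError("mean_center needs a multi-spectrum dataset")
            out = out.with_matrix(out.matrix - out.matrix.mean(axis=0))
        else:
            out = _apply_rowwise(out, step)
    return out


def rowwise_recipe(r: PreprocessRecipe) -> PreprocessRecipe:
    """The recipe with dataset-level centering removed (used by model fits,
    which center against the calibration mean instead)."""
    return PreprocessRecipe(tuple(s for s in r.steps if s.name != "mean_center"))
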