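"""Synthetic live-cell Raman spectrum generator.

Emulates the statistical structure of 785 nm line-scan acquisitions from
five human lung cell cultures (the A549 carcinoma and MRC5 fibroblast
immortalized lines plus three bronchial-epithelial primary cultures):

* a shared set of 19 fingerprint bands assigned to lipids, proteins,
  nucleic acids and carbohydrates, with class differences expressed purely
  as amplitude offsets on those bands;
* a smooth order-5 polynomial fluorescence/substrate baseline, optionally
  with a broad quartz hump near 1450 cm^-1;
* multiplicative lognormal between-cell and within-cell amplitude
  variability;
* shot-like noise (Gaussian, variance proportional to signal plus a dark
  floor) and sparse cosmic-ray spikes 1-3 grid points wide.

Every generator is a pure function of its configuration, including the
seed, so downstream stages can be tested against stored ground truth.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectral_data import (
    HyperspectralMap,
    SpectralDataset,
    Spectrum,
    SpectrumMeta,
    WavenumberAxis,
)

__all__ = [
    "BandDefinition",
    "ClassTemplate",
    "SimulationConfig",
    "GroundTruth",
    "band_profile",
    "default_templates",
    "discriminatory_centers",
    "render_clean_spectrum",
    "simulate_dataset",
    "simulate_map",
    "default_cell_layout",
    "simulate_photodamage_series",
]

#: Class labels of the five simulated cultures.
CLASS_LABELS = ["A549", "MRC5", "ATCC", "LONZA", "PAP243"]

#: Fingerprint band centers (cm^-1) grouped by biochemical assignment.
BAND_ASSIGNMENTS: dict[str, tuple[float, ...]] = {
    "lipid": (718.0, 1264.0, 1301.0, 1440.0),
    "protein": (641.0, 1003.0, 1166.0, 1239.0, 1580.0, 1658.0, 1674.0),
    "nucleic_acid": (784.0, 828.0, 1316.0, 1458.0),
    "carbohydrate": (881.0, 944.0, 1043.0, 1085.0),
}

# Relative peak amplitudes of the shared template (arbitrary units; the
# 1003 cm^-1 phenylalanine ring-breathing mode is the reference at 1.0).
_BASE_AMPLITUDES: dict[float, float] = {
    641.0: 0.25, 718.0: 0.30, 784.0: 0.45, 828.0: 0.22, 881.0: 0.22,
    944.0: 0.25, 1003.0: 1.00, 1043.0: 0.30, 1085.0: 0.40, 1166.0: 0.25,
    1239.0: 0.45, 1264.0: 0.40, 1301.0: 0.50, 1316.0: 0.35, 1440.0: 0.90,
    1458.0: 0.40, 1580.0: 0.30, 1658.0: 0.85, 1674.0: 0.40,
}

# Per-class multiplicative offsets on assignment groups (and single bands).
# A549 carries elevated lipid bands (droplet-rich carcinoma); MRC5 carries
# an elevated 784 cm^-1 DNA band; the three epithelial cultures differ
# pairwise by smaller protein/carbohydrate offsets.
_CLASS_EFFECTS: dict[str, dict[str, float]] = {
    "A549": {"lipid": 1.40},
    "MRC5": {"784": 1.50, "nucleic_acid": 1.18, "lipid": 0.88},
    "ATCC": {"protein": 1.12, "carbohydrate": 0.93},
    "LONZA": {"protein": 0.97, "carbohydrate": 1.12},
    "PAP243": {"protein": 0.83, "carbohydrate": 1.18, "nucleic_acid": 1.24},
}

#: O-H stretch bands added only when the axis reaches beyond 2700 cm^-1.
_WATER_BANDS = ((3250.0, 180.0, 0.6), (3430.0, 160.0, 0.9))

# Default baseline polynomial (coefficients in the unit coordinate
# u = (nu - 600)/1200, low order first): decreasing fluorescence tail
# with positive curvature, amplitude a few times the strongest band.
_BASELINE_COEFFS = (3.0, -3.2, 1.6, -0.3, 0.0, 0.1)


@dataclass(frozen=True)
class BandDefinition:
    """One vibrational band: center/width/amplitude plus an assignment tag."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"
    assignment: str = "background"

    def __post_init__(self) -> None:
        if self.fwhm < 3.0:
            raise ValueError(
                f"fwhm {self.fwhm} below the 3 cm^-1 instrument resolution floor"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class ClassTemplate:
    """Noise-free forward model of one cell class.

    All class templates share the same band centers; classes differ only
    in band amplitudes (the planted effect sizes).
    """

    class_label: str
    bands: tuple[BandDefinition, ...]
    baseline_coeffs: tuple[float, ...] = _BASELINE_COEFFS
    water_bands: tuple[BandDefinition, ...] = ()

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.bands])

    def band_index(self, center: float, tol: float = 0.5) -> int:
        idx = np.flatnonzero(np.abs(self.centers - center) <= tol)
        if idx.size == 0:
            raise KeyError(f"no band at {center} cm^-1")
        return int(idx[0])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the line-scan simulation.

    Defaults reproduce the acquisition design: five classes, 30 cells per
    class, 10-point line scans (1500 spectra total) on a 600-1800 cm^-1
    fingerprint grid at 1 cm^-1 spacing.
    """

    axis_lo: float = 600.0
    axis_hi: float = 1800.0
    axis_step: float = 1.0
    n_cells_per_class: int = 30
    n_points_per_cell: int = 10
    cell_amplitude_cv: float = 0.10
    point_amplitude_cv: float = 0.06
    baseline_cv: float = 0.10
    noise_model: str = "shot"
    noise_scale: float = 0.01
    dark_floor: float = 0.5
    cosmic_ray_rate: float = 0.1
    cosmic_ray_amplitude_range: tuple[float, float] = (10.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cell_amplitude_cv", "point_amplitude_cv", "baseline_cv",
            "noise_scale", "cosmic_ray_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_model not in ("shot", "additive"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_cells_per_class < 1 or self.n_points_per_cell < 1:
            raise ValueError("need at least one cell and one point per cell")

    def make_axis(self) -> WavenumberAxis:
        return WavenumberAxis.regular(self.axis_lo, self.axis_hi, self.axis_step)


@dataclass
class GroundTruth:
    """What the simulator planted, one record per generated spectrum/pixel."""

    labels: pd.DataFrame | None = None
    band_centers: np.ndarray | None = None
    band_multipliers: np.ndarray | None = None
    clean_matrix: np.ndarray | None = None
    spike_positions: list[np.ndarray] = field(default_factory=list)
    region_labels: np.ndarray | None = None
    planted_slopes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def band_profile(axis: np.ndarray, band: BandDefinition, amplitude: float | None = None) -> np.ndarray:
    """Closed-form band profile with unit-amplitude peak scaling.

    Lorentzian: A * g^2 / ((nu - c)^2 + g^2), g = FWHM/2.
    Gaussian:   A * exp(-4 ln2 (nu - c)^2 / FWHM^2).
    """
    a = band.amplitude if amplitude is None else amplitude
    d = axis - band.center
    if band.shape == "lorentzian":
        g = band.fwhm / 2.0
        return a * g * g / (d * d + g * g)
    return a * np.exp(-4.0 * math.log(2.0) * d * d / (band.fwhm * band.fwhm))


def _baseline(axis: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    u = (axis - 600.0) / 1200.0
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


def default_templates(fwhm: float = 12.0, shape: str = "lorentzian") -> list[ClassTemplate]:
    """Five class templates sharing 19 fingerprint band centers.

    Classes differ only in amplitude: the carcinoma-like template has
    elevated lipid bands, the fibroblast-like one an elevated DNA band at
    784 cm^-1, and the three epithelial templates differ pairwise by
    smaller protein/carbohydrate offsets.
    """
    templates = []
    water = tuple(
        BandDefinition(c, w, a, "gaussian", "water") for c, w, a in _WATER_BANDS
    )
    for label in CLASS_LABELS:
        effects = _CLASS_EFFECTS[label]
        bands = []
        for assignment, centers in BAND_ASSIGNMENTS.items():
            for c in centers:
                mult = effects.get(f"{c:g}", effects.get(assignment, 1.0))
                bands.append(
                    BandDefinition(c, fwhm, _BASE_AMPLITUDES[c] * mult, shape, assignment)
                )
        bands.sort(key=lambda b: b.center)
        templates.append(ClassTemplate(label, tuple(bands), water_bands=water))
    return templates


def discriminatory_centers(templates: list[ClassTemplate]) -> np.ndarray:
    """Band centers whose amplitude differs between at least two classes."""
    centers = templates[0].centers
    amps = np.vstack([t.amplitudes for t in templates])
    varying = np.ptp(amps, axis=0) > 1e-12
    return centers[varying]


def render_clean_spectrum(
    t: ClassTemplate,
    axis: WavenumberAxis,
    band_scale: np.ndarray | None = None,
    include_baseline: bool = True,
    baseline_scale: float = 1.0,
) -> Spectrum:
    """Deterministic noise-free spectrum: sum of bands + polynomial baseline.

    ``band_scale`` multiplies each band's template amplitude (one entry per
    band).  Water bands are added only where the axis reaches past
    2700 cm^-1.
    """
    v = axis.values
    if band_scale is None:
        band_scale = np.ones(len(t.bands))
    band_scale = np.asarray(band_scale, dtype=float)
    if band_scale.shape != (len(t.bands),):
        raise ValueError(
            f"band_scale has shape {band_scale.shape}, expected ({len(t.bands)},)"
        )
    if np.any(band_scale < 0):
        raise ValueError("band_scale entries must be >= 0")
    y = np.zeros_like(v)
    for band, s in zip(t.bands, band_scale):
        y += band_profile(v, band, band.amplitude * s)
    if v[-1] > 2700.0:
        for band in t.water_bands:
            y += band_profile(v, band)
    if include_baseline:
        y = y + baseline_scale * _baseline(v, t.baseline_coeffs)
    return Spectrum(axis, y, SpectrumMeta(cell_line=t.class_label))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _noise_sigma(clean: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.noise_model == "shot":
        return cfg.noise_scale * np.sqrt(np.clip(clean, 0.0, None) + cfg.dark_floor)
    return np.full_like(clean, cfg.noise_scale)


def _inject_cosmic_rays(
    y: np.ndarray, sigma: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add Poisson(rate) positive spike events, 1-3 points wide; returns positions."""
    n_events = rng.poisson(cfg.cosmic_ray_rate)
    hit: list[int] = []
    lo, hi = cfg.cosmic_ray_amplitude_range
    for _ in range(n_events):
        pos = int(rng.integers(0, y.size))
        width = int(rng.integers(1, 4))
        amp = rng.uniform(lo, hi)
        local = max(float(sigma[pos]), 1e-3 * max(float(np.max(np.abs(y))), 1.0))
        for w in range(width):
            j = pos + w
            if j < y.size:
                # triangular decay across multi-point hits
                y[j] += amp * local * (1.0 - 0.4 * w)
                hit.append(j)
    return np.array(sorted(set(hit)), dtype=int)


def simulate_dataset(
    cfg: SimulationConfig, templates: list[ClassTemplate] | None = None
) -> tuple[SpectralDataset, GroundTruth]:
    """Simulate the full line-scan study: classes x cells x points spectra.

    Per-cell band multipliers are drawn once per cell (lognormal, CV =
    ``cell_amplitude_cv``, independent per band); per-point multipliers are
    drawn per spectrum (CV = ``point_amplitude_cv``).  Noise and cosmic-ray
    spikes are then added on top of the stored clean spectra.
    """
    if templates is None:
        templates = default_templates()
    axis = cfg.make_axis()
    v = axis.values
    rng = np.random.default_rng(cfg.seed)
    n_bands = len(templates[0].bands)

    rows, clean_rows, metas, truth_rows, mults, spikes = [], [], [], [], [], []
    for t in templates:
        profiles = np.vstack([band_profile(v, b) for b in t.bands])  # n_bands x p
        base = _baseline(v, t.baseline_coeffs)
        for ci in range(cfg.n_cells_per_class):
            cell_id = f"{t.class_label}_c{ci:03d}"
            cell_mult = _lognormal_factors(rng, cfg.cell_amplitude_cv, n_bands)
            cell_baseline = float(
                _lognormal_factors(rng, cfg.baseline_cv, 1)[0]
            )
            for pi in range(cfg.n_points_per_cell):
                point_mult = _lognormal_factors(rng, cfg.point_amplitude_cv, n_bands)
                m = cell_mult * point_mult
                clean = m @ profiles + cell_baseline * base
                sigma = _noise_sigma(clean, cfg)
                y = clean + (rng.standard_normal(v.size) * sigma
                             if cfg.noise_scale > 0 else 0.0)
                y = np.array(y, dtype=float)
                pos = _inject_cosmic_rays(y, sigma, cfg, rng)
                rows.append(y)
                clean_rows.append(clean)
                spikes.append(pos)
                mults.append(m)
                metas.append(
                    {
                        "cell_line": t.class_label,
                        "cell_id": cell_id,
                        "point_index": pi,
                        "scan_index": 0,
                        "excitation_nm": 785,
                        "exposure_s": 1.0,
                        "accumulations": 30,
                    }
                )
                truth_rows.append(
                    {"cell_line": t.class_label, "cell_id": cell_id, "point_index": pi}
                )
    dataset = SpectralDataset(axis, np.vstack(rows), pd.DataFrame(metas))
    truth = GroundTruth(
        labels=pd.DataFrame(truth_rows),
        band_centers=templates[0].centers,
        band_multipliers=np.vstack(mults),
        clean_matrix=np.vstack(clean_rows),
        spike_positions=spikes,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Hyperspectral maps
# ---------------------------------------------------------------------------

REGION_LABELS = ("background", "cytoplasm", "nucleus", "lipid_droplet")

# Region-specific multipliers applied per assignment group on top of the
# class template; background pixels carry baseline (substrate/media) only.
_REGION_EFFECTS: dict[str, dict[str, float]] = {
    "background": {"lipid": 0.0, "protein": 0.0, "nucleic_acid": 0.0, "carbohydrate": 0.0},
    "cytoplasm": {},
    "nucleus": {"nucleic_acid": 2.5, "lipid": 0.5, "protein": 1.1},
    "lipid_droplet": {"lipid": 6.0, "protein": 0.8, "nucleic_acid": 0.4, "carbohydrate": 0.6},
}


def default_cell_layout(grid_shape: tuple[int, int]) -> np.ndarray:
    """Elliptical cell with an elliptical nucleus and one circular droplet.

    Returns an (nx, ny) array of region label strings.
    """
    nx, ny = grid_shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    layout = np.full(grid_shape, "background", dtype=object)
    cell = ((x - cx) / (0.42 * nx)) ** 2 + ((y - cy) / (0.38 * ny)) ** 2 <= 1.0
    layout[cell] = "cytoplasm"
    nucleus = ((x - cx + 0.08 * nx) / (0.16 * nx)) ** 2 + (
        (y - cy) / (0.14 * ny)
    ) ** 2 <= 1.0
    layout[nucleus] = "nucleus"
    droplet = ((x - cx - 0.22 * nx) ** 2 + (y - cy - 0.18 * ny) ** 2) <= (0.08 * max(nx, ny)) ** 2
    layout[droplet & cell] = "lipid_droplet"
    return layout.astype(str)


def simulate_map(
    t: ClassTemplate,
    grid_shape: tuple[int, int] = (24, 24),
    step_um: float = 0.5,
    region_layout: np.ndarray | None = None,
    cfg: SimulationConfig | None = None,
) -> tuple[HyperspectralMap, GroundTruth]:
    """Render an area scan with region-dependent chemistry per pixel.

    Droplet pixels carry strongly elevated lipid bands, nucleus pixels
    elevated nucleic-acid bands; background pixels are baseline + noise
    only.  Ground truth stores the region label per (flattened) pixel.
    """
    if cfg is None:
        cfg = SimulationConfig()
    axis = cfg.make_axis()
    v = axis.values
    if region_layout is None:
        region_layout = default_cell_layout(grid_shape)
    region_layout = np.asarray(region_layout, dtype=str)
    if region_layout.shape != tuple(grid_shape):
        raise ValueError(
            f"region_layout shape {region_layout.shape} != grid {tuple(grid_shape)}"
        )
    unknown = set(region_layout.ravel()) - set(REGION_LABELS)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    profiles = np.vstack([band_profile(v, b) for b in t.bands])
    base = _baseline(v, t.baseline_coeffs)
    assignments = [b.assignment for b in t.bands]
    region_mult = {
        r: np.array([_REGION_EFFECTS[r].get(a, 1.0) for a in assignments])
        for r in REGION_LABELS
    }
    flat = region_layout.ravel()
    n_bands = len(t.bands)
    rows = []
    for r in flat:
        m = region_mult[r] * _lognormal_factors(rng, cfg.point_amplitude_cv, n_bands)
        clean = m @ profiles + base
        sigma = _noise_sigma(clean, cfg)
        y = clean + (rng.standard_normal(v.size) * sigma if cfg.noise_scale > 0 else 0.0)
        rows.append(y)
    hmap = HyperspectralMap(tuple(grid_shape), step_um, axis, np.vstack(rows))
    truth = GroundTruth(region_labels=flat.copy(), band_centers=t.centers)
    return hmap, truth


# ---------------------------------------------------------------------------
# Photodamage time series
# ---------------------------------------------------------------------------

_RATIO_RE = re.compile(r"^I\((\d+(?:\.\d+)?)/(\d+(?:\.\d+)?)\)$")


def parse_ratio_name(name: str) -> tuple[float, float]:
    """Parse 'I(a/b)' into the two band positions (cm^-1)."""
    m = _RATIO_RE.match(name)
    if m is None:
        raise ValueError(f"ratio name {name!r} not of the form I(a/b)")
    return float(m.group(1)), float(m.group(2))


def _windowed_max(v: np.ndarray, y: np.ndarray, center: float, half_window: float = 8.0) -> float:
    mask = (v >= center - half_window) & (v <= center + half_window)
    return float(np.max(y[mask]))


def simulate_photodamage_series(
    t: ClassTemplate,
    n_scans: int = 8,
    planted_slopes: dict[str, float] | None = None,
    cfg: SimulationConfig | None = None,
) -> tuple[SpectralDataset, GroundTruth]:
    """Longitudinal line-scan series with planted linear ratio trends.

    For each named ratio I(a/b), the numerator band's amplitude at scan k
    is solved so that the clean windowed-max ratio equals r0 + slope * k,
    with r0 the scan-0 value; all other bands are held fixed.  8 scans
    mirror the 785 nm protocol, 4 the 488 nm one.
    """
    if cfg is None:
        cfg = SimulationConfig()
    if n_scans < 2:
        raise ValueError("need n_scans >= 2")
    if planted_slopes is None:
        planted_slopes = {"I(1003/1301)": 0.0}
    axis = cfg.make_axis()
    v = axis.values
    rng = np.random.default_rng(cfg.seed)

    parsed = {name: parse_ratio_name(name) for name in planted_slopes}
    base_clean = render_clean_spectrum(t, axis, include_baseline=False).intensities
    # contribution of everything except the numerator band, per ratio
    numerators = {}
    for name, (a, b) in parsed.items():
        ai = t.band_index(a)
        rest = base_clean - band_profile(v, t.bands[ai])
        numerators[name] = (ai, rest)

    rows, metas = [], []
    for k in range(n_scans):
        scale = np.ones(len(t.bands))
        clean = base_clean.copy()
        for name, (a, b) in parsed.items():
            ai, rest = numerators[name]
            i_b = _windowed_max(v, base_clean, b)
            r0 = _windowed_max(v, base_clean, a) / i_b
            target = (r0 + planted_slopes[name] * k) * i_b
            # peak = band amplitude + neighbour tails at the band's grid max
            mask = (v >= a - 8.0) & (v <= a + 8.0)
            prof_unit = band_profile(v, t.bands[ai], 1.0)
            jmax = np.flatnonzero(mask)[np.argmax((rest + t.bands[ai].amplitude * prof_unit)[mask])]
            amp = (target - rest[jmax]) / prof_unit[jmax]
            clean = clean + (amp - t.bands[ai].amplitude) * prof_unit
            scale[ai] = amp / t.bands[ai].amplitude
        sigma = _noise_sigma(clean, cfg)
        y = clean + (rng.standard_normal(v.size) * sigma if cfg.noise_scale > 0 else 0.0)
        rows.append(y)
        metas.append(
            {
                "cell_line": t.class_label,
                "cell_id": f"{t.class_label}_series",
                "point_index": 0,
                "scan_index": k,
                "excitation_nm": 785 if n_scans >= 8 else 488,
                "exposure_s": 1.0,
                "accumulations": 30,
            }
        )
    dataset = SpectralDataset(axis, np.vstack(rows), pd.DataFrame(metas))
    truth = GroundTruth(planted_slopes=dict(planted_slopes))
    return dataset, truth
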