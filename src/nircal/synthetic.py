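"""Synthetic NIR spectra of instant tea with known ground truth.

The generator emulates the statistical structure of a powdered-tea NIR
dataset: four components (moisture, caffeine, tea polyphenols, tea
polysaccharides) with concentration ranges matching published
composition statistics, Gaussian absorption bands placed inside the
wavenumber regions reported informative for each component, Beer-Lambert
additivity (absorbance linear in concentration), and per-sample
multiplicative scatter gain, additive offset, a low-order baseline and
white noise — exactly the distortion family SNV is meant to remove.

Polyphenol and polysaccharide bands intentionally share regions with the
other components (as the real assignments do), so those two are the hard
targets for wavelength selection and calibration alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .segmentation import SegmentScheme, make_segments
from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "BandSpec",
    "ComponentSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_tea_config",
    "simulate",
    "planted_segments",
    "background_spectrum",
    "matrix_modes",
]

COMPONENTS = ("moisture", "caffeine", "tea_polyphenols", "tea_polysaccharides")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (cm^-1), sd width (cm^-1),
    amplitude in absorbance units per % concentration at the peak."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("band width and amplitude must be > 0")


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    concentration_range: tuple[float, float]
    bands: tuple[BandSpec, ...]
    mean: float | None = None  # for the truncated-normal option
    sd: float | None = None

    def __post_init__(self):
        lo, hi = self.concentration_range
        if not lo < hi:
            raise ValueError("concentration range must have min < max")
        if not self.bands:
            raise ValueError("component needs at least one band")


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 118
    grid_high: float = 10_000.0
    grid_low: float = 4_000.0
    n_vars: int = 6539
    components: tuple[ComponentSpec, ...] = ()
    scatter_gain_range: tuple[float, float] = (0.8, 1.2)
    scatter_offset_range: tuple[float, float] = (-0.1, 0.1)
    baseline_amplitude: float = 0.05
    baseline_degree: int = 2
    background_amplitude: float = 2.5
    matrix_modes_per_segment: int = 3
    matrix_sd: float = 0.015
    matrix_mode_width: float | None = None  # cm^-1 sd; default segment span / 10
    noise_sd: float = 0.002
    concentration_law: str = "uniform"  # or "truncnorm"
    seed: int = 0

    def __post_init__(self):
        if self.n_vars < 2:
            raise ValueError("n_vars must be >= 2")
        if self.scatter_gain_range[0] <= 0:
            raise ValueError("scatter gain must stay strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_degree not in (0, 1, 2):
            raise ValueError("baseline_degree must be 0, 1 or 2")
        lo, hi = min(self.grid_low, self.grid_high), max(self.grid_low, self.grid_high)
        for c in self.components:
            for b in c.bands:
                if not lo <= b.center <= hi:
                    raise ValueError(
                        f"band center {b.center} outside grid [{lo}, {hi}]"
                    )

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.grid_high, self.grid_low, self.n_vars)


@dataclass
class GroundTruth:
    """What the generator knows: true concentrations and where the signal lives."""

    concentrations: dict[str, np.ndarray]
    informative_segments: dict[str, list[int]]
    gains: np.ndarray | None = None
    offsets: np.ndarray | None = None


def default_tea_config(seed: int = 0, n_samples: int = 118, n_vars: int = 6539) -> SimulationConfig:
    """The instant-tea emulation: published content ranges, bands inside the
    reported informative regions, and moderate scatter/noise.

    Moisture and caffeine get compact two-band signatures in nearly clean
    regions; polyphenols and polysaccharides get many weaker bands that
    overlap each other's and the first two components' regions.
    """
    comps = (
        ComponentSpec(
            "moisture",
            (3.76, 6.29),
            (
                BandSpec(7009.0, 25.0, 0.040),  # O-H first overtone region
                BandSpec(7945.0, 18.0, 0.028),  # O-H combination region
            ),
            mean=4.79,
            sd=0.60,
        ),
        ComponentSpec(
            "caffeine",
            (0.48, 2.80),
            (
                BandSpec(4735.0, 40.0, 0.060),  # amine combination bands
                BandSpec(7230.0, 22.0, 0.050),
            ),
            mean=1.69,
            sd=0.67,  # sd a uniform law on the printed range supports
        ),
        ComponentSpec(
            "tea_polyphenols",
            (18.70, 22.40),
            (
                BandSpec(5020.0, 50.0, 0.010),  # phenolic O-H combination
                BandSpec(6780.0, 28.0, 0.010),
                BandSpec(7520.0, 28.0, 0.010),
                BandSpec(8095.0, 30.0, 0.010),  # shares the moisture region
            ),
            mean=20.93,
            sd=0.89,
        ),
        ComponentSpec(
            "tea_polysaccharides",
            (18.00, 24.50),
            (
                BandSpec(4680.0, 28.0, 0.004),  # shares the caffeine region
                BandSpec(6160.0, 50.0, 0.008),
                BandSpec(7255.0, 12.0, 0.004),  # shares the caffeine region
                BandSpec(8135.0, 30.0, 0.008),  # shares the moisture region
                BandSpec(9010.0, 45.0, 0.008),
                BandSpec(9870.0, 50.0, 0.008),
            ),
            mean=21.18,
            sd=1.88,
        ),
    )
    return SimulationConfig(
        n_samples=n_samples, n_vars=n_vars, components=comps, seed=seed
    )


def background_spectrum(cfg: SimulationConfig) -> np.ndarray:
    """Fixed matrix absorbance common to every sample.

    Powdered-plant NIR spectra share a large, smooth absorbance envelope
    (broad water/cellulose bands rising toward low wavenumber) on which
    the composition-dependent bands sit. Scaled by
    ``cfg.background_amplitude``; zero amplitude removes it.
    """
    wn = cfg.wavenumbers
    t = (cfg.grid_high - wn) / (cfg.grid_high - cfg.grid_low)

    def g(center, width, h):
        return h * np.exp(-0.5 * ((wn - center) / width) ** 2)

    shape = (
        0.30
        + 0.40 * t
        + g(8900.0, 700.0, 0.50)
        + g(6900.0, 900.0, 0.90)
        + g(5200.0, 500.0, 1.20)
        + g(4400.0, 350.0, 1.00)
        # fine structure at sub-segment scale, homogeneous across the axis
        + 0.25 * np.sin(2 * np.pi * 40 * t)
    )
    return cfg.background_amplitude * shape


def matrix_modes(cfg: SimulationConfig) -> np.ndarray:
    """Smooth modes of sample-to-sample matrix variability.

    Real powdered samples differ in everything besides the calibrated
    components (other constituents, particle/packing effects beyond a
    single gain); that shows up as smooth, many-degree-of-freedom
    structure across the axis. Modeled as fixed Gaussians (unit peak
    height) whose per-sample coefficients are N(0, matrix_sd) —
    ``matrix_modes_per_segment`` of them laid out inside each block of
    the default 21-block partition of the axis, so nuisance structure is
    independent across blocks. Returns (n_modes, n_vars).
    """
    if cfg.matrix_modes_per_segment == 0:
        return np.zeros((0, cfg.n_vars))
    wn = cfg.wavenumbers
    scheme = make_segments(cfg.n_vars, min(21, cfg.n_vars))
    rows = []
    k = cfg.matrix_modes_per_segment
    fractions = np.linspace(0.25, 0.75, k) if k > 1 else np.array([0.5])
    for s, e in scheme.boundaries:
        lo = min(wn[s], wn[e - 1])
        hi = max(wn[s], wn[e - 1])
        span = hi - lo
        width = cfg.matrix_mode_width if cfg.matrix_mode_width else span / 10
        for f in fractions:
            center = lo + f * span
            rows.append(np.exp(-0.5 * ((wn - center) / width) ** 2))
    return np.vstack(rows)


def _band_matrix(cfg: SimulationConfig) -> np.ndarray:
    """(n_components, n_vars) pure-component spectra at 1% concentration."""
    wn = cfg.wavenumbers
    rows = []
    for comp in cfg.components:
        spec = np.zeros_like(wn)
        for b in comp.bands:
            spec += b.amplitude * np.exp(-0.5 * ((wn - b.center) / b.width) ** 2)
        rows.append(spec)
    return np.vstack(rows)


def _draw_concentrations(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for comp in cfg.components:
        lo, hi = comp.concentration_range
        if cfg.concentration_law == "uniform":
            cols.append(rng.uniform(lo, hi, cfg.n_samples))
        elif cfg.concentration_law == "truncnorm":
            m = comp.mean if comp.mean is not None else 0.5 * (lo + hi)
            s = comp.sd if comp.sd is not None else (hi - lo) / 4
            a, b = (lo - m) / s, (hi - m) / s
            cols.append(
                truncnorm.rvs(a, b, loc=m, scale=s, size=cfg.n_samples, random_state=rng)
            )
        else:
            raise ValueError(f"unknown concentration law {cfg.concentration_law!r}")
    return np.column_stack(cols)


def simulate(cfg: SimulationConfig) -> tuple[SpectraSet, list[ReferenceTable], GroundTruth]:
    """Draw a seeded synthetic dataset.

    Per sample: concentrations within their configured ranges; clean
    spectrum = fixed background + per-sample matrix variation + sum over
    components of concentration x pure band shape; observed =
    gain * (clean + baseline) + offset + N(0, noise_sd), with gain,
    offset, matrix-mode coefficients and the baseline polynomial drawn
    per sample.
    """
    if not cfg.components:
        raise ValueError("config has no components")
    rng = np.random.default_rng(cfg.seed)
    conc = _draw_concentrations(cfg, rng)
    clean = conc @ _band_matrix(cfg) + background_spectrum(cfg)
    modes = matrix_modes(cfg)
    if modes.shape[0] and cfg.matrix_sd > 0:
        clean = clean + rng.normal(0.0, cfg.matrix_sd, (cfg.n_samples, modes.shape[0])) @ modes

    t = np.linspace(0.0, 1.0, cfg.n_vars)  # normalized axis for the baseline
    n = cfg.n_samples
    base_coef = rng.uniform(
        -cfg.baseline_amplitude, cfg.baseline_amplitude, (n, cfg.baseline_degree + 1)
    )
    baseline = sum(base_coef[:, [d]] * t**d for d in range(cfg.baseline_degree + 1))
    gains = rng.uniform(*cfg.scatter_gain_range, n)
    offsets = rng.uniform(*cfg.scatter_offset_range, n)
    noise = rng.normal(0.0, cfg.noise_sd, (n, cfg.n_vars)) if cfg.noise_sd > 0 else 0.0
    observed = gains[:, None] * (clean + baseline) + offsets[:, None] + noise

    ids = [f"S{i + 1:03d}" for i in range(n)]
    spectra = SpectraSet(cfg.wavenumbers, observed, ids)
    tables = [
        ReferenceTable(comp.name, dict(zip(ids, conc[:, j])))
        for j, comp in enumerate(cfg.components)
    ]
    truth = GroundTruth(
        concentrations={c.name: conc[:, j] for j, c in enumerate(cfg.components)},
        informative_segments=planted_segments(cfg, make_segments(cfg.n_vars, 21)),
        gains=gains,
        offsets=offsets,
    )
    return spectra, tables, truth


def planted_segments(cfg: SimulationConfig, scheme: SegmentScheme) -> dict[str, list[int]]:
    """Segments whose wavenumber span overlaps any band's +-2.5 sd interval,
    per component — the recovery target for wavelength selection."""
    if scheme.n_vars != cfg.n_vars:
        raise ValueError("scheme does not match the simulation grid")
    wn = cfg.wavenumbers
    seg_spans = [
        (min(wn[s], wn[e - 1]), max(wn[s], wn[e - 1])) for s, e in scheme.boundaries
    ]
    out: dict[str, list[int]] = {}
    for comp in cfg.components:
        hits: set[int] = set()
        for b in comp.bands:
            lo, hi = b.center - 2.5 * b.width, b.center + 2.5 * b.width
            for k, (slo, shi) in enumerate(seg_spans):
                if slo <= hi and lo <= shi:
                    hits.add(k)
        out[comp.name] = sorted(hits)
    return out
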