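"""Synthetic mid-IR spectrum generator with flower/seed/leaf band structure.

Every stage of the package is testable without instrument data: this module
generates absorbance spectra as sums of Gaussian/Lorentzian bands on the
4000-400 cm^-1 grid at 1 cm^-1 spacing, with a sloped linear baseline and
additive Gaussian noise.  The default class templates place their bands at
the characteristic flower, seed and leaf positions of the band-assignment
library (ester carbonyl near 1736/1743/1729 cm^-1, amide I/II for seed,
oxalate for leaf, saccharide C-O stretches below 1200 cm^-1), with
amplitudes scaled once so that the simulated transmission obeys the
acceptance window (maximum %T >= 60, strongest band bottoming out within
10-30 %T).

Within-class variation is modelled as a global lognormal amplitude scale,
small per-band lognormal jitter and baseline jitter; noise is additive
Gaussian in absorbance (sigma 0.005 by default).  Temperature-perturbation
series scale each band's amplitude by its own linear temperature
coefficient, optionally through a sigmoidal response with a per-band
midpoint so that lead/lag ground truth is known.  All generators are
bit-reproducible given (template, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, ParameterError
from .spectra_io import (
    MODE_ABSORBANCE,
    PerturbationSeries,
    Spectrum,
    SpectrumCollection,
)

DEFAULT_GRID = np.arange(400.0, 4001.0, 1.0)
DEFAULT_TEMPERATURES = np.arange(20.0, 121.0, 10.0)


@dataclass(frozen=True)
class Band:
    """One vibrational band: centre, FWHM, peak amplitude, shape, T response.

    ``temp_coefficient`` is the fractional amplitude change per degree C
    relative to 20 C; ``temp_midpoint_C`` switches the response to a
    sigmoid centred there (used to create asynchronous structure with a
    known response order).
    """

    center: float
    width: float = 20.0
    amplitude: float = 0.3
    shape: str = "gaussian"
    temp_coefficient: float = 0.0
    temp_midpoint_C: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError("band width (FWHM) must be positive")
        if self.amplitude < 0:
            raise ParameterError("band amplitude must be nonnegative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ParameterError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class ClassTemplate:
    """Band set plus baseline and noise model for one sample class."""

    label: str
    bands: tuple
    baseline_offset: float = 0.02
    baseline_slope: float = 5e-6          # absorbance per cm^-1
    noise_sigma: float = 0.005
    scale_jitter_sigma: float = 0.05      # lognormal global amplitude scale
    band_jitter_sigma: float = 0.03       # lognormal per-band amplitude jitter
    baseline_jitter_sigma: float = 0.005  # additive offset jitter

    def __post_init__(self) -> None:
        bands = tuple(self.bands)
        if len(bands) < 3:
            raise ParameterError("a class template needs >= 3 bands")
        if self.noise_sigma < 0:
            raise ParameterError("noise sigma must be nonnegative")
        object.__setattr__(self, "bands", bands)


def band_profile(b: Band, grid: np.ndarray) -> np.ndarray:
    """Evaluate one band on the grid; the value at the centre is the amplitude."""
    grid = np.asarray(grid, dtype=float)
    d = grid - b.center
    if b.shape == "gaussian":
        return b.amplitude * np.exp(-4.0 * math.log(2.0) * d ** 2 / b.width ** 2)
    half = b.width / 2.0
    return b.amplitude * half ** 2 / (d ** 2 + half ** 2)


def _band_sum(bands, grid: np.ndarray, scale: np.ndarray | None = None) -> np.ndarray:
    out = np.zeros_like(np.asarray(grid, dtype=float))
    for i, b in enumerate(bands):
        s = 1.0 if scale is None else float(scale[i])
        if s != 1.0:
            b = replace(b, amplitude=b.amplitude * s)
        out += band_profile(b, grid)
    return out


def default_templates() -> dict[str, ClassTemplate]:
    """Flower, leaf and seed templates with library band positions.

    Amplitudes were fixed once so each class's strongest absorbance is
    ~0.6-0.7, i.e. the simulated strongest band sits near 20-25 %T and the
    baseline keeps the maximum transmission above 60%.  Temperature
    coefficients differ between compound classes so that thermal
    perturbation produces non-trivial 2D correlation structure.
    """
    flower = ClassTemplate(
        label="flower",
        bands=(
            Band(1736, 20, 0.30, temp_coefficient=-0.0020),
            Band(1626, 20, 0.45, temp_coefficient=-0.0035),
            Band(1443, 20, 0.25, temp_coefficient=-0.0015),
            Band(1145, 20, 0.55, temp_coefficient=-0.0030),
            Band(1102, 20, 0.50, temp_coefficient=-0.0025),
            Band(1058, 20, 0.60, temp_coefficient=-0.0040),
        ),
    )
    leaf = ClassTemplate(
        label="leaf",
        bands=(
            Band(1729, 20, 0.25, temp_coefficient=-0.0018),
            Band(1624, 20, 0.65, temp_coefficient=-0.0042),
            Band(1318, 20, 0.45, temp_coefficient=-0.0028),
            Band(1156, 20, 0.40, temp_coefficient=-0.0022),
            Band(1098, 20, 0.35, temp_coefficient=-0.0012),
            Band(1050, 20, 0.40, temp_coefficient=-0.0032),
        ),
    )
    seed = ClassTemplate(
        label="seed",
        bands=(
            Band(1743, 20, 0.65, temp_coefficient=-0.0038),
            Band(1648, 20, 0.55, temp_coefficient=-0.0030),
            Band(1548, 20, 0.40, temp_coefficient=-0.0020),
            Band(1459, 20, 0.30, temp_coefficient=-0.0014),
            Band(1159, 20, 0.45, temp_coefficient=-0.0026),
            Band(1079, 20, 0.40, temp_coefficient=-0.0018),
            Band(1019, 20, 0.50, temp_coefficient=-0.0034),
        ),
    )
    return {"flower": flower, "leaf": leaf, "seed": seed}


def blend_templates(templates: dict[str, ClassTemplate],
                    separation: float) -> dict[str, ClassTemplate]:
    """Scale between-class distinctness by a single separation knob.

    Each class's band amplitudes (on the union of all band centres) are
    interpolated between the across-class mean (separation 0: identical
    classes) and their own values (separation 1: full distinctness).
    Amplitudes are clipped at zero for separation > 1.
    """
    if separation < 0:
        raise ParameterError("separation must be nonnegative")
    centers = sorted({b.center for t in templates.values() for b in t.bands})
    by_class = {}
    for name, t in templates.items():
        amp = {b.center: b.amplitude for b in t.bands}
        coeff = {b.center: b.temp_coefficient for b in t.bands}
        width = {b.center: b.width for b in t.bands}
        by_class[name] = (amp, coeff, width)
    out = {}
    for name, t in templates.items():
        amp, coeff, width = by_class[name]
        new_bands = []
        for c in centers:
            mean_amp = float(np.mean([bc[0].get(c, 0.0) for bc in by_class.values()]))
            mean_coeff = float(np.mean([bc[1].get(c, 0.0) for bc in by_class.values()]))
            a = max(0.0, mean_amp + separation * (amp.get(c, 0.0) - mean_amp))
            k = mean_coeff + separation * (coeff.get(c, 0.0) - mean_coeff)
            if a > 1e-12:
                new_bands.append(Band(c, width.get(c, 20.0), a, temp_coefficient=k))
        out[name] = replace(t, bands=tuple(new_bands))
    return out


def generate_spectrum(template: ClassTemplate, seed: int,
                      grid: np.ndarray | None = None,
                      sample_id: str | None = None) -> Spectrum:
    """One absorbance spectrum: jittered band sum + baseline + noise."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_bands = len(template.bands)
    g = rng.lognormal(0.0, template.scale_jitter_sigma) \
        if template.scale_jitter_sigma > 0 else 1.0
    per_band = rng.lognormal(0.0, template.band_jitter_sigma, size=n_bands) \
        if template.band_jitter_sigma > 0 else np.ones(n_bands)
    offset = template.baseline_offset
    if template.baseline_jitter_sigma > 0:
        offset += rng.normal(0.0, template.baseline_jitter_sigma)
    y = _band_sum(template.bands, grid, scale=g * per_band)
    y = y + offset + template.baseline_slope * (grid - grid[0])
    if template.noise_sigma > 0:
        y = y + rng.normal(0.0, template.noise_sigma, size=grid.size)
    return Spectrum(
        wavenumbers=grid, intensities=y, mode=MODE_ABSORBANCE,
        sample_id=sample_id or f"{template.label}_seed{seed}",
        class_label=template.label,
        meta={"synthetic": True, "template": template.label, "seed": int(seed)},
    )


def generate_dataset(templates: dict[str, ClassTemplate] | None = None,
                     n_per_class: dict[str, int] | None = None,
                     seed: int = 0,
                     grid: np.ndarray | None = None) -> SpectrumCollection:
    """Labelled collection; defaults to the 34/80/7 flower/leaf/seed design."""
    templates = templates or default_templates()
    n_per_class = n_per_class or {"flower": 34, "leaf": 80, "seed": 7}
    rng = np.random.default_rng(seed)
    spectra = []
    labels = []
    for name, n in n_per_class.items():
        if n < 2:
            raise ParameterError(f"need >= 2 samples per class, got {n} for {name!r}")
        t = templates[name]
        for i in range(n):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            spectra.append(generate_spectrum(t, sub, grid=grid,
                                             sample_id=f"{name}_{i:03d}"))
            labels.append(name)
    return SpectrumCollection(tuple(spectra), tuple(labels))


def _temperature_response(b: Band, temperatures: np.ndarray) -> np.ndarray:
    """Per-temperature amplitude factor for one band (>= 0)."""
    dT = temperatures - 20.0
    if b.temp_midpoint_C is None:
        resp = 1.0 + b.temp_coefficient * dT
    else:
        # sigmoidal response with total change temp_coefficient * 100 C,
        # centred at temp_midpoint_C: earlier midpoints respond first
        total = b.temp_coefficient * 100.0
        resp = 1.0 + total / (1.0 + np.exp(-(temperatures - b.temp_midpoint_C) / 10.0))
    return np.clip(resp, 0.0, None)


def generate_perturbation_series(template: ClassTemplate, seed: int = 0,
                                 temperatures: np.ndarray | None = None,
                                 grid: np.ndarray | None = None,
                                 noise_sigma: float | None = None) -> PerturbationSeries:
    """Thermal-perturbation series (default 20-120 C in 10 C steps).

    Band amplitudes follow each band's own temperature response; bands with
    a ``temp_midpoint_C`` respond sigmoidally and the induced lead/lag order
    is recorded in the series metadata as ground truth.
    """
    temps = DEFAULT_TEMPERATURES if temperatures is None else \
        np.asarray(temperatures, dtype=float)
    if temps.size < 3:
        raise ParameterError("a perturbation series needs >= 3 temperatures")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sigma = template.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)
    base = template.baseline_offset + template.baseline_slope * (grid - grid[0])
    spectra = []
    for T in temps:
        y = np.zeros_like(grid)
        for b in template.bands:
            factor = float(_temperature_response(b, np.asarray([T]))[0])
            y += band_profile(replace(b, amplitude=b.amplitude * factor), grid)
        y = y + base
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, size=grid.size)
        spectra.append(Spectrum(
            wavenumbers=grid, intensities=y, mode=MODE_ABSORBANCE,
            sample_id=f"{template.label}_T{T:g}", class_label=template.label,
            temperature_C=float(T),
            meta={"synthetic": True, "seed": int(seed)},
        ))
    lag_order = sorted(
        (b.center for b in template.bands if b.temp_midpoint_C is not None),
        key=lambda c: next(b.temp_midpoint_C for b in template.bands
                           if b.center == c),
    )
    return PerturbationSeries(
        spectra=tuple(spectra), temperatures_C=temps,
        meta={"response_order": tuple(lag_order), "seed": int(seed)},
    )


def generate_adulterated(flower: ClassTemplate, leaf: ClassTemplate,
                         fraction_leaf: float, seed: int = 0,
                         grid: np.ndarray | None = None) -> Spectrum:
    """Flower/leaf mixture: convex combination of band sets before noise."""
    if not 0.0 <= fraction_leaf <= 1.0:
        raise DomainError("fraction_leaf must lie in [0, 1]")
    f = float(fraction_leaf)
    bands = tuple(
        [replace(b, amplitude=b.amplitude * (1.0 - f)) for b in flower.bands
         if b.amplitude * (1.0 - f) > 0] +
        [replace(b, amplitude=b.amplitude * f) for b in leaf.bands
         if b.amplitude * f > 0]
    )
    mix = ClassTemplate(
        label="query",
        bands=bands if len(bands) >= 3 else bands + tuple(
            replace(b, amplitude=0.0) for b in flower.bands[:3 - len(bands)]),
        baseline_offset=(1 - f) * flower.baseline_offset + f * leaf.baseline_offset,
        baseline_slope=(1 - f) * flower.baseline_slope + f * leaf.baseline_slope,
        noise_sigma=(1 - f) * flower.noise_sigma + f * leaf.noise_sigma,
        scale_jitter_sigma=flower.scale_jitter_sigma,
        band_jitter_sigma=flower.band_jitter_sigma,
        baseline_jitter_sigma=flower.baseline_jitter_sigma,
    )
    s = generate_spectrum(mix, seed, grid=grid,
                          sample_id=f"mixture_leaf{f:g}_seed{seed}")
    meta = dict(s.meta)
    meta["fraction_leaf"] = f
    return replace(s, meta=meta, class_label="query")
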