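"""Baseline correction, smoothing, normalisation and second-derivative spectra.

The second-derivative (SD-IR) transform uses a Savitzky-Golay filter with a
13-point window and quadratic local polynomials by default — the minimum
polynomial order that supports a second derivative and the common choice of
instrument software.  Derivatives are scaled per unit wavenumber (the filter
is given the grid spacing), so results do not depend on grid resolution.
Absorbance maxima appear as SD minima.

Baselines default to the parameter-free rubber-band correction (lower convex
hull of the trace); Eilers' asymmetric least squares is available as an
option for baselines that dip below the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import DegenerateDataError, GridError, ModeError, ParameterError
from .spectra_io import (
    MODE_ABSORBANCE,
    MODE_SECOND_DERIVATIVE,
    MODE_TRANSMITTANCE,
    Spectrum,
    percent_transmittance_to_absorbance,
)

BASELINE_METHODS = ("rubberband", "asls", "none")
NORMALIZE_METHODS = ("none", "snv", "minmax")


@dataclass(frozen=True)
class PreprocessConfig:
    """Ordered preprocessing recipe.

    ``sg_window`` is the odd Savitzky-Golay point count (13 by default, the
    slope-calculation window used for SD-IR); setting it to 0 disables
    smoothing when no derivative is requested.  ``derivative`` is 0 (leave
    the absorbance trace) or 2 (SD-IR output).
    """

    sg_window: int = 13
    sg_polyorder: int = 2
    baseline: str = "rubberband"
    normalize: str = "none"
    derivative: int = 2

    def __post_init__(self) -> None:
        if self.sg_window:
            if self.sg_window % 2 == 0:
                raise ParameterError("sg_window must be odd")
            if self.sg_window < self.sg_polyorder + 2:
                raise ParameterError("sg_window must be >= sg_polyorder + 2")
        if self.baseline not in BASELINE_METHODS:
            raise ParameterError(f"unknown baseline method {self.baseline!r}")
        if self.normalize not in NORMALIZE_METHODS:
            raise ParameterError(f"unknown normalize method {self.normalize!r}")
        if self.derivative not in (0, 2):
            raise ParameterError("derivative must be 0 or 2")
        if self.derivative == 2 and not self.sg_window:
            raise ParameterError("derivative=2 requires a nonzero sg_window")


def _check_window(s: Spectrum, window: int, polyorder: int) -> None:
    if window % 2 == 0:
        raise ParameterError("Savitzky-Golay window must be odd")
    if window < polyorder + 2:
        raise ParameterError("window must be >= polyorder + 2")
    if window > len(s):
        raise ParameterError(
            f"window {window} exceeds spectrum length {len(s)}"
        )
    if not s.is_uniform():
        raise GridError("Savitzky-Golay filtering requires a uniform grid")


def savgol_smooth(s: Spectrum, window: int = 13, polyorder: int = 2) -> Spectrum:
    """Least-squares local-polynomial smoothing; the grid is unchanged.

    Edge points are handled by fitting a polynomial to the terminal window
    (scipy's ``interp`` mode), flagged in metadata.
    """
    _check_window(s, window, polyorder)
    y = savgol_filter(s.intensities, window, polyorder, mode="interp")
    return s.with_intensities(y, sg_smooth={"window": window, "polyorder": polyorder,
                                            "edges": "terminal-window polynomial"})


def second_derivative(s: Spectrum, window: int = 13, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay second derivative per unit wavenumber (SD-IR).

    Requires an absorbance spectrum (convert %T first).  The derivative is
    scaled by the grid spacing, so values are in absorbance per cm^-2
    regardless of sampling interval.
    """
    if s.mode == MODE_TRANSMITTANCE:
        raise ModeError("convert %T to absorbance before the second derivative")
    _check_window(s, window, polyorder)
    delta = float(np.diff(s.wavenumbers)[0])
    y = savgol_filter(s.intensities, window, polyorder, deriv=2, delta=delta,
                      mode="interp")
    return s.with_intensities(
        y, mode=MODE_SECOND_DERIVATIVE,
        sd={"window": window, "polyorder": polyorder,
            "edges": "terminal-window polynomial"},
    )


def _lower_convex_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull (Andrew's monotone chain), x ascending."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # cross product of (k-j) x (i-j); <= 0 means k is not below the chord
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (x[i] - x[j]) * (y[k] - y[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubber-band baseline: lower convex hull evaluated on the grid.

    Returns ``(baseline, corrected)``.  The corrected trace is nonnegative
    with zero endpoints by construction.
    """
    if s.mode == MODE_TRANSMITTANCE:
        raise ModeError("rubber-band baseline operates on absorbance spectra")
    if len(s) < 3:
        raise ParameterError("rubber-band baseline needs >= 3 points")
    idx = _lower_convex_hull(s.wavenumbers, s.intensities)
    base = np.interp(s.wavenumbers, s.wavenumbers[idx], s.intensities[idx])
    corrected = s.intensities - base
    corrected[corrected < 0] = 0.0  # clip float dust; hull guarantees >= 0
    return (
        s.with_intensities(base, baseline_role="baseline"),
        s.with_intensities(corrected, baseline={"method": "rubberband"}),
    )


def asls_baseline(s: Spectrum, lam: float = 1e6, p: float = 0.01,
                  n_iter: int = 10) -> tuple[Spectrum, Spectrum]:
    """Asymmetric-least-squares baseline (Eilers & Boelens).

    ``lam`` controls stiffness, ``p`` the asymmetry (weights for points above
    the baseline).  Returns ``(baseline, corrected)``; unlike the rubber
    band, the corrected trace may be slightly negative in noise.
    """
    if s.mode == MODE_TRANSMITTANCE:
        raise ModeError("AsLS baseline operates on absorbance spectra")
    y = s.intensities
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    DDt = lam * (D @ D.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + DDt).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    corrected = y - z
    return (
        s.with_intensities(z, baseline_role="baseline"),
        s.with_intensities(corrected, baseline={"method": "asls", "lam": lam, "p": p}),
    )


def normalize(s: Spectrum, method: str) -> Spectrum:
    """Standard-normal-variate (mean 0, sd 1) or min-max (0..1) scaling."""
    y = s.intensities
    if method == "snv":
        sd = float(np.std(y))
        if sd == 0:
            raise DegenerateDataError("SNV is undefined for a constant spectrum")
        out = (y - np.mean(y)) / sd
    elif method == "minmax":
        rng = float(np.max(y) - np.min(y))
        if rng == 0:
            raise DegenerateDataError("min-max is undefined for a constant spectrum")
        out = (y - np.min(y)) / rng
    else:
        raise ParameterError(f"unknown normalization {method!r}")
    return s.with_intensities(out, normalized=method)


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Deterministic composition: %T->A, baseline, smooth, normalize, derivative.

    The applied steps are recorded in the result's metadata.  With everything
    switched off (``sg_window=0``, baseline and normalize ``none``,
    ``derivative=0``) an absorbance spectrum passes through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    steps: list[str] = []
    out = s
    if out.mode == MODE_TRANSMITTANCE:
        out = percent_transmittance_to_absorbance(out)
        steps.append("percent_transmittance_to_absorbance")
    if cfg.baseline == "rubberband":
        _, out = rubberband_baseline(out)
        steps.append("rubberband_baseline")
    elif cfg.baseline == "asls":
        _, out = asls_baseline(out)
        steps.append("asls_baseline")
    if cfg.sg_window and cfg.derivative == 0:
        out = savgol_smooth(out, cfg.sg_window, cfg.sg_polyorder)
        steps.append(f"savgol_smooth({cfg.sg_window},{cfg.sg_polyorder})")
    if cfg.normalize != "none":
        out = normalize(out, cfg.normalize)
        steps.append(f"normalize({cfg.normalize})")
    if cfg.derivative == 2:
        out = second_derivative(out, cfg.sg_window, cfg.sg_polyorder)
        steps.append(f"second_derivative({cfg.sg_window},{cfg.sg_polyorder})")
    meta = dict(out.meta)
    meta["preprocess"] = tuple(steps)
    return Spectrum(out.wavenumbers, out.intensities, out.mode, out.sample_id,
                    out.class_label, out.temperature_C, meta)
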