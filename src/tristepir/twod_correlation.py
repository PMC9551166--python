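"""Generalized two-dimensional correlation spectroscopy (2D-COS).

A temperature-perturbation series of m spectra is reduced to dynamic spectra
(each spectrum minus a reference, by default the series mean).  The
synchronous map

    Phi(v1, v2) = 1/(m-1) * sum_j  ytilde_j(v1) * ytilde_j(v2)

is the covariance of intensity fluctuations: auto-peaks on its diagonal mark
bands whose intensity responds to the perturbation, and the sign of a cross
peak tells whether two bands move in the same or opposite direction.  The
asynchronous map applies the discrete Hilbert-Noda transform N,

    Psi(v1, v2) = 1/(m-1) * sum_j ytilde_j(v1) * sum_k N[j,k] * ytilde_k(v2),
    N[j,k] = 0 if j == k else 1/(pi * (k - j)),

and is zero whenever all bands share one response profile; a nonzero Psi
encodes the sequential order of band responses (Noda's rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, GridError, ParameterError, RangeError
from .peak_analysis import PeakTable
from .spectra_io import PerturbationSeries, Spectrum

SAME_DIRECTION = "same_direction"
OPPOSITE_DIRECTION = "opposite_direction"
UNCOORDINATED = "uncoordinated"


@dataclass(frozen=True)
class DynamicSpectra:
    """Mean-centred perturbation series: m rows x n wavenumber columns."""

    matrix: np.ndarray
    grid: np.ndarray
    temperatures_C: np.ndarray
    reference: str = "mean"
    ref_scale: float | None = None   # max |intensity| before centring

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ParameterError("dynamic spectra must be a 2-D matrix")
        if m.shape[0] < 3:
            raise DegenerateDataError("need >= 3 perturbation spectra")
        if m.shape[1] != np.asarray(self.grid).size:
            raise GridError("grid length does not match matrix columns")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "temperatures_C",
                           np.asarray(self.temperatures_C, dtype=float))

    @property
    def n_perturbations(self) -> int:
        return int(self.matrix.shape[0])


def dynamic_spectra(series: PerturbationSeries,
                    window: tuple[float, float] | None = None,
                    reference: str = "mean") -> DynamicSpectra:
    """Subtract the reference spectrum; optionally restrict to a window.

    ``reference`` is ``"mean"`` (series average, the common convention) or
    ``"first"`` (lowest-temperature spectrum).  ``window`` is an inclusive
    (lo, hi) wavenumber range in either order, e.g. the 1800-1250 and
    1250-850 cm^-1 regions.
    """
    Y = series.to_matrix()
    grid = series.grid
    if window is not None:
        lo, hi = sorted(float(v) for v in window)
        if lo < grid[0] - 1e-9 or hi > grid[-1] + 1e-9:
            raise RangeError(f"window ({lo:g}, {hi:g}) outside grid range")
        mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
        Y = Y[:, mask]
        grid = grid[mask]
    if reference == "mean":
        ref = Y.mean(axis=0)
    elif reference == "first":
        ref = Y[0]
    else:
        raise ParameterError(f"unknown reference {reference!r}")
    return DynamicSpectra(Y - ref, grid, series.temperatures_C, reference,
                          ref_scale=float(np.max(np.abs(Y))))


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """Discrete Hilbert-Noda transform matrix: antisymmetric, zero diagonal."""
    if m < 2:
        raise ParameterError("Hilbert-Noda matrix needs m >= 2")
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * (k - j))
    N[j == k] = 0.0
    return N


def synchronous_map(d: DynamicSpectra) -> np.ndarray:
    """Covariance map Phi; its diagonal is the per-wavenumber variance."""
    m = d.n_perturbations
    return d.matrix.T @ d.matrix / (m - 1)


def asynchronous_map(d: DynamicSpectra) -> np.ndarray:
    """Hilbert-Noda transformed map Psi (antisymmetric, zero diagonal)."""
    m = d.n_perturbations
    if m < 3:
        raise DegenerateDataError("asynchronous map is degenerate below 3 spectra")
    N = hilbert_noda_matrix(m)
    return d.matrix.T @ N @ d.matrix / (m - 1)


@dataclass(frozen=True)
class TwoDMaps:
    """Synchronous (Phi) and asynchronous (Psi) maps over one window."""

    phi: np.ndarray
    psi: np.ndarray
    grid: np.ndarray
    window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def compute(cls, d: DynamicSpectra,
                window: tuple[float, float] | None = None) -> "TwoDMaps":
        meta = {} if d.ref_scale is None else {"ref_scale": d.ref_scale}
        return cls(synchronous_map(d), asynchronous_map(d), d.grid, window,
                   meta)

    def validate(self, tol: float = 1e-10) -> None:
        """Assert the structural invariants of generalized 2D correlation."""
        scale = max(float(np.max(np.abs(self.phi))), 1.0)
        if np.max(np.abs(self.phi - self.phi.T)) >= tol * scale:
            raise AssertionError("synchronous map is not symmetric")
        if np.min(np.diag(self.phi)) < -tol * scale:
            raise AssertionError("synchronous diagonal has negative variance")
        if np.max(np.abs(self.psi + self.psi.T)) >= tol * scale:
            raise AssertionError("asynchronous map is not antisymmetric")
        if np.max(np.abs(np.diag(self.psi))) >= tol * scale:
            raise AssertionError("asynchronous diagonal is not zero")

    def index_of(self, wavenumber: float) -> int:
        i = int(np.argmin(np.abs(self.grid - wavenumber)))
        if abs(self.grid[i] - wavenumber) > 1e-6:
            raise RangeError(f"{wavenumber:g} cm^-1 is not on the map grid")
        return i


@dataclass(frozen=True)
class CrossPeakCall:
    """Sign-rule interpretation of one (v1, v2) cross peak."""

    nu1: float
    nu2: float
    phi: float
    psi: float
    coordination: str            # same_direction / opposite_direction / uncoordinated
    sequence: str                # "nu1 before nu2", "nu1 after nu2", "indeterminate"


def classify_cross_peak(maps: TwoDMaps, nu1: float, nu2: float,
                        eps: float | None = None) -> CrossPeakCall:
    """Apply Noda's sign rules at (nu1, nu2).

    Phi > 0: the two band intensities change in the same direction under the
    perturbation; Phi < 0: opposite directions; |Phi| below the magnitude
    floor: the variations are not coordinated and no cross peak is called.
    The sequence hint follows sign(Phi * Psi): positive means nu1 responds
    before nu2, negative after; |Psi| below the floor leaves it
    indeterminate.  ``eps`` defaults to 5% of max|Phi|.
    """
    if nu1 == nu2:
        raise ParameterError("cross peaks need two distinct wavenumbers")
    i = maps.index_of(nu1)
    j = maps.index_of(nu2)
    phi = float(maps.phi[i, j])
    psi = float(maps.psi[i, j])
    if eps is None:
        eps = 0.05 * float(np.max(np.abs(maps.phi)))
    if abs(phi) < eps:
        return CrossPeakCall(nu1, nu2, phi, psi, UNCOORDINATED, "indeterminate")
    coordination = SAME_DIRECTION if phi > 0 else OPPOSITE_DIRECTION
    if abs(psi) < eps:
        sequence = "indeterminate"
    elif phi * psi > 0:
        sequence = "nu1 before nu2"
    else:
        sequence = "nu1 after nu2"
    return CrossPeakCall(nu1, nu2, phi, psi, coordination, sequence)


def extract_auto_peaks(maps: TwoDMaps, min_prominence: float = 0.02) -> PeakTable:
    """Local maxima along the synchronous diagonal, ranked by height."""
    from scipy.signal import find_peaks

    diag = np.diag(maps.phi)
    span = float(np.max(diag) - np.min(diag))
    ref_scale = maps.meta.get("ref_scale")
    if ref_scale is not None and np.max(diag) < (1e-9 * ref_scale) ** 2:
        span = 0.0   # fluctuations at numerical-cancellation level
    if span == 0:
        empty = np.empty(0)
        return PeakTable(empty, empty.copy(), empty.copy(), "synchronous_diagonal")
    idx, props = find_peaks(diag, prominence=min_prominence * span)
    order = np.argsort(diag[idx])[::-1]
    return PeakTable(
        positions=maps.grid[idx][order],
        intensities=diag[idx][order],
        prominences=props["prominences"][order],
        source_mode="synchronous_diagonal",
    )


def write_map_csv(maps: TwoDMaps, phi_path, psi_path) -> None:
    """Export both maps as dense CSV with a wavenumber header row/column."""
    for M, path in ((maps.phi, phi_path), (maps.psi, psi_path)):
        df = pd.DataFrame(M, index=maps.grid, columns=maps.grid)
        df.index.name = "wavenumber_cm1"
        df.to_csv(path)
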