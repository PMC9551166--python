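"""Reading, writing, validation and standardisation of mid-IR spectra.

The package works on transmission FT-IR spectra recorded over the mid-infrared
region (4000-400 cm^-1).  Internally every spectrum is stored on a strictly
ascending wavenumber grid; the descending display convention of IR plots is a
rendering concern only.  Three intensity modes are distinguished:

``percent_transmittance``
    Raw instrument output, values in (0, 100].
``absorbance``
    Beer-Lambert scale, ``A = 2 - log10(%T)``.
``second_derivative``
    Savitzky-Golay second derivative of an absorbance spectrum (bands appear
    as minima).

File formats are deliberately plain: two-column CSV with optional ``#``
metadata headers, a JCAMP-DX 4.24 subset (AFFN and basic SQZ/DIF compression),
and a TSV manifest for collections and temperature-perturbation series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    GridError,
    ModeError,
    RangeError,
    SpectrumFormatError,
    SpectrumParseError,
)

MODE_TRANSMITTANCE = "percent_transmittance"
MODE_ABSORBANCE = "absorbance"
MODE_SECOND_DERIVATIVE = "second_derivative"
MODES = (MODE_TRANSMITTANCE, MODE_ABSORBANCE, MODE_SECOND_DERIVATIVE)

CLASS_LABELS = ("flower", "leaf", "seed", "query")


@dataclass(frozen=True)
class Spectrum:
    """One IR trace on a wavenumber grid.

    Wavenumbers are stored strictly ascending; a descending input grid is
    sorted (together with its intensities) on construction.  Duplicate
    wavenumbers and non-finite values are rejected.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    mode: str = MODE_ABSORBANCE
    sample_id: str = ""
    class_label: str | None = None
    temperature_C: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise SpectrumFormatError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise SpectrumFormatError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
            raise SpectrumFormatError("non-finite values in spectrum")
        order = np.argsort(w, kind="stable")
        w = w[order]
        y = y[order]
        if np.any(np.diff(w) == 0):
            dup = w[:-1][np.diff(w) == 0][0]
            raise SpectrumFormatError(f"duplicate wavenumber {dup:g} cm^-1")
        if self.mode not in MODES:
            raise ModeError(f"unknown intensity mode {self.mode!r}")
        if self.mode == MODE_TRANSMITTANCE and (np.any(y <= 0) or np.any(y > 100)):
            raise DomainError("percent transmittance must lie in (0, 100]")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        w.setflags(write=False)
        y.setflags(write=False)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def grid_spacing(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9 * abs(d[0])))

    def with_intensities(self, intensities: np.ndarray, mode: str | None = None,
                         **meta_updates) -> "Spectrum":
        """Copy with new intensities on the same grid (and optionally new mode)."""
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            mode=self.mode if mode is None else mode,
            meta=new_meta,
        )


@dataclass(frozen=True)
class PerturbationSeries:
    """Ordered spectra of one sample at strictly increasing temperatures.

    This is the input of generalized 2D correlation analysis; below three
    temperatures the asynchronous map is degenerate, so shorter series are
    rejected outright.
    """

    spectra: tuple
    temperatures_C: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        temps = np.asarray(self.temperatures_C, dtype=float)
        if len(spectra) < 3:
            raise SpectrumFormatError("a perturbation series needs >= 3 spectra")
        if temps.size != len(spectra):
            raise SpectrumFormatError("temperatures and spectra count differ")
        if np.any(np.diff(temps) <= 0):
            raise SpectrumFormatError("temperatures must be strictly increasing")
        grid = spectra[0].wavenumbers
        mode = spectra[0].mode
        for s in spectra[1:]:
            if len(s) != len(grid) or not np.array_equal(s.wavenumbers, grid):
                raise GridError("all spectra in a series must share one grid")
            if s.mode != mode:
                raise ModeError("all spectra in a series must share one mode")
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "temperatures_C", temps)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def mode(self) -> str:
        return self.spectra[0].mode

    def to_matrix(self) -> np.ndarray:
        """Stack the series as an (m temperatures x n wavenumbers) matrix."""
        return np.vstack([s.intensities for s in self.spectra])


@dataclass(frozen=True)
class SpectrumCollection:
    """Labelled spectra on a common grid (the chemometrics input)."""

    spectra: tuple
    labels: tuple

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        labels = tuple(self.labels)
        if not spectra:
            raise SpectrumFormatError("empty collection")
        if len(labels) != len(spectra):
            raise SpectrumFormatError("labels and spectra count differ")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if len(s) != len(grid) or not np.array_equal(s.wavenumbers, grid):
                raise GridError("all spectra in a collection must share one grid")
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def classes(self) -> tuple:
        """Distinct labels in first-occurrence (declared) order."""
        seen: list = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack([s.intensities for s in self.spectra])
        y = np.asarray(self.labels, dtype=object)
        return X, y

    def map(self, fn) -> "SpectrumCollection":
        """Apply ``fn`` to every spectrum, keeping labels."""
        return SpectrumCollection(tuple(fn(s) for s in self.spectra), self.labels)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("sample_id", "mode", "class", "temperature_C")


def read_spectrum_csv(path, mode: str | None = None) -> Spectrum:
    """Read a two-column ``wavenumber,intensity`` CSV.

    ``#``-prefixed header lines may carry metadata (``# sample_id=...``,
    ``# mode=...``, ``# class=...``, ``# temperature_C=...``).  An explicit
    ``mode`` argument overrides the file's metadata.  A single non-numeric
    first row is tolerated as a column header; any other non-numeric row is a
    parse error.
    """
    path = Path(path)
    meta: dict = {}
    w: list[float] = []
    y: list[float] = []
    header_allowed = True
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([\w.]+)\s*=\s*(.*)$", line)
                if m and m.group(1) in _META_KEYS:
                    meta[m.group(1)] = m.group(2).strip()
                continue
            parts = [p.strip() for p in re.split(r"[,\t;]", line) if p.strip()]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                w.append(float(parts[0]))
                y.append(float(parts[1]))
            except ValueError:
                if header_allowed and not w:
                    header_allowed = False
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(w) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    file_mode = meta.get("mode")
    use_mode = mode or file_mode or MODE_ABSORBANCE
    temp = meta.get("temperature_C")
    return Spectrum(
        wavenumbers=np.asarray(w),
        intensities=np.asarray(y),
        mode=use_mode,
        sample_id=meta.get("sample_id", path.stem),
        class_label=meta.get("class") or None,
        temperature_C=float(temp) if temp not in (None, "") else None,
        meta={"source": str(path)},
    )


def write_spectrum_csv(s: Spectrum, path) -> None:
    """Write a spectrum as CSV with metadata headers.

    Wavenumbers are written descending (the IR display convention); reading
    sorts them back, so a round trip reproduces the spectrum to < 1e-9.
    """
    path = Path(path)
    lines = [f"# sample_id={s.sample_id}", f"# mode={s.mode}"]
    if s.class_label is not None:
        lines.append(f"# class={s.class_label}")
    if s.temperature_C is not None:
        lines.append(f"# temperature_C={s.temperature_C:g}")
    lines.append("wavenumber_cm-1,intensity")
    for wv, it in zip(s.wavenumbers[::-1], s.intensities[::-1]):
        lines.append(f"{wv:.10g},{it:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JCAMP-DX subset
# ---------------------------------------------------------------------------

_SQZ = {c: v for v, c in zip(range(10), "@ABCDEFGHI")}
_SQZ.update({c: -v for v, c in zip(range(1, 10), "abcdefghi")})
_DIF = {c: v for v, c in zip(range(10), "%JKLMNOPQR")}
_DIF.update({c: -v for v, c in zip(range(1, 10), "jklmnopqrs")})
_TOKEN_RE = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?|[@A-Za-z%][0-9.]*")


def _decode_asdf_line(line: str) -> tuple[float, list[float]]:
    """Decode one ``X Y Y ...`` line in AFFN with optional SQZ/DIF digits.

    Returns (x_value, y_values).  DUP compression is rejected explicitly.
    """
    tokens = _TOKEN_RE.findall(line)
    if len(tokens) < 2:
        raise SpectrumFormatError(f"unparseable JCAMP data line: {line!r}")
    try:
        x = float(tokens[0])
    except ValueError:
        raise SpectrumFormatError(f"bad abscissa in JCAMP line: {line!r}") from None
    def _expand(digit: int, rest: str) -> float:
        sign = -1.0 if digit < 0 else 1.0
        return sign * float(f"{abs(digit)}{rest}" if rest else str(abs(digit)))

    ys: list[float] = []
    for tok in tokens[1:]:
        lead = tok[0]
        if lead in "STUVWXYZ":
            raise SpectrumFormatError(
                f"unsupported JCAMP compression (DUP digit {lead!r})"
            )
        if lead in _SQZ:
            ys.append(_expand(_SQZ[lead], tok[1:]))
        elif lead in _DIF:
            if not ys:
                raise SpectrumFormatError("DIF digit with no preceding ordinate")
            ys.append(ys[-1] + _expand(_DIF[lead], tok[1:]))
        else:
            try:
                ys.append(float(tok))
            except ValueError:
                raise SpectrumFormatError(
                    f"unsupported JCAMP token {tok!r}"
                ) from None
    return x, ys


def read_jcampdx(path) -> Spectrum:
    """Read a JCAMP-DX 4.24 spectrum (AFFN plus basic SQZ/DIF compression).

    Supports ``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)`` blocks with
    ``##XFACTOR``/``##YFACTOR`` scaling; the intensity mode is inferred from
    ``##YUNITS`` (TRANSMITTANCE -> percent_transmittance, ABSORBANCE ->
    absorbance).  Unknown compression (DUP) is rejected explicitly.
    """
    path = Path(path)
    records: dict[str, str] = {}
    data_lines: list[str] = []
    data_kind: str | None = None
    in_data = False
    for raw in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            in_data = False
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "").replace("-", "").replace("_", "")
            value = value.strip()
            records[label] = value
            if label == "XYDATA":
                data_kind = "xydata"
                in_data = True
            elif label == "XYPOINTS":
                data_kind = "xypoints"
                in_data = True
        elif in_data:
            data_lines.append(line.strip())
    if data_kind is None or not data_lines:
        raise SpectrumFormatError(f"{path}: no ##XYDATA or ##XYPOINTS block")

    xfactor = float(records.get("XFACTOR", "1") or 1)
    yfactor = float(records.get("YFACTOR", "1") or 1)
    yunits = records.get("YUNITS", "").upper()
    if "TRANSMIT" in yunits:
        mode = MODE_TRANSMITTANCE
    elif "ABSORB" in yunits:
        mode = MODE_ABSORBANCE
    else:
        mode = MODE_ABSORBANCE

    xs: list[float] = []
    ys: list[float] = []
    if data_kind == "xypoints":
        for line in data_lines:
            nums = re.findall(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?", line)
            if len(nums) % 2:
                raise SpectrumFormatError(f"{path}: odd value count in XYPOINTS line")
            for i in range(0, len(nums), 2):
                xs.append(float(nums[i]) * xfactor)
                ys.append(float(nums[i + 1]) * yfactor)
    else:
        # X++(Y..Y): abscissa of each subsequent Y advances by the grid step.
        rows = [_decode_asdf_line(line) for line in data_lines]
        npoints = int(float(records.get("NPOINTS", "0") or 0))
        firstx = float(records.get("FIRSTX", rows[0][0] * xfactor) or 0)
        lastx = float(records.get("LASTX", "0") or 0)
        total = sum(len(r[1]) for r in rows)
        if npoints and lastx and npoints > 1:
            step = (lastx - firstx) / (npoints - 1)
        elif len(rows) > 1 and len(rows[0][1]) > 0:
            step = (rows[1][0] - rows[0][0]) * xfactor / len(rows[0][1])
        else:
            step = xfactor
        x0 = firstx
        k = 0
        for _, yvals in rows:
            for yv in yvals:
                xs.append(x0 + k * step)
                ys.append(yv * yfactor)
                k += 1
        if npoints and total != npoints:
            raise SpectrumFormatError(
                f"{path}: NPOINTS={npoints} but decoded {total} ordinates"
            )
    if len(xs) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 points decoded")
    return Spectrum(
        wavenumbers=np.asarray(xs),
        intensities=np.asarray(ys),
        mode=mode,
        sample_id=records.get("TITLE", path.stem),
        meta={"source": str(path), "format": "jcamp-dx"},
    )


# ---------------------------------------------------------------------------
# Conversions / resampling / QC
# ---------------------------------------------------------------------------

def percent_transmittance_to_absorbance(s: Spectrum) -> Spectrum:
    """Beer-Lambert conversion ``A = 2 - log10(%T)``."""
    if s.mode != MODE_TRANSMITTANCE:
        raise ModeError(f"expected percent_transmittance input, got {s.mode}")
    if np.any(s.intensities <= 0):
        raise DomainError("nonpositive %T cannot be converted to absorbance")
    return s.with_intensities(2.0 - np.log10(s.intensities), mode=MODE_ABSORBANCE)


def absorbance_to_percent_transmittance(s: Spectrum) -> Spectrum:
    """Inverse Beer-Lambert conversion ``%T = 10^(2 - A)``.

    Negative absorbance (possible as noise around a zero baseline) would map
    above 100 %T, outside the physical range; such excursions are capped at
    100 the way a transmission instrument reports them.
    """
    if s.mode != MODE_ABSORBANCE:
        raise ModeError(f"expected absorbance input, got {s.mode}")
    pct = np.minimum(10.0 ** (2.0 - s.intensities), 100.0)
    return s.with_intensities(pct, mode=MODE_TRANSMITTANCE)


def resample_to_grid(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linear interpolation onto a target grid; extrapolation is refused."""
    grid = np.sort(np.asarray(grid, dtype=float))
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    if grid[0] < lo - 1e-12 or grid[-1] > hi + 1e-12:
        raise RangeError(
            f"target grid [{grid[0]:g}, {grid[-1]:g}] outside source range "
            f"[{lo:g}, {hi:g}]"
        )
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return replace(s, wavenumbers=grid, intensities=y,
                   meta={**s.meta, "resampled": True})


@dataclass(frozen=True)
class QCResult:
    """Acceptance verdict for a transmission spectrum."""

    accepted: bool
    max_percent_T: float
    min_percent_T: float
    reasons: tuple

    def __bool__(self) -> bool:
        return self.accepted


def qc_accept(s: Spectrum) -> QCResult:
    """Transmission-quality acceptance rule for a %T spectrum.

    Accept iff the achieved transmission reaches 60% (``max %T >= 60``) and
    the strongest band bottoms out between 10 and 30 %T (``min %T in
    [10, 30]``).  A too-strong pellet (min below 10) and a too-weak one (min
    above 30) are both rejected, with the failing clause reported.
    """
    if s.mode != MODE_TRANSMITTANCE:
        raise ModeError("qc_accept requires a percent_transmittance spectrum")
    tmax = float(np.max(s.intensities))
    tmin = float(np.min(s.intensities))
    reasons = []
    if tmax < 60.0:
        reasons.append(f"achieved transmission {tmax:.1f}% < 60%")
    if tmin < 10.0:
        reasons.append(f"strongest band at {tmin:.1f}%T below 10% (peak too strong)")
    elif tmin > 30.0:
        reasons.append(f"strongest band at {tmin:.1f}%T above 30% (peak too weak)")
    return QCResult(not reasons, tmax, tmin, tuple(reasons))


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def read_manifest(path) -> SpectrumCollection:
    """Read a collection manifest TSV with columns path/class/temperature_C/sample_id.

    Relative spectrum paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "path" not in df.columns:
        raise SpectrumFormatError(f"{path}: manifest needs a 'path' column")
    spectra = []
    labels = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        s = read_spectrum_csv(p)
        label = row.get("class", s.class_label)
        updates = {}
        if "sample_id" in df.columns and not pd.isna(row["sample_id"]):
            updates["sample_id"] = str(row["sample_id"])
        if "temperature_C" in df.columns and not pd.isna(row["temperature_C"]):
            updates["temperature_C"] = float(row["temperature_C"])
        if label is not None and not (isinstance(label, float) and pd.isna(label)):
            updates["class_label"] = str(label)
        if updates:
            s = replace(s, **updates)
        spectra.append(s)
        labels.append(s.class_label)
    return SpectrumCollection(tuple(spectra), tuple(labels))


def read_series_manifest(path) -> PerturbationSeries:
    """Read a perturbation-series manifest TSV (one spectrum per temperature)."""
    coll = read_manifest(path)
    temps = [s.temperature_C for s in coll.spectra]
    if any(t is None for t in temps):
        raise SpectrumFormatError("series manifest rows need temperature_C values")
    order = np.argsort(temps)
    return PerturbationSeries(
        spectra=tuple(coll.spectra[i] for i in order),
        temperatures_C=np.asarray(temps, dtype=float)[order],
    )


def write_collection(coll: SpectrumCollection, directory) -> Path:
    """Write each spectrum as CSV plus a ``manifest.tsv``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(coll.spectra):
        name = f"{s.sample_id or f'sample_{i:04d}'}.csv"
        write_spectrum_csv(s, directory / name)
        rows.append({
            "path": name,
            "class": s.class_label if s.class_label is not None else "",
            "temperature_C": "" if s.temperature_C is None else s.temperature_C,
            "sample_id": s.sample_id,
        })
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
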