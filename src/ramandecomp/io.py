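"""Reading, validating and writing Raman spectra as plain-text files.

A spectrum is a single wavenumber-indexed intensity trace.  The canonical
interchange format is two-column numeric text (CSV or TSV) with ``#``
comment lines carrying ``key: value`` metadata; JCAMP-DX files in the
uncompressed AFFN ``XYDATA=(X++(Y..Y))`` and ``XYPOINTS=(XY..XY)`` forms
are read-only.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Spectrum", "SpectrumParseError", "read_spectrum", "write_spectrum"]

#: decimal places used by :func:`write_spectrum`; round-trip precision contract
WRITE_PRECISION = 8


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed or validated."""


@dataclass
class Spectrum:
    """One Raman trace: intensity I(nu) on a strictly ascending cm^-1 axis.

    Parameters
    ----------
    wavenumber
        Raman shift axis in cm^-1, strictly increasing after construction
        (length >= 2; descending input is re-sorted, exact duplicates are
        collapsed by mean).
    intensity
        Intensity in arbitrary units, same length as the axis.
    meta
        Free-form acquisition metadata (sample id, replicate index, laser
        power in W, scan count, physical state ``solid``/``liquid`` ...).
        Transform provenance is appended under the ``history`` key.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise ValueError("wavenumber and intensity must be 1-D and equal length")
        if wn.size < 2:
            raise ValueError(f"spectrum needs >= 2 points, got {wn.size}")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(it))):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(wn) <= 0):
            order = np.argsort(wn, kind="stable")
            wn, it = wn[order], it[order]
            if np.any(np.diff(wn) == 0):
                wn, it = _collapse_duplicates(wn, it)
            if wn.size < 2:
                raise ValueError("fewer than 2 unique wavenumbers after collapse")
        self.wavenumber = wn
        self.intensity = it

    def __len__(self) -> int:
        return self.wavenumber.size

    @property
    def step(self) -> float:
        """Median axis spacing in cm^-1."""
        return float(np.median(np.diff(self.wavenumber)))

    def replace(self, intensity: np.ndarray | None = None, note: str | None = None) -> "Spectrum":
        """Copy with new intensities and an optional provenance note."""
        meta = dict(self.meta)
        if note:
            meta["history"] = list(meta.get("history", [])) + [note]
        return Spectrum(
            self.wavenumber.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            meta,
        )

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of the intensity onto ``grid`` (cm^-1)."""
        return np.interp(grid, self.wavenumber, self.intensity)


def _collapse_duplicates(wn: np.ndarray, it: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse, counts = np.unique(wn, return_inverse=True, return_counts=True)
    sums = np.zeros_like(uniq)
    np.add.at(sums, inverse, it)
    return uniq, sums / counts


# ---------------------------------------------------------------------------
# text dialects

_META_RE = re.compile(r"^#\s*([^:]+?)\s*:\s*(.*)$")


def _parse_meta_value(raw: str) -> Any:
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def _read_text(path: str, sep: str) -> Spectrum:
    meta: dict[str, Any] = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _META_RE.match(line)
                if m:
                    key, raw = m.group(1), m.group(2)
                    if key == "history":
                        meta.setdefault("history", []).append(raw)
                    else:
                        meta[key] = _parse_meta_value(raw)
                continue
            parts = [p for p in re.split(sep, line) if p != ""]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not xs:
        raise SpectrumParseError(f"{path}: no data rows")
    try:
        return Spectrum(np.array(xs), np.array(ys), meta)
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JCAMP-DX (uncompressed AFFN forms only)

_NUM_RE = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp(path: str) -> Spectrum:
    meta: dict[str, Any] = {}
    mode = None  # "xydata" | "xypoints"
    xfactor = yfactor = 1.0
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("$$")[0].rstrip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "XYDATA":
                    mode = "xydata"
                elif key == "XYPOINTS":
                    mode = "xypoints"
                elif key == "END":
                    mode = None
                elif value and key not in ("XYDATA", "XYPOINTS"):
                    meta[key.lower()] = _parse_meta_value(value)
                continue
            if mode is None:
                continue
            nums = [float(t) for t in _NUM_RE.findall(line)]
            if not nums:
                raise SpectrumParseError(f"{path}:{lineno}: unparseable data line {line!r}")
            if mode == "xydata":
                # (X++(Y..Y)): first number is the abscissa of the first Y
                x0, yvals = nums[0], nums[1:]
                if not yvals:
                    raise SpectrumParseError(f"{path}:{lineno}: XYDATA line without Y values")
                dx = meta.get("deltax")
                if dx is None:
                    last = meta.get("lastx", None)
                    first = meta.get("firstx", x0)
                    npoints = meta.get("npoints")
                    if last is not None and npoints and npoints > 1:
                        dx = (float(last) - float(first)) / (int(npoints) - 1)
                    else:
                        dx = 1.0
                for i, y in enumerate(yvals):
                    xs.append(x0 + i * float(dx))
                    ys.append(y)
            else:  # xypoints: alternating X, Y
                if len(nums) % 2:
                    raise SpectrumParseError(f"{path}:{lineno}: odd number of values in XYPOINTS")
                xs.extend(nums[0::2])
                ys.extend(nums[1::2])
    if not xs:
        raise SpectrumParseError(f"{path}: no XYDATA/XYPOINTS block")
    wn = np.array(xs) * xfactor
    it = np.array(ys) * yfactor
    keep = {k: v for k, v in meta.items() if k in ("title", "origin", "owner", "sampling procedure")}
    try:
        return Spectrum(wn, it, keep)
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# public API

_DIALECTS = {"csv": r"[,\s]+", "tsv": r"[\t\s]+"}


def read_spectrum(path: str | os.PathLike, dialect: str = "csv") -> Spectrum:
    """Read one spectrum.

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``"jcamp"``.  Text dialects accept
    ``#`` comment lines with ``key: value`` metadata; descending axes are
    re-sorted ascending and duplicate wavenumbers collapsed by mean.
    """
    path = os.fspath(path)
    if dialect == "jcamp":
        return _read_jcamp(path)
    try:
        sep = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use csv|tsv|jcamp") from None
    return _read_text(path, sep)


def write_spectrum(s: Spectrum, path: str | os.PathLike, precision: int = WRITE_PRECISION) -> str:
    """Write ``s`` as two-column CSV with ``#`` metadata header; returns path."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for key, value in s.meta.items():
            if key == "history":
                for note in value:
                    fh.write(f"# history: {note}\n")
            else:
                fh.write(f"# {key}: {value}\n")
        for x, y in zip(s.wavenumber, s.intensity):
            fh.write(f"{x:.{precision}f},{y:.{precision}f}\n")
    return path
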