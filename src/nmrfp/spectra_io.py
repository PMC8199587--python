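"""Reading, writing, calibrating and binning of 1-D frequency-domain NMR spectra.

A spectrum is a (ppm, intensity) trace for one serum sample and one pulse
sequence (NOESY 1D, CPMG or diffusion-edited).  The feature space of the
fingerprint classifier is obtained by calibrating the ppm axis to the
anomeric glucose doublet at 5.24 ppm, segmenting 0.2-10.0 ppm into 0.05 ppm
bins, integrating each bin, and dropping bins that overlap the configured
exclusion windows (residual water, ethanol contamination, noise trims).
With the default grid this yields 156 retained bins out of 196.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

try:  # Python >= 3.9
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

PULSE_SEQUENCES = ("NOESY", "CPMG", "Diffusion")

GLUCOSE_ANOMERIC_PPM = 5.24


@dataclass
class Spectrum:
    """One frequency-domain trace: strictly ascending ppm axis + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    pulse_seq: str = "NOESY"

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least two points")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending axis: reorder ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")
        if self.pulse_seq not in PULSE_SEQUENCES:
            raise ValueError(f"unknown pulse sequence {self.pulse_seq!r}")

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), self.sample_id, self.pulse_seq)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a two-column TSV with a header carrying sample id and pulse sequence."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={spectrum.sample_id}\tpulse_seq={spectrum.pulse_seq}\n")
        fh.write("ppm\tintensity\n")
        for p, v in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{p:.6f}\t{v:.8e}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Parse a two-column TSV spectrum file written by :func:`write_spectrum`.

    Malformed rows raise with the offending line number; a descending ppm axis
    is accepted and reordered ascending.
    """
    path = Path(path)
    sample_id, pulse_seq = "", "NOESY"
    ppm, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if tok.startswith("sample_id="):
                        sample_id = tok.split("=", 1)[1]
                    elif tok.startswith("pulse_seq="):
                        pulse_seq = tok.split("=", 1)[1]
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if cols and cols[0] == "ppm":
                continue
            if len(cols) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {len(cols)}")
            try:
                ppm.append(float(cols[0]))
                inten.append(float(cols[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    if len(ppm) < 2:
        raise ValueError(f"{path}: fewer than two data rows")
    return Spectrum(np.array(ppm), np.array(inten), sample_id=sample_id, pulse_seq=pulse_seq)


def calibrate_to_glucose(spectrum: Spectrum, search_halfwidth: float = 0.1) -> Spectrum:
    """Rigidly shift the ppm axis so the window maximum sits on the glucose
    anomeric doublet position (5.24 ppm).

    The maximum-intensity point within 5.24 +/- ``search_halfwidth`` is taken
    as the doublet apex; intensities are untouched.  A window that is empty or
    flat triggers a warning and the spectrum is returned unshifted.
    """
    lo = GLUCOSE_ANOMERIC_PPM - search_halfwidth
    hi = GLUCOSE_ANOMERIC_PPM + search_halfwidth
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not mask.any():
        warnings.warn("glucose search window empty; spectrum left uncalibrated")
        return spectrum.copy()
    win = spectrum.intensity[mask]
    if np.ptp(win) == 0:
        warnings.warn("glucose search window flat; spectrum left uncalibrated")
        return spectrum.copy()
    apex = spectrum.ppm[mask][np.argmax(win)]
    shift = GLUCOSE_ANOMERIC_PPM - apex
    out = spectrum.copy()
    out.ppm = out.ppm + shift
    return out


def calibration_shift(spectrum: Spectrum, search_halfwidth: float = 0.1) -> float:
    """The rigid shift :func:`calibrate_to_glucose` would apply (0 if flat)."""
    calibrated = calibrate_to_glucose(spectrum, search_halfwidth)
    return float(calibrated.ppm[0] - spectrum.ppm[0])


@dataclass
class BinGrid:
    """Uniform chemical-shift binning grid with exclusion windows.

    Defaults: 0.2-10.0 ppm at 0.05 ppm width (196 raw bins) with exclusion
    windows removing residual water, sporadic ethanol contamination and the
    noisy spectral edges -- 40 bins, leaving 156.
    """

    lo: float = 0.2
    hi: float = 10.0
    width: float = 0.05
    exclusions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hi <= self.lo or self.width <= 0:
            raise ValueError("require lo < hi and width > 0")
        n = (self.hi - self.lo) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(hi - lo) / width must be an integer number of bins")
        self.exclusions = [(float(a), float(b)) for a, b in self.exclusions]
        for a, b in self.exclusions:
            if not (self.lo <= a < b <= self.hi):
                raise ValueError(f"exclusion window ({a}, {b}) outside grid range")
        ordered = sorted(self.exclusions)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 < b1:
                raise ValueError("exclusion windows overlap")

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.n_bins + 1)

    def retained_mask(self) -> np.ndarray:
        """Boolean mask over raw bins; a bin overlapping any exclusion is dropped."""
        e = self.edges()
        keep = np.ones(self.n_bins, dtype=bool)
        tol = 1e-9  # edges touching a window boundary do not count as overlap
        for a, b in self.exclusions:
            keep &= ~((e[:-1] < b - tol) & (e[1:] > a + tol))
        return keep

    def retained_edges(self) -> list[tuple[float, float]]:
        e = self.edges()
        keep = self.retained_mask()
        return [(float(e[i]), float(e[i + 1])) for i in np.nonzero(keep)[0]]

    @classmethod
    def default(cls) -> "BinGrid":
        return default_bin_grid()


def _load_default_grid_config() -> dict:
    cfg_text = (_pkg_files("nmrfp") / "data" / "binning.yaml").read_text()
    return yaml.safe_load(cfg_text)


def default_bin_grid() -> BinGrid:
    """The packaged default grid (config-defined exclusion windows)."""
    cfg = _load_default_grid_config()
    return BinGrid(
        lo=cfg["lo"],
        hi=cfg["hi"],
        width=cfg["width"],
        exclusions=[tuple(w["window"]) for w in cfg["exclusions"]],
    )


def trapezoid_window_integral(spectrum: Spectrum, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """Exact trapezoidal integrals of the piecewise-linear spectrum over windows.

    Window endpoints need not coincide with grid points; the cumulative
    trapezoid is evaluated at arbitrary positions by linear interpolation of
    the intensity at the cut point.
    """
    x, y = spectrum.ppm, spectrum.intensity
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))])

    def F(pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        idx = np.clip(np.searchsorted(x, pos, side="right"), 1, len(x) - 1)
        x0, y0 = x[idx - 1], y[idx - 1]
        ypos = y0 + (y[idx] - y0) * (pos - x0) / (x[idx] - x0)
        return cum[idx - 1] + 0.5 * (y0 + ypos) * (pos - x0)

    windows = np.asarray(windows, dtype=float)
    return F(windows[:, 1]) - F(windows[:, 0])


def bin_spectrum(spectrum: Spectrum, grid: BinGrid | None = None) -> np.ndarray:
    """Integrate a calibrated spectrum over the retained bins of ``grid``.

    Bins are half-open [lo, hi) on the ascending axis (the last bin closed);
    since the integral is insensitive to single points this only fixes the
    bookkeeping convention.  Raises if the spectrum does not cover the grid.
    """
    grid = grid or default_bin_grid()
    if spectrum.ppm[0] > grid.lo or spectrum.ppm[-1] < grid.hi:
        raise ValueError(
            f"spectrum covers [{spectrum.ppm[0]:.3f}, {spectrum.ppm[-1]:.3f}] ppm "
            f"but the grid needs [{grid.lo}, {grid.hi}]"
        )
    return trapezoid_window_integral(spectrum, grid.retained_edges())


@dataclass
class BinnedMatrix:
    """Samples x retained-bins matrix with bookkeeping for edges and ids."""

    values: np.ndarray
    bin_edges: list[tuple[float, float]]
    sample_ids: list[str]
    pulse_seq: str
    calibration_shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.bin_edges)):
            raise ValueError("values shape inconsistent with sample_ids / bin_edges")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{a:.2f}-{b:.2f}" for a, b in self.bin_edges]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = f"sample_id[{self.pulse_seq}]"
        df.to_csv(path)


def assemble_matrix(
    spectra: Sequence[Spectrum],
    grid: BinGrid | None = None,
    calibrate: bool = True,
    search_halfwidth: float = 0.1,
) -> BinnedMatrix:
    """Calibrate and bin a set of same-pulse-sequence spectra into one matrix.

    Rows follow input order; per-sample calibration shifts are recorded on the
    returned matrix.  Duplicate sample ids or mixed pulse sequences raise.
    """
    if not spectra:
        raise ValueError("no spectra given")
    grid = grid or default_bin_grid()
    seqs = {s.pulse_seq for s in spectra}
    if len(seqs) > 1:
        raise ValueError(f"mixed pulse sequences: {sorted(seqs)}")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")
    rows, shifts = [], []
    for s in spectra:
        if calibrate:
            cal = calibrate_to_glucose(s, search_halfwidth)
            shifts.append(float(cal.ppm[0] - s.ppm[0]))
        else:
            cal = s
            shifts.append(0.0)
        rows.append(bin_spectrum(cal, grid))
    return BinnedMatrix(
        values=np.vstack(rows),
        bin_edges=grid.retained_edges(),
        sample_ids=ids,
        pulse_seq=spectra[0].pulse_seq,
        calibration_shifts=np.array(shifts),
    )
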