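"""Topographic-prominence peak detection and band-intensity extraction.

Peaks are local maxima ranked by topographic prominence: the height of a
peak above the higher of the two lowest saddles separating it from
higher terrain (or from the signal ends).  Mean spectra of the two
classes are compared at a stated prominence floor (0.01 for the
transfected/control comparison, 0.05 for the cell-line survey), and
band intensities are read off as the maximum normalized intensity inside
a band window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .spectra import Band, Spectrum

__all__ = [
    "Peak",
    "PeakList",
    "find_peaks",
    "band_window_mask",
    "band_intensity",
    "compare_peak_presence",
]

#: extraction half-window for point bands, cm⁻¹
DEFAULT_HALF_WINDOW = 4.0

#: matching tolerance for peak-presence comparison, cm⁻¹
DEFAULT_MATCH_TOL = 5.0


@dataclass(frozen=True)
class Peak:
    channel: int
    wavenumber: float
    height: float
    prominence: float
    left_base: int
    right_base: int


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]
    prominence_threshold: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array([p.wavenumber for p in self.peaks])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber": [p.wavenumber for p in self.peaks],
                "height": [p.height for p in self.peaks],
                "prominence": [p.prominence for p in self.peaks],
            }
        )


def find_peaks(s: Spectrum, prominence_min: float) -> PeakList:
    """All local maxima with topographic prominence >= ``prominence_min``.

    Plateau maxima are reported at the leftmost plateau channel
    (deterministic tie-break).  Prominence is computed with windows
    extending to the signal ends, so an isolated peak on flat terrain has
    prominence equal to its height above that terrain.
    """
    if prominence_min <= 0:
        raise ValueError("prominence_min must be > 0")
    y = s.intensities
    if y.size < 3:
        raise ValueError("need at least 3 channels to find peaks")
    idx, props = scipy.signal.find_peaks(
        y, prominence=prominence_min, plateau_size=(1, None)
    )
    peaks = []
    for k in range(idx.size):
        ch = int(props["left_edges"][k])  # leftmost plateau channel
        peaks.append(
            Peak(
                channel=ch,
                wavenumber=float(s.wavenumbers[ch]),
                height=float(y[ch]),
                prominence=float(props["prominences"][k]),
                left_base=int(props["left_bases"][k]),
                right_base=int(props["right_bases"][k]),
            )
        )
    return PeakList(tuple(peaks), prominence_threshold=prominence_min)


def band_window_mask(
    wavenumbers: np.ndarray,
    band: Band,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> np.ndarray:
    """Boolean channel mask of a band's extraction window.

    Point bands (lo == hi) are expanded by ``half_window`` on both sides;
    range bands use their printed range as-is.
    """
    if band.is_point:
        lo, hi = band.lo - half_window, band.hi + half_window
    else:
        lo, hi = band.lo, band.hi
    mask = (wavenumbers >= lo) & (wavenumbers <= hi)
    if not np.any(mask):
        if hi < wavenumbers[0] or lo > wavenumbers[-1]:
            raise ValueError(
                f"band {band.name!r} window ({lo}, {hi}) lies outside axis "
                f"[{wavenumbers[0]}, {wavenumbers[-1]}]"
            )
        # band narrower than the channel spacing: snap to nearest channel
        mask[np.argmin(np.abs(wavenumbers - band.center))] = True
    return mask


def band_intensity(
    s: Spectrum, band: Band, half_window: float = DEFAULT_HALF_WINDOW
) -> float:
    """Maximum intensity inside the band's extraction window."""
    mask = band_window_mask(s.wavenumbers, band, half_window)
    return float(np.max(s.intensities[mask]))


def compare_peak_presence(
    mean_a: Spectrum,
    mean_b: Spectrum,
    prominence_min: float,
    match_tol: float = DEFAULT_MATCH_TOL,
) -> pd.DataFrame:
    """Flag peaks of two mean spectra as shared or unique to one class.

    Peaks whose centers differ by at most ``match_tol`` cm⁻¹ are matched
    greedily in order of increasing distance.  Returns a table with
    columns ``wavenumber_a, wavenumber_b, wavenumber, flag`` where flag
    is ``shared``, ``unique_a`` or ``unique_b``.
    """
    if not np.array_equal(mean_a.wavenumbers, mean_b.wavenumbers):
        raise ValueError("mean spectra must share one wavenumber axis")
    pa = find_peaks(mean_a, prominence_min)
    pb = find_peaks(mean_b, prominence_min)
    wa, wb = pa.wavenumbers, pb.wavenumbers
    pairs = [
        (abs(x - y), i, j)
        for i, x in enumerate(wa)
        for j, y in enumerate(wb)
        if abs(x - y) <= match_tol
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for dist, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append(
            {
                "wavenumber_a": wa[i],
                "wavenumber_b": wb[j],
                "wavenumber": 0.5 * (wa[i] + wb[j]),
                "flag": "shared",
            }
        )
    for i, x in enumerate(wa):
        if i not in used_a:
            rows.append(
                {
                    "wavenumber_a": x,
                    "wavenumber_b": np.nan,
                    "wavenumber": x,
                    "flag": "unique_a",
                }
            )
    for j, y in enumerate(wb):
        if j not in used_b:
            rows.append(
                {
                    "wavenumber_a": np.nan,
                    "wavenumber_b": y,
                    "wavenumber": y,
                    "flag": "unique_b",
                }
            )
    df = pd.DataFrame(
        rows, columns=["wavenumber_a", "wavenumber_b", "wavenumber", "flag"]
    )
    return df.sort_values("wavenumber", ignore_index=True)
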