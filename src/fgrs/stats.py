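"""Group summaries, the double-SD channel rule, rank-sum tests, Cohen's d.

For two labelled groups of preprocessed spectra the module computes
per-channel mean ± SD summaries, the absolute difference spectrum
|mean_a − mean_b|, and selects classification channels by the double-SD
rule: a channel is kept when its absolute mean difference exceeds
``multiplier`` (default 2) times a standard deviation threshold.  The
default threshold is the across-channel SD of the absolute-difference
spectrum, i.e. one horizontal line over the whole fingerprint; a
per-channel pooled-SD variant is available behind ``mode``.

Per-band group differences are tested with the two-sided Mann–Whitney
U test (exact enumeration for small samples, normal approximation with
tie correction otherwise) and sized with pooled-SD Cohen's d:

    d = (mean_x − mean_y) / s_p,
    s_p² = ((n_x − 1) s_x² + (n_y − 1) s_y²) / (n_x + n_y − 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .peaks import DEFAULT_HALF_WINDOW, band_window_mask
from .spectra import Band, BandPanel, SpectraSet, Spectrum

__all__ = [
    "GroupSummary",
    "FeatureMask",
    "BandStatRow",
    "group_mean_sd",
    "abs_diff_spectrum",
    "double_sd_mask",
    "mann_whitney_u",
    "cohens_d",
    "significance_stars",
    "band_intensity_samples",
    "band_stats_table",
    "band_stats_frame",
]

#: largest per-group sample size for which the exact rank-sum null is used
EXACT_RANKSUM_MAX_N = 8


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: Spectrum
    sd: np.ndarray  # per-channel sample SD (n-1 denominator)
    n: int


@dataclass(frozen=True)
class FeatureMask:
    mask: np.ndarray  # boolean per channel
    threshold_value: float
    multiplier: float

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.mask))

    def to_frame(self, wavenumbers: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber": wavenumbers, "selected": self.mask.astype(int)}
        )


@dataclass(frozen=True)
class BandStatRow:
    band: Band
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_stat: float
    p_value: float
    d: float  # signed; magnitude reported in tables
    stars: str


def group_mean_sd(sset: SpectraSet, label: str) -> GroupSummary:
    """Per-channel mean and sample SD of all spectra carrying ``label``."""
    grp = sset.select_label(label)
    if grp.n_spectra < 2:
        raise ValueError(
            f"label {label!r}: need >= 2 spectra for a group summary"
        )
    mean = grp.intensities.mean(axis=0)
    sd = grp.intensities.std(axis=0, ddof=1)
    return GroupSummary(
        label=label,
        mean=Spectrum(grp.wavenumbers, mean, sample_id=f"mean[{label}]"),
        sd=sd,
        n=grp.n_spectra,
    )


def abs_diff_spectrum(a: GroupSummary, b: GroupSummary) -> Spectrum:
    """Absolute value of the spectral difference of the group means."""
    if not np.array_equal(a.mean.wavenumbers, b.mean.wavenumbers):
        raise ValueError("group summaries are on different axes")
    return Spectrum(
        a.mean.wavenumbers,
        np.abs(a.mean.intensities - b.mean.intensities),
        sample_id=f"absdiff[{a.label},{b.label}]",
    )


def double_sd_mask(
    a: GroupSummary,
    b: GroupSummary,
    multiplier: float = 2.0,
    mode: str = "scalar",
) -> FeatureMask:
    """Channels whose |mean difference| exceeds an SD-based threshold.

    ``mode="scalar"`` (default): one threshold for all channels,
    ``multiplier`` x the across-channel sample SD of the
    absolute-difference spectrum — the single horizontal cut-off line.
    ``mode="per_channel"``: channelwise ``multiplier`` x pooled
    between-group SD.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    diff = abs_diff_spectrum(a, b).intensities
    if mode == "scalar":
        threshold = multiplier * float(np.std(diff, ddof=1))
        mask = diff > threshold
        return FeatureMask(mask=mask, threshold_value=threshold,
                           multiplier=multiplier)
    if mode == "per_channel":
        pooled = np.sqrt(
            ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        )
        mask = diff > multiplier * pooled
        return FeatureMask(
            mask=mask,
            threshold_value=float(multiplier * np.median(pooled)),
            multiplier=multiplier,
        )
    raise ValueError("mode must be 'scalar' or 'per_channel'")


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns ``(U_x, p)``.

    U is assigned from midranks.  The exact permutation null is used when
    both samples have at most ``EXACT_RANKSUM_MAX_N`` observations and no
    ties are present; otherwise the normal approximation with continuity
    and tie correction.  ``U_x + U_y == n_x * n_y`` always.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = max(x.size, y.size) <= EXACT_RANKSUM_MAX_N and not has_ties
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Signed pooled-SD Cohen's d of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Cohen's d needs >= 2 observations per sample")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if not sp2 > 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def significance_stars(p: float) -> str:
    """``***`` p <= 1e-3, ``**`` p <= 1e-2, ``*`` p < 0.05, else empty."""
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def band_intensity_samples(
    sset: SpectraSet,
    band: Band,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> np.ndarray:
    """Per-spectrum band intensity (window maximum), vectorized."""
    mask = band_window_mask(sset.wavenumbers, band, half_window)
    return sset.intensities[:, mask].max(axis=1)


def band_stats_table(
    sset: SpectraSet,
    labels: tuple[str, str],
    panel: BandPanel,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> list[BandStatRow]:
    """One :class:`BandStatRow` per panel band for the two labelled groups."""
    la, lb = labels
    a = sset.select_label(la)
    b = sset.select_label(lb)
    rows = []
    for band in panel:
        xa = band_intensity_samples(a, band, half_window)
        xb = band_intensity_samples(b, band, half_window)
        u, p = mann_whitney_u(xa, xb)
        d = cohens_d(xa, xb)
        rows.append(
            BandStatRow(
                band=band,
                mean_a=float(xa.mean()),
                sd_a=float(xa.std(ddof=1)),
                mean_b=float(xb.mean()),
                sd_b=float(xb.std(ddof=1)),
                u_stat=u,
                p_value=p,
                d=d,
                stars=significance_stars(p),
            )
        )
    return rows


def band_stats_frame(rows: list[BandStatRow]) -> pd.DataFrame:
    """Flatten band-stat rows to the exported CSV layout (|d| reported)."""
    return pd.DataFrame(
        {
            "band": [r.band.name for r in rows],
            "assignment": [r.band.assignment for r in rows],
            "mean_a": [r.mean_a for r in rows],
            "sd_a": [r.sd_a for r in rows],
            "mean_b": [r.mean_b for r in rows],
            "sd_b": [r.sd_b for r in rows],
            "U": [r.u_stat for r in rows],
            "p": [r.p_value for r in rows],
            "d_abs": [abs(r.d) for r in rows],
            "stars": [r.stars for r in rows],
        }
    )
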