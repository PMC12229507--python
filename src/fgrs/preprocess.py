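"""Spectral preprocessing: crop, AsLS baseline, despike, normalize.

The pipeline applied to every spectrum, in this fixed order:

1. crop to the fingerprint region (default 400–1800 cm⁻¹);
2. asymmetric-least-squares (AsLS) baseline removal — iteratively solve
   for the baseline z minimizing  Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σⱼ (Δ² z)ⱼ²
   with wᵢ = p where yᵢ > zᵢ and 1 − p otherwise, so the smooth baseline
   hugs the fluorescence background from below while ignoring peaks;
3. cosmic-ray removal — a spike is a local maximum whose topographic
   prominence exceeds the amide I reference intensity (the maximum of the
   baseline-corrected signal inside the amide I window, default
   1640–1680 cm⁻¹) and whose width at half prominence spans at most
   ``max_width_channels`` channels; spikes are replaced by linear
   interpolation across their bases, and the pass repeats until no spike
   remains (idempotent);
4. normalization to the greatest spectral intensity (max = 1); unit-L2
   normalization is available behind ``normalize="l2"``.

Despiking runs on the baseline-corrected, pre-normalization scale so the
amide threshold is evaluated in the same units as the spike heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal
import scipy.sparse

from .spectra import SpectraSet, Spectrum

__all__ = [
    "AslsConfig",
    "CosmicRayConfig",
    "PreprocessConfig",
    "crop_fingerprint",
    "asls_baseline",
    "asls_correct",
    "remove_cosmic_rays",
    "normalize_max",
    "normalize_l2",
    "preprocess_set",
]


@dataclass(frozen=True)
class AslsConfig:
    """AsLS smoothness/asymmetry parameters.

    ``lam`` is the second-difference penalty weight (larger = stiffer
    baseline), ``asym_p`` the asymmetry weight given to points above the
    baseline.  Defaults are the standard choice for fingerprint Raman.
    """

    lam: float = 1e5
    asym_p: float = 0.01
    max_iter: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.asym_p < 1:
            raise ValueError("asym_p must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class CosmicRayConfig:
    amide_window: tuple[float, float] = (1640.0, 1680.0)
    max_width_channels: int = 3
    max_passes: int = 10

    def __post_init__(self) -> None:
        if self.max_width_channels < 1:
            raise ValueError("max_width_channels must be >= 1")


@dataclass(frozen=True)
class PreprocessConfig:
    crop: tuple[float, float] = (400.0, 1800.0)
    asls: AslsConfig = field(default_factory=AslsConfig)
    cosmic: CosmicRayConfig = field(default_factory=CosmicRayConfig)
    normalize: str = "max"  # "max" | "l2" | "off"

    def __post_init__(self) -> None:
        if not self.crop[0] < self.crop[1]:
            raise ValueError("crop lo must be < hi")
        if self.normalize not in ("max", "l2", "off"):
            raise ValueError("normalize must be 'max', 'l2' or 'off'")


def crop_fingerprint(s: Spectrum, lo: float = 400.0, hi: float = 1800.0) -> Spectrum:
    """Retain exactly the channels with ``lo <= wavenumber <= hi``."""
    if not lo < hi:
        raise ValueError("crop lo must be < hi")
    keep = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not np.any(keep):
        raise ValueError(
            f"crop ({lo}, {hi}) leaves no channel of axis "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return Spectrum(
        s.wavenumbers[keep], s.intensities[keep], s.sample_id, s.label
    )


# ---------------------------------------------------------------------------
# AsLS baseline


def _second_diff_penalty_bands(n: int) -> np.ndarray:
    """Upper banded form (3, n) of D₂ᵀD₂ for solveh_banded."""
    D = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    P = (D.T @ D).todia()
    ab = np.zeros((3, n))
    offsets = {int(o): i for i, o in enumerate(P.offsets)}
    data = P.data
    ab[0, 2:] = data[offsets[2]][2:]   # second superdiagonal
    ab[1, 1:] = data[offsets[1]][1:]   # first superdiagonal
    ab[2, :] = data[offsets[0]]        # main diagonal
    return ab


def asls_baseline(
    y: np.ndarray, cfg: AslsConfig = AslsConfig()
) -> tuple[np.ndarray, int]:
    """AsLS baseline of ``y``; returns ``(baseline, n_iterations)``.

    Solves the banded, symmetric positive-definite normal equations
    ``(W + λ D₂ᵀD₂) z = W y`` with Cholesky-banded factorization, updating
    the asymmetric weights until the mean absolute weight change falls
    below ``tol`` or ``max_iter`` is reached.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("AsLS needs a 1-D signal of length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("AsLS input contains non-finite values")
    n = y.size
    pen = cfg.lam * _second_diff_penalty_bands(n)
    w = np.ones(n)
    z = y
    it = 0
    for it in range(1, cfg.max_iter + 1):
        ab = pen.copy()
        ab[2, :] += w
        z = scipy.linalg.solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, cfg.asym_p, 1.0 - cfg.asym_p)
        delta = float(np.mean(np.abs(w_new - w)))
        w = w_new
        if delta <= cfg.tol:
            break
    return z, it


def asls_correct(
    s: Spectrum, cfg: AslsConfig = AslsConfig()
) -> tuple[Spectrum, Spectrum]:
    """Baseline-correct a spectrum; returns ``(corrected, baseline)``."""
    z, _ = asls_baseline(s.intensities, cfg)
    return s.with_intensities(s.intensities - z), s.with_intensities(z)


# ---------------------------------------------------------------------------
# Cosmic-ray removal


def _amide_reference(s: Spectrum, window: tuple[float, float]) -> float:
    """Spike-robust amide I reference: window max of the 3-point median.

    A cosmic ray landing inside the amide window would otherwise inflate
    the reference above its own prominence and mask itself; a 3-point
    median erases single-channel spikes while leaving the broad amide
    band (several channels wide) essentially intact.
    """
    lo, hi = window
    sel = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not np.any(sel):
        raise ValueError(
            f"amide window ({lo}, {hi}) does not intersect the axis"
        )
    smoothed = scipy.signal.medfilt(s.intensities, kernel_size=3)
    return float(np.max(smoothed[sel]))


def remove_cosmic_rays(
    s: Spectrum, cfg: CosmicRayConfig = CosmicRayConfig()
) -> tuple[Spectrum, int]:
    """Remove sharp spikes towering above the amide I reference intensity.

    A spike is a local maximum with topographic prominence greater than
    the amide I reference (max corrected intensity in ``amide_window``)
    and width at half prominence of at most ``max_width_channels``
    channels.  Spikes are replaced by linear interpolation between their
    prominence bases; passes repeat until none remain, so the operation
    is idempotent.  Returns ``(cleaned, n_removed)``.
    """
    y = s.intensities.copy()
    n_removed = 0
    for _ in range(cfg.max_passes):
        ref = _amide_reference(s.with_intensities(y), cfg.amide_window)
        peaks, props = scipy.signal.find_peaks(y, prominence=ref * (1 + 1e-12))
        if peaks.size == 0:
            break
        widths, _, left_ips, right_ips = scipy.signal.peak_widths(
            y, peaks, rel_height=0.5,
            prominence_data=(
                props["prominences"], props["left_bases"], props["right_bases"]
            ),
        )
        sharp = widths <= cfg.max_width_channels
        if not np.any(sharp):
            break
        for k in np.nonzero(sharp)[0]:
            # repair only the spike's actual extent (its half-prominence
            # feet), so a spike riding on a Raman band does not take the
            # band apex with it
            lb = int(np.floor(left_ips[k]))
            rb = int(np.ceil(right_ips[k]))
            lb = max(min(lb, int(peaks[k]) - 1), 0)
            rb = min(max(rb, int(peaks[k]) + 1), y.size - 1)
            inside = np.arange(lb + 1, rb)
            y[inside] = np.interp(
                inside, [lb, rb], [y[lb], y[rb]]
            )
            n_removed += 1
    return s.with_intensities(y), n_removed


# ---------------------------------------------------------------------------
# Normalization


def normalize_max(s: Spectrum) -> Spectrum:
    """Divide by the greatest spectral intensity so that max(out) == 1."""
    m = float(np.max(s.intensities))
    if not m > 0:
        raise ValueError(
            f"spectrum {s.sample_id!r}: non-positive maximum, cannot normalize"
        )
    return s.with_intensities(s.intensities / m)


def normalize_l2(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm (alternative reading of the protocol)."""
    nrm = float(np.linalg.norm(s.intensities))
    if not nrm > 0:
        raise ValueError(f"spectrum {s.sample_id!r}: zero norm")
    return s.with_intensities(s.intensities / nrm)


# ---------------------------------------------------------------------------
# Whole-set pipeline


def preprocess_set(
    sset: SpectraSet, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[SpectraSet, list[dict]]:
    """Crop, baseline, despike and normalize every spectrum of a set.

    Returns the processed set and a per-spectrum log of
    ``{"sample_id", "n_cosmic_removed", "asls_iterations"}``.
    """
    if sset.n_spectra == 0:
        raise ValueError("cannot preprocess an empty SpectraSet")
    out: list[Spectrum] = []
    log: list[dict] = []
    for s in sset:
        try:
            c = crop_fingerprint(s, *cfg.crop)
            z, n_iter = asls_baseline(c.intensities, cfg.asls)
            corrected = c.with_intensities(c.intensities - z)
            cleaned, n_removed = remove_cosmic_rays(corrected, cfg.cosmic)
            if cfg.normalize == "max":
                final = normalize_max(cleaned)
            elif cfg.normalize == "l2":
                final = normalize_l2(cleaned)
            else:
                final = cleaned
        except ValueError as exc:
            raise ValueError(f"sample {s.sample_id!r}: {exc}") from exc
        out.append(final)
        log.append(
            {
                "sample_id": s.sample_id,
                "n_cosmic_removed": n_removed,
                "asls_iterations": n_iter,
            }
        )
    return SpectraSet.from_spectra(out, label_set=sset.label_set), log
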