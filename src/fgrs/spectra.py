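"""Domain types and tabular I/O for single-cell Raman spectra.

A :class:`Spectrum` is one acquired trace: an ascending wavenumber axis
(Raman shift, cm⁻¹) with one intensity per channel (arbitrary units).  A
:class:`SpectraSet` collects spectra that share one axis, with optional
class labels (e.g. ``"high"`` / ``"low"`` Cx43 content).  Spectra are
exchanged as plain delimited text in two dialects:

``wide``
    first column ``wavenumber``, one column per spectrum (labels dropped);
``long``
    columns ``sample_id, wavenumber, intensity, label``.

A :class:`BandPanel` names the Raman shifts of interest with their
molecular assignment; point shifts are encoded as ``lo == hi``, reported
ranges (e.g. 752–760 cm⁻¹) as ``lo < hi``.  The default panel bundled
with the package covers the classic fingerprint bands (glycogen 480,
cytochrome c 746–750, tryptophan 752–760, phenylalanine 1003, amide
III/II/I, CH₂/CH₃ deformation 1449–1452, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "Band",
    "BandPanel",
    "AxisMismatchError",
    "SpectraParseError",
    "read_spectra_table",
    "write_spectra_table",
    "load_band_panel",
    "default_band_panel",
    "validate_spectra_set",
]


class AxisMismatchError(ValueError):
    """Spectra placed on a shared axis do not agree channel-for-channel."""


class SpectraParseError(ValueError):
    """A spectra table could not be parsed (bad cell, missing column...)."""


def _check_axis(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 channels")
    if not np.all(np.isfinite(values)):
        raise ValueError("wavenumber axis contains non-finite values")
    if not np.all(np.diff(values) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return values


@dataclass(frozen=True)
class Spectrum:
    """One Raman spectrum on an ascending wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = "s0"
    label: str | None = None

    def __post_init__(self) -> None:
        wn = _check_axis(self.wavenumbers)
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != wn.shape:
            raise ValueError(
                f"spectrum {self.sample_id!r}: {y.size} intensities for "
                f"{wn.size} wavenumbers"
            )
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass
class SpectraSet:
    """Spectra on one shared axis, stored row-wise as a matrix."""

    wavenumbers: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_channels)
    sample_ids: list[str]
    labels: list[str | None]
    label_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = _check_axis(self.wavenumbers)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        n, m = self.intensities.shape
        if m != self.wavenumbers.size:
            raise AxisMismatchError(
                f"intensity matrix has {m} channels, axis has "
                f"{self.wavenumbers.size}"
            )
        if len(self.sample_ids) != n:
            raise ValueError("one sample_id required per spectrum")
        if len(self.labels) != n:
            raise ValueError("one label entry required per spectrum")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[Spectrum],
        label_set: tuple[str, ...] | None = None,
    ) -> "SpectraSet":
        if not spectra:
            raise ValueError("cannot build a SpectraSet from zero spectra")
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != axis.shape or not np.array_equal(
                s.wavenumbers, axis
            ):
                raise AxisMismatchError(
                    f"spectrum {s.sample_id!r} is on a different wavenumber axis"
                )
        return cls(
            wavenumbers=axis.copy(),
            intensities=np.vstack([s.intensities for s in spectra]),
            sample_ids=[s.sample_id for s in spectra],
            labels=[s.label for s in spectra],
            label_set=label_set,
        )

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            self.wavenumbers,
            self.intensities[i],
            sample_id=self.sample_ids[i],
            label=self.labels[i],
        )

    def __iter__(self) -> Iterable[Spectrum]:
        return (self.spectrum(i) for i in range(self.n_spectra))

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            label_set=self.label_set,
        )

    def select_label(self, label: str) -> "SpectraSet":
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        if not idx:
            raise ValueError(f"no spectra carry label {label!r}")
        return self.subset(idx)

    def concat(self, other: "SpectraSet") -> "SpectraSet":
        if not np.array_equal(self.wavenumbers, other.wavenumbers):
            raise AxisMismatchError("cannot concatenate sets on different axes")
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=np.vstack([self.intensities, other.intensities]),
            sample_ids=self.sample_ids + other.sample_ids,
            labels=self.labels + other.labels,
            label_set=self.label_set or other.label_set,
        )


# ---------------------------------------------------------------------------
# Bands


@dataclass(frozen=True)
class Band:
    """A named Raman shift (point) or shift range with its assignment."""

    name: str
    lo: float
    hi: float
    assignment: str = "other"

    _ASSIGNMENTS = ("protein", "nucleic_acid", "lipid", "other")

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"band {self.name!r}: lo {self.lo} > hi {self.hi}")
        if self.assignment not in self._ASSIGNMENTS:
            raise ValueError(
                f"band {self.name!r}: assignment {self.assignment!r} not one of "
                f"{self._ASSIGNMENTS}"
            )

    @property
    def is_point(self) -> bool:
        return self.lo == self.hi

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class BandPanel:
    """Ordered collection of uniquely named bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate band names: {dupes}")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]


# ---------------------------------------------------------------------------
# I/O


def read_spectra_table(path: str | Path, dialect: str = "wide") -> SpectraSet:
    """Read a delimited spectra table (``wide`` or ``long`` dialect)."""
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2:
            raise SpectraParseError(f"{path}: wide table needs >= 2 columns")
        body = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(body.isna().values)
        if bad.size:
            r, c = bad[0]
            raise SpectraParseError(
                f"{path}: non-numeric cell at data row {r + 1}, "
                f"column {df.columns[c]!r}"
            )
        axis = body.iloc[:, 0].to_numpy()
        spectra = [
            Spectrum(axis, body[col].to_numpy(), sample_id=str(col))
            for col in df.columns[1:]
        ]
        return SpectraSet.from_spectra(spectra)
    if dialect == "long":
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "label": str},
            float_precision="round_trip",
        )
        required = {"sample_id", "wavenumber", "intensity"}
        if not required.issubset(df.columns):
            raise SpectraParseError(
                f"{path}: long table needs columns {sorted(required)}"
            )
        for col in ("wavenumber", "intensity"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().idxmax())
                raise SpectraParseError(
                    f"{path}: non-numeric {col!r} at data row {row + 1}"
                )
            df[col] = vals
        has_label = "label" in df.columns
        spectra = []
        axis = None
        # groupby(sort=False) keeps first-appearance order as spectrum order
        for sid, grp in df.groupby("sample_id", sort=False):
            wn = grp["wavenumber"].to_numpy()
            if axis is None:
                axis = wn
            elif wn.shape != axis.shape or not np.array_equal(wn, axis):
                raise AxisMismatchError(
                    f"{path}: sample {sid!r} is on a different wavenumber axis"
                )
            label = None
            if has_label:
                lab = grp["label"].iloc[0]
                label = None if pd.isna(lab) else str(lab)
            spectra.append(
                Spectrum(wn, grp["intensity"].to_numpy(), sample_id=str(sid),
                         label=label)
            )
        if not spectra:
            raise SpectraParseError(f"{path}: empty long table")
        return SpectraSet.from_spectra(spectra)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectra_table(
    sset: SpectraSet, path: str | Path, dialect: str = "wide"
) -> Path:
    """Write a :class:`SpectraSet` as delimited text; round-trips losslessly."""
    path = Path(path)
    if sset.n_spectra == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    if dialect == "wide":
        df = pd.DataFrame({"wavenumber": sset.wavenumbers})
        for i, sid in enumerate(sset.sample_ids):
            df[sid] = sset.intensities[i]
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    if dialect == "long":
        n, m = sset.intensities.shape
        df = pd.DataFrame(
            {
                "sample_id": np.repeat(sset.sample_ids, m),
                "wavenumber": np.tile(sset.wavenumbers, n),
                "intensity": sset.intensities.ravel(),
                "label": np.repeat(
                    [lab if lab is not None else "" for lab in sset.labels], m
                ),
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


def load_band_panel(path: str | Path) -> BandPanel:
    """Load a band panel CSV with columns ``name, lo, hi, assignment``."""
    df = pd.read_csv(path)
    required = {"name", "lo", "hi", "assignment"}
    if not required.issubset(df.columns):
        raise SpectraParseError(
            f"{path}: band panel needs columns {sorted(required)}"
        )
    bands = tuple(
        Band(
            name=str(row["name"]),
            lo=float(row["lo"]),
            hi=float(row["hi"]),
            assignment=str(row["assignment"]),
        )
        for _, row in df.iterrows()
    )
    return BandPanel(bands)


def default_band_panel() -> BandPanel:
    """The packaged fingerprint band panel (19 bands, 480–1660 cm⁻¹)."""
    with resources.as_file(
        resources.files("fgrs").joinpath("data/band_panel.csv")
    ) as p:
        return load_band_panel(p)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class Violation:
    sample_id: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_spectra_set(sset: SpectraSet) -> ValidationReport:
    """Report per-spectrum violations; empty report iff the set is valid.

    Pure: never mutates its input.  Checks non-finite intensities, missing
    labels and labels outside the declared ``label_set``.
    """
    report = ValidationReport()
    for i, sid in enumerate(sset.sample_ids):
        row = sset.intensities[i]
        if not np.all(np.isfinite(row)):
            n_bad = int(np.sum(~np.isfinite(row)))
            report.violations.append(
                Violation(sid, f"{n_bad} non-finite intensity value(s)")
            )
        lab = sset.labels[i]
        if sset.label_set is not None:
            if lab is None:
                report.violations.append(Violation(sid, "missing class label"))
            elif lab not in sset.label_set:
                report.violations.append(
                    Violation(
                        sid,
                        f"label {lab!r} outside declared set {sset.label_set}",
                    )
                )
    return report
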