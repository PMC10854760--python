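"""Core spectrum data model, normalization, and pre-similarity filtering.

An MS/MS spectrum is a precursor m/z plus a peak list of fragment
(m/z, intensity) pairs.  All operations here keep peak lists strictly
ascending in m/z; duplicate m/z values are merged by summing intensity
when a spectrum is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumLibrary",
    "FilterConfig",
    "normalize",
    "filter_spectrum",
    "inchikey14",
]


class Peak(NamedTuple):
    """A single fragment peak: m/z in Thomson, non-negative intensity."""

    mz: float
    intensity: float


def _prepare_peaks(mz, intensities):
    mz = np.asarray(mz, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if mz.shape != intensities.shape or mz.ndim != 1:
        raise ValueError("mz and intensities must be 1-D arrays of equal length")
    if mz.size and np.any(mz <= 0):
        raise ValueError("all m/z values must be positive")
    if intensities.size and np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")
    order = np.argsort(mz, kind="stable")
    mz, intensities = mz[order], intensities[order]
    # merge exact duplicate m/z by summing intensity so downstream code
    # always sees a strictly ascending grid
    if mz.size > 1 and np.any(np.diff(mz) == 0):
        unique_mz, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(unique_mz)
        np.add.at(summed, inverse, intensities)
        mz, intensities = unique_mz, summed
    mz.setflags(write=False)
    intensities.setflags(write=False)
    return mz, intensities


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum with sorted fragment peaks.

    Parameters
    ----------
    precursor_mz
        m/z of the ion selected for fragmentation (Th); ``None`` when the
        source record carried no precursor.
    mz, intensities
        Fragment peak arrays; sorted ascending and duplicate-merged on
        construction.
    identifier
        Opaque unique id within a library (MGF TITLE / MSP Name).
    inchikey
        Full InChIKey when known; ``None`` otherwise.
    normalized
        Which intensity normalization has been applied: ``"none"``,
        ``"max"`` or ``"sum"``.
    scheme
        Provenance tag naming the weighting scheme applied, if any.
    """

    precursor_mz: Optional[float]
    mz: np.ndarray
    intensities: np.ndarray
    identifier: str = ""
    inchikey: Optional[str] = None
    normalized: str = "none"
    scheme: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        mz, intensities = _prepare_peaks(self.mz, self.intensities)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", intensities)

    def __len__(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensities)]

    def with_intensities(self, intensities, *, normalized=None, scheme=None,
                         mz=None) -> "Spectrum":
        """Copy of this spectrum with replaced peak intensities."""
        return replace(
            self,
            mz=self.mz if mz is None else mz,
            intensities=np.asarray(intensities, dtype=float),
            normalized=self.normalized if normalized is None else normalized,
            scheme=self.scheme if scheme is None else scheme,
        )


@dataclass
class SpectrumLibrary:
    """An ordered collection of spectra with unique identifiers."""

    spectra: list[Spectrum]
    source: str = ""

    def __post_init__(self):
        ids = [s.identifier for s in self.spectra]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate spectrum identifier: {dup!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.spectra:
                if s.identifier == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]


def normalize(spectrum: Spectrum, mode: str = "max") -> Spectrum:
    """Scale intensities by the spectrum maximum (``max``) or total (``sum``).

    Idempotent: normalizing an already-normalized spectrum is a no-op
    up to floating point.
    """
    if mode not in ("max", "sum"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if len(spectrum) == 0 or not np.any(spectrum.intensities > 0):
        raise ValueError("cannot normalize a spectrum with no positive intensity")
    denom = spectrum.intensities.max() if mode == "max" else spectrum.intensities.sum()
    return spectrum.with_intensities(spectrum.intensities / denom, normalized=mode)


@dataclass(frozen=True)
class FilterConfig:
    """Pre-similarity filtering rules.

    Defaults mimic common preprocessing for small-molecule library
    benchmarks; every threshold is configurable and any rule can be
    disabled by setting it to ``None`` (or ``min_peaks=0``).
    """

    precursor_exclusion: Optional[float] = 1.5   # Da around the precursor
    min_relative_intensity: Optional[float] = 0.001  # fraction of base peak
    min_peaks: int = 5
    require_precursor: bool = True


def filter_spectrum(spectrum: Spectrum, rules: FilterConfig = FilterConfig()):
    """Apply peak/spectrum filters; return the filtered spectrum or ``None``.

    Rules, in order: drop peaks near the precursor, drop peaks below the
    relative-intensity floor, reject spectra with too few remaining
    peaks, reject spectra lacking a precursor m/z.  Rejection is a value
    (``None``), not an error.
    """
    if rules.require_precursor and spectrum.precursor_mz is None:
        return None
    mz, inten = spectrum.mz, spectrum.intensities
    if rules.precursor_exclusion is not None and spectrum.precursor_mz is not None:
        keep = np.abs(mz - spectrum.precursor_mz) > rules.precursor_exclusion
        mz, inten = mz[keep], inten[keep]
    if rules.min_relative_intensity is not None and inten.size and inten.max() > 0:
        keep = inten >= rules.min_relative_intensity * inten.max()
        mz, inten = mz[keep], inten[keep]
    if mz.size < rules.min_peaks:
        return None
    return spectrum.with_intensities(inten, mz=mz)


def inchikey14(key: str) -> str:
    """First 14 characters of an InChIKey (the 2D-connectivity block)."""
    if key is None or len(key) < 14:
        raise ValueError(f"InChIKey too short for a 14-character prefix: {key!r}")
    return key[:14].upper()
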