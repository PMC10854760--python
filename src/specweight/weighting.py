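"""Intensity-weighting transforms applied to spectra before scoring.

Four families are implemented:

* classic power-law weighting ``I^n * (m/z)^m`` (Sokolow, Stein & Scott,
  Horai, Kim parameterizations, plus intensity-only ``m=0``);
* frequency-aware weighting ``(I / I_max)^n * f(m/z)^q`` where f is the
  relative occurrence frequency of the peak's m/z bin in a reference
  library — the max-normalization makes low peaks compete on relative
  rather than raw intensity, and common m/z values are weighted up;
* entropy-conditional weighting: spectra with spectral entropy S < 3
  nats get intensities raised to the power 0.25 (1 + S), spectra with
  S >= 3 pass through unchanged (continuous at the boundary, where the
  exponent reaches 1);
* binarization (every surviving peak gets intensity 1).

Weighting never moves or merges peaks; only intensities change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .frequency import FrequencyTable
from .spectra import Spectrum

__all__ = [
    "WeightScheme",
    "SCHEMES",
    "classic_weight",
    "frequency_weight",
    "entropy_weight",
    "binarize",
    "apply_scheme",
    "get_scheme",
]


@dataclass(frozen=True)
class WeightScheme:
    """A named weighting parameterization.

    Exactly one mode is active: ``classic`` (intensity exponent ``n``
    and m/z exponent ``m``), ``frequency`` (``n`` plus a frequency
    exponent, with per-spectrum max-normalization), ``entropy``, or
    ``binarize``.  ``none`` passes spectra through untouched.
    """

    name: str
    mode: str  # none | classic | frequency | entropy | binarize
    intensity_exponent: float = 1.0
    mz_exponent: float = 0.0
    frequency_exponent: float = 0.25

    def __post_init__(self):
        if self.mode not in ("none", "classic", "frequency", "entropy", "binarize"):
            raise ValueError(f"unknown weighting mode {self.mode!r}")

    @property
    def needs_table(self) -> bool:
        return self.mode == "frequency"


#: Registry of the weighting parameterizations benchmarked here.
SCHEMES: dict[str, WeightScheme] = {
    s.name: s
    for s in (
        WeightScheme("unweighted", "none"),
        WeightScheme("sokolow", "classic", intensity_exponent=0.5, mz_exponent=0.5),
        WeightScheme("stein_scott", "classic", intensity_exponent=0.6, mz_exponent=3.0),
        WeightScheme("horai", "classic", intensity_exponent=0.5, mz_exponent=2.0),
        WeightScheme("kim", "classic", intensity_exponent=0.53, mz_exponent=1.3),
        WeightScheme("intensity_only", "classic", intensity_exponent=0.5, mz_exponent=0.0),
        WeightScheme("proposed", "frequency", intensity_exponent=0.25,
                     frequency_exponent=0.25),
        WeightScheme("proposed_intensity", "frequency", intensity_exponent=0.25,
                     frequency_exponent=0.0),
        WeightScheme("entropy", "entropy"),
        WeightScheme("binarized", "binarize"),
    )
}


def get_scheme(name: str) -> WeightScheme:
    """Look up a preset, or parse ``custom:n=…,m=…`` into a classic scheme."""
    if name in SCHEMES:
        return SCHEMES[name]
    if name.startswith("custom:"):
        params = {}
        for token in name[len("custom:"):].split(","):
            key, _, value = token.partition("=")
            params[key.strip()] = float(value)
        return WeightScheme(
            name, "classic",
            intensity_exponent=params.get("n", 1.0),
            mz_exponent=params.get("m", 0.0),
        )
    raise KeyError(f"unknown weighting scheme {name!r}; "
                   f"presets: {', '.join(sorted(SCHEMES))}")


def classic_weight(spectrum: Spectrum, n: float, m: float) -> Spectrum:
    """Power-law weighting ``I^n * (m/z)^m`` on raw intensities."""
    if np.any(spectrum.intensities < 0):
        raise ValueError("negative intensities cannot be weighted")
    weighted = spectrum.intensities ** n * spectrum.mz ** m
    return spectrum.with_intensities(weighted, normalized="none")


def frequency_weight(
    spectrum: Spectrum,
    table: FrequencyTable,
    n: float = 0.25,
    freq_exp: float = 0.25,
) -> Spectrum:
    """Frequency-aware weighting ``(I / I_max)^n * f(m/z)^freq_exp``.

    ``I_max`` is the maximum intensity of the input spectrum, so the
    result is invariant to rescaling the raw intensities.
    """
    if len(spectrum) == 0 or spectrum.intensities.max() <= 0:
        raise ValueError("spectrum has no positive intensity to normalize by")
    rel = spectrum.intensities / spectrum.intensities.max()
    freqs = np.array([table.lookup(mz) for mz in spectrum.mz])
    weighted = rel ** n * freqs ** freq_exp
    return spectrum.with_intensities(weighted, normalized="none")


def spectral_entropy(spectrum: Spectrum) -> float:
    """Shannon entropy (nats) of the sum-normalized intensities."""
    if len(spectrum) == 0:
        raise ValueError("spectral entropy of an empty spectrum is undefined")
    total = spectrum.intensities.sum()
    if total <= 0:
        raise ValueError("spectrum is not sum-normalizable")
    p = spectrum.intensities / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def entropy_weight(spectrum: Spectrum) -> Spectrum:
    """Entropy-conditional reweighting of low-entropy spectra.

    S >= 3 nats: unchanged.  S < 3: intensities raised to the power
    0.25 (1 + S).  The exponent reaches 1 exactly at S = 3, so the
    transform is continuous across the branch point.
    """
    s = spectral_entropy(spectrum)
    if s >= 3.0:
        return spectrum.with_intensities(spectrum.intensities)
    exponent = 0.25 * (1.0 + s)
    return spectrum.with_intensities(spectrum.intensities ** exponent,
                                     normalized="none")


def binarize(spectrum: Spectrum) -> Spectrum:
    """Set every positive-intensity peak to 1; drop zero-intensity peaks."""
    keep = spectrum.intensities > 0
    return spectrum.with_intensities(
        np.ones(int(keep.sum())), mz=spectrum.mz[keep], normalized="none")


def apply_scheme(
    spectrum: Spectrum,
    scheme: WeightScheme | str,
    table: Optional[FrequencyTable] = None,
) -> Spectrum:
    """Dispatch a spectrum through the named weighting scheme.

    The result carries a ``scheme`` provenance tag.  Frequency-mode
    schemes require a built :class:`FrequencyTable`.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if scheme.mode == "none":
        out = spectrum.with_intensities(spectrum.intensities)
    elif scheme.mode == "classic":
        out = classic_weight(spectrum, scheme.intensity_exponent, scheme.mz_exponent)
    elif scheme.mode == "frequency":
        if table is None:
            raise ValueError(
                f"scheme {scheme.name!r} needs an m/z frequency table")
        out = frequency_weight(spectrum, table, scheme.intensity_exponent,
                               scheme.frequency_exponent)
    elif scheme.mode == "entropy":
        out = entropy_weight(spectrum)
    else:
        out = binarize(spectrum)
    return out.with_intensities(out.intensities, scheme=scheme.name)
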