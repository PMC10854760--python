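"""Tolerance-based peak matching and matched-peak similarity metrics.

Peak matching pairs fragments of two spectra whose m/z values agree
within a tolerance (direct matches) and, for the modified cosine, also
fragments whose m/z difference equals the precursor mass difference
(shifted matches) — the signature of a shared substructure carrying a
single modification.  Candidate pairs are accepted greedily in
descending order of intensity product, each peak used at most once,
mirroring mainstream implementations; an exhaustive optimal assignment
exists only as a test oracle.

Metrics accept spectra that have already been weighted.  Cosine-type
metrics consume the weighted intensities directly (norms over all
peaks); probability-type metrics (entropy, fidelity, Bhattacharyya)
sum-renormalize first so weighted intensities form a distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .spectra import Spectrum
from .weighting import spectral_entropy

__all__ = [
    "PeakMatch",
    "MatchResult",
    "SimilarityScore",
    "match_peaks",
    "cosine_score",
    "modified_cosine",
    "spectral_entropy",
    "entropy_similarity",
    "fidelity_similarity",
    "bhattacharya1_similarity",
    "register_metric",
    "available_metrics",
    "score_pair",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 0.1  # Th; fragment-level matching tolerance


@dataclass(frozen=True)
class PeakMatch:
    index_a: int
    index_b: int
    kind: str  # direct | shifted


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[PeakMatch, ...]
    tolerance: float
    precursor_diff: Optional[float]


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    metric: str
    scheme: Optional[str] = None
    n_matches: int = 0

    def __float__(self) -> float:
        return self.value


def match_peaks(
    a: Spectrum,
    b: Spectrum,
    tolerance: float = DEFAULT_TOLERANCE,
    allow_shift: bool = False,
) -> MatchResult:
    """Greedy one-to-one peak matching between two spectra.

    Candidates are all peak pairs with ``|mz_a - mz_b| <= tolerance``
    plus, when ``allow_shift``, pairs with
    ``|(mz_a - mz_b) - (prec_a - prec_b)| <= tolerance``.  Candidates
    are accepted in descending order of intensity product; ties break on
    smaller match residual, then smaller indices.  A pair satisfying
    both rules is recorded once, as direct.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot match peaks of an empty spectrum")
    precursor_diff = None
    if allow_shift:
        if a.precursor_mz is None or b.precursor_mz is None:
            raise ValueError("shifted matching requires precursor m/z on both spectra")
        precursor_diff = a.precursor_mz - b.precursor_mz

    diff = a.mz[:, None] - b.mz[None, :]
    prod = a.intensities[:, None] * b.intensities[None, :]

    direct = np.abs(diff) <= tolerance
    candidates = []  # (-product, residual, i, j, kind)
    for i, j in zip(*np.nonzero(direct)):
        candidates.append((-prod[i, j], abs(diff[i, j]), int(i), int(j), "direct"))
    if allow_shift:
        shifted = (np.abs(diff - precursor_diff) <= tolerance) & ~direct
        for i, j in zip(*np.nonzero(shifted)):
            candidates.append((-prod[i, j], abs(diff[i, j] - precursor_diff),
                               int(i), int(j), "shifted"))
    candidates.sort(key=lambda c: c[:4])

    used_a, used_b = set(), set()
    matches = []
    for _, _, i, j, kind in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(PeakMatch(i, j, kind))
    return MatchResult(tuple(matches), tolerance, precursor_diff)


def _cosine_from_matches(a: Spectrum, b: Spectrum, result: MatchResult,
                         metric: str) -> SimilarityScore:
    norm_a = float(np.linalg.norm(a.intensities))
    norm_b = float(np.linalg.norm(b.intensities))
    if norm_a == 0 or norm_b == 0:
        raise ValueError("cosine similarity of a zero-norm spectrum is undefined")
    num = sum(a.intensities[m.index_a] * b.intensities[m.index_b]
              for m in result.matches)
    value = float(np.clip(num / (norm_a * norm_b), 0.0, 1.0))
    return SimilarityScore(value, metric, a.scheme, len(result.matches))


def cosine_score(a: Spectrum, b: Spectrum,
                 tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Cosine similarity over directly matched peaks.

    Numerator sums intensity products of matched pairs; the norms run
    over all peaks of each spectrum, so unmatched peaks pull the score
    down.
    """
    result = match_peaks(a, b, tolerance, allow_shift=False)
    return _cosine_from_matches(a, b, result, "cosine")


def modified_cosine(a: Spectrum, b: Spectrum,
                    tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Cosine similarity whose matching also admits precursor-shifted pairs."""
    result = match_peaks(a, b, tolerance, allow_shift=True)
    return _cosine_from_matches(a, b, result, "modified_cosine")


def _probability_vectors(a: Spectrum, b: Spectrum):
    ta, tb = a.intensities.sum(), b.intensities.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("spectrum is not sum-normalizable")
    return a.intensities / ta, b.intensities / tb


def entropy_similarity(a: Spectrum, b: Spectrum,
                       tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Spectral-entropy similarity of two sum-normalized spectra.

    A merged half-weight mixture is built from the match: each matched
    pair contributes one atom (p_a + p_b)/2, each unmatched peak an atom
    at half its probability.  The similarity is
    ``1 - (2 S_AB - S_A - S_B) / ln 4``, which is 1 for identical
    spectra and 0 for fully disjoint ones.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("entropy similarity of an empty spectrum is undefined")
    p, q = _probability_vectors(a, b)
    result = match_peaks(a, b, tolerance, allow_shift=False)
    matched_a = {m.index_a for m in result.matches}
    matched_b = {m.index_b for m in result.matches}
    merged = [(p[m.index_a] + q[m.index_b]) / 2 for m in result.matches]
    merged += [p[i] / 2 for i in range(len(a)) if i not in matched_a]
    merged += [q[j] / 2 for j in range(len(b)) if j not in matched_b]
    merged = np.asarray(merged)
    merged = merged[merged > 0]
    s_ab = float(-np.sum(merged * np.log(merged)))
    s_a = spectral_entropy(a)
    s_b = spectral_entropy(b)
    value = 1.0 - (2.0 * s_ab - s_a - s_b) / np.log(4.0)
    return SimilarityScore(float(np.clip(value, 0.0, 1.0)), "entropy",
                           a.scheme, len(result.matches))


def _fidelity(a: Spectrum, b: Spectrum, tolerance: float):
    p, q = _probability_vectors(a, b)
    result = match_peaks(a, b, tolerance, allow_shift=False)
    f = sum(np.sqrt(p[m.index_a] * q[m.index_b]) for m in result.matches)
    return float(np.clip(f, 0.0, 1.0)), len(result.matches)


def fidelity_similarity(a: Spectrum, b: Spectrum,
                        tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Bhattacharyya coefficient Σ √(p·q) over matched, sum-normalized peaks."""
    f, n = _fidelity(a, b, tolerance)
    return SimilarityScore(f, "fidelity", a.scheme, n)


def bhattacharya1_similarity(a: Spectrum, b: Spectrum,
                             tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Squared-arccos Bhattacharyya distance mapped to a [0, 1] similarity.

    D = (arccos F)² with F the fidelity coefficient; the similarity is
    1 - D / (π/2)² so F=1 maps to 1 and F=0 (disjoint spectra) to 0.
    """
    f, n = _fidelity(a, b, tolerance)
    d = np.arccos(f) ** 2
    value = 1.0 - d / (np.pi / 2) ** 2
    return SimilarityScore(float(np.clip(value, 0.0, 1.0)), "bhattacharya_1",
                           a.scheme, n)


_METRICS: dict[str, Callable[..., SimilarityScore]] = {
    "cosine": cosine_score,
    "modified_cosine": modified_cosine,
    "entropy": entropy_similarity,
    "fidelity": fidelity_similarity,
    "bhattacharya_1": bhattacharya1_similarity,
}


def register_metric(name: str, func: Callable[..., SimilarityScore]) -> None:
    """Add a matched-peak metric ``func(a, b, tolerance)`` to the registry."""
    if name in _METRICS:
        raise ValueError(f"metric {name!r} is already registered")
    _METRICS[name] = func


def available_metrics() -> list[str]:
    return sorted(_METRICS)


def score_pair(a: Spectrum, b: Spectrum, metric: str = "modified_cosine",
               tolerance: float = DEFAULT_TOLERANCE) -> SimilarityScore:
    """Score a spectrum pair with a registered metric by name."""
    if metric not in _METRICS:
        raise KeyError(f"unknown metric {metric!r}; "
                       f"available: {', '.join(available_metrics())}")
    out = _METRICS[metric](a, b, tolerance)
    if not isinstance(out, SimilarityScore):
        out = SimilarityScore(float(out), metric, a.scheme)
    return out
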