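"""Evaluation harnesses: alignment-vs-structure benchmarking and library search.

Two tasks are covered.

*Spectral alignment*: pairs of spectra with a known structural
similarity (Tanimoto coefficient of the source molecules' fingerprints)
are scored with a metric; pairs with Tanimoto > 0.7 are the positive
class, and the harness reports the score cutoff maximizing the F-beta
score, contingency tables at that cutoff, and the KL divergence between
the score distribution and the Tanimoto distribution.

*Library search*: each query spectrum is scored against all reference
spectra inside a precursor ppm window and hits are ranked; true
positives share the query's first-14 InChIKey characters.  Reported:
precision@K, AUC-ROC, and no-match query counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .frequency import FrequencyTable
from .spectra import Spectrum, SpectrumLibrary, inchikey14
from .similarity import DEFAULT_TOLERANCE, score_pair
from .weighting import WeightScheme, apply_scheme

__all__ = [
    "BenchmarkPair",
    "SearchHit",
    "EvalReport",
    "tanimoto",
    "label_pairs",
    "optimal_cutoff",
    "contingency",
    "kl_to_reference",
    "library_search",
    "precision_at_k",
    "auc_roc",
    "count_no_match_queries",
    "dominant_peak_profile",
    "evaluate_alignment",
]


@dataclass(frozen=True)
class BenchmarkPair:
    """Two spectra plus the structural similarity of their molecules."""

    spectrum_a: Spectrum
    spectrum_b: Spectrum
    tanimoto: float
    stratum: str = ""

    def __post_init__(self):
        if not 0.0 <= self.tanimoto <= 1.0:
            raise ValueError("tanimoto coefficient must lie in [0, 1]")


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    library_id: str
    score: float
    delta_ppm: float
    is_true_positive: Optional[bool]


@dataclass
class EvalReport:
    """Per-metric evaluation tables, serializable to JSON."""

    tables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.tables)


def tanimoto(fp_a: Sequence[int], fp_b: Sequence[int]) -> float:
    """Jaccard similarity of two equal-length bit vectors.

    Defined as 1.0 when both vectors are all-zero (identical empty
    fingerprints).
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return int(np.sum(a & b)) / union


def label_pairs(pairs: Sequence[BenchmarkPair], threshold: float = 0.7,
                boundary_positive: bool = False) -> np.ndarray:
    """Binary labels: 1 iff tanimoto > threshold (strictly, by default)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    t = np.array([p.tanimoto for p in pairs])
    return (t >= threshold).astype(int) if boundary_positive else (t > threshold).astype(int)


def _fbeta(tp, fp, fn, beta):
    b2 = beta * beta
    denom = (1 + b2) * tp + b2 * fn + fp
    return np.where(denom > 0, (1 + b2) * tp / np.maximum(denom, 1e-300), 0.0)


def optimal_cutoff(scores, labels, beta: float = 1.0) -> tuple[float, float]:
    """Score cutoff maximizing the F-beta score (score >= cutoff → positive).

    Candidate cutoffs are the observed unique scores plus a 0.01-step
    grid on [0, 1]; ties resolve to the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("optimal_cutoff needs both classes present")
    candidates = np.unique(np.concatenate([scores, np.round(np.arange(0, 101) * 0.01, 2)]))
    pred = scores[None, :] >= candidates[:, None]
    pos = labels == 1
    tp = (pred & pos[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~pos[None, :]).sum(axis=1).astype(float)
    fn = (~pred & pos[None, :]).sum(axis=1).astype(float)
    f = _fbeta(tp, fp, fn, beta)
    best = int(np.argmax(f))  # argmax returns the first (lowest) maximizer
    return float(candidates[best]), float(f[best])


def contingency(scores, labels, cutoff: float) -> dict[str, int]:
    """TP/FP/FN/TN counts with prediction rule score >= cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    pos = labels == 1
    return {
        "tp": int(np.sum(pred & pos)),
        "fp": int(np.sum(pred & ~pos)),
        "fn": int(np.sum(~pred & pos)),
        "tn": int(np.sum(~pred & ~pos)),
    }


def kl_to_reference(scores, reference_scores, n_bins: int = 20,
                    eps: float = 1e-10) -> float:
    """KL(scores ‖ reference) between histograms on [0, 1], in nats.

    Both samples are histogrammed into ``n_bins`` equal bins; ``eps`` is
    added to every bin before normalizing so empty reference bins do not
    produce infinities.  Note KL is asymmetric: this measures how badly
    the reference distribution codes for the score distribution.
    """
    scores = np.asarray(scores, dtype=float)
    reference_scores = np.asarray(reference_scores, dtype=float)
    if scores.size == 0 or reference_scores.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    p = np.histogram(np.clip(scores, 0, 1), bins=edges)[0].astype(float) + eps
    q = np.histogram(np.clip(reference_scores, 0, 1), bins=edges)[0].astype(float) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def auc_roc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC-ROC needs both classes present")
    ranks = rankdata(scores)  # midranks
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def library_search(
    queries: SpectrumLibrary,
    library: SpectrumLibrary,
    ppm: float = 10.0,
    metric: str = "modified_cosine",
    scheme: WeightScheme | str = "unweighted",
    table: Optional[FrequencyTable] = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[str, list[SearchHit]]:
    """Rank library spectra inside a precursor ppm window per query.

    The candidate window half-width is ``ppm * precursor_mz / 1e6``.
    Both spectra of a candidate pair are weighted with ``scheme`` before
    scoring.  Hits are ranked by descending score; ties break on smaller
    precursor deviation, then library identifier.  ``is_true_positive``
    is InChIKey-14 equality when both keys are present, else ``None``.
    """
    for s in list(queries) + list(library):
        if s.precursor_mz is None:
            raise ValueError(f"spectrum {s.identifier!r} lacks a precursor m/z")
    lib_prec = np.array([s.precursor_mz for s in library])
    weighted_lib: dict[int, Spectrum] = {}
    results: dict[str, list[SearchHit]] = {}
    for q in queries:
        window = ppm * q.precursor_mz / 1e6
        idx = np.nonzero(np.abs(lib_prec - q.precursor_mz) <= window)[0]
        wq = apply_scheme(q, scheme, table)
        hits = []
        for i in idx:
            if i not in weighted_lib:
                weighted_lib[i] = apply_scheme(library[int(i)], scheme, table)
            ref = weighted_lib[i]
            s = score_pair(wq, ref, metric, tolerance)
            delta_ppm = (q.precursor_mz - library[int(i)].precursor_mz) \
                / q.precursor_mz * 1e6
            tp = None
            if q.inchikey and library[int(i)].inchikey:
                tp = inchikey14(q.inchikey) == inchikey14(library[int(i)].inchikey)
            hits.append(SearchHit(q.identifier, library[int(i)].identifier,
                                  s.value, delta_ppm, tp))
        hits.sort(key=lambda h: (-h.score, abs(h.delta_ppm), h.library_id))
        results[q.identifier] = hits
    return results


def precision_at_k(results: dict[str, list[SearchHit]], k: int = 1) -> float:
    """Average fraction of true positives among each query's top-K hits.

    Per query the denominator is min(k, hits returned); queries with no
    hits contribute 0 and stay in the average.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not results:
        return 0.0
    precisions = []
    for hits in results.values():
        if not hits:
            precisions.append(0.0)
            continue
        top = hits[: min(k, len(hits))]
        precisions.append(sum(1 for h in top if h.is_true_positive) / len(top))
    return float(np.mean(precisions))


def count_no_match_queries(results: dict[str, list[SearchHit]],
                           score_threshold: float = 0.5) -> tuple[int, int]:
    """Queries with no hit, and no true-positive hit, above a score threshold."""
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score threshold must lie in [0, 1]")
    no_match = no_tp = 0
    for hits in results.values():
        if not any(h.score > score_threshold for h in hits):
            no_match += 1
        if not any(h.score > score_threshold and h.is_true_positive for h in hits):
            no_tp += 1
    return no_match, no_tp


def dominant_peak_profile(spectrum: Spectrum) -> tuple[int, float]:
    """Peak count and the base peak's share of total intensity.

    A share above 0.7 (or a very small peak count) marks the regime
    where intensity weighting is expected to hurt rather than help: the
    one informative alignment is the dominant peak, and boosting the
    unmatched minor peaks dilutes it.
    """
    if len(spectrum) == 0:
        raise ValueError("profile of an empty spectrum is undefined")
    total = spectrum.intensities.sum()
    share = float(spectrum.intensities.max() / total) if total > 0 else 0.0
    return len(spectrum), share


def evaluate_alignment(
    pairs: Sequence[BenchmarkPair],
    metric: str = "modified_cosine",
    scheme: WeightScheme | str = "unweighted",
    table: Optional[FrequencyTable] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    tanimoto_threshold: float = 0.7,
    beta: float = 1.0,
    kl_bins: int = 20,
) -> EvalReport:
    """Score benchmark pairs and summarize cutoff, F-beta, counts and KL."""
    scores = np.array([
        score_pair(apply_scheme(p.spectrum_a, scheme, table),
                   apply_scheme(p.spectrum_b, scheme, table),
                   metric, tolerance).value
        for p in pairs
    ])
    tanimotos = np.array([p.tanimoto for p in pairs])
    labels = label_pairs(pairs, tanimoto_threshold)
    cutoff, fbeta = optimal_cutoff(scores, labels, beta)
    report = EvalReport({
        "metric": metric,
        "scheme": scheme if isinstance(scheme, str) else scheme.name,
        "n_pairs": len(pairs),
        "optimal_cutoff": cutoff,
        "fbeta": fbeta,
        "beta": beta,
        "contingency": contingency(scores, labels, cutoff),
        "kl_divergence": kl_to_reference(scores, tanimotos, kl_bins),
        "auc_roc": auc_roc(scores, labels),
        "scores": scores.tolist(),
    })
    return report
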