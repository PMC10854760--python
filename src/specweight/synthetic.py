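"""Seeded synthetic spectra, analog pairs, and benchmark sets.

Real evaluations of spectral-similarity weighting run on large licensed
libraries; this module generates small synthetic stand-ins with the
statistical structure those evaluations rely on:

* a molecule is a *template*: a set of fragment m/z values on a coarse
  grid, each carrying a log-normal base intensity (``σ = 1``, so every
  spectrum has a long tail of genuinely low peaks);
* a measured spectrum is a noisy replicate of a template — fragment
  dropout, m/z jitter, multiplicative intensity noise, a handful of
  low-intensity chemical/electronic noise peaks at arbitrary m/z, an
  optional dominant-peak boost — max-normalized;
* a structural *analog* shares a fraction of a template's fragments and
  carries the remainder shifted by a constant neutral loss, precursor
  shifted alike, so modified cosine can recover the shifted matches;
  benchmark partner molecules generalize this: only part of the
  non-shared fragments carry the neutral-loss shift, the rest are
  simply different fragments, while shared fragments keep their
  characteristic abundances;
* fingerprints assign one bit per true fragment identity, so the
  Tanimoto coefficient of two templates tracks their fragment-set
  Jaccard overlap by construction — the modeling choice that makes
  structure-vs-spectrum benchmarking meaningful without real
  chemistry.  Noise peaks are measurement artifacts and never enter a
  fingerprint.

Everything is deterministic given the config seed; per-template streams
are split by stable hashing of (seed, template_id) so adding templates
never perturbs existing ones.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .benchmark import BenchmarkPair, tanimoto
from .spectra import Spectrum, SpectrumLibrary

__all__ = [
    "MoleculeTemplate",
    "GeneratorConfig",
    "BenchmarkSet",
    "make_templates",
    "make_analog",
    "spectrum_from_template",
    "make_benchmark",
    "make_search_benchmark",
    "write_benchmark",
]

_FP_BITS = 4096


def _stable_rng(*tokens) -> np.random.Generator:
    """Generator seeded by stable 32-bit hashes of the given tokens."""
    entropy = [t if isinstance(t, (int, np.integer))
               else zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(e) & 0x7FFFFFFF
                                                         for e in entropy]))


def _fragment_bits(fragment_mzs: Sequence[float]) -> np.ndarray:
    """One fingerprint bit per fragment identity (0.01-Th grid key)."""
    fp = np.zeros(_FP_BITS, dtype=bool)
    for mz in fragment_mzs:
        key = int(round(mz * 100))
        fp[zlib.crc32(str(key).encode()) % _FP_BITS] = True
    return fp


def _synthetic_inchikey(rng: np.random.Generator) -> str:
    block = "".join(rng.choice(list(string.ascii_uppercase), size=14))
    return f"{block}-SYNTHETICSAAA-N"


@dataclass(frozen=True)
class MoleculeTemplate:
    """A synthetic molecule: fragments, base intensities, fingerprint."""

    template_id: str
    precursor_mz: float
    fragment_mzs: tuple[float, ...]
    base_intensities: tuple[float, ...]
    fingerprint: np.ndarray
    inchikey: str

    @property
    def inchikey14(self) -> str:
        return self.inchikey[:14]

    @property
    def scaffold_index(self) -> int:
        """Index of the highest-base-intensity (scaffold) fragment."""
        return int(np.argmax(self.base_intensities))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmarks.

    Noise magnitudes are chosen so that replicates of one template stay
    recognizably similar (m/z jitter well below half the matching
    tolerance; moderate multiplicative intensity noise) while noise
    peaks and dropout give intensity weighting something real to fail
    on.  ``noise_peaks_lambda`` is the Poisson mean of per-spectrum
    junk peaks, each drawn at an arbitrary m/z with a relative
    intensity in ``noise_intensity`` — negligible for unweighted cosine
    but substantial once low intensities are amplified.
    """

    seed: int = 0
    n_templates: int = 50
    peaks_per_template: tuple[int, int] = (10, 40)
    dominant_peaks_per_template: tuple[int, int] = (4, 8)
    precursor_range: tuple[float, float] = (250.0, 950.0)
    min_fragment_mz: float = 50.0
    fragment_grid: float = 0.25      # Th; grid spacing > 2x default tolerance
    mz_jitter_sd: float = 0.01       # Th
    intensity_noise_sd: float = 0.4  # sd of multiplicative log-noise
    dropout_prob: float = 0.1
    noise_peaks_lambda: float = 12.0
    noise_intensity: tuple[float, float] = (0.01, 0.08)  # relative to base peak
    dominant_peak_prob: float = 0.1
    dominant_share: float = 0.8
    dominant_share_range: tuple[float, float] = (0.55, 0.9)
    analog_overlap: tuple[float, float] = (0.05, 1.0)
    analog_mass_shift: float = 162.0528  # hexose-like neutral loss, Th
    shift_fraction: float = 0.05     # benchmark partners: fraction of
                                     # non-shared fragments carrying the shift
    impostor_overlap: tuple[float, float] = (0.05, 0.15)

    def __post_init__(self):
        for p in (self.dropout_prob, self.dominant_peak_prob, self.dominant_share,
                  self.shift_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and shares must lie in [0, 1]")
        if self.mz_jitter_sd >= 0.05:
            raise ValueError("mz_jitter_sd must stay below tolerance/2 (0.05 Th)")


def _sample_template(config: GeneratorConfig, template_id: str,
                     n_peaks_range: tuple[int, int]) -> MoleculeTemplate:
    rng = _stable_rng(config.seed, template_id)
    precursor = float(rng.uniform(*config.precursor_range))
    n_peaks = int(rng.integers(n_peaks_range[0], n_peaks_range[1] + 1))
    grid_max = int((precursor - 2.0 - config.min_fragment_mz) / config.fragment_grid)
    if grid_max < n_peaks:
        raise ValueError("fragment grid too small for the requested peak count")
    idx = rng.choice(grid_max, size=n_peaks, replace=False)
    frags = np.sort(config.min_fragment_mz + idx * config.fragment_grid)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)
    return MoleculeTemplate(
        template_id=template_id,
        precursor_mz=precursor,
        fragment_mzs=tuple(float(m) for m in frags),
        base_intensities=tuple(float(b) for b in base),
        fingerprint=_fragment_bits(frags),
        inchikey=_synthetic_inchikey(rng),
    )


def make_templates(config: GeneratorConfig, n: Optional[int] = None,
                   prefix: str = "T",
                   n_peaks_range: Optional[tuple[int, int]] = None
                   ) -> list[MoleculeTemplate]:
    """Deterministically generate molecule templates from the config seed."""
    n = config.n_templates if n is None else n
    n_peaks_range = n_peaks_range or config.peaks_per_template
    return [_sample_template(config, f"{prefix}{i:04d}", n_peaks_range)
            for i in range(n)]


def make_analog(template: MoleculeTemplate, overlap: float, mass_shift: float,
                seed: int, shift_fraction: float = 1.0) -> MoleculeTemplate:
    """Structural analog sharing ``ceil(overlap * n)`` fragments.

    The retained set always includes the scaffold fragment; retained
    fragments keep their characteristic base intensities (fragments of
    a shared substructure ionize similarly).  Of the non-retained
    fragments, a ``shift_fraction`` carry the constant
    ``+mass_shift`` neutral-loss offset (the signal precursor-shifted
    matching recovers; the default 1.0 shifts them all) and the rest
    are replaced by unrelated fragments.  The precursor shifts by
    ``+mass_shift`` and the fingerprint is rebuilt from the new
    fragment set, so the analog's Tanimoto to its parent approximates
    ``overlap``.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = _stable_rng(seed, template.template_id, "analog")
    n = len(template.fragment_mzs)
    n_keep = int(np.ceil(overlap * n))
    scaffold = template.scaffold_index
    keep: set[int] = set()
    if n_keep > 0:
        keep = {scaffold}
        if n_keep > 1:
            others = np.array([i for i in range(n) if i != scaffold])
            keep |= {int(c) for c in rng.choice(others, size=n_keep - 1,
                                                replace=False)}
    grid_max = int((template.precursor_mz - 2.0 - 50.0) / 0.25)
    used = {int(round((m - 50.0) / 0.25)) for m in template.fragment_mzs}
    frags, base = [], []
    for i in range(n):
        if i in keep:
            frags.append(template.fragment_mzs[i])
            base.append(template.base_intensities[i])
        elif rng.random() < shift_fraction:
            # the same substructure carrying the modification: the
            # fragment shifts but keeps its characteristic abundance
            frags.append(template.fragment_mzs[i] + mass_shift)
            base.append(template.base_intensities[i])
        else:
            idx = int(rng.integers(grid_max))
            while idx in used:
                idx = int(rng.integers(grid_max))
            used.add(idx)
            frags.append(50.0 + idx * 0.25)
            base.append(float(rng.lognormal(0.0, 1.0)))
    order = np.argsort(frags)
    frags = tuple(float(frags[i]) for i in order)
    base = tuple(float(base[i]) for i in order)
    return MoleculeTemplate(
        template_id=f"{template.template_id}_an{seed}",
        precursor_mz=template.precursor_mz + mass_shift,
        fragment_mzs=frags,
        base_intensities=base,
        fingerprint=_fragment_bits(frags),
        inchikey=_synthetic_inchikey(rng),
    )


def spectrum_from_template(
    template: MoleculeTemplate,
    config: GeneratorConfig,
    replicate_seed: int = 0,
    noiseless: bool = False,
    force_dominant: Optional[bool] = None,
    dominant_mz: Optional[float] = None,
    dominant_share: Optional[float] = None,
) -> Spectrum:
    """A measured replicate: dropout, jitter, noise, optional dominant boost.

    With ``noiseless=True`` the spectrum reproduces the template
    fragments exactly (max-normalized, no noise peaks).  A dominant
    boost raises one peak — the one nearest ``dominant_mz``, or the
    most intense — to ``dominant_share`` of the total intensity; the
    boosted peak is exempt from dropout.  If every fragment would drop
    out, dropout is retried disabled and the spectrum is flagged in its
    metadata.
    """
    rng = _stable_rng(config.seed, template.template_id, "rep", replicate_seed)
    mz = np.array(template.fragment_mzs)
    inten = np.array(template.base_intensities)
    meta = {}
    dominant = (force_dominant if force_dominant is not None
                else (not noiseless and dominant_mz is None
                      and rng.random() < config.dominant_peak_prob))
    if dominant_mz is not None:
        dominant = True
    if not noiseless:
        keep = rng.random(mz.size) >= config.dropout_prob
        if dominant:
            target = (int(np.argmin(np.abs(mz - dominant_mz)))
                      if dominant_mz is not None else int(np.argmax(inten)))
            keep[target] = True
        if not keep.any():
            meta["dropout_disabled"] = True
            keep = np.ones(mz.size, dtype=bool)
        mz, inten = mz[keep], inten[keep]
        mz = mz + rng.normal(0.0, config.mz_jitter_sd, size=mz.size)
        inten = inten * np.exp(rng.normal(0.0, config.intensity_noise_sd,
                                          size=inten.size))
        k_noise = int(rng.poisson(config.noise_peaks_lambda))
        if k_noise:
            noise_mz = rng.uniform(config.min_fragment_mz,
                                   template.precursor_mz - 2.0, size=k_noise)
            lo, hi = config.noise_intensity
            noise_inten = rng.uniform(lo, hi, size=k_noise) * inten.max()
            mz = np.concatenate([mz, noise_mz])
            inten = np.concatenate([inten, noise_inten])
    if dominant and mz.size > 1:
        target = (int(np.argmin(np.abs(mz - dominant_mz)))
                  if dominant_mz is not None else int(np.argmax(inten)))
        share = dominant_share if dominant_share is not None else config.dominant_share
        rest = inten.sum() - inten[target]
        inten[target] = share / (1.0 - share) * rest
    inten = inten / inten.max()
    return Spectrum(
        precursor_mz=template.precursor_mz,
        mz=mz,
        intensities=inten,
        identifier=f"{template.template_id}_r{replicate_seed}",
        inchikey=template.inchikey,
        normalized="max",
        metadata=meta,
    )


@dataclass
class BenchmarkSet:
    """Everything the evaluation harnesses need, generated from one seed."""

    pairs: list[BenchmarkPair]
    queries: SpectrumLibrary
    reference: SpectrumLibrary
    fingerprints: dict[str, np.ndarray]
    templates: list[MoleculeTemplate] = field(default_factory=list)


def make_benchmark(
    config: GeneratorConfig,
    n_pairs: int = 500,
    dominant_fraction: float = 0.2,
    n_library_templates: int = 50,
) -> BenchmarkSet:
    """Labeled spectrum pairs in two strata, plus query/reference libraries.

    The ``no_dominant`` stratum mixes, in fixed proportion, unrelated
    template pairs (9/20), scaffold-sharing impostors with low fragment
    overlap (3/20), analogs spanning the configured overlap range
    (7/20), and same-molecule replicate pairs (1/20) — a mostly
    dissimilar population with a thin band of true matches, as in
    random-pair alignment benchmarks.  The ``dominant`` stratum draws
    few-fragment templates across the full overlap range and boosts the
    shared scaffold fragment in both spectra to a share drawn from
    ``dominant_share_range``: the regime where one aligned peak carries
    the whole unweighted score, for better (true analogs) or worse
    (impostors).
    """
    rng = _stable_rng(config.seed, "benchmark")
    n_dom = int(round(n_pairs * dominant_fraction))
    n_main = n_pairs - n_dom
    main_templates = make_templates(config, n=n_main, prefix="M")
    dom_templates = make_templates(config, n=n_dom, prefix="D",
                                   n_peaks_range=config.dominant_peaks_per_template)

    pairs: list[BenchmarkPair] = []
    for k, t in enumerate(main_templates):
        slot = k % 20
        if slot < 9:      # unrelated pair
            t2 = main_templates[(k + 7) % n_main]
            sa = spectrum_from_template(t, config, 2 * k, force_dominant=False)
            sb = spectrum_from_template(t2, config, 2 * k + 1, force_dominant=False)
            coeff = tanimoto(t.fingerprint, t2.fingerprint)
        elif slot < 12:   # impostor: shares little beyond the scaffold
            u = float(rng.uniform(*config.impostor_overlap))
            t2 = make_analog(t, u, config.analog_mass_shift, seed=k,
                             shift_fraction=0.0)
            sa = spectrum_from_template(t, config, 2 * k, force_dominant=False)
            sb = spectrum_from_template(t2, config, 2 * k + 1, force_dominant=False)
            coeff = tanimoto(t.fingerprint, t2.fingerprint)
        elif slot < 19:   # analog across the overlap range
            u = float(rng.uniform(*config.analog_overlap))
            t2 = make_analog(t, u, config.analog_mass_shift, seed=k,
                             shift_fraction=config.shift_fraction)
            sa = spectrum_from_template(t, config, 2 * k, force_dominant=False)
            sb = spectrum_from_template(t2, config, 2 * k + 1, force_dominant=False)
            coeff = tanimoto(t.fingerprint, t2.fingerprint)
        else:             # replicate pair: same molecule measured twice
            sa = spectrum_from_template(t, config, 2 * k, force_dominant=False)
            sb = spectrum_from_template(t, config, 2 * k + 1, force_dominant=False)
            coeff = 1.0
        pairs.append(BenchmarkPair(sa, sb, coeff, stratum="no_dominant"))

    for k, t in enumerate(dom_templates):
        u = float(rng.uniform(*config.analog_overlap))
        t2 = make_analog(t, u, config.analog_mass_shift, seed=100_000 + k,
                         shift_fraction=config.shift_fraction)
        scaffold_mz = t.fragment_mzs[t.scaffold_index]
        s1 = float(rng.uniform(*config.dominant_share_range))
        s2 = float(rng.uniform(*config.dominant_share_range))
        sa = spectrum_from_template(t, config, 2 * k,
                                    dominant_mz=scaffold_mz, dominant_share=s1)
        sb = spectrum_from_template(t2, config, 2 * k + 1,
                                    dominant_mz=scaffold_mz, dominant_share=s2)
        pairs.append(BenchmarkPair(sa, sb, tanimoto(t.fingerprint, t2.fingerprint),
                                   stratum="dominant"))

    lib_templates = main_templates[:min(n_library_templates, n_main)]
    reference = SpectrumLibrary(
        [spectrum_from_template(t, config, noiseless=True) for t in lib_templates],
        source="synthetic-reference")
    queries = SpectrumLibrary(
        [spectrum_from_template(t, config, replicate_seed=99_000 + i)
         for i, t in enumerate(lib_templates)],
        source="synthetic-queries")
    fingerprints = {t.inchikey14: t.fingerprint
                    for t in main_templates + dom_templates}
    return BenchmarkSet(pairs, queries, reference, fingerprints,
                        main_templates + dom_templates)


def make_search_benchmark(
    config: GeneratorConfig,
    n_reference: int = 200,
    n_queries: int = 500,
    exact_copy_fraction: float = 0.1,
) -> BenchmarkSet:
    """Query and reference libraries for the ppm-windowed search task.

    The reference holds one clean spectrum per template; queries are
    noisy replicates cycling over the templates, with a fraction left
    noiseless (exact copies of their reference entry).  True positives
    share the template's InChIKey-14.
    """
    templates = make_templates(config, n=n_reference, prefix="L")
    reference = SpectrumLibrary(
        [spectrum_from_template(t, config, noiseless=True) for t in templates],
        source="synthetic-reference")
    n_exact = int(round(n_queries * exact_copy_fraction))
    query_spectra = []
    for i in range(n_queries):
        t = templates[i % len(templates)]
        s = spectrum_from_template(t, config, replicate_seed=50_000 + i,
                                   noiseless=i < n_exact)
        query_spectra.append(replace(s, identifier=f"Q{i:05d}_{t.template_id}"))
    queries = SpectrumLibrary(query_spectra, source="synthetic-queries")
    fingerprints = {t.inchikey14: t.fingerprint for t in templates}
    return BenchmarkSet([], queries, reference, fingerprints, templates)


def write_benchmark(bench: BenchmarkSet, outdir) -> dict[str, str]:
    """Write libraries (MGF), fingerprints and pair labels (TSV) to a directory."""
    import os

    from .io import write_mgf

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    if len(bench.queries):
        paths["queries"] = os.path.join(outdir, "queries.mgf")
        write_mgf(bench.queries, paths["queries"])
    if len(bench.reference):
        paths["reference"] = os.path.join(outdir, "reference.mgf")
        write_mgf(bench.reference, paths["reference"])
    paths["fingerprints"] = os.path.join(outdir, "fingerprints.tsv")
    with open(paths["fingerprints"], "w") as fh:
        for key14, bits in bench.fingerprints.items():
            fh.write(f"{key14}\t{''.join('1' if b else '0' for b in bits)}\n")
    if bench.pairs:
        paths["pairs"] = os.path.join(outdir, "pairs.tsv")
        with open(paths["pairs"], "w") as fh:
            fh.write("id_a\tid_b\ttanimoto\tstratum\n")
            for p in bench.pairs:
                fh.write(f"{p.spectrum_a.identifier}\t{p.spectrum_b.identifier}"
                         f"\t{p.tanimoto:.6f}\t{p.stratum}\n")
    return paths
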