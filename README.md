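# specweight

Intensity weighting for MS/MS spectral similarity: amplify the
low-intensity fragments that carry structural information, weight
peaks by how often their m/z occurs in a reference library, and
measure what that does to spectral alignment and library search.

## The problem

Untargeted metabolomics annotates unknown compounds by comparing their
tandem mass spectra against libraries of known spectra. The workhorse
scores — cosine and modified cosine over matched peaks, spectral
entropy similarity — are dominated by the tallest peaks: two spectra
that share their base peak score high even when every minor fragment
disagrees, and genuinely related spectra score low when their shared
evidence sits in the intensity tail. A long line of fixes raises
intensities to a fractional power and/or multiplies by a power of m/z
before scoring.

`specweight` implements that family plus a frequency-aware scheme in
which each peak's weighted intensity is

```
w = (I / I_max)^0.25 · f(m/z)^0.25
```

where `I_max` is the spectrum's base-peak intensity and `f(m/z)` is the
fraction of spectra in a reference library showing a peak in the same
0.1 Th m/z bin. Low peaks are amplified on a relative-intensity scale;
peaks at commonly observed masses count more; rare (often noise)
masses are damped. Alongside it: the classic power-law schemes
(Sokolow 0.5/0.5, Stein–Scott 0.6/3, Horai 0.5/2, Kim 0.53/1.3,
intensity-only 0.5/0), entropy-conditional weighting
(I → I^{0.25(1+S)} for spectra with spectral entropy S < 3 nats),
and binarization.

The package is aimed at people building or evaluating spectral
matching pipelines: it couples the weighting transforms to five
matched-peak metrics (cosine, modified cosine, spectral entropy,
fidelity, Bhattacharyya-1, plus a registration point for more), a
structural-alignment benchmark harness (F1-optimal cutoffs,
contingency tables, KL divergence against Tanimoto coefficients), a
ppm-windowed library-search harness (precision@K, AUC-ROC), and a
seeded synthetic-spectrum generator so everything runs and is tested
without licensed libraries.

## A worked example

Score a molecule against its glycoside (a +162.05 Th neutral-loss
analog): two fragments align directly, three only after allowing the
precursor mass difference (`examples/02_pair_similarity.py`):

```text
direct matches: 2, with precursor shift: 5
  bhattacharya_1: 0.5457  (2 matched peaks)
          cosine: 0.6007  (2 matched peaks)
         entropy: 0.4898  (2 matched peaks)
        fidelity: 0.4899  (2 matched peaks)
 modified_cosine: 0.9974  (5 matched peaks)
```

Only modified cosine credits the shifted fragments, which is why it is
the metric of choice for finding structurally related (not identical)
compounds.

Weighting enters before scoring. On a seeded synthetic benchmark of
600 labeled pairs (`examples/03_alignment_benchmark.py`):

```text
     unweighted: optimal cutoff 0.63, F1 0.513, KL to Tanimoto 0.207, AUC 0.834
 intensity_only: optimal cutoff 0.69, F1 0.597, KL to Tanimoto 0.314, AUC 0.902
       proposed: optimal cutoff 0.63, F1 0.786, KL to Tanimoto 0.270, AUC 0.970
no-dominant stratum F1: unweighted 0.662 vs weighted 0.884
```

Frequency-aware weighting separates structural analogs from unrelated
pairs far better than raw intensities (F1 0.513 → 0.786 at the
Tanimoto > 0.7 labeling), because shared low-intensity fragments get a
voice in the score. The flip side — spectra dominated by a single peak,
where weighting amplifies the junk around the one informative
alignment — is demonstrated in `examples/05_dominant_peak_advisory.py`,
together with the per-spectrum advisory that flags that regime.

Every capability has a short narrative script under `examples/`, and a
`specweight` command-line tool exposes the same operations
(`specweight simulate`, `freq-table`, `weight`, `pair`, `search`,
`benchmark`).

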