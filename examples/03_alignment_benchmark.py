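"""Structural-alignment benchmark: does weighting help find analogs?

Generates a seeded synthetic benchmark of 600 spectrum pairs labeled by
the Tanimoto coefficient of their source molecules, scores every pair
with modified cosine before and after frequency-aware weighting, and
reports the F1-optimal cutoff, F1 score, and KL divergence between the
score and Tanimoto distributions.
"""

import numpy as np

from specweight import (
    GeneratorConfig,
    SpectrumLibrary,
    build_frequency_table,
    evaluate_alignment,
    label_pairs,
    make_benchmark,
    optimal_cutoff,
)

bench = make_benchmark(GeneratorConfig(seed=7), n_pairs=600)
spectra = SpectrumLibrary(
    [s for p in bench.pairs for s in (p.spectrum_a, p.spectrum_b)])
table = build_frequency_table(spectra)

for scheme in ("unweighted", "intensity_only", "proposed"):
    report = evaluate_alignment(bench.pairs, metric="modified_cosine",
                                scheme=scheme, table=table).to_dict()
    print(f"{scheme:>15}: optimal cutoff {report['optimal_cutoff']:.2f}, "
          f"F1 {report['fbeta']:.3f}, KL to Tanimoto {report['kl_divergence']:.3f}, "
          f"AUC {report['auc_roc']:.3f}")

nd = [p for p in bench.pairs if p.stratum == "no_dominant"]
dom = [p for p in bench.pairs if p.stratum == "dominant"]
print(f"\nstrata: {len(nd)} ordinary pairs, {len(dom)} dominant-peak pairs")

def f1(pairs, scheme):
    report = evaluate_alignment(pairs, scheme=scheme, table=table).to_dict()
    return report["fbeta"]

print(f"no-dominant stratum F1: unweighted {f1(nd, 'unweighted'):.3f} "
      f"vs weighted {f1(nd, 'proposed'):.3f}")

print("\nWeighting raises F1 on ordinary spectra (low-intensity shared")
print("fragments get a voice), and the weighted score distribution no")
print("longer piles up near 1 — at the full benchmark scale of")
print("scripts/acceptance.py its optimal cutoff sits below the unweighted")
print("one. On the dominant-peak stratum the same amplification backfires —")
print("see the dominant-peak example and the methods note.")
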