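"""ppm-windowed library search with precision@K evaluation.

Generates a clean 100-molecule reference library and 200 noisy query
replicates, searches each query inside 10 ppm and 5,000 ppm precursor
windows with modified cosine, and reports precision@K and no-match
counts. True positives are hits sharing the query's InChIKey-14.
"""

from specweight import (
    GeneratorConfig,
    build_frequency_table,
    count_no_match_queries,
    library_search,
    make_search_benchmark,
    precision_at_k,
)

bench = make_search_benchmark(GeneratorConfig(seed=11),
                              n_reference=100, n_queries=200)
table = build_frequency_table(bench.reference)

for ppm in (10, 5000):
    for scheme in ("unweighted", "proposed"):
        results = library_search(bench.queries, bench.reference, ppm=ppm,
                                 metric="modified_cosine", scheme=scheme,
                                 table=table)
        p1 = precision_at_k(results, 1)
        p5 = precision_at_k(results, 5)
        no_match, _ = count_no_match_queries(results, 0.5)
        n_cand = sum(len(h) for h in results.values())
        print(f"{ppm:>5} ppm, {scheme:>10}: precision@1 {p1:.3f}, "
              f"precision@5 {p5:.3f}, {no_match} queries without a hit "
              f"above 0.5, {n_cand} candidates total")

print("\nAt 10 ppm the precursor window almost always contains only the")
print("true molecule, so precision is driven by whether the noisy replicate")
print("still outscores nothing at all; at 5,000 ppm more decoy candidates")
print("enter each window and precision can only stay equal or drop.")
print("Weighting rescues low-scoring noisy queries (fewer no-match queries).")
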