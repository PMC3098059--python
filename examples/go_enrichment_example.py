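"""GO-term enrichment of peak-adjacent genes.

Builds a 20-gene universe where one biological-process term annotates 5
genes, then asks whether a 4-gene sample containing 3 of them is enriched.
The raw p-value is the hypergeometric upper tail P(X >= 3) with
N=20, K=5, n=4.
"""

from peakannot import GeneTermMap, enrich, enrichment_to_dataframe

genes = {f"g{i}": {f"GO:{1000000 + i:07d}"} for i in range(1, 21)}
for g in ("g1", "g2", "g3", "g4", "g5"):
    genes[g].add("GO:0000001")
gene_map = GeneTermMap(
    {"BP": {g: frozenset(t) for g, t in genes.items()}},
    term_names={"GO:0000001": "toy biological process"},
)

sample = {"g1", "g2", "g3", "g20"}
result = enrich(sample, gene_map, max_p=1.0, min_go_term=2, adjust="BH")
print(enrichment_to_dataframe(result).to_string(index=False))
# The single candidate term has K=5 of N=20 universe genes and k=3 of the
# n=4 sampled genes: p_raw = 155/4845 ~= 0.032 (FDR equals it with one test).
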