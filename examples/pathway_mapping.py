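"""Map SNPs to genes and genes to pathway-level SNP sets.

Builds a toy annotation in memory: SNP positions, two gene bodies, and a
two-pathway GMT-style gene-set collection, then shows the 5 kb-window
SNP -> gene assignment and the deduplicating gene -> pathway union.
"""

from scpca import GeneInterval, map_snps_to_genes, pathway_snpsets

snp_positions = [
    ("1", 4_000),    # 5 kb upstream of geneA -> assigned
    ("1", 12_000),   # inside geneA
    ("1", 19_500),   # in the geneA/geneB overlap -> both genes
    ("1", 26_000),   # inside geneB
    ("1", 40_000),   # far from both -> unassigned
]
genes = [
    GeneInterval("geneA", "1", 9_000, 20_000),
    GeneInterval("geneB", "1", 19_000, 30_000),
]

gene_sets = map_snps_to_genes(snp_positions, genes, window_bp=5000)
for s in gene_sets:
    print(f"{s.set_id}: SNP columns {[int(i) for i in s.snp_indices]}")

pathways = [("pw_both", ["geneA", "geneB"]), ("pw_a_only", ["geneA"])]
pw_sets = pathway_snpsets(pathways, gene_sets)
for s in pw_sets:
    print(f"{s.set_id}: SNP columns {[int(i) for i in s.snp_indices]}")
# pw_both holds the union of both genes' SNPs with the shared SNP at
# position 19,500 counted once.
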