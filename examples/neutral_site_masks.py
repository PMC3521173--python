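"""Fourfold-degenerate and intronic neutral-reference site masks.

Builds a two-exon gene whose CDS is ATG GGA | GCT TAA and shows which third
codon positions are fourfold degenerate, then the first-intron-removal rule.
"""

from enhscan import GeneModel, Isoform, fourfold_sites, intron_sites

genome = {"chr1": "T" * 10 + "ATGGGA" + "C" * 100 + "GCTTAA" + "T" * 5}
iso = Isoform("t1", exons=[(10, 16), (116, 122)], cds=[(10, 16), (116, 122)])
gene = GeneModel("demo", "chr1", "+", [iso])

mask = fourfold_sites(gene, genome)
print("CDS codons: ATG GGA GCT TAA")
print("fourfold third positions (genomic):", list(mask.positions))
print("(GGA and GCT are fourfold families; ATG and the stop contribute none)")
print()

multi = GeneModel(
    "demo2", "chr1", "+",
    [Isoform("t1", exons=[(0, 50), (550, 600), (900, 950), (1150, 1200)], cds=[(0, 48)])],
)
intron_mask = intron_sites(multi)
print(f"gene with introns of 500/300/200 bp -> intron mask of {len(intron_mask)} positions")
print("(the 5'-most intron is removed: it may contain regulatory motifs)")
single = GeneModel("demo3", "chr1", "+", [Isoform("t1", [(0, 50), (550, 600)], [(0, 48)])])
print(f"single-intron gene -> {len(intron_sites(single))} intron positions "
      "(such genes keep only the fourfold reference)")
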