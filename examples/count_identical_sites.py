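"""Count SNP and identical (synonymous) sites in an ortholog CDS pair.

Identical sites — SNP columns whose codon change is silent — measure how
much of the divergence between two genomes is neutral, and were used to
rank how closely the cotton A-genomes are related.
"""

from ltrburst import CDSPairAlignment, count_sites

# a short aligned CDS pair: one synonymous change (GCT->GCC, Ala/Ala),
# one nonsynonymous change (AAA->GAA, Lys/Glu), one codon deleted
seq_a = "ATGGCTAAATTGGAA"
seq_b = "ATGGCCGAA---GAA"
counts = count_sites(CDSPairAlignment(seq_a, seq_b))

print(f"compared columns:  {counts.compared_columns}")
print(f"SNP sites:         {counts.snp_sites}")
print(f"identical sites:   {counts.identical_sites}")
print()
print("Of the SNP columns, those whose codons translate identically in both")
print("sequences are 'identical sites' (synonymous); gap columns are never")
print("compared, and the deleted codon keeps the reading frame intact.")
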