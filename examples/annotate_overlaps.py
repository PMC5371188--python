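"""Overlap differential CNVRs with gene and QTL annotation intervals.

Any feature sharing at least 1 bp with a CNVR counts as copy-number
variable ("completely or partially" overlapping); QTL hits connect the
regions to previously mapped trait intervals.
"""

from rdcnv import (AnnotationRecord, Cnvr, overlap_features,
                   summarize_gene_coverage)

cnvrs = [
    Cnvr("chr1", 100_000, 130_000, "deletion"),
    Cnvr("chr1", 400_000, 420_000, "duplication"),
    Cnvr("chr2", 50_000, 90_000, "both"),
]
genes = [
    AnnotationRecord("chr1", 95_000, 105_000, "ENSBTAG01", "GENE_A", "gene",
                     "protein_coding"),
    AnnotationRecord("chr1", 410_000, 415_000, "ENSBTAG02", "GENE_B", "gene",
                     "protein_coding"),
    AnnotationRecord("chr2", 300_000, 320_000, "ENSBTAG03", "GENE_C", "gene",
                     "miRNA"),
]
qtls = [
    AnnotationRecord("chr2", 0, 2_000_000, "QTL_7", "MilkFatPct", "qtl",
                     "fat percentage"),
]

print("gene overlaps (CNVR, gene, shared bp):")
for cnvr, gene, ov in overlap_features(cnvrs, genes):
    print(f"  {cnvr.chrom}:{cnvr.start}-{cnvr.end}  {gene.name:8s} {ov:>6d} bp")

n_hit, frac, n_genes = summarize_gene_coverage(cnvrs, genes)
print(f"\n{n_hit} of {len(cnvrs)} CNVRs contain a gene "
      f"({100 * frac:.1f}%); {n_genes} distinct genes hit")

print("\nQTL overlaps:")
for cnvr, qtl, ov in overlap_features(cnvrs, qtls):
    print(f"  {cnvr.chrom}:{cnvr.start}-{cnvr.end} lies in {qtl.name} "
          f"({qtl.attribute}), {ov} bp shared")
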