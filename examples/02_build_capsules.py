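"""Build CpG capsules from annotation columns, genomic bins and gene sets.

Uses the bundled deterministic annotation fixture (Illumina 450k dialect) to
group CpGs by gene, by island relation, by fixed-width genomic windows, and
by a small gene-set collection, then applies the minimum-CpG filter. Each
printed capsule lists the CpGs it contains; the filter keeps only capsules
with strictly more than the threshold number of CpGs.
"""

from methylcaps.capsules import (
    build_from_annotation,
    build_from_gene_sets,
    build_genomic_bins,
    filter_min_cpgs,
)
from methylcaps.simulate import FIXTURE_CHROM_SIZES, make_annotation_fixture

ann = make_annotation_fixture()
universe = list(ann.index)

genes = build_from_annotation(ann, universe, "UCSC_RefGene_Name")
print("gene capsules:", {k: v for k, v in genes.capsules.items()})

islands = build_from_annotation(ann, universe, "Relation_to_UCSC_CpG_Island")
print("island-relation capsule sizes:", islands.d)

coords = {c: (r["chrom"], int(r["pos"])) for c, r in ann.iterrows()}
bins = build_genomic_bins(coords, FIXTURE_CHROM_SIZES, width=1000, step=500)
print("overlapping 1-kb bins (step 500):", {k: len(v) for k, v in bins.capsules.items()})

sets = build_from_gene_sets({"WNT_LIKE": ["GENEA", "GENEC"], "EMPTY": ["NOPE"]}, genes)
print("gene-set capsules:", sets.capsules)

filtered = filter_min_cpgs(genes, min_cpgs=2)
print("gene capsules with more than 2 CpGs:", list(filtered.capsules))
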