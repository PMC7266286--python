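"""Targeted-sequencing panel and qRT-PCR gene sets.

The assay targets 21 genes recurrently altered in malignant pleural
mesothelioma (MPM) plus the TERT promoter region (locus name ``TERT_prom``).
Expression is measured for 9 predictor genes, a 55-gene epithelioid/
sarcomatoid signature, the TERT transcript, and 5 housekeeping genes.
"""

from __future__ import annotations

# 21 coding genes of the targeted panel.  The three most frequently mutated
# loci (BAP1, NF2, TERT promoter) dominate the MPM mutation landscape; the
# rest are recurrent MPM tumor-suppressors/oncogenes.
PANEL_GENES: tuple[str, ...] = (
    "BAP1", "NF2", "TP53", "SETD2", "LATS2", "ARID2", "SMARCA4",
    "KMT2D", "ARID1A", "CDKN2A", "PBRM1", "SETDB1", "SF3B1", "DDX3X",
    "TRAF7", "RB1", "PTCH1", "PIK3CA", "KRAS", "NRAS", "CUL1",
)

TERT_PROM = "TERT_prom"

#: All loci of the mutation matrix: 21 genes + the TERT promoter.
PANEL_LOCI: tuple[str, ...] = PANEL_GENES + (TERT_PROM,)

# Synthetic GRCh37-style coordinates used by the cohort generator; one
# region per locus so planted variants carry consistent (chrom, pos).
GENE_REGIONS: dict[str, tuple[str, int]] = {
    gene: (f"chr{(i % 22) + 1}", 10_000_000 + 1_000_000 * i)
    for i, gene in enumerate(PANEL_GENES)
}
GENE_REGIONS[TERT_PROM] = ("chr5", 1_295_000)

# TERT promoter hotspot sites (GRCh37, chr5).  1,295,228 is the canonical
# core-promoter hotspot (C228T); the other two sites sit in the TERT 5'UTR.
# Positions are configuration: promoter variants at other positions are
# classified as noncoding.
DEFAULT_TERT_HOTSPOTS: tuple[tuple[str, int], ...] = (
    ("chr5", 1_295_228),   # core promoter
    ("chr5", 1_295_161),   # 5'UTR site 1
    ("chr5", 1_295_135),   # 5'UTR site 2
)

#: Relative shares of the three hotspot sites among promoter-mutant tumors
#: (cohort-level frequencies of roughly 9.7%, 1.9% and 0.4%).
DEFAULT_HOTSPOT_WEIGHTS: tuple[float, ...] = (0.81, 0.155, 0.035)

HOUSEKEEPING_GENES: tuple[str, ...] = ("18S", "ACTB", "CLTC", "GAPDH", "TBP")

# 9-gene molecular-subtype predictor: three marker genes per binary task.
TASK_GENES: dict[str, tuple[str, str, str]] = {
    "C1_vs_C2": ("ADAM19", "ETS1", "PDCD1LG2"),
    "C1A_vs_C1B": ("CLDN1", "DSC3", "SLC24A3"),
    "C2A_vs_C2B": ("CHL1", "ECM2", "PTPN13"),
}
PREDICTOR_GENES: tuple[str, ...] = tuple(
    g for genes in TASK_GENES.values() for g in genes
)

#: Synthetic identifiers for the 55-gene E/S deconvolution signature (the
#: real signature gene list is not bundled; any centroid table with matching
#: row names can be supplied instead).
SIGNATURE_GENES: tuple[str, ...] = tuple(f"SIG{i:02d}" for i in range(1, 56))

SUBTYPES_LEVEL1 = ("C1", "C2")
SUBTYPES_LEVEL2 = ("C1A", "C1B", "C2A", "C2B")

HISTOLOGIES = ("MME", "MMB", "MMS", "MMD", "lympho")
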