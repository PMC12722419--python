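"""Gene constants for the seven recurrent uveal-melanoma-associated mutations (UMAMs).

Gq-pathway genes carry the clonal initiating hotspot mutation; BSE genes
(BAP1/SF3B1/EIF1AX) are the secondary drivers that stratify metastatic risk.
"""

from __future__ import annotations

# Canonical order doubles as the tie-break for purity-source selection.
GQ_GENES: tuple[str, ...] = ("GNAQ", "GNA11", "PLCB4", "CYSLTR2")
BSE_GENES: tuple[str, ...] = ("BAP1", "SF3B1", "EIF1AX")
UMAM_GENES: tuple[str, ...] = GQ_GENES + BSE_GENES

#: chromosome of each gene (hg19/hg38 arm-level identical)
GENE_CHROM: dict[str, str] = {
    "GNAQ": "9",
    "GNA11": "19",
    "PLCB4": "20",
    "CYSLTR2": "13",
    "BAP1": "3",
    "SF3B1": "2",
    "EIF1AX": "X",
}

#: representative hotspot coordinates (hg19) used by the simulator's VCF export
GENE_POS_HG19: dict[str, int] = {
    "GNAQ": 80412493,
    "GNA11": 3118942,
    "PLCB4": 9389364,
    "CYSLTR2": 49281090,
    "BAP1": 52440278,
    "SF3B1": 198266834,
    "EIF1AX": 20159709,
}

#: hotspot protein labels for the oncoprint / simulated cohorts
GQ_HOTSPOTS: dict[str, tuple[str, ...]] = {
    "GNAQ": ("Q209P", "Q209L", "R183Q"),
    "GNA11": ("Q209L", "R183C"),
    "PLCB4": ("D630N",),
    "CYSLTR2": ("L129Q",),
}


def is_gq(gene: str) -> bool:
    return gene in GQ_GENES


def is_bse(gene: str) -> bool:
    return gene in BSE_GENES


def is_x_linked(gene: str) -> bool:
    return GENE_CHROM.get(gene) == "X"
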