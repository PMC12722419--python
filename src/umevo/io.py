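"""Reading and writing the pipeline's tabular and VCF interchange formats.

Tables travel as TSV.  Simulated per-sample variant calls can be exported
as VCF with AD/DP FORMAT fields and annotation scores in INFO; reading VCF
goes through pysam.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=SPLICE_AI,Number=1,Type=Float,Description="SpliceAI delta score">
##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">
##INFO=<ID=PP2,Number=1,Type=Float,Description="PolyPhen2 score">
##INFO=<ID=CLNPATH,Number=0,Type=Flag,Description="ClinVar pathogenic">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##reference={assembly}
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def variants_to_vcf(variants: pd.DataFrame, sample_id: str, path: str,
                    assembly: str = "hg19") -> None:
    """Write one sample's variant calls as a single-sample VCF."""
    sub = variants[variants["sample_id"] == sample_id]
    lines = [_VCF_HEADER.format(sample=sample_id, assembly=assembly)]
    for _, r in sub.sort_values(["chrom", "pos"]).iterrows():
        info = [f"GENE={r['gene']}"]
        for key, name in (("splice_ai", "SPLICE_AI"), ("sift", "SIFT"),
                          ("polyphen2", "PP2")):
            val = r.get(key)
            if val is not None and not (isinstance(val, float)
                                        and np.isnan(val)):
                info.append(f"{name}={float(val):.4f}")
        if bool(r.get("clinvar_pathogenic")) is True:
            info.append("CLNPATH")
        dp = int(r["ref_count"]) + int(r["alt_count"])
        lines.append(
            f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t"
            f"PASS\t{';'.join(info)}\tGT:AD:DP\t"
            f"0/1:{int(r['ref_count'])},{int(r['alt_count'])}:{dp}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_variants_vcf(path: str) -> pd.DataFrame:
    """Read a (single-sample) VCF written by :func:`variants_to_vcf` or any
    VCF carrying AD/DP and the annotation INFO keys."""
    import pysam  # deferred: only needed for VCF ingestion

    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        assembly = "hg19"
        for rec in vcf.header.records:
            if rec.key == "reference":
                assembly = str(rec.value)
        for rec in vcf:
            for sid in samples:
                fmt = rec.samples[sid]
                ad = fmt.get("AD")
                if ad is None:
                    continue
                rows.append({
                    "sample_id": sid,
                    "gene": rec.info.get("GENE"),
                    "chrom": rec.chrom, "pos": rec.pos,
                    "assembly": assembly,
                    "ref": rec.ref, "alt": rec.alts[0],
                    "ref_count": int(ad[0]), "alt_count": int(ad[1]),
                    "splice_ai": rec.info.get("SPLICE_AI"),
                    "sift": rec.info.get("SIFT"),
                    "polyphen2": rec.info.get("PP2"),
                    "clinvar_pathogenic": bool(rec.info.get("CLNPATH", False)),
                })
    return pd.DataFrame(rows)


def export_cohort(sim, outdir: str, write_vcfs: bool = False) -> dict:
    """Write a simulated cohort's tables (and optional per-sample VCFs)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "clinical": os.path.join(outdir, "cohort.tsv"),
        "variants": os.path.join(outdir, "variants.tsv"),
        "panel": os.path.join(outdir, "panel.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_tsv(sim.clinical, paths["clinical"])
    write_tsv(sim.variants, paths["variants"])
    write_tsv(sim.panel, paths["panel"])
    write_tsv(sim.truth_frame, paths["truth"])
    if write_vcfs:
        vcf_dir = os.path.join(outdir, "vcf")
        os.makedirs(vcf_dir, exist_ok=True)
        for sid in sim.clinical["sample_id"]:
            variants_to_vcf(sim.variants, sid,
                            os.path.join(vcf_dir, f"{sid}.vcf"))
        paths["vcf_dir"] = vcf_dir
    return paths
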