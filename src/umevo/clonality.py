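"""Tumor purity and cancer-cell-fraction estimation.

The founder Gq mutation is taken as clonal and heterozygous, so it sits at
50% VAF within tumor cells and tumor purity is TP = min(2 x VAF_Gq, 1).
BSE VAFs are purity-corrected (VAF/TP) and converted to CCF under a
gene-specific allelic model:

* SF3B1 (chr2, copy-stable): CCF = min(2 x corrected VAF, 1)
* EIF1AX (chrX): females as SF3B1; males hemizygous, CCF = min(cv, 1)
* BAP1 (3p21): with 3p retention, CCF = min(2 x cv, 1); with LOH3p (copy
  loss or isodisomy, both taken clonal), CCF = min(cv, 1); with no usable
  LOH call (confidence < 2) the CCF is left undefined and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genes import BSE_GENES, GQ_GENES


class AllelicModel(str, Enum):
    HET_AUTOSOME = "het_autosome"
    X_FEMALE = "x_female"
    X_MALE = "x_male"
    BAP1_RETENTION = "bap1_retention"
    BAP1_LOH = "bap1_loh"


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: str
    tp: float | None
    source_gene: str | None
    source_vaf: float | None
    capped: bool
    estimable: bool


@dataclass(frozen=True)
class CCFEstimate:
    sample_id: str
    gene: str
    raw_vaf: float
    corrected_vaf: float | None   # may exceed 1; None when TP not estimable
    ccf: float | None             # None when not computable (e.g. no LOH call)
    allelic_model: AllelicModel | None
    inconsistent: bool            # pre-cap value exceeded 1
    flagged_reason: str | None = None


_GQ_RANK = {g: i for i, g in enumerate(GQ_GENES)}


def estimate_purity(variants: pd.DataFrame, sample_id: str | None = None
                    ) -> PurityEstimate:
    """Estimate tumor purity from the highest-VAF pathogenic Gq mutation.

    ``variants`` holds one sample's classified calls (columns: sample_id,
    gene, vaf, pathogenic_call).  Ties on VAF break by canonical gene order
    GNAQ > GNA11 > PLCB4 > CYSLTR2 so output is deterministic.  Absence of
    a Gq mutation is a flagged state, not an error.
    """
    if sample_id is None:
        ids = variants["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("pass sample_id when the table mixes samples")
        sample_id = ids[0]
    else:
        variants = variants[variants["sample_id"] == sample_id]
    gq = variants[variants["gene"].isin(GQ_GENES)]
    if "pathogenic_call" in gq.columns:
        gq = gq[gq["pathogenic_call"] == "pathogenic"]
    if gq.empty:
        return PurityEstimate(sample_id=sample_id, tp=None, source_gene=None,
                              source_vaf=None, capped=False, estimable=False)
    order = gq.assign(_rank=gq["gene"].map(_GQ_RANK)).sort_values(
        ["vaf", "_rank"], ascending=[False, True])
    top = order.iloc[0]
    vaf = float(top["vaf"])
    tp = min(2.0 * vaf, 1.0)
    return PurityEstimate(sample_id=sample_id, tp=tp,
                          source_gene=str(top["gene"]), source_vaf=vaf,
                          capped=2.0 * vaf > 1.0, estimable=True)


def correct_vaf(vaf_bse: float, tp: float | None) -> float | None:
    """Purity-corrected VAF = VAF/TP, left uncapped (values > 1 are flagged
    downstream).  Returns None when purity is not estimable."""
    if tp is None:
        return None
    if not (0.0 < tp <= 1.0):
        raise ValueError("tp must lie in (0, 1]")
    return vaf_bse / tp


def estimate_ccf(gene: str, corrected_vaf: float | None, sex: str,
                 loh3p_status: str | None = None,
                 loh3p_usable: bool = True) -> tuple[float | None,
                                                     AllelicModel | None,
                                                     bool, str | None]:
    """CCF under the gene-specific allelic model.

    Returns (ccf, model, inconsistent, flagged_reason).  For BAP1 a usable
    LOH3p call is required; ``loh3p_status=None`` or ``loh3p_usable=False``
    leaves the CCF undefined.
    """
    if gene not in BSE_GENES:
        raise ValueError(f"{gene!r} is not a BSE gene")
    if corrected_vaf is None:
        return None, None, False, "purity_not_estimable"
    if corrected_vaf < 0:
        raise ValueError("corrected_vaf must be non-negative")
    if gene == "SF3B1":
        model, mult = AllelicModel.HET_AUTOSOME, 2.0
    elif gene == "EIF1AX":
        if sex == "male":
            model, mult = AllelicModel.X_MALE, 1.0
        else:
            model, mult = AllelicModel.X_FEMALE, 2.0
    else:  # BAP1
        if loh3p_status is None or not loh3p_usable:
            return None, None, False, "no_usable_loh3p_call"
        if loh3p_status in ("loss", "isodisomy"):
            model, mult = AllelicModel.BAP1_LOH, 1.0
        else:
            model, mult = AllelicModel.BAP1_RETENTION, 2.0
    raw = corrected_vaf * mult
    return min(raw, 1.0), model, raw > 1.0, None


class ClonalityEstimator(BaseEstimator):
    """Per-sample purity and BSE CCF estimation over a classified cohort.

    scikit-learn-style transformer: ``fit`` stores the LOH3p call table and
    clinical sex; ``transform`` maps a classified variant table to one
    purity row and one CCF row per (sample, BSE gene).

    Parameters
    ----------
    require_pathogenic : bool
        Restrict both the Gq purity source and the BSE numerators to
        variants called pathogenic.
    min_loh_confidence : int
        LOH3p confidence required for BAP1 allelic-model selection.
    """

    def __init__(self, require_pathogenic: bool = True,
                 min_loh_confidence: int = 2):
        self.require_pathogenic = require_pathogenic
        self.min_loh_confidence = min_loh_confidence

    def fit(self, clinical: pd.DataFrame,
            loh_calls: pd.DataFrame | None = None) -> "ClonalityEstimator":
        """Record per-sample sex and LOH3p calls used by ``transform``."""
        self.sex_ = dict(zip(clinical["sample_id"], clinical["sex"]))
        if loh_calls is not None and len(loh_calls):
            self.loh_ = loh_calls.set_index("sample_id")[
                ["status", "confidence"]].to_dict("index")
        else:
            self.loh_ = {}
        return self

    def transform(self, variants: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (purity table, CCF table) for all samples in ``variants``."""
        if not hasattr(self, "sex_"):
            raise RuntimeError("ClonalityEstimator must be fit before transform")
        df = variants
        if self.require_pathogenic and "pathogenic_call" in df.columns:
            usable = df[df["pathogenic_call"] == "pathogenic"]
        else:
            usable = df
        purity_rows, ccf_rows = [], []
        for sid, sub in usable.groupby("sample_id", sort=True):
            pe = estimate_purity(sub, sample_id=sid)
            purity_rows.append({
                "sample_id": sid, "tp": pe.tp, "source_gene": pe.source_gene,
                "source_vaf": pe.source_vaf, "capped": pe.capped,
                "estimable": pe.estimable})
            sex = self.sex_.get(sid, "female")
            loh = self.loh_.get(sid)
            loh_status = loh["status"] if loh else None
            loh_usable = (loh is not None
                          and loh["confidence"] >= self.min_loh_confidence)
            for _, row in sub[sub["gene"].isin(BSE_GENES)].iterrows():
                vaf = float(row["vaf"])
                cv = correct_vaf(vaf, pe.tp)
                ccf, model, inconsistent, reason = estimate_ccf(
                    row["gene"], cv, sex, loh_status, loh_usable)
                ccf_rows.append({
                    "sample_id": sid, "gene": row["gene"], "raw_vaf": vaf,
                    "corrected_vaf": cv, "ccf": ccf,
                    "allelic_model": model.value if model else None,
                    "inconsistent": inconsistent, "flagged_reason": reason})
        purity = pd.DataFrame(purity_rows, columns=[
            "sample_id", "tp", "source_gene", "source_vaf", "capped",
            "estimable"])
        ccf = pd.DataFrame(ccf_rows, columns=[
            "sample_id", "gene", "raw_vaf", "corrected_vaf", "ccf",
            "allelic_model", "inconsistent", "flagged_reason"])
        if len(purity):
            purity["tp"] = purity["tp"].astype(float)
        return purity, ccf

    def fit_transform(self, clinical: pd.DataFrame, variants: pd.DataFrame,
                      loh_calls: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
        return self.fit(clinical, loh_calls).transform(variants)
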