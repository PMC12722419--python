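"""End-to-end glue: classify, estimate, call, and merge a cohort.

`analyze_cohort` runs the full estimation chain on a simulated (or real)
cohort — pathogenicity classification, purity-aware LOH3p calling, purity
and CCF estimation — and returns the per-analysis tables plus a merged
per-sample table ready for the statistics and reporting layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonality import ClonalityEstimator, estimate_purity
from .genes import BSE_GENES, GQ_GENES
from .loh import LOH3pCaller
from .simulate import SimulatedCohort
from .variants import classify_frame, PathogenicityRuleEngine


@dataclass
class CohortEstimates:
    classified: pd.DataFrame
    purity: pd.DataFrame
    ccf: pd.DataFrame
    loh: pd.DataFrame
    merged: pd.DataFrame  # clinical + mutation flags + tp + CCFs + LOH


def analyze_cohort(sim: SimulatedCohort | None = None, *,
                   clinical: pd.DataFrame | None = None,
                   variants: pd.DataFrame | None = None,
                   panel: pd.DataFrame | None = None,
                   engine: PathogenicityRuleEngine | None = None,
                   loh_caller: LOH3pCaller | None = None,
                   clonality: ClonalityEstimator | None = None
                   ) -> CohortEstimates:
    """Run classification, LOH calling and clonality over a cohort.

    LOH calling is purity-aware: purity is estimated first from the Gq
    variants, passed to the LOH3p caller, and the resulting calls select
    the BAP1 allelic model.
    """
    if sim is not None:
        clinical, variants, panel = sim.clinical, sim.variants, sim.panel
    if clinical is None or variants is None:
        raise ValueError("need clinical and variant tables")

    classified = classify_frame(variants, engine)

    # purity first (needed for the purity-aware LOH threshold)
    pathogenic = classified[classified["pathogenic_call"] == "pathogenic"]
    purity_rows = [estimate_purity(sub, sample_id=sid)
                   for sid, sub in pathogenic.groupby("sample_id")]
    tp_map = {p.sample_id: p.tp for p in purity_rows if p.estimable}

    if panel is not None and len(panel):
        caller = (loh_caller or LOH3pCaller()).fit()
        loh = caller.predict(panel, purity=tp_map)
    else:
        loh = pd.DataFrame(columns=["sample_id", "status", "confidence",
                                    "median_mirrored_baf", "median_lfc",
                                    "n_informative", "usable", "is_loh"])

    est = (clonality or ClonalityEstimator()).fit(clinical, loh)
    purity, ccf = est.transform(classified)

    merged = clinical.copy()
    for g in GQ_GENES + BSE_GENES:
        carriers = set(pathogenic.loc[pathogenic["gene"] == g, "sample_id"])
        merged[f"mut_{g}"] = merged["sample_id"].isin(carriers)
    merged["any_bse"] = merged[[f"mut_{g}" for g in BSE_GENES]].any(axis=1)
    merged = merged.merge(purity[["sample_id", "tp"]], on="sample_id",
                          how="left")
    for g in BSE_GENES:
        sub = ccf[ccf["gene"] == g][["sample_id", "ccf"]].rename(
            columns={"ccf": f"ccf_{g}"})
        sub = sub.groupby("sample_id", as_index=False).first()
        merged = merged.merge(sub, on="sample_id", how="left")
    if len(loh):
        merged = merged.merge(
            loh[["sample_id", "status", "confidence", "usable"]].rename(
                columns={"status": "loh3p_status",
                         "confidence": "loh3p_confidence",
                         "usable": "loh3p_usable"}),
            on="sample_id", how="left")
        merged["loh3p"] = (merged["loh3p_usable"].fillna(False).astype(bool)
                           & merged["loh3p_status"].isin(["loss",
                                                          "isodisomy"]))
    else:
        merged["loh3p"] = False
    return CohortEstimates(classified=classified, purity=purity, ccf=ccf,
                           loh=loh, merged=merged)
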