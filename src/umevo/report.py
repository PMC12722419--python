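"""Evolutionary-state inference and cohort reporting.

Encodes the evolutionary readouts: the small-tumor definition (thickness
<= 2.5 mm and diameter <= 12 mm, inclusive), small-versus-large cohort
contrasts, a Class-transition classifier driven by the discriminant score
(a low score on either side of the SVM decision boundary marks a tumor
possibly in transition between Class 1 and Class 2), an oncoprint-style
sample x feature table with mutual-exclusivity summaries, and per-case
evolution timelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genes import BSE_GENES, GQ_GENES
from .stats import association_scan, AssociationResult

#: clonal/subclonal label cutoff on the CCF scale
CLONALITY_LABEL_CUTOFF = 0.5
#: default "low discriminant score" cutoff for the transition classifier
DEFAULT_TRANSITION_THRESHOLD = 0.2

TRANSITION_STATES = ("stable_class1", "transitional_class1",
                     "transitional_class2", "established_class2")


class InputError(ValueError):
    pass


def flag_small_tumor(thickness_mm: float, diameter_mm: float,
                     max_thickness: float = 2.5,
                     max_diameter: float = 12.0) -> bool:
    """Small-tumor rule: thickness <= 2.5 mm AND diameter <= 12 mm,
    boundaries inclusive."""
    if thickness_mm <= 0 or diameter_mm <= 0:
        raise InputError("tumor dimensions must be positive")
    return thickness_mm <= max_thickness and diameter_mm <= max_diameter


def small_vs_large_contrast(cohort: pd.DataFrame,
                            seed: int | None = None) -> dict:
    """Contrast small vs larger tumors on class, PRAME, BAP1, any-BSE,
    purity and within-class discriminant score.

    ``cohort`` needs thickness_mm, diameter_mm, gep_class, prame, optional
    mut_BAP1/any_bse/tp columns.  Returns per-variable results plus the
    direction of each continuous effect (mean small minus mean large).
    """
    df = cohort.copy()
    df["small"] = [flag_small_tumor(t, d) for t, d in
                   zip(df["thickness_mm"], df["diameter_mm"])]
    n_small = int(df["small"].sum())
    if n_small == 0 or n_small == len(df):
        return {"defined": False, "reason": "one size stratum is empty",
                "n_small": n_small, "n_large": len(df) - n_small}

    variables: dict[str, str] = {"gep_class": "categorical",
                                 "prame": "categorical"}
    for extra in ("mut_BAP1", "any_bse"):
        if extra in df.columns:
            variables[extra] = "categorical"
    if "tp" in df.columns:
        variables["tp"] = "continuous"
    results = association_scan(df, "small", variables, seed=seed)

    directions: dict[str, float] = {}
    small, large = df[df["small"]], df[~df["small"]]
    if "tp" in df.columns:
        directions["tp"] = float(small["tp"].mean() - large["tp"].mean())
    directions["class1_enrichment"] = float(
        (small["gep_class"] == "Class1").mean()
        - (large["gep_class"] == "Class1").mean())
    # within-class discriminant-score contrast
    dscore_results: dict[str, AssociationResult] = {}
    for cls in ("Class1", "Class2"):
        sub = df[df["gep_class"] == cls]
        if sub["small"].nunique() == 2 and len(sub) > 2:
            r = association_scan(sub, "small", {"dscore": "continuous"})[0]
            dscore_results[cls] = r
            directions[f"dscore_{cls}"] = float(
                sub.loc[sub["small"], "dscore"].mean()
                - sub.loc[~sub["small"], "dscore"].mean())
    return {"defined": True, "n_small": n_small,
            "n_large": len(df) - n_small, "results": results,
            "dscore_by_class": dscore_results, "directions": directions}


# ---------------------------------------------------------------------------
# transition-state classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionState:
    sample_id: str
    small_tumor: bool
    bse_status: str          # none | SF3B1 | EIF1AX | BAP1 | multiple
    transition_state: str
    rationale: tuple[str, ...]


def _bse_status(mutations: dict[str, bool] | None) -> str:
    present = [g for g in BSE_GENES if mutations and mutations.get(g)]
    if not present:
        return "none"
    if len(present) > 1:
        return "multiple"
    return present[0]


def classify_transition(sample_id: str, gep_class: str, dscore: float,
                        thickness_mm: float, diameter_mm: float,
                        mutations: dict[str, bool] | None = None,
                        loh3p: bool = False,
                        ccf_bap1: float | None = None,
                        threshold: float = DEFAULT_TRANSITION_THRESHOLD
                        ) -> EvolutionState:
    """Assign a Class-1-to-Class-2 transition state.

    A Class 1 tumor with a low discriminant score and evidence of BAP1
    pathway damage (mutation or LOH3p) is transitional on the Class 1 side;
    a Class 2 tumor with a low score is transitional on the Class 2 side;
    otherwise the tumor is stable Class 1 / established Class 2.  Each
    triggered rule is recorded in the rationale.
    """
    if dscore is None or (isinstance(dscore, float) and np.isnan(dscore)):
        raise InputError(f"{sample_id}: discriminant score missing")
    rationale: list[str] = []
    bap1_mut = bool(mutations and mutations.get("BAP1"))
    low = dscore < threshold
    if low:
        rationale.append(f"dscore {dscore:.3f} < threshold {threshold}")
    if bap1_mut:
        rationale.append("BAP1 mutation present")
    if loh3p:
        rationale.append("LOH3p present")
    if ccf_bap1 is not None and ccf_bap1 < CLONALITY_LABEL_CUTOFF:
        rationale.append(f"subclonal BAP1 (CCF {ccf_bap1:.2f} < "
                         f"{CLONALITY_LABEL_CUTOFF})")
    if gep_class == "Class1":
        state = ("transitional_class1" if low and (bap1_mut or loh3p)
                 else "stable_class1")
    elif gep_class == "Class2":
        state = "transitional_class2" if low else "established_class2"
    else:
        raise InputError(f"unknown class label {gep_class!r}")
    return EvolutionState(
        sample_id=sample_id,
        small_tumor=flag_small_tumor(thickness_mm, diameter_mm),
        bse_status=_bse_status(mutations), transition_state=state,
        rationale=tuple(rationale))


class TransitionClassifier(BaseEstimator):
    """Cohort-level transition-state classifier (scikit-learn-style).

    Parameters
    ----------
    threshold : float
        Discriminant-score cutoff below which a tumor counts as
        transitional (absolute-score scale, default 0.2).
    """

    def __init__(self, threshold: float = DEFAULT_TRANSITION_THRESHOLD):
        self.threshold = threshold

    def fit(self, X=None, y=None) -> "TransitionClassifier":
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        self.threshold_ = self.threshold
        self.classes_ = np.asarray(TRANSITION_STATES)
        return self

    def predict(self, cohort: pd.DataFrame,
                mutation_cols: dict[str, str] | None = None,
                loh_col: str = "loh3p",
                ccf_bap1_col: str = "ccf_BAP1") -> pd.DataFrame:
        """One row per sample with state, BSE status and rationale.

        ``mutation_cols`` maps gene -> boolean column (default mut_<gene>).
        """
        if not hasattr(self, "threshold_"):
            self.fit()
        mutation_cols = mutation_cols or {
            g: f"mut_{g}" for g in BSE_GENES}
        rows = []
        for _, r in cohort.iterrows():
            muts = {g: bool(r.get(col, False))
                    for g, col in mutation_cols.items()}
            ccf = r.get(ccf_bap1_col)
            ccf = None if ccf is None or (isinstance(ccf, float)
                                          and np.isnan(ccf)) else float(ccf)
            st = classify_transition(
                r["sample_id"], r["gep_class"], float(r["dscore"]),
                float(r["thickness_mm"]), float(r["diameter_mm"]),
                mutations=muts, loh3p=bool(r.get(loh_col, False)),
                ccf_bap1=ccf, threshold=self.threshold_)
            rows.append({
                "sample_id": st.sample_id, "small_tumor": st.small_tumor,
                "bse_status": st.bse_status,
                "transition_state": st.transition_state,
                "rationale": "; ".join(st.rationale)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# oncoprint and timelines
# ---------------------------------------------------------------------------

def build_oncoprint(cohort: pd.DataFrame, variants: pd.DataFrame | None = None
                    ) -> dict:
    """Sample x feature oncoprint table with mutual-exclusivity summaries.

    Rows are ordered deterministically by class, then BSE mutation pattern,
    then descending discriminant score.  Returns {'table': DataFrame,
    'co_occurrence': {'multi_gq': [...], 'multi_bse': [...]}}.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    df = cohort.copy()
    if variants is not None and len(variants):
        for g in GQ_GENES + BSE_GENES:
            carriers = set(variants.loc[variants["gene"] == g, "sample_id"])
            df[f"mut_{g}"] = df["sample_id"].isin(carriers)
    mut_cols = [c for c in df.columns if c.startswith("mut_")]
    bse_cols = [f"mut_{g}" for g in BSE_GENES if f"mut_{g}" in df.columns]
    gq_cols = [f"mut_{g}" for g in GQ_GENES if f"mut_{g}" in df.columns]
    df["_bse_pattern"] = (
        df[bse_cols].astype(int).astype(str).agg("".join, axis=1)
        if bse_cols else "")
    df = df.sort_values(["gep_class", "_bse_pattern", "dscore"],
                        ascending=[True, False, False],
                        kind="mergesort").drop(columns="_bse_pattern")
    keep = (["sample_id", "gep_class", "prame", "dscore", "thickness_mm",
             "diameter_mm", "sex"]
            + mut_cols
            + [c for c in ("mfs_event", "os_event") if c in df.columns])
    keep = [c for c in keep if c in df.columns]
    table = df[keep].reset_index(drop=True)

    multi_gq = (table.loc[table[gq_cols].sum(axis=1) >= 2, "sample_id"]
                .tolist() if gq_cols else [])
    multi_bse = (table.loc[table[bse_cols].sum(axis=1) >= 2, "sample_id"]
                 .tolist() if bse_cols else [])
    return {"table": table,
            "co_occurrence": {"multi_gq": multi_gq, "multi_bse": multi_bse}}


def clonality_label(ccf: float) -> str:
    return "near-clonal" if ccf >= CLONALITY_LABEL_CUTOFF else "sub-clonal"


def case_timeline(sample: pd.Series | dict,
                  ccf_estimates: pd.DataFrame | None,
                  loh_call: dict | pd.Series | None,
                  gq_gene: str | None = None) -> dict:
    """Ordered per-case evolution summary, serialisable to JSON.

    Events run founder Gq mutation -> BSE mutations (with clonal/subclonal
    labels at the CCF 0.5 cutoff) -> LOH3p -> class/discriminant score ->
    outcome.  A sample without a Gq mutation is excluded (cohort inclusion
    requires one); a missing clonality table yields a partial summary.
    """
    s = dict(sample)
    if gq_gene is None:
        return {"sample_id": s.get("sample_id"), "included": False,
                "reason": "no Gq mutation (inclusion criterion)"}
    events: list[dict] = [{"event": "founder_gq", "gene": gq_gene,
                           "label": "clonal"}]
    partial = False
    if ccf_estimates is None or len(ccf_estimates) == 0:
        partial = True
    else:
        for _, row in ccf_estimates.sort_values(
                "ccf", ascending=False, na_position="last").iterrows():
            if row.get("ccf") is None or (isinstance(row.get("ccf"), float)
                                          and np.isnan(row["ccf"])):
                events.append({"event": "bse_mutation", "gene": row["gene"],
                               "label": "ccf_undefined"})
                partial = True
            else:
                events.append({"event": "bse_mutation", "gene": row["gene"],
                               "ccf": float(row["ccf"]),
                               "label": clonality_label(float(row["ccf"]))})
    if loh_call is not None:
        lc = dict(loh_call)
        if lc.get("status") in ("loss", "isodisomy"):
            events.append({"event": "loh3p", "status": lc["status"],
                           "confidence": int(lc.get("confidence", 0))})
    events.append({"event": "classification",
                   "gep_class": s.get("gep_class"),
                   "dscore": float(s.get("dscore", np.nan)),
                   "prame": s.get("prame")})
    events.append({"event": "outcome",
                   "mfs_months": s.get("mfs_months"),
                   "mfs_event": s.get("mfs_event"),
                   "os_months": s.get("os_months"),
                   "os_event": s.get("os_event"),
                   "diameter_mm": s.get("diameter_mm")})
    return {"sample_id": s.get("sample_id"), "included": True,
            "partial": partial, "events": events}
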