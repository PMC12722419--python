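"""Chromosome-3p LOH calling from the targeted copy-number panel.

At each germline-heterozygous panel locus the mirrored B-allele frequency
(max(b, 1-b)) and the log2 fold-change of read depth against a panel of
normals are computed.  Whole-arm calls follow the pattern: copy loss shifts
the mirrored BAF toward 1/(2-purity) with depressed depth (lfc < 0);
copy-neutral isodisomy shifts BAF with depth near the normals; retention
stays at BAF 0.5.  Confidence (0-3) is scored automatically from the
dispersion (median absolute deviation) of the per-locus summaries and the
number of informative loci; a confidence of 2 or 3 marks the call usable
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

P3_STATES = ("retention", "loss", "isodisomy")


@dataclass(frozen=True)
class CallerThresholds:
    """Numeric thresholds of the LOH3p caller (all config-exposed)."""

    baf_tolerance: float = 0.08   # threshold sits this far below 1/(2-tp)
    fixed_baf_threshold: float = 0.60  # used when purity is unknown
    lfc_margin: float = 0.15      # |lfc| <= margin counts as "approximately 0"
    min_depth: int = 30           # per-locus depth below this is excluded
    min_loci: int = 10            # fewer informative loci forces confidence 0


@dataclass(frozen=True)
class ConfidenceBounds:
    """Dispersion/count bounds per confidence level (3 = high)."""

    mad_baf: tuple[float, float, float] = (0.04, 0.07, 0.12)
    mad_lfc: tuple[float, float, float] = (0.25, 0.45, 0.80)
    n_loci: tuple[int, int, int] = (40, 20, 5)


@dataclass(frozen=True)
class LOH3pCall:
    sample_id: str
    status: str                  # retention | loss | isodisomy
    confidence: int              # 0-3
    median_mirrored_baf: float
    median_lfc: float
    n_informative: int

    @property
    def usable(self) -> bool:
        return self.confidence >= 2

    @property
    def is_loh(self) -> bool:
        return self.status in ("loss", "isodisomy")


def compute_baf_lfc(panel: pd.DataFrame, min_depth: int = 30) -> pd.DataFrame:
    """Per-locus mirrored BAF and depth log fold-change for one sample.

    ``panel`` columns: locus_id, ref_count, alt_count, normals_depth and an
    ``informative`` flag (germline heterozygous).  Loci that are
    uninformative or below ``min_depth`` total reads are excluded from the
    returned summary table.
    """
    df = panel.copy()
    total = df["ref_count"] + df["alt_count"]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(total > 0, df["alt_count"] / total, np.nan)
        lfc = np.log2(total / df["normals_depth"])
    df["total_depth"] = total
    df["mirrored_baf"] = np.maximum(b, 1.0 - b)
    df["lfc"] = lfc
    keep = df.get("informative", pd.Series(True, index=df.index)).astype(bool)
    keep &= total >= min_depth
    return df.loc[keep, ["locus_id", "total_depth", "mirrored_baf", "lfc"]]


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def score_confidence(per_locus: pd.DataFrame,
                     bounds: ConfidenceBounds | None = None) -> int:
    """Confidence 0-3 from dispersion and locus count.

    A level is granted only when both MADs are within that level's bound and
    enough informative loci are present, so adding noise or dropping loci
    can never raise the score.
    """
    b = bounds or ConfidenceBounds()
    n = len(per_locus)
    if n == 0:
        return 0
    mad_baf = _mad(per_locus["mirrored_baf"].to_numpy())
    mad_lfc = _mad(per_locus["lfc"].to_numpy())
    for level, i in ((3, 0), (2, 1), (1, 2)):
        if (mad_baf <= b.mad_baf[i] and mad_lfc <= b.mad_lfc[i]
                and n >= b.n_loci[i]):
            return level
    return 0


def call_loh3p(panel: pd.DataFrame, tp: float | None = None,
               thresholds: CallerThresholds | None = None,
               bounds: ConfidenceBounds | None = None,
               sample_id: str | None = None) -> LOH3pCall:
    """Call the 3p state for one sample's panel.

    With purity known, the BAF threshold is the purity-aware LOH expectation
    1/(2-tp) minus ``baf_tolerance`` (normal-cell admixture keeps observed
    BAF below 1, so a literal BAF=1 rule would miss LOH at realistic
    purity); otherwise a fixed threshold is used.  Loss requires depressed
    depth (median lfc < -lfc_margin); isodisomy requires depth near the
    normals (|median lfc| <= lfc_margin).
    """
    thr = thresholds or CallerThresholds()
    if sample_id is None:
        ids = panel["sample_id"].unique() if "sample_id" in panel else ["?"]
        sample_id = str(ids[0])
    per_locus = compute_baf_lfc(panel, min_depth=thr.min_depth)
    n = len(per_locus)
    if n == 0:
        return LOH3pCall(sample_id=sample_id, status="retention",
                         confidence=0, median_mirrored_baf=np.nan,
                         median_lfc=np.nan, n_informative=0)
    mbaf = float(np.median(per_locus["mirrored_baf"]))
    mlfc = float(np.median(per_locus["lfc"]))
    if tp is not None and 0.0 < tp <= 1.0:
        baf_threshold = 1.0 / (2.0 - tp) - thr.baf_tolerance
    else:
        baf_threshold = thr.fixed_baf_threshold
    if mbaf >= baf_threshold and mlfc < -thr.lfc_margin:
        status = "loss"
    elif mbaf >= baf_threshold and abs(mlfc) <= thr.lfc_margin:
        status = "isodisomy"
    else:
        status = "retention"
    confidence = score_confidence(per_locus, bounds)
    if n < thr.min_loci:
        confidence = 0
    return LOH3pCall(sample_id=sample_id, status=status,
                     confidence=confidence, median_mirrored_baf=mbaf,
                     median_lfc=mlfc, n_informative=n)


class LOH3pCaller(BaseEstimator):
    """Cohort-level 3p LOH caller (scikit-learn-style).

    ``fit`` freezes the thresholds; ``predict`` maps a multi-sample panel
    table (and optionally per-sample purity) to one call row per sample.

    Parameters mirror :class:`CallerThresholds` / :class:`ConfidenceBounds`.
    """

    def __init__(self, baf_tolerance: float = 0.08,
                 fixed_baf_threshold: float = 0.60,
                 lfc_margin: float = 0.15, min_depth: int = 30,
                 min_loci: int = 10,
                 confidence_bounds: ConfidenceBounds | None = None):
        self.baf_tolerance = baf_tolerance
        self.fixed_baf_threshold = fixed_baf_threshold
        self.lfc_margin = lfc_margin
        self.min_depth = min_depth
        self.min_loci = min_loci
        self.confidence_bounds = confidence_bounds

    def fit(self, X=None, y=None) -> "LOH3pCaller":
        if not (0.0 < self.baf_tolerance < 0.5):
            raise ValueError("baf_tolerance must be in (0, 0.5)")
        if self.lfc_margin <= 0:
            raise ValueError("lfc_margin must be positive")
        self.thresholds_ = CallerThresholds(
            baf_tolerance=self.baf_tolerance,
            fixed_baf_threshold=self.fixed_baf_threshold,
            lfc_margin=self.lfc_margin, min_depth=self.min_depth,
            min_loci=self.min_loci)
        self.bounds_ = self.confidence_bounds or ConfidenceBounds()
        return self

    def predict(self, panel: pd.DataFrame,
                purity: pd.DataFrame | dict | None = None) -> pd.DataFrame:
        """One row per sample: status, confidence, summaries, usable flag.

        ``purity`` may be a dict sample_id -> tp or a DataFrame with columns
        (sample_id, tp).
        """
        if not hasattr(self, "thresholds_"):
            self.fit()
        tp_map: dict = {}
        if isinstance(purity, pd.DataFrame):
            tp_map = dict(zip(purity["sample_id"], purity["tp"]))
        elif isinstance(purity, dict):
            tp_map = purity
        rows = []
        for sid, sub in panel.groupby("sample_id", sort=True):
            tp = tp_map.get(sid)
            tp = None if tp is None or (isinstance(tp, float) and np.isnan(tp)) else float(tp)
            call = call_loh3p(sub, tp=tp, thresholds=self.thresholds_,
                              bounds=self.bounds_, sample_id=sid)
            rows.append({
                "sample_id": sid, "status": call.status,
                "confidence": call.confidence,
                "median_mirrored_baf": call.median_mirrored_baf,
                "median_lfc": call.median_lfc,
                "n_informative": call.n_informative,
                "usable": call.usable, "is_loh": call.is_loh})
        return pd.DataFrame(rows, columns=[
            "sample_id", "status", "confidence", "median_mirrored_baf",
            "median_lfc", "n_informative", "usable", "is_loh"])
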