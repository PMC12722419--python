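"""Variant classification and the pathogenicity rule engine.

Variant types follow the standard somatic taxonomy (nonsense, stop-loss,
start-loss, frameshift/non-frameshift indel, block substitution, splice
site, missense).  Pathogenicity is called from precomputed annotation
scores with inclusive thresholds: SpliceAI >= 0.5 with a predicted
acceptor/donor loss or gain for splice-site variants; for missense,
ClinVar-pathogenic OR SIFT <= 0.05 OR PolyPhen2 >= 0.5; truncating and
in/del/block types are pathogenic by type alone.  A missense variant with
no annotation at all is *indeterminate*, a state distinct from
not-pathogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genes import UMAM_GENES

SPLICE_AI_THRESHOLD = 0.5
SIFT_THRESHOLD = 0.05
POLYPHEN2_THRESHOLD = 0.5
DEFAULT_SPLICE_WINDOW = 2  # +/- bp around the canonical donor/acceptor


class VariantType(str, Enum):
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    BLOCK_SUBSTITUTION = "block_substitution"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"


#: variant types pathogenic by type alone
_TYPE_RULE_PATHOGENIC = frozenset({
    VariantType.NONSENSE, VariantType.STOP_LOSS, VariantType.START_LOSS,
    VariantType.FRAMESHIFT_INDEL, VariantType.NONFRAMESHIFT_INDEL,
    VariantType.BLOCK_SUBSTITUTION,
})

SPLICE_EFFECTS = frozenset({"acceptor_loss", "acceptor_gain",
                            "donor_loss", "donor_gain"})


class PathogenicityCall(str, Enum):
    PATHOGENIC = "pathogenic"
    NOT_PATHOGENIC = "not_pathogenic"
    INDETERMINATE = "indeterminate"


class Basis(str, Enum):
    TYPE_RULE = "type_rule"
    SPLICE_AI = "splice_ai"
    CLINVAR = "clinvar"
    SIFT = "sift"
    POLYPHEN2 = "polyphen2"
    NONE = "none"


class ClassificationError(ValueError):
    """Raised when a variant cannot be typed from the given context."""


class AssemblyError(ValueError):
    """Raised on a genome-assembly mismatch in a keyed join."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant call with read counts and annotation scores."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    assembly: str = "hg19"
    protein_change: str | None = None
    ref_count: int = 0
    alt_count: int = 0
    splice_ai: float | None = None
    sift: float | None = None
    polyphen2: float | None = None
    clinvar_pathogenic: bool | None = None
    splice_effect: str | None = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def vaf(self) -> float:
        total = self.ref_count + self.alt_count
        return self.alt_count / total if total else float("nan")

    @property
    def n_changed_nt(self) -> int:
        """Number of nucleotide changes (substituted + inserted/deleted)."""
        same_len = min(len(self.ref), len(self.alt))
        subs = sum(a != b for a, b in zip(self.ref[:same_len],
                                          self.alt[:same_len]))
        return subs + abs(len(self.ref) - len(self.alt))


@dataclass(frozen=True)
class CodonContext:
    """Reading-frame information needed to type a substitution.

    ``splice_distance`` is the signed distance (bp) to the nearest canonical
    splice donor/acceptor, None when not near an exon boundary.
    """

    creates_stop: bool = False
    removes_stop: bool = False
    removes_start: bool = False
    codons_affected: int = 1
    splice_distance: int | None = None


@dataclass(frozen=True)
class VariantClassification:
    variant_type: VariantType
    call: PathogenicityCall
    basis: Basis
    tier: str  # "I" | "II" | "III" | "untiered"


def classify_variant_type(v: VariantCall,
                          context: CodonContext | None = None,
                          splice_window: int = DEFAULT_SPLICE_WINDOW
                          ) -> VariantType:
    """Assign exactly one variant type.

    Splice-window proximity takes precedence; then indels by frame; then
    substitutions by codon context.  An SNV without context cannot be
    distinguished between nonsense and missense and raises.
    """
    ctx = context or CodonContext()
    if (ctx.splice_distance is not None
            and abs(ctx.splice_distance) <= splice_window):
        return VariantType.SPLICE_SITE
    dlen = len(v.alt) - len(v.ref)
    if dlen != 0:
        return (VariantType.FRAMESHIFT_INDEL if dlen % 3 != 0
                else VariantType.NONFRAMESHIFT_INDEL)
    if len(v.ref) > 1 and ctx.codons_affected >= 2:
        return VariantType.BLOCK_SUBSTITUTION
    if context is None:
        raise ClassificationError(
            "codon context required to type a substitution "
            f"({v.gene} {v.chrom}:{v.pos} {v.ref}>{v.alt})")
    if ctx.creates_stop:
        return VariantType.NONSENSE
    if ctx.removes_stop:
        return VariantType.STOP_LOSS
    if ctx.removes_start:
        return VariantType.START_LOSS
    return VariantType.MISSENSE


def call_pathogenic(v: VariantCall, variant_type: VariantType
                    ) -> tuple[PathogenicityCall, Basis]:
    """Apply the pathogenicity rules for a typed variant.

    Missense bases are attributed in the order ClinVar, SIFT, PolyPhen2
    (the call itself is an OR, so order affects reporting only).
    """
    if variant_type in _TYPE_RULE_PATHOGENIC:
        return PathogenicityCall.PATHOGENIC, Basis.TYPE_RULE
    if variant_type is VariantType.SPLICE_SITE:
        if (v.splice_ai is not None and v.splice_ai >= SPLICE_AI_THRESHOLD
                and v.splice_effect in SPLICE_EFFECTS):
            return PathogenicityCall.PATHOGENIC, Basis.SPLICE_AI
        return PathogenicityCall.NOT_PATHOGENIC, Basis.NONE
    # missense
    if (v.clinvar_pathogenic is None and v.sift is None
            and v.polyphen2 is None):
        return PathogenicityCall.INDETERMINATE, Basis.NONE
    if v.clinvar_pathogenic:
        return PathogenicityCall.PATHOGENIC, Basis.CLINVAR
    if v.sift is not None and v.sift <= SIFT_THRESHOLD:
        return PathogenicityCall.PATHOGENIC, Basis.SIFT
    if v.polyphen2 is not None and v.polyphen2 >= POLYPHEN2_THRESHOLD:
        return PathogenicityCall.PATHOGENIC, Basis.POLYPHEN2
    return PathogenicityCall.NOT_PATHOGENIC, Basis.NONE


#: default tier lookup: pathogenic variants in the seven recurrent genes are
#: tier I (strong clinical significance); anything else untiered
DEFAULT_TIERS: dict[str, str] = {g: "I" for g in UMAM_GENES}


def assign_tier(gene: str, call: PathogenicityCall,
                tiers: dict[str, str] | None = None) -> str:
    if call is not PathogenicityCall.PATHOGENIC:
        return "untiered"
    return (tiers or DEFAULT_TIERS).get(gene, "III")


class PathogenicityRuleEngine(BaseEstimator):
    """Rule-based pathogenicity classifier over precomputed annotations.

    A stateless scikit-learn-style classifier: ``fit`` validates parameters
    and sets ``rules_``; ``predict`` maps variants (with their codon
    contexts) to :class:`VariantClassification`.

    Parameters
    ----------
    splice_window : int
        Half-width (bp) of the canonical splice-site window.
    splice_ai_threshold, sift_threshold, polyphen2_threshold : float
        Inclusive score cutoffs.
    tiers : dict or None
        Gene -> tier lookup used for pathogenic variants.
    """

    def __init__(self, splice_window: int = DEFAULT_SPLICE_WINDOW,
                 splice_ai_threshold: float = SPLICE_AI_THRESHOLD,
                 sift_threshold: float = SIFT_THRESHOLD,
                 polyphen2_threshold: float = POLYPHEN2_THRESHOLD,
                 tiers: dict | None = None):
        self.splice_window = splice_window
        self.splice_ai_threshold = splice_ai_threshold
        self.sift_threshold = sift_threshold
        self.polyphen2_threshold = polyphen2_threshold
        self.tiers = tiers

    def fit(self, X=None, y=None) -> "PathogenicityRuleEngine":
        for name in ("splice_ai_threshold", "sift_threshold",
                     "polyphen2_threshold"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        self.rules_ = {
            "splice_ai": self.splice_ai_threshold,
            "sift": self.sift_threshold,
            "polyphen2": self.polyphen2_threshold,
        }
        return self

    def predict_one(self, v: VariantCall,
                    context: CodonContext | None = None
                    ) -> VariantClassification:
        vt = classify_variant_type(v, context, self.splice_window)
        call, basis = self._call(v, vt)
        return VariantClassification(
            variant_type=vt, call=call, basis=basis,
            tier=assign_tier(v.gene, call, self.tiers))

    def predict(self, variants: Sequence[VariantCall],
                contexts: Sequence[CodonContext | None] | None = None
                ) -> list[VariantClassification]:
        if not hasattr(self, "rules_"):
            self.fit()
        if contexts is None:
            contexts = [None] * len(variants)
        return [self.predict_one(v, c) for v, c in zip(variants, contexts)]

    def _call(self, v: VariantCall, vt: VariantType
              ) -> tuple[PathogenicityCall, Basis]:
        # same rule structure as call_pathogenic but with configured cutoffs
        if vt in _TYPE_RULE_PATHOGENIC:
            return PathogenicityCall.PATHOGENIC, Basis.TYPE_RULE
        if vt is VariantType.SPLICE_SITE:
            if (v.splice_ai is not None
                    and v.splice_ai >= self.splice_ai_threshold
                    and v.splice_effect in SPLICE_EFFECTS):
                return PathogenicityCall.PATHOGENIC, Basis.SPLICE_AI
            return PathogenicityCall.NOT_PATHOGENIC, Basis.NONE
        if (v.clinvar_pathogenic is None and v.sift is None
                and v.polyphen2 is None):
            return PathogenicityCall.INDETERMINATE, Basis.NONE
        if v.clinvar_pathogenic:
            return PathogenicityCall.PATHOGENIC, Basis.CLINVAR
        if v.sift is not None and v.sift <= self.sift_threshold:
            return PathogenicityCall.PATHOGENIC, Basis.SIFT
        if v.polyphen2 is not None and v.polyphen2 >= self.polyphen2_threshold:
            return PathogenicityCall.PATHOGENIC, Basis.POLYPHEN2
        return PathogenicityCall.NOT_PATHOGENIC, Basis.NONE


# ---------------------------------------------------------------------------
# BAP1 functional (SGE) comparison
# ---------------------------------------------------------------------------

def filter_complex_bap1(variants: Iterable[VariantCall],
                        max_changes: int = 4
                        ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition BAP1 variants into (kept, excluded) by nucleotide-change
    count; complex alterations (>= 5 changed nucleotides) are excluded."""
    kept, excluded = [], []
    for v in variants:
        (kept if v.n_changed_nt <= max_changes else excluded).append(v)
    return kept, excluded


@dataclass(frozen=True)
class SGERecord:
    """One saturation-genome-editing record keyed by hg38 start/ref/alt."""

    pos: int
    ref: str
    alt: str
    functional_class: str  # "depleted" | "not_depleted"
    functional_score: float


def join_sge(variants: Sequence[VariantCall], table: Sequence[SGERecord]
             ) -> pd.DataFrame:
    """Match variants to an SGE table on hg38 start position, ref and alt.

    Variants not tagged hg38 raise :class:`AssemblyError` (a silent hg19
    join would be wrong by construction).  Unmatched variants are flagged
    ``unmapped``.
    """
    for v in variants:
        if v.assembly != "hg38":
            raise AssemblyError(
                f"SGE join requires hg38 coordinates; {v.sample_id} "
                f"{v.gene} is tagged {v.assembly!r}")
    index = {(r.pos, r.ref, r.alt): r for r in table}
    rows = []
    for v in variants:
        rec = index.get((v.pos, v.ref, v.alt))
        rows.append({
            "sample_id": v.sample_id, "gene": v.gene, "pos": v.pos,
            "ref": v.ref, "alt": v.alt,
            "mapped": rec is not None,
            "functional_class": rec.functional_class if rec else None,
            "functional_score": rec.functional_score if rec else np.nan,
        })
    return pd.DataFrame(rows)


def compare_functional_by_class(annotated: pd.DataFrame,
                                class_labels: pd.Series | dict
                                ) -> dict[str, float]:
    """Compare SGE depletion and scores between Class 1 and Class 2 tumors.

    Two-tailed Fisher exact on the depleted x class 2x2 table, and a
    two-tailed rank-sum test on the functional scores.
    """
    df = annotated[annotated["mapped"]].copy()
    labels = pd.Series(class_labels)
    df["gep_class"] = df["sample_id"].map(labels)
    if df["gep_class"].nunique() < 2:
        raise ValueError("both classes need at least one annotated variant")
    table = np.zeros((2, 2), dtype=int)
    for j, cls in enumerate(("Class1", "Class2")):
        sub = df[df["gep_class"] == cls]
        table[0, j] = int((sub["functional_class"] == "depleted").sum())
        table[1, j] = int((sub["functional_class"] != "depleted").sum())
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    s1 = df.loc[df["gep_class"] == "Class1", "functional_score"].dropna()
    s2 = df.loc[df["gep_class"] == "Class2", "functional_score"].dropna()
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both classes need functional scores")
    _, wilcoxon_p = stats.mannwhitneyu(s1, s2, alternative="two-sided")
    return {"fisher_p": float(fisher_p), "wilcoxon_p": float(wilcoxon_p),
            "table": table.tolist(),
            "n_class1": int(len(s1)), "n_class2": int(len(s2))}


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def classify_frame(variants: pd.DataFrame,
                   engine: PathogenicityRuleEngine | None = None
                   ) -> pd.DataFrame:
    """Classify a variant table (simulator output or TSV) row by row.

    Uses the ``variant_type_hint`` column when present to build the codon
    context (simulated variants carry one); rows without a hint must be
    typable from alleles alone.
    """
    eng = (engine or PathogenicityRuleEngine()).fit()
    out = []
    for _, row in variants.iterrows():
        v = VariantCall(
            sample_id=row["sample_id"], gene=row["gene"],
            chrom=str(row.get("chrom", "")), pos=int(row.get("pos", 0)),
            ref=row.get("ref", "N"), alt=row.get("alt", "N"),
            assembly=row.get("assembly", "hg19"),
            protein_change=row.get("protein_change"),
            ref_count=int(row["ref_count"]), alt_count=int(row["alt_count"]),
            splice_ai=_opt(row.get("splice_ai")),
            sift=_opt(row.get("sift")),
            polyphen2=_opt(row.get("polyphen2")),
            clinvar_pathogenic=_opt_bool(row.get("clinvar_pathogenic")),
            splice_effect=row.get("splice_effect") or None,
        )
        ctx = _context_from_hint(row.get("variant_type_hint"))
        cls = eng.predict_one(v, ctx)
        out.append({
            "sample_id": v.sample_id, "gene": v.gene, "vaf": v.vaf,
            "ref_count": v.ref_count, "alt_count": v.alt_count,
            "variant_type": cls.variant_type.value,
            "pathogenic_call": cls.call.value, "basis": cls.basis.value,
            "tier": cls.tier,
        })
    return pd.DataFrame(out)


def _opt(x) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return float(x)


def _opt_bool(x) -> bool | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return bool(x)


def _context_from_hint(hint) -> CodonContext | None:
    if hint is None or (isinstance(hint, float) and np.isnan(hint)):
        return None
    mapping = {
        "missense": CodonContext(),
        "nonsense": CodonContext(creates_stop=True),
        "stop_loss": CodonContext(removes_stop=True),
        "start_loss": CodonContext(removes_start=True),
        "splice_site": CodonContext(splice_distance=1),
        "frameshift_indel": CodonContext(),
        "nonframeshift_indel": CodonContext(),
        "block_substitution": CodonContext(codons_affected=2),
    }
    return mapping.get(str(hint), CodonContext())
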