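"""Variant typing, pathogenicity rules, BAP1 filtering and SGE joins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from umevo import (CodonContext, PathogenicityCall, PathogenicityRuleEngine,
                   SGERecord, VariantCall, VariantType, call_pathogenic,
                   classify_variant_type, compare_functional_by_class,
                   filter_complex_bap1, join_sge)
from umevo.variants import AssemblyError, Basis, ClassificationError


def vc(ref="A", alt="T", gene="BAP1", assembly="hg19", **kw):
    return VariantCall(sample_id="S1", gene=gene, chrom="3", pos=100,
                       ref=ref, alt=alt, assembly=assembly, **kw)


class TestClassifyType:
    def test_stop_creating_snv_is_nonsense(self):
        assert classify_variant_type(
            vc(), CodonContext(creates_stop=True)) is VariantType.NONSENSE

    def test_two_base_deletion_is_frameshift(self):
        assert classify_variant_type(
            vc(ref="ATG", alt="A")) is VariantType.FRAMESHIFT_INDEL

    def test_in_frame_insertion(self):
        assert classify_variant_type(
            vc(ref="A", alt="AGGG")) is VariantType.NONFRAMESHIFT_INDEL

    def test_splice_window_takes_precedence(self):
        assert classify_variant_type(
            vc(), CodonContext(splice_distance=2)) is VariantType.SPLICE_SITE
        assert classify_variant_type(
            vc(), CodonContext(splice_distance=3)) is VariantType.MISSENSE

    def test_multi_codon_substitution_is_block(self):
        assert classify_variant_type(
            vc(ref="ATGATG", alt="CCCCCC"),
            CodonContext(codons_affected=2)) is VariantType.BLOCK_SUBSTITUTION

    def test_snv_without_context_raises(self):
        with pytest.raises(ClassificationError):
            classify_variant_type(vc(), None)

    def test_types_are_mutually_exclusive_and_total(self):
        # every well-formed (allele, context) combination yields one type
        contexts = [CodonContext(), CodonContext(creates_stop=True),
                    CodonContext(removes_stop=True),
                    CodonContext(removes_start=True),
                    CodonContext(splice_distance=1),
                    CodonContext(codons_affected=2)]
        alleles = [("A", "T"), ("AT", "A"), ("A", "ATTT"), ("ATGATG", "CCCCCC")]
        for ref, alt in alleles:
            for ctx in contexts:
                t = classify_variant_type(vc(ref=ref, alt=alt), ctx)
                assert isinstance(t, VariantType)


class TestCallPathogenic:
    def test_truncating_types_pathogenic_by_type_rule(self):
        for t in (VariantType.NONSENSE, VariantType.STOP_LOSS,
                  VariantType.START_LOSS, VariantType.FRAMESHIFT_INDEL,
                  VariantType.NONFRAMESHIFT_INDEL,
                  VariantType.BLOCK_SUBSTITUTION):
            call, basis = call_pathogenic(vc(), t)
            assert call is PathogenicityCall.PATHOGENIC
            assert basis is Basis.TYPE_RULE

    def test_splice_ai_threshold_inclusive(self):
        ok = vc(splice_ai=0.5, splice_effect="donor_loss")
        call, basis = call_pathogenic(ok, VariantType.SPLICE_SITE)
        assert call is PathogenicityCall.PATHOGENIC and basis is Basis.SPLICE_AI
        below = vc(splice_ai=0.4, splice_effect="donor_loss")
        assert call_pathogenic(below, VariantType.SPLICE_SITE)[0] is \
            PathogenicityCall.NOT_PATHOGENIC

    def test_splice_requires_predicted_site_change(self):
        v = vc(splice_ai=0.9, splice_effect=None)
        assert call_pathogenic(v, VariantType.SPLICE_SITE)[0] is \
            PathogenicityCall.NOT_PATHOGENIC

    def test_missense_sift_boundary_inclusive(self):
        v = vc(sift=0.05, polyphen2=0.1)
        call, basis = call_pathogenic(v, VariantType.MISSENSE)
        assert call is PathogenicityCall.PATHOGENIC and basis is Basis.SIFT

    def test_missense_polyphen_boundary_inclusive(self):
        v = vc(sift=0.5, polyphen2=0.5)
        call, basis = call_pathogenic(v, VariantType.MISSENSE)
        assert call is PathogenicityCall.PATHOGENIC and basis is Basis.POLYPHEN2

    def test_missense_clinvar_takes_reporting_precedence(self):
        v = vc(clinvar_pathogenic=True, sift=0.01)
        call, basis = call_pathogenic(v, VariantType.MISSENSE)
        assert basis is Basis.CLINVAR

    def test_unannotated_missense_is_indeterminate(self):
        call, basis = call_pathogenic(vc(), VariantType.MISSENSE)
        assert call is PathogenicityCall.INDETERMINATE
        assert basis is Basis.NONE

    def test_annotated_benign_missense_not_pathogenic(self):
        v = vc(sift=0.4, polyphen2=0.2, clinvar_pathogenic=False)
        assert call_pathogenic(v, VariantType.MISSENSE)[0] is \
            PathogenicityCall.NOT_PATHOGENIC


class TestRuleEngine:
    def test_engine_matches_function_on_boundary_grid(self):
        eng = PathogenicityRuleEngine().fit()
        eps = 1e-6
        scores = [None, 0.0, 0.05 - eps, 0.05, 0.05 + eps, 0.5 - eps, 0.5,
                  0.5 + eps, 1.0]
        for sift in scores:
            for pp2 in scores:
                for clv in (None, True, False):
                    v = vc(sift=sift, polyphen2=pp2, clinvar_pathogenic=clv)
                    assert eng._call(v, VariantType.MISSENSE) == \
                        call_pathogenic(v, VariantType.MISSENSE)

    def test_get_set_params_roundtrip(self):
        eng = PathogenicityRuleEngine(sift_threshold=0.01)
        params = eng.get_params()
        assert params["sift_threshold"] == 0.01
        eng.set_params(splice_window=5)
        assert eng.splice_window == 5

    def test_tier_assigned_only_when_pathogenic(self):
        eng = PathogenicityRuleEngine().fit()
        res = eng.predict_one(vc(sift=0.01), CodonContext())
        assert res.tier == "I"
        res2 = eng.predict_one(vc(sift=0.9, polyphen2=0.1), CodonContext())
        assert res2.tier == "untiered"


class TestFilterComplexBap1:
    def test_partition_and_boundaries(self):
        snv = vc()
        del4 = vc(ref="ATGCA", alt="A")        # 4 deleted nucleotides
        block6 = vc(ref="ATGATG", alt="CCCCCC")  # 6 substituted
        kept, excluded = filter_complex_bap1([snv, del4, block6])
        assert kept == [snv, del4]
        assert excluded == [block6]

    def test_exact_partition_preserves_order(self, rng):
        pool = [vc(ref="A" * int(rng.integers(1, 8)), alt="T")
                for _ in range(30)]
        kept, excluded = filter_complex_bap1(pool)
        assert sorted(map(id, kept + excluded)) == sorted(map(id, pool))


class TestSgeJoin:
    def test_keyed_lookup_and_unmapped_flag(self):
        table = [SGERecord(pos=100, ref="A", alt="T",
                           functional_class="depleted", functional_score=-2.0)]
        hit = vc(assembly="hg38")
        miss = VariantCall(sample_id="S2", gene="BAP1", chrom="3", pos=999,
                           ref="G", alt="C", assembly="hg38")
        out = join_sge([hit, miss], table)
        assert out.loc[0, "mapped"] and out.loc[0, "functional_class"] == "depleted"
        assert not out.loc[1, "mapped"]

    def test_hg19_variants_refused(self):
        with pytest.raises(AssemblyError):
            join_sge([vc(assembly="hg19")], [])

    def test_set_intersection_on_synthetic_table(self, rng):
        # 300 synthetic variants, 250 present in a synthetic SGE table
        positions = rng.choice(100000, size=300, replace=False)
        variants = [VariantCall(sample_id=f"S{i}", gene="BAP1", chrom="3",
                                pos=int(p), ref="A", alt="T", assembly="hg38")
                    for i, p in enumerate(positions)]
        table = [SGERecord(pos=int(p), ref="A", alt="T",
                           functional_class="depleted", functional_score=0.0)
                 for p in positions[:250]]
        out = join_sge(variants, table)
        assert int(out["mapped"].sum()) == 250
        assert int((~out["mapped"]).sum()) == 50


def fisher_enumeration(table):
    """Two-sided Fisher p by hypergeometric enumeration (independent oracle)."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: sps.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestCompareFunctionalByClass:
    def _annotated(self, table):
        rows, labels = [], {}
        i = 0
        for j, cls in enumerate(("Class1", "Class2")):
            for k, fclass in enumerate(("depleted", "not_depleted")):
                for _ in range(table[k][j]):
                    sid = f"S{i}"
                    rows.append({"sample_id": sid, "gene": "BAP1",
                                 "mapped": True, "functional_class": fclass,
                                 "functional_score": float(k) + i * 1e-4})
                    labels[sid] = cls
                    i += 1
        return pd.DataFrame(rows), labels

    def test_fisher_matches_enumeration_oracle(self):
        table = [[8, 1], [2, 9]]  # depleted x class
        df, labels = self._annotated(table)
        out = compare_functional_by_class(df, labels)
        assert out["fisher_p"] == pytest.approx(fisher_enumeration(table),
                                                rel=1e-6)
        assert out["fisher_p"] == pytest.approx(0.005477, abs=5e-4)

    def test_identical_scores_give_null_wilcoxon(self, rng):
        scores = rng.normal(size=12)
        rows = []
        labels = {}
        for i, s in enumerate(scores):
            for j, cls in enumerate(("Class1", "Class2")):
                sid = f"S{i}_{j}"
                rows.append({"sample_id": sid, "gene": "BAP1", "mapped": True,
                             "functional_class": "depleted",
                             "functional_score": float(s)})
                labels[sid] = cls
        out = compare_functional_by_class(pd.DataFrame(rows), labels)
        assert out["wilcoxon_p"] > 0.9

    def test_degenerate_margin_gives_p_one(self):
        df, labels = self._annotated([[5, 5], [0, 0]])
        out = compare_functional_by_class(df, labels)
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        df, labels = self._annotated([[3, 0], [2, 0]])
        with pytest.raises(ValueError):
            compare_functional_by_class(df, labels)
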