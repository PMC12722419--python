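"""Synthetic cohort generator.

Generates uveal-melanoma cohorts with the statistical structure the
downstream estimators assume — a clonal heterozygous Gq founder mutation
(present at 50% VAF in tumor cells), subclonal BSE mutations, size-dependent
tumor purity, chromosome-3p copy states, binomial read sampling at variant
and panel loci, a discriminant score that inverts progressively after BAP1
loss, and class/mutation-dependent survival — while retaining the generative
ground truth for every sample so estimator recovery can be measured.

Two read models are exposed.  ``paper_consistent`` draws reads from the
allelic expectations the purity/CCF formulas invert (so those estimators are
unbiased by construction); ``copy_aware`` additionally dilutes the mutant
allele pool by the normal diploid admixture at LOH loci, which makes the
estimator's bias at such loci measurable rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .config import SimConfig, ConfigurationError
from .genes import (BSE_GENES, GENE_CHROM, GENE_POS_HG19, GQ_GENES,
                    GQ_HOTSPOTS, is_x_linked)

P3State = Literal["retention", "loss", "isodisomy"]

#: 3p arm span (bp) over which the panel's 74 loci are placed
_P3_ARM_SPAN = (1_000_000, 89_000_000)


@dataclass
class SyntheticTruth:
    """Generative parameters retained for one simulated tumor."""

    sample_id: str
    sex: str                       # "female" | "male"
    true_purity: float
    true_ccf: dict[str, float]     # BSE gene -> fraction (founder Gq is 1.0)
    true_3p_state: P3State
    true_class: str                # "Class1" | "Class2"
    true_dscore: float
    months_since_bap1_loss: float | None

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_purity <= 1.0):
            raise ConfigurationError("true_purity outside [0, 1]")
        if not (0.0 <= self.true_dscore <= 1.0):
            raise ConfigurationError("true_dscore outside [0, 1]")
        for g, c in self.true_ccf.items():
            if not (0.0 <= c <= 1.0):
                raise ConfigurationError(f"true CCF for {g} outside [0, 1]")


@dataclass
class SimulatedCohort:
    """Bundle of simulated tables; one row per sample/variant/locus."""

    clinical: pd.DataFrame
    variants: pd.DataFrame
    panel: pd.DataFrame
    truth: list[SyntheticTruth] = field(repr=False)
    config: SimConfig = field(repr=False)

    @property
    def truth_frame(self) -> pd.DataFrame:
        return truth_to_frame(self.truth)


def truth_to_frame(truth: list[SyntheticTruth]) -> pd.DataFrame:
    rows = []
    for t in truth:
        row = {
            "sample_id": t.sample_id,
            "sex": t.sex,
            "true_purity": t.true_purity,
            "true_3p_state": t.true_3p_state,
            "true_class": t.true_class,
            "true_dscore": t.true_dscore,
            "months_since_bap1_loss": t.months_since_bap1_loss,
        }
        for g in BSE_GENES:
            row[f"true_ccf_{g}"] = t.true_ccf.get(g, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expected allele fractions (the generative arithmetic)
# ---------------------------------------------------------------------------

def expected_vaf(gene: str, purity: float, ccf: float, sex: str,
                 p3_state: P3State, read_model: str) -> float:
    """Expected variant allele fraction under the chosen read model.

    ``paper_consistent`` inverts the estimator arithmetic exactly:
    purity*CCF/2 at heterozygous loci and purity*CCF at hemizygous loci
    (male X, or BAP1 after 3p loss/isodisomy).  ``copy_aware`` mixes allele
    pools: purity*CCF*copies_mut / (purity*copies_tumor + (1-purity)*2),
    with the normal compartment contributing one copy on the male X.
    """
    hemizygous_x = is_x_linked(gene) and sex == "male"
    bap1_loh = gene == "BAP1" and p3_state in ("loss", "isodisomy")
    if read_model == "paper_consistent":
        if hemizygous_x or bap1_loh:
            return purity * ccf
        return purity * ccf / 2.0
    if read_model == "copy_aware":
        if hemizygous_x:
            return purity * ccf / (purity + (1.0 - purity))
        if gene == "BAP1" and p3_state == "loss":
            # all tumor cells carry one 3p copy (LOH taken clonal)
            return purity * ccf / (purity + 2.0 * (1.0 - purity))
        if gene == "BAP1" and p3_state == "isodisomy":
            # mutant haplotype duplicated: 2 mutant copies of 2 tumor copies
            return 2.0 * purity * ccf / (2.0 * purity + 2.0 * (1.0 - purity))
        return purity * ccf / 2.0
    raise ConfigurationError(f"unknown read_model {read_model!r}")


def expected_mirrored_baf(p3_state: P3State, purity: float) -> float:
    """Expected mirrored B-allele frequency at an informative 3p panel locus.

    Allele-pool arithmetic: under copy loss the retained allele is carried by
    every tumor cell once and by normal cells once of two, giving
    1/(2-purity); under isodisomy the duplicated haplotype gives
    (1+purity)/2; retention stays at 1/2.
    """
    if p3_state == "retention":
        return 0.5
    if p3_state == "loss":
        return 1.0 / (2.0 - purity)
    if p3_state == "isodisomy":
        return (1.0 + purity) / 2.0
    raise ConfigurationError(f"unknown 3p state {p3_state!r}")


def expected_depth_factor(p3_state: P3State, purity: float) -> float:
    """Tumor/normal read-depth ratio at 3p: (2-purity)/2 under loss, else 1."""
    if p3_state == "loss":
        return (2.0 - purity) / 2.0
    return 1.0


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

def simulate_variant_reads(truth: SyntheticTruth, gene: str, depth: float,
                           read_model: str, rng: np.random.Generator,
                           ccf: float | None = None) -> dict:
    """Draw binomial read counts for one mutation in one tumor.

    The founder Gq mutation is taken at CCF 1; BSE CCFs come from the truth
    record unless overridden.  Returns a plain dict (one variant-table row).
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    if ccf is None:
        ccf = 1.0 if gene in GQ_GENES else truth.true_ccf.get(gene)
    if ccf is None:
        raise ConfigurationError(f"{gene} has no true CCF in this tumor")
    evaf = expected_vaf(gene, truth.true_purity, ccf, truth.sex,
                        truth.true_3p_state, read_model)
    total = max(int(rng.poisson(depth)), 1)
    alt = int(rng.binomial(total, min(max(evaf, 0.0), 1.0)))
    return {
        "sample_id": truth.sample_id,
        "gene": gene,
        "chrom": GENE_CHROM[gene],
        "pos": GENE_POS_HG19[gene],
        "assembly": "hg19",
        "ref_count": total - alt,
        "alt_count": alt,
        "true_ccf": ccf,
        "expected_vaf": evaf,
    }


def simulate_cnv_panel(truth: SyntheticTruth, config: SimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the chromosome-3p copy-number panel for one tumor.

    Informative (germline heterozygous) loci get binomial B-allele counts at
    the state- and purity-dependent expectation; uninformative loci are
    homozygous.  Per-locus depth carries multiplicative log-normal noise and
    is scaled by (2-purity)/2 under copy loss.
    """
    n = config.n_panel_loci
    pos = np.linspace(*_P3_ARM_SPAN, n).astype(int)
    informative = rng.random(n) >= config.panel_dropout
    depth_factor = expected_depth_factor(truth.true_3p_state, truth.true_purity)
    noise = np.exp(rng.normal(0.0, config.depth_noise_sd, n))
    depth = np.maximum(rng.poisson(config.depth_panel * depth_factor * noise), 1)

    mbaf = expected_mirrored_baf(truth.true_3p_state, truth.true_purity)
    # which allele (ref vs alt) sits on the favoured haplotype is random
    flip = rng.random(n) < 0.5
    p_alt = np.where(flip, mbaf, 1.0 - mbaf)
    # uninformative loci are homozygous ref or alt in the germline
    hom_alt = rng.random(n) < 0.5
    p_alt = np.where(informative, p_alt, np.where(hom_alt, 1.0, 0.0))
    alt = rng.binomial(depth, p_alt)

    return pd.DataFrame({
        "sample_id": truth.sample_id,
        "locus_id": [f"3p_{i:03d}" for i in range(n)],
        "chrom": "3",
        "pos": pos,
        "ref_count": depth - alt,
        "alt_count": alt,
        "normals_depth": float(config.depth_panel),
        "informative": informative,
    })


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def _draw_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def _saturation(months: float, tau: float) -> float:
    return 1.0 - np.exp(-months / tau)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (clinical, variants, 3p panel, truth).

    Deterministic for a fixed config: every draw comes from a single
    generator seeded with ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sm, pm, dm, vm = (config.size_model, config.purity_model,
                      config.dscore_model, config.survival_model)

    clinical_rows, variant_rows, panel_frames, truths = [], [], [], []
    for i in range(config.n_patients):
        sid = f"S{i:05d}"
        sex = "male" if rng.random() < config.male_fraction else "female"
        cls = "Class1" if rng.random() < config.class1_fraction else "Class2"

        # --- driver genotype -------------------------------------------------
        gq_primary = _draw_categorical(rng, config.gq_prevalences)
        gq_genes = [gq_primary]
        if rng.random() < config.second_gq_prob:
            others = [g for g in GQ_GENES if g != gq_primary]
            gq_genes.append(others[rng.choice(len(others))])

        bse_probs = (config.bse_probs_class1 if cls == "Class1"
                     else config.bse_probs_class2)
        first = _draw_categorical(rng, bse_probs)
        bse_genes = [] if first == "none" else [first]
        if bse_genes and rng.random() < config.second_bse_prob:
            others = [g for g in BSE_GENES if g not in bse_genes]
            bse_genes.append(others[rng.choice(len(others))])

        # --- size ------------------------------------------------------------
        dmean = sm.diameter_mean_class1 if cls == "Class1" else sm.diameter_mean_class2
        dmean += sum(sm.diameter_shift.get(g, 0.0) for g in bse_genes)
        diameter = float(np.clip(rng.normal(dmean, sm.diameter_sd),
                                 sm.diameter_min, sm.diameter_max))
        thickness = float(np.clip(
            sm.thickness_intercept + sm.thickness_slope * diameter
            + rng.normal(0.0, sm.thickness_sd),
            sm.thickness_min, sm.thickness_max))
        small = (thickness <= config.small_thickness_mm
                 and diameter <= config.small_diameter_mm)

        # --- purity ----------------------------------------------------------
        mean, sd = ((pm.small_mean, pm.small_sd) if small
                    else (pm.large_mean, pm.large_sd))
        purity = float(np.clip(rng.normal(mean, sd), pm.lo, pm.hi))

        # --- 3p state --------------------------------------------------------
        if "BAP1" in bse_genes:
            p3 = _draw_categorical(rng, config.p3_probs_bap1_mut)
        elif cls == "Class2":
            p3 = _draw_categorical(rng, config.p3_probs_bap1_wt_class2)
        else:
            p3 = _draw_categorical(rng, config.p3_probs_bap1_wt_class1)

        # --- CCFs ------------------------------------------------------------
        ccf: dict[str, float] = {}
        for g in bse_genes:
            if g == "BAP1":
                ccf[g] = float(np.clip(rng.beta(6.0, 2.0), 0.05, 1.0))
            else:
                trend = 0.25 + 0.55 * (diameter - sm.diameter_min) / (
                    sm.diameter_max - sm.diameter_min)
                ccf[g] = float(np.clip(trend + rng.normal(0.0, 0.15), 0.05, 1.0))

        # --- BAP1 dosage deficit and discriminant process --------------------
        deficit = 0.0
        if "BAP1" in bse_genes:
            deficit += ccf["BAP1"] / 2.0
        if p3 in ("loss", "isodisomy"):
            deficit += 0.5
        months: float | None = None
        if deficit > 0.0:
            months = float(np.clip(
                4.0 * (diameter - sm.diameter_min) + rng.normal(0.0, 8.0),
                0.0, 120.0))
            z = (-1.0 + dm.slope * deficit * _saturation(months, dm.tau_months)
                 + rng.normal(0.0, dm.noise_sd))
        else:
            z = -1.0 + rng.normal(0.0, dm.noise_sd)
        dscore = float(np.clip(abs(z), 0.0, 1.0))

        # --- PRAME -----------------------------------------------------------
        p_pos = (config.prame_pos_class1 if cls == "Class1"
                 else config.prame_pos_class2)
        prame = "positive" if rng.random() < p_pos else "negative"

        # --- survival --------------------------------------------------------
        is2 = 1.0 if cls == "Class2" else 0.0
        isp = 1.0 if prame == "positive" else 0.0
        h_mfs = vm.mfs_base_hazard * np.exp(
            vm.mfs_log_hr_class2 * is2 + vm.mfs_log_hr_prame * isp
            + vm.mfs_log_hr_diameter * (diameter - 12.0))
        h_os = vm.os_base_hazard * np.exp(
            vm.os_log_hr_class2 * is2 + vm.os_log_hr_prame * isp
            + vm.os_log_hr_diameter * (diameter - 12.0))
        t_mfs = rng.exponential(1.0 / h_mfs)
        t_os = rng.exponential(1.0 / h_os)
        hz = config.censoring_horizon_months
        mfs_months, mfs_event = min(t_mfs, hz), t_mfs <= hz
        os_months, os_event = min(t_os, hz), t_os <= hz

        truth = SyntheticTruth(
            sample_id=sid, sex=sex, true_purity=purity, true_ccf=ccf,
            true_3p_state=p3, true_class=cls, true_dscore=dscore,
            months_since_bap1_loss=months)
        truths.append(truth)

        # --- reads -----------------------------------------------------------
        for k, g in enumerate(gq_genes):
            gq_ccf = 1.0 if k == 0 else float(rng.uniform(0.2, 0.8))
            row = simulate_variant_reads(truth, g, config.depth_variant,
                                         config.read_model, rng, ccf=gq_ccf)
            row.update(_variant_identity(g, rng))
            variant_rows.append(row)
        for g in bse_genes:
            row = simulate_variant_reads(truth, g, config.depth_variant,
                                         config.read_model, rng)
            row.update(_variant_identity(g, rng))
            variant_rows.append(row)

        panel_frames.append(simulate_cnv_panel(truth, config, rng))

        clinical_rows.append({
            "sample_id": sid, "sex": sex, "age_at_entry": float(
                np.clip(rng.normal(62.0, 13.0), 18.0, 99.0)),
            "thickness_mm": thickness, "diameter_mm": diameter,
            "ciliary_body": bool(rng.random() < 0.18),
            "iris_color": ["blue_green", "intermediate", "brown"][
                rng.choice(3, p=[0.55, 0.25, 0.20])],
            "gep_class": cls, "prame": prame, "dscore": dscore,
            "mfs_months": mfs_months, "mfs_event": bool(mfs_event),
            "os_months": os_months, "os_event": bool(os_event),
        })

    clinical = pd.DataFrame(clinical_rows, columns=[
        "sample_id", "sex", "age_at_entry", "thickness_mm", "diameter_mm",
        "ciliary_body", "iris_color", "gep_class", "prame", "dscore",
        "mfs_months", "mfs_event", "os_months", "os_event"])
    variants = pd.DataFrame(variant_rows, columns=[
        "sample_id", "gene", "chrom", "pos", "assembly", "ref", "alt",
        "protein_change", "variant_type_hint", "ref_count", "alt_count",
        "splice_ai", "sift", "polyphen2", "clinvar_pathogenic",
        "splice_effect", "true_ccf", "expected_vaf"])
    panel = (pd.concat(panel_frames, ignore_index=True) if panel_frames
             else pd.DataFrame(columns=[
                 "sample_id", "locus_id", "chrom", "pos", "ref_count",
                 "alt_count", "normals_depth", "informative"]))
    return SimulatedCohort(clinical=clinical, variants=variants, panel=panel,
                           truth=truths, config=config)


def _variant_identity(gene: str, rng: np.random.Generator) -> dict:
    """Attach alleles, a protein label and annotation scores to a simulated
    mutation, drawn to be consistent with a pathogenic call for the gene's
    typical mutation spectrum."""
    bases = "ACGT"
    ref = bases[rng.choice(4)]
    alt = bases[(bases.index(ref) + 1 + rng.choice(3)) % 4]
    if gene in GQ_GENES:
        protein = GQ_HOTSPOTS[gene][rng.choice(len(GQ_HOTSPOTS[gene]))]
        return {"ref": ref, "alt": alt, "protein_change": protein,
                "variant_type_hint": "missense", "splice_ai": None,
                "sift": float(rng.uniform(0.0, 0.04)),
                "polyphen2": float(rng.uniform(0.6, 1.0)),
                "clinvar_pathogenic": True, "splice_effect": None}
    if gene == "BAP1":
        # BAP1 spectrum: truncating, splice and missense mutations
        kind = ["nonsense", "frameshift_indel", "splice_site", "missense"][
            rng.choice(4, p=[0.3, 0.3, 0.2, 0.2])]
        if kind == "frameshift_indel":
            ref = ref + bases[rng.choice(4)] + bases[rng.choice(4)]
        if kind == "splice_site":
            return {"ref": ref, "alt": alt, "protein_change": "splice",
                    "variant_type_hint": kind,
                    "splice_ai": float(rng.uniform(0.6, 1.0)), "sift": None,
                    "polyphen2": None, "clinvar_pathogenic": None,
                    "splice_effect": "donor_loss"}
        if kind == "missense":
            return {"ref": ref, "alt": alt, "protein_change": "missense",
                    "variant_type_hint": kind, "splice_ai": None,
                    "sift": float(rng.uniform(0.0, 0.05)),
                    "polyphen2": float(rng.uniform(0.5, 1.0)),
                    "clinvar_pathogenic": None, "splice_effect": None}
        return {"ref": ref, "alt": alt, "protein_change": "truncating",
                "variant_type_hint": kind, "splice_ai": None, "sift": None,
                "polyphen2": None, "clinvar_pathogenic": None,
                "splice_effect": None}
    protein = "R625C" if gene == "SF3B1" else "G9R"
    return {"ref": ref, "alt": alt, "protein_change": protein,
            "variant_type_hint": "missense", "splice_ai": None,
            "sift": float(rng.uniform(0.0, 0.04)),
            "polyphen2": float(rng.uniform(0.5, 1.0)),
            "clinvar_pathogenic": bool(rng.random() < 0.5),
            "splice_effect": None}


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Estimator accuracy against generative truth."""

    purity_bias: float
    purity_mae: float
    n_purity: int
    ccf_bias: dict[str, float]
    ccf_mae: dict[str, float]
    n_ccf: dict[str, int]
    loh_confusion: pd.DataFrame | None  # truth rows x called columns


_P3_STATES = ("retention", "loss", "isodisomy")


def recovery_report(truth: pd.DataFrame | list[SyntheticTruth],
                    purity: pd.DataFrame | None = None,
                    ccf: pd.DataFrame | None = None,
                    loh: pd.DataFrame | None = None) -> RecoveryReport:
    """Compare estimates with generative truth, joined on sample_id.

    ``purity`` needs columns (sample_id, tp); ``ccf`` (sample_id, gene, ccf);
    ``loh`` (sample_id, status).  Estimates for samples absent from the truth
    table raise an alignment error.
    """
    tf = truth if isinstance(truth, pd.DataFrame) else truth_to_frame(truth)
    tf = tf.set_index("sample_id")

    def _check_ids(df: pd.DataFrame, what: str) -> None:
        missing = set(df["sample_id"]) - set(tf.index)
        if missing:
            raise KeyError(f"{what} contains unknown sample ids: "
                           f"{sorted(missing)[:5]}")

    purity_bias = purity_mae = np.nan
    n_purity = 0
    if purity is not None and len(purity):
        _check_ids(purity, "purity estimates")
        est = purity.dropna(subset=["tp"])
        diff = est["tp"].to_numpy() - tf.loc[est["sample_id"], "true_purity"].to_numpy()
        n_purity = len(diff)
        if n_purity:
            purity_bias = float(np.mean(diff))
            purity_mae = float(np.mean(np.abs(diff)))

    ccf_bias: dict[str, float] = {}
    ccf_mae: dict[str, float] = {}
    n_ccf: dict[str, int] = {}
    if ccf is not None and len(ccf):
        _check_ids(ccf, "CCF estimates")
        for g, sub in ccf.dropna(subset=["ccf"]).groupby("gene"):
            col = f"true_ccf_{g}"
            if col not in tf.columns:
                continue
            tr = tf.loc[sub["sample_id"], col].to_numpy()
            ok = ~np.isnan(tr)
            diff = sub["ccf"].to_numpy()[ok] - tr[ok]
            n_ccf[g] = int(ok.sum())
            ccf_bias[g] = float(np.mean(diff)) if len(diff) else np.nan
            ccf_mae[g] = float(np.mean(np.abs(diff))) if len(diff) else np.nan

    confusion = None
    if loh is not None and len(loh):
        _check_ids(loh, "LOH calls")
        tr = tf.loc[loh["sample_id"], "true_3p_state"].to_numpy()
        called = loh["status"].to_numpy()
        confusion = pd.DataFrame(0, index=list(_P3_STATES),
                                 columns=list(_P3_STATES))
        for t, c in zip(tr, called):
            confusion.loc[t, c] += 1

    return RecoveryReport(purity_bias=purity_bias, purity_mae=purity_mae,
                          n_purity=n_purity, ccf_bias=ccf_bias,
                          ccf_mae=ccf_mae, n_ccf=n_ccf,
                          loh_confusion=confusion)
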