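"""Simulation configuration.

Defaults reproduce the cohort structure of the study population this package
models: 62.8% Class 1 tumors, Gq founder mutations in essentially every
tumor, size-dependent tumor purity (mean 58.6% in small tumors versus 81.9%
in larger ones), predominantly BAP1-linked chromosome-3p loss, and a
discriminant score that inverts progressively after biallelic BAP1 loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

from .genes import GQ_GENES, BSE_GENES


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


ReadModel = Literal["paper_consistent", "copy_aware"]


@dataclass
class SizeModel:
    """Tumor dimensions, in millimetres, conditional on 15-GEP class.

    Diameter is drawn from a truncated normal per class; thickness follows a
    linear trend on diameter plus noise, bounded below at 1.0 mm.
    """

    diameter_mean_class1: float = 11.5
    diameter_mean_class2: float = 14.8
    diameter_sd: float = 4.2
    diameter_min: float = 3.0
    diameter_max: float = 29.0
    thickness_slope: float = 0.34
    thickness_intercept: float = 1.1
    thickness_sd: float = 1.6
    thickness_min: float = 1.0
    thickness_max: float = 18.0
    #: additive diameter shifts by BSE genotype (EIF1AX tumors are smaller,
    #: BAP1 tumors larger)
    diameter_shift: dict = field(
        default_factory=lambda: {"EIF1AX": -1.5, "BAP1": 1.0, "SF3B1": 0.5}
    )


@dataclass
class PurityModel:
    """Tumor purity by size stratum (fractions, truncated normal)."""

    small_mean: float = 0.586
    small_sd: float = 0.15
    large_mean: float = 0.819
    large_sd: float = 0.10
    lo: float = 0.10
    hi: float = 1.00


@dataclass
class DscoreModel:
    """Latent discriminant process: z = -1 + slope * deficit * sat(t) + noise.

    ``deficit`` is the fraction of BAP1 allelic dosage lost (mutant CCF plus
    LOH contribution, over two alleles); ``sat(t) = 1 - exp(-t/tau)`` captures
    the lag with which transcriptional change accrues after BAP1 loss.
    The reported discriminant score is clamp(|z|, 0, 1).
    """

    slope: float = 2.6
    tau_months: float = 24.0
    noise_sd: float = 0.25


@dataclass
class SurvivalModel:
    """Exponential event times with log-linear hazards.

    Baseline hazards are per month; coefficients are log hazard ratios.
    """

    mfs_base_hazard: float = 0.0018  # ~90% 5-yr MFS for Class 1 baseline
    os_base_hazard: float = 0.0030
    mfs_log_hr_class2: float = 2.0
    mfs_log_hr_prame: float = 0.7
    mfs_log_hr_diameter: float = 0.03  # per mm
    os_log_hr_class2: float = 1.2
    os_log_hr_prame: float = 0.4
    os_log_hr_diameter: float = 0.02


@dataclass
class SimConfig:
    n_patients: int = 1000
    seed: int = 0
    class1_fraction: float = 0.628
    #: marginal prevalence of each primary Gq mutation (normalised at draw)
    gq_prevalences: dict = field(
        default_factory=lambda: {
            "GNAQ": 0.489, "GNA11": 0.465, "PLCB4": 0.022, "CYSLTR2": 0.012
        }
    )
    #: probability of a rare second Gq mutation (6/1140 in the cohort modeled)
    second_gq_prob: float = 0.005
    #: BSE genotype probabilities conditional on class; chosen so the
    #: marginals approximate BAP1 32%, SF3B1 17%, EIF1AX 27%
    bse_probs_class1: dict = field(
        default_factory=lambda: {
            "none": 0.38, "BAP1": 0.035, "SF3B1": 0.225, "EIF1AX": 0.36
        }
    )
    bse_probs_class2: dict = field(
        default_factory=lambda: {
            "none": 0.10, "BAP1": 0.80, "SF3B1": 0.07, "EIF1AX": 0.03
        }
    )
    #: probability that a second, distinct BSE mutation co-occurs (26/1140)
    second_bse_prob: float = 0.023
    #: chromosome-3p state probabilities conditional on BAP1 mutation status
    p3_probs_bap1_mut: dict = field(
        default_factory=lambda: {"retention": 0.15, "loss": 0.70, "isodisomy": 0.15}
    )
    p3_probs_bap1_wt_class2: dict = field(
        default_factory=lambda: {"retention": 0.50, "loss": 0.40, "isodisomy": 0.10}
    )
    p3_probs_bap1_wt_class1: dict = field(
        default_factory=lambda: {"retention": 0.97, "loss": 0.02, "isodisomy": 0.01}
    )
    male_fraction: float = 0.518
    prame_pos_class1: float = 0.18
    prame_pos_class2: float = 0.60
    size_model: SizeModel = field(default_factory=SizeModel)
    purity_model: PurityModel = field(default_factory=PurityModel)
    dscore_model: DscoreModel = field(default_factory=DscoreModel)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    depth_variant: float = 1000.0
    depth_panel: float = 300.0
    n_panel_loci: int = 74
    #: probability a panel locus is germline-uninformative (homozygous)
    panel_dropout: float = 0.2
    #: multiplicative log-normal depth noise (sigma of log depth)
    depth_noise_sd: float = 0.10
    read_model: ReadModel = "paper_consistent"
    censoring_horizon_months: float = 96.0
    #: small-tumor definition (inclusive bounds)
    small_thickness_mm: float = 2.5
    small_diameter_mm: float = 12.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        probs = [self.class1_fraction, self.second_gq_prob, self.second_bse_prob,
                 self.male_fraction, self.prame_pos_class1, self.prame_pos_class2,
                 self.panel_dropout]
        probs += list(self.gq_prevalences.values())
        for d in (self.bse_probs_class1, self.bse_probs_class2,
                  self.p3_probs_bap1_mut, self.p3_probs_bap1_wt_class2,
                  self.p3_probs_bap1_wt_class1):
            probs += list(d.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.depth_variant <= 0 or self.depth_panel <= 0:
            raise ConfigurationError("sequencing depths must be positive")
        if self.n_panel_loci < 2:
            raise ConfigurationError("n_panel_loci must be >= 2")
        if self.read_model not in ("paper_consistent", "copy_aware"):
            raise ConfigurationError(f"unknown read_model {self.read_model!r}")
        for g in self.gq_prevalences:
            if g not in GQ_GENES:
                raise ConfigurationError(f"unknown Gq gene {g!r}")
        for d in (self.bse_probs_class1, self.bse_probs_class2):
            for g in d:
                if g != "none" and g not in BSE_GENES:
                    raise ConfigurationError(f"unknown BSE gene {g!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, sub in (("size_model", SizeModel), ("purity_model", PurityModel),
                         ("dscore_model", DscoreModel), ("survival_model", SurvivalModel)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
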