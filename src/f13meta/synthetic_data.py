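"""Synthetic case-control genotype studies with known truth.

The generator emulates the structure of a genetic-association meta-analysis
of a biallelic polymorphism: each study draws its control genotypes
multinomially from Hardy-Weinberg proportions at a configurable Leu-allele
frequency, then tilts the case genotype distribution so that the
carrier-versus-noncarrier (dominant) odds ratio equals a study-specific
true value drawn from ``Normal(ln(true_or_dominant), tau^2)``. Within
carriers the Val/Leu : Leu/Leu split keeps its HWE ratio, so the truth is
injected on the dominant contrast and the other genetic models' true
effects are emergent.

Defaults mirror a premature-MI-style meta-analysis: 13 studies, case
groups of 30-400, control groups of 50-800, Leu-allele frequency 0.25
(typical of European-ancestry samples), dominant OR 0.8, no between-study
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import pooling
from .genetic_models import GeneticModel, derive_all
from .hwe import hwe_chi_square
from .study_io import StudyRecord, StudySet


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters; a single integer seed governs all draws.

    ``hwe_f`` is the fixation-index-style heterozygote deficit applied to
    control genotype proportions when ``hwe_in_controls`` is False.
    """

    k_studies: int = 13
    n_cases_range: tuple[int, int] = (30, 400)
    n_controls_range: tuple[int, int] = (50, 800)
    leu_freq: float = 0.25
    true_or_dominant: float = 0.8
    tau: float = 0.0
    hwe_in_controls: bool = True
    hwe_f: float = 0.3
    disease: str = "MI"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.leu_freq < 1.0):
            raise ValueError("leu_freq must lie in (0, 1)")
        if self.true_or_dominant <= 0:
            raise ValueError("true_or_dominant must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        for lo, hi in (self.n_cases_range, self.n_controls_range):
            if lo < 1 or hi < lo:
                raise ValueError("sample-size ranges must be non-empty and >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """The generating values behind a simulated StudySet."""

    true_or_dominant: float
    tau: float
    leu_freq: float
    study_log_ors: tuple[float, ...]


def _control_genotype_probs(cfg: SimulationConfig) -> np.ndarray:
    q = cfg.leu_freq
    p = 1.0 - q
    if cfg.hwe_in_controls:
        probs = np.array([p * p, 2 * p * q, q * q])
    else:
        f = cfg.hwe_f
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    if np.any(probs < 0):
        raise ValueError("degenerate config: negative genotype probability")
    return probs


def simulate_study_set(cfg: SimulationConfig) -> tuple[StudySet, TruthRecord]:
    """Draw a StudySet of ``cfg.k_studies`` synthetic studies.

    Identical configs (including the seed) yield identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    ctrl_probs = _control_genotype_probs(cfg)
    carrier_p_ctrl = float(ctrl_probs[1] + ctrl_probs[2])
    # Val/Leu : Leu/Leu split within carriers, preserved in cases
    r_vl = float(ctrl_probs[1] / carrier_p_ctrl)

    records = []
    log_ors = []
    for i in range(cfg.k_studies):
        n_cases = int(rng.integers(cfg.n_cases_range[0], cfg.n_cases_range[1] + 1))
        n_controls = int(rng.integers(cfg.n_controls_range[0],
                                      cfg.n_controls_range[1] + 1))
        log_or = float(rng.normal(np.log(cfg.true_or_dominant), cfg.tau))
        log_ors.append(log_or)

        odds_ctrl = carrier_p_ctrl / (1.0 - carrier_p_ctrl)
        odds_case = np.exp(log_or) * odds_ctrl
        carrier_p_case = odds_case / (1.0 + odds_case)
        case_probs = np.array([1.0 - carrier_p_case,
                               carrier_p_case * r_vl,
                               carrier_p_case * (1.0 - r_vl)])

        kvv, kvl, kll = rng.multinomial(n_controls, ctrl_probs)
        cvv, cvl, cll = rng.multinomial(n_cases, case_probs)
        records.append(StudyRecord(
            study_id=f"sim{i + 1:03d}",
            population="synthetic",
            disease=cfg.disease,
            n_cases=n_cases, n_controls=n_controls,
            cases_vv=int(cvv), cases_vl=int(cvl), cases_ll=int(cll),
            controls_vv=int(kvv), controls_vl=int(kvl), controls_ll=int(kll),
            nos_score=9,
        ))
    truth = TruthRecord(
        true_or_dominant=cfg.true_or_dominant,
        tau=cfg.tau,
        leu_freq=cfg.leu_freq,
        study_log_ors=tuple(log_ors),
    )
    return StudySet(disease=cfg.disease, studies=tuple(records)), truth


@dataclass(frozen=True)
class ExperimentSummary:
    reps: int
    rejection_rate_fixed: float
    rejection_rate_random: float
    hwe_rejection_rate: float


def type1_power_experiment(cfg: SimulationConfig, reps: int) -> ExperimentSummary:
    """Monte-Carlo rejection rates of the pooled z-test and the HWE check.

    Each replicate simulates a study set (replicate index added to the
    seed), pools the dominant-model tables by both methods, and tests every
    control group for HWE. Under ``true_or_dominant=1, tau=0`` the pooled
    rejection rates estimate the type-I error; otherwise they estimate
    power.
    """
    if reps < 100:
        raise ValueError("at least 100 replicates required for a stable rate")
    rej_fixed = rej_random = 0
    hwe_rej = hwe_total = 0
    for r in range(reps):
        rep_cfg = SimulationConfig(**{**cfg.__dict__, "seed": (cfg.seed + r) % (2**31)})
        studies, _ = simulate_study_set(rep_cfg)
        tables, _ = derive_all(studies, GeneticModel.DOMINANT)
        if pooling.pool_fixed_mh(tables).p < 0.05:
            rej_fixed += 1
        if pooling.pool_random_dl(tables).p < 0.05:
            rej_random += 1
        for s in studies:
            res = hwe_chi_square(*s.genotype_counts("controls"))
            hwe_total += 1
            if not res.in_equilibrium:
                hwe_rej += 1
    return ExperimentSummary(
        reps=reps,
        rejection_rate_fixed=rej_fixed / reps,
        rejection_rate_random=rej_random / reps,
        hwe_rejection_rate=hwe_rej / hwe_total,
    )
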