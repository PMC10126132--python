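"""Synthetic inputs for every pipeline stage.

The study's raw clinical data are not deposited, so this module generates
statistically analogous inputs with known ("planted") truth:

* a case-control cohort whose clinical covariate marginals match the published
  cohort description (age means, smoking splits, pack-/quit-years) and whose
  binary microRNA calls follow a logistic model with planted per-microRNA
  case odds ratios;
* multi-tissue binary profile sets with a per-tissue concordance parameter —
  the probability a tissue's call copies the individual's latent lung profile
  rather than an independent population draw;
* realtime-PCR plates (duplicate wells with Ct and melt temperature) whose
  ground-truth presence calls are retained for end-to-end scoring validation.

Every generator takes a single integer seed, is bit-reproducible, and returns
a machine-readable truth record alongside its data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panels import DEFAULT_MIR_PANEL, TOPOGRAPHY_TISSUES
from .qpcr import WellRecord
from .topography import TissueProfileSet

__all__ = [
    "CohortSimParams",
    "TopoSimParams",
    "generate_cohort",
    "generate_tissue_profiles",
    "generate_qpcr_plate",
    "default_cohort_params",
]

#: microRNAs carrying a planted case-enrichment odds ratio in the default
#: cohort (the analogues of the markers the adjusted logistic screen flags).
DEFAULT_PLANTED_MIRS = ("miR-21", "miR-33b", "miR-212")
DEFAULT_PLANTED_OR = 2.5

_STAGE_LEVELS = ("I", "II", "III", "IV")
# published case stage distribution (I 33.13, II 12.05, III 31.33, IV 11.45 %
# of all cases; the remainder unstaged metastases/other), renormalized
_STAGE_PROBS = np.array([0.3313, 0.1205, 0.3133, 0.1145])
_STAGE_PROBS = _STAGE_PROBS / _STAGE_PROBS.sum()
_HISTOLOGY_LEVELS = ("adeno", "squamous", "undiff_nsclc", "small_cell", "mets_other")
_HISTOLOGY_PROBS = np.array([0.500, 0.211, 0.157, 0.090, 0.042])
_HISTOLOGY_PROBS = _HISTOLOGY_PROBS / _HISTOLOGY_PROBS.sum()


def _check_simplex(name: str, probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability simplex summing to 1, got {probs}")
    return p


@dataclass
class CohortSimParams:
    """Parameters of the synthetic case-control cohort.

    Covariate defaults reproduce the published cohort's marginals: case /
    control mean ages 66.93 / 56.40 y, smoking splits (current, former, never)
    of (.434, .476, .090) / (.205, .416, .378), pack-years means 43.43 / 19.21
    and quit-years means 7.33 / 9.40.  Spread parameters (age sd 10 y,
    gamma shape for tobacco dose with cv 0.8) are package choices — the source
    tables report means only.  Underlying-lung-disease group probabilities are
    normalized approximations of overlapping published category rates.
    """

    n_cases: int = 166
    n_controls: int = 185
    age_mean_case: float = 66.93
    age_mean_control: float = 56.40
    age_sd: float = 10.0
    gender_male_prob_case: float = 0.488
    gender_male_prob_control: float = 0.497
    # order: (current, former, never)
    smoking_probs_case: tuple[float, float, float] = (0.434, 0.476, 0.090)
    smoking_probs_control: tuple[float, float, float] = (0.205, 0.416, 0.379)
    pack_years_mean_case: float = 43.43
    pack_years_mean_control: float = 19.21
    quit_years_mean_case: float = 7.33
    quit_years_mean_control: float = 9.40
    tobacco_cv: float = 0.8  # gamma coefficient of variation for dose variables
    # order: (risk, granulomatous_airway, none_other)
    uld_probs_case: tuple[float, float, float] = (0.66, 0.04, 0.30)
    uld_probs_control: tuple[float, float, float] = (0.45, 0.11, 0.44)
    mir_panel: tuple[str, ...] = DEFAULT_MIR_PANEL
    mir_baseline_prevalence: float | Mapping[str, float] = 0.35
    mir_odds_ratios: Mapping[str, float] = field(default_factory=dict)
    #: optional confounding: extra log-odds of mir presence for current/former
    #: smokers in both arms (off by default so planted ORs stay interpretable)
    smoking_mir_log_or: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        _check_simplex("smoking_probs_case", self.smoking_probs_case)
        _check_simplex("smoking_probs_control", self.smoking_probs_control)
        _check_simplex("uld_probs_case", self.uld_probs_case)
        _check_simplex("uld_probs_control", self.uld_probs_control)
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for mir, or_ in self.mir_odds_ratios.items():
            if or_ <= 0:
                raise ValueError(f"odds ratio for {mir} must be > 0, got {or_}")

    def prevalence_of(self, mir: str) -> float:
        if isinstance(self.mir_baseline_prevalence, Mapping):
            p = self.mir_baseline_prevalence.get(mir, 0.35)
        else:
            p = float(self.mir_baseline_prevalence)
        if not (0 < p < 1):
            raise ValueError(f"baseline prevalence for {mir} must be in (0,1), got {p}")
        return p


def default_cohort_params(seed: int = 0, **overrides) -> CohortSimParams:
    """The default study-analogue cohort: published covariate marginals with
    odds ratio 2.5 planted on the miR-21 / miR-33b / miR-212 analogues."""
    kwargs = dict(
        mir_odds_ratios={m: DEFAULT_PLANTED_OR for m in DEFAULT_PLANTED_MIRS},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSimParams(**kwargs)


def _gamma_from_mean_cv(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def generate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort; returns (cohort frame, truth record).

    MicroRNA presence follows logit(p) = logit(baseline) + log(OR)*case
    (+ optional smoking link); pack-years are zero for never-smokers and
    quit-years nonzero only for former smokers.  Missingness is completely at
    random at ``missing_rate``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cases + params.n_controls
    status = np.array(["case"] * params.n_cases + ["control"] * params.n_controls)
    is_case = status == "case"

    age = np.where(
        is_case,
        rng.normal(params.age_mean_case, params.age_sd, n),
        rng.normal(params.age_mean_control, params.age_sd, n),
    )
    age = np.clip(age, 22.0, None)
    male_p = np.where(is_case, params.gender_male_prob_case, params.gender_male_prob_control)
    gender = np.where(rng.random(n) < male_p, "male", "female")

    levels = np.array(["current", "former", "never"])
    smoking = np.empty(n, dtype=object)
    for arm, probs in (
        (is_case, params.smoking_probs_case),
        (~is_case, params.smoking_probs_control),
    ):
        k = int(arm.sum())
        smoking[arm] = rng.choice(levels, size=k, p=np.asarray(probs))

    pack_years = np.zeros(n)
    quit_years = np.zeros(n)
    for arm, py_mean, qy_mean in (
        (is_case, params.pack_years_mean_case, params.quit_years_mean_case),
        (~is_case, params.pack_years_mean_control, params.quit_years_mean_control),
    ):
        ever = arm & (smoking != "never")
        pack_years[ever] = _gamma_from_mean_cv(rng, py_mean, params.tobacco_cv, int(ever.sum()))
        former = arm & (smoking == "former")
        quit_years[former] = _gamma_from_mean_cv(rng, qy_mean, params.tobacco_cv, int(former.sum()))

    uld_levels = np.array(["risk", "granulomatous_airway", "none_other"])
    uld = np.empty(n, dtype=object)
    uld[is_case] = rng.choice(uld_levels, size=params.n_cases, p=np.asarray(params.uld_probs_case))
    uld[~is_case] = rng.choice(
        uld_levels, size=params.n_controls, p=np.asarray(params.uld_probs_control)
    )

    stage = np.full(n, None, dtype=object)
    histology = np.full(n, None, dtype=object)
    stage[is_case] = rng.choice(np.array(_STAGE_LEVELS), size=params.n_cases, p=_STAGE_PROBS)
    histology[is_case] = rng.choice(
        np.array(_HISTOLOGY_LEVELS), size=params.n_cases, p=_HISTOLOGY_PROBS
    )

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "status": status,
            "age": np.round(age, 2),
            "gender": gender,
            "smoking_status": smoking,
            "pack_years": np.round(pack_years, 2),
            "quit_years": np.round(quit_years, 2),
            "uld_group": uld,
            "stage": stage,
            "histology": histology,
        }
    )

    smoker = (smoking != "never").astype(float)
    for mir in params.mir_panel:
        base = params.prevalence_of(mir)
        or_ = float(params.mir_odds_ratios.get(mir, 1.0))
        logit = math.log(base / (1 - base)) + np.log(or_) * is_case.astype(float)
        logit = logit + params.smoking_mir_log_or * smoker
        p = 1.0 / (1.0 + np.exp(-logit))
        calls = (rng.random(n) < p).astype(float)
        if params.missing_rate > 0:
            calls[rng.random(n) < params.missing_rate] = np.nan
        df[mir] = pd.array(
            [pd.NA if math.isnan(c) else int(c) for c in calls], dtype="Int64"
        )

    truth = {
        "params": {
            **{k: v for k, v in asdict(params).items() if k != "mir_odds_ratios"},
            "mir_odds_ratios": dict(params.mir_odds_ratios),
        },
        "planted_mirs": sorted(m for m, o in params.mir_odds_ratios.items() if o != 1.0),
    }
    return df, truth


@dataclass
class TopoSimParams:
    """Parameters of the multi-tissue profile generator.

    ``tissue_concordance`` maps each tissue to the probability that its call
    for a given microRNA copies the individual's latent lung profile rather
    than being drawn independently at the population prevalence.  Two tissues
    with concordances c_a and c_b then agree beyond chance in proportion to
    c_a * c_b — concordance between a pair is an emergent product of the
    per-tissue parameters.

    The defaults emulate the observed airway-topography pattern: exhaled
    breath condensate strongly shares the deep-lung (lavage) fingerprint,
    weakly shares bronchial-brush/sputum, and is marginally concordant with
    mouthwash.
    """

    n_individuals: int = 12
    n_mirs: int = 13
    tissues: tuple[str, ...] = TOPOGRAPHY_TISSUES
    tissue_concordance: Mapping[str, float] = field(
        default_factory=lambda: {"EBC": 0.5, "BAL": 0.5, "BB": 0.15, "SP": 0.2, "MW": 0.3}
    )
    latent_prevalence: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_mirs < 1:
            raise ValueError("need at least 1 microRNA")
        if not (0 < self.latent_prevalence < 1):
            raise ValueError("latent_prevalence must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for t in self.tissues:
            c = self.tissue_concordance.get(t)
            if c is None or not (0 <= c <= 1):
                raise ValueError(f"tissue {t!r} needs a concordance in [0, 1], got {c}")


def generate_tissue_profiles(params: TopoSimParams) -> tuple[TissueProfileSet, dict]:
    """Draw a multi-tissue profile set; returns (profile set, truth record
    containing the latent per-individual lung profiles)."""
    rng = np.random.default_rng(params.seed)
    individuals = [f"I{i:02d}" for i in range(params.n_individuals)]
    mirs = [f"miR-t{j:02d}" for j in range(params.n_mirs)]
    latent = (rng.random((params.n_individuals, params.n_mirs)) < params.latent_prevalence).astype(
        float
    )
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for t in params.tissues:
        c = float(params.tissue_concordance[t])
        copy = rng.random((params.n_individuals, params.n_mirs)) < c
        indep = (rng.random((params.n_individuals, params.n_mirs)) < params.latent_prevalence)
        obs = np.where(copy, latent, indep.astype(float))
        if params.missing_rate > 0:
            obs = obs.astype(float)
            obs[rng.random(obs.shape) < params.missing_rate] = np.nan
        for i, ind in enumerate(individuals):
            profiles[(ind, t)] = obs[i].astype(float)
    pset = TissueProfileSet(
        individuals=individuals, tissues=list(params.tissues), mirs=mirs, profiles=profiles
    )
    truth = {
        "params": {
            **{k: v for k, v in asdict(params).items() if k != "tissue_concordance"},
            "tissue_concordance": dict(params.tissue_concordance),
        },
        "latent_profiles": {ind: latent[i].astype(int).tolist() for i, ind in enumerate(individuals)},
    }
    return pset, truth


def generate_qpcr_plate(
    n_samples: int,
    mir_panel: Sequence[str] | None = None,
    prevalence: float = 0.5,
    tm_jitter_sd: float = 0.0,
    seed: int = 0,
    *,
    n_replicates: int = 2,
    artifact_prob: float = 0.0,
    artifact_tm_offset: float = 4.0,
    ct_present_mean: float = 33.0,
    ct_present_sd: float = 3.0,
) -> tuple[list[WellRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate well-level realtime-PCR data with known truth.

    Returns (wells, reference-Tm table, truth-call table).  Truly present
    microRNAs amplify in every replicate with Ct well below the positivity
    cutoff and a melt temperature jittered around the primerset reference;
    truly absent microRNAs either fail to amplify or (with ``artifact_prob``)
    produce an off-temperature artifact product at ``artifact_tm_offset``
    degrees from the reference.
    """
    if tm_jitter_sd < 0:
        raise ValueError("tm_jitter_sd must be >= 0")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    if not (0 <= artifact_prob <= 1):
        raise ValueError("artifact_prob must be in [0, 1]")
    panel = list(mir_panel) if mir_panel is not None else list(DEFAULT_MIR_PANEL)
    rng = np.random.default_rng(seed)
    ref_tm = {m: float(np.round(rng.uniform(75.0, 88.0), 2)) for m in panel}
    samples = [f"P{i:03d}" for i in range(n_samples)]

    wells: list[WellRecord] = []
    truth_rows = []
    for s in samples:
        for m in panel:
            present = bool(rng.random() < prevalence)
            truth_rows.append({"sample_id": s, "mir_id": m, "truth_call": int(present)})
            for rep in range(1, n_replicates + 1):
                if present:
                    ct = float(np.clip(rng.normal(ct_present_mean, ct_present_sd), 20.0, 43.5))
                    tm = float(ref_tm[m] + rng.normal(0.0, tm_jitter_sd)) if tm_jitter_sd > 0 else ref_tm[m]
                    tm = float(np.clip(tm, 50.5, 99.5))
                    wells.append(WellRecord(s, m, rep, ct=round(ct, 2), tm=round(tm, 2)))
                elif rng.random() < artifact_prob:
                    ct = float(np.clip(rng.normal(38.0, 2.0), 20.0, 43.5))
                    tm = float(np.clip(ref_tm[m] + artifact_tm_offset, 50.5, 99.5))
                    wells.append(WellRecord(s, m, rep, ct=round(ct, 2), tm=round(tm, 2)))
                else:
                    wells.append(WellRecord(s, m, rep, ct=None, tm=None))
    ref_df = pd.DataFrame(
        {"mir_id": panel, "reference_tm": [ref_tm[m] for m in panel]}
    )
    truth_df = pd.DataFrame(truth_rows)
    return wells, ref_df, truth_df
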