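"""Synthetic cohorts with the statistical structure of DM1 somatic mosaicism.

The generator has three layers:

1. **Somatic process** — each blood-cell lineage carries an expanded allele
   that performs a compound-Poisson length walk: mutation events arrive at
   a constant per-lineage Poisson rate proportional to the *progenitor*
   repeat length (per repeat, per year) and modulated by a gamma-distributed
   per-lineage factor; each event expands the allele by a geometric step
   with high probability and contracts it otherwise.  Lineage-rate
   heterogeneity keeps the lower edge of the distribution anchored near
   the progenitor length (which is why its 10th percentile estimates the
   progenitor allele) while the upper tail expands, giving the
   characteristic right skew.  This is the simplest process consistent
   with the known phenomenology (instability grows with length and age and
   is biased toward expansion); it is a stand-in, not a mechanistic claim.
   Repeat interruptions act as a single multiplicative *stabilization
   factor* f <= 1 on the event rate of the whole allele.
2. **Observation** — single-molecule small-pool PCR: reactions each amplify
   a Poisson number of molecules drawn from the cell population, sizes pick
   up multiplicative lognormal sizing noise, molecules below the detection
   limit are lost, and reactions accumulate until at least 200 alleles are
   sized.
3. **Cohorts** — a reference cohort of 136 uninterrupted-expansion patients
   (121 symptomatic) sampled at two time points, and a small study cohort
   of 7 interrupted + 4 control patients with paired time points and buccal
   samples, emitted in the pipeline's own input format.

Age at onset is generated from the progenitor length and the subject's
*true* instability propensity (individual rate multiplier, including the
stabilization factor for interrupted alleles), so that the residual-as-
covariate onset model has signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AlleleSample, PatientRecord
from .metrics import summarize_sample
from .patterns import parse_interruption_pattern

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "StudyCohortSpec",
    "simulate_trajectory",
    "sample_small_pool",
    "generate_reference_cohort",
    "generate_study_cohort",
]

#: Shortest pathogenic expansion; alleles are floored here.
MIN_EXPANSION = 50.0

#: Largest expansion carried by the simulation, matching the few-thousand
#: repeat ceiling of observed expanded alleles.
MAX_EXPANSION = 4000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the somatic process and the small-pool PCR observation.

    Units: ``expansion_rate`` is mutation events per repeat per year;
    ``step_size_mean`` is repeats per event; ``sizing_cv`` is the
    fractional standard deviation of gel sizing; ``min_detectable`` is the
    smallest sizable allele in repeats.
    """

    expansion_rate: float = 0.003
    contraction_fraction: float = 0.15
    step_size_mean: float = 2.5
    stabilization_factor: float = 0.4
    n_lineages: int = 300
    lineage_rate_shape: float = 2.0
    poisson_lambda: float = 7.0
    sizing_cv: float = 0.02
    min_detectable: float = 55.0
    target_alleles: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_rate <= 0 or self.step_size_mean < 1:
            raise ValueError("expansion_rate must be > 0 and step mean >= 1")
        if not 0 < self.stabilization_factor <= 1:
            raise ValueError("stabilization_factor must lie in (0, 1]")
        if not 0 <= self.contraction_fraction < 0.5:
            raise ValueError(
                "contraction_fraction must be < 0.5 (expansion bias)"
            )
        if min(self.n_lineages, self.poisson_lambda, self.target_alleles) <= 0:
            raise ValueError("counts and rates must be positive")
        if self.lineage_rate_shape <= 0:
            raise ValueError("lineage_rate_shape must be positive")
        if self.sizing_cv < 0 or self.min_detectable <= 0:
            raise ValueError("sizing_cv must be >= 0, min_detectable > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Reference-cohort layout and the generative age-at-onset model.

    ``individual_log_sd`` is the SD of the per-subject log rate multiplier
    (heritable individual-specific instability).  Age at onset is drawn as
    ``log10(AO) = ao_intercept + ao_epal_coef*log10(ePAL) +
    ao_propensity_coef*z + noise`` where z is the subject's standardised
    log instability propensity.
    """

    n_subjects: int = 136
    n_symptomatic: int = 121
    epal_range: tuple[float, float] = (120.0, 800.0)
    age_range: tuple[float, float] = (18.0, 60.0)
    interval_range: tuple[float, float] = (2.5, 11.0)
    individual_log_sd: float = 0.15
    ao_intercept: float = 3.35
    ao_epal_coef: float = -0.80
    ao_propensity_coef: float = -0.09
    ao_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not 0 <= self.n_symptomatic <= self.n_subjects:
            raise ValueError("n_symptomatic must be <= n_subjects")
        if self.interval_range[0] <= 0:
            raise ValueError("sampling interval must be positive")
        if self.ao_noise_sd < 0 or self.individual_log_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class StudyCohortSpec:
    """Layout of the small two-group study cohort."""

    n_interrupted: int = 7
    n_control: int = 4
    epal_range: tuple[float, float] = (200.0, 550.0)
    age_range: tuple[float, float] = (20.0, 55.0)
    interval_range_interrupted: tuple[float, float] = (2.5, 4.0)
    interval_range_control: tuple[float, float] = (4.0, 11.0)
    n_buccal_interrupted: int = 4
    n_buccal_control: int = 1
    buccal_progenitor_offset: float = 100.0
    buccal_rate_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.n_interrupted < 1 or self.n_control < 0:
            raise ValueError("study cohort needs at least one interrupted subject")


# synthetic interruption patterns (pattern text, 3'-block trinucleotides)
_SYNTH_PATTERNS = (
    ("(CTG)n CTC (CTG)26", 27),
    ("(CTG)n (CCGCTG)3 (CTG)17", 23),
    ("(CTG)n (CCG)3 (CTG)7 CCG (CTG)8", 19),
    ("(CTG)n (CCG)36 (CTG)12", 48),
    ("(CTG)n (CCGCTG)2 CTG CCG (CTG)17", 23),
)


def _lineage_factors(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-lineage mutation-rate factors (mean 1, gamma distributed).

    Rate heterogeneity across cell lineages is what keeps the lower edge
    of the allele frequency distribution anchored near the progenitor
    length (slow lineages barely move) while the upper tail expands —
    producing the right-skewed distributions whose 10th percentile is a
    usable progenitor-length estimate.
    """
    return rng.gamma(
        config.lineage_rate_shape,
        1.0 / config.lineage_rate_shape,
        config.n_lineages,
    )


def _evolve(
    lengths: np.ndarray,
    years: float,
    rates: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance all lineages by ``years``; ``rates`` are the per-lineage
    mutation-event rates in events per year (constant over the advance)."""
    lengths = lengths.astype(float).copy()
    n = lengths.size
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (n,))
    p_step = 1.0 / config.step_size_mean
    remaining = float(years)
    while remaining > 1e-12:
        dt = min(1.0, remaining)
        remaining -= dt
        events = rng.poisson(rates * dt)
        total = int(events.sum())
        if total == 0:
            continue
        signs = np.where(
            rng.random(total) < config.contraction_fraction, -1.0, 1.0
        )
        steps = rng.geometric(p_step, total).astype(float)
        owner = np.repeat(np.arange(n), events)
        delta = np.bincount(owner, weights=signs * steps, minlength=n)
        lengths = np.clip(lengths + delta, MIN_EXPANSION, MAX_EXPANSION)
    return lengths


def simulate_trajectory(
    config: SimulationConfig,
    progenitor_length: float,
    age: float,
    *,
    rng: np.random.Generator | None = None,
    rate_multiplier: float = 1.0,
    stabilization: float = 1.0,
) -> np.ndarray:
    """Cell-population repeat lengths after ``age`` years of somatic drift.

    Each of ``config.n_lineages`` lineages starts at the progenitor length
    and evolves independently; its event rate is
    ``expansion_rate * stabilization * rate_multiplier * progenitor_length``
    times the lineage's gamma factor.  ``stabilization`` is f (1 for pure
    alleles, < 1 for interrupted ones); ``rate_multiplier`` carries
    individual-specific propensity.
    """
    if progenitor_length < MIN_EXPANSION:
        raise ValueError(
            f"progenitor_length must be >= {MIN_EXPANSION:g} repeats"
        )
    if age < 0:
        raise ValueError("age must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = np.full(config.n_lineages, float(progenitor_length))
    if age == 0:
        return lengths
    rates = (
        config.expansion_rate * stabilization * rate_multiplier
        * progenitor_length * _lineage_factors(config, rng)
    )
    return _evolve(lengths, age, rates, config, rng)


def sample_small_pool(
    population: np.ndarray,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Observe a cell population by single-molecule small-pool PCR.

    Reactions each amplify Poisson(lambda) molecules drawn uniformly (with
    replacement) from the population; observed sizes carry multiplicative
    lognormal sizing noise with CV ``sizing_cv``; molecules below
    ``min_detectable`` are lost.  Reactions accumulate until at least
    ``target_alleles`` detectable molecules have been sized.
    """
    population = np.asarray(population, dtype=float)
    if population.size == 0:
        raise ValueError("population is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if population.max() < config.min_detectable:
        raise ValueError(
            "entire population lies below the detection limit "
            f"({config.min_detectable:g} repeats)"
        )
    if config.sizing_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.sizing_cv**2)))
        mu = -0.5 * sigma**2
    sized: list[np.ndarray] = []
    n_sized = 0
    while n_sized < config.target_alleles:
        k = int(rng.poisson(config.poisson_lambda))
        if k == 0:
            continue
        mol = rng.choice(population, size=k, replace=True)
        if config.sizing_cv > 0:
            mol = mol * rng.lognormal(mu, sigma, k)
        mol = mol[mol >= config.min_detectable]
        if mol.size:
            sized.append(mol)
            n_sized += mol.size
    return np.concatenate(sized)


def _observe_subject(
    pid: str,
    tissue: str,
    progenitor: float,
    ages: tuple[float, ...],
    multiplier: float,
    stabilization: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[AlleleSample]:
    """Simulate one subject's lineage population and size it at each age."""
    rates = (
        config.expansion_rate * stabilization * multiplier * progenitor
        * _lineage_factors(config, rng)
    )
    lengths = np.full(config.n_lineages, float(progenitor))
    samples = []
    prev_age = 0.0
    for tp, age in zip(("t1", "t2"), ages):
        lengths = _evolve(lengths, age - prev_age, rates, config, rng)
        prev_age = age
        sizes = sample_small_pool(lengths, config, rng=rng)
        samples.append(
            AlleleSample(
                patient_id=pid,
                tissue=tissue,
                timepoint=tp,
                age_at_sampling=float(age),
                sizes=sizes,
            )
        )
    return samples


def _draw_age_at_onset(
    spec: CohortSpec, epal: float, z_propensity: float,
    rng: np.random.Generator,
) -> float:
    log_ao = (
        spec.ao_intercept
        + spec.ao_epal_coef * np.log10(epal)
        + spec.ao_propensity_coef * z_propensity
        + rng.normal(0.0, spec.ao_noise_sd)
    )
    return float(10.0**log_ao)


def generate_reference_cohort(
    spec: CohortSpec,
    config: SimulationConfig,
    *,
    seed: int | None = None,
    return_samples: bool = False,
):
    """Reference cohort of uninterrupted-expansion patients.

    Returns a long-format DataFrame with one row per subject and time
    point: ``patient_id, timepoint, group, epal, age_at_sampling, si,
    mode, age_at_onset, interval`` (``epal``/``si``/``mode`` are the
    *observed* small-pool statistics).  Asymptomatic subjects
    (``n_subjects - n_symptomatic``) carry missing age at onset.
    With ``return_samples=True`` also returns the raw allele samples.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    all_samples: list[AlleleSample] = []
    asym = set(
        rng.choice(
            spec.n_subjects, spec.n_subjects - spec.n_symptomatic,
            replace=False,
        ).tolist()
    )
    for i in range(spec.n_subjects):
        pid = f"R{i + 1:03d}"
        epal_true = float(rng.uniform(*spec.epal_range))
        as1 = float(rng.uniform(*spec.age_range))
        interval = float(rng.uniform(*spec.interval_range))
        z = float(rng.normal())
        multiplier = float(np.exp(spec.individual_log_sd * z))
        ao = (
            None if i in asym
            else _draw_age_at_onset(spec, epal_true, z, rng)
        )
        samples = _observe_subject(
            pid, "blood", epal_true, (as1, as1 + interval),
            multiplier, 1.0, config, rng,
        )
        all_samples.extend(samples)
        for s in samples:
            summ = summarize_sample(s)
            rows.append(
                {
                    "patient_id": pid,
                    "timepoint": s.timepoint,
                    "group": "reference",
                    "epal": summ.p10,
                    "age_at_sampling": s.age_at_sampling,
                    "si": summ.si,
                    "mode": summ.mode,
                    "age_at_onset": ao,
                    "interval": interval,
                    "true_epal": epal_true,
                    "true_z": z,
                }
            )
    frame = pd.DataFrame(rows)
    if return_samples:
        return frame, all_samples
    return frame


def generate_study_cohort(
    cohort_spec: CohortSpec,
    study_spec: StudyCohortSpec,
    config: SimulationConfig,
    *,
    seed: int | None = None,
) -> tuple[dict[str, PatientRecord], list[AlleleSample]]:
    """Two-group study cohort: interrupted patients (stabilized alleles,
    f < 1) and uninterrupted controls, paired blood time points, buccal
    samples for a subset, in the pipeline's own metadata/allele format.

    Age at onset is drawn from the cohort AO model using each subject's
    *effective* instability propensity — individual multiplier times the
    stabilization factor — which is what makes interruption carriers
    later-onset than their progenitor length alone predicts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: dict[str, PatientRecord] = {}
    samples: list[AlleleSample] = []
    sexes = ("F", "M")

    def make_subject(pid, group, f, pattern_text, override, interval_range,
                     with_buccal):
        epal_true = float(rng.uniform(*study_spec.epal_range))
        as1 = float(rng.uniform(*study_spec.age_range))
        interval = float(rng.uniform(*interval_range))
        z = float(rng.normal())
        multiplier = float(np.exp(cohort_spec.individual_log_sd * z))
        # effective propensity includes stabilization
        z_eff = (
            cohort_spec.individual_log_sd * z + np.log(f)
        ) / max(cohort_spec.individual_log_sd, 1e-9)
        ao = _draw_age_at_onset(cohort_spec, epal_true, z_eff, rng)
        subj_samples = _observe_subject(
            pid, "blood", epal_true, (as1, as1 + interval),
            multiplier, f, config, rng,
        )
        if with_buccal:
            # tissue-specific dynamics: larger progenitor pool, slower rate
            buccal_epal = epal_true + study_spec.buccal_progenitor_offset
            buccal_pop = _evolve(
                np.full(config.n_lineages, buccal_epal),
                as1 + interval,
                config.expansion_rate
                * study_spec.buccal_rate_factor
                * f
                * multiplier
                * buccal_epal
                * _lineage_factors(config, rng),
                config,
                rng,
            )
            subj_samples.append(
                AlleleSample(
                    patient_id=pid,
                    tissue="buccal",
                    timepoint="t2",
                    age_at_sampling=as1 + interval,
                    sizes=sample_small_pool(buccal_pop, config, rng=rng),
                )
            )
        pattern = (
            parse_interruption_pattern(pattern_text) if pattern_text else None
        )
        records[pid] = PatientRecord(
            patient_id=pid,
            sex=sexes[len(records) % 2],
            group=group,
            age_at_onset=ao,
            pattern=pattern,
            interrupted_block_override=override,
            samples=subj_samples,
        )
        samples.extend(subj_samples)

    for i in range(study_spec.n_interrupted):
        text, block = _SYNTH_PATTERNS[i % len(_SYNTH_PATTERNS)]
        make_subject(
            f"SI{i + 1:02d}", "interrupted", config.stabilization_factor,
            text, block, study_spec.interval_range_interrupted,
            with_buccal=i < study_spec.n_buccal_interrupted,
        )
    for i in range(study_spec.n_control):
        make_subject(
            f"SC{i + 1:02d}", "control", 1.0, "(CTG)n", None,
            study_spec.interval_range_control,
            with_buccal=i < study_spec.n_buccal_control,
        )
    return records, samples
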