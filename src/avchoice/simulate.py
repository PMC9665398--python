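"""Synthetic survey generator.

Produces complete surveys — discrete-choice records, framed categorical
preferences and 1-7 Likert willingness responses — with the statistical
structure the downstream analysis assumes:

* individual preference/sensitivity parameters drawn from the
  population-level normal hierarchy (sensitivity truncated below 0, since
  a negative sensitivity would invert a respondent's preference
  ordering);
* binary choices drawn from the inverse-probit link on scaled utility
  differences over the 36-scenario design;
* framing-dependent categorical preferences: a latent unframed draw per
  participant, with the two family framings switching to the
  frame-congruent option with a per-frame probability, and the moral
  question drawn independently (moral views need not match purchase
  choices);
* condition-dependent Likert responses: a latent normal per participant,
  decremented under a mandate whenever the mandated programme differs
  from the participant's (unframed) preferred programme, then discretised
  to 1..7.

Every generator is deterministic under its seed; the full-survey driver
splits one master seed into independent per-table streams so individual
tables can be regenerated in isolation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import (
    ChoiceRecord,
    ChoiceScenario,
    Condition,
    Country,
    Frame,
    LikertResponse,
    PreferenceChoice,
    PreferenceResponse,
    Program,
    generate_choice_design,
)
from .model import _sample_truncnorm_lower, choice_probability, utility_difference

__all__ = [
    "PopulationSpec",
    "CategoricalSpec",
    "LikertSpec",
    "SurveySpec",
    "draw_individuals",
    "simulate_choices",
    "simulate_preferences",
    "simulate_likert",
    "simulate_survey",
    "load_preset",
    "available_presets",
]

#: Mandate condition -> programme it imposes.
MANDATED_PROGRAM = {
    Condition.MANDATE_MOST: PreferenceChoice.MOST,
    Condition.MANDATE_PED: PreferenceChoice.PEDESTRIANS,
    Condition.MANDATE_OCC: PreferenceChoice.OCCUPANTS,
}

_FRAME_CONGRUENT = {
    Frame.FAMILY_PASSENGER: PreferenceChoice.OCCUPANTS,
    Frame.FAMILY_PEDESTRIAN: PreferenceChoice.PEDESTRIANS,
}

_CHOICE_ORDER = [
    PreferenceChoice.MOST,
    PreferenceChoice.OCCUPANTS,
    PreferenceChoice.PEDESTRIANS,
    PreferenceChoice.RANDOM,
]


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level truth for the choice-model hierarchy.

    Utilities in £k relative to save-the-most; ``Htau`` in 1/£k; ``Ht``
    and ``Ht2`` are the precisions of the utility and sensitivity
    individual distributions.
    """

    HPed: float
    HOcc: float
    Htau: float
    Ht: float
    Ht2: float
    n_participants: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Ht <= 0 or self.Ht2 <= 0:
            raise ValueError("precisions Ht and Ht2 must be positive")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass(frozen=True)
class CategoricalSpec:
    """Marginal algorithm-preference distribution plus per-frame switch
    probabilities toward the frame-congruent option."""

    base_probs: dict[PreferenceChoice, float]
    frame_shift: dict[Frame, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.base_probs.get(c, 0.0) for c in _CHOICE_ORDER)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"base_probs must sum to 1, got {total}")
        for frame, pi in self.frame_shift.items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"frame_shift[{frame}] must be in [0, 1], got {pi}")


@dataclass(frozen=True)
class LikertSpec:
    """Latent-normal Likert model: baseline mean/sd and the pre-
    discretisation decrement applied when the mandated programme is not
    the participant's preferred one."""

    baseline_mean: float
    baseline_sd: float
    mandate_drop: float

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")


@dataclass(frozen=True)
class SurveySpec:
    """Everything needed to generate one country's full survey."""

    country: Country
    population: PopulationSpec
    categorical: CategoricalSpec
    likert: LikertSpec


def _participant_ids(country: Country, n: int) -> list[str]:
    return [f"{country.value}{i:04d}" for i in range(1, n + 1)]


def draw_individuals(
    spec: PopulationSpec, country: Country = Country.UK, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw individual (ped, occ, tau) parameters from the hierarchy.

    ``tau`` is truncated below at 0 (the analysis model itself keeps the
    untruncated hierarchy; with the default precisions the truncated mass
    is negligible).  Returns a frame indexed by participant_id.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_participants
    sd_u = 1.0 / np.sqrt(spec.Ht)
    sd_t = 1.0 / np.sqrt(spec.Ht2)
    ped = rng.normal(spec.HPed, sd_u, n)
    occ = rng.normal(spec.HOcc, sd_u, n)
    # truncated-below-0 normal via robust inverse CDF
    tau = spec.Htau + sd_t * _sample_truncnorm_lower(rng, np.full(n, -spec.Htau / sd_t))
    return pd.DataFrame(
        {"ped": ped, "occ": occ, "tau": tau}, index=_participant_ids(country, n)
    )


def simulate_choices(
    individuals: pd.DataFrame,
    scenarios: list[ChoiceScenario] | None = None,
    seed: int = 0,
    country: Country = Country.UK,
    rng: np.random.Generator | None = None,
) -> list[ChoiceRecord]:
    """One Bernoulli(Phi(tau_i * dU)) record per (individual, scenario)."""
    scenarios = scenarios if scenarios is not None else generate_choice_design()
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(seed)
    records: list[ChoiceRecord] = []
    ped = individuals["ped"].to_numpy()
    occ = individuals["occ"].to_numpy()
    tau = individuals["tau"].to_numpy()
    ids = list(individuals.index)
    for s in scenarios:
        dpr = s.car_b.price - s.car_a.price
        a_p = (s.car_a.program is Program.PEDESTRIANS) - (s.car_b.program is Program.PEDESTRIANS)
        a_o = (s.car_a.program is Program.OCCUPANTS) - (s.car_b.program is Program.OCCUPANTS)
        p_a = choice_probability(dpr + a_p * ped + a_o * occ, tau)
        took_a = rng.random(len(ids)) < p_a
        records.extend(
            ChoiceRecord(pid, country, s.scenario_id, "A" if a else "B")
            for pid, a in zip(ids, took_a)
        )
    return records


def _draw_categorical(
    rng: np.random.Generator, probs: dict[PreferenceChoice, float], n: int
) -> np.ndarray:
    p = np.array([probs.get(c, 0.0) for c in _CHOICE_ORDER])
    return rng.choice(len(_CHOICE_ORDER), size=n, p=p / p.sum())


def simulate_preferences(
    spec: CategoricalSpec,
    frames: list[Frame] | None = None,
    n: int = 100,
    seed: int = 0,
    country: Country = Country.UK,
    rng: np.random.Generator | None = None,
) -> list[PreferenceResponse]:
    """Framed categorical preferences with per-participant consistency.

    A single latent unframed draw underlies the unframed and family-framed
    responses; each family framing switches the latent draw to its
    congruent option with the frame's switch probability.  The moral
    question is an independent draw from the same marginal.
    """
    frames = frames if frames is not None else list(Frame)
    rng = rng if rng is not None else np.random.default_rng(seed)
    ids = _participant_ids(country, n)
    latent = _draw_categorical(rng, spec.base_probs, n)
    out: list[PreferenceResponse] = []
    for frame in frames:
        if frame is Frame.MORAL:
            codes = _draw_categorical(rng, spec.base_probs, n)
        elif frame in _FRAME_CONGRUENT:
            pi = spec.frame_shift.get(frame, 0.0)
            switch = rng.random(n) < pi
            congruent = _CHOICE_ORDER.index(_FRAME_CONGRUENT[frame])
            codes = np.where(switch, congruent, latent)
        else:
            codes = latent
        out.extend(
            PreferenceResponse(pid, country, frame, _CHOICE_ORDER[c])
            for pid, c in zip(ids, codes)
        )
    return out


def simulate_likert(
    spec: LikertSpec,
    preferences: list[PreferenceResponse],
    n: int | None = None,
    seed: int = 0,
    country: Country = Country.UK,
    rng: np.random.Generator | None = None,
) -> list[LikertResponse]:
    """Baseline and mandate-condition Likert responses.

    Each participant has one latent Normal(baseline_mean, baseline_sd)
    willingness; a mandate subtracts ``mandate_drop`` from the latent
    value iff the mandated programme differs from the participant's
    unframed preferred programme (a RANDOM preference counts as
    different from every mandate).  Latents are rounded then clipped to
    1..7.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    preferred = {
        p.participant_id: p.choice for p in preferences if p.frame is Frame.UNFRAMED
    }
    ids = sorted(preferred) if n is None else _participant_ids(country, n)
    latent = rng.normal(spec.baseline_mean, spec.baseline_sd, len(ids))

    def discretise(x: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(x), 1, 7).astype(int)

    out: list[LikertResponse] = []
    for cond in Condition:
        if cond is Condition.BASELINE:
            values = discretise(latent)
        else:
            mandated = MANDATED_PROGRAM[cond]
            differs = np.array([preferred.get(pid) != mandated for pid in ids])
            values = discretise(latent - spec.mandate_drop * differs)
        out.extend(
            LikertResponse(pid, country, cond, int(v)) for pid, v in zip(ids, values)
        )
    return out


def simulate_survey(
    spec: SurveySpec, seed: int = 0
) -> dict[str, list]:
    """Generate a full synthetic survey: choices, preferences, likert.

    Uses one independent pseudo-random stream per table, split from the
    master seed, so each table can be regenerated on its own.
    """
    master = np.random.SeedSequence(seed)
    ss_ind, ss_choice, ss_pref, ss_lik = master.spawn(4)
    individuals = draw_individuals(
        spec.population, spec.country, rng=np.random.default_rng(ss_ind)
    )
    scenarios = generate_choice_design()
    records = simulate_choices(
        individuals, scenarios, country=spec.country, rng=np.random.default_rng(ss_choice)
    )
    preferences = simulate_preferences(
        spec.categorical,
        n=spec.population.n_participants,
        country=spec.country,
        rng=np.random.default_rng(ss_pref),
    )
    likert = simulate_likert(
        spec.likert,
        preferences,
        n=spec.population.n_participants,
        country=spec.country,
        rng=np.random.default_rng(ss_lik),
    )
    return {
        "individuals": individuals,
        "scenarios": scenarios,
        "choices": records,
        "preferences": preferences,
        "likert": likert,
    }


def _load_preset_config() -> dict:
    text = (
        importlib.resources.files("avchoice").joinpath("presets.yaml").read_text("utf-8")
    )
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_load_preset_config()["presets"])


def load_preset(
    name: str, n_participants: int | None = None, seed: int = 0
) -> SurveySpec:
    """Load a shipped country preset, optionally overriding the sample size."""
    config = _load_preset_config()["presets"]
    if name not in config:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(config)}")
    c = config[name]
    pop = c["population"]
    return SurveySpec(
        country=Country(c["country"]),
        population=PopulationSpec(
            HPed=pop["HPed"],
            HOcc=pop["HOcc"],
            Htau=pop["Htau"],
            Ht=pop["Ht"],
            Ht2=pop["Ht2"],
            n_participants=n_participants or c["n_participants"],
            seed=seed,
        ),
        categorical=CategoricalSpec(
            base_probs={
                PreferenceChoice(k): v for k, v in c["categorical"]["base_probs"].items()
            },
            frame_shift={
                Frame(k): v for k, v in c["categorical"]["frame_shift"].items()
            },
        ),
        likert=LikertSpec(
            baseline_mean=c["likert"]["baseline_mean"],
            baseline_sd=c["likert"]["baseline_sd"],
            mandate_drop=c["likert"]["mandate_drop"],
        ),
    )
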