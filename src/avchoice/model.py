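"""Hierarchical Bayesian probit model of driverless-car purchase choices.

The model
---------
Each participant *i* chooses between two cars A and B.  The utility
difference combines the price difference with the difference in
programme utility (save-the-most is the zero reference)::

    dU(A, B) = (price_B - price_A) + (prog_A - prog_B)

with ``prog`` equal to 0 for MOST, ``Ped_i`` for PEDESTRIANS and
``Occ_i`` for OCCUPANTS, all in thousands of pounds.  The probability of
choosing A is the inverse-probit of the utility difference scaled by the
participant's sensitivity ``tau_i``::

    P(A) = Phi(tau_i * dU)

and each observed choice is a single Bernoulli trial.  Individual
parameters are drawn from population-level normals,

    Ped_i ~ N(HPed, 1/Ht),  Occ_i ~ N(HOcc, 1/Ht),  tau_i ~ N(Htau, 1/Ht2)

with weakly-informative priors HPed, HOcc ~ N(0, 10) (variance 10 on the
pound-thousand scale) and Gamma(1/2, 1/2) priors on Htau, Ht and Ht2.

The sampler
-----------
Posterior sampling uses latent-variable (Albert-Chib) data augmentation:
each Bernoulli choice is represented by a truncated-normal latent
variable, after which every block is conditionally conjugate — the
individual (Ped, Occ) pairs and tau, and the hyperparameters HPed, HOcc,
Ht, Ht2 are Gibbs-updated in closed form.  Only Htau, whose gamma prior
is not conjugate to the normal hierarchy, takes a scalar random-walk
Metropolis step, with its proposal scale adapted during burn-in only so
that the retained chain is a fixed-kernel Markov chain.

Willingness to pay is reported as the price premium a programme carries
relative to save-the-most: ``premium = -1000 * utility`` in pounds, so a
positive premium means the population prefers save-the-most and would
need a discount of that size to accept the alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import log_ndtr, ndtr, ndtri
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .design import CarOffer, ChoiceRecord, ChoiceScenario, Program
from .diagnostics import hdi as _hdi
from .diagnostics import rhat as _rhat
from .io import choices_to_frame

__all__ = [
    "PriorConfig",
    "ModelConfig",
    "HyperParams",
    "PosteriorSamples",
    "WtpReport",
    "HierarchicalProbitChoiceModel",
    "utility_difference",
    "choice_probability",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
    "wtp_report",
    "posterior_predictive_check",
]

_HYPER_NAMES = ("HPed", "HOcc", "Htau", "Ht", "Ht2")


@dataclass(frozen=True)
class PriorConfig:
    """Priors on the population-level parameters (all config-overridable).

    ``utility_prior_precision`` is the precision of the zero-mean normal
    prior on HPed and HOcc (default 1/10, i.e. variance 10 in £k²);
    ``gamma_shape``/``gamma_rate`` parameterise the Gamma priors on Htau,
    Ht and Ht2 (default shape 1/2, rate 1/2).
    """

    utility_prior_mean: float = 0.0
    utility_prior_precision: float = 0.1
    gamma_shape: float = 0.5
    gamma_rate: float = 0.5


@dataclass(frozen=True)
class ModelConfig:
    """Sampler configuration.

    ``n_samples`` counts total iterations per chain including the
    ``n_burnin`` discarded ones (the convention of the survey's original
    3-chain, 50 000-sample, 5 000-burn-in fits).
    """

    n_chains: int = 3
    n_samples: int = 5_000
    n_burnin: int = 1_000
    seed: int = 0
    rhat_threshold: float = 1.1
    hdi_mass: float = 0.95
    thin: int = 1
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not self.n_samples > self.n_burnin >= 0:
            raise ValueError("need n_samples > n_burnin >= 0")
        if not 0 < self.hdi_mass < 1:
            raise ValueError("hdi_mass must be in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class HyperParams:
    """Population-level parameters of the hierarchy."""

    HPed: float
    HOcc: float
    Htau: float
    Ht: float
    Ht2: float


def _program_utility(program: Program | str, ped: float, occ: float) -> float:
    program = Program(program)
    if program is Program.PEDESTRIANS:
        return ped
    if program is Program.OCCUPANTS:
        return occ
    return 0.0


def utility_difference(car_a: CarOffer, car_b: CarOffer, ped: float, occ: float) -> float:
    """Signed utility difference dU(A, B) in £k; positive favours car A."""
    return (car_b.price - car_a.price) + (
        _program_utility(car_a.program, ped, occ) - _program_utility(car_b.program, ped, occ)
    )


def choice_probability(delta_u, tau):
    """P(choose A) = Phi(tau * dU), the inverse-probit link."""
    return ndtr(np.asarray(tau) * np.asarray(delta_u))


def log_likelihood(
    records: list[ChoiceRecord],
    scenarios: list[ChoiceScenario],
    individuals: pd.DataFrame,
) -> float:
    """Bernoulli log likelihood of the observed choices.

    ``individuals`` is indexed by participant_id with columns
    ``ped, occ, tau``.  Returns 0 for an empty record set; a probability
    of exactly 0 at an observed choice yields ``-inf``, never an
    exception.
    """
    if not records:
        return 0.0
    by_id = {s.scenario_id: s for s in scenarios}
    total = 0.0
    for rec in records:
        s = by_id[rec.scenario_id]
        row = individuals.loc[rec.participant_id]
        du = utility_difference(s.car_a, s.car_b, row["ped"], row["occ"])
        # log P(A) = log_ndtr(tau*dU); log P(B) = log_ndtr(-tau*dU)
        sign = 1.0 if rec.choice == "A" else -1.0
        total += float(log_ndtr(sign * row["tau"] * du))
    return total


def log_prior(
    hyper: HyperParams,
    individuals: pd.DataFrame | None = None,
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Joint log density of hyperparameters and (optionally) individuals.

    Normal priors on HPed/HOcc, Gamma priors on Htau/Ht/Ht2, plus the
    hierarchical normal terms for each individual.  Returns ``-inf``
    whenever a gamma-distributed quantity or precision is <= 0.
    """
    if hyper.Htau <= 0 or hyper.Ht <= 0 or hyper.Ht2 <= 0:
        return -math.inf
    sd_u = 1.0 / math.sqrt(priors.utility_prior_precision)
    total = norm.logpdf(hyper.HPed, priors.utility_prior_mean, sd_u)
    total += norm.logpdf(hyper.HOcc, priors.utility_prior_mean, sd_u)
    for x in (hyper.Htau, hyper.Ht, hyper.Ht2):
        total += gamma_dist.logpdf(x, priors.gamma_shape, scale=1.0 / priors.gamma_rate)
    if individuals is not None and len(individuals):
        sd_t = 1.0 / math.sqrt(hyper.Ht)
        sd_t2 = 1.0 / math.sqrt(hyper.Ht2)
        total += norm.logpdf(individuals["ped"], hyper.HPed, sd_t).sum()
        total += norm.logpdf(individuals["occ"], hyper.HOcc, sd_t).sum()
        total += norm.logpdf(individuals["tau"], hyper.Htau, sd_t2).sum()
    return float(total)


def _sample_truncnorm_lower(rng: np.random.Generator, a: np.ndarray) -> np.ndarray:
    """Draw T ~ N(0,1) conditioned on T > a, elementwise.

    Uses the complementary inverse-CDF ``T = -ndtri((1-u) * ndtr(-a))``,
    which stays accurate far into the right tail (sf values near 1e-300).
    """
    u = rng.random(a.shape)
    return -ndtri((1.0 - u) * ndtr(-a))


@dataclass
class _Design:
    """Preprocessed choice data shared by all chains."""

    participant_ids: list[str]
    idx: np.ndarray  # record -> participant code
    dprice: np.ndarray  # price_B - price_A (£k)
    a_ped: np.ndarray  # coefficient of Ped_i in dU: {-1, 0, +1}
    a_occ: np.ndarray
    sign: np.ndarray  # +1 if A chosen, -1 if B
    # per-participant constants of the bivariate (Ped, Occ) update
    s_pp: np.ndarray
    s_po: np.ndarray
    s_oo: np.ndarray

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)


def _build_design(X: pd.DataFrame) -> _Design:
    required = {"participant_id", "program_a", "price_a", "program_b", "price_b", "choice"}
    missing = required - set(X.columns)
    if missing:
        raise ValueError(f"choice frame is missing columns {sorted(missing)}")
    codes, uniques = pd.factorize(X["participant_id"], sort=True)
    a_ped = (X["program_a"] == Program.PEDESTRIANS.value).to_numpy(float) - (
        X["program_b"] == Program.PEDESTRIANS.value
    ).to_numpy(float)
    a_occ = (X["program_a"] == Program.OCCUPANTS.value).to_numpy(float) - (
        X["program_b"] == Program.OCCUPANTS.value
    ).to_numpy(float)
    dprice = X["price_b"].to_numpy(float) - X["price_a"].to_numpy(float)
    choice = X["choice"].to_numpy()
    if not np.isin(choice, ("A", "B")).all():
        raise ValueError("choice column must contain only 'A' and 'B'")
    sign = np.where(choice == "A", 1.0, -1.0)
    n = len(uniques)
    return _Design(
        participant_ids=[str(u) for u in uniques],
        idx=codes,
        dprice=dprice,
        a_ped=a_ped,
        a_occ=a_occ,
        sign=sign,
        s_pp=np.bincount(codes, weights=a_ped * a_ped, minlength=n),
        s_po=np.bincount(codes, weights=a_ped * a_occ, minlength=n),
        s_oo=np.bincount(codes, weights=a_occ * a_occ, minlength=n),
    )


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with convergence diagnostics.

    ``hyper`` has shape (chain, draw, 5) ordered (HPed, HOcc, Htau, Ht,
    Ht2); ``individual`` has shape (chain, draw, participant, 3) ordered
    (Ped, Occ, tau).  R-hat is computed for every retained parameter.
    """

    hyper: np.ndarray
    individual: np.ndarray
    participant_ids: list[str]
    hdi_mass: float
    accept_rate_htau: float
    config: ModelConfig | None = None

    def __post_init__(self) -> None:
        self.rhat_hyper = {
            name: float(_rhat(self.hyper[:, :, k])) for k, name in enumerate(_HYPER_NAMES)
        }
        if self.individual.shape[2]:
            r = _rhat(self.individual)  # (participant, 3)
            self.rhat_individual = pd.DataFrame(
                r, index=self.participant_ids, columns=["Ped", "Occ", "tau"]
            )
        else:
            self.rhat_individual = pd.DataFrame(columns=["Ped", "Occ", "tau"])

    def get(self, name: str) -> np.ndarray:
        """Draws (chain, draw) of a hyperparameter, or (chain, draw,
        participant) of 'Ped', 'Occ' or 'tau'."""
        if name in _HYPER_NAMES:
            return self.hyper[:, :, _HYPER_NAMES.index(name)]
        ind = {"Ped": 0, "Occ": 1, "tau": 2}
        if name in ind:
            return self.individual[:, :, :, ind[name]]
        raise KeyError(name)

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def hdi(self, name: str, mass: float | None = None) -> tuple[float, float]:
        return _hdi(self.get(name).ravel(), mass if mass is not None else self.hdi_mass)

    @property
    def max_rhat(self) -> float:
        values = list(self.rhat_hyper.values())
        if len(self.rhat_individual):
            values.append(float(self.rhat_individual.to_numpy().max()))
        return max(values)

    def individual_means(self) -> pd.DataFrame:
        """Posterior mean (Ped, Occ, tau) per participant."""
        m = self.individual.mean(axis=(0, 1))
        return pd.DataFrame(m, index=self.participant_ids, columns=["ped", "occ", "tau"])

    def to_dataset(self) -> xr.Dataset:
        data = {
            name: (("chain", "draw"), self.hyper[:, :, k])
            for k, name in enumerate(_HYPER_NAMES)
        }
        for k, name in enumerate(("Ped", "Occ", "tau")):
            data[name] = (("chain", "draw", "participant"), self.individual[:, :, :, k])
        return xr.Dataset(
            data,
            coords={
                "chain": np.arange(self.hyper.shape[0]),
                "draw": np.arange(self.hyper.shape[1]),
                "participant": self.participant_ids,
            },
            attrs={"hdi_mass": self.hdi_mass, "accept_rate_htau": self.accept_rate_htau},
        )

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={name: self.get(name) for name in (*_HYPER_NAMES, "Ped", "Occ", "tau")},
            coords={"participant": self.participant_ids},
            dims={"Ped": ["participant"], "Occ": ["participant"], "tau": ["participant"]},
        )

    def save(self, path) -> None:
        """Persist as netCDF (classic format, no extra dependencies)."""
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        ds = xr.load_dataset(path, engine="scipy")
        hyper = np.stack([ds[name].values for name in _HYPER_NAMES], axis=-1)
        individual = np.stack([ds[name].values for name in ("Ped", "Occ", "tau")], axis=-1)
        return cls(
            hyper=hyper,
            individual=individual,
            participant_ids=[str(p) for p in ds["participant"].values],
            hdi_mass=float(ds.attrs.get("hdi_mass", 0.95)),
            accept_rate_htau=float(ds.attrs.get("accept_rate_htau", np.nan)),
        )


class HierarchicalProbitChoiceModel:
    """Hierarchical Bayesian probit discrete-choice model (estimator API).

    Parameters mirror :class:`ModelConfig`; after :meth:`fit` the
    posterior is available as ``posterior_`` and summaries via
    :meth:`wtp_report` and :meth:`predict_proba`.

    Examples
    --------
    >>> model = HierarchicalProbitChoiceModel(n_samples=2000, n_burnin=500, seed=1)
    >>> model.fit(frame)          # tidy frame from io.choices_to_frame  # doctest: +SKIP
    >>> model.posterior_.mean("HPed")                                    # doctest: +SKIP
    """

    def __init__(
        self,
        n_chains: int = 3,
        n_samples: int = 5_000,
        n_burnin: int = 1_000,
        seed: int = 0,
        rhat_threshold: float = 1.1,
        hdi_mass: float = 0.95,
        thin: int = 1,
        priors: PriorConfig = PriorConfig(),
    ):
        self.n_chains = n_chains
        self.n_samples = n_samples
        self.n_burnin = n_burnin
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.hdi_mass = hdi_mass
        self.thin = thin
        self.priors = priors

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_samples": self.n_samples,
            "n_burnin": self.n_burnin,
            "seed": self.seed,
            "rhat_threshold": self.rhat_threshold,
            "hdi_mass": self.hdi_mass,
            "thin": self.thin,
            "priors": self.priors,
        }

    def set_params(self, **params) -> "HierarchicalProbitChoiceModel":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @property
    def config(self) -> ModelConfig:
        return ModelConfig(
            n_chains=self.n_chains,
            n_samples=self.n_samples,
            n_burnin=self.n_burnin,
            seed=self.seed,
            rhat_threshold=self.rhat_threshold,
            hdi_mass=self.hdi_mass,
            thin=self.thin,
            priors=self.priors,
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalProbitChoiceModel":
        """Fit to a tidy choice frame (see :func:`avchoice.io.choices_to_frame`).

        ``X`` needs columns participant_id, program_a, price_a, program_b,
        price_b (prices in £k) and — unless ``y`` is given — choice
        ('A'/'B').  An empty frame is allowed and samples the prior.
        """
        config = self.config  # validates
        if y is not None:
            X = X.copy()
            X["choice"] = np.asarray(y)
        design = _build_design(X) if len(X) else _build_design(_empty_frame())
        self.posterior_ = _run_chains(design, config)
        self.design_ = design
        self.n_participants_ = design.n_participants
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(choose A) per row, using posterior-mean individual parameters
        for known participants and population means otherwise."""
        self._check_fitted()
        means = self.posterior_.individual_means()
        h = {name: self.posterior_.mean(name) for name in _HYPER_NAMES}
        ped = np.full(len(X), h["HPed"])
        occ = np.full(len(X), h["HOcc"])
        tau = np.full(len(X), h["Htau"])
        known = X["participant_id"].astype(str).isin(means.index).to_numpy()
        if known.any():
            sub = means.loc[X["participant_id"].astype(str)[known]]
            ped[known] = sub["ped"].to_numpy()
            occ[known] = sub["occ"].to_numpy()
            tau[known] = sub["tau"].to_numpy()
        a_ped = (X["program_a"] == Program.PEDESTRIANS.value).to_numpy(float) - (
            X["program_b"] == Program.PEDESTRIANS.value
        ).to_numpy(float)
        a_occ = (X["program_a"] == Program.OCCUPANTS.value).to_numpy(float) - (
            X["program_b"] == Program.OCCUPANTS.value
        ).to_numpy(float)
        du = (
            X["price_b"].to_numpy(float)
            - X["price_a"].to_numpy(float)
            + a_ped * ped
            + a_occ * occ
        )
        return ndtr(tau * du)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Majority-side prediction: 'A' where P(A) >= 0.5."""
        return np.where(self.predict_proba(X) >= 0.5, "A", "B")

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Hit rate of majority-side predictions against observed choices."""
        observed = np.asarray(y) if y is not None else X["choice"].to_numpy()
        return float((self.predict(X) == observed).mean())

    def wtp_report(self) -> "WtpReport":
        self._check_fitted()
        return wtp_report(self.posterior_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("model is not fitted; call fit() first")


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "program_a": pd.Series(dtype=str),
            "price_a": pd.Series(dtype=float),
            "program_b": pd.Series(dtype=str),
            "price_b": pd.Series(dtype=float),
            "choice": pd.Series(dtype=str),
        }
    )


def _run_chains(design: _Design, config: ModelConfig) -> PosteriorSamples:
    n_keep = (config.n_samples - config.n_burnin) // config.thin
    n = design.n_participants
    hyper = np.empty((config.n_chains, n_keep, 5))
    individual = np.empty((config.n_chains, n_keep, n, 3))
    accept = []
    root = np.random.SeedSequence(config.seed)
    for chain, ss in enumerate(root.spawn(config.n_chains)):
        h, ind, acc = _run_one_chain(design, config, np.random.default_rng(ss))
        hyper[chain] = h
        individual[chain] = ind
        accept.append(acc)
    return PosteriorSamples(
        hyper=hyper,
        individual=individual,
        participant_ids=design.participant_ids,
        hdi_mass=config.hdi_mass,
        accept_rate_htau=float(np.mean(accept)),
        config=config,
    )


def _run_one_chain(
    design: _Design, config: ModelConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    pr = config.priors
    n = design.n_participants
    n_rec = design.idx.size
    a_g, b_g = pr.gamma_shape, pr.gamma_rate
    mu0, prec0 = pr.utility_prior_mean, pr.utility_prior_precision

    # init at prior/population means, jittered per chain
    h_ped = mu0 + 0.5 * rng.standard_normal()
    h_occ = mu0 + 0.5 * rng.standard_normal()
    h_tau = abs(a_g / b_g * (1.0 + 0.1 * rng.standard_normal()))
    h_t = a_g / b_g
    h_t2 = a_g / b_g
    ped = np.full(n, h_ped) + 0.1 * rng.standard_normal(n)
    occ = np.full(n, h_occ) + 0.1 * rng.standard_normal(n)
    tau = np.full(n, h_tau) + 0.01 * rng.standard_normal(n)

    n_keep = (config.n_samples - config.n_burnin) // config.thin
    hyper_out = np.empty((n_keep, 5))
    ind_out = np.empty((n_keep, n, 3))
    step = 0.1  # Htau RW proposal sd, adapted during burn-in only
    log_step = math.log(step)
    accepted = 0
    proposed = 0
    kept = 0

    idx = design.idx
    dp, ap, ao, sign = design.dprice, design.a_ped, design.a_occ, design.sign

    for it in range(config.n_samples):
        if n_rec:
            tau_r = tau[idx]
            du = dp + ap * ped[idx] + ao * occ[idx]
            m = tau_r * du
            # latent z | rest: N(m, 1) truncated to the observed side of 0
            z = m + sign * _sample_truncnorm_lower(rng, -sign * m)

            # (Ped_i, Occ_i) | z, tau, hypers: bivariate normal, closed form
            w = z - tau_r * dp
            bp = np.bincount(idx, weights=tau_r * ap * w, minlength=n) + h_t * h_ped
            bo = np.bincount(idx, weights=tau_r * ao * w, minlength=n) + h_t * h_occ
            t2 = tau * tau
            p11 = t2 * design.s_pp + h_t
            p12 = t2 * design.s_po
            p22 = t2 * design.s_oo + h_t
            det = p11 * p22 - p12 * p12
            c11, c12, c22 = p22 / det, -p12 / det, p11 / det
            mean_p = c11 * bp + c12 * bo
            mean_o = c12 * bp + c22 * bo
            l11 = np.sqrt(c11)
            l21 = c12 / l11
            l22 = np.sqrt(c22 - l21 * l21)
            e1 = rng.standard_normal(n)
            e2 = rng.standard_normal(n)
            ped = mean_p + l11 * e1
            occ = mean_o + l21 * e1 + l22 * e2

            # tau_i | z, Ped, Occ, hypers: scalar normal
            du = dp + ap * ped[idx] + ao * occ[idx]
            prec_t = np.bincount(idx, weights=du * du, minlength=n) + h_t2
            mean_t = (np.bincount(idx, weights=du * z, minlength=n) + h_t2 * h_tau) / prec_t
            tau = mean_t + rng.standard_normal(n) / np.sqrt(prec_t)

        # HPed, HOcc | individuals: conjugate normal
        prec_h = prec0 + n * h_t
        h_ped = (prec0 * mu0 + h_t * ped.sum()) / prec_h + rng.standard_normal() / math.sqrt(prec_h)
        h_occ = (prec0 * mu0 + h_t * occ.sum()) / prec_h + rng.standard_normal() / math.sqrt(prec_h)

        # Htau | tau: random-walk Metropolis (gamma prior breaks conjugacy)
        prop = h_tau + math.exp(log_step) * rng.standard_normal()
        proposed += 1
        acc_prob = 0.0
        if prop > 0:
            def _lp(x: float) -> float:
                return (a_g - 1.0) * math.log(x) - b_g * x - 0.5 * h_t2 * float(
                    np.square(tau - x).sum()
                )
            log_alpha = _lp(prop) - _lp(h_tau)
            acc_prob = min(1.0, math.exp(min(log_alpha, 0.0)))
            if rng.random() < acc_prob:
                h_tau = prop
                accepted += 1
        if it < config.n_burnin:
            log_step += (acc_prob - 0.44) / math.sqrt(it + 1.0)

        # Ht, Ht2 | individuals, hyper means: conjugate gamma
        ss_u = float(np.square(ped - h_ped).sum() + np.square(occ - h_occ).sum())
        h_t = rng.gamma(a_g + n, 1.0 / (b_g + 0.5 * ss_u))
        ss_t = float(np.square(tau - h_tau).sum())
        h_t2 = rng.gamma(a_g + 0.5 * n, 1.0 / (b_g + 0.5 * ss_t))

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            hyper_out[kept] = (h_ped, h_occ, h_tau, h_t, h_t2)
            ind_out[kept, :, 0] = ped
            ind_out[kept, :, 1] = occ
            ind_out[kept, :, 2] = tau
            kept += 1

    return hyper_out[:kept], ind_out[:kept], accepted / max(proposed, 1)


def sample_posterior(
    records: list[ChoiceRecord],
    scenarios: list[ChoiceScenario],
    config: ModelConfig | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of the hierarchical probit model.

    Thin wrapper over :class:`HierarchicalProbitChoiceModel` for callers
    holding domain objects rather than a tidy frame.  An empty record set
    samples the prior.
    """
    config = config or ModelConfig()
    frame = choices_to_frame(scenarios, records) if records else _empty_frame()
    model = HierarchicalProbitChoiceModel(**{**config.__dict__})
    model.fit(frame)
    return model.posterior_


@dataclass
class WtpReport:
    """Willingness-to-pay summary in pounds, relative to save-the-most.

    A positive premium means the programme is disfavoured: the population
    would need a price discount of that size to accept it over
    save-the-most.  ``premiums`` maps programme name to (mean, lo, hi) in
    £; ``individual_premiums`` holds per-participant posterior-mean
    premiums; ``tau_negative_mass`` is the posterior-predictive
    probability that a new individual's sensitivity is negative, and
    ``tau_mass_flag`` is set when it exceeds 1%.
    """

    premiums: dict[str, tuple[float, float, float]]
    individual_premiums: pd.DataFrame
    hdi_mass: float
    tau_negative_mass: float

    @property
    def tau_mass_flag(self) -> bool:
        return self.tau_negative_mass > 0.01

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"program": prog, "premium_gbp": m, "hdi_lo_gbp": lo, "hdi_hi_gbp": hi}
                for prog, (m, lo, hi) in self.premiums.items()
            ]
        )


def wtp_report(posterior: PosteriorSamples) -> WtpReport:
    """Convert posterior utilities (£k) to price premiums (£)."""
    premiums: dict[str, tuple[float, float, float]] = {
        Program.MOST.value: (0.0, 0.0, 0.0)  # reference programme
    }
    for prog, name in ((Program.PEDESTRIANS, "HPed"), (Program.OCCUPANTS, "HOcc")):
        mean = -1000.0 * posterior.mean(name)
        lo, hi = posterior.hdi(name)
        premiums[prog.value] = (mean, -1000.0 * hi, -1000.0 * lo)
    means = posterior.individual_means()
    individual = pd.DataFrame(
        {
            Program.PEDESTRIANS.value: -1000.0 * means["ped"],
            Program.OCCUPANTS.value: -1000.0 * means["occ"],
        }
    )
    # P(tau_new < 0) = E[Phi(-Htau * sqrt(Ht2))] over hyper draws
    neg_mass = float(
        np.mean(ndtr(-posterior.get("Htau") * np.sqrt(posterior.get("Ht2"))))
    )
    return WtpReport(
        premiums=premiums,
        individual_premiums=individual,
        hdi_mass=posterior.hdi_mass,
        tau_negative_mass=neg_mass,
    )


def posterior_predictive_check(
    posterior: PosteriorSamples,
    records: list[ChoiceRecord],
    scenarios: list[ChoiceScenario],
) -> pd.DataFrame:
    """Observed vs model-predicted A-share per scenario, plus a hit rate.

    The prediction for a scenario averages Phi(tau_i * dU_i) over
    posterior draws and individuals.  The returned frame has one row per
    scenario (columns observed_share, predicted_share, n) and carries the
    overall record-level hit rate in ``frame.attrs['hit_rate']``.
    """
    frame = choices_to_frame(scenarios, records)
    by_id = {s.scenario_id: s for s in scenarios}
    part_index = {p: k for k, p in enumerate(posterior.participant_ids)}
    # posterior mean of Phi(tau dU) per (participant, scenario)
    ped = posterior.get("Ped").reshape(-1, len(part_index))
    occ = posterior.get("Occ").reshape(-1, len(part_index))
    tau = posterior.get("tau").reshape(-1, len(part_index))
    rows = []
    pred_by_scenario: dict[int, np.ndarray] = {}
    for sid, s in sorted(by_id.items()):
        dpr = s.car_b.price - s.car_a.price
        a_p = (s.car_a.program is Program.PEDESTRIANS) - (s.car_b.program is Program.PEDESTRIANS)
        a_o = (s.car_a.program is Program.OCCUPANTS) - (s.car_b.program is Program.OCCUPANTS)
        du = dpr + a_p * ped + a_o * occ  # (draw, participant)
        p = ndtr(tau * du).mean(axis=0)  # per participant
        pred_by_scenario[sid] = p
        sub = frame[frame["scenario_id"] == sid]
        observed = float((sub["choice"] == "A").mean()) if len(sub) else np.nan
        rows.append(
            {
                "scenario_id": sid,
                "observed_share": observed,
                "predicted_share": float(p.mean()),
                "n": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    hits = 0
    for rec in records:
        p = pred_by_scenario[rec.scenario_id][part_index[rec.participant_id]]
        predicted = "A" if p >= 0.5 else "B"
        hits += predicted == rec.choice
    out.attrs["hit_rate"] = hits / len(records) if records else float("nan")
    return out
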