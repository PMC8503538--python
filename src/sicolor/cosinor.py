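"""Bayesian random-intercept cosinor linear mixed model.

The response (a PC1 colour score) is modelled as

    y_i = M + dM*m_i + beta*x_i + gamma*z_i + delta*s_i
          + d_beta*m_i*x_i + d_gamma*m_i*z_i + d_delta*m_i*s_i
          + u_pop(i) + e_i

with cosinor terms x = cos(2*pi*t/tau), z = sin(2*pi*t/tau) (t the capture
day-of-year, tau the period, 365 days for a circannual rhythm), m a male
indicator (female is the reference level), s the standardized snout-to-vent
length, u_p ~ Normal(0, sigma_population) a population random intercept and
e_i ~ Normal(0, sigma_error).  Priors are weakly-informative normals on the
coefficients and half-Cauchy on the two standard deviations.

Sampling uses a seeded Gibbs scheme: the coefficient block and the random
intercepts have conjugate normal full conditionals; the two standard
deviations are updated by slice sampling on the log scale.  Convergence is
monitored with the split R-hat diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "COEF_NAMES",
    "IndividualRecord",
    "CosinorDesign",
    "PriorSpec",
    "MCMCSettings",
    "FULL_SCALE_MCMC",
    "PosteriorDraws",
    "ConvergenceWarning",
    "standardize_svl",
    "cosinor_terms",
    "build_design",
    "log_posterior",
    "fit_cosinor_lmm",
]

COEF_NAMES = ("mesor", "d_mesor", "beta", "gamma", "delta", "d_beta", "d_gamma", "d_delta")

_SEX_ALIASES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
}

ADULT_MIN_SVL = 50.0  # mm; smaller animals are juveniles and excluded upstream


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when split R-hat exceeds its threshold."""


@dataclass
class IndividualRecord:
    """One adult lizard: identity, site, sex, body size, capture day, colour score."""

    id: str
    population: str
    sex: str
    svl: float
    day: float
    score: float | None = None

    def __post_init__(self):
        sex = _SEX_ALIASES.get(str(self.sex).strip().lower())
        if sex is None:
            raise ValueError(f"unknown sex label {self.sex!r}")
        self.sex = sex
        if self.svl < ADULT_MIN_SVL:
            raise ValueError(f"juvenile record (SVL {self.svl} < {ADULT_MIN_SVL} mm)")
        if not 1 <= self.day <= 366:
            raise ValueError(f"day-of-year out of range: {self.day}")


@dataclass
class CosinorDesign:
    """Design matrix for the cosinor LMM, plus the population grouping."""

    responses: np.ndarray              # (n,)
    X: np.ndarray                      # (n, 8) columns in COEF_NAMES order
    group: np.ndarray                  # (n,) population index
    populations: list[str]             # index -> label
    tau: float
    column_names: tuple[str, ...] = COEF_NAMES

    @property
    def n_populations(self) -> int:
        return len(self.populations)


@dataclass
class PriorSpec:
    """Priors: Normal(0, sd) on coefficients, half-Cauchy(scale) on both sigmas.

    ``coef_spread`` is interpreted according to ``coef_spread_is``: as a
    precision (JAGS convention; 0.001 gives sd ~= 31.6, effectively flat on
    the score scale) or directly as a standard deviation.
    """

    coef_mean: float = 0.0
    coef_spread: float = 0.001
    coef_spread_is: str = "precision"  # "precision" | "sd"
    sd_scale: float = 25.0             # half-Cauchy scale for sigma_error, sigma_population

    def __post_init__(self):
        if self.coef_spread <= 0 or self.sd_scale <= 0:
            raise ValueError("prior spread parameters must be positive")
        if self.coef_spread_is not in ("precision", "sd"):
            raise ValueError("coef_spread_is must be 'precision' or 'sd'")

    @property
    def coef_sd(self) -> float:
        if self.coef_spread_is == "precision":
            return 1.0 / math.sqrt(self.coef_spread)
        return self.coef_spread


@dataclass
class MCMCSettings:
    """Chain geometry.  Defaults are a desk-scale run; see ``FULL_SCALE_MCMC``."""

    chains: int = 3
    iterations: int = 6000
    burnin: int = 1000
    thinning: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burnin must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


FULL_SCALE_MCMC = MCMCSettings(chains=3, iterations=34000, burnin=4000, thinning=3, seed=0)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, kept per chain for diagnostics."""

    params: dict[str, np.ndarray]      # name -> (chains, n_kept)
    populations: list[str]
    tau: float
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    settings: MCMCSettings | None = None

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated."""
        return self.params[name].reshape(-1)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return first.size


def standardize_svl(svl_values: Sequence[float]) -> np.ndarray:
    """Center and scale SVL to mean 0, sample sd 1, pooled over all rows."""
    v = np.asarray(svl_values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("zero variance: need at least 2 distinct SVL values")
    return (v - v.mean()) / v.std(ddof=1)


def cosinor_terms(day, tau: float = 365.0):
    """Cosinor regressors x = cos(2*pi*day/tau), z = sin(2*pi*day/tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    ang = 2.0 * np.pi * np.asarray(day, dtype=float) / tau
    return np.cos(ang), np.sin(ang)


def build_design(records: Sequence[IndividualRecord], tau: float = 365.0) -> CosinorDesign:
    """Assemble the fixed-effect matrix and population grouping from records.

    Row order follows the input.  Sex is coded female = 0, male = 1 so all
    male parameters are offsets from the female reference level.
    """
    if any(r.score is None for r in records):
        raise ValueError("all records need a score to build a design")
    y = np.array([r.score for r in records], dtype=float)
    day = np.array([r.day for r in records], dtype=float)
    x, z = cosinor_terms(day, tau)
    m = np.array([1.0 if r.sex == "male" else 0.0 for r in records])
    s = standardize_svl([r.svl for r in records])
    X = np.column_stack([np.ones_like(y), m, x, z, s, m * x, m * z, m * s])
    populations = sorted({r.population for r in records})
    pop_index = {p: i for i, p in enumerate(populations)}
    group = np.array([pop_index[r.population] for r in records], dtype=int)
    return CosinorDesign(responses=y, X=X, group=group, populations=populations, tau=tau)


def _half_cauchy_logpdf(sigma: float, scale: float) -> float:
    if sigma <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((sigma / scale) ** 2)


def log_posterior(params: dict, design: CosinorDesign, priors: PriorSpec) -> float:
    """Unnormalized log posterior density of the full parameter set.

    ``params`` holds ``coefs`` (length 8, COEF_NAMES order), ``u`` (one
    intercept per population), ``sigma_error`` and ``sigma_population``.
    Returns -inf when either sigma is non-positive (the density's support
    boundary); non-finite parameter values are an error.
    """
    coefs = np.asarray(params["coefs"], dtype=float)
    u = np.asarray(params["u"], dtype=float)
    se = float(params["sigma_error"])
    sp = float(params["sigma_population"])
    if not (np.all(np.isfinite(coefs)) and np.all(np.isfinite(u))
            and np.isfinite(se) and np.isfinite(sp)):
        raise ValueError("non-finite parameter values")
    if coefs.size != design.X.shape[1]:
        raise ValueError("coefficient vector has wrong length")
    if u.size != design.n_populations:
        raise ValueError("one random intercept per population is required")
    if se <= 0 or sp <= 0:
        return -np.inf
    mu = design.X @ coefs + u[design.group]
    resid = design.responses - mu
    n = resid.size
    loglik = -0.5 * n * math.log(2 * math.pi) - n * math.log(se) - 0.5 * float(resid @ resid) / se**2
    p = u.size
    log_u = -0.5 * p * math.log(2 * math.pi) - p * math.log(sp) - 0.5 * float(u @ u) / sp**2
    csd = priors.coef_sd
    dev = coefs - priors.coef_mean
    log_coef = (-0.5 * coefs.size * math.log(2 * math.pi) - coefs.size * math.log(csd)
                - 0.5 * float(dev @ dev) / csd**2)
    log_sd = _half_cauchy_logpdf(se, priors.sd_scale) + _half_cauchy_logpdf(sp, priors.sd_scale)
    return loglik + log_u + log_coef + log_sd


def _slice_sample_log_sigma(log_sigma: float, logdens, rng, width: float = 1.0,
                            max_steps: int = 50) -> float:
    """One slice-sampling update of log(sigma) for a univariate log density."""
    y0 = logdens(log_sigma)
    logy = y0 + math.log(rng.uniform()) if y0 > -np.inf else -np.inf
    lo = log_sigma - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logdens(lo) <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logdens(hi) <= logy:
            break
        hi += width
    while True:
        prop = rng.uniform(lo, hi)
        if logdens(prop) > logy:
            return prop
        if prop < log_sigma:
            lo = prop
        else:
            hi = prop


def _run_chain(design: CosinorDesign, priors: PriorSpec, mcmc: MCMCSettings,
               seed_seq: np.random.SeedSequence,
               fixed_sigma_error: float | None,
               fixed_sigma_population: float | None) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed_seq)
    X, y, group = design.X, design.responses, design.group
    n, k = X.shape
    P = design.n_populations
    onehot = np.eye(P)[group]
    W = np.concatenate([X, onehot], axis=1)  # joint fixed + random design
    WtW = W.T @ W
    Wty = W.T @ y
    csd = priors.coef_sd
    coef_prior_prec = np.full(k, 1.0 / csd**2)
    prior_mean_term = np.concatenate([np.full(k, priors.coef_mean / csd**2), np.zeros(P)])
    hc = priors.sd_scale

    # initial state: ridge least squares, zero intercepts, residual scale
    coefs = np.linalg.solve(X.T @ X + np.diag(coef_prior_prec), X.T @ y)
    u = np.zeros(P)
    resid0 = y - X @ coefs
    se = fixed_sigma_error if fixed_sigma_error is not None else max(float(resid0.std()), 1e-3)
    sp = fixed_sigma_population if fixed_sigma_population is not None else max(se, 1e-3)

    n_kept = -((mcmc.iterations - mcmc.burnin) // -mcmc.thinning)
    out = {name: np.empty(n_kept) for name in COEF_NAMES}
    out["sigma_error"] = np.empty(n_kept)
    out["sigma_population"] = np.empty(n_kept)
    for label in design.populations:
        out[f"u_{label}"] = np.empty(n_kept)

    kept = 0
    for it in range(mcmc.iterations):
        # (coefficients, u) | sigmas : one joint conjugate normal block, which
        # avoids the slow intercept <-> random-intercept random walk of
        # separate updates
        prior_prec = np.concatenate([coef_prior_prec, np.full(P, 1.0 / sp**2)])
        prec = WtW / se**2 + np.diag(prior_prec)
        rhs = Wty / se**2 + prior_mean_term
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(k + P))
        coefs, u = theta[:k], theta[k:]

        resid = y - X @ coefs - u[group]
        ssr = float(resid @ resid)
        uu = float(u @ u)

        # sigma_error | rest : slice on log scale (includes the Jacobian)
        if fixed_sigma_error is None:
            def ld_se(ls, _ssr=ssr):
                s = math.exp(ls)
                return (-n * ls - 0.5 * _ssr / s**2 + _half_cauchy_logpdf(s, hc) + ls)
            se = math.exp(_slice_sample_log_sigma(math.log(se), ld_se, rng))

        # sigma_population | rest
        if fixed_sigma_population is None:
            def ld_sp(ls, _uu=uu):
                s = math.exp(ls)
                return (-P * ls - 0.5 * _uu / s**2 + _half_cauchy_logpdf(s, hc) + ls)
            sp = math.exp(_slice_sample_log_sigma(math.log(sp), ld_sp, rng))

        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thinning == 0:
            for j, name in enumerate(COEF_NAMES):
                out[name][kept] = coefs[j]
            out["sigma_error"][kept] = se
            out["sigma_population"][kept] = sp
            for p_idx, label in enumerate(design.populations):
                out[f"u_{label}"][kept] = u[p_idx]
            kept += 1
    return out


def fit_cosinor_lmm(design: CosinorDesign, priors: PriorSpec | None = None,
                    mcmc: MCMCSettings | None = None,
                    fixed_sigma_error: float | None = None,
                    fixed_sigma_population: float | None = None,
                    rhat_threshold: float = 1.1) -> PosteriorDraws:
    """Draw from the cosinor LMM posterior by Gibbs sampling.

    Burn-in is discarded and thinning applied per chain; split R-hat is
    computed per parameter and a ``ConvergenceWarning`` is issued (never an
    error) when any exceeds ``rhat_threshold``.  Fully reproducible given
    ``mcmc.seed``.  The ``fixed_sigma_*`` arguments clamp a standard
    deviation instead of sampling it (useful for validation against the
    conjugate Gaussian sub-case).
    """
    import arviz as az

    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCSettings()
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chain_draws = [
        _run_chain(design, priors, mcmc, s, fixed_sigma_error, fixed_sigma_population)
        for s in seeds
    ]
    params = {
        name: np.stack([cd[name] for cd in chain_draws])
        for name in chain_draws[0]
    }
    rhat: dict[str, float] = {}
    for name, arr in params.items():
        if np.ptp(arr) == 0:  # clamped or degenerate parameter
            rhat[name] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat[name] = float(az.rhat(arr))
    converged = all(r <= rhat_threshold for r in rhat.values() if np.isfinite(r))
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v > rhat_threshold}
        warnings.warn(f"split R-hat above {rhat_threshold}: {bad}", ConvergenceWarning)
    return PosteriorDraws(
        params=params,
        populations=list(design.populations),
        tau=design.tau,
        rhat=rhat,
        converged=converged,
        settings=mcmc,
    )
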