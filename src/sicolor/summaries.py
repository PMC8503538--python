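"""Posterior summaries for cosinor rhythm parameters.

Turns raw MCMC draws into the quantities a rhythmometry study reports:
per-sex MESOR, amplitude, acrophase and calendar peak date, male-female
contrast probabilities, evidence of seasonality, and the share of residual
variance carried by the population random intercept.  Point estimates use
the half-sample mode (HSM), a mode estimator robust to skewed posteriors;
intervals are highest-density intervals (HDI) from the shortest contiguous
window of sorted draws.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "hsm",
    "hdi",
    "amplitude_acrophase",
    "AmplitudePhase",
    "sex_specific_draws",
    "prob_greater",
    "seasonality_evidence",
    "variance_partition",
    "circular_peak_hdi",
    "peak_day_to_date",
    "summarize_posterior",
]

# cumulative days before each month, non-leap year
_MONTH_STARTS = np.cumsum([0] + [calendar.monthrange(2019, m)[1] for m in range(1, 12)])


def hsm(samples: Sequence[float]) -> float:
    """Half-sample mode: recursive shortest-half mode estimator.

    At each step keep the shortest contiguous window of ``ceil(n/2)``
    sorted points (ties broken toward the smallest start index) and
    recurse; terminal cases are n=1 (the value), n=2 (the mean) and n=3
    (mean of the closest pair, or of all three on a full tie).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size == 0:
        raise ValueError("hsm requires a non-empty sample")
    while True:
        n = x.size
        if n == 1:
            return float(x[0])
        if n == 2:
            return float(0.5 * (x[0] + x[1]))
        if n == 3:
            d01 = x[1] - x[0]
            d12 = x[2] - x[1]
            if d01 < d12:
                return float(0.5 * (x[0] + x[1]))
            if d12 < d01:
                return float(0.5 * (x[1] + x[2]))
            return float(x.mean())
        m = int(np.ceil(n / 2))
        widths = x[m - 1:] - x[: n - m + 1]
        i = int(np.argmin(widths))  # first minimum = smallest start index
        x = x[i: i + m]


def hdi(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: shortest window of ``ceil(mass*n)`` sorted draws.

    Ties are broken toward the smallest lower bound.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("hdi requires at least 2 samples")
    # an interval needs two endpoints, so the window never shrinks below 2
    m = min(max(int(np.ceil(mass * n)), 2), n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class AmplitudePhase:
    """Amplitude, acrophase and peak timing of a single-component cosinor."""

    amplitude: np.ndarray | float
    acrophase: np.ndarray | float
    peak_day: np.ndarray | float
    degenerate: np.ndarray | bool


def amplitude_acrophase(beta, gamma, tau: float = 365.0) -> AmplitudePhase:
    """Convert cosinor coefficients to amplitude, acrophase and peak day.

    The model ``M + beta*cos(2*pi*t/tau) + gamma*sin(2*pi*t/tau)`` equals
    ``M + A*cos(2*pi*t/tau + phi)`` with ``A = sqrt(beta^2 + gamma^2)`` and
    ``phi = atan2(-gamma, beta)``; the peak falls at
    ``t = (-phi mod 2*pi) * tau / (2*pi)``.  When beta = gamma = 0 the phase
    is undefined and is returned as 0 with ``degenerate`` set.
    """
    b = np.asarray(beta, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(g))):
        raise ValueError("cosinor coefficients must be finite")
    amp = np.hypot(b, g)
    degen = (b == 0) & (g == 0)
    phi = np.where(degen, 0.0, np.arctan2(-g, b))
    peak = (np.mod(-phi, 2 * np.pi)) * tau / (2 * np.pi)
    if np.ndim(beta) == 0 and np.ndim(gamma) == 0:
        return AmplitudePhase(float(amp), float(phi), float(peak), bool(degen))
    return AmplitudePhase(amp, phi, peak, degen)


def sex_specific_draws(draws, tau: float | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Per-sex posterior draws of (MESOR, amplitude, acrophase, peak day, size slope).

    Female parameters are the reference level; male parameters add the
    male-offset draws.  ``amplitude_acrophase`` is applied draw by draw so
    all derived quantities propagate full posterior uncertainty.
    """
    if tau is None:
        tau = getattr(draws, "tau", 365.0)
    get = draws.flat
    out: dict[str, dict[str, np.ndarray]] = {}
    for sex, off in (("female", 0.0), ("male", 1.0)):
        mesor = get("mesor") + off * get("d_mesor")
        beta = get("beta") + off * get("d_beta")
        gamma = get("gamma") + off * get("d_gamma")
        slope = get("delta") + off * get("d_delta")
        ap = amplitude_acrophase(beta, gamma, tau=tau)
        out[sex] = {
            "mesor": mesor,
            "beta": beta,
            "gamma": gamma,
            "amplitude": ap.amplitude,
            "acrophase": ap.acrophase,
            "peak_day": ap.peak_day,
            "size_slope": slope,
        }
    return out


def prob_greater(a_draws, b_draws) -> float:
    """P(a > b) over paired posterior draws; ties count one half."""
    a = np.asarray(a_draws, dtype=float)
    b = np.asarray(b_draws, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw arrays must be paired (equal length)")
    return float(np.mean((a > b) + 0.5 * (a == b)))


def seasonality_evidence(amplitude_draws, threshold: float = 0.0) -> float:
    """Fraction of amplitude draws exceeding ``threshold`` (default 0)."""
    a = np.asarray(amplitude_draws, dtype=float)
    return float(np.mean(a > threshold))


def variance_partition(sigma_pop_draws, sigma_err_draws, mass: float = 0.95):
    """Share of residual variance carried by the population intercept.

    Per draw: ``sigma_pop^2 / (sigma_pop^2 + sigma_err^2)``.  Returns the
    proportion draws plus an (HSM, HDI) summary.
    """
    sp = np.asarray(sigma_pop_draws, dtype=float)
    se = np.asarray(sigma_err_draws, dtype=float)
    props = sp**2 / (sp**2 + se**2)
    return props, {"hsm": hsm(props), "hdi95": hdi(props, mass)}


def circular_peak_hdi(peak_day_draws, mass: float = 0.95, tau: float = 365.0) -> tuple[float, float]:
    """HDI of a peak-day posterior that may wrap the year boundary.

    Rotates the draws so that their HSM maps to ``tau/2``, applies the
    linear HDI, and rotates back; the returned endpoints are on the
    original circle and may satisfy lower > upper when the interval wraps
    1 January.
    """
    d = np.mod(np.asarray(peak_day_draws, dtype=float), tau)
    shift = tau / 2 - hsm(d)
    lo, hi = hdi(np.mod(d + shift, tau), mass)
    return float(np.mod(lo - shift, tau)), float(np.mod(hi - shift, tau))


def peak_day_to_date(day_of_year: float) -> str:
    """Map a (possibly fractional) day-of-year to a calendar date string.

    Non-leap calendar, day 1 = 1 January; fractional days round to the
    nearest integer day.  Day 0 (a peak exactly at the year origin) is
    reported as 1 January.
    """
    d = float(day_of_year)
    if not 0.0 <= d <= 365.0:
        raise ValueError(f"day of year out of range [0, 365]: {d}")
    di = int(round(d))
    if di == 0:
        di = 1
    month = int(np.searchsorted(_MONTH_STARTS, di, side="right"))
    day_in_month = di - int(_MONTH_STARTS[month - 1])
    return f"{day_in_month} {calendar.month_name[month]}"


def summarize_posterior(draws, channel: str = "", amplitude_threshold: float = 0.0) -> dict:
    """Full rhythm summary of one fitted model's posterior draws.

    Returns a nested dict: per-sex MESOR / amplitude / acrophase / peak day
    and date / size slope (each HSM + HDI95 + HDI50), male-female contrast
    probabilities, per-sex seasonality evidence P(A > threshold), the
    population variance partition, and per-population intercept summaries.
    """
    tau = getattr(draws, "tau", 365.0)
    per_sex = sex_specific_draws(draws, tau=tau)

    def _summ(x):
        return {"hsm": hsm(x), "hdi95": list(hdi(x, 0.95)), "hdi50": list(hdi(x, 0.50))}

    out: dict = {"channel": channel, "tau": tau, "sexes": {}}
    for sex, d in per_sex.items():
        peak_hsm = hsm(d["peak_day"])
        out["sexes"][sex] = {
            "mesor": _summ(d["mesor"]),
            "amplitude": _summ(d["amplitude"]),
            "acrophase_rad": _summ(d["acrophase"]),
            "peak_day": {
                "hsm": peak_hsm,
                "hdi95": list(circular_peak_hdi(d["peak_day"], 0.95, tau)),
                "hdi50": list(circular_peak_hdi(d["peak_day"], 0.50, tau)),
            },
            "peak_date": peak_day_to_date(peak_hsm % tau),
            "size_slope": _summ(d["size_slope"]),
            "p_amplitude_gt_threshold": seasonality_evidence(
                d["amplitude"], amplitude_threshold
            ),
        }
    m, f = per_sex["male"], per_sex["female"]
    out["contrasts"] = {
        "p_mesor_m_gt_f": prob_greater(m["mesor"], f["mesor"]),
        "p_amplitude_m_gt_f": prob_greater(m["amplitude"], f["amplitude"]),
        "p_size_slope_m_gt_f": prob_greater(m["size_slope"], f["size_slope"]),
    }
    props, vp = variance_partition(draws.flat("sigma_population"), draws.flat("sigma_error"))
    out["variance_partition"] = vp
    out["populations"] = {
        label: _summ(draws.flat(f"u_{label}")) for label in getattr(draws, "populations", [])
    }
    return out
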