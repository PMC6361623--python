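"""Extrinsic drive: surrogate afferent spike trains and Ornstein-Uhlenbeck
background conductances.

Afferent ensembles emulate cortical units recorded upstream of BL: each
surrogate train combines the temporal rate profile of one donor unit
(rescaled to a 1-Hz mean) with the mean rate of another, drawn
independently with replacement, and realizes spikes as an inhomogeneous
Poisson process on a 1-ms grid.  Because the donor recordings themselves
are not packaged, a synthetic donor pool is provided: log-normal mean rates
(median ~1.5 Hz, heavy tail to ~10 Hz) and rate profiles built as
exponentiated OU processes with a 100-ms correlation time.  These fixtures
are synthetic stand-ins for in vivo donor statistics.

Stochastic background synaptic bombardment is modeled per cell as an
excitatory/inhibitory point-conductance pair following OU dynamics,

    dg/dt = -(g - g0)/tau + D * chi(t),

advanced with the exact discretization
g(t+dt) = g0 + (g(t)-g0) exp(-dt/tau) + A N(0,1),
A = sd * sqrt(1 - exp(-2 dt/tau)), so the stationary SD equals ``sd``.
The background current is I = ge (V - Ee) + gi (V - Ei) with Ee = 0 and
Ei = -75 mV; negative conductance excursions are clamped to zero at
use-time only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateProfile",
    "OuSpec",
    "OU_SPECS",
    "surrogate_trains",
    "poisson_train",
    "ou_step",
    "ou_amplitude",
    "background_current",
    "synthetic_donor_pool",
]

BIN_MS = 1.0


@dataclass(frozen=True)
class RateProfile:
    """Instantaneous-rate series (Hz) at 1-ms resolution with unit mean."""

    rates_hz: np.ndarray
    donor_mean_hz: float = 1.0

    def __post_init__(self):
        r = np.asarray(self.rates_hz, dtype=float)
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")

    @staticmethod
    def rescaled(raw_rates_hz, donor_mean_hz: float = 1.0) -> "RateProfile":
        """Rescale an arbitrary non-negative series to a 1-Hz time average."""
        r = np.asarray(raw_rates_hz, dtype=float)
        mean = r.mean()
        if mean <= 0:
            raise ValueError("profile must have positive mean rate")
        return RateProfile(rates_hz=r / mean, donor_mean_hz=donor_mean_hz)


@dataclass(frozen=True)
class OuSpec:
    g0: float  # nS, stationary mean
    sd: float  # nS, stationary SD
    tau: float  # ms
    reversal: float  # mV

    def __post_init__(self):
        if self.tau <= 0 or self.sd < 0:
            raise ValueError("tau must be positive and sd non-negative")


#: point-conductance parameters per archetype (excitatory, inhibitory)
OU_SPECS = {
    "PN": (
        OuSpec(g0=3.2, sd=3.0, tau=2.728, reversal=0.0),
        OuSpec(g0=21.0, sd=8.0, tau=10.49, reversal=-75.0),
    ),
    "FSI": (
        OuSpec(g0=1.2, sd=0.1, tau=2.728, reversal=0.0),
        OuSpec(g0=5.7, sd=2.6, tau=10.49, reversal=-75.0),
    ),
}


def ou_amplitude(spec: OuSpec, dt_ms: float) -> float:
    return spec.sd * math.sqrt(1.0 - math.exp(-2.0 * dt_ms / spec.tau))


def ou_step(g: float, spec: OuSpec, dt_ms: float,
            rng: np.random.Generator) -> float:
    """Exact-discretization OU update (stationary mean g0, SD spec.sd)."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-dt_ms / spec.tau)
    return spec.g0 + (g - spec.g0) * decay + ou_amplitude(spec, dt_ms) * rng.standard_normal()


def background_current(g_e, g_i, v, e_e: float = 0.0, e_i: float = -75.0):
    """Background current in pA for conductances in nS; conductances are
    floored at zero at use time."""
    ge = np.maximum(np.asarray(g_e, dtype=float), 0.0)
    gi = np.maximum(np.asarray(g_i, dtype=float), 0.0)
    return ge * (np.asarray(v, float) - e_e) + gi * (np.asarray(v, float) - e_i)


# ---------------------------------------------------------------------------
# Surrogate spike trains
# ---------------------------------------------------------------------------

def poisson_train(rate_profile_hz: np.ndarray, rng: np.random.Generator,
                  bin_ms: float = BIN_MS) -> np.ndarray:
    """Spike times (ms) from per-bin Poisson draws; multiple spikes per bin
    are kept and jittered uniformly within the bin."""
    lam = np.asarray(rate_profile_hz, dtype=float) * bin_ms * 1e-3
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(counts.size), counts)
    if idx.size == 0:
        return np.empty(0)
    times = (idx + rng.random(idx.size)) * bin_ms
    return np.sort(times)


def surrogate_trains(profiles: list[RateProfile], rates_hz, n: int,
                     seed: int, duration_ms: float | None = None):
    """Generate ``n`` surrogate trains: independent (profile, mean rate)
    combinations with replacement, Poisson-realized per 1-ms bin.

    Returns a list of spike-time arrays (ms)."""
    rates_hz = np.asarray(rates_hz, dtype=float)
    if len(profiles) == 0 or rates_hz.size == 0:
        raise ValueError("profile and rate pools must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        prof = profiles[rng.integers(len(profiles))]
        rate = rates_hz[rng.integers(rates_hz.size)]
        series = prof.rates_hz * rate
        if duration_ms is not None:
            nbin = int(round(duration_ms / BIN_MS))
            reps = int(np.ceil(nbin / series.size))
            series = np.tile(series, reps)[:nbin]
        out.append(poisson_train(series, rng))
    return out


def synthetic_donor_pool(n_units: int, duration_ms: float, seed: int,
                         corr_tau_ms: float = 100.0,
                         lognorm_mu: float = math.log(1.5),
                         lognorm_sigma: float = 0.8):
    """Synthetic donor pool standing in for in vivo cortical units.

    Mean rates are log-normal (median exp(mu) Hz, heavy tail to ~10 Hz);
    rate profiles are exponentiated OU series with the given correlation
    time, rescaled to unit mean.  Returns (profiles, mean_rates_hz)."""
    rng = np.random.default_rng(seed)
    nbin = int(round(duration_ms / BIN_MS))
    mean_rates = rng.lognormal(lognorm_mu, lognorm_sigma, size=n_units)
    profiles = []
    decay = math.exp(-BIN_MS / corr_tau_ms)
    amp = math.sqrt(1.0 - decay * decay)
    for _ in range(n_units):
        x = np.empty(nbin)
        x[0] = rng.standard_normal()
        noise = rng.standard_normal(nbin - 1)
        for i in range(1, nbin):
            x[i] = x[i - 1] * decay + amp * noise[i - 1]
        profiles.append(RateProfile.rescaled(np.exp(x)))
    return profiles, mean_rates
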