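"""Instrument-realistic synthetic data with known ground truth.

Each generator emulates one of the four measurement channels analysed by the
package — nano-DSF thermograms, mass-photometry event streams, sedimentation
peak tables, and HDX-MS uptake tables — so that every downstream fitting or
classification routine can be exercised against a known truth.  Outputs are
fully determined by the integer seed; with ``noise_sd = 0`` every generator
equals its closed-form model exactly.

None of the generators simulates instrument physics (optical contrast,
Lamm-equation transport, exchange kinetics at residue level): they draw from
the same statistical models the analysis modules fit, which is what makes
parameter recovery a meaningful round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nanodsf import Thermogram, fraction_unfolded
from .constants import celsius_to_kelvin

__all__ = [
    "GeneratorTransition",
    "simulate_thermogram",
    "simulate_mp_events",
    "simulate_auc_peaks",
    "simulate_hdx",
]


@dataclass
class GeneratorTransition:
    """One two-state transition of the thermogram generator.

    ``amplitude`` is the signal step contributed by the transition; ``tm_c``
    fixes ΔS = ΔH / Tm(K) so the generating Tm is exact by construction.
    """

    dH: float          # cal/mol
    tm_c: float        # °C
    amplitude: float   # signal units

    def __post_init__(self):
        if self.dH <= 0:
            raise ValueError("ΔH must be positive")
        if self.dS <= 0:
            raise ValueError("ΔS must be positive")

    @property
    def dS(self) -> float:
        return self.dH / celsius_to_kelvin(self.tm_c)


def simulate_thermogram(first: GeneratorTransition | None,
                        second: GeneratorTransition | None = None,
                        grid=(30.0, 100.0, 0.1),
                        noise_sd: float = 1e-3,
                        seed: int = 0,
                        baseline=(0.002, 0.75),
                        min_tm_separation: float = 2.0,
                        sample_id: str = "synthetic",
                        replicate: int = 0) -> Thermogram:
    """Simulate an F350/F330 melting curve.

    The noiseless model is a single global linear baseline plus additive
    two-state steps,

        E(T) = q·T + p + Δ1·fU1(T) + Δ2·fU2(T),

    which reproduces the sequential-transition shape of capsid thermograms
    while keeping each windowed fit well posed (the folded and unfolded
    baselines of each transition share the slope q).  Gaussian noise of the
    given SD is added i.i.d. on the signal.

    Transitions closer than ``min_tm_separation`` °C are rejected: windowed
    sequential fitting cannot separate them.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lo, hi, step = grid
    if not lo < hi or step <= 0:
        raise ValueError("grid must be (lo, hi, step) with lo < hi, step > 0")
    if first is not None and second is not None:
        if abs(first.tm_c - second.tm_c) < min_tm_separation:
            raise ValueError(
                f"transition Tm values differ by less than {min_tm_separation} °C; "
                "sequential windowed fitting cannot resolve them")
    t = np.arange(lo, hi + 0.5 * step, step)
    slope, intercept = baseline
    y = slope * t + intercept
    truth = {"baseline": baseline, "noise_sd": noise_sd, "seed": seed}
    for name, tr in (("first", first), ("second", second)):
        if tr is None:
            continue
        y = y + tr.amplitude * fraction_unfolded(tr.dH, tr.dS, celsius_to_kelvin(t))
        truth[name] = {"dH": tr.dH, "dS": tr.dS, "tm_c": tr.tm_c,
                       "amplitude": tr.amplitude}
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return Thermogram(t, y, sample_id=sample_id, replicate=replicate,
                      ground_truth=truth)


def simulate_mp_events(components, n_events: int, unbinding_prob: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Simulate a mass-photometry event list.

    ``components`` is a list of ``(label, mean_da, sd_da, weight)`` (or
    ``(mean, sd, weight)``, auto-labelled); weights must sum to 1.  Each
    landing event draws its mass from the Gaussian mixture; with probability
    ``unbinding_prob`` the event is an unbinding (departure) event and its
    mass is recorded with negative sign.  Ground-truth component labels are
    kept alongside the signed masses.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if not 0 <= unbinding_prob <= 1:
        raise ValueError("unbinding_prob must lie in [0, 1]")
    comps = []
    for i, c in enumerate(components):
        if len(c) == 4:
            label, mean, sd, w = c
        else:
            mean, sd, w = c
            label = f"c{i}"
        comps.append((str(label), float(mean), float(sd), float(w)))
    weights = np.array([c[3] for c in comps])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(comps), size=n_events, p=weights)
    means = np.array([c[1] for c in comps])[idx]
    sds = np.array([c[2] for c in comps])[idx]
    mass = rng.normal(means, sds)
    unbind = rng.random(n_events) < unbinding_prob
    signed = np.where(unbind, -np.abs(mass), np.abs(mass))
    return pd.DataFrame({
        "mass_da": signed,
        "true_component": [comps[i][0] for i in idx],
        "is_unbinding": unbind,
    })


def simulate_auc_peaks(species, jitter: float = 0.0, seed: int = 0,
                       total_area: float = 1.0) -> pd.DataFrame:
    """Simulate a sedimentation-velocity peak table.

    ``species`` is a list of ``(s_value_S, mass_fraction, a260_a230)``.  Peak
    s values receive Gaussian jitter of the given SD (svedbergs); areas at
    230 nm are proportional to mass fraction and the 260 nm areas follow the
    species ratio exactly.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for s, frac, ratio in species:
        if s <= 0:
            raise ValueError("s values must be positive")
        s_obs = s + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        a230 = total_area * frac
        rows.append({"s_S": s_obs, "area_230": a230, "area_260": a230 * ratio,
                     "true_s_S": s, "true_ratio": ratio})
    return pd.DataFrame(rows, columns=["s_S", "area_230", "area_260",
                                       "true_s_S", "true_ratio"])


def simulate_hdx(peptides, plateaus: dict, rate_constants: dict,
                 times=(15.0, 30.0, 180.0, 600.0, 3600.0),
                 noise_sd: float = 0.0, n_replicates: int = 3,
                 seed: int = 0) -> pd.DataFrame:
    """Simulate per-peptide deuterium-uptake time series for several states.

    Uptake follows a single-exponential approach to a per-state plateau,
    ``D(t) = plateau · (1 − exp(−k·t))``, plus Gaussian noise.  ``peptides``
    is a list of ``(start, end, modification)``; ``plateaus`` and
    ``rate_constants`` map state → {peptide_key: value} or state → scalar
    applied to every peptide.  Times are labeling durations in seconds.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for pep in peptides:
        start, end, mod = pep
        key = (start, end, mod)
        for state in plateaus:
            plat = plateaus[state]
            plat = plat[key] if isinstance(plat, dict) else plat
            if plat < 0:
                raise ValueError("uptake plateau must be non-negative")
            k = rate_constants[state]
            k = k[key] if isinstance(k, dict) else k
            for t in times:
                clean = plat * (1.0 - np.exp(-k * t))
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({"start": start, "end": end,
                                 "modification": mod, "state": state,
                                 "time_s": t, "replicate": rep,
                                 "uptake_da": max(clean + noise, 0.0)})
    return pd.DataFrame(rows)
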