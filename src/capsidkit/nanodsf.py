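"""Two-state thermal-unfolding analysis of nano-DSF thermograms.

A nano-DSF instrument reports the ratio of intrinsic tryptophan fluorescence
at 350 nm and 330 nm (F350/F330) as a function of temperature.  For a
two-state (folded ⇌ unfolded) equilibrium the unfolded fraction is

    fU(T) = exp(-ΔH/RT + ΔS/R) / (1 + exp(-ΔH/RT + ΔS/R))

and the observed signal interpolates between two linear baselines,

    E(T) = EF + (EU - EF) · fU,   EF = a·T + b,   EU = c·T + d.

This module fits that model to thermograms by nonlinear least squares with
the constraint scheme used for sequential capsid transitions: the first
(minor) transition is fitted with a shared baseline slope (a = c), and the
second (major) transition inherits the first transition's unfolded baseline
as its folded baseline.  Derived quantities are the melting temperature
Tm = ΔH/ΔS (fU = 0.5), the onset temperature where fU = 0.05, and per-gram
thermodynamics used to decide whether an unfolding domain behaves like a
compact globular protein.

Temperatures at the interface are °C; all thermodynamic evaluation is in K.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .constants import R_CAL, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "Thermogram",
    "TransitionParams",
    "TransitionFit",
    "PerGramThermo",
    "FitError",
    "fraction_unfolded",
    "predict_signal",
    "fit_first_transition",
    "fit_second_transition",
    "melting_temperature",
    "onset_temperature",
    "per_gram",
    "read_thermograms",
    "fits_to_table",
]

#: Globular-protein ranges at ~62 °C for specific enthalpy (cal/g) and
#: specific entropy (cal/(K·g)), from classical protein calorimetry.
GLOBULAR_H_RANGE = (5.7, 8.7)
GLOBULAR_S_RANGE = (1.7e-2, 2.7e-2)

DEFAULT_FIRST_WINDOW = (45.0, 70.0)
DEFAULT_SECOND_WINDOW = (65.0, 85.0)


class FitError(RuntimeError):
    """Raised when a transition fit fails (no transition, non-convergence)."""


@dataclass
class Thermogram:
    """A single melting curve: temperature grid (°C) vs F350/F330 signal."""

    temperature: np.ndarray
    signal: np.ndarray
    sample_id: str = ""
    replicate: int = 0
    ground_truth: dict | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(~np.isfinite(self.signal)):
            raise ValueError("signal contains missing values")

    def window(self, lo: float, hi: float) -> "Thermogram":
        """Restrict to temperatures in [lo, hi] °C."""
        m = (self.temperature >= lo) & (self.temperature <= hi)
        return Thermogram(self.temperature[m], self.signal[m],
                          self.sample_id, self.replicate, self.ground_truth)


@dataclass
class TransitionParams:
    """Two-state transition parameters with linear folded/unfolded baselines.

    ΔH in cal/mol, ΔS in cal/(K·mol); a, c are baseline slopes per °C and
    b, d the intercepts (signal units) of the folded and unfolded baselines.
    """

    dH: float
    dS: float
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if self.dH <= 0 or self.dS <= 0:
            raise ValueError("ΔH and ΔS must be positive")


@dataclass
class TransitionFit:
    """Result of fitting one transition window."""

    params: TransitionParams
    tm_c: float
    tonset_c: float
    residual_rms: float
    stderr: dict = field(default_factory=dict)
    window: tuple = (None, None)
    constraint_mode: str = "free"
    success: bool = True
    message: str = ""


@dataclass
class PerGramThermo:
    """Mass-normalized thermodynamics for domain assignment."""

    h: float          # cal/g
    s_g: float        # cal/(K·g)
    domain_mass: float  # g/mol
    within_globular_range: bool


# ----------------------------------------------------------------------------
# closed-form model
# ----------------------------------------------------------------------------

def fraction_unfolded(dH: float, dS: float, T_kelvin):
    """Unfolded fraction at absolute temperature T (K).

    Monotone increasing in T when ΔH, ΔS > 0; equals 0.5 at Tm = ΔH/ΔS.
    """
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    x = -dH / (R_CAL * T) + dS / R_CAL
    # logistic in x, overflow-safe for large |x|
    xp = np.clip(x, 0, None)
    xn = np.clip(x, None, 0)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-xp)),
                   np.exp(xn) / (1.0 + np.exp(xn)))
    return out if out.ndim else float(out)


def predict_signal(params: TransitionParams, temperature_c):
    """Model signal E(T) = EF + (EU − EF)·fU on a °C grid."""
    t = np.asarray(temperature_c, dtype=float)
    ef = params.a * t + params.b
    eu = params.c * t + params.d
    fu = fraction_unfolded(params.dH, params.dS, celsius_to_kelvin(t))
    return ef + (eu - ef) * fu


def melting_temperature(dH: float, dS: float) -> float:
    """Tm (°C) where fU = 0.5, i.e. ΔH/ΔS in kelvin."""
    if dH <= 0 or dS <= 0:
        raise ValueError("ΔH and ΔS must be positive")
    return kelvin_to_celsius(dH / dS)


def onset_temperature(dH: float, dS: float, f_onset: float = 0.05) -> float:
    """Temperature (°C) where fU = f_onset (default 0.05), in closed form.

    Solving fU(T) = f gives T = ΔH / (ΔS + R·ln((1−f)/f)); the log term is
    positive for f < 0.5 so Tonset < Tm always.
    """
    if dH <= 0 or dS <= 0:
        raise ValueError("ΔH and ΔS must be positive")
    if not 0 < f_onset < 0.5:
        raise ValueError("f_onset must lie in (0, 0.5)")
    t_k = dH / (dS + R_CAL * np.log((1 - f_onset) / f_onset))
    return kelvin_to_celsius(t_k)


def per_gram(dH: float, dS: float, domain_mass: float,
             h_range=GLOBULAR_H_RANGE, s_range=GLOBULAR_S_RANGE) -> PerGramThermo:
    """Normalize ΔH, ΔS by a candidate domain mass (g/mol).

    A transition is assigned to a domain if the specific enthalpy and entropy
    fall inside the globular-protein ranges.
    """
    if domain_mass <= 0:
        raise ValueError("domain mass must be positive")
    h = dH / domain_mass
    s_g = dS / domain_mass
    within = (h_range[0] <= h <= h_range[1]) and (s_range[0] <= s_g <= s_range[1])
    return PerGramThermo(h=h, s_g=s_g, domain_mass=domain_mass,
                         within_globular_range=within)


# ----------------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------------

def _initial_guesses(tg: Thermogram, dh0: float = 1e5):
    """Seed Tm at the steepest point of the window and baselines from the
    outer 20% of points on each side.

    The derivative is taken on a smoothed curve over a ~1 °C kernel so that
    point noise does not dominate the location of a shallow transition.
    """
    t, y = tg.temperature, tg.signal
    step = float(np.median(np.diff(t)))
    k = max(1, int(round(0.5 / step)))
    if len(t) > 2 * k + 4:
        kernel = np.ones(2 * k + 1) / (2 * k + 1)
        ys = np.convolve(y, kernel, mode="valid")   # aligned with t[k:-k]
        ts = t[k:len(t) - k]
    else:
        ys, ts = y, t
    dy = np.gradient(ys, ts)
    tm0 = float(ts[np.argmax(dy)])
    n = max(2, int(0.2 * len(t)))
    a0, b0 = np.polyfit(t[:n], y[:n], 1)
    c0, d0 = np.polyfit(t[-n:], y[-n:], 1)
    return tm0, dh0, (a0, b0), (c0, d0)


def _fit_transition(tg: Thermogram, window, constraint_mode: str,
                    inherited: TransitionFit | None = None,
                    f_onset: float = 0.05, dh0: float = 1e5) -> TransitionFit:
    lo, hi = window
    sub = tg.window(lo, hi)
    if len(sub.temperature) < 20:
        raise ValueError("fit window must contain at least 20 points")

    tm0, dh_init, (a0, b0), (c0, d0) = _initial_guesses(sub, dh0)
    # keep the seeded Tm strictly inside the window
    tm0 = min(max(tm0, lo + 1.0), hi - 1.0)

    p = Parameters()
    p.add("dH", value=dh_init, min=1e3, max=5e6)
    # parametrize by Tm (K): better conditioned than fitting ΔS directly
    p.add("tm_k", value=celsius_to_kelvin(tm0),
          min=celsius_to_kelvin(lo), max=celsius_to_kelvin(hi))
    if constraint_mode == "second" and inherited is not None:
        # folded baseline fixed to the first transition's unfolded baseline
        p.add("a", value=inherited.params.c, vary=False)
        p.add("b", value=inherited.params.d, vary=False)
        p.add("c", value=c0)
        p.add("d", value=d0)
    elif constraint_mode == "first":
        p.add("a", value=a0)
        p.add("b", value=b0)
        p.add("c", expr="a")          # shared slope a = c
        p.add("d", value=d0)
    else:
        p.add("a", value=a0)
        p.add("b", value=b0)
        p.add("c", value=c0)
        p.add("d", value=d0)

    t = sub.temperature
    y = sub.signal

    def resid(pars):
        dh = pars["dH"].value
        ds = dh / pars["tm_k"].value
        tp = TransitionParams(dh, ds, pars["a"].value, pars["b"].value,
                              pars["c"].value, pars["d"].value)
        return predict_signal(tp, t) - y

    res = minimize(resid, p, method="leastsq", xtol=1e-10, ftol=1e-10)
    dh = res.params["dH"].value
    ds = dh / res.params["tm_k"].value
    fitted = TransitionParams(dh, ds, res.params["a"].value, res.params["b"].value,
                              res.params["c"].value, res.params["d"].value)
    rms = float(np.sqrt(np.mean(res.residual ** 2)))
    tm_c = melting_temperature(dh, ds)

    # reject non-transitions: amplitude must exceed the residual scatter and
    # Tm must sit inside the window rather than pinned at a bound
    amp = abs((fitted.c * tm_c + fitted.d) - (fitted.a * tm_c + fitted.b))
    edge = min(tm_c - lo, hi - tm_c)
    if not res.success or amp < 5 * max(rms, 1e-12) or edge < 0.5:
        raise FitError(
            f"no resolvable transition in window {lo}-{hi} °C "
            f"(amplitude {amp:.3g}, residual rms {rms:.3g}, Tm {tm_c:.1f} °C)"
        )

    stderr = {name: (res.params[name].stderr or float("nan"))
              for name in ("dH", "tm_k")}
    return TransitionFit(
        params=fitted,
        tm_c=tm_c,
        tonset_c=onset_temperature(dh, ds, f_onset),
        residual_rms=rms,
        stderr=stderr,
        window=(lo, hi),
        constraint_mode=constraint_mode,
    )


def fit_first_transition(tg: Thermogram, window=DEFAULT_FIRST_WINDOW,
                         f_onset: float = 0.05) -> TransitionFit:
    """Fit the first (minor) transition with the shared-slope constraint a = c.

    Raises :class:`FitError` when the window holds no resolvable transition
    (e.g. capsids lacking the domain that unfolds first).
    """
    return _fit_transition(tg, window, "first", f_onset=f_onset)


def fit_second_transition(tg: Thermogram, window=DEFAULT_SECOND_WINDOW,
                          inherited: TransitionFit | None = None,
                          f_onset: float = 0.05) -> TransitionFit:
    """Fit the second (major) transition.

    When ``inherited`` is given, its unfolded baseline (c, d) is frozen as
    this window's folded baseline (a, b); its window must precede this one.
    Single-transition samples are fitted with free baselines.
    """
    if inherited is not None:
        if inherited.window[1] is not None and inherited.window[0] >= window[0]:
            raise ValueError("inherited fit's window must precede the target window")
        mode = "second"
    else:
        mode = "free"
    return _fit_transition(tg, window, mode, inherited=inherited,
                           f_onset=f_onset, dh0=3e5)


# ----------------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------------

def read_thermograms(path_or_buf) -> list[Thermogram]:
    """Read thermograms from delimited text with columns
    temperature_C, signal, sample_id, replicate."""
    df = pd.read_csv(path_or_buf, comment="#")
    out = []
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        grp = grp.sort_values("temperature_C")
        out.append(Thermogram(grp["temperature_C"].to_numpy(),
                              grp["signal"].to_numpy(),
                              sample_id=str(sid), replicate=int(rep)))
    return out


def fits_to_table(fits: dict[str, list[tuple[TransitionFit | None, TransitionFit | None]]]
                  ) -> pd.DataFrame:
    """Summarize per-replicate (first, second) fits as mean ± SD per sample.

    Mirrors the conventional melting-parameter table: Tonset1, Tm1, ΔH1, ΔS1,
    Tonset2, Tm2, ΔH2, ΔS2.
    """
    rows = []
    for sid, pairs in fits.items():
        row = {"sample_id": sid}
        for idx, name in ((0, "1"), (1, "2")):
            vals = {k: [] for k in ("Tonset", "Tm", "dH", "dS")}
            for pair in pairs:
                f = pair[idx]
                if f is None:
                    continue
                vals["Tonset"].append(f.tonset_c)
                vals["Tm"].append(f.tm_c)
                vals["dH"].append(f.params.dH)
                vals["dS"].append(f.params.dS)
            for k, v in vals.items():
                row[f"{k}{name}_mean"] = float(np.mean(v)) if v else float("nan")
                row[f"{k}{name}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
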