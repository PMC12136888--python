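"""Mass-photometry population analysis.

Mass photometry records single-particle landing (binding) events on a glass
surface; interferometric contrast is converted to mass through a linear
calibration against protein standards.  Departure (unbinding) events appear
with negative sign.  For AAV preparations the positive-mass histogram in the
2–7 MDa window decomposes into empty particles (EP, capsid only), full
particles (FP, capsid + designed genome) and overpackaged particles (OP),
plus a low-mass noise population near zero.

This module fits that decomposition by least squares on the binned histogram
(a sum of Gaussians, one per population), computes the EP area ratio with a
noise-derived significance threshold, quantifies binding/unbinding fractions,
and detects antibody-binding mass shifts between paired measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MassCalibration",
    "MixtureComponent",
    "SpeciesMixtureFit",
    "EPRatioResult",
    "fit_mass_calibration",
    "build_histogram",
    "fit_species_mixture",
    "ep_ratio",
    "noise_threshold",
    "unbinding_fraction",
    "detect_antibody_binding",
]

#: Default analysis window (Da) and bin width (Da) for AAV-size particles.
DEFAULT_MASS_RANGE = (2.0e6, 7.0e6)
DEFAULT_BIN_WIDTH = 5.0e4

#: Default EP-ratio significance threshold: noise fraction mean + 3 SD for a
#: control full-particle sample (printed constant; recompute with
#: :func:`noise_threshold` for a new control).
DEFAULT_EP_THRESHOLD = 0.148


@dataclass
class MassCalibration:
    """Linear contrast→mass mapping fitted to standards."""

    slope: float       # Da per contrast unit
    intercept: float   # Da
    standards: list = field(default_factory=list)
    residuals: np.ndarray | None = None

    def to_mass(self, contrast):
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept


@dataclass
class MixtureComponent:
    label: str
    mean: float    # Da
    sd: float      # Da
    area: float    # event counts


@dataclass
class SpeciesMixtureFit:
    components: list[MixtureComponent]
    bin_width: float
    residual_rms: float
    total_counts: float

    def component(self, label: str) -> MixtureComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no component labelled {label!r}")


@dataclass
class EPRatioResult:
    ep_ratio: float
    threshold: float
    significant: bool


def fit_mass_calibration(standards) -> MassCalibration:
    """Ordinary least-squares line through (contrast, known mass) standards.

    ``standards``: iterable of ``(name, known_mass_da, measured_contrast)``.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("need at least two calibration standards")
    contrast = np.array([s[2] for s in standards], dtype=float)
    mass = np.array([s[1] for s in standards], dtype=float)
    if len(np.unique(contrast)) != len(contrast):
        raise ValueError("calibration standards have duplicate contrasts")
    slope, intercept = np.polyfit(contrast, mass, 1)
    resid = mass - (slope * contrast + intercept)
    return MassCalibration(slope=float(slope), intercept=float(intercept),
                           standards=standards, residuals=resid)


def build_histogram(masses, bin_width: float = DEFAULT_BIN_WIDTH,
                    mass_range=DEFAULT_MASS_RANGE):
    """Bin masses into half-open bins [lo, hi): returns (edges, counts).

    An event exactly on an interior edge falls in the upper bin; an event
    equal to the top of the range is out of range.  Total counts equal the
    number of in-range events.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = mass_range
    if hi <= lo:
        raise ValueError("empty mass range")
    m = np.asarray(masses, dtype=float)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((m - lo) / bin_width).astype(int)
    ok = (m >= lo) & (m < edges[-1]) & (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    return edges, counts


def _gauss_counts(centers, mean, sd, area, bin_width):
    return area * bin_width / (sd * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((centers - mean) / sd) ** 2)


def fit_species_mixture(hist, component_specs, mean_tolerance: float = 0.20,
                        merge_sd_factor: float = 1.0) -> SpeciesMixtureFit:
    """Least-squares fit of a sum of Gaussians to a binned mass histogram.

    ``hist`` is ``(edges, counts)`` from :func:`build_histogram`;
    ``component_specs`` is a list of ``(label, initial_mean_da)`` or
    ``(label, initial_mean_da, initial_sd_da)``.  Fitted means are bounded to
    ±``mean_tolerance`` of their initial guesses so that neighbouring
    populations keep their identity.  Component areas are the analytic
    Gaussian integrals (event counts).  Components whose fitted means lie
    within ``merge_sd_factor`` × the wider component's SD of each other are
    unresolvable and are merged with a warning.
    """
    edges, counts = hist
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("histogram is empty")
    if not component_specs:
        raise ValueError("need at least one component spec")
    bin_width = float(edges[1] - edges[0])
    centers = 0.5 * (edges[:-1] + edges[1:])

    specs = []
    for spec in component_specs:
        if len(spec) == 3:
            label, mu0, sd0 = spec
        else:
            label, mu0 = spec
            sd0 = 3 * bin_width
        specs.append((str(label), float(mu0), float(sd0)))

    n = len(specs)
    x0, lo, hi = [], [], []
    total = counts.sum()
    for _, mu0, sd0 in specs:
        x0 += [mu0, sd0, total / n]
        lo += [mu0 * (1 - mean_tolerance), bin_width / 2, 0.0]
        hi += [mu0 * (1 + mean_tolerance), (edges[-1] - edges[0]), total * 1.5]

    def model(x):
        y = np.zeros_like(centers)
        for i in range(n):
            mu, sd, area = x[3 * i: 3 * i + 3]
            y += _gauss_counts(centers, mu, sd, area, bin_width)
        return y

    res = least_squares(lambda x: model(x) - counts, x0, bounds=(lo, hi),
                        xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise RuntimeError(f"mixture fit failed to converge: {res.message}")

    comps = [MixtureComponent(specs[i][0], *res.x[3 * i: 3 * i + 3])
             for i in range(n)]

    # merge components that collapsed onto the same population
    merged: list[MixtureComponent] = []
    for c in sorted(comps, key=lambda c: c.mean):
        if merged and abs(c.mean - merged[-1].mean) <= merge_sd_factor * max(
                c.sd, merged[-1].sd):
            prev = merged[-1]
            warnings.warn(
                f"components {prev.label!r} and {c.label!r} collapsed onto the "
                f"same mean ({prev.mean:.3g} Da); merging", stacklevel=2)
            w = prev.area + c.area
            if w > 0:
                prev.mean = (prev.mean * prev.area + c.mean * c.area) / w
                prev.sd = max(prev.sd, c.sd)
            prev.area = w
            prev.label = f"{prev.label}+{c.label}"
        else:
            merged.append(c)

    rms = float(np.sqrt(np.mean((model(res.x) - counts) ** 2)))
    return SpeciesMixtureFit(components=merged, bin_width=bin_width,
                             residual_rms=rms, total_counts=float(total))


def ep_ratio(mix: SpeciesMixtureFit,
             threshold: float = DEFAULT_EP_THRESHOLD) -> EPRatioResult:
    """EP area fraction among the particle populations (EP, FP, OP).

    Significant iff the fraction strictly exceeds the threshold (default is
    the noise-derived +3 SD constant 14.8%).
    """
    labels = {c.label: c.area for c in mix.components}
    if "FP" not in labels:
        raise KeyError("mixture fit has no FP component")
    ep = float(labels.get("EP", 0.0))
    denom = ep + float(labels["FP"]) + float(labels.get("OP", 0.0))
    ratio = ep / denom if denom > 0 else 0.0
    return EPRatioResult(ep_ratio=ratio, threshold=threshold,
                         significant=ratio > threshold)


def noise_threshold(noise_mean: float, noise_sd: float, k: float = 3.0) -> float:
    """Significance threshold from a control sample's noise fraction:
    mean + k·SD (default k = 3)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    return noise_mean + k * noise_sd


def unbinding_fraction(masses) -> float:
    """Fraction of unbinding (negative-mass) events among all events.

    Events at exactly zero count as binding.
    """
    m = np.asarray(masses, dtype=float)
    if m.size == 0:
        raise ValueError("empty event set")
    return float(np.count_nonzero(m < 0) / m.size)


def detect_antibody_binding(pre_fit: SpeciesMixtureFit,
                            post_fit: SpeciesMixtureFit,
                            min_shift: float | None = None):
    """Decide whether the FP population gained mass between two measurements
    (e.g. after incubation with an antibody).

    The shift is the difference of fitted FP means.  When ``min_shift`` is
    not given it defaults to 3× the pooled standard error of the two means
    (SE ≈ sd/√area).  Returns ``(bound, shift_da, min_shift)``.
    """
    pre = pre_fit.component("FP")
    post = post_fit.component("FP")
    shift = post.mean - pre.mean
    if min_shift is None:
        se_pre = pre.sd / np.sqrt(max(pre.area, 1.0))
        se_post = post.sd / np.sqrt(max(post.area, 1.0))
        min_shift = 3.0 * float(np.hypot(se_pre, se_post))
    return shift > min_shift, float(shift), float(min_shift)
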