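"""Reproducible end-to-end workflow orchestration.

A run is described by a single YAML config (paths, stage parameters, seed,
output directory).  ``run_pipeline`` executes the requested stages in method
order — simulate, fit-dsf, mp-fit, hydro, mass, hdx — writing delimited-text
tables (each with a header comment recording package version and seed), a
structured YAML summary and a plain-text log.  The same config and seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import hdx, hydro, massmodel, mp, nanodsf, synthetic

__all__ = ["RunConfig", "run_pipeline", "default_demo_config"]

log = logging.getLogger("capsidkit")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: str = "capsidkit_run"
    stages: list = field(default_factory=lambda: [
        "simulate", "fit-dsf", "mp-fit", "hydro", "mass", "hdx"])
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(seed=int(raw.get("seed", 0)),
                  outdir=raw.get("outdir", "capsidkit_run"),
                  stages=raw.get("stages", cls().stages),
                  params=raw.get("params", {}),
                  inputs=raw.get("inputs", {}))
        cfg.validate()
        return cfg

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, "outdir": self.outdir,
                            "stages": list(self.stages), "params": self.params,
                            "inputs": self.inputs}, fh, sort_keys=True)

    def validate(self):
        for name, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")
        known = {"simulate", "fit-dsf", "mp-fit", "hydro", "mass", "hdx"}
        bad = [s for s in self.stages if s not in known]
        if bad:
            raise ValueError(f"unknown stages: {bad}")


def _write_table(df: pd.DataFrame, path: Path, seed: int):
    with open(path, "w") as fh:
        fh.write(f"# capsidkit {__version__} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def default_demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """A self-contained demo run: simulate every channel, then analyse it."""
    return RunConfig(seed=seed, outdir=outdir, params={
        "thermogram": {"tm1_c": 62.0, "dh1": 1.46e5, "tm2_c": 73.7,
                       "dh2": 3.21e5, "amp1": 0.03, "amp2": 0.25,
                       "noise_sd": 1e-3, "replicates": 3},
        "mp": {"components": [["EP", 3.73e6, 1.5e5, 0.2],
                              ["FP", 4.51e6, 1.5e5, 0.6],
                              ["OP", 5.30e6, 1.5e5, 0.2]],
               "n_events": 5000, "unbinding_prob": 0.0},
        "auc": {"species": [[54.6, 0.2, 0.58], [66.0, 0.2, 0.16],
                            [91.3, 0.6, 0.47]], "jitter": 0.0},
        "hydro": {"mass_mda": 4.55, "s": 91.3,
                  "protein_mda": 3.73, "dna_mda": 0.8},
        "mass": {"vp_counts": [5, 5, 50],
                 "vp_monomer_kda": [81.6, 66.6, 59.8],
                 "genome_bases": 2521,
                 "op_mass_mda": 5.3,
                 "cargo_candidates": [["large", 1.6e6], ["full", 0.8e6],
                                      ["fragment", 0.2e6]],
                 "cargo_tolerance": 0.05e6},
        "hdx": {"plateau_control": 2.0, "plateau_heated": 3.0,
                "rate": 0.05, "noise_sd": 0.05},
    })


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict.

    A stage failure raises after writing a failure marker, leaving earlier
    outputs in place.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary = {"version": __version__, "seed": config.seed, "stages": {}}
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            _STAGES[stage](config, outdir, state, summary)
            dt = time.perf_counter() - t0
            summary["stages"].setdefault(stage, {})["wall_s"] = round(dt, 3)
            log.info("stage %s: done in %.2fs", stage, dt)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage failed: {exc}\n")
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return summary


# ----------------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path, state: dict, summary: dict):
    seed = cfg.seed
    p = cfg.params.get("thermogram", {})
    reps = []
    for r in range(p.get("replicates", 3)):
        tg = synthetic.simulate_thermogram(
            synthetic.GeneratorTransition(p.get("dh1", 1.46e5),
                                          p.get("tm1_c", 62.0),
                                          p.get("amp1", 0.03)),
            synthetic.GeneratorTransition(p.get("dh2", 3.21e5),
                                          p.get("tm2_c", 73.7),
                                          p.get("amp2", 0.25)),
            noise_sd=p.get("noise_sd", 1e-3), seed=seed * 1000 + r,
            sample_id="demo", replicate=r)
        reps.append(tg)
    state["thermograms"] = reps
    df = pd.concat([pd.DataFrame({"temperature_C": tg.temperature,
                                  "signal": tg.signal,
                                  "sample_id": tg.sample_id,
                                  "replicate": tg.replicate}) for tg in reps])
    _write_table(df, outdir / "thermograms.csv", seed)

    pm = cfg.params.get("mp", {})
    ev = synthetic.simulate_mp_events(
        [tuple(c) for c in pm.get("components", [])],
        pm.get("n_events", 5000), pm.get("unbinding_prob", 0.0), seed=seed)
    state["mp_events"] = ev
    _write_table(ev, outdir / "mp_events.csv", seed)

    pa = cfg.params.get("auc", {})
    peaks = synthetic.simulate_auc_peaks(
        [tuple(s) for s in pa.get("species", [])], pa.get("jitter", 0.0),
        seed=seed)
    state["auc_peaks"] = peaks
    _write_table(peaks, outdir / "auc_peaks.csv", seed)

    ph = cfg.params.get("hdx", {})
    table = synthetic.simulate_hdx(
        [(101, 131, ""), (205, 229, "acetyl"), (562, 578, "")],
        plateaus={"control": ph.get("plateau_control", 2.0),
                  "heated": ph.get("plateau_heated", 3.0)},
        rate_constants={"control": ph.get("rate", 0.05),
                        "heated": ph.get("rate", 0.05)},
        noise_sd=ph.get("noise_sd", 0.05), seed=seed)
    state["hdx_table"] = table
    _write_table(table, outdir / "hdx_uptake.csv", seed)


def _stage_fit_dsf(cfg: RunConfig, outdir: Path, state: dict, summary: dict):
    if "thermograms" in state:
        tgs = state["thermograms"]
    else:
        tgs = nanodsf.read_thermograms(cfg.inputs["thermograms"])
    pairs = []
    for tg in tgs:
        first = nanodsf.fit_first_transition(tg)
        second = nanodsf.fit_second_transition(tg, inherited=first)
        pairs.append((first, second))
    table = nanodsf.fits_to_table({tgs[0].sample_id: pairs})
    _write_table(table, outdir / "dsf_fits.csv", cfg.seed)
    summary["stages"]["fit-dsf"] = {
        "tm1_c": round(float(np.mean([p[0].tm_c for p in pairs])), 3),
        "tm2_c": round(float(np.mean([p[1].tm_c for p in pairs])), 3),
    }


def _stage_mp_fit(cfg: RunConfig, outdir: Path, state: dict, summary: dict):
    if "mp_events" in state:
        ev = state["mp_events"]
    else:
        ev = pd.read_csv(cfg.inputs["mp_events"], comment="#")
    masses = ev["mass_da"].to_numpy()
    hist = mp.build_histogram(masses[masses > 0])
    pm = cfg.params.get("mp", {})
    specs = [(c[0], c[1]) for c in pm.get("components", [])]
    fit = mp.fit_species_mixture(hist, specs)
    ratio = mp.ep_ratio(fit)
    rows = [{"label": c.label, "mean_da": c.mean, "sd_da": c.sd,
             "area_counts": c.area} for c in fit.components]
    _write_table(pd.DataFrame(rows), outdir / "mp_species.csv", cfg.seed)
    summary["stages"]["mp-fit"] = {
        "ep_ratio": round(ratio.ep_ratio, 4),
        "ep_significant": bool(ratio.significant),
        "unbinding_fraction": round(mp.unbinding_fraction(masses), 4),
    }


def _stage_hydro(cfg: RunConfig, outdir: Path, state: dict, summary: dict):
    ph = cfg.params.get("hydro", {})
    vbar = hydro.capsid_genome_vbar(ph.get("protein_mda", 3.73) * 1e6,
                                    ph.get("dna_mda", 0.8) * 1e6)
    ffr = hydro.frictional_ratio(ph.get("mass_mda", 4.55) * 1e6,
                                 ph.get("s", 91.3), vbar)
    peaks = state.get("auc_peaks")
    if peaks is None and "auc_peaks" in cfg.inputs:
        peaks = pd.read_csv(cfg.inputs["auc_peaks"], comment="#")
    rows = []
    if peaks is not None:
        for row in peaks.itertuples():
            pk = hydro.SedimentationPeak(row.s_S, row.area_230, row.area_260)
            rows.append({"s_S": pk.s, "ratio": pk.ratio,
                         "label": hydro.classify_peak(pk)})
        _write_table(pd.DataFrame(rows), outdir / "peak_labels.csv", cfg.seed)
    summary["stages"]["hydro"] = {"composite_vbar": round(vbar, 4),
                                  "f_over_f0": round(ffr, 3)}


def _stage_mass(cfg: RunConfig, outdir: Path, state: dict, summary: dict):
    pm = cfg.params.get("mass", {})
    comp = massmodel.ParticleComposition(
        tuple(pm.get("vp_counts", (5, 5, 50))),
        tuple(1e3 * m for m in pm.get("vp_monomer_kda", (81.6, 66.6, 59.8))))
    empty = massmodel.particle_mass(comp)
    full = empty + pm.get("genome_bases", 2521) * comp.per_base_mass
    cargo = massmodel.cargo_mass(pm.get("op_mass_mda", 5.3) * 1e6, empty)
    sols = massmodel.enumerate_cargo_compositions(
        cargo, [tuple(c) for c in pm.get("cargo_candidates", [])],
        pm.get("cargo_tolerance", 0.05e6))
    rows = [{"counts": ";".join(f"{k}x{v}" for k, v in s.counts.items()) or "empty",
             "total_mass_da": s.total_mass, "residual_da": s.residual}
            for s in sols]
    _write_table(pd.DataFrame(rows, columns=["counts", "total_mass_da",
                                             "residual_da"]),
                 outdir / "cargo_solutions.csv", cfg.seed)
    summary["stages"]["mass"] = {"empty_mda": round(empty / 1e6, 3),
                                 "full_mda": round(full / 1e6, 3),
                                 "op_cargo_mda": round(cargo / 1e6, 3),
                                 "n_cargo_solutions": len(sols)}


def _stage_hdx(cfg: RunConfig, outdir: Path, state: dict, summary: dict):
    if "hdx_table" in state:
        table = state["hdx_table"]
    else:
        table = hdx.read_uptake_table(cfg.inputs["hdx_uptake"])
    diffs = hdx.accumulated_differences(table, "control", "heated")
    flags = hdx.flag_peptides(diffs)
    _write_table(flags, outdir / "hdx_flags.csv", cfg.seed)
    summary["stages"]["hdx"] = {
        "n_peptides": len(flags),
        "n_significant": int(flags["significant"].sum()),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "fit-dsf": _stage_fit_dsf,
    "mp-fit": _stage_mp_fit,
    "hydro": _stage_hydro,
    "mass": _stage_mass,
    "hdx": _stage_hdx,
}
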