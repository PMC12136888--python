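"""Differential deuterium-uptake analysis for HDX-MS.

Hydrogen/deuterium exchange MS reports, per proteolytic peptide and labeling
time, the mass increase (Da) from backbone-amide deuteration.  Comparing two
states (e.g. heated vs control capsids), the per-time difference of replicate
means is summed across the labeling-time series to give an *accumulated*
uptake difference per peptide; peptides whose accumulated difference exceeds
a global threshold (default 3.281 Da) are flagged as significantly changed.

Peptides are identified by (start, end, modification) on 1-based inclusive
VP1 residue coordinates; N-terminally modified duplicates of a span (e.g.
acetylated peptides) are distinct species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeptideDifference",
    "accumulated_difference",
    "accumulated_differences",
    "flag_peptides",
    "read_uptake_table",
    "DEFAULT_UPTAKE_THRESHOLD",
]

#: Global significance threshold on accumulated uptake difference, Da.
DEFAULT_UPTAKE_THRESHOLD = 3.281

REQUIRED_COLUMNS = ["start", "end", "modification", "state", "time_s",
                    "replicate", "uptake_da"]


@dataclass
class PeptideDifference:
    """Accumulated uptake difference (treated − control) for one peptide."""

    start: int
    end: int
    modification: str
    per_time: dict            # time_s -> mean difference, Da
    accumulated: float        # Da, sum over the time series
    pooled_sd: float          # Da
    significant: bool = False


def _validate(df: pd.DataFrame):
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table missing columns: {missing}")
    if (df["uptake_da"] < 0).any():
        raise ValueError("uptake values must be non-negative")


def accumulated_difference(control: pd.DataFrame, treated: pd.DataFrame
                           ) -> PeptideDifference:
    """Accumulated uptake difference for a single peptide.

    Both frames must cover one peptide with identical labeling-time series;
    per-time differences are differences of replicate means, the accumulated
    value their sum, and the pooled SD the root-sum-of-squares over times of
    the per-time pooled variances of the difference.
    """
    _validate(control)
    _validate(treated)
    keys_c = set(map(tuple, control[["start", "end", "modification"]].values))
    keys_t = set(map(tuple, treated[["start", "end", "modification"]].values))
    if len(keys_c) != 1 or keys_c != keys_t:
        raise ValueError("both states must cover exactly one common peptide")
    times_c = sorted(control["time_s"].unique())
    times_t = sorted(treated["time_s"].unique())
    if times_c != times_t:
        missing = sorted(set(times_c) ^ set(times_t))
        raise ValueError(f"mismatched labeling-time series; unmatched times: {missing}")

    start, end, mod = next(iter(keys_c))
    per_time, variances = {}, []
    for t in times_c:
        uc = control.loc[control["time_s"] == t, "uptake_da"]
        ut = treated.loc[treated["time_s"] == t, "uptake_da"]
        per_time[t] = float(ut.mean() - uc.mean())
        var_c = uc.var(ddof=1) / len(uc) if len(uc) > 1 else 0.0
        var_t = ut.var(ddof=1) / len(ut) if len(ut) > 1 else 0.0
        variances.append(var_c + var_t)
    accumulated = float(sum(per_time.values()))
    pooled_sd = float(np.sqrt(sum(variances)))
    return PeptideDifference(start=int(start), end=int(end), modification=str(mod),
                             per_time=per_time, accumulated=accumulated,
                             pooled_sd=pooled_sd)


def accumulated_differences(table: pd.DataFrame, control_state: str,
                            treated_state: str) -> list[PeptideDifference]:
    """Per-peptide accumulated differences for every peptide present in both
    states of a long-format uptake table."""
    _validate(table)
    out = []
    for key, grp in table.groupby(["start", "end", "modification"], sort=True):
        c = grp[grp["state"] == control_state]
        t = grp[grp["state"] == treated_state]
        if c.empty or t.empty:
            continue
        out.append(accumulated_difference(c, t))
    return out


def flag_peptides(differences, threshold: float = DEFAULT_UPTAKE_THRESHOLD
                  ) -> pd.DataFrame:
    """Flag peptides whose accumulated difference strictly exceeds the
    threshold; returns a tidy per-peptide table."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    for d in differences:
        d.significant = d.accumulated > threshold
        rows.append({"start": d.start, "end": d.end,
                     "modification": d.modification,
                     "accumulated_da": d.accumulated,
                     "pooled_sd_da": d.pooled_sd,
                     "significant": d.significant})
    return pd.DataFrame(rows, columns=["start", "end", "modification",
                                       "accumulated_da", "pooled_sd_da",
                                       "significant"])


def read_uptake_table(path_or_buf) -> pd.DataFrame:
    """Read an uptake table from delimited text with columns
    start, end, modification, state, time_s, replicate, uptake_da."""
    df = pd.read_csv(path_or_buf, comment="#")
    if "modification" in df.columns:
        df["modification"] = df["modification"].fillna("").astype(str)
    _validate(df)
    return df
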