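"""Long-format CSV / JSON / TSV interchange.

Canonical schemas (UTF-8, "." decimal, exact headers):

* thermal ramps:   enzyme, solvent, conc_pct_vv, channel, temperature_C, signal
* kinetic traces:  enzyme, solvent, conc_pct_vv, temperature_C, time_s, a340,
                   enzyme_conc_mg_ml, path_length_cm [, extinction_coeff]
* activity profile: enzyme, solvent, conc_pct_vv, temperature_C,
                   specific_activity, sem, n

Concentrations are always % (v/v) and temperatures °C at every file
boundary. Malformed input is rejected with the offending line numbers;
rows are never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityPoint, KineticTrace, ActivityFit, DEFAULT_EXTINCTION_NADPH
from .stability import StabilityTable, RankedEnzyme
from .unfolding import ThermalRamp, UnfoldingFit

__all__ = [
    "SchemaError",
    "read_ramps",
    "write_ramps",
    "read_traces",
    "write_traces",
    "read_profile",
    "write_profile",
    "write_fits",
    "read_fits",
    "write_table",
    "read_table",
    "write_ranking",
]

RAMP_COLUMNS = ["enzyme", "solvent", "conc_pct_vv", "channel", "temperature_C", "signal"]
TRACE_COLUMNS = [
    "enzyme", "solvent", "conc_pct_vv", "temperature_C", "time_s", "a340",
    "enzyme_conc_mg_ml", "path_length_cm",
]
PROFILE_COLUMNS = [
    "enzyme", "solvent", "conc_pct_vv", "temperature_C", "specific_activity", "sem", "n",
]


class SchemaError(ValueError):
    """The file does not conform to the documented long-format schema."""


def _read_csv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        values = np.empty(len(df), dtype=float)
        bad = []
        # float() round-trips exactly, unlike pandas' fast parser
        for i, cell in enumerate(df[col].to_numpy()):
            try:
                values[i] = float(cell)
            except (TypeError, ValueError):
                bad.append(i)
        if bad:
            # +2: header line plus 1-based numbering
            lines = [int(df.index[i]) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: non-numeric value(s) in column {col!r} at line(s) {lines}"
            )
        df[col] = values
    return df


def read_ramps(path, solvent: str | None = None, enzyme: str | None = None) -> list[ThermalRamp]:
    """Load thermal ramps from long-format CSV, optionally filtered."""
    df = _read_csv(path, RAMP_COLUMNS, ["conc_pct_vv", "temperature_C", "signal"])
    if solvent is not None:
        df = df[df["solvent"] == solvent]
    if enzyme is not None:
        df = df[df["enzyme"] == enzyme]
    ramps = []
    keys = ["enzyme", "solvent", "conc_pct_vv", "channel"]
    for (enz, solv, conc, channel), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("temperature_C")
        temps = grp["temperature_C"].to_numpy()
        if np.unique(temps).size != temps.size:
            raise SchemaError(
                f"{path}: duplicate temperature within condition "
                f"({enz}, {solv}, {conc}, {channel})"
            )
        ramps.append(
            ThermalRamp(
                enzyme=enz, solvent=solv, c_solv=float(conc), channel=channel,
                temperatures=temps, signal=grp["signal"].to_numpy(),
            )
        )
    return ramps


def write_ramps(path, ramps: Iterable[ThermalRamp]) -> None:
    rows = []
    for r in ramps:
        for t, s in zip(r.temperatures, r.signal):
            rows.append((r.enzyme, r.solvent, r.c_solv, r.channel, t, s))
    pd.DataFrame(rows, columns=RAMP_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_traces(path, solvent: str | None = None) -> list[KineticTrace]:
    """Load kinetic A340 traces from long-format CSV."""
    numeric = ["conc_pct_vv", "temperature_C", "time_s", "a340",
               "enzyme_conc_mg_ml", "path_length_cm", "extinction_coeff"]
    df = _read_csv(path, TRACE_COLUMNS, numeric)
    if solvent is not None:
        df = df[df["solvent"] == solvent]
    has_eps = "extinction_coeff" in df.columns
    traces = []
    keys = ["enzyme", "solvent", "conc_pct_vv", "temperature_C"]
    for (enz, solv, conc, temp), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy()
        if np.unique(times).size != times.size:
            raise SchemaError(
                f"{path}: duplicate time within condition ({enz}, {solv}, {conc}, {temp})"
            )
        eps = float(grp["extinction_coeff"].iloc[0]) if has_eps else DEFAULT_EXTINCTION_NADPH
        traces.append(
            KineticTrace(
                enzyme=enz, solvent=solv, c_solv=float(conc),
                temperature_c=float(temp),
                times=times, a340=grp["a340"].to_numpy(),
                enzyme_conc=float(grp["enzyme_conc_mg_ml"].iloc[0]),
                path_length=float(grp["path_length_cm"].iloc[0]),
                extinction_coeff=eps,
            )
        )
    return traces


def write_traces(path, traces: Iterable[KineticTrace]) -> None:
    rows = []
    for tr in traces:
        for t, a in zip(tr.times, tr.a340):
            rows.append(
                (tr.enzyme, tr.solvent, tr.c_solv, tr.temperature_c, t, a,
                 tr.enzyme_conc, tr.path_length, tr.extinction_coeff)
            )
    cols = TRACE_COLUMNS + ["extinction_coeff"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_profile(path, solvent: str | None = None) -> list[ActivityPoint]:
    df = _read_csv(
        path, PROFILE_COLUMNS,
        ["conc_pct_vv", "temperature_C", "specific_activity", "sem", "n"],
    )
    if solvent is not None:
        df = df[df["solvent"] == solvent]
    return [
        ActivityPoint(
            c_solv=float(r.conc_pct_vv),
            temperature_c=float(r.temperature_C),
            specific_activity=float(r.specific_activity),
            sem=float(r.sem),
            n_replicates=int(r.n),
        )
        for r in df.itertuples()
    ]


def write_profile(path, points: Iterable[ActivityPoint],
                  enzyme: str = "enzyme", solvent: str = "solvent") -> None:
    rows = [
        (enzyme, solvent, p.c_solv, p.temperature_c, p.specific_activity, p.sem,
         p.n_replicates)
        for p in points
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def _unfolding_fit_record(enzyme: str, solvent: str, fit: UnfoldingFit) -> dict:
    p = fit.params
    return {
        "enzyme": enzyme,
        "solvent": solvent,
        "temperature_C": p.temperature_c,
        "c_u50": p.c_u50,
        "m_folding": p.m_folding,
        "alpha_f": p.alpha_f,
        "beta_f": p.beta_f,
        "alpha_u": p.alpha_u,
        "beta_u": p.beta_u,
        "rss": fit.residual_sum_squares,
        "converged": fit.converged,
        "analyzable": fit.analyzable,
        "n_points": fit.n_points,
    }


def _activity_fit_record(enzyme: str, solvent: str, fit: ActivityFit) -> dict:
    p = fit.params
    return {
        "enzyme": enzyme,
        "solvent": solvent,
        "temperature_C": p.temperature_c,
        "xi": p.xi,
        "nu": p.nu,
        "sigma": p.sigma,
        "c_a_max": p.c_a_max,
        "c_a50": p.c_a50,
        "m_folding": p.m_folding,
        "cost": fit.cost,
        "converged": fit.converged,
        "n_points": fit.n_points,
    }


def write_fits(path, fits: Sequence[tuple[str, str, UnfoldingFit | ActivityFit]]) -> None:
    """Write fit records as a JSON array of {enzyme, solvent, ...} objects."""
    records = []
    for enzyme, solvent, fit in fits:
        if isinstance(fit, UnfoldingFit):
            records.append(_unfolding_fit_record(enzyme, solvent, fit))
        else:
            records.append(_activity_fit_record(enzyme, solvent, fit))
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")


def read_fits(path) -> list[dict]:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise SchemaError(f"{path}: expected a JSON array of fit records")
    return records


def write_table(path, table: StabilityTable) -> None:
    """StabilityTable as TSV, enzymes x measures, 'NA' for missing."""
    enzymes = table.enzymes
    data = {
        measure: [table.get(e, measure) for e in enzymes]
        for measure in table.measure_names
    }
    df = pd.DataFrame(data, index=pd.Index(enzymes, name="enzyme"))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_table(path) -> StabilityTable:
    df = pd.read_csv(path, sep="\t", index_col="enzyme")
    table = StabilityTable()
    for measure in df.columns:
        for enzyme, value in df[measure].items():
            if pd.notna(value):
                table.set(enzyme, measure, float(value))
    return table


def write_ranking(path, ranked: Sequence[RankedEnzyme], missing: Sequence[str] = ()) -> None:
    """Ranking as TSV with numeric ranks and the '+' symbol encoding."""
    lines = ["enzyme\tvalue\trank\tsymbols"]
    for r in ranked:
        lines.append(f"{r.enzyme}\t{r.value:g}\t{r.rank:g}\t{r.symbols}")
    for e in missing:
        lines.append(f"{e}\tNA\tNA\tunranked")
    Path(path).write_text("\n".join(lines) + "\n")
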