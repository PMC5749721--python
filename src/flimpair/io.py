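"""Readers, writers and packaged reference tables.

All tabular interchange is comma-separated UTF-8 text with a mandatory
header row; units are fixed by the schema (wavelengths nm, lifetimes ns,
bin widths ps, timepoints minutes) and never embedded in cells.  Readers
validate and reject malformed values rather than silently coercing them.

Three small reference tables ship with the package:

* ``fluorophores.csv`` — photophysical constants of the nine benchmark
  fluorescent proteins (four donors, five acceptors);
* ``pair_photophysics.csv`` — published quantum yields, overlap integrals
  and Förster radii of the ten benchmark donor-acceptor pairs;
* ``benchmark_evaluations.csv`` — published static and dynamic Z′ and
  FRET-efficiency summaries of those pairs on both FLIM platforms.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import CELL_COLUMNS, AssayEvaluation
from .spectra import FluorophoreRecord, Spectrum
from .timecourse import TimecourseSummary

__all__ = [
    "read_fluorophore_table",
    "load_reference_fluorophores",
    "load_pair_photophysics",
    "load_benchmark_evaluations",
    "read_spectrum",
    "read_cell_measurements",
    "write_cell_measurements",
    "read_decay_histogram",
    "write_report",
]

_FLUOROPHORE_COLUMNS = ("name", "ex_nm", "em_nm", "tau_ns", "qy", "eps_e3")


def _data_path(name: str):
    return resources.files("flimpair.data").joinpath(name)


def read_fluorophore_table(path) -> list[FluorophoreRecord]:
    """Read a fluorophore property table into validated records.

    Requires columns ``name, ex_nm, em_nm, tau_ns, qy, eps_e3`` (lifetime
    and quantum yield may be empty for acceptors, extinction for donors);
    extra columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty fluorophore table")
    missing = [c for c in _FLUOROPHORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in _FLUOROPHORE_COLUMNS + ("role",)]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=2)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                FluorophoreRecord(
                    name=str(row["name"]),
                    ex_peak=float(row["ex_nm"]),
                    em_peak=float(row["em_nm"]),
                    lifetime_tau=None if pd.isna(row["tau_ns"]) else float(row["tau_ns"]),
                    quantum_yield_phi=None if pd.isna(row["qy"]) else float(row["qy"]),
                    extinction_eps=None if pd.isna(row["eps_e3"]) else float(row["eps_e3"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def load_reference_fluorophores() -> list[FluorophoreRecord]:
    """The nine benchmark fluorescent proteins shipped with the package."""
    with resources.as_file(_data_path("fluorophores.csv")) as p:
        return read_fluorophore_table(p)


def load_pair_photophysics() -> pd.DataFrame:
    """Published (QY, J, r0) of the ten benchmark pairs, indexed by pair name."""
    with resources.as_file(_data_path("pair_photophysics.csv")) as p:
        return pd.read_csv(p, index_col="pair")


def load_benchmark_evaluations() -> pd.DataFrame:
    """Published static/dynamic Z′ and %E summaries for the benchmark pairs."""
    with resources.as_file(_data_path("benchmark_evaluations.csv")) as p:
        return pd.read_csv(p)


def read_spectrum(path, kind: str = "emission_normalized") -> Spectrum:
    """Read a two-column (wavelength_nm, value) spectrum file.

    The header row is optional; FPbase-style CSV exports are accepted.
    """
    try:
        df = pd.read_csv(path, comment="#")
        # no-header files parse with numeric-looking column names
        float(df.columns[0])
        df = pd.read_csv(path, comment="#", header=None)
    except (ValueError, TypeError):
        pass
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")
    sub = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce").dropna()
    order = np.argsort(sub.iloc[:, 0].to_numpy())
    return Spectrum(
        sub.iloc[order, 0].to_numpy(), sub.iloc[order, 1].to_numpy(), kind=kind
    )


def read_cell_measurements(path) -> pd.DataFrame:
    """Read a per-cell measurement table, validating types and uniqueness.

    Rows with non-positive lifetimes are rejected with a logged warning;
    duplicate (cell, timepoint) rows raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df[list(CELL_COLUMNS)].copy()
    for col in ("timepoint_min", "intensity", "lifetime_ns"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = df["lifetime_ns"] <= 0
    if bad.any():
        warnings.warn(
            f"{path}: rejected {int(bad.sum())} row(s) with non-positive lifetime",
            stacklevel=2,
        )
        df = df[~bad]
    dup = df.duplicated(subset=["cell_id", "timepoint_min"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (cell_id, timepoint) rows")
    return df.reset_index(drop=True)


def write_cell_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_decay_histogram(path, window_ns: float | None = None):
    """Read a (time_ps, counts) decay histogram file."""
    from .td import DecayHistogram

    df = pd.read_csv(path)
    if not {"time_ps", "counts"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_ps, counts")
    t = df["time_ps"].to_numpy(float)
    widths = np.diff(t)
    if t.size < 2 or not np.allclose(widths, widths[0]):
        raise ValueError(f"{path}: time axis must be uniform")
    bin_width = float(widths[0])
    return DecayHistogram(
        df["counts"].to_numpy(float),
        bin_width_ps=bin_width,
        window_ns=window_ns or (t[-1] + bin_width) * 1e-3,
    )


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(
    evaluations: list[AssayEvaluation],
    summaries: list[TimecourseSummary],
    path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write evaluations/summaries as a tidy CSV plus a provenance JSON.

    ``path`` is the CSV destination; a sibling ``<stem>.json`` carries the
    full-precision records together with the seed, a hash of the run
    configuration, and the package version, so any run is reproducible
    from its report alone.
    """
    path = Path(path)
    rows = [
        {
            "pair": ev.pair,
            "platform": ev.platform,
            "mode": ev.mode,
            "E_mean": ev.E_mean,
            "E_sd": ev.E_sd,
            "Zprime_mean": ev.Zprime_mean,
            "Zprime_sd": ev.Zprime_sd,
            "n_days": ev.n_days,
        }
        for ev in evaluations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pair", "platform", "mode", "E_mean", "E_sd",
            "Zprime_mean", "Zprime_sd", "n_days",
        ],
    ).to_csv(path, index=False)
    payload = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "config": config or {},
        "evaluations": rows,
        "timecourse_summaries": [
            {
                "construct": s.construct,
                "platform": s.platform,
                "quantity": s.quantity,
                "n_cells": s.n_cells,
                "endpoint_mean": s.endpoint_mean,
                "endpoint_median": s.endpoint_median,
                "endpoint_percentiles": {str(k): v for k, v in s.endpoint_percentiles.items()},
                "total_sd": s.total_sd,
            }
            for s in summaries
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2, sort_keys=True))
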