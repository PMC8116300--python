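"""Configuration, readout/calibration CSV I/O and report writing.

File formats
------------
Readout CSV (one row per pellet, header required)::

    pellet_id,position,counts,background

``background`` may be omitted (defaults to 0: validation counts are already
background-reduced; raw-mode subtraction is opt-in per file).

Calibration CSV::

    source,component,position,k_hat,sd_k

with k in mSv per count.  Because the factor applied to a component's dose is
not deducible from the table layout alone, the run configuration carries an
explicit component -> factor selection (``factors:`` block).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .bayes import PosteriorGrid
from .core import CalibrationFactor, Component, DoseEstimate, PelletReadout, Position, SourceSpec
from .errors import ConfigError, DataError
from .mc import McConfig

__all__ = [
    "RunConfig",
    "load_config",
    "read_readouts",
    "read_calibration",
    "write_calibration",
    "select_factor",
    "write_report",
]

_TOP_KEYS = {
    "method",
    "option",
    "readouts",
    "calibration",
    "source",
    "theta",
    "sigma_theta",
    "sigma_n_fraction",
    "factors",
    "mc",
    "output",
    "log_level",
}
_SOURCE_KEYS = {"name", "beta_transmission"}
_MC_KEYS = {"n_iter", "seed", "sigma_n_mode"}
_FACTOR_KEYS = {"source", "position"}


@dataclass(frozen=True)
class RunConfig:
    """A validated assessment run configuration."""

    method: str
    option: "int | None"
    readouts: "str | None"
    calibration: "str | None"
    source: SourceSpec
    theta: "float | None"
    sigma_theta: "float | None"
    sigma_n_fraction: float
    factors: dict
    mc: McConfig
    output: "str | None"
    log_level: str = "INFO"


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key {where}{key!r}")


def load_config(path: "str | Path") -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with the offending key named; the
    method/option combination must be coherent (classical runs take no
    option; option 1 needs ``theta`` and ``sigma_theta``; option 2 needs a
    fixed ``theta``; option 3 needs ``theta`` and ``sigma_theta``).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _reject_unknown(raw, _TOP_KEYS, "")

    method = raw.get("method", "classical")
    if method not in ("classical", "bayes", "mc"):
        raise ConfigError(f"method must be classical, bayes or mc, got {method!r}")

    option = raw.get("option")
    if method == "classical":
        if option is not None:
            raise ConfigError("the classical method takes no option")
    else:
        if option not in (1, 2, 3):
            raise ConfigError(f"method {method!r} requires option 1, 2 or 3")

    source_raw = raw.get("source") or {}
    _reject_unknown(source_raw, _SOURCE_KEYS, "source.")
    source = SourceSpec(
        name=source_raw.get("name", "Sr-90/Y-90"),
        beta_transmission=float(source_raw.get("beta_transmission", 0.25)),
    )

    mc_raw = raw.get("mc") or {}
    _reject_unknown(mc_raw, _MC_KEYS, "mc.")
    mc = McConfig(
        option=option if (method == "mc" and option) else 1,
        n_iter=int(mc_raw.get("n_iter", 100_000)),
        seed=int(mc_raw.get("seed", 0)),
        sigma_n_mode=mc_raw.get("sigma_n_mode", "fixed-counts"),
    )

    factors = raw.get("factors") or {}
    for comp, sel in factors.items():
        if comp not in ("beta", "gamma"):
            raise ConfigError(f"factors key must be beta or gamma, got {comp!r}")
        _reject_unknown(sel or {}, _FACTOR_KEYS, f"factors.{comp}.")

    theta = raw.get("theta")
    sigma_theta = raw.get("sigma_theta")
    theta = None if theta is None else float(theta)
    sigma_theta = None if sigma_theta is None else float(sigma_theta)
    if option in (1, 3) and (theta is None or sigma_theta is None):
        raise ConfigError(f"option {option} requires theta and sigma_theta (a theta prior)")
    if option == 2 and theta is None:
        raise ConfigError("option 2 requires a fixed theta")
    if theta is not None and not 0.0 <= theta <= 1.0:
        raise ConfigError(f"theta must be in [0, 1], got {theta}")

    sigma_n_fraction = float(raw.get("sigma_n_fraction", 0.05))
    if not sigma_n_fraction > 0:
        raise ConfigError("sigma_n_fraction must be positive")

    return RunConfig(
        method=method,
        option=option,
        readouts=raw.get("readouts"),
        calibration=raw.get("calibration"),
        source=source,
        theta=theta,
        sigma_theta=sigma_theta,
        sigma_n_fraction=sigma_n_fraction,
        factors=factors,
        mc=mc,
        output=raw.get("output"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def read_readouts(path: "str | Path") -> list[PelletReadout]:
    """Read a pellet readout CSV (columns pellet_id, position, counts[, background])."""
    try:
        table = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise DataError(f"readout file not found: {path}") from exc
    required = {"pellet_id", "position", "counts"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"readout CSV missing columns: {sorted(missing)}")
    if "background" not in table.columns:
        table = table.assign(background=0.0)
    try:
        return [
            PelletReadout(
                counts=float(row.counts),
                position=Position(row.position),
                background=float(row.background),
            )
            for row in table.itertuples()
        ]
    except ValueError as exc:
        raise DataError(f"invalid readout row: {exc}") from exc


def read_calibration(path: "str | Path") -> pd.DataFrame:
    """Read a calibration CSV (columns source, component, position, k_hat, sd_k)."""
    try:
        table = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise DataError(f"calibration file not found: {path}") from exc
    required = {"source", "component", "position", "k_hat", "sd_k"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"calibration CSV missing columns: {sorted(missing)}")
    return table


def write_calibration(factors: Iterable[CalibrationFactor], path: "str | Path") -> None:
    """Write calibration factors in the standard CSV format."""
    rows = [
        {
            "source": f.source,
            "component": f.component.value,
            "position": f.position.value,
            "k_hat": f.k_hat,
            "sd_k": f.sd,
        }
        for f in factors
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def select_factor(
    calibration: pd.DataFrame,
    component: "Component | str",
    selection: "dict | None" = None,
) -> CalibrationFactor:
    """Select the calibration factor to apply to a component's dose.

    Rows are filtered by ``component`` plus any keys of ``selection``
    (``source``, ``position``); exactly one row must remain.
    """
    comp = Component(component)
    mask = calibration["component"] == comp.value
    for key, value in (selection or {}).items():
        mask &= calibration[key] == value
    hits = calibration[mask]
    if len(hits) != 1:
        raise DataError(
            f"calibration selection for {comp.value!r} matched {len(hits)} rows; "
            "narrow it with a factors: block (source/position)"
        )
    row = hits.iloc[0]
    return CalibrationFactor(
        k_hat=float(row.k_hat),
        sd=float(row.sd_k),
        source=str(row.source),
        position=Position(row.position),
        component=comp,
    )


def config_hash(path: "str | Path") -> str:
    """Short SHA-256 of a config file, for report provenance headers."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def write_report(
    estimates: Sequence[DoseEstimate],
    path: "str | Path",
    *,
    posteriors: "dict[str, PosteriorGrid] | None" = None,
    seed: "int | None" = None,
    config_digest: "str | None" = None,
    theta_mode: "str | None" = None,
) -> None:
    """Write a dose report CSV (3-decimal mSv, 2-sigma uncertainties).

    Run metadata is embedded as ``#`` header comments.  Posterior grids, if
    given, are written next to the report as two-column CSVs
    (``dose_mSv,density``), one per key.
    """
    if not estimates:
        raise DataError("no estimates to report")
    path = Path(path)
    lines = [f"# tldose {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_digest is not None:
        lines.append(f"# config_sha256={config_digest}")
    if theta_mode is not None:
        lines.append(f"# theta_mode={theta_mode}")
    lines.append("component,dose_mSv,u2sigma_mSv,method")
    for est in estimates:
        value, unc = est.rounded()
        lines.append(f"{est.component.value},{value:.3f},{unc:.3f},{est.method}")
    path.write_text("\n".join(lines) + "\n")
    for name, grid in (posteriors or {}).items():
        dump = path.with_name(f"{path.stem}_posterior_{name}.csv")
        pd.DataFrame({"dose_mSv": grid.dose_grid, "density": grid.density}).to_csv(
            dump, index=False
        )
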