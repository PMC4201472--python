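"""Config parsing, plate-reader CSV ingestion, and report/manifest writing.

The interchange format is plain headered CSV. A plate-reader export must
carry the columns ``well, condition, fluorescence, total_luminescence,
em485, em530``; wells whose ``condition`` equals ``donor_only`` define the
BRET baseline (mean em530/em485 over those wells), which is subtracted from
every other well's ratio. Simulator grid CSVs are adapted by mapping
acceptor count to a fluorescence proxy and donor count to a luminescence
proxy.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hexlattice import LatticeConfig
from .simulator import PRESETS, InteractionParams
from .analysis import bret_ratio, intensity_ratio

log = logging.getLogger("qbretsim")

REQUIRED_WELL_COLUMNS = (
    "well",
    "condition",
    "fluorescence",
    "total_luminescence",
    "em485",
    "em530",
)

DONOR_ONLY = "donor_only"

_CONFIG_KEYS = {
    "lattice",
    "n_donor",
    "n_acceptor",
    "params",
    "preset",
    "n_steps",
    "n_rep",
    "seed",
}
_PAIR_KEYS = {"dd", "da", "aa"}


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written alongside every CLI output."""

    subcommand: str
    config: dict
    master_seed: int
    package_version: str
    timestamp: str
    inputs: list
    outputs: list

    @classmethod
    def create(cls, subcommand, config, master_seed, inputs, outputs):
        from . import __version__

        return cls(
            subcommand=subcommand,
            config=config,
            master_seed=master_seed,
            package_version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _params_from_dict(d: dict) -> InteractionParams:
    unknown = set(d) - _PAIR_KEYS
    if unknown:
        raise ValueError(f"unknown params keys: {sorted(unknown)}")
    kwargs = {}
    for pair, sub in d.items():
        bad = set(sub) - {"p_assoc", "p_diss"}
        if bad:
            raise ValueError(f"unknown keys under params.{pair}: {sorted(bad)}")
        if "p_assoc" in sub:
            kwargs[f"p_assoc_{pair}"] = float(sub["p_assoc"])
        if "p_diss" in sub:
            kwargs[f"p_diss_{pair}"] = float(sub["p_diss"])
    return InteractionParams(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a simulation config from JSON/YAML plus overrides.

    Returns a dict with keys ``lattice`` (LatticeConfig), ``params``
    (InteractionParams), ``n_donor``, ``n_acceptor``, ``n_steps``, ``n_rep``,
    ``seed``; defaults are a 100x100 lattice, 1000 steps, 5 replicates.
    A ``preset`` key ("non_specific" or "specific") expands to the standard
    probability matrix. Unknown keys fail with the offending name.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}  # YAML is a JSON superset
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw)}")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    lat = raw.get("lattice", {})
    bad = set(lat) - {"width", "height"}
    if bad:
        raise ValueError(f"unknown keys under lattice: {sorted(bad)}")
    lattice = LatticeConfig(
        width=int(lat.get("width", 100)), height=int(lat.get("height", 100))
    )
    if "preset" in raw and "params" in raw:
        raise ValueError("give either 'preset' or 'params', not both")
    if "preset" in raw:
        name = raw["preset"]
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        params = PRESETS[name]
    elif "params" in raw:
        params = _params_from_dict(raw["params"])
    else:
        params = PRESETS["non_specific"]
    return {
        "lattice": lattice,
        "params": params,
        "n_donor": int(raw.get("n_donor", 500)),
        "n_acceptor": int(raw.get("n_acceptor", 500)),
        "n_steps": int(raw.get("n_steps", 1000)),
        "n_rep": int(raw.get("n_rep", 5)),
        "seed": int(raw.get("seed", 0)),
    }


def read_wells(path, baseline: bool = True) -> pd.DataFrame:
    """Read a plate-reader CSV into an analyzable well table.

    Derives ``bret_ratio`` (em530/em485 minus the donor-only baseline) and
    ``intensity_ratio`` (fluorescence/total_luminescence); drops donor-only
    and unreadable wells (NaN, nonpositive denominators) with a logged count.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing required column(s): {missing}")
    donor_only = df[df["condition"] == DONOR_ONLY]
    base = 0.0
    if baseline:
        if donor_only.empty:
            raise ValueError(
                "no donor-only wells (condition == 'donor_only') for baseline"
            )
        base = float((donor_only["em530"] / donor_only["em485"]).mean())
    wells = df[df["condition"] != DONOR_ONLY].copy()
    n_in = len(wells)
    numeric = ["fluorescence", "total_luminescence", "em485", "em530"]
    wells[numeric] = wells[numeric].apply(pd.to_numeric, errors="coerce")
    ok = (
        wells[numeric].notna().all(axis=1)
        & (wells["total_luminescence"] > 0)
        & (wells["em485"] > 0)
    )
    dropped = n_in - int(ok.sum())
    if dropped:
        log.info("dropped %d unanalyzable wells out of %d", dropped, n_in)
    wells = wells[ok].copy()
    wells["bret_ratio"] = bret_ratio(wells["em530"], wells["em485"], base)
    wells["intensity_ratio"] = intensity_ratio(
        wells["fluorescence"], wells["total_luminescence"]
    )
    wells.attrs["donor_only_baseline"] = base
    return wells.reset_index(drop=True)


def adapt_simulation_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Map a simulator grid table onto the well schema: acceptor count
    becomes the fluorescence proxy, donor count the luminescence proxy, and
    the simulated BRET the (already baseline-free) BRET ratio."""
    out = pd.DataFrame(
        {
            "fluorescence": df["n_acceptor"].astype(float),
            "total_luminescence": df["n_donor"].astype(float),
            "bret_ratio": df["bret"].astype(float),
        }
    )
    out["intensity_ratio"] = out["fluorescence"] / out["total_luminescence"]
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(report, path) -> None:
    """Serialize a fit/classification report (dataclasses allowed) as JSON;
    non-finite numbers become nulls."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))
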