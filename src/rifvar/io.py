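"""File formats: spectra, per-nucleus tables, config, reports, manifests.

* Single-track spectra: two-column TSV ``z_Gy``, ``probability`` with header.
* Per-nucleus tables: TSV or CSV, dialect auto-detected from the extension,
  UTF-8, mandatory header row; counts stay integers, energies are written
  with 6 significant digits.
* Config: YAML mapping; reports and manifests: JSON with sorted keys so a
  fixed seed yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .population import PopulationConfig
from .spectrum import SingleTrackSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_records",
    "write_records",
    "load_config",
    "population_config_from_mapping",
    "config_hash",
    "write_json",
    "build_manifest",
]


def read_spectrum(path) -> SingleTrackSpectrum:
    """Read a single-track spectrum from a two-column TSV (z_Gy, probability)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("z_Gy", "probability"):
        if col not in df.columns:
            raise ValueError(f"spectrum file {path} is missing column {col!r}")
    return SingleTrackSpectrum(df["z_Gy"].to_numpy(float), df["probability"].to_numpy(float))


def write_spectrum(spectrum: SingleTrackSpectrum, path) -> None:
    df = pd.DataFrame({"z_Gy": spectrum.z_grid, "probability": spectrum.pmf})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sep_for(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab", ".txt"):
        return "\t"
    raise ValueError(f"cannot infer table dialect from extension {suffix!r}; use .csv or .tsv")


def read_records(path) -> pd.DataFrame:
    """Read a per-nucleus table (TSV/CSV by extension, header mandatory)."""
    return pd.read_csv(path, sep=_sep_for(path))


def write_records(df: pd.DataFrame, path) -> None:
    """Write a per-nucleus table; floats carry 6 significant digits."""
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6g")


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def population_config_from_mapping(mapping: dict, **overrides) -> PopulationConfig:
    """Build a PopulationConfig from a config mapping plus keyword overrides.

    Unknown keys raise a schema error naming the offending field.
    """
    merged = {**mapping, **overrides}
    valid = set(PopulationConfig.__dataclass_fields__)
    unknown = set(merged) - valid
    if unknown:
        raise ValueError(f"unknown population config field(s): {sorted(unknown)}")
    return PopulationConfig(**merged)


def config_hash(obj) -> str:
    """Stable SHA-256 of a JSON-serializable config, key order independent."""
    canonical = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def build_manifest(config: dict, seeds: dict, outputs: list[str]) -> dict:
    """Run manifest: tool version, config hash, seeds, outputs, timestamp."""
    return {
        "tool": "rifvar",
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        "seeds": seeds,
        "outputs": list(outputs),
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
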