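"""Structured-text configuration and tabular output.

Parameter sets round-trip through YAML; tables are written as TSV/CSV with
a comment header naming units and the package version, so any run is fully
reproducible from its config, seed and outputs.
"""

from __future__ import annotations

import hashlib
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .core import GKKinetics, ReducedModelParams, TransporterKinetics

__all__ = [
    "ConfigError",
    "load_reduced_params",
    "dump_reduced_params",
    "reduced_params_to_dict",
    "write_table",
    "config_hash",
]

try:
    _VERSION = version("betaglut")
except PackageNotFoundError:  # pragma: no cover - only outside an install
    _VERSION = "unknown"

REQUIRED_KEYS = (
    "km_glut1_mM",
    "km_glut2_mM",
    "vmax_normal_glut1",
    "vmax_normal_glut2",
    "epsilon1",
    "epsilon2",
    "gk_s_half_mM",
    "gk_hill_exponent",
    "vmax_gk",
    "volume_per_1e5_cells_L",
)


class ConfigError(ValueError):
    """Malformed or incomplete configuration file."""


def reduced_params_to_dict(params: ReducedModelParams) -> dict:
    return {
        "km_glut1_mM": params.glut1.km,
        "km_glut2_mM": params.glut2.km,
        "vmax_normal_glut1": params.glut1.vmax_normal,
        "vmax_normal_glut2": params.glut2.vmax_normal,
        "epsilon1": params.glut1.epsilon,
        "epsilon2": params.glut2.epsilon,
        "gk_s_half_mM": params.gk.s_half,
        "gk_hill_exponent": params.gk.hill_exponent,
        "vmax_gk": params.gk.vmax_gk,
        "volume_per_1e5_cells_L": params.volume_per_1e5_cells,
    }


def load_reduced_params(path: str | Path) -> ReducedModelParams:
    """Read a reduced-model parameter file, validating every required key."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # yaml errors carry line/column marks
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    data = raw.get("reduced", raw)
    missing = [k for k in REQUIRED_KEYS if k not in data]
    if missing:
        raise ConfigError(
            f"{path}: missing required kinetic constant(s): {', '.join(missing)}"
        )
    return ReducedModelParams(
        glut1=TransporterKinetics(
            "GLUT1", float(data["km_glut1_mM"]),
            float(data["vmax_normal_glut1"]), float(data["epsilon1"]),
        ),
        glut2=TransporterKinetics(
            "GLUT2", float(data["km_glut2_mM"]),
            float(data["vmax_normal_glut2"]), float(data["epsilon2"]),
        ),
        gk=GKKinetics(
            float(data["gk_s_half_mM"]), float(data["gk_hill_exponent"]),
            float(data["vmax_gk"]),
        ),
        volume_per_1e5_cells=float(data["volume_per_1e5_cells_L"]),
    )


def dump_reduced_params(
    params: ReducedModelParams, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a parameter file with unit comments and optional provenance."""
    path = Path(path)
    lines = [
        f"# betaglut v{_VERSION} reduced-model parameters",
        "# units: concentrations mM, fluxes nmol/min/1e5 cells, volume litres",
    ]
    if provenance:
        lines.append("# calibration anchor residuals (relative):")
        for key, res in provenance.items():
            lines.append(f"#   {key}: {res:+.3e}")
    body = yaml.safe_dump(
        {"reduced": reduced_params_to_dict(params)}, sort_keys=False
    )
    path.write_text("\n".join(lines) + "\n" + body)


def config_hash(path: str | Path) -> str:
    """Short content hash of a config file, for run logs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    units: str = "",
    fmt: str = "tsv",
    seed: int | None = None,
) -> None:
    """Write a table with a provenance comment header."""
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r} (use 'tsv' or 'csv')")
    header = [f"# betaglut v{_VERSION}"]
    if units:
        header.append(f"# units: {units}")
    if seed is not None:
        header.append(f"# seed: {seed}")
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    sep = {"tsv": "\t", "csv": ","}[fmt]
    return pd.read_csv(path, sep=sep, comment="#")
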