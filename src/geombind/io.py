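"""File formats, result serialization and run manifests.

PMF profiles travel as two-column whitespace text with ``#`` header lines
carrying ``key=value`` metadata (the Colvars-style ``.pmf`` dialect — a
bare ``#`` header above two numeric columns — also parses).  Dihedral
series are two-column (ϕ1, ϕ2) text in degrees.  Cycle results serialize
to a schema-versioned JSON document.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .conformer_analysis import DihedralSeries
from .cycle_composer import CONTRIBUTION_NAMES, CycleContribution, CycleResult
from .eabf_sampler import PMFProfile
from .errors import ConfigurationError, ContractError
from .toy_systems import TrajectoryRecord

SCHEMA_VERSION = 1

#: JSON schema (minimal, versioned in-repo) for serialized cycle results
CYCLE_RESULT_SCHEMA = {
    "schema_version": int,
    "dg_bind_kcal_mol": float,
    "error_kcal_mol": float,
    "keq_A3": float,
    "v_standard_A3": float,
    "temperature_K": float,
    "contributions": list,
}


# ----------------------------------------------------------------------
# PMF files
# ----------------------------------------------------------------------
_KNOWN_META = ("cv", "units", "bin_width", "temperature", "estimator", "window_id")


def write_pmf(path, profile: PMFProfile) -> None:
    """Write a profile as two-column text with key=value header lines.

    Counts and gradients ride along as extra columns declared in the
    header, so a write→read round trip is lossless to 1e-12.
    """
    path = Path(path)
    cols = ["center", "free_energy"]
    arrays = [profile.centers, profile.values]
    if profile.counts is not None:
        cols.append("count")
        arrays.append(profile.counts)
    if profile.gradient is not None:
        cols.append("gradient")
        arrays.append(profile.gradient)
    lines = ["# geombind pmf"]
    for key, val in profile.metadata.items():
        lines.append(f"# {key}={val}")
    lines.append("# columns=" + ",".join(cols))
    body = np.column_stack(arrays)
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in body:
            fh.write(" ".join(f"{x:.12g}" for x in row) + "\n")


def read_pmf(path, temperature: Optional[float] = None) -> PMFProfile:
    """Read a PMF text file (native or Colvars-style dialect).

    A temperature must be available — from the header or the
    ``temperature`` argument — because downstream composition needs β.
    Unknown header metadata is preserved.  Non-monotone centers (e.g.
    shuffled rows) are an error.
    """
    path = Path(path)
    meta = {}
    cols = None
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if "=" in text:
                    key, _, val = text.partition("=")
                    key = key.strip()
                    val = val.strip()
                    if key == "columns":
                        cols = val.split(",")
                    else:
                        meta[key] = _coerce(val)
                continue
            rows.append([float(x) for x in line.split()])
    if not rows:
        raise ContractError(f"{path}: no data rows")
    data = np.asarray(rows)
    if data.shape[1] < 2:
        raise ContractError(f"{path}: need at least two columns")
    if cols is None:
        cols = ["center", "free_energy"] + [f"col{i}" for i in range(2, data.shape[1])]
    centers = data[:, cols.index("center")]
    values = data[:, cols.index("free_energy")]
    if np.any(np.diff(centers) <= 0):
        raise ContractError(f"{path}: bin centers must increase strictly")
    if temperature is not None:
        meta.setdefault("temperature", float(temperature))
    if "temperature" not in meta:
        raise ContractError(
            f"{path}: no temperature in the header; pass temperature= "
            "(composition needs β)"
        )
    counts = data[:, cols.index("count")] if "count" in cols else None
    grad = data[:, cols.index("gradient")] if "gradient" in cols else None
    return PMFProfile(
        centers=centers,
        values=values,
        counts=counts if counts is not None else np.ones_like(values),
        metadata=meta,
        gradient=grad,
    )


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val in ("True", "False"):
        return val == "True"
    return val


# ----------------------------------------------------------------------
# dihedral series
# ----------------------------------------------------------------------
def write_dihedral_series(path, series: DihedralSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# geombind dihedral series\n# columns=phi1,phi2\n")
        if series.time_stride_ps is not None:
            fh.write(f"# time_stride_ps={series.time_stride_ps}\n")
        for p1, p2 in series.frames:
            fh.write(f"{p1:.6f} {p2:.6f}\n")


def read_dihedral_series(path) -> DihedralSeries:
    path = Path(path)
    stride = None
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "time_stride_ps=" in line:
                    stride = float(line.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ContractError(f"{path}: need two columns of angles")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ContractError(f"{path}: empty series")
    return DihedralSeries(frames=np.asarray(rows), time_stride_ps=stride)


# ----------------------------------------------------------------------
# trajectory records
# ----------------------------------------------------------------------
def write_trajectory(path, record: TrajectoryRecord) -> None:
    """Whitespace-delimited CV record with a ``#`` metadata header."""
    path = Path(path)
    cols = ["step", "time_ps", *record.cv_names, "potential", "kinetic"]
    with path.open("w") as fh:
        fh.write("# geombind trajectory\n")
        fh.write(f"# seed={record.seed}\n")
        fh.write("# columns=" + ",".join(cols) + "\n")
        for i in range(len(record.steps)):
            vals = [record.steps[i], record.time_ps[i]]
            vals.extend(record.cv_values[i])
            vals.extend([record.potential[i], record.kinetic[i]])
            fh.write(" ".join(f"{v:.10g}" for v in vals) + "\n")


# ----------------------------------------------------------------------
# contributions tables and cycle results
# ----------------------------------------------------------------------
def read_contributions(path) -> list:
    """CSV with columns (name, dg_kcal_mol, error_kcal_mol, time_ns)."""
    df = pd.read_csv(path)
    required = {"name", "dg_kcal_mol"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: contributions file needs columns {sorted(required)}"
        )
    out = []
    for _, row in df.iterrows():
        err = row.get("error_kcal_mol")
        t = row.get("time_ns")
        out.append(
            CycleContribution(
                name=str(row["name"]),
                dg=float(row["dg_kcal_mol"]),
                error=None if pd.isna(err) else float(err),
                time_ns=None if pd.isna(t) else float(t),
            )
        )
    return out


def write_contributions(path, contributions) -> None:
    df = pd.DataFrame(
        [
            {
                "name": c.name,
                "dg_kcal_mol": c.dg,
                "error_kcal_mol": c.error,
                "time_ns": c.time_ns,
            }
            for c in contributions
        ]
    )
    df.to_csv(path, index=False)


def cycle_result_to_dict(result: CycleResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "dg_bind_kcal_mol": result.dg_bind,
        "error_kcal_mol": result.error,
        "keq_A3": result.keq,
        "v_standard_A3": result.v_standard,
        "temperature_K": result.temperature,
        "contributions": [
            {
                "name": c.name,
                "dg_kcal_mol": c.dg,
                "error_kcal_mol": c.error,
                "time_ns": c.time_ns,
            }
            for c in result.contributions
        ],
    }


def validate_result_dict(doc: dict) -> None:
    """Schema-validate a serialized cycle result."""
    for key, typ in CYCLE_RESULT_SCHEMA.items():
        if key not in doc:
            raise ContractError(f"result document missing {key!r}")
        if typ is float and not isinstance(doc[key], (int, float)):
            raise ContractError(f"result field {key!r} must be numeric")
        if typ in (int, list) and not isinstance(doc[key], typ):
            raise ContractError(f"result field {key!r} must be {typ.__name__}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ContractError(
            f"unsupported schema version {doc['schema_version']}"
        )
    names = [c["name"] for c in doc["contributions"]]
    if sorted(names) != sorted(CONTRIBUTION_NAMES):
        raise ContractError("contributions do not cover the nine cycle terms")


def format_cycle_table(result: CycleResult) -> str:
    """Human-readable composition table (contribution, ΔG, time)."""
    label = {
        "c_site": "dG_c(site)",
        "Theta_site": "dG_Theta(site)",
        "Phi_site": "dG_Phi(site)",
        "Psi_site": "dG_Psi(site)",
        "theta_site": "dG_theta(site)",
        "phi_site": "dG_phi(site)",
        "separation_term": "-kT ln(S*I*C)",
        "c_bulk": "dG_c(bulk)",
        "o_bulk": "dG_o(bulk)",
    }
    lines = [
        f"{'contribution':<18s} {'PMF (kcal/mol)':>16s} {'time (ns)':>10s}",
        "-" * 46,
    ]
    for c in result.contributions:
        err = f" ± {c.error:.1f}" if c.error is not None else ""
        t = f"{c.time_ns:.0f}" if c.time_ns is not None else "-"
        lines.append(f"{label[c.name]:<18s} {c.dg:>10.1f}{err:<6s} {t:>10s}")
    lines.append("-" * 46)
    tot = result.total_time_ns
    lines.append(
        f"{'dG_bind':<18s} {result.dg_bind:>10.1f} ± {result.error:.1f}"
        f" {tot if tot is not None else '-':>8}"
    )
    return "\n".join(lines)


# ----------------------------------------------------------------------
# run manifest
# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Everything needed to recreate a run: config snapshot, seeds,
    package version and per-stage notes."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()
        if not self.version:
            from . import __version__

            self.version = __version__

    def note_stage(self, name: str, **info) -> None:
        self.stages.append({"name": name, **info})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
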