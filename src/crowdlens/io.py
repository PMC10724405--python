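"""Readers/writers shared by all modules: delimited tables, extended-XYZ
trajectories, species tables, and run manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .composition import SpeciesSpec
from .engine.core import Frames

__all__ = [
    "TableSchema",
    "SchemaError",
    "read_table",
    "write_table",
    "read_species_table",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Required column names mapped to dtypes ('float', 'int', 'str')."""

    name: str
    columns: dict

TURBIDITY_SCHEMA = TableSchema("turbidity", {"condition": "str", "peg_percent": "float", "od": "float"})
KINETICS_SCHEMA = TableSchema("kinetics", {"time_min": "float", "od": "float"})
TENSION_SCHEMA = TableSchema(
    "tension",
    {"condition": "str", "drop_id": "str", "time_s": "float", "gamma_mN_per_m": "float"},
)
SPECIES_SCHEMA = TableSchema(
    "species",
    {"name": "str", "diameter_nm": "float", "mass_g": "float"},
)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a comma- or tab-delimited table and validate it against a schema.

    Missing columns and unparsable numeric cells raise :class:`SchemaError`
    naming the offending column (and row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name} table {path} is missing required column(s): {', '.join(missing)}"
        )
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.columns.items():
        if kind == "str":
            out[col] = df[col].astype(str)
        else:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, plus header
                raise SchemaError(
                    f"{schema.name} table {path}: unparsable numeric value "
                    f"{df[col][bad.idxmax()]!r} in column {col!r} (line {row})"
                )
            out[col] = vals.astype(float if kind == "float" else int)
    # keep any extra columns verbatim
    for col in df.columns:
        if col not in out.columns:
            out[col] = df[col]
    return out


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a delimited table at full float precision.

    Uses pandas' default shortest-round-trip float repr, so numeric values
    survive a write/read cycle bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_species_table(path) -> list[SpeciesSpec]:
    """Species table columns: name, diameter_nm, mass_g [, mass_ratio, mw_kda]."""
    df = read_table(path, SPECIES_SCHEMA)
    specs = []
    for _, row in df.iterrows():
        ratio = float(row["mass_ratio"]) if "mass_ratio" in df.columns else None
        mw = float(row["mw_kda"]) if "mw_kda" in df.columns else None
        specs.append(
            SpeciesSpec(
                name=str(row["name"]),
                diameter_nm=float(row["diameter_nm"]),
                mass_g=float(row["mass_g"]),
                mass_ratio=ratio,
                molecular_weight_kda=mw,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# extended-XYZ trajectories
# ---------------------------------------------------------------------------

def write_trajectory(frames: Frames, path) -> None:
    """Extended-XYZ with per-frame metadata (time, box edge, packing fraction).

    Columns: species id, x, y, z, vx, vy, vz, diameter.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = frames.positions.shape[1] if frames.n_frames else 0
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            d = frames.diameters[f]
            phi = float((np.pi / 6.0 * d**3).sum() / frames.box_edge**3)
            fh.write(f"{n}\n")
            fh.write(
                f'Lattice="{frames.box_edge:.17g} 0 0 0 {frames.box_edge:.17g} 0 0 0 '
                f'{frames.box_edge:.17g}" Properties=species:I:1:pos:R:3:velo:R:3:diameter:R:1 '
                f"Time={frames.times[f]:.17g} phi={phi:.17g}\n"
            )
            for i in range(n):
                p = frames.positions[f, i]
                v = frames.velocities[f, i]
                fh.write(
                    f"{frames.species_id[i]} "
                    f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                    f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g} {d[i]:.17g}\n"
                )


def read_trajectory(path) -> Frames:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    times, poss, vels, diams = [], [], [], []
    species = None
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise ValueError(f"malformed frame header at line {k + 1} of {path}") from exc
        header = lines[k + 1]
        fields = dict(
            part.split("=", 1) for part in _split_header(header) if "=" in part
        )
        lat = fields.get("Lattice", "").strip('"').split()
        if len(lat) == 9:
            box = float(lat[0])
        times.append(float(fields.get("Time", len(times))))
        sp = np.empty(n, dtype=np.int64)
        p = np.empty((n, 3))
        v = np.zeros((n, 3))
        d = np.zeros(n)
        for i in range(n):
            parts = lines[k + 2 + i].split()
            sp[i] = int(parts[0])
            p[i] = [float(x) for x in parts[1:4]]
            if len(parts) >= 7:
                v[i] = [float(x) for x in parts[4:7]]
            if len(parts) >= 8:
                d[i] = float(parts[7])
        species = sp
        poss.append(p)
        vels.append(v)
        diams.append(d)
        k += 2 + n
    if box is None:
        if not times:  # zero-frame file round-trips to an empty Frames
            return Frames(
                times=np.empty(0), positions=np.empty((0, 0, 3)),
                velocities=np.empty((0, 0, 3)), diameters=np.empty((0, 0)),
                species_id=np.empty(0, dtype=np.int64), box_edge=0.0,
            )
        raise ValueError(f"no Lattice metadata found in {path}")
    nf = len(times)
    n = len(species) if species is not None else 0
    return Frames(
        times=np.asarray(times, dtype=float),
        positions=np.asarray(poss).reshape(nf, n, 3),
        velocities=np.asarray(vels).reshape(nf, n, 3),
        diameters=np.asarray(diams).reshape(nf, n),
        species_id=species if species is not None else np.empty(0, dtype=np.int64),
        box_edge=box,
    )


def _split_header(header: str) -> list[str]:
    """Split an extended-XYZ comment line on spaces outside double quotes."""
    parts = []
    cur = []
    in_q = False
    for ch in header:
        if ch == '"':
            in_q = not in_q
            cur.append(ch)
        elif ch == " " and not in_q:
            if cur:
                parts.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        parts.append("".join(cur))
    return parts


def write_manifest(out_dir, command: str, seed: Optional[int], config: dict) -> Path:
    """Drop a manifest (config echo + package version + seed) beside run outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "crowdlens",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
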