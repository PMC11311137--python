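"""Readers and writers for the package's plain-text schemas.

Conventions: physical quantities carry their units in the column names or
header keys (``time_min``, ``window_area_mm2``, ``g_G_per_cm`` ...); readers
validate invariants and reject rather than coerce, reporting the offending
line number.  Count CSVs carry their metadata in ``# key = value`` header
lines; trajectories use an extended-XYZ comment line with the box lengths.
"""

from __future__ import annotations

import csv
import io as _io
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nucleation_kinetics import CountTimeSeries
from .polymer_mw import DilutionViscositySeries, PGSTEDecay
from .speciation import SolutionRecipe
from .trajectory import TrajectoryFrame


def _parse_float(token: str, path, line_no: int, column: str) -> float:
    token = token.strip()
    try:
        return float(token)
    except ValueError:
        hint = ""
        if "," in token:
            hint = " (decimal commas are not accepted; use '.' as the decimal separator)"
        raise ValidationError(
            f"{path}:{line_no}: cannot parse {column} value {token!r}{hint}"
        ) from None


# ---------------------------------------------------------------- counts ----

def read_counts_csv(path: str | Path) -> CountTimeSeries:
    """Read a crystal-count series.

    Format: ``# key = value`` header lines (window_area_mm2 required; sigma
    and label optional, or supplied via a ``<name>.toml`` sidecar), then a
    ``time_min,count`` table.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, int]] = []
    header_seen = False
    with path.open(newline="") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if "=" in stripped:
                    key, _, value = stripped.lstrip("# ").partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = next(csv.reader([stripped]))
            if not header_seen:
                if [f.strip() for f in fields] != ["time_min", "count"]:
                    raise ValidationError(
                        f"{path}:{line_no}: expected header 'time_min,count', "
                        f"got {stripped!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}:{line_no}: expected 2 columns, got {len(fields)} "
                    "(a decimal comma would split a value into extra columns)"
                )
            t = _parse_float(fields[0], path, line_no, "time_min")
            c = _parse_float(fields[1], path, line_no, "count")
            if c != int(c):
                raise ValidationError(
                    f"{path}:{line_no}: count must be an integer, got {fields[1]!r}"
                )
            if rows and t <= rows[-1][0]:
                raise ValidationError(
                    f"{path}:{line_no}: times must be strictly increasing "
                    f"({t} follows {rows[-1][0]})"
                )
            if rows and int(c) < rows[-1][1]:
                raise ValidationError(
                    f"{path}:{line_no}: cumulative counts must be non-decreasing "
                    f"({int(c)} follows {rows[-1][1]})"
                )
            rows.append((t, int(c)))
    sidecar = path.with_suffix(".toml")
    if sidecar.exists():
        with sidecar.open("rb") as fh:
            meta.update({k: str(v) for k, v in tomllib.load(fh).items()})
    if "window_area_mm2" not in meta:
        raise ValidationError(
            f"{path}: missing window_area_mm2 (header '# window_area_mm2 = ...' "
            "or sidecar TOML)"
        )
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return CountTimeSeries(
        times=tuple(t for t, _ in rows),
        counts=tuple(c for _, c in rows),
        window_area=float(meta["window_area_mm2"]),
        sigma=float(meta.get("sigma", "nan")),
        label=meta.get("label", path.stem),
    )


def write_counts_csv(series: CountTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# window_area_mm2 = {float(series.window_area)!r}\n")
        fh.write(f"# sigma = {float(series.sigma)!r}\n")
        if series.label:
            fh.write(f"# label = {series.label}\n")
        fh.write("time_min,count\n")
        for t, c in zip(series.times, series.counts):
            fh.write(f"{float(t)!r},{int(c)}\n")


# ----------------------------------------------------------------- rates ----

def read_rates_csv(path: str | Path) -> pd.DataFrame:
    """Read a ``sigma,j0,j0_se`` table of per-experiment rates."""
    df = pd.read_csv(path)
    required = {"sigma", "j0"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "j0_se" not in df.columns:
        df["j0_se"] = 0.0
    if (df["sigma"] <= 0).any():
        bad = int(df.index[df["sigma"] <= 0][0]) + 2
        raise ValidationError(f"{path}:{bad}: sigma must be > 0")
    if (df["j0"] <= 0).any():
        bad = int(df.index[df["j0"] <= 0][0]) + 2
        raise ValidationError(f"{path}:{bad}: j0 must be > 0 to take its logarithm")
    return df


# ---------------------------------------------------------------- recipe ----

def read_recipe(path: str | Path) -> SolutionRecipe:
    """Solution recipe from TOML (keys) or CSV (single data row)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with path.open("rb") as fh:
            data = tomllib.load(fh)
    else:
        df = pd.read_csv(path)
        if len(df) != 1:
            raise ValidationError(f"{path}: recipe CSV must have exactly one row")
        data = df.iloc[0].to_dict()
    background = []
    for key, charge in (("na_M", 1), ("cl_M", -1)):
        if key in data and float(data[key]) > 0:
            background.append((charge, float(data[key])))
    for entry in data.get("background_ions", []):
        background.append((int(entry[0]), float(entry[1])))
    return SolutionRecipe(
        total_calcium=float(data["ca_total_M"]),
        total_carbonate=float(data["co3_total_M"]),
        pH=float(data.get("pH", data.get("ph", 10.0))),
        temperature=float(data.get("temp_C", 22.0)),
        background_ions=tuple(background),
    )


# ------------------------------------------------- viscosity / diffusion ----

def read_dilution_csv(path: str | Path) -> DilutionViscositySeries:
    """``conc_g_per_mL,eta_sp`` dilution table."""
    df = pd.read_csv(path)
    for col in ("conc_g_per_mL", "eta_sp"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return DilutionViscositySeries(
        concentrations=tuple(df["conc_g_per_mL"].astype(float)),
        specific_viscosities=tuple(df["eta_sp"].astype(float)),
    )


def read_decay_csv(path: str | Path, params_path: str | Path) -> PGSTEDecay:
    """``g_G_per_cm,intensity`` table plus a TOML file of acquisition params
    (i0, delta_small_s, delta_big_s, optional gyromagnetic)."""
    df = pd.read_csv(path)
    for col in ("g_G_per_cm", "intensity"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    with Path(params_path).open("rb") as fh:
        params = tomllib.load(fh)
    kwargs = {}
    if "gyromagnetic" in params:
        kwargs["gyromagnetic"] = float(params["gyromagnetic"])
    if "noise_tolerance" in params:
        kwargs["noise_tolerance"] = float(params["noise_tolerance"])
    return PGSTEDecay(
        gradient_strengths=tuple(df["g_G_per_cm"].astype(float)),
        intensities=tuple(df["intensity"].astype(float)),
        i0=float(params["i0"]),
        delta_small=float(params["delta_small_s"]),
        delta_big=float(params["delta_big_s"]),
        **kwargs,
    )


# ------------------------------------------------------------------- NMR ----

def read_nmr_toml(path: str | Path) -> dict:
    """NMR integrals and/or elemental wt% from a TOML file.

    Returns the raw dict; sections ``[nmr]`` and ``[elemental]`` are both
    optional.
    """
    with Path(path).open("rb") as fh:
        return tomllib.load(fh)


# ------------------------------------------------------------------- XYZ ----

def write_xyz(frames, path: str | Path) -> None:
    """Extended-XYZ writer; the comment line carries box lengths and pbc."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            fh.write(f"{len(frame.labels)}\n")
            bx, by, bz = (float(b) for b in frame.box)
            pbc = "T" if frame.periodic else "F"
            fh.write(f'box="{bx!r} {by!r} {bz!r}" pbc={pbc}\n')
            for label, (x, y, z) in zip(frame.labels, frame.positions):
                fh.write(f"{label} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path: str | Path) -> list[TrajectoryFrame]:
    """Read the extended-XYZ convention written by :func:`write_xyz`."""
    path = Path(path)
    frames = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValidationError(f"{path}:{i + 1}: expected an atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box, periodic = _parse_xyz_comment(comment, path, i + 2)
        labels, positions = [], []
        for j in range(n):
            line_no = i + 2 + j
            if line_no >= len(lines):
                raise ValidationError(f"{path}: truncated frame at line {line_no + 1}")
            parts = lines[line_no].split()
            if len(parts) < 4:
                raise ValidationError(
                    f"{path}:{line_no + 1}: expected 'label x y z'"
                )
            labels.append(parts[0])
            positions.append([_parse_float(p, path, line_no + 1, "coordinate")
                              for p in parts[1:4]])
        frames.append(TrajectoryFrame(np.array(positions), tuple(labels),
                                      box, periodic))
        i += 2 + n
    if not frames:
        raise ValidationError(f"{path}: no frames")
    return frames


def _parse_xyz_comment(comment: str, path, line_no: int):
    import re

    m = re.search(r'box="([^"]+)"', comment)
    if not m:
        raise ValidationError(
            f'{path}:{line_no}: comment line must carry box="Lx Ly Lz"'
        )
    parts = m.group(1).split()
    if len(parts) != 3:
        raise ValidationError(f"{path}:{line_no}: box needs three lengths")
    box = tuple(float(p) for p in parts)
    periodic = "pbc=F" not in comment
    return box, periodic


def read_pdb_frames(path: str | Path) -> list[TrajectoryFrame]:
    """Minimal PDB reader: CRYST1 box, ATOM/HETATM coordinates, atom-name
    labels, MODEL/ENDMDL frame separation."""
    path = Path(path)
    box = None
    frames: list[TrajectoryFrame] = []
    labels: list[str] = []
    positions: list[list[float]] = []

    def flush():
        nonlocal labels, positions
        if positions:
            if box is None:
                raise ValidationError(f"{path}: missing CRYST1 record")
            frames.append(TrajectoryFrame(np.array(positions), tuple(labels),
                                          box, periodic=True))
        labels, positions = [], []

    with path.open() as fh:
        for line in fh:
            record = line[:6].strip()
            if record == "CRYST1":
                box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
            elif record in ("ATOM", "HETATM"):
                labels.append(line[12:16].strip())
                positions.append([float(line[30:38]), float(line[38:46]),
                                  float(line[46:54])])
            elif record == "ENDMDL":
                flush()
    flush()
    if not frames:
        raise ValidationError(f"{path}: no coordinates found")
    return frames
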