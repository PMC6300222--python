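"""Reading and writing centerline airway geometries.

Two equivalent on-disk dialects:

* CSV with header ``s_m,area_m2,perimeter_m,x_m,y_m,z_m,region`` (one row per
  station, SI units).  Airway name/variant travel in ``# key: value`` comment
  lines above the header.
* JSON with ``name``, ``variant``, ``meta`` and a ``stations`` list.

Floats are serialised with ``repr`` (shortest exact round-trip form), so a
write -> read -> write cycle is byte-identical.  Readers validate every
airway invariant and report the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CenterlineAirway, InvalidGeometryError

__all__ = ["write_csv", "read_csv", "write_json", "read_json", "read_airway", "write_airway"]

CSV_HEADER = "s_m,area_m2,perimeter_m,x_m,y_m,z_m,region"


def write_csv(airway: CenterlineAirway, path: str | Path) -> None:
    lines = [f"# name: {airway.name}", f"# variant: {airway.variant}"]
    for key in sorted(airway.meta):
        lines.append(f"# meta.{key}: {airway.meta[key]!r}")
    lines.append(CSV_HEADER)
    for i in range(len(airway)):
        x, y, z = airway.points[i]
        lines.append(
            f"{float(airway.s[i])!r},{float(airway.area[i])!r},"
            f"{float(airway.perimeter[i])!r},{float(x)!r},{float(y)!r},"
            f"{float(z)!r},{airway.region[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_csv(path: str | Path) -> CenterlineAirway:
    path = Path(path)
    name, variant, meta = path.stem, "custom", {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            key, _, value = line[1:].partition(":")
            key, value = key.strip(), value.strip()
            if key == "name":
                name = value
            elif key == "variant":
                variant = value
            elif key.startswith("meta."):
                try:
                    meta[key[5:]] = eval(value, {"__builtins__": {}})  # repr'ed scalars
                except Exception:
                    meta[key[5:]] = value
    df = pd.read_csv(path, skiprows=header_rows, float_precision="round_trip")
    expected = CSV_HEADER.split(",")
    if list(df.columns) != expected:
        raise InvalidGeometryError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    try:
        return CenterlineAirway(
            name=name,
            variant=variant,
            s=df["s_m"].to_numpy(),
            area=df["area_m2"].to_numpy(),
            perimeter=df["perimeter_m"].to_numpy(),
            points=df[["x_m", "y_m", "z_m"]].to_numpy(),
            region=df["region"].to_numpy(dtype=object),
            meta=meta,
        )
    except InvalidGeometryError as err:
        raise InvalidGeometryError(f"{path}: {err}") from err


def write_json(airway: CenterlineAirway, path: str | Path) -> None:
    payload = {
        "name": airway.name,
        "variant": airway.variant,
        "meta": airway.meta,
        "stations": [
            {
                "s": float(airway.s[i]),
                "area": float(airway.area[i]),
                "perimeter": float(airway.perimeter[i]),
                "point": [float(v) for v in airway.points[i]],
                "region": str(airway.region[i]),
            }
            for i in range(len(airway))
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_json(path: str | Path) -> CenterlineAirway:
    payload = json.loads(Path(path).read_text())
    try:
        st = payload["stations"]
        return CenterlineAirway(
            name=payload.get("name", Path(path).stem),
            variant=payload.get("variant", "custom"),
            s=np.array([row["s"] for row in st], dtype=float),
            area=np.array([row["area"] for row in st], dtype=float),
            perimeter=np.array([row["perimeter"] for row in st], dtype=float),
            points=np.array([row["point"] for row in st], dtype=float),
            region=np.array([row["region"] for row in st], dtype=object),
            meta=payload.get("meta", {}),
        )
    except (KeyError, TypeError) as err:
        raise InvalidGeometryError(f"{path}: malformed airway JSON ({err})") from err
    except InvalidGeometryError as err:
        raise InvalidGeometryError(f"{path}: {err}") from err


def read_airway(path: str | Path) -> CenterlineAirway:
    """Dispatch on file suffix (.csv or .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_json(path)
    return read_csv(path)


def write_airway(airway: CenterlineAirway, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        write_json(airway, path)
    else:
        write_csv(airway, path)
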