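"""File I/O: ENVI-style cubes, HDF5 single-file cubes, CSV tables.

Two cube containers are supported:

* An ENVI dialect — an ASCII ``.hdr`` next to a flat binary file.  The
  header carries ``samples``/``lines``/``bands``, the interleave
  (``bip``/``bil``/``bsq``), the wavelength list and its units, and a
  ``data kind`` field distinguishing raw-count cubes from calibrated
  reflectance.  Wavelengths in micrometres are converted to nm on read.
* A single HDF5 file (``.h5``/``.hdf5``) holding the array, the grid and
  the metadata — convenient for tests and pipelines.

Spectra matrices and colour tables travel as CSV (wavelengths as the
header row; ``sample_id,L,a,b,group`` for colour references).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cube import HypercubeRaw, ReferenceFrame, ReflectanceCube
from .grid import WavelengthGrid

__all__ = [
    "read_cube",
    "write_cube",
    "read_envi",
    "write_envi",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_colour_table",
    "write_colour_table",
]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v).name: k for k, v in _ENVI_DTYPES.items()}


def _header_path(path: Path) -> Path:
    return path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")


def _data_path(path: Path) -> Path:
    if path.suffix != ".hdr":
        return path
    stem = path.with_suffix("")
    if stem.exists():
        return stem
    raise FileNotFoundError(f"no binary file found for header {path}")


def parse_envi_header(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs; brace lists may span lines."""
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict = {}
    body = text.lstrip()[len("ENVI"):]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            depth, close = 0, -1
            for i, ch in enumerate(rest):
                if ch == "{":
                    depth += 1
                elif ch == "}":
                    depth -= 1
                    if depth == 0:
                        close = i
                        break
            if close < 0:
                raise ValueError(f"unterminated brace list for header field {key!r}")
            value = rest[1:close].strip()
            pos = offset + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl].strip()
            pos = offset + nl
        if key:
            fields[key] = value
    return fields


def read_envi(path) -> HypercubeRaw | ReflectanceCube:
    """Read an ENVI header + flat binary cube.

    ``path`` may point at either the header or the binary file.  The
    declared sizes are checked against the binary payload before any
    reshaping; a truncated or padded file raises with expected vs actual
    byte counts.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr}")
    fields = parse_envi_header(hdr.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field {exc}") from exc
    dtype_code = int(fields.get("data type", 5))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bip").lower()
    offset = int(fields.get("header offset", 0))

    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array(
            [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
        )
        units = fields.get("wavelength units", "nanometers").lower()
        if units.startswith("micro"):
            wavelengths = wavelengths * 1000.0
        elif not units.startswith("nano") and units != "unknown":
            raise ValueError(f"unsupported wavelength units {units!r}")
        if wavelengths.size != bands:
            raise ValueError(
                f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
            )
    if wavelengths is None:
        raise ValueError("ENVI header carries no wavelength list")

    data_file = _data_path(path)
    payload = data_file.read_bytes()[offset:]
    expected = lines * samples * bands * dtype.itemsize
    if len(payload) != expected:
        raise ValueError(
            f"binary payload of {data_file} has {len(payload)} bytes, "
            f"expected {expected} ({lines}x{samples}x{bands} {dtype.name})"
        )
    flat = np.frombuffer(payload, dtype=dtype)
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = np.ascontiguousarray(data, dtype=float)

    grid = WavelengthGrid(wavelengths)
    kind = fields.get("data kind", "raw").lower()
    meta = json.loads(fields["meta"]) if "meta" in fields else {}
    if kind == "reflectance":
        return ReflectanceCube(data=data, grid=grid, provenance=meta)
    return HypercubeRaw(data=data, grid=grid, meta=meta)


def write_envi(cube, path, interleave: str = "bip") -> Path:
    """Write a cube as ENVI header + flat float64 binary; returns the
    binary path.  Roundtrip through :func:`read_envi` is bit-exact."""
    path = Path(path)
    if path.suffix == ".hdr":
        raise ValueError("pass the binary path; the .hdr name is derived from it")
    data = np.asarray(cube.data, dtype=np.float64)
    lines, samples, bands = data.shape
    if interleave == "bip":
        ordered = data
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    elif interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    kind = "reflectance" if isinstance(cube, ReflectanceCube) else "raw"
    meta = cube.provenance if isinstance(cube, ReflectanceCube) else cube.meta
    wl = ", ".join(f"{v:g}" for v in cube.grid.values)
    header = (
        "ENVI\n"
        "description = {hsicolor cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES['float64']}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data kind = {kind}\n"
        "wavelength units = Nanometers\n"
        f"meta = {{{json.dumps(_jsonable(meta))}}}\n"
        f"wavelength = {{{wl}}}\n"
    )
    _header_path(path).write_text(header)
    path.write_bytes(np.ascontiguousarray(ordered).tobytes())
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_hdf5(cube, path: Path) -> Path:
    kind = "reflectance" if isinstance(cube, ReflectanceCube) else "raw"
    meta = cube.provenance if isinstance(cube, ReflectanceCube) else cube.meta
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(cube.data, dtype=np.float64))
        f.create_dataset("wavelength_nm", data=cube.grid.values)
        f.attrs["kind"] = kind
        f.attrs["meta"] = json.dumps(_jsonable(meta))
    return path


def _read_hdf5(path: Path):
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        grid = WavelengthGrid(f["wavelength_nm"][()])
        kind = f.attrs.get("kind", "raw")
        meta = json.loads(f.attrs.get("meta", "{}"))
    if kind == "reflectance":
        return ReflectanceCube(data=data, grid=grid, provenance=meta)
    return HypercubeRaw(data=data, grid=grid, meta=meta)


def write_cube(cube, path) -> Path:
    """Write a cube; container chosen by extension (.h5/.hdf5 → HDF5,
    anything else → ENVI pair)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _write_hdf5(cube, path)
    return write_envi(cube, path)


def read_cube(path) -> HypercubeRaw | ReflectanceCube:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path)
    return read_envi(path)


def read_reference(path, kind: str) -> ReferenceFrame:
    """Read a reference frame stored as a cube file."""
    cube = read_cube(path)
    return ReferenceFrame(data=cube.data, kind=kind)


def write_spectra_csv(X: np.ndarray, grid: WavelengthGrid, path, sample_ids=None) -> Path:
    df = pd.DataFrame(np.asarray(X, dtype=float),
                      columns=[f"{v:g}" for v in grid.values])
    if sample_ids is not None:
        df.insert(0, "sample_id", list(sample_ids))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_spectra_csv(path) -> tuple[np.ndarray, WavelengthGrid, list]:
    """Read a spectra CSV; returns (X, grid, sample_ids)."""
    df = pd.read_csv(path)
    ids = list(df.pop("sample_id")) if "sample_id" in df.columns else list(range(len(df)))
    grid = WavelengthGrid(np.array([float(c) for c in df.columns]))
    return df.to_numpy(dtype=float), grid, ids


def write_colour_table(colours: np.ndarray, groups, path, sample_ids=None) -> Path:
    colours = np.asarray(colours, dtype=float)
    n = len(colours)
    df = pd.DataFrame({
        "sample_id": list(sample_ids) if sample_ids is not None else list(range(n)),
        "L": colours[:, 0], "a": colours[:, 1], "b": colours[:, 2],
        "group": list(groups),
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_colour_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"L", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"colour table missing columns {sorted(missing)}")
    return df
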