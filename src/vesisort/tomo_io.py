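"""Image-stack and table I/O for the vesicle classification pipeline.

Stacks are held as ``TomogramStack`` objects: a 3D numpy array in (z, y, x)
axis order plus the physical voxel spacing in nm, given as (x, y, z).
Multi-page TIFF goes through :mod:`tifffile`; MRC (MRC2014 dialect) is read
and written directly at the struct level.  Feature tables are plain pandas
DataFrames with the four feature columns ``r, gv, GVSD, distAZ`` and a
``label`` column restricted to the codes C (clear core), D (dense core),
N (non-determinable) and E (error / non-assignable).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TomogramStack",
    "VALID_LABEL_CODES",
    "DEFAULT_FEATURE_COLUMNS",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_feature_csv",
    "write_feature_csv",
    "write_color_label_stack",
    "write_result_log",
    "read_result_log",
]

#: allowed label codes in feature CSV files
VALID_LABEL_CODES = frozenset({"C", "D", "N", "E"})

#: default CSV column schema when a file carries no header
DEFAULT_FEATURE_COLUMNS = ("r", "gv", "GVSD", "distAZ", "label")

#: colors used for the classified label stack (RGB, uint8)
CLASS_COLORS = {"CCV": (255, 0, 255), "DCV": (0, 255, 0)}  # magenta / green

#: numeric class codes used in the plain-text result log
LOG_CLASS_CODES = {"CCV": 1, "DCV": 0}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class TomogramStack:
    """A 3D gray-value volume with anisotropic voxel spacing.

    Parameters
    ----------
    voxels:
        3D array indexed (z, y, x).
    spacing:
        voxel size in nm as (x, y, z); all entries must be positive.
    id:
        tomogram identifier string.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim == 2:  # single image -> 1-slice stack
            vox = vox[np.newaxis, :, :]
        if vox.ndim != 3:
            raise FormatError(f"expected 2D or 3D image data, got {vox.ndim}D")
        if vox.shape[0] < 1:
            raise FormatError("stack must contain at least one slice")
        if not np.all(np.isfinite(np.asarray(vox, dtype=float))):
            raise FormatError("stack contains non-finite gray values")
        self.voxels = vox
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise FormatError(f"spacing must be 3 positive numbers, got {self.spacing}")
        self.spacing = sp

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


# ---------------------------------------------------------------------------
# MRC2014 (minimal dialect: modes 0/1/2/6, no extended header on write)
# ---------------------------------------------------------------------------

_MRC_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_DTYPE_MODES = {np.dtype(v): k for k, v in _MRC_MODE_DTYPES.items()}


def _read_mrc(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: not an MRC file (header truncated)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MRC_MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    if min(nx, ny, nz) < 1:
        raise FormatError(f"{path}: invalid MRC dimensions {(nx, ny, nz)}")
    dtype = np.dtype(_MRC_MODE_DTYPES[mode]).newbyteorder("<")
    offset = 1024 + max(nsymbt, 0)
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    voxels = data.reshape(nz, ny, nx).astype(_MRC_MODE_DTYPES[mode])
    spacing = None
    if all(c > 0 for c in cella) and min(mx, my, mz) > 0:
        # cell dimensions interpreted in nm (tomography convention used here)
        spacing = (cella[0] / mx, cella[1] / my, cella[2] / mz)
    return voxels, spacing


def _write_mrc(path: Path, stack: TomogramStack) -> None:
    vox = np.ascontiguousarray(stack.voxels)
    dtype = np.dtype(vox.dtype)
    if dtype not in _MRC_DTYPE_MODES:
        vox = vox.astype(np.float32)
        dtype = np.dtype(np.float32)
    mode = _MRC_DTYPE_MODES[dtype]
    nz, ny, nx = vox.shape
    sx, sy, sz = stack.spacing
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * sx, ny * sy, nz * sz)  # cella (nm)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    stats = vox.astype(np.float64)
    struct.pack_into("<3f", header, 76, float(stats.min()), float(stats.max()),
                     float(stats.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(stats.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(vox.astype(dtype.newbyteorder("<"), copy=False).tobytes())


# ---------------------------------------------------------------------------
# stack read / write
# ---------------------------------------------------------------------------

def _is_mrc(path: Path) -> bool:
    return path.suffix.lower() in {".mrc", ".rec", ".st", ".map"}


def read_stack(path, spacing: Sequence[float] | None = None,
               id: str | None = None) -> TomogramStack:
    """Read a multi-page TIFF or MRC file into a :class:`TomogramStack`.

    ``spacing`` (nm, as (x, y, z)) overrides any header information; for MRC
    files with a valid cell size the header spacing is used when no override
    is given.  2D images are promoted to one-slice stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    header_spacing = None
    if _is_mrc(path):
        voxels, header_spacing = _read_mrc(path)
    else:
        try:
            voxels = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"cannot read image file {path}: {exc}") from exc
    if voxels.ndim not in (2, 3):
        raise FormatError(f"{path}: expected 2D or 3D data, got {voxels.ndim}D")
    eff_spacing = tuple(spacing) if spacing is not None else (header_spacing or (1.0, 1.0, 1.0))
    return TomogramStack(voxels=voxels, spacing=eff_spacing, id=id or path.stem)


def write_stack(path, stack: TomogramStack) -> None:
    """Write a stack as multi-page TIFF or MRC depending on the extension."""
    path = Path(path)
    if _is_mrc(path):
        _write_mrc(path, stack)
    else:
        tifffile.imwrite(path, stack.voxels, photometric="minisblack")


# ---------------------------------------------------------------------------
# feature CSV (S7-style layout: four features + label code)
# ---------------------------------------------------------------------------

def read_feature_csv(path, columns: Sequence[str] = DEFAULT_FEATURE_COLUMNS,
                     ) -> pd.DataFrame:
    """Read a feature table CSV.

    A header row naming the columns is used when present; otherwise the
    ``columns`` schema (default ``r, gv, GVSD, distAZ, label``) is applied.
    The returned DataFrame carries the source id in ``df.attrs["source"]``.
    """
    path = Path(path)
    first = ""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    has_header = False
    if first:
        # a header row has non-numeric cells in the feature positions
        cells = [c.strip() for c in first.split(",")]
        has_header = any(not _is_number(c) for c in cells[:4])
    if has_header:
        df = pd.read_csv(path)
    else:
        df = pd.read_csv(path, header=None, names=list(columns))
    if first and df.shape[1] != 5:
        raise FormatError(f"{path}: expected 5 columns, found {df.shape[1]}")
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in columns[:-1]}
                          | {columns[-1]: pd.Series(dtype=str)})
    label_col = df.columns[-1] if "label" not in df.columns else "label"
    feature_cols = [c for c in df.columns if c != label_col]
    for col in feature_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}")
        df[col] = vals
    labels = df[label_col].astype(str).str.strip()
    bad_codes = sorted(set(labels) - VALID_LABEL_CODES)
    if bad_codes:
        raise FormatError(
            f"{path}: invalid label code(s) {bad_codes}; allowed: C, D, N, E")
    df[label_col] = labels
    if label_col != "label":
        df = df.rename(columns={label_col: "label"})
    df.attrs["source"] = path.stem
    return df


def write_feature_csv(path, table: pd.DataFrame,
                      columns: Sequence[str] = DEFAULT_FEATURE_COLUMNS) -> None:
    """Write a feature table with an explicit header row."""
    out = table.loc[:, list(columns)]
    bad = sorted(set(out[columns[-1]].astype(str)) - VALID_LABEL_CODES)
    if bad:
        raise FormatError(f"invalid label code(s) {bad} in table")
    out.to_csv(path, index=False)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# classified outputs: color label stack, composite, result log
# ---------------------------------------------------------------------------

def write_color_label_stack(labels: np.ndarray, classes: Mapping[int, str],
                            path=None, original: TomogramStack | None = None,
                            composite_path=None) -> np.ndarray:
    """Render a classified label map as an RGB stack.

    CCV voxels are magenta, DCV voxels green, background black.  When
    ``original`` is given a composite overlay (gray original + colors at
    vesicle voxels) is also produced and optionally written to
    ``composite_path``.

    Raises
    ------
    FormatError
        if a label id present in the map has no class assignment.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    missing = [int(i) for i in ids if int(i) not in classes]
    if missing:
        raise FormatError(f"label id(s) {missing} have no class assignment")
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for i in ids:
        cls = classes[int(i)]
        if cls not in CLASS_COLORS:
            raise FormatError(f"unknown class {cls!r} for label {int(i)}")
        rgb[labels == i] = CLASS_COLORS[cls]
    if path is not None:
        tifffile.imwrite(path, rgb)
    if original is not None:
        gray = np.asarray(original.voxels, dtype=np.float64)
        lo, hi = gray.min(), gray.max()
        scaled = ((gray - lo) / (hi - lo) * 255 if hi > lo
                  else np.zeros_like(gray)).astype(np.uint8)
        composite = np.repeat(scaled[..., np.newaxis], 3, axis=-1)
        mask = labels > 0
        composite[mask] = (0.5 * composite[mask] + 0.5 * rgb[mask]).astype(np.uint8)
        if composite_path is not None:
            tifffile.imwrite(composite_path, composite)
    return rgb


def write_result_log(table: pd.DataFrame, classes: Mapping[int, str],
                     path) -> None:
    """Write the plain-text result log.

    One row per vesicle with the four features and the numeric class code
    (CCV = 1, DCV = 0), followed by a footer with per-class counts.
    """
    feature_cols = ["r", "gv", "GVSD", "distAZ"]
    lines = ["id\tr\tgv\tGVSD\tdistAZ\tclass"]
    n_ccv = n_dcv = 0
    for idx, row in table.iterrows():
        vid = int(row["id"]) if "id" in table.columns else int(idx)
        cls = classes[int(vid)]
        code = LOG_CLASS_CODES[cls]
        if cls == "CCV":
            n_ccv += 1
        else:
            n_dcv += 1
        feats = "\t".join(repr(float(row[c])) for c in feature_cols)
        lines.append(f"{vid}\t{feats}\t{code}")
    lines.append(f"# CCV count: {n_ccv}")
    lines.append(f"# DCV count: {n_dcv}")
    lines.append(f"# total: {n_ccv + n_dcv}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_result_log(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse a result log back into a feature table and count dict."""
    rows, counts = [], {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("# CCV count:"):
            counts["CCV"] = int(line.split(":")[1])
        elif line.startswith("# DCV count:"):
            counts["DCV"] = int(line.split(":")[1])
        elif line.startswith("#") or line.startswith("id\t"):
            continue
        elif line.strip():
            vid, r, gv, gvsd, dist, code = line.split("\t")
            rows.append({"id": int(vid), "r": float(r), "gv": float(gv),
                         "GVSD": float(gvsd), "distAZ": float(dist),
                         "class": "CCV" if int(code) == 1 else "DCV"})
    return pd.DataFrame(rows), counts
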