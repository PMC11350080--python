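"""Spectral tables, hyperspectral cubes, and their I/O.

Absorbance spectra live on a shared wavenumber axis (cm^-1), stored in
descending order (instrument convention, e.g. 3900 -> 800). Two container
types cover the two acquisition modes: :class:`SpectrumTable` for bulk
ATR spectra of pulverized tissue with per-sample metadata, and
:class:`HyperCube` for FTIR images (rows x cols x channels) with a tissue
mask. Readers accept CSV (wide or long) for tables and ENVI
(header + raw binary, BSQ/BIL/BIP) for cubes.

Preprocessing follows standard FTIR practice: truncation to the
fingerprint region (1800-800 cm^-1) and vector (unit L2) normalization
of each spectrum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RangeError",
    "WavenumberAxis",
    "SampleMeta",
    "SpectrumTable",
    "HyperCube",
    "TRAIT_NAMES",
    "read_envi",
    "write_envi",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "truncate_range",
    "vector_normalize",
    "background_mask",
]

#: The three adventitious-root formation traits carried per genotype:
#: rooting percentage after 10 d on +IBA, 21 d on +IBA, and 21 d on -IBA.
TRAIT_NAMES = ("ar10_ibap", "ar21_ibap", "ar21_ibam")

GROUPS = ("easy", "difficult", "unknown")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class RangeError(ValueError):
    """A wavenumber range selection is empty or invalid."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotonic wavenumber axis in cm^-1, stored descending.

    Ascending input is flipped on construction; callers building a
    container directly must supply channel data already in
    descending-axis order (the readers in this module take care of it).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("axis needs at least two wavenumbers")
        diffs = np.diff(vals)
        if np.all(diffs > 0):
            vals = vals[::-1]
        elif not np.all(diffs < 0):
            raise ValueError("wavenumber axis must be strictly monotonic")
        if vals.min() < 400.0 or vals.max() > 4000.0:
            raise ValueError("wavenumbers must lie within [400, 4000] cm^-1")
        vals = np.ascontiguousarray(vals)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:  # noqa: D105
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def slice_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.values >= lo) & (self.values <= hi)


def _canonical_channel_order(axis_values: np.ndarray) -> slice:
    """Slice that flips channel-major data when the raw axis is ascending."""
    return slice(None, None, -1) if axis_values[1] > axis_values[0] else slice(None)


@dataclass
class SampleMeta:
    sample_id: str
    genotype: str = ""
    group: str = "unknown"
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name, value in self.traits.items():
            if value is not None and not (0.0 <= value <= 100.0):
                raise ValueError(f"trait {name}={value} outside [0, 100]")


@dataclass
class SpectrumTable:
    """Bulk absorbance spectra (n_samples x n_channels) plus metadata."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    meta: list[SampleMeta]

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x channels)")
        if self.absorbance.shape[1] != len(self.axis):
            raise ValueError("absorbance column count != axis length")
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("meta length != number of samples")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite absorbance values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    def subset(self, indices: Sequence[int]) -> "SpectrumTable":
        idx = list(indices)
        return SpectrumTable(
            self.axis, self.absorbance[idx].copy(), [self.meta[i] for i in idx]
        )


@dataclass
class HyperCube:
    """FTIR image: rows x cols x channels with a boolean tissue mask."""

    axis: WavenumberAxis
    data: np.ndarray
    mask: np.ndarray | None = None
    pixel_size_um: float = 11.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x channels)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError("cube channel count != axis length")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape != spatial shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def masked_spectra(self) -> np.ndarray:
        """Unmasked pixel spectra in row-major order, shape (n_pixels, n_channels)."""
        return self.data[self.mask]


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {2: np.int16, 4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.int16): 2, np.dtype(np.float32): 4, np.dtype(np.float64): 5}
_INTERLEAVES = ("bsq", "bil", "bip")


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # Collapse multi-line { ... } blocks before splitting into fields.
    text = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text, flags=re.S
    )
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _require(fields: dict[str, str], key: str) -> str:
    if key not in fields:
        raise FormatError(f"ENVI header missing required field {key!r}")
    return fields[key]


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/binary pair into a :class:`HyperCube`.

    Supports data types 2 (int16, with optional ``reflectance scale
    factor``), 4 (float32) and 5 (float64), all three interleaves and
    both byte orders. The wavelength block supplies the axis; the mask
    defaults to all-true.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    try:
        samples = int(_require(fields, "samples"))
        lines = int(_require(fields, "lines"))
        bands = int(_require(fields, "bands"))
        dtype_code = int(_require(fields, "data type"))
    except ValueError as exc:
        raise FormatError(f"unparseable numeric ENVI header field: {exc}") from exc
    interleave = _require(fields, "interleave").lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported data type code {dtype_code}")
    byte_order = int(fields.get("byte order", "0"))

    wl_block = _require(fields, "wavelength")
    wl = np.array(
        [float(v) for v in wl_block.strip().strip("{}").replace(",", " ").split()]
    )
    if wl.size != bands:
        raise FormatError(
            f"wavelength count {wl.size} != bands {bands} in ENVI header"
        )

    binary_path = header_path.with_suffix("")  # foo.hdr -> foo
    if not binary_path.exists():
        candidates = [header_path.with_suffix(ext) for ext in (".dat", ".img", ".raw")]
        binary_path = next((c for c in candidates if c.exists()), binary_path)
    if not binary_path.exists():
        raise FormatError(f"ENVI binary file for {header_path} not found")

    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder(
        ">" if byte_order == 1 else "<"
    )
    raw = np.fromfile(binary_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"ENVI binary holds {raw.size} values, header declares {expected}"
        )

    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)
    cube = cube.astype(float)

    if dtype_code == 2 and "reflectance scale factor" in fields:
        cube = cube / float(fields["reflectance scale factor"])

    pixel_size = float(fields.get("pixel size um", "11.0"))

    order = _canonical_channel_order(wl)
    axis = WavenumberAxis(wl)
    return HyperCube(axis=axis, data=cube[:, :, order], pixel_size_um=pixel_size)


def write_envi(
    cube: HyperCube,
    path: str | Path,
    dtype: str = "float64",
    interleave: str = "bsq",
    byte_order: int = 0,
) -> Path:
    """Write a cube as an ENVI header (``.hdr``) + raw binary pair.

    Returns the header path. Masked pixels are written as stored (the
    mask itself is not part of the ENVI format).
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _ENVI_CODES:
        raise FormatError(f"unsupported dtype {dtype!r}")
    path = Path(path)
    header_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    binary_path = header_path.with_suffix("")

    rows, cols, bands = cube.shape
    data = cube.data
    if interleave == "bsq":
        arr = data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = data.transpose(0, 2, 1)
    else:
        arr = data
    out = np.ascontiguousarray(
        arr, dtype=np_dtype.newbyteorder(">" if byte_order == 1 else "<")
    )
    out.tofile(binary_path)

    wl = ", ".join(f"{v:.6f}" for v in cube.axis.values)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np_dtype]}\n"
        f"interleave = {interleave}\n"
        f"byte order = {byte_order}\n"
        f"pixel size um = {cube.pixel_size_um}\n"
        "wavelength units = Wavenumber\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return header_path


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "genotype", "group"] + [f"trait_{t}" for t in TRAIT_NAMES]


def _meta_to_frame(meta: list[SampleMeta]) -> pd.DataFrame:
    rows = []
    for m in meta:
        row = {"sample_id": m.sample_id, "genotype": m.genotype, "group": m.group}
        for t in TRAIT_NAMES:
            row[f"trait_{t}"] = m.traits.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLS)


def _frame_to_meta(df: pd.DataFrame) -> list[SampleMeta]:
    meta = []
    for _, row in df.iterrows():
        traits = {}
        for t in TRAIT_NAMES:
            col = f"trait_{t}"
            if col in row and pd.notna(row[col]):
                traits[t] = float(row[col])
        meta.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                genotype=str(row.get("genotype", "") or ""),
                group=str(row.get("group", "unknown") or "unknown"),
                traits=traits,
            )
        )
    return meta


def write_metadata_csv(meta: list[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    _meta_to_frame(meta).to_csv(path, index=False)
    return path


def read_metadata_csv(path: str | Path) -> list[SampleMeta]:
    return _frame_to_meta(pd.read_csv(path))


def read_spectra_csv(
    path: str | Path,
    layout: str = "wide",
    meta_path: str | Path | None = None,
) -> SpectrumTable:
    """Read a spectral table from CSV.

    ``wide``: one row per sample; leading metadata columns (``sample_id``
    and optionally genotype/group/traits), remaining headers numeric
    wavenumbers. ``long``: columns exactly (sample_id, wavenumber,
    absorbance); metadata comes from the optional sidecar ``meta_path``.
    """
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        meta_cols = [c for c in df.columns if c in _META_COLS]
        wn_cols = [c for c in df.columns if c not in _META_COLS]
        try:
            wns = np.array([float(c) for c in wn_cols])
        except ValueError as exc:
            raise FormatError(f"unparseable wavenumber column header: {exc}") from exc
        if "sample_id" not in meta_cols:
            df.insert(0, "sample_id", [f"s{i}" for i in range(len(df))])
        meta = _frame_to_meta(df)
        matrix = df[wn_cols].to_numpy(dtype=float)
    elif layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        expected = {"sample_id", "wavenumber", "absorbance"}
        if set(df.columns) != expected:
            raise FormatError(
                f"long layout requires columns {sorted(expected)}, got {list(df.columns)}"
            )
        if df.duplicated(subset=["sample_id", "wavenumber"]).any():
            dup = df[df.duplicated(subset=["sample_id", "wavenumber"])].iloc[0]
            raise FormatError(
                f"duplicate (sample, wavenumber) pair: ({dup['sample_id']}, {dup['wavenumber']})"
            )
        sample_order = list(dict.fromkeys(df["sample_id"].astype(str)))
        wide = df.pivot(index="sample_id", columns="wavenumber", values="absorbance")
        if wide.isna().any().any():
            raise FormatError("ragged long table: missing (sample, wavenumber) cells")
        wide = wide.loc[sample_order]
        wns = wide.columns.to_numpy(dtype=float)
        matrix = wide.to_numpy(dtype=float)
        if meta_path is not None:
            side = {m.sample_id: m for m in read_metadata_csv(meta_path)}
            meta = [side.get(s, SampleMeta(sample_id=s)) for s in sample_order]
        else:
            meta = [SampleMeta(sample_id=s) for s in sample_order]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if not np.all(np.isfinite(matrix)):
        raise FormatError("non-finite absorbance values in CSV")
    order = np.argsort(wns)[::-1]
    return SpectrumTable(WavenumberAxis(wns[order]), matrix[:, order], meta)


def write_spectra_csv(
    table: SpectrumTable,
    path: str | Path,
    layout: str = "wide",
    meta_path: str | Path | None = None,
) -> Path:
    path = Path(path)
    if layout == "wide":
        df = _meta_to_frame(table.meta)
        spec = pd.DataFrame(
            table.absorbance, columns=[repr(float(v)) for v in table.axis.values]
        )
        # %.17g round-trips float64 exactly through text
        pd.concat([df, spec], axis=1).to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        n, m = table.absorbance.shape
        df = pd.DataFrame(
            {
                "sample_id": np.repeat(table.sample_ids, m),
                "wavenumber": np.tile(table.axis.values, n),
                "absorbance": table.absorbance.ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")
        if meta_path is not None:
            write_metadata_csv(table.meta, meta_path)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def truncate_range(obj: SpectrumTable | HyperCube, lo: float, hi: float):
    """Keep channels with lo <= wavenumber <= hi (closed interval)."""
    if lo >= hi:
        raise RangeError(f"invalid range [{lo}, {hi}]")
    keep = obj.axis.slice_mask(lo, hi)
    if keep.sum() < 2:
        raise RangeError(f"range [{lo}, {hi}] retains fewer than 2 channels")
    axis = WavenumberAxis(obj.axis.values[keep])
    if isinstance(obj, SpectrumTable):
        return SpectrumTable(axis, obj.absorbance[:, keep].copy(), list(obj.meta))
    return HyperCube(axis, obj.data[:, :, keep].copy(), obj.mask.copy(), obj.pixel_size_um)


def vector_normalize(obj: SpectrumTable | HyperCube):
    """Scale every spectrum to unit Euclidean norm.

    Masked cube pixels are left untouched; a zero-norm spectrum among
    the samples / unmasked pixels raises, naming the offender.
    """
    if isinstance(obj, SpectrumTable):
        norms = np.linalg.norm(obj.absorbance, axis=1)
        if np.any(norms == 0):
            bad = [obj.meta[i].sample_id for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"zero-norm spectra for samples {bad}")
        return SpectrumTable(obj.axis, obj.absorbance / norms[:, None], list(obj.meta))
    norms = np.linalg.norm(obj.data, axis=2)
    bad = obj.mask & (norms == 0)
    if np.any(bad):
        pix = list(zip(*np.nonzero(bad)))[:10]
        raise ValueError(f"zero-norm spectra at pixels {pix}")
    data = obj.data.copy()
    safe = np.where(norms == 0, 1.0, norms)
    data /= safe[:, :, None]
    return HyperCube(obj.axis, data, obj.mask.copy(), obj.pixel_size_um)


def background_mask(
    cube: HyperCube, quantile: float = 0.1, lo: float = 800.0, hi: float = 1800.0
) -> np.ndarray:
    """Mask of pixels whose total fingerprint absorbance exceeds a quantile.

    A crude background/substrate filter: pixels whose summed absorbance
    over [lo, hi] falls at or below the given quantile are marked
    non-tissue (False).
    """
    keep = cube.axis.slice_mask(lo, hi)
    totals = cube.data[:, :, keep].sum(axis=2)
    threshold = np.quantile(totals[cube.mask], quantile)
    return cube.mask & (totals > threshold)
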