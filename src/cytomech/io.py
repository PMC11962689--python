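"""Readers and writers for the package's data containers.

Force volumes use a portable HDF5 layout (vendor raw formats are
proprietary and out of scope):

    /meta                 attrs: rows, cols, pitch_m, setpoint_N,
                          spring_constant_N_per_m
    /topography           optional float64 height dataset (m)
    /curves/<row>_<col>   attrs: direction; datasets: z_piezo (m),
                          deflection (m)

A plain-text one-curve-per-file dialect is also supported: '#'-prefixed
``key: value`` header lines followed by two whitespace-separated columns
``z_piezo_nm  deflection_nm``.  All quantities are converted to SI on read.

Images are 8/16-bit grayscale TIFF; tables are RFC-4180 CSV with a header
row.  Integer image round trips and container round trips are bit-exact.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .containers import ForceCurve, ForceVolumeMap, ImageGray
from .errors import SchemaError, UnsupportedFormatError

__all__ = [
    "write_force_volume",
    "read_force_volume",
    "write_curve_txt",
    "read_curve_txt",
    "read_image",
    "write_image",
    "write_table",
    "read_table",
]

_META_REQUIRED = ("rows", "cols", "pitch_m", "setpoint_N",
                  "spring_constant_N_per_m")


def write_force_volume(fv: ForceVolumeMap, path, topography=None) -> None:
    """Write a force-volume map to the HDF5 container."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["rows"] = fv.rows
        meta.attrs["cols"] = fv.cols
        meta.attrs["pitch_m"] = fv.pitch
        meta.attrs["setpoint_N"] = fv.setpoint
        meta.attrs["spring_constant_N_per_m"] = fv.curves[0].spring_constant
        if topography is not None:
            f.create_dataset("topography", data=np.asarray(topography,
                                                           dtype=np.float64))
        grp = f.create_group("curves")
        for c in fv.curves:
            g = grp.create_group(f"{c.pixel[0]}_{c.pixel[1]}")
            g.attrs["direction"] = c.direction
            if c.spring_constant != fv.curves[0].spring_constant:
                g.attrs["spring_constant_N_per_m"] = c.spring_constant
            g.create_dataset("z_piezo", data=c.z_piezo)
            g.create_dataset("deflection", data=c.deflection)


def read_force_volume(path) -> ForceVolumeMap:
    """Read the HDF5 container back into a :class:`ForceVolumeMap`.

    Raises :class:`SchemaError` naming the first missing field and
    :class:`CorruptRecordError` (from the containers) on structural
    violations such as z/deflection length mismatches.
    """
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise SchemaError("missing required group 'meta'")
        meta = f["meta"].attrs
        for key in _META_REQUIRED:
            if key not in meta:
                raise SchemaError(f"missing required field 'meta/{key}'")
        rows, cols = int(meta["rows"]), int(meta["cols"])
        k_default = float(meta["spring_constant_N_per_m"])
        if "curves" not in f:
            raise SchemaError("missing required group 'curves'")
        grp = f["curves"]
        curves = []
        for r in range(rows):
            for c in range(cols):
                name = f"{r}_{c}"
                if name not in grp:
                    raise SchemaError(f"missing curve group 'curves/{name}'")
                g = grp[name]
                for ds in ("z_piezo", "deflection"):
                    if ds not in g:
                        raise SchemaError(
                            f"curve 'curves/{name}' lacks dataset '{ds}'")
                curves.append(ForceCurve(
                    z_piezo=g["z_piezo"][()],
                    deflection=g["deflection"][()],
                    spring_constant=float(
                        g.attrs.get("spring_constant_N_per_m", k_default)),
                    pixel=(r, c),
                    direction=str(g.attrs.get("direction", "approach")),
                ))
        return ForceVolumeMap(rows=rows, cols=cols, pitch=float(meta["pitch_m"]),
                              curves=curves, setpoint=float(meta["setpoint_N"]))


def write_curve_txt(curve: ForceCurve, path) -> None:
    """Write one curve in the plain-text dialect (nm columns)."""
    with open(path, "w", newline="\n") as f:
        f.write(f"# spring_constant_N_per_m: {float(curve.spring_constant)!r}\n")
        f.write(f"# direction: {curve.direction}\n")
        f.write(f"# pixel: {curve.pixel[0]} {curve.pixel[1]}\n")
        f.write("# z_piezo_nm deflection_nm\n")
        for z, d in zip(curve.z_piezo, curve.deflection):
            f.write(f"{float(z * 1e9)!r} {float(d * 1e9)!r}\n")


def read_curve_txt(path) -> ForceCurve:
    """Read the plain-text one-curve dialect; converts nm to metres."""
    header: dict[str, str] = {}
    z, d = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    header[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SchemaError(f"malformed data line: {line!r}")
            z.append(float(parts[0]))
            d.append(float(parts[1]))
    if "spring_constant_N_per_m" not in header:
        raise SchemaError("missing required field 'spring_constant_N_per_m'")
    pixel = (0, 0)
    if "pixel" in header:
        pr, pc = header["pixel"].split()
        pixel = (int(pr), int(pc))
    return ForceCurve(
        z_piezo=np.asarray(z) * 1e-9,
        deflection=np.asarray(d) * 1e-9,
        spring_constant=float(header["spring_constant_N_per_m"]),
        pixel=pixel,
        direction=header.get("direction", "approach"),
    )


def read_image(path, scale: float, allow_float: bool = False) -> ImageGray:
    """Read an 8/16-bit grayscale TIFF.

    ``scale`` is the physical pixel size in um/px (images carry no reliable
    calibration of their own).  RGB images are rejected; float TIFFs are
    rejected unless ``allow_float`` is set.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        raise UnsupportedFormatError(
            "multi-channel image; convert to single-channel grayscale first"
        )
    if arr.dtype.kind == "f" and not allow_float:
        raise UnsupportedFormatError(
            "float TIFF; pass allow_float=True to read it"
        )
    return ImageGray(pixels=arr, scale=scale)


def write_image(img, path) -> None:
    """Write an array or :class:`ImageGray` as TIFF (dtype preserved)."""
    arr = img.pixels if isinstance(img, ImageGray) else np.asarray(img)
    tifffile.imwrite(str(path), arr)


def write_table(rows, path, fieldnames=None) -> None:
    """Write records as RFC-4180 CSV with a header row.

    ``rows`` is a sequence of dicts (field order from ``fieldnames`` or the
    first record) or a pandas DataFrame.
    """
    path = Path(path)
    try:
        import pandas as pd
        if isinstance(rows, pd.DataFrame):
            rows = rows.to_dict("records")
            fieldnames = fieldnames or list(rows[0].keys()) if rows else fieldnames
    except ImportError:  # pragma: no cover
        pass
    rows = list(rows)
    if fieldnames is None:
        if not rows:
            raise ValueError("cannot infer header from an empty table")
        fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)


def read_table(path):
    """Read a CSV written by :func:`write_table` into a DataFrame."""
    import pandas as pd
    return pd.read_csv(path)
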