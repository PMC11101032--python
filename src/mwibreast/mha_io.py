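"""MetaImage (MHA) volume I/O and MATLAB-container export.

Reading and writing go through SimpleITK, which implements the MetaImage
standard (including zlib-compressed payloads).  Before handing a file to
SimpleITK, :func:`read_mha` validates the ASCII header itself so that
malformed files produce precise errors naming the offending key instead of
opaque ITK exceptions.

Dielectric property maps are additionally exportable as a version-5 MATLAB
container (via :mod:`scipy.io`) holding variables ``permittivity``,
``conductivity``, ``frequency_GHz`` and ``spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy.io import savemat

from .errors import DimensionalityError, FormatError
from .volume import SUPPORTED_DTYPES, Volume3D, check_same_geometry

_MET_TO_DTYPE = {v: k for k, v in SUPPORTED_DTYPES.items()}

_REQUIRED_KEYS = ("ObjectType", "NDims", "DimSize", "ElementType", "ElementDataFile")


@dataclass
class PropertyMaps:
    """Paired relative-permittivity / effective-conductivity volumes."""

    permittivity: Volume3D
    conductivity: Volume3D
    frequency_ghz: float

    def __post_init__(self) -> None:
        check_same_geometry(self.permittivity, self.conductivity)


def _parse_header(path: Path) -> dict[str, str]:
    """Parse the ASCII key = value header of a local (.mha) MetaImage file."""
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(
                    f"{path}: header ended before key 'ElementDataFile'"
                )
            try:
                text = line.decode("ascii").strip()
            except UnicodeDecodeError as exc:
                raise FormatError(f"{path}: non-ASCII bytes in header") from exc
            if not text:
                continue
            if "=" not in text:
                raise FormatError(
                    f"{path}: malformed header line (no '='): {text[:60]!r}"
                )
            key, _, value = text.partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
    return header


def _validate_header(path: Path, header: dict[str, str]) -> None:
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    if header["NDims"] != "3":
        raise DimensionalityError(
            f"{path}: NDims={header['NDims']}, only 3D volumes are supported"
        )
    if header["ElementType"] not in _MET_TO_DTYPE:
        raise FormatError(
            f"{path}: unsupported ElementType {header['ElementType']!r}; "
            f"expected one of {sorted(_MET_TO_DTYPE)}"
        )
    dims = header["DimSize"].split()
    if len(dims) != 3 or not all(d.isdigit() and int(d) >= 1 for d in dims):
        raise FormatError(f"{path}: malformed DimSize {header['DimSize']!r}")


def read_mha(path: str | Path) -> Volume3D:
    """Read a 3D MetaImage (.mha) file.

    Supports MET_SHORT, MET_FLOAT and MET_DOUBLE element types with
    compressed or uncompressed payloads.  Raises :class:`FormatError` for a
    malformed header (naming the offending key) and
    :class:`DimensionalityError` when ``NDims != 3``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    header = _parse_header(path)
    _validate_header(path, header)
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.dtype.name not in SUPPORTED_DTYPES:
        raise FormatError(
            f"{path}: payload decoded to unsupported dtype {data.dtype.name}"
        )
    return Volume3D(data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_mha(vol: Volume3D, path: str | Path, compressed: bool = False) -> None:
    """Write ``vol`` as a standards-conforming local MetaImage (.mha) file.

    The header records ElementSpacing, Offset and ElementType; with
    ``compressed=True`` the raw payload is zlib-deflated.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = sitk.GetImageFromArray(vol.data)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path), useCompression=bool(compressed))


def export_matlab(maps: PropertyMaps, path: str | Path) -> None:
    """Write property maps to a MATLAB v5 container.

    Variables: ``permittivity`` and ``conductivity`` (3D arrays in (z, y, x)
    order), scalar ``frequency_GHz`` and ``spacing_mm``.
    """
    check_same_geometry(maps.permittivity, maps.conductivity)
    savemat(
        str(path),
        {
            "permittivity": maps.permittivity.data,
            "conductivity": maps.conductivity.data,
            "frequency_GHz": float(maps.frequency_ghz),
            "spacing_mm": np.asarray(maps.permittivity.spacing, dtype=float),
        },
        format="5",
    )


def export_single_matlab(vol: Volume3D, name: str, frequency_ghz: float,
                         path: str | Path) -> None:
    """Write one property volume to its own MATLAB v5 container."""
    savemat(
        str(path),
        {
            name: vol.data,
            "frequency_GHz": float(frequency_ghz),
            "spacing_mm": np.asarray(vol.spacing, dtype=float),
        },
        format="5",
    )
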