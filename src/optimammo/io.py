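"""Text-based input/output for curves, maps and cohort tables.

Time-resolved curves travel as 2-column delimited text (time_ps, counts)
with a ``# wavelength_nm=`` header; maps as delimited text matrices with a
JSON sidecar of per-map ranges, optionally also as 16-bit grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_curve",
    "read_curve",
    "write_map_text",
    "read_map_text",
    "write_map_tiff",
    "write_map_sidecar",
    "write_cohort",
    "read_cohort",
]


def write_curve(path, time_ps, counts, wavelength_nm) -> None:
    """Write a time-resolved curve as 2-column text with a wavelength header."""
    arr = np.column_stack([np.asarray(time_ps, float), np.asarray(counts, float)])
    header = f"wavelength_nm={wavelength_nm:g}\ntime_ps counts"
    np.savetxt(path, arr, header=header)


def read_curve(path):
    """Read a curve written by :func:`write_curve`.

    Returns (time_ps, counts, wavelength_nm).
    """
    wavelength = float("nan")
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "wavelength_nm=" in line:
                wavelength = float(line.split("wavelength_nm=")[1].strip())
                break
    arr = np.loadtxt(path)
    return arr[:, 0], arr[:, 1], wavelength


def write_map_text(path, image) -> None:
    """Write a 2-D map as a delimited text matrix (NaN for out-of-mask)."""
    np.savetxt(path, np.asarray(image, float))


def read_map_text(path):
    return np.loadtxt(path)


def write_map_tiff(path, image) -> None:
    """Write a 2-D map as 16-bit grayscale TIFF, linearly rescaled.

    NaN (out-of-mask) pixels map to 0; the in-mask range spans 1..65535.
    The quantitative values live in the text/sidecar outputs.
    """
    import tifffile

    img = np.asarray(image, float)
    finite = np.isfinite(img)
    out = np.zeros(img.shape, dtype=np.uint16)
    if finite.any():
        lo, hi = np.nanmin(img), np.nanmax(img)
        span = hi - lo if hi > lo else 1.0
        out[finite] = (1 + 65534 * (img[finite] - lo) / span).astype(np.uint16)
    tifffile.imwrite(path, out)


def write_map_sidecar(path, ranges: dict) -> None:
    """JSON sidecar of per-map (min, max) ranges, mirroring color-bar limits."""
    serializable = {
        str(k): [float(v[0]), float(v[1])] for k, v in ranges.items()
    }
    Path(path).write_text(json.dumps(serializable, indent=2))


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
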