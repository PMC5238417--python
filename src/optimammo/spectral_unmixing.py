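"""Spectral decomposition of absorption differences into tissue constituents.

The absorption difference between lesion and average breast tissue at the
seven instrument wavelengths is related linearly to constituent
concentration differences through the Beer law,

    delta_mua(lambda) = sum_i eps_i(lambda) * delta_C_i,

with i in {Hb, HbO2, water, lipid, collagen}.  With 7 wavelengths and 5
constituents the system is overdetermined and solved by unconstrained
linear least squares: the delta_C are signed differences, so no
non-negativity is imposed (a non-negative mode exists for absolute
compositions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "CONSTITUENTS",
    "ExtinctionSpectra",
    "CompositionDelta",
    "load_extinction_table",
    "unmix",
    "total_hemoglobin",
    "oxygen_saturation",
    "derived_hemoglobin",
]

#: Constituent order used everywhere: hemoglobins in uM, the rest in mg/cm^3.
CONSTITUENTS = ("Hb", "HbO2", "water", "lipid", "collagen")


@dataclass(frozen=True)
class ExtinctionSpectra:
    """Extinction-coefficient matrix eps_i(lambda).

    ``matrix`` has one row per wavelength (sorted ascending) and one column
    per constituent in :data:`CONSTITUENTS` order.  Units: cm^-1/uM for the
    hemoglobins, cm^-1/(mg/cm^3) for water, lipid and collagen.
    """

    wavelengths: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.wavelengths), len(CONSTITUENTS)):
            raise ValueError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.wavelengths)} wavelengths x {len(CONSTITUENTS)} constituents"
            )
        if np.any(m < 0):
            raise ValueError("extinction coefficients must be non-negative")
        if np.linalg.matrix_rank(m) < len(CONSTITUENTS):
            raise ValueError("extinction matrix is rank deficient")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def absorption(self, concentrations: np.ndarray) -> np.ndarray:
        """Forward Beer law: mua(lambda) for a concentration vector."""
        return self.matrix @ np.asarray(concentrations, dtype=float)


@dataclass
class CompositionDelta:
    """Concentration differences between lesion and average breast tissue.

    dHb, dHbO2 in uM; dWater, dLipid, dCollagen in mg/cm^3.  Values are
    signed: a lesion can hold less of a constituent than average tissue.
    """

    dHb: float
    dHbO2: float
    dWater: float
    dLipid: float
    dCollagen: float

    @property
    def dtHb(self) -> float:
        """Total-hemoglobin difference, dHb + dHbO2 (uM)."""
        return self.dHb + self.dHbO2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.dHb, self.dHbO2, self.dWater, self.dLipid, self.dCollagen]
        )

    @classmethod
    def from_array(cls, values) -> "CompositionDelta":
        v = np.asarray(values, dtype=float)
        if v.shape != (5,):
            raise ValueError("expected 5 values (Hb, HbO2, water, lipid, collagen)")
        return cls(*v)


def load_extinction_table(path=None) -> ExtinctionSpectra:
    """Load an extinction table CSV (first column wavelength_nm, then one
    column per constituent).  Rows are sorted by wavelength; the condition
    number of the resulting matrix is logged.

    Without ``path`` the packaged default table is used.  The packaged
    values are literature-like defaults (hemoglobin molar extinctions and
    water/lipid/collagen-type-I bulk absorption per unit density); all
    quantitative workflows in this package are round-trip consistent and do
    not depend on their absolute accuracy.
    """
    if path is None:
        ref = resources.files("optimammo.data") / "extinction_defaults.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    if "wavelength_nm" not in table.columns:
        raise ValueError("extinction table must have a wavelength_nm column")
    missing = [c for c in CONSTITUENTS if c not in table.columns]
    if missing:
        raise ValueError(f"extinction table missing constituents: {missing}")
    table = table.sort_values("wavelength_nm").reset_index(drop=True)
    spectra = ExtinctionSpectra(
        wavelengths=tuple(float(w) for w in table["wavelength_nm"]),
        matrix=table[list(CONSTITUENTS)].to_numpy(dtype=float),
    )
    logger.info(
        "loaded extinction table: %d wavelengths, condition number %.3g",
        len(spectra.wavelengths),
        spectra.condition_number,
    )
    return spectra


def unmix(
    delta_mua_vec: np.ndarray,
    spectra: ExtinctionSpectra,
    non_negative: bool = False,
) -> tuple[CompositionDelta, np.ndarray]:
    """Invert the Beer law for one absorption-difference vector.

    Returns the least-squares constituent differences and the residual
    vector delta_mua - eps @ delta_C.  ``non_negative=True`` switches to a
    non-negative solve for absolute compositions; it is not the pathway
    for signed differences.
    """
    b = np.asarray(delta_mua_vec, dtype=float)
    if b.shape != (len(spectra.wavelengths),):
        raise ValueError(
            f"expected {len(spectra.wavelengths)} absorption values, got {b.shape}"
        )
    if not np.all(np.isfinite(b)):
        raise ValueError("delta_mua values must be finite")
    if non_negative:
        x, _ = nnls(spectra.matrix, b)
    else:
        x, *_ = np.linalg.lstsq(spectra.matrix, b, rcond=None)
    residual = b - spectra.matrix @ x
    return CompositionDelta.from_array(x), residual


def total_hemoglobin(hb: float, hbo2: float) -> float:
    """tHb = Hb + HbO2; valid for absolute values and signed differences."""
    return hb + hbo2


def oxygen_saturation(hb: float, hbo2: float) -> float:
    """SO2 = HbO2 / (Hb + HbO2) on absolute concentrations.

    Signed differences carry no saturation information, so negative inputs
    are rejected rather than silently producing a meaningless ratio.
    """
    if hb < 0 or hbo2 < 0:
        raise ValueError(
            "oxygen saturation is defined for absolute concentrations only "
            "(non-negative); got a signed-difference-like input"
        )
    thb = hb + hbo2
    if thb == 0:
        raise ValueError("Hb and HbO2 cannot both be zero")
    return hbo2 / thb


def derived_hemoglobin(dhb: float, dhbo2: float) -> dict:
    """Derived hemoglobin quantities for a pair of (possibly signed) values.

    Always returns the total-hemoglobin difference; includes SO2 only when
    the inputs are valid absolute concentrations.
    """
    out = {"dtHb": total_hemoglobin(dhb, dhbo2)}
    if dhb >= 0 and dhbo2 >= 0 and (dhb + dhbo2) > 0:
        out["SO2"] = oxygen_saturation(dhb, dhbo2)
    return out
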