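"""Optical properties of pure tissue components.

The absorption coefficient of a tissue compartment is the concentration-
weighted sum of the absorption spectra of its chromophores,

    mu_a(lambda) = sum_i c_i * eps_i(lambda) + background,

and the reduced scattering coefficient follows the usual power law

    mu_s'(lambda) = a * (lambda / 500 nm)^(-b),

where ``a`` is the scattering intensity (the value of mu_s' at the 500 nm
reference wavelength) and ``b`` the scattering power (default 2 for soft
tissue).

The packaged chromophore library holds oxygenated / deoxygenated whole
blood, melanosome, and water absorption as two-column text tables
(wavelength_nm, mu_a in mm^-1 per unit volume fraction); units and
conversion notes live in ``data/library.json``.  Evaluation between table
nodes is piecewise linear; evaluation outside a table's range is an error,
never an extrapolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ChromophoreSpectrum",
    "AbsorptionRecipe",
    "ScatteringModel",
    "ChromophoreLibrary",
    "mix_absorption",
    "reduced_scattering",
    "blood_absorption",
]

REFERENCE_WAVELENGTH_NM = 500.0


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Tabulated absorption of one pure component.

    ``values`` are absorption per unit concentration (mm^-1 per volume
    fraction for every packaged chromophore).
    """

    name: str
    wavelengths_nm: np.ndarray
    values: np.ndarray
    units: str = "mm^-1 per volume fraction"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or v.shape != wl.shape:
            raise ValueError(f"{self.name}: malformed table")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError(f"{self.name}: values must be finite and non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    def __call__(self, wavelengths_nm) -> np.ndarray:
        """Piecewise-linear evaluation; out-of-range wavelengths raise."""
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if wl.min() < lo or wl.max() > hi:
            raise ValueError(
                f"{self.name}: requested wavelengths outside tabulated "
                f"range [{lo:g}, {hi:g}] nm"
            )
        return np.interp(wl, self.wavelengths_nm, self.values)


@dataclass(frozen=True)
class AbsorptionRecipe:
    """Composition of one tissue compartment.

    ``components`` maps chromophore names to concentrations (volume
    fractions for the packaged library); ``background`` is a constant,
    wavelength-independent absorption in mm^-1.
    """

    components: tuple = field(default_factory=tuple)
    background: float = 0.0

    def __post_init__(self):
        comps = tuple((str(n), float(c)) for n, c in self.components)
        for name, c in comps:
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")
        total = sum(c for _, c in comps)
        if total > 1.0 + 1e-9:
            raise ValueError(f"volume fractions sum to {total:g} > 1")
        if self.background < 0:
            raise ValueError("background absorption must be >= 0")
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class ScatteringModel:
    """Power-law reduced scattering: a at 500 nm, exponent b (default 2)."""

    a: float
    b: float = 2.0

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("scattering intensity a must be >= 0")
        if self.b <= 0:
            raise ValueError("scattering power b must be > 0")


class ChromophoreLibrary:
    """Named collection of :class:`ChromophoreSpectrum` tables."""

    def __init__(self, spectra: Iterable[ChromophoreSpectrum]):
        self._spectra = {s.name: s for s in spectra}

    def __getitem__(self, name: str) -> ChromophoreSpectrum:
        try:
            return self._spectra[name]
        except KeyError:
            raise KeyError(
                f"unknown chromophore {name!r}; available: {sorted(self._spectra)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._spectra

    def names(self):
        return sorted(self._spectra)

    _default = None

    @classmethod
    def default(cls) -> "ChromophoreLibrary":
        """The packaged library (whole blood oxy/deoxy, melanosome, water)."""
        if cls._default is None:
            meta = json.loads(
                resources.files("hsiq.data").joinpath("library.json").read_text()
            )
            spectra = []
            for name in ("hemoglobin_oxy", "hemoglobin_deoxy", "melanosome", "water"):
                txt = resources.files("hsiq.data").joinpath(f"{name}.txt").read_text()
                rows = [
                    line.split()
                    for line in txt.splitlines()
                    if line.strip() and not line.startswith("#")
                ]
                arr = np.array(rows, dtype=float)
                spectra.append(
                    ChromophoreSpectrum(
                        name, arr[:, 0], arr[:, 1], units=meta[name]["units"]
                    )
                )
            cls._default = cls(spectra)
        return cls._default


def mix_absorption(
    recipe: AbsorptionRecipe,
    wavelengths_nm,
    library: ChromophoreLibrary | None = None,
) -> np.ndarray:
    """Total absorption mu_a(lambda) [mm^-1] of a compartment.

    Sums concentration-weighted chromophore absorption over the recipe and
    adds the constant background term.
    """
    library = library or ChromophoreLibrary.default()
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    mu_a = np.full(wl.shape, float(recipe.background))
    for name, conc in recipe.components:
        mu_a = mu_a + conc * library[name](wl)
    return mu_a


def reduced_scattering(model: ScatteringModel, wavelengths_nm) -> np.ndarray:
    """mu_s'(lambda) = a * (lambda/500 nm)^(-b) [mm^-1]."""
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    if np.any(wl <= 0):
        raise ValueError("wavelengths must be positive")
    return model.a * (wl / REFERENCE_WAVELENGTH_NM) ** (-model.b)


def blood_absorption(
    B: float,
    S: float,
    wavelengths_nm,
    library: ChromophoreLibrary | None = None,
) -> np.ndarray:
    """Whole-blood term B*(S*eps_oxy + (1-S)*eps_deoxy) [mm^-1]."""
    library = library or ChromophoreLibrary.default()
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    return B * (
        S * library["hemoglobin_oxy"](wl) + (1.0 - S) * library["hemoglobin_deoxy"](wl)
    )
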