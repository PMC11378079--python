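"""Layered optical models of skin and gingiva.

Skin is a three-layer stack (epidermis 0.1 mm, dermis 2 mm, semi-infinite
subcutis); gingiva is a four-layer stack (epithelium 0.2 mm, lamina propria
1.5 mm, dentin 2 mm, semi-infinite pulp).  The four free parameters are the
blood volume fraction B (perfusing the dermis / lamina propria), the
hemoglobin oxygen saturation S, the melanosome volume fraction fm (in the
epidermis / epithelium) and the scattering intensity a shared by all free
tissue layers.  Water content is fixed per layer (50% in the top layer, 70%
in the perfused layer) and a small constant background absorption is applied
in the top two layers.  All layers use refractive index 1.4 and anisotropy
g = 0.9; the deep fixed layers (subcutis, dentin, pulp) carry literature
default compositions and constant reduced scattering.

Tissue models are declarative (:class:`LayerSpec` lists) and serializable to
YAML so alternate anatomies can be declared without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .chromophores import (
    AbsorptionRecipe,
    ChromophoreLibrary,
    ScatteringModel,
    blood_absorption,
    mix_absorption,
    reduced_scattering,
)

__all__ = [
    "TissueParams",
    "OpticalLayer",
    "LayerStack",
    "LayerSpec",
    "TissueModel",
    "skin_model",
    "gingiva_model",
    "build_skin",
    "build_gingiva",
    "get_model",
]

DEFAULT_N = 1.4
DEFAULT_G = 0.9
DEFAULT_BACKGROUND = 0.025  # mm^-1, constant, top two layers


@dataclass(frozen=True)
class TissueParams:
    """Free tissue parameters: the inversion target vector.

    B, S, fm are dimensionless fractions in [0, 1]; a is the reduced
    scattering at 500 nm in mm^-1.  W, when given, overrides the per-layer
    default water fractions of the free layers.
    """

    B: float
    S: float
    fm: float
    a: float
    W: float | None = None

    def __post_init__(self):
        for name in ("B", "S", "fm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.a < 0:
            raise ValueError(f"a={self.a!r} must be >= 0")
        if self.W is not None and not 0.0 <= self.W <= 1.0:
            raise ValueError(f"W={self.W!r} outside [0, 1]")


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer on the working wavelength grid."""

    name: str
    thickness_mm: float  # np.inf marks the semi-infinite bottom layer
    n: float
    mu_a: np.ndarray  # mm^-1 per wavelength
    mu_s_reduced: np.ndarray  # mm^-1 per wavelength
    g: float

    def __post_init__(self):
        if not (self.thickness_mm > 0):
            raise ValueError("layer thickness must be positive")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        mu_a = np.asarray(self.mu_a, dtype=float)
        mu_s = np.asarray(self.mu_s_reduced, dtype=float)
        if mu_a.shape != mu_s.shape:
            raise ValueError("mu_a / mu_s' length mismatch")
        if np.any(mu_a < 0) or np.any(mu_s < 0):
            raise ValueError("negative optical coefficients")
        if not (np.all(np.isfinite(mu_a)) and np.all(np.isfinite(mu_s))):
            raise ValueError("non-finite optical coefficients")
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_s_reduced", mu_s)

    @property
    def semi_infinite(self) -> bool:
        return np.isinf(self.thickness_mm)


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers, top first, below an ambient medium."""

    layers: tuple
    n_ambient: float = 1.0

    def __post_init__(self):
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("stack needs at least one layer")
        for lay in layers[:-1]:
            if lay.semi_infinite:
                raise ValueError("only the last layer may be semi-infinite")
        if not layers[-1].semi_infinite:
            raise ValueError("the last layer must be semi-infinite")
        object.__setattr__(self, "layers", layers)

    @property
    def n_wavelengths(self) -> int:
        return self.layers[0].mu_a.size


@dataclass(frozen=True)
class LayerSpec:
    """Declarative layer: composition plus which free parameters it uses.

    ``blood`` is "free" (uses params.B/params.S), "none", or a fixed
    ``(B, S)`` pair; ``melanin`` toggles the fm channel; ``scattering`` is
    "free" (a-power-law) or a fixed constant mu_s' in mm^-1.
    """

    name: str
    thickness_mm: float | None  # None -> semi-infinite
    water: float = 0.0
    background: float = 0.0
    melanin: bool = False
    blood: object = "none"
    scattering: object = "free"
    n: float = DEFAULT_N
    g: float = DEFAULT_G


@dataclass(frozen=True)
class TissueModel:
    """A named ordered list of :class:`LayerSpec`."""

    name: str
    layers: tuple
    n_ambient: float = 1.0
    scattering_power: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))

    # -- construction ---------------------------------------------------

    def build(
        self,
        params: TissueParams,
        wavelengths_nm,
        library: ChromophoreLibrary | None = None,
    ) -> LayerStack:
        """Instantiate the stack for one parameter vector."""
        library = library or ChromophoreLibrary.default()
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        base = self.base_absorption(wl, library)
        musp_free = reduced_scattering(
            ScatteringModel(params.a, self.scattering_power), wl
        )
        layers = []
        for i, spec in enumerate(self.layers):
            mu_a = base[i].copy()
            if spec.melanin:
                mu_a += params.fm * library["melanosome"](wl)
            if spec.blood == "free":
                mu_a += blood_absorption(params.B, params.S, wl, library)
            if (
                params.W is not None
                and spec.water > 0
                and (spec.melanin or spec.blood == "free")
            ):
                # optional W override applies to the free tissue layers only
                mu_a += (params.W - spec.water) * library["water"](wl)
            musp = (
                musp_free
                if spec.scattering == "free"
                else np.full(wl.shape, float(spec.scattering))
            )
            layers.append(
                OpticalLayer(
                    spec.name,
                    np.inf if spec.thickness_mm is None else spec.thickness_mm,
                    spec.n,
                    mu_a,
                    musp,
                    spec.g,
                )
            )
        return LayerStack(tuple(layers), n_ambient=self.n_ambient)

    def base_absorption(self, wavelengths_nm, library=None) -> np.ndarray:
        """Per-layer mu_a without the free fm/B terms, shape (L, n_wl).

        Contains water, background and any fixed blood composition; this is
        the parameter-independent part of each layer's absorption.
        """
        library = library or ChromophoreLibrary.default()
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        rows = []
        for spec in self.layers:
            comps = []
            if spec.water > 0:
                comps.append(("water", spec.water))
            mu = mix_absorption(
                AbsorptionRecipe(tuple(comps), background=spec.background), wl, library
            )
            if isinstance(spec.blood, (tuple, list)):
                bfix, sfix = spec.blood
                mu = mu + blood_absorption(bfix, sfix, wl, library)
            rows.append(mu)
        return np.vstack(rows)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layers"] = [asdict(s) for s in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TissueModel":
        layers = tuple(
            LayerSpec(**{**s, "blood": tuple(s["blood"])
                         if isinstance(s["blood"], list) else s["blood"]})
            for s in d["layers"]
        )
        return cls(
            name=d["name"],
            layers=layers,
            n_ambient=d.get("n_ambient", 1.0),
            scattering_power=d.get("scattering_power", 2.0),
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TissueModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def skin_model() -> TissueModel:
    """Three-layer skin: epidermis / dermis / semi-infinite subcutis."""
    return TissueModel(
        name="skin",
        layers=(
            LayerSpec("epidermis", 0.1, water=0.50,
                      background=DEFAULT_BACKGROUND, melanin=True),
            LayerSpec("dermis", 2.0, water=0.70,
                      background=DEFAULT_BACKGROUND, blood="free"),
            LayerSpec("subcutis", None, water=0.15,
                      blood=(0.005, 0.7), scattering=1.2),
        ),
    )


def gingiva_model() -> TissueModel:
    """Four-layer gingiva: epithelium / lamina propria / dentin / pulp."""
    return TissueModel(
        name="gingiva",
        layers=(
            LayerSpec("epithelium", 0.2, water=0.50,
                      background=DEFAULT_BACKGROUND, melanin=True),
            LayerSpec("lamina_propria", 1.5, water=0.70,
                      background=DEFAULT_BACKGROUND, blood="free"),
            LayerSpec("dentin", 2.0, background=0.3, scattering=3.0),
            LayerSpec("pulp", None, water=0.80,
                      blood=(0.05, 0.7), scattering=1.0),
        ),
    )


_MODELS = {"skin": skin_model, "gingiva": gingiva_model}


def get_model(name) -> TissueModel:
    if isinstance(name, TissueModel):
        return name
    try:
        return _MODELS[name]()
    except KeyError:
        raise ValueError(f"unknown tissue model {name!r}") from None


def build_skin(params: TissueParams, wavelengths_nm, library=None) -> LayerStack:
    return skin_model().build(params, wavelengths_nm, library)


def build_gingiva(params: TissueParams, wavelengths_nm, library=None) -> LayerStack:
    return gingiva_model().build(params, wavelengths_nm, library)
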