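"""Sample geometry and scalar transport relations.

Units are fixed package-wide: lengths in micrometres (um), times in
picoseconds (ps), hence the vacuum speed of light ``C_UM_PS`` = 299.792458
um/ps.  Absorption is stored as the coefficient ``mu_a`` (1/um); the
absorption length ``l_a`` = 1/mu_a may be given at construction instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import yaml

#: vacuum speed of light in package units (um / ps)
C_UM_PS = 299.792458


def transport_mfp(l_s: float, g: float) -> float:
    """Transport mean free path l_t = l_s / (1 - g).

    The similarity relation maps an anisotropic random walk with step
    length ``l_s`` and single-scattering anisotropy ``g`` (mean cosine of
    the deflection angle) onto an isotropic walk with this rescaled step.

    Parameters
    ----------
    l_s : float
        Scattering mean free path (um), > 0.
    g : float
        Anisotropy factor, in [0, 1).
    """
    if l_s <= 0:
        raise ValueError(f"l_s must be positive, got {l_s}")
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    return l_s / (1.0 - g)


def energy_velocity(n: float) -> float:
    """Energy (phase) velocity v = c/n in um/ps for refractive index n >= 1."""
    if n < 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return C_UM_PS / n


def diffusion_coefficient(l_t: float, n: float) -> float:
    """Diffusion coefficient D = l_t * v / 3 (um^2/ps) with v = c/n."""
    if l_t <= 0:
        raise ValueError(f"l_t must be positive, got {l_t}")
    return l_t * energy_velocity(n) / 3.0


def optical_thickness(L: float, l_t: float) -> float:
    """Dimensionless optical thickness L / l_t (rule of thumb: diffusive for >= 8)."""
    if L <= 0 or l_t <= 0:
        raise ValueError("L and l_t must be positive")
    return L / l_t


def transport_albedo(l_t: float, l_a: float) -> float:
    """Transport single-scattering albedo l_a / (l_a + l_t).

    Equals (1/l_t) / (1/l_t + 1/l_a): the fraction of extinction events that
    are (transport-)scattering rather than absorption.
    """
    if l_t <= 0 or l_a <= 0:
        raise ValueError("l_t and l_a must be positive")
    return l_a / (l_a + l_t)


def effective_index_from_delay(delta_t: float, L: float) -> float:
    """Effective refractive index n = 1 + c*dt/L from the ballistic time shift.

    ``delta_t`` (ps) is the extra arrival delay a sample of thickness ``L``
    (um) imposes on a collimated pulse relative to free propagation.
    """
    if delta_t < 0:
        raise ValueError(f"delay must be non-negative, got {delta_t}")
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    return 1.0 + C_UM_PS * delta_t / L


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer of a turbid slab.

    Parameters
    ----------
    thickness : float
        Layer thickness (um), > 0.
    l_s : float
        Scattering mean free path (um), > 0.
    g : float
        Scattering anisotropy (mean cosine), in [0, 1).
    mu_a : float
        Absorption coefficient (1/um), >= 0.  ``mu_a = 0`` encodes no
        absorption.  Alternatively pass ``l_a`` (um) to the constructor.
    n : float
        Refractive index, >= 1.
    """

    thickness: float
    l_s: float
    g: float = 0.0
    mu_a: float = 0.0
    n: float = 1.0

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        if self.l_s <= 0:
            raise ValueError(f"l_s must be positive, got {self.l_s}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @classmethod
    def from_l_a(cls, thickness, l_s, g=0.0, l_a=math.inf, n=1.0) -> "OpticalLayer":
        """Construct with an absorption length l_a (um); l_a = inf means none."""
        if l_a <= 0:
            raise ValueError(f"l_a must be positive, got {l_a}")
        mu_a = 0.0 if math.isinf(l_a) else 1.0 / l_a
        return cls(thickness=thickness, l_s=l_s, g=g, mu_a=mu_a, n=n)

    @classmethod
    def isotropic(cls, thickness, l_t, mu_a=0.0, n=1.0) -> "OpticalLayer":
        """Isotropic-scattering layer specified directly by its l_t (= l_s at g=0)."""
        return cls(thickness=thickness, l_s=l_t, g=0.0, mu_a=mu_a, n=n)

    @property
    def l_t(self) -> float:
        """Transport mean free path l_s/(1-g) (um)."""
        return transport_mfp(self.l_s, self.g)

    @property
    def l_a(self) -> float:
        """Absorption length 1/mu_a (um); inf when non-absorbing."""
        return math.inf if self.mu_a == 0 else 1.0 / self.mu_a

    def to_dict(self) -> dict:
        return {
            "thickness": self.thickness,
            "l_s": self.l_s,
            "g": self.g,
            "mu_a": self.mu_a,
            "n": self.n,
        }


@dataclass(frozen=True)
class LayeredSlab:
    """An ordered stack of :class:`OpticalLayer` between two clear media.

    Layers run front (illuminated, z=0) to back; ``n_front``/``n_back`` are
    the refractive indices of the external media.
    """

    layers: tuple
    n_front: float = 1.0
    n_back: float = 1.0

    def __post_init__(self):
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 1:
            raise ValueError("a slab needs at least one layer")
        if not all(isinstance(l, OpticalLayer) for l in layers):
            raise TypeError("layers must be OpticalLayer instances")
        if self.n_front < 1.0 or self.n_back < 1.0:
            raise ValueError("external indices must be >= 1")

    @classmethod
    def homogeneous(cls, L, l_s, g=0.0, mu_a=0.0, n=1.0,
                    n_front=1.0, n_back=1.0) -> "LayeredSlab":
        return cls((OpticalLayer(L, l_s, g, mu_a, n),), n_front, n_back)

    @property
    def L(self) -> float:
        """Total thickness (um)."""
        return sum(l.thickness for l in self.layers)

    @property
    def is_symmetric(self) -> bool:
        return self.layers == self.layers[::-1]

    def reversed(self) -> "LayeredSlab":
        return LayeredSlab(self.layers[::-1], self.n_back, self.n_front)

    @property
    def ballistic_time(self) -> float:
        """Minimum front-to-back traversal time sum(thickness_i * n_i / c) (ps)."""
        return sum(l.thickness * l.n / C_UM_PS for l in self.layers)

    def to_dict(self) -> dict:
        return {
            "n_front": self.n_front,
            "n_back": self.n_back,
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredSlab":
        layers = tuple(OpticalLayer(**ld) for ld in d["layers"])
        return cls(layers, d.get("n_front", 1.0), d.get("n_back", 1.0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LayeredSlab":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def symmetric_five_layer(thicknesses: Sequence[float], l_ts: Sequence[float],
                         n: float = 1.52, mu_a: float = 0.0,
                         n_front: float = 1.0, n_back: float = 1.0) -> LayeredSlab:
    """Build the symmetric outer/interstitial/core/interstitial/outer stack.

    ``thicknesses`` and ``l_ts`` give (outer, interstitial, core) values; the
    stack is mirrored about the core so the layer sequence equals its reverse.
    Scattering is isotropic per layer (layers differ by scatterer density,
    i.e. by l_t only).
    """
    t_o, t_i, t_c = thicknesses
    l_o, l_i, l_c = l_ts
    layers = tuple(
        OpticalLayer.isotropic(t, lt, mu_a=mu_a, n=n)
        for t, lt in [(t_o, l_o), (t_i, l_i), (t_c, l_c), (t_i, l_i), (t_o, l_o)]
    )
    slab = LayeredSlab(layers, n_front, n_back)
    assert slab.is_symmetric
    return slab


@dataclass(frozen=True)
class TransportSummary:
    """Diffusive-scale scalars for a homogeneous description of a sample."""

    l_t: float
    D: float
    v: float
    optical_thickness: float
    albedo: float

    @classmethod
    def from_layer(cls, layer: OpticalLayer, L: float | None = None) -> "TransportSummary":
        L = layer.thickness if L is None else L
        l_t = layer.l_t
        v = energy_velocity(layer.n)
        return cls(
            l_t=l_t,
            D=diffusion_coefficient(l_t, layer.n),
            v=v,
            optical_thickness=optical_thickness(L, l_t),
            albedo=transport_albedo(l_t, layer.l_a) if layer.mu_a > 0 else 1.0,
        )
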