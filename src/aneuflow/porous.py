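"""Darcy–Forchheimer porous-layer model of a flow-diverting stent.

A flow-diverting stent is a fine braided wire mesh deployed across the
aneurysm neck.  Resolving individual wires is prohibitively expensive, so the
mesh is replaced by a thin homogeneous porous layer that exerts a volumetric
momentum sink on the fluid,

    S_i = -( mu/K * v_i  +  C * 1/2 * rho * |v| * v_i ),

with permeability ``K`` (viscous, Darcy term) and inertial loss coefficient
``C`` (Forchheimer term).  Defaults correspond to a typical braided
flow-diverter: 150 um layer thickness, K = 0.001489 mm^2, C = 7665 m^-1.

Because the layer is thin compared with every other length scale, it can also
be lumped into a pressure-jump condition across the neck,

    dP(v_n) = thickness * ( mu/K * v_n + C * 1/2 * rho * v_n^2 ),

which is what the steady-flow surrogate uses to attenuate sac inflow.
All quantities are SI (m, s, kg, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluidProps",
    "PorousLayerSpec",
    "source_term",
    "pressure_drop",
    "transmission_factor",
]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties (defaults: blood).

    rho : density, kg/m^3
    mu  : dynamic viscosity, Pa s
    """

    rho: float = 1050.0
    mu: float = 0.0035

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.mu > 0):
            raise ValueError("rho and mu must be positive")


@dataclass(frozen=True)
class PorousLayerSpec:
    """Thin porous layer standing in for the stent wire mesh.

    thickness    : layer thickness, m (default 150 um)
    permeability : Darcy permeability K, m^2 (default 0.001489 mm^2)
    loss_coeff   : Forchheimer loss coefficient C, 1/m (default 7665)
    """

    thickness: float = 150e-6
    permeability: float = 1.489e-9
    loss_coeff: float = 7665.0

    def __post_init__(self) -> None:
        if not (self.thickness > 0 and self.permeability > 0 and self.loss_coeff > 0):
            raise ValueError("thickness, permeability and loss_coeff must be positive")

    @classmethod
    def from_stent_units(
        cls,
        thickness_um: float = 150.0,
        K_mm2: float = 0.001489,
        C_per_m: float = 7665.0,
    ) -> "PorousLayerSpec":
        """Build a spec from the units stent properties are usually quoted in."""
        return cls(
            thickness=thickness_um * 1e-6,
            permeability=K_mm2 * 1e-6,
            loss_coeff=C_per_m,
        )


def source_term(
    v: np.ndarray,
    props: FluidProps = FluidProps(),
    layer: PorousLayerSpec = PorousLayerSpec(),
) -> np.ndarray:
    """Darcy–Forchheimer momentum sink for velocity ``v`` inside the layer.

    Parameters
    ----------
    v : array-like, shape (3,) or (n, 3)
        Velocity, m/s.

    Returns
    -------
    ndarray with the shape of ``v``: momentum source, Pa/m.  Antiparallel to
    ``v`` and odd under ``v -> -v``.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    speed = np.linalg.norm(v, axis=-1, keepdims=True)
    return -(props.mu / layer.permeability * v
             + layer.loss_coeff * 0.5 * props.rho * speed * v)


def pressure_drop(
    v_n,
    props: FluidProps = FluidProps(),
    layer: PorousLayerSpec = PorousLayerSpec(),
):
    """Pressure jump across the layer at face-normal speed ``v_n`` (m/s).

    The volumetric sink integrated over the (thin) layer thickness:
    ``dP = thickness * (mu/K * v_n + C/2 * rho * v_n^2)``, in Pa.
    Zero at rest, strictly increasing and convex in ``v_n``.
    """
    v_n = np.asarray(v_n, dtype=float)
    if np.any(v_n < 0):
        raise ValueError("normal speed must be >= 0 (check face orientation)")
    dp = layer.thickness * (props.mu / layer.permeability * v_n
                            + layer.loss_coeff * 0.5 * props.rho * v_n ** 2)
    return dp if dp.ndim else float(dp)


def transmission_factor(
    v_approach: float,
    driving_dp: float,
    props: FluidProps = FluidProps(),
    layer: PorousLayerSpec = PorousLayerSpec(),
) -> float:
    """Fraction of the approach speed transmitted through the layer.

    Solves ``pressure_drop(v_through) = driving_dp`` for ``v_through`` (the
    positive root of the Forchheimer quadratic) and returns
    ``min(1, v_through / v_approach)``.  Monotone increasing in the driving
    pressure and decreasing in C and 1/K.
    """
    if v_approach < 0:
        raise ValueError("approach speed must be >= 0")
    if driving_dp <= 0:
        raise ValueError("driving pressure must be > 0")
    a = layer.thickness * layer.loss_coeff * 0.5 * props.rho
    b = layer.thickness * props.mu / layer.permeability
    # positive branch of a*v^2 + b*v - dp = 0
    v_through = (-b + np.sqrt(b * b + 4.0 * a * driving_dp)) / (2.0 * a)
    if v_approach == 0.0:
        return 1.0
    return float(min(1.0, v_through / v_approach))
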