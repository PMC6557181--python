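"""Ground-truth validation systems rendered as multi-contrast reflectivity
curves.

Two silicon/water systems exercise every stage of the pipeline without any
measured data:

* a rough three-layer slab stack (three 50 A layers, 5 A roughness,
  non-solvent SLDs 5, 0 and 2 x 10^-6 A^-2, the third layer 50% hydrated),
* a parabolic layer formed by a close-packed arrangement of 250 A-radius
  silica nanoparticles, discretized to 20 slabs with 10 A roughness.

Curves are generated by Névot-Croce reflectivity evaluated exactly at every
Gaussian resolution offset (delta q/q = 10%), keeping points up to
q = 0.25 A^-1 and down to R = 10^-6, the usual background limit of neutron
reflectometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import erf

from .abeles import LayerStack, nevot_croce_reflectivity, resolution_offsets, _FWHM
from .profiles import ContrastCurve

__all__ = [
    "SOLVENT_SLD",
    "MATERIAL_SLD",
    "GroundTruthSystem",
    "three_layer_system",
    "parabolic_nanoparticle_system",
    "render_contrast_series",
    "default_q_grid",
]

#: solvent SLD registry (1/Angstrom^2); all overridable per call
SOLVENT_SLD = {
    "D2O": 6.35e-6,
    "SMW": 2.07e-6,  # silicon-matched water, 38% D2O
    "H2O": -0.56e-6,
    "SiO2MW": 3.5e-6,  # silica-matched water
}

MATERIAL_SLD = {
    "Si": 2.07e-6,
    "SiO2": 3.5e-6,
}


def default_q_grid(n: int = 150, q_min: float = 0.005, q_max: float = 0.25) -> np.ndarray:
    """Log-spaced q grid mimicking a two-wavelength reflectometer's
    coverage."""
    return np.geomspace(q_min, q_max, n)


@dataclass
class GroundTruthSystem:
    """A known interfacial structure plus the rendering conventions.

    ``thicknesses``/``dry_slds``/``hydrations``/``roughnesses`` describe the
    generating slab stack (non-solvent SLD and solvent fraction per slab);
    the composite SLD at a given solvent contrast is
    dry_sld*(1-h) + h*rho_solvent.
    """

    name: str
    thicknesses: np.ndarray
    dry_slds: np.ndarray
    hydrations: np.ndarray
    roughnesses: np.ndarray  # one per interface, len(thicknesses)+1
    rho_fronting: float = MATERIAL_SLD["Si"]
    contrasts: Sequence[tuple[str, float]] = field(
        default_factory=lambda: [(k, SOLVENT_SLD[k]) for k in ("D2O", "SMW", "H2O")]
    )
    q_max: float = 0.25
    r_floor: float = 1e-6
    dq_over_q: float = 0.10

    def __post_init__(self) -> None:
        self.thicknesses = np.asarray(self.thicknesses, dtype=float)
        self.dry_slds = np.asarray(self.dry_slds, dtype=float)
        self.hydrations = np.asarray(self.hydrations, dtype=float)
        self.roughnesses = np.asarray(self.roughnesses, dtype=float)
        n = self.thicknesses.size
        if self.dry_slds.size != n or self.hydrations.size != n:
            raise ValueError("slab arrays must have equal length")
        if self.roughnesses.size != n + 1:
            raise ValueError("need one roughness per interface")

    @property
    def extent(self) -> float:
        """Total extent of the non-solvent structure."""
        return float(self.thicknesses.sum())

    def stack(self, rho_solvent: float) -> LayerStack:
        comp = self.dry_slds * (1.0 - self.hydrations) + self.hydrations * rho_solvent
        slds = np.concatenate([[self.rho_fronting], comp, [rho_solvent]])
        return LayerStack(self.thicknesses, slds, self.roughnesses)

    def truth_composite(self, z, rho_solvent: float) -> np.ndarray:
        """Composite SLD profile of the generating stack, with each interface
        smeared by its Gaussian roughness (the real-space counterpart of the
        Névot-Croce damping)."""
        z = np.asarray(z, dtype=float)
        stack = self.stack(rho_solvent)
        bounds = np.concatenate([[0.0], np.cumsum(self.thicknesses)])
        val = np.full_like(z, stack.slds[0])
        for b, sig, lo, hi in zip(
            bounds, self.roughnesses, stack.slds[:-1], stack.slds[1:]
        ):
            if sig > 0:
                w = 0.5 * (1.0 + erf((z - b) / (np.sqrt(2.0) * sig)))
            else:
                w = (z >= b).astype(float)
            val = val + (hi - lo) * w
        return val

    def truth_hydration(self, z) -> np.ndarray:
        """Solvent volume fraction profile of the generating stack (same
        roughness smearing as the SLD)."""
        z = np.asarray(z, dtype=float)
        hyd = np.concatenate([[0.0], self.hydrations, [1.0]])
        bounds = np.concatenate([[0.0], np.cumsum(self.thicknesses)])
        val = np.full_like(z, hyd[0])
        for b, sig, lo, hi in zip(bounds, self.roughnesses, hyd[:-1], hyd[1:]):
            if sig > 0:
                w = 0.5 * (1.0 + erf((z - b) / (np.sqrt(2.0) * sig)))
            else:
                w = (z >= b).astype(float)
            val = val + (hi - lo) * w
        return val


def three_layer_system() -> GroundTruthSystem:
    """Hypothetical three-layer structure on silicon: 50 A layers with 5 A
    roughness, non-solvent SLDs (5, 0, 2) x 10^-6 A^-2, third layer 50%
    solvent-penetrated; contrasts D2O, SMW and H2O."""
    return GroundTruthSystem(
        name="three_layer",
        thicknesses=[50.0, 50.0, 50.0],
        dry_slds=[5e-6, 0.0, 2e-6],
        hydrations=[0.0, 0.0, 0.5],
        roughnesses=[5.0, 5.0, 5.0, 5.0],
    )


def parabolic_nanoparticle_system(
    radius: float = 250.0,
    sld: float = MATERIAL_SLD["SiO2"],
    phi_max: float = 0.9069,
    n_layers: int = 20,
    roughness: float = 10.0,
) -> GroundTruthSystem:
    """Parabolic SLD profile of close-packed spherical silica nanoparticles
    at the silicon surface.

    The non-solvent volume fraction follows the equatorial cross-section of a
    sphere layer, phi(z) = phi_max * [1 - (z - R)^2 / R^2] on 0 <= z <= 2R
    (phi_max defaults to the 2-D hexagonal close-packing fraction), rendered
    as ``n_layers`` slabs with Névot-Croce roughness for curve generation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = 2.0 * radius / n_layers
    centers = (np.arange(n_layers) + 0.5) * d
    phi = phi_max * (1.0 - (centers - radius) ** 2 / radius**2)
    phi = np.clip(phi, 0.0, 1.0)
    return GroundTruthSystem(
        name="parabolic_nanoparticle",
        thicknesses=np.full(n_layers, d),
        dry_slds=phi * sld,
        hydrations=1.0 - phi,
        roughnesses=np.full(n_layers + 1, roughness),
    )


def render_contrast_series(
    system: GroundTruthSystem,
    q_grid: Optional[np.ndarray] = None,
    noise: float = 0.0,
    seed: Optional[int] = None,
    p: int = 17,
    span: float = 2.5,
) -> list[ContrastCurve]:
    """Smeared, truncated reflectivity curves for every contrast of a system.

    Reflectivity is Névot-Croce with the system's roughnesses, smeared by the
    Gaussian p-point average evaluated exactly at every offset q, then
    truncated at ``q <= q_max`` and ``R >= r_floor``.  Optional multiplicative
    Gaussian noise of fractional amplitude ``noise`` adds a per-point dR
    column (dR = noise * R, floored at 1e-7).
    """
    if q_grid is None:
        q_grid = default_q_grid(q_max=system.q_max)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid <= 0) or np.any(np.diff(q_grid) <= 0):
        raise ValueError("q grid must be positive and increasing")
    rng = np.random.default_rng(seed)
    x, wg = resolution_offsets(p, span)
    curves = []
    for label, rho_solvent in system.contrasts:
        stack = system.stack(rho_solvent)
        keep_q = q_grid[q_grid <= system.q_max]
        qoff = keep_q[:, None] * (1.0 + (system.dq_over_q / _FWHM) * x[None, :])
        r_off = nevot_croce_reflectivity(stack, qoff.ravel()).reshape(qoff.shape)
        r_smeared = r_off @ wg
        if noise > 0:
            r_obs = r_smeared * (1.0 + noise * rng.standard_normal(r_smeared.size))
            dR = np.maximum(noise * r_smeared, 1e-7)
        else:
            r_obs = r_smeared
            dR = None
        keep = r_obs >= system.r_floor
        curves.append(
            ContrastCurve(
                q=keep_q[keep],
                R=r_obs[keep],
                dR=dR[keep] if dR is not None else None,
                dq_over_q=system.dq_over_q,
                rho_fronting=system.rho_fronting,
                rho_solvent=rho_solvent,
                label=label,
            )
        )
    return curves
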