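"""Two-profile interfacial model: non-solvent SLD and hydration on N equal
sub-layers.

The interfacial region of total extension ``D`` between semi-infinite fronting
(solid or air, SLD ``rho_fronting``) and backing (solvent, SLD
``rho_solvent``) media is split into ``N`` equally thick sub-layers.  Each
sub-layer ``n`` carries a non-solvent component SLD ``rho_n`` and a hydration
(solvent volume fraction) ``h_n`` in [0, 1].  Virtual boundary layers impose
``h_0 = 0`` at the fronting side and ``h_{N+1} = 1`` at the backing side; they
are boundary conditions, never free parameters.  Both profiles are smeared by
a Gaussian error function with a single global smoothing length ``sigma``
shared by the SLD and hydration profiles, and the composite SLD seen by the
neutrons is

    rho'(z) = rho(z) * [1 - h(z)] + h(z) * rho_solvent.

Coordinates: z = 0 at the fronting/film boundary, increasing toward the
backing (solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf

__all__ = [
    "InterfacialModel",
    "ContrastCurve",
    "sigma_limits",
    "smeared_component",
    "composite_sld",
    "discretize",
    "profile_table",
]

#: tolerance used when validating box constraints
_BOUND_TOL = 1e-12


def sigma_limits(q_max: float) -> tuple[float, float]:
    """Admissible range of the smoothing length: pi/(4 q_max) .. pi/(2 q_max).

    These are the estimated limits of the spatial resolution set by the
    maximum measured wavevector transfer.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    return np.pi / (4.0 * q_max), np.pi / (2.0 * q_max)


@dataclass
class InterfacialModel:
    """Free parameters of the reconstruction: rho_n, h_n and sigma.

    Parameters
    ----------
    D : float
        Total extension of the interfacial layer (Angstrom, > 0).
    rho : ndarray, shape (N,)
        Non-solvent component SLD per sub-layer (1/Angstrom^2).
    h : ndarray, shape (N,)
        Hydration (solvent volume fraction) per sub-layer, in [0, 1].
    sigma : float
        Error-function smoothing length (Angstrom).
    rho_min, rho_max : float
        Box bounds on rho; default to the H2O and D2O SLDs, the natural
        limits for non-deuterated aqueous systems.
    q_max : float, optional
        When set, ``sigma`` must satisfy pi/(4 q_max) <= sigma <= pi/(2 q_max).
    """

    D: float
    rho: np.ndarray
    h: np.ndarray
    sigma: float
    rho_min: float = -0.56e-6
    rho_max: float = 6.35e-6
    q_max: Optional[float] = None

    def __post_init__(self) -> None:
        self.rho = np.ascontiguousarray(self.rho, dtype=float)
        self.h = np.ascontiguousarray(self.h, dtype=float)
        if not np.isfinite(self.D) or self.D <= 0:
            raise ValueError("D must be a positive length")
        if self.rho.ndim != 1 or self.h.shape != self.rho.shape:
            raise ValueError("rho and h must be 1-d arrays of equal length")
        if self.N < 1:
            raise ValueError("at least one sub-layer is required")
        if np.any(self.h < -_BOUND_TOL) or np.any(self.h > 1 + _BOUND_TOL):
            raise ValueError("hydration values must lie in [0, 1]")
        if np.any(self.rho < self.rho_min - _BOUND_TOL) or np.any(
            self.rho > self.rho_max + _BOUND_TOL
        ):
            raise ValueError("rho values must lie within [rho_min, rho_max]")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("sigma must be a positive length")
        if self.q_max is not None:
            lo, hi = sigma_limits(self.q_max)
            if not (lo - _BOUND_TOL <= self.sigma <= hi + _BOUND_TOL):
                raise ValueError(
                    f"sigma={self.sigma:g} outside resolution limits "
                    f"[{lo:g}, {hi:g}] for q_max={self.q_max:g}"
                )

    @property
    def N(self) -> int:
        """Number of sub-layers."""
        return self.rho.size

    @property
    def d(self) -> float:
        """Sub-layer thickness D/N."""
        return self.D / self.N

    @property
    def boundaries(self) -> np.ndarray:
        """The N+1 internal boundary positions 0, d, 2d, ..., D."""
        return np.linspace(0.0, self.D, self.N + 1)

    def copy(self) -> "InterfacialModel":
        return InterfacialModel(
            D=self.D,
            rho=self.rho.copy(),
            h=self.h.copy(),
            sigma=self.sigma,
            rho_min=self.rho_min,
            rho_max=self.rho_max,
            q_max=self.q_max,
        )


@dataclass
class ContrastCurve:
    """One reflectivity curve measured (or simulated) at a given solvent
    contrast.

    ``q`` must be strictly increasing and positive; points with non-positive
    reflectivity cannot enter the score (its log term is undefined for them)
    and are expected to have been dropped by the reader, which records the
    count.
    """

    q: np.ndarray
    R: np.ndarray
    rho_fronting: float
    rho_solvent: float
    dR: Optional[np.ndarray] = None
    dq: Optional[np.ndarray] = None  # absolute per-point resolution widths
    dq_over_q: float = 0.10
    label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.q = np.ascontiguousarray(self.q, dtype=float)
        self.R = np.ascontiguousarray(self.R, dtype=float)
        if self.q.ndim != 1 or self.R.shape != self.q.shape:
            raise ValueError("q and R must be 1-d arrays of equal length")
        if self.q.size == 0:
            raise ValueError(f"contrast curve {self.label!r} has no usable points")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if np.any(self.R <= 0):
            raise ValueError(
                "non-positive reflectivities must be dropped before constructing "
                "a ContrastCurve"
            )
        for name in ("dR", "dq"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.ascontiguousarray(arr, dtype=float)
                if arr.shape != self.q.shape:
                    raise ValueError(f"{name} must match the shape of q")
                setattr(self, name, arr)
        if self.dq_over_q < 0:
            raise ValueError("dq_over_q must be non-negative")

    @property
    def q_max(self) -> float:
        return float(self.q[-1])

    def resolution_fractions(self) -> np.ndarray:
        """Per-point fractional resolution dq/q; the dq column, when present,
        overrides the global dq_over_q."""
        if self.dq is not None:
            return self.dq / self.q
        return np.full_like(self.q, self.dq_over_q)


def _erf_steps(z: np.ndarray, boundaries: np.ndarray, sigma: float) -> np.ndarray:
    """Smeared unit steps 0.5*(1+erf((z - z_b)/(sqrt(2) sigma))) for every
    boundary; far tails (erf weight < 1e-12) evaluate to exact 0/1."""
    x = (np.asarray(z, dtype=float)[..., None] - boundaries) / (np.sqrt(2.0) * sigma)
    w = np.empty_like(x)
    inner = np.abs(x) <= 6.0
    w[inner] = 0.5 * (1.0 + erf(x[inner]))
    w[x > 6.0] = 1.0
    w[x < -6.0] = 0.0
    return w


def smeared_component(
    model: InterfacialModel,
    z,
    which: str,
    rho_fronting: Optional[float] = None,
    rho_backing: Optional[float] = None,
):
    """Error-function-smeared profile value(s) at depth(s) ``z``.

    ``which`` selects the non-solvent SLD profile (``"sld"``) or the hydration
    profile (``"hydration"``).  For the SLD profile the outer plateaus are the
    fronting and backing SLDs (``rho_fronting`` required; ``rho_backing``
    defaults to the last sub-layer value, i.e. no extra step at z = D).  The
    hydration plateaus are the boundary conditions h_0 = 0 and h_{N+1} = 1.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    if which == "hydration":
        plateaus = np.concatenate([[0.0], model.h, [1.0]])
    elif which == "sld":
        if rho_fronting is None:
            raise ValueError("rho_fronting is required for the SLD profile")
        back = model.rho[-1] if rho_backing is None else rho_backing
        plateaus = np.concatenate([[rho_fronting], model.rho, [back]])
    else:
        raise ValueError("which must be 'sld' or 'hydration'")
    w = _erf_steps(z, model.boundaries, model.sigma)
    val = plateaus[0] + w @ np.diff(plateaus)
    return val if val.ndim else float(val)


def composite_sld(model: InterfacialModel, z, rho_solvent: float, rho_fronting: float):
    """Composite SLD rho'(z) = rho(z)[1 - h(z)] + h(z) rho_solvent.

    The non-solvent profile keeps its last sub-layer value as the backing
    plateau (it is contrast-independent); the hydration boundary condition
    h_{N+1} = 1 alone carries the transition to the pure solvent beyond
    z = D, so that transition is a single clean erf step.
    """
    rho = smeared_component(model, z, "sld", rho_fronting=rho_fronting)
    h = smeared_component(model, z, "hydration")
    return rho * (1.0 - h) + h * rho_solvent


def discretize(
    model: InterfacialModel,
    rho_solvent: float,
    rho_fronting: float,
    padding: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the composite SLD on the sub-layer grid for the matrix engine.

    Returns ``(thicknesses, slds)`` where ``slds`` has the fronting and
    backing half-spaces prepended/appended.  The sampling is extended by
    ``padding`` (default 3 sigma, whole sub-layers) beyond [0, D] so the
    smeared tails are captured; samples are taken at layer centres.
    """
    d = model.d
    if padding is None:
        padding = 3.0 * model.sigma
    n_pad = int(np.ceil(max(padding, 0.0) / d))
    centers = (np.arange(-n_pad, model.N + n_pad) + 0.5) * d
    sld = composite_sld(model, centers, rho_solvent, rho_fronting)
    thick = np.full(centers.size, d)
    slds = np.concatenate([[rho_fronting], sld, [rho_solvent]])
    return thick, slds


def profile_table(
    model: InterfacialModel,
    contrasts: list[ContrastCurve],
    z_grid: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Profile export columns: z, non-solvent SLD, hydration and the composite
    SLD for each contrast, on a user-settable z grid (default 1 A spacing over
    [-20, D+20])."""
    if z_grid is None:
        z_grid = np.arange(-20.0, model.D + 20.0 + 0.5, 1.0)
    z_grid = np.asarray(z_grid, dtype=float)
    cols: dict[str, np.ndarray] = {"z": z_grid}
    front = contrasts[0].rho_fronting if contrasts else 0.0
    cols["rho_nonsolvent"] = np.asarray(
        smeared_component(model, z_grid, "sld", rho_fronting=front)
    )
    cols["hydration"] = np.asarray(smeared_component(model, z_grid, "hydration"))
    for c in contrasts:
        name = c.label or f"solvent_{c.rho_solvent:g}"
        cols[f"rho_composite_{name}"] = np.asarray(
            composite_sld(model, z_grid, c.rho_solvent, c.rho_fronting)
        )
    return cols
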