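"""Specular reflectivity of stratified media (Abelès matrix formalism) and
Gaussian instrumental resolution smearing.

The reflectivity of a stack of uniform layers is computed exactly from the
ordered product of 2x2 characteristic matrices built from the Fresnel
coefficients r_{n,n+1} = (k_n - k_{n+1})/(k_n + k_{n+1}), with
k_n = [q^2/4 - 4 pi (rho_n - rho_fronting)]^{1/2} the neutron wavevector in
layer n (principal complex branch, decaying evanescent waves).  Interfacial
roughness for synthetic ground-truth generation uses the Névot-Croce damping
of each Fresnel coefficient, exp(-2 k_n k_{n+1} sigma_r^2).

Instrumental resolution: a Gaussian of FWHM (dq/q)*q, applied as a
p-point weighted average spanning +-2.5 standard deviations (weight tail
< 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .profiles import ContrastCurve, InterfacialModel, smeared_component

__all__ = [
    "LayerStack",
    "wavevector",
    "reflectivity",
    "nevot_croce_reflectivity",
    "resolution_offsets",
    "smear_resolution",
    "FitWorkspace",
    "forward_curve",
]

#: conversion of a FWHM to a Gaussian standard deviation
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class LayerStack:
    """A stratified medium: L interior layers between two half-spaces.

    thicknesses : (L,) interior layer thicknesses (> 0), Angstrom
    slds : (L+2,) SLDs ordered fronting, layers..., backing (1/Angstrom^2)
    roughnesses : optional (L+1,) Névot-Croce roughness per interface, Angstrom
    """

    thicknesses: np.ndarray
    slds: np.ndarray
    roughnesses: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.thicknesses = np.ascontiguousarray(self.thicknesses, dtype=float)
        self.slds = np.ascontiguousarray(self.slds, dtype=float)
        if self.slds.size != self.thicknesses.size + 2:
            raise ValueError("need len(slds) == len(thicknesses) + 2")
        if np.any(self.thicknesses <= 0):
            raise ValueError("interior layer thicknesses must be positive")
        if self.roughnesses is not None:
            self.roughnesses = np.ascontiguousarray(self.roughnesses, dtype=float)
            if self.roughnesses.size != self.thicknesses.size + 1:
                raise ValueError("need len(roughnesses) == len(thicknesses) + 1")
            if np.any(self.roughnesses < 0):
                raise ValueError("roughnesses must be non-negative")


def wavevector(q, sld, rho_fronting):
    """Neutron wavevector k = [q^2/4 - 4 pi (rho - rho_fronting)]^{1/2}.

    Principal complex branch with non-negative imaginary part: purely
    imaginary (evanescent) when q^2/4 < 4 pi (rho - rho_fronting).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    rad = q * q / 4.0 - 4.0 * np.pi * (np.asarray(sld) - rho_fronting)
    return np.sqrt(rad.astype(complex))


def _reflectivity(stack: LayerStack, q, rough: np.ndarray) -> np.ndarray:
    q = np.ascontiguousarray(np.atleast_1d(q), dtype=float)
    if np.any(q <= 0) or not np.all(np.isfinite(q)):
        raise ValueError("q must be positive and finite")
    out = np.empty_like(q)
    _kernels.abeles_matrix(q, stack.thicknesses, stack.slds, rough, out)
    return out


def reflectivity(stack: LayerStack, q) -> np.ndarray:
    """Specular reflectivity R(q) of a sharp-interface stack; R in [0, 1]."""
    rough = np.zeros(stack.thicknesses.size + 1)
    return _reflectivity(stack, q, rough)


def nevot_croce_reflectivity(stack: LayerStack, q) -> np.ndarray:
    """Reflectivity with Gaussian interfacial roughness in the Névot-Croce
    approximation; identical to :func:`reflectivity` at zero roughness."""
    if stack.roughnesses is None:
        raise ValueError("stack.roughnesses is required")
    return _reflectivity(stack, q, stack.roughnesses)


def resolution_offsets(p: int = 17, span: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Sampling positions (in Gaussian standard deviations) and normalised
    weights of the p-point resolution average."""
    if p % 2 == 0 or p < 3:
        raise ValueError("p must be an odd integer >= 3")
    x = np.linspace(-span, span, p)
    w = np.exp(-0.5 * x * x)
    return x, w / w.sum()


def smear_resolution(
    q, R, dq_over_q: float, p: int = 17, span: float = 2.5
) -> np.ndarray:
    """Resolution-smear a tabulated curve by the Gaussian p-point average.

    Each point is replaced by the weighted average of the curve at
    q*(1 + (dq/q)/FWHM-to-sigma * x_a), interpolated log-log from the input
    table; offsets falling outside the tabulated range are dropped with the
    weights renormalised.  ``dq_over_q = 0`` returns the input unchanged.
    """
    q = np.asarray(q, dtype=float)
    R = np.asarray(R, dtype=float)
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be non-negative")
    x, w = resolution_offsets(p, span)
    if dq_over_q == 0.0:
        return R.copy()
    lnq = np.log(q)
    lnR = np.log(np.maximum(R, 1e-300))
    factors = 1.0 + (dq_over_q / _FWHM) * x
    acc = np.zeros_like(R)
    wsum = np.zeros_like(R)
    for fa, wa in zip(factors, w):
        qa = q * fa
        inside = (qa >= q[0]) & (qa <= q[-1])
        vals = np.exp(np.interp(np.log(qa[inside]), lnq, lnR))
        acc[inside] += wa * vals
        wsum[inside] += wa
    return acc / wsum


def _fine_grid(
    q: np.ndarray,
    frac: np.ndarray,
    x: np.ndarray,
    total_thickness: float,
    min_points: int = 260,
    points_per_fringe: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-spaced evaluation grid covering all resolution offsets of the data
    points, dense enough to resolve Kiessig fringes of the full stack with
    cubic interpolation, plus the Catmull-Rom interpolation table.

    Returns (qfine, idx, w4): base indices (nd, p) and cubic weights
    (nd, p, 4) such that ln R(qoff[j, a]) = sum_m w4[j, a, m] *
    ln R(qfine[idx[j, a] + m]).
    """
    qoff = q[:, None] * (1.0 + (frac[:, None] / _FWHM) * x[None, :])
    qlo, qhi = qoff.min(), qoff.max()
    span = np.log(qhi / qlo)
    n = max(
        min_points,
        int(np.ceil(points_per_fringe * total_thickness * qhi * span / (2.0 * np.pi))),
    )
    dln = span / (n - 1)
    lnlo = np.log(qlo) - 2.0 * dln
    lnhi = np.log(qhi) + 2.0 * dln
    nfine = n + 4
    lngrid = np.linspace(lnlo, lnhi, nfine)
    dln = (lnhi - lnlo) / (nfine - 1)
    qfine = np.exp(lngrid)

    u = (np.log(qoff) - lnlo) / dln
    i = np.floor(u).astype(np.int64)
    if i.min() < 1 or i.max() > nfine - 3:
        raise AssertionError("interpolation stencil fell off the fine grid")
    return qfine, np.ascontiguousarray(i - 1), _catmull_rom(u - i)


def _catmull_rom(t: np.ndarray) -> np.ndarray:
    w4 = np.empty(t.shape + (4,))
    t2 = t * t
    t3 = t2 * t
    w4[..., 0] = 0.5 * (-t3 + 2.0 * t2 - t)
    w4[..., 1] = 0.5 * (3.0 * t3 - 5.0 * t2 + 2.0)
    w4[..., 2] = 0.5 * (-3.0 * t3 + 4.0 * t2 + t)
    w4[..., 3] = 0.5 * (t3 - t2)
    return np.ascontiguousarray(w4)


class FitWorkspace:
    """Pre-computed geometry, fine grids and smearing tables for repeated
    forward evaluations of an N-sub-layer model against a set of contrast
    curves.

    This is the canonical forward path shared by :func:`forward_curve` and the
    annealing score: exact Abelès reflectivity on a per-contrast log-q fine
    grid, then the Gaussian p-point resolution average with cubic
    interpolation in (ln q, ln R).
    """

    def __init__(
        self,
        contrasts: Sequence[ContrastCurve],
        D: float,
        N: int = 50,
        p: int = 17,
        span: float = 2.5,
        subdivide: int = 2,
        exact_edge: bool = True,
    ):
        if not contrasts:
            raise ValueError("at least one contrast curve is required")
        if D <= 0:
            raise ValueError("D must be positive")
        fronts = {c.rho_fronting for c in contrasts}
        if len(fronts) != 1:
            raise ValueError(
                "all contrasts must share the fronting medium (the non-solvent "
                "profile is contrast-independent)"
            )
        self.contrasts = list(contrasts)
        self.D = float(D)
        self.N = int(N)
        self.d = self.D / self.N
        self.rho_fronting = fronts.pop()
        self.q_max = max(c.q_max for c in contrasts)
        smin, smax = np.pi / (4 * self.q_max), np.pi / (2 * self.q_max)
        self.sigma_limits = (smin, smax)

        # sampling geometry for the matrix engine: the composite profile is
        # sliced `subdivide` times finer than the parameter sub-layers (the
        # staircase error of slab sampling falls off quadratically in the
        # slice thickness), padded by >= 3 sigma_max on both sides
        if subdivide < 1:
            raise ValueError("subdivide must be >= 1")
        self.subdivide = int(subdivide)
        ds = self.d / self.subdivide
        n_pad_s = int(np.ceil(3.0 * smax / ds))
        L = self.N * self.subdivide + 2 * n_pad_s
        self.n_pad = n_pad_s
        self.zsamp = (np.arange(-n_pad_s, self.N * self.subdivide + n_pad_s) + 0.5) * ds
        self.thick = np.full(L, ds)
        self.zb = np.linspace(0.0, self.D, self.N + 1)
        total = self.D + 2 * n_pad_s * ds

        self.x, self.wg = resolution_offsets(p, span)
        self.rho_solv = np.array([c.rho_solvent for c in contrasts])
        nd_max = max(c.q.size for c in contrasts)
        C = len(contrasts)
        qfines = []
        self.idx = np.zeros((C, nd_max, p), dtype=np.int64)
        self.w4 = np.zeros((C, nd_max, p, 4))
        self.ndata = np.array([c.q.size for c in contrasts], dtype=np.int64)
        for ci, c in enumerate(contrasts):
            qf, idx, w4 = _fine_grid(c.q, c.resolution_fractions(), self.x, total)
            # a total-reflection critical edge is a sqrt cusp in R(q) that no
            # practical interpolation grid can resolve, and the q^4-weighted
            # score amplifies errors there; data points whose resolution
            # window touches the cusp are therefore evaluated exactly at
            # every offset, appended to the evaluation grid and addressed
            # through degenerate (0,1,0,0) stencils
            plateau = c.R >= 0.99
            if exact_edge and plateau.any():
                q99 = c.q[plateau].max()
                above = (c.q > q99) & (c.R <= 0.2)
                q20 = c.q[above].min() if above.any() else 1.2 * q99
                frac_all = c.resolution_fractions()
                off_lo = c.q * (1.0 + (frac_all / _FWHM) * self.x[0])
                off_hi = c.q * (1.0 + (frac_all / _FWHM) * self.x[-1])
                edge = (off_hi >= 0.95 * q99) & (off_lo <= 1.3 * q20)
                frac = frac_all[edge]
                qoff = c.q[edge, None] * (
                    1.0 + (frac[:, None] / _FWHM) * self.x[None, :]
                )
                flat = qoff.ravel()
                pos = qf.size + np.arange(flat.size).reshape(qoff.shape)
                idx[edge] = pos - 1
                w4[edge] = np.array([0.0, 1.0, 0.0, 0.0])
                # sentinels keep the 4-point stencil reads in bounds
                qf = np.concatenate([qf, flat, np.full(3, flat[-1])])
            qfines.append(qf)
            self.idx[ci, : c.q.size] = idx
            self.w4[ci, : c.q.size] = w4
        nf_max = max(qf.size for qf in qfines)
        self.nfine = np.array([qf.size for qf in qfines], dtype=np.int64)
        self.qfine = np.zeros((C, nf_max))
        for ci, qf in enumerate(qfines):
            # pad with the last value so the kernel never sees q <= 0; the
            # kernels only evaluate the first nfine[ci] entries
            self.qfine[ci, : qf.size] = qf
            self.qfine[ci, qf.size :] = qf[-1]

        # scratch buffers for the kernels
        self._plat_rho = np.empty(self.N + 1)
        self._plat_h = np.empty(self.N + 2)
        self._dry = np.empty(L)
        self._hyd = np.empty(L)
        self._estep = np.empty(L)
        self._sld = np.empty(L + 2)
        self._rough0 = np.zeros(L + 1)
        self._logbuf = np.empty(nf_max)
        self._rs = np.empty(nd_max)

    def _check(self, model: InterfacialModel) -> None:
        if model.N != self.N:
            raise ValueError("model N does not match workspace")
        if abs(model.D - self.D) > 1e-9:
            raise ValueError("model D does not match workspace")

    def forward(self, model: InterfacialModel) -> list[np.ndarray]:
        """Smeared theoretical reflectivity on every contrast's q grid."""
        self._check(model)
        plat_rho = np.concatenate([[self.rho_fronting], model.rho])
        plat_h = np.concatenate([[0.0], model.h, [1.0]])
        _kernels.smeared_profiles(
            self.zb, plat_rho, plat_h, model.sigma, self.zsamp,
            self._dry, self._hyd, self._estep,
        )
        out = []
        L = self.zsamp.size
        for ci, c in enumerate(self.contrasts):
            rsolv = self.rho_solv[ci]
            sld = np.empty(L + 2)
            sld[0] = self.rho_fronting
            sld[-1] = rsolv
            sld[1:-1] = self._dry * (1.0 - self._hyd) + self._hyd * rsolv
            rs = np.empty(c.q.size)
            nf = self.nfine[ci]
            _kernels.forward_logsmear(
                self.qfine[ci, :nf], self.thick, sld, self._rough0,
                self.idx[ci, : c.q.size], self.w4[ci, : c.q.size], self.wg,
                rs, self._logbuf[:nf],
            )
            out.append(rs)
        return out


def forward_curve(model: InterfacialModel, contrast: ContrastCurve) -> np.ndarray:
    """Theoretical resolution-smeared reflectivity of ``model`` evaluated on
    the experimental q grid of ``contrast``."""
    ws = FitWorkspace([contrast], D=model.D, N=model.N)
    return ws.forward(model)[0]
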