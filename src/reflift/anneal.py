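"""Simulated-annealing reconstruction of the SLD/hydration profiles.

The score measures the agreement with all contrast curves simultaneously: per
contrast the mean squared difference of the q^4-weighted reflectivities,
normalised by the mean of the q^4-weighted experimental curve, plus the mean
squared difference of the log reflectivities; the two-term form handles the
entire q range evenly.

Each run is a Metropolis cooling stage followed by a greedy polish.  The
cooling starts from a random profile and redraws one parameter afresh within
its admissible interval per trial (rho_n within [rho_min, rho_max], h_n
within [0, 1], sigma within the resolution limits), accepting when df <= 0
or with probability exp(-df/T), with ``trials_per_layer * N`` moves per
temperature, T' = cooling * T, and a stop after ``stop_rejections``
consecutive rejections.  After freeze-out a zero-temperature quench cascade
of shrinking local steps refines the profile on the accurate engine
sampling, and the result is canonicalized against the exact
translation degeneracy of substrate-like leading material.  Several
independent runs are performed and the best-scoring model is the solution;
low-score runs can be averaged to damp truncation ripple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .abeles import FitWorkspace
from .profiles import ContrastCurve, InterfacialModel, smeared_component, composite_sld

__all__ = [
    "ScoreConfig",
    "Constraint",
    "AnnealSchedule",
    "AnnealResult",
    "score",
    "propose_move",
    "anneal_run",
    "multi_run",
    "average_profiles",
]

logger = logging.getLogger(__name__)


class ScoreConfig:
    """The data side of the score: contrast curves plus their per-curve
    normalisers (the mean of the q^4-multiplied experimental curve)."""

    def __init__(self, contrasts: Sequence[ContrastCurve]):
        if not contrasts:
            raise ValueError("at least one contrast curve is required")
        self.contrasts = list(contrasts)
        C = len(self.contrasts)
        nd_max = max(c.q.size for c in self.contrasts)
        self.ndata = np.array([c.q.size for c in self.contrasts], dtype=np.int64)
        self.q4 = np.zeros((C, nd_max))
        self.q4rexp = np.zeros((C, nd_max))
        self.logrexp = np.zeros((C, nd_max))
        self.normalizers = np.empty(C)
        for ci, c in enumerate(self.contrasts):
            nd = c.q.size
            self.q4[ci, :nd] = c.q**4
            self.q4rexp[ci, :nd] = c.q**4 * c.R
            self.logrexp[ci, :nd] = np.log(c.R)
            self.normalizers[ci] = np.mean(c.q**4 * c.R)
        self.inorm = 1.0 / self.normalizers
        self._workspaces: dict[tuple[float, int], FitWorkspace] = {}

    @property
    def M_c(self) -> int:
        return len(self.contrasts)

    def workspace(self, D: float, N: int, subdivide: int = 2,
                  exact_edge: bool = True) -> FitWorkspace:
        key = (float(D), int(N), int(subdivide), bool(exact_edge))
        if key not in self._workspaces:
            self._workspaces[key] = FitWorkspace(
                self.contrasts, D=D, N=N, subdivide=subdivide,
                exact_edge=exact_edge,
            )
        return self._workspaces[key]


@dataclass
class Constraint:
    """Freeze part of a profile over a depth range.

    kind : ``"fix_hydration"`` or ``"fix_sld"``
    value : the frozen hydration fraction or non-solvent SLD (1/Angstrom^2)
    """

    z_range: tuple[float, float]
    kind: str
    value: float

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if not lo < hi:
            raise ValueError("need z_lo < z_hi")
        if self.kind not in ("fix_hydration", "fix_sld"):
            raise ValueError("kind must be 'fix_hydration' or 'fix_sld'")
        if self.kind == "fix_hydration" and not 0.0 <= self.value <= 1.0:
            raise ValueError("fixed hydration must lie in [0, 1]")

    def layer_indices(self, D: float, N: int) -> np.ndarray:
        """Sub-layers whose centres fall inside the constrained range."""
        lo, hi = self.z_range
        if lo < 0 or hi > D:
            raise ValueError("constraint range must lie within [0, D]")
        centers = (np.arange(N) + 0.5) * (D / N)
        return np.nonzero((centers >= lo) & (centers <= hi))[0]


@dataclass
class AnnealSchedule:
    """Cooling schedule: T0 = 1, 100*N trials per temperature, T' = 0.9 T,
    stop after 100 consecutive rejections (global counter)."""

    t0: float = 1.0
    trials_per_layer: int = 100  # trials per temperature = trials_per_layer * N
    cooling: float = 0.9
    stop_rejections: int = 100
    t_min: float = 1e-6  # freeze-out floor: stop once T falls below this
    # greedy T = 0 polish after freeze-out: one stage per local step width,
    # each stopping after `quench_rejections` consecutive rejections or
    # `quench_blocks` trial blocks
    quench_widths: tuple = (0.1, 0.03, 0.01)
    quench_blocks: int = 10
    quench_rejections: int = 400
    # skip the remaining polish stages when the best score is still above
    # this after a stage: a run frozen in a structurally wrong basin cannot
    # be rescued by zero-temperature refinement
    quench_gate: float = 1e-2
    # independent cooling attempts per run (best frozen state is kept);
    # extra attempts trade wall time for basin-finding reliability
    cooling_attempts: int = 1
    max_temps: int = 4000
    max_trials: int = 50_000_000
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.t0 < 0 or self.trials_per_layer < 1 or self.stop_rejections < 1:
            raise ValueError("schedule parameters must be positive")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")

    @classmethod
    def fast(cls) -> "AnnealSchedule":
        """Reduced-effort schedule (15*N trials per temperature, cooling
        0.85, earlier freeze-out) for quick reconstructions and
        continuous-integration runs."""
        return cls(trials_per_layer=8, cooling=0.85, t_min=3e-5,
                   quench_blocks=6, quench_rejections=300,
                   cooling_attempts=2)


@dataclass
class AnnealResult:
    """Outcome of one annealing run."""

    model: InterfacialModel  # best-so-far model
    final_model: InterfacialModel
    f: float  # score of the best model
    f_final: float
    seed: int
    n_trials: int
    n_temps: int
    trace: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    aborted: bool = False


def _free_indices(
    D: float, N: int, constraints: Sequence[Constraint]
) -> tuple[np.ndarray, np.ndarray, list[tuple[np.ndarray, str, float]]]:
    fixed_rho = np.zeros(N, dtype=bool)
    fixed_h = np.zeros(N, dtype=bool)
    applied = []
    for con in constraints:
        idx = con.layer_indices(D, N)
        applied.append((idx, con.kind, con.value))
        if con.kind == "fix_sld":
            fixed_rho[idx] = True
        else:
            fixed_h[idx] = True
    free_rho = np.nonzero(~fixed_rho)[0].astype(np.int64)
    free_h = np.nonzero(~fixed_h)[0].astype(np.int64)
    if free_rho.size == 0 and free_h.size == 0:
        raise ValueError("model is fully constrained; nothing to anneal")
    return free_rho, free_h, applied


def score(model: InterfacialModel, config: ScoreConfig) -> float:
    """Score f >= 0 of a model against all contrasts; 0 iff the theoretical
    curves reproduce the experimental ones at every kept point."""
    ws = config.workspace(model.D, model.N)
    return float(
        _kernels.score_model(
            model.rho, model.h, model.sigma, ws.rho_fronting, ws.zb, ws.zsamp,
            ws.thick, ws.rho_solv, ws.qfine, ws.nfine, ws.idx, ws.w4, ws.wg,
            config.ndata, config.q4, config.q4rexp, config.logrexp, config.inorm,
            ws._plat_rho, ws._plat_h, ws._dry, ws._hyd, ws._estep, ws._sld,
            ws._rough0, ws._logbuf, ws._rs,
        )
    )


def propose_move(
    model: InterfacialModel,
    rng: np.random.Generator,
    move_mix: Optional[tuple[float, float, float]] = None,
    constraints: Sequence[Constraint] = (),
    local_frac: float = 0.5,
    local_width: float = 0.1,
) -> InterfacialModel:
    """One Metropolis trial: change exactly one free parameter within its
    admissible interval.

    With probability ``local_frac`` the change is a uniform step of
    half-width ``local_width`` times the interval, clipped to the bounds
    (the refinement move); otherwise the parameter is redrawn uniformly over
    the whole interval (the exploration move).  ``move_mix`` gives the
    probabilities of a rho-, h- and sigma-move; by default each free
    parameter is equally likely (so rho- and h-moves have probability
    ~N/(2N+1) each and the sigma-move 1/(2N+1))."""
    free_rho, free_h, _ = _free_indices(model.D, model.N, constraints)
    if model.q_max is None:
        raise ValueError("model.q_max must be set to bound sigma moves")
    n_free = free_rho.size + free_h.size + 1
    if move_mix is None:
        move_mix = (free_rho.size / n_free, free_h.size / n_free, 1.0 / n_free)
    trial = model.copy()
    u = rng.random()
    local = rng.random() < local_frac

    def draw(old, lo, hi):
        if local:
            return float(np.clip(old + rng.uniform(-1, 1) * local_width * (hi - lo),
                                 lo, hi))
        return rng.uniform(lo, hi)

    if u < move_mix[0] and free_rho.size:
        n = rng.choice(free_rho)
        trial.rho[n] = draw(trial.rho[n], model.rho_min, model.rho_max)
    elif u < move_mix[0] + move_mix[1] and free_h.size:
        n = rng.choice(free_h)
        trial.h[n] = draw(trial.h[n], 0.0, 1.0)
    else:
        lo, hi = np.pi / (4 * model.q_max), np.pi / (2 * model.q_max)
        trial.sigma = draw(trial.sigma, lo, hi)
    return trial


def _leading_invisible(
    rho: np.ndarray, h: np.ndarray, sigma: float, D: float,
    rho_fronting: float, tol_rho: float = 0.4e-6, tol_h: float = 0.15,
) -> int:
    """Number of sub-layers at the wall whose *smeared* profiles are
    optically indistinguishable from the fronting medium in every solvent
    contrast (dry, at the substrate's SLD).

    Such a region makes the profile translation-degenerate: shifting the
    structure deeper and filling the gap with substrate-like material leaves
    every reflectivity curve unchanged, so no multi-contrast data set can
    anchor the absolute position.  The canonical representative reported by
    the search is the one flush against the wall.  The test runs on the
    smeared profiles because, at large sigma, wiggly sub-layer values can
    average to an invisible region without any single layer matching the
    substrate."""
    from .profiles import InterfacialModel, smeared_component

    N = rho.size
    d = D / N
    model = InterfacialModel(D=D, rho=rho, h=np.clip(h, 0.0, 1.0),
                             sigma=sigma)
    zg = np.arange(0.25 * d, D, 0.5 * d)
    dry = smeared_component(model, zg, "sld", rho_fronting=rho_fronting)
    hyd = smeared_component(model, zg, "hydration")
    visible = (np.abs(dry - rho_fronting) > tol_rho) | (hyd > tol_h)
    if not visible.any():
        return 0
    z_first = zg[visible][0]
    return int(z_first // d)


def _build_model(
    ws: FitWorkspace, rho: np.ndarray, h: np.ndarray, sigma: float,
    rho_min: float, rho_max: float,
) -> InterfacialModel:
    return InterfacialModel(
        D=ws.D, rho=rho.copy(), h=np.clip(h, 0.0, 1.0), sigma=sigma,
        rho_min=rho_min, rho_max=rho_max, q_max=ws.q_max,
    )


def anneal_run(
    config: ScoreConfig,
    D: float,
    constraints: Sequence[Constraint] = (),
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
    N: int = 50,
    rho_min: float = -0.56e-6,
    rho_max: float = 6.35e-6,
    init_model: Optional[InterfacialModel] = None,
    local_frac: float = 0.8,
    sigma_weight: float = 10.0,
    subdivide: int = 2,
    search_subdivide: int = 1,
    coarse_N: Optional[int] = 25,
) -> AnnealResult:
    """One simulated-annealing run at fixed overall extension D.

    The profile starts from a random (rho_n, h_n) distribution honouring any
    constraints, with sigma = pi/(4 q_max).  The cooling stage uses fresh
    uniform draws (pure exploration, on the cheaper ``search_subdivide``
    engine sampling); once the schedule freezes out, a greedy T = 0 quench
    cascade polishes the solution on the accurate ``subdivide`` sampling
    with a mix of local steps of shrinking width (``schedule.quench_widths``,
    applied with probability ``local_frac``) and fresh draws.  The reported
    score is from the accurate sampling.  The run is bitwise deterministic
    given ``seed``.
    """
    schedule = schedule or AnnealSchedule()
    # cooling may search a reduced model; it always uses the exact
    # critical-edge evaluation, which encodes the absolute composite-SLD
    # levels that select the correct (rho, h) decomposition basin
    use_coarse = (
        coarse_N is not None and init_model is None
        and 0 < coarse_N < N and N % coarse_N == 0
    )
    N_cool = coarse_N if use_coarse else N
    ws = config.workspace(D, N_cool, subdivide=search_subdivide)
    smin, smax = ws.sigma_limits
    free_rho_c, free_h_c, applied_c = _free_indices(D, N_cool, constraints)

    rho = np.full(N_cool, 0.5 * (rho_min + rho_max))
    h = np.full(N_cool, 0.5)
    sigma0 = smin
    randomize = 1
    if init_model is not None:
        rho[:] = init_model.rho
        h[:] = init_model.h
        sigma0 = init_model.sigma
        randomize = 0
    for idx, kind, value in applied_c:
        if kind == "fix_sld":
            rho[idx] = value
        else:
            h[idx] = value

    def _move_mix(nfr: int, nfh: int) -> tuple[float, float]:
        # each free parameter equally likely, with the single global sigma
        # counted `sigma_weight` times (it couples to every layer, so a
        # higher draw rate helps escape wrong-smoothing basins)
        n_free = nfr + nfh + sigma_weight
        return nfr / n_free, nfh / n_free

    p_rho, p_h = _move_mix(free_rho_c.size, free_h_c.size)

    best_rho = np.empty(N_cool)
    best_h = np.empty(N_cool)
    mt = schedule.max_temps
    trace_T = np.empty(mt)
    trace_fcur = np.empty(mt)
    trace_fbest = np.empty(mt)
    trace_acc = np.zeros(mt, dtype=np.int64)

    def _score_args(w: FitWorkspace):
        return (
            w.rho_fronting, w.zb, w.zsamp, w.thick, w.rho_solv, w.qfine,
            w.nfine, w.idx, w.w4, w.wg, config.ndata, config.q4, config.q4rexp,
            config.logrexp, config.inorm, w._plat_rho, w._plat_h, w._dry,
            w._hyd, w._estep, w._sld, w._rough0, w._logbuf, w._rs,
        )

    n_attempts = schedule.cooling_attempts if init_model is None else 1
    init_rho = rho.copy()
    init_h = h.copy()
    best_f = np.inf
    n_temps = n_trials = 0
    for attempt in range(max(n_attempts, 1)):
        a_rho = init_rho.copy()
        a_h = init_h.copy()
        a_best_rho = np.empty(N_cool)
        a_best_h = np.empty(N_cool)
        # odd attempts start sigma mid-range: the wrong-smoothing trap
        # correlates with sigma frozen at its spec'd initial lower bound
        a_sigma0 = sigma0 if attempt % 2 == 0 else 0.5 * (smin + smax)
        a_f, a_sigma, a_f_final, a_sigma_final, a_temps, a_trials, abort = (
            _kernels.anneal_loop(
                (seed + 7919 * attempt) % 2**31, a_rho, a_h, a_sigma0,
                rho_min, rho_max, smin, smax,
                free_rho_c, free_h_c, p_rho, p_h, 0.0, 0.0,
                schedule.t0, schedule.trials_per_layer * N, schedule.cooling,
                schedule.stop_rejections, schedule.t_min, schedule.max_trials,
                randomize, *_score_args(ws),
                a_best_rho, a_best_h,
                trace_T[n_temps:], trace_fcur[n_temps:],
                trace_fbest[n_temps:], trace_acc[n_temps:],
            )
        )
        if abort:
            raise FloatingPointError(
                f"non-finite score during annealing run (seed={seed}); "
                f"trace up to temperature step {a_temps} retained"
            )
        n_temps += a_temps
        n_trials += a_trials
        if a_f < best_f:
            best_f, best_sigma = a_f, a_sigma
            f_final, sigma_final = a_f_final, a_sigma_final
            best_rho, best_h = a_best_rho, a_best_h
            rho, h = a_rho, a_h
    free_rho, free_h, applied = _free_indices(D, N, constraints)
    if use_coarse:
        # replicate the frozen coarse profile onto the full grid
        rep = N // N_cool
        rho = np.repeat(best_rho, rep)
        h = np.repeat(best_h, rep)
        for idx, kind, value in applied:
            if kind == "fix_sld":
                rho[idx] = value
            else:
                h[idx] = value
        best_rho = rho.copy()
        best_h = h.copy()
    p_rho, p_h = _move_mix(free_rho.size, free_h.size)
    traces = [
        (trace_T[:n_temps].copy(), trace_fcur[:n_temps].copy(),
         trace_fbest[:n_temps].copy(), trace_acc[:n_temps].copy()),
    ]
    if schedule.quench_widths:
        ws_fine = config.workspace(D, N, subdivide=subdivide)
        fine_args = _score_args(ws_fine)
        qb = schedule.quench_blocks
        for istage, width in enumerate(schedule.quench_widths):
            # greedy polish of the frozen state, resumed from the running best
            rho[:] = best_rho
            h[:] = best_h
            q_T = np.empty(qb)
            q_fcur = np.empty(qb)
            q_fbest = np.empty(qb)
            q_acc = np.zeros(qb, dtype=np.int64)
            (best_f, best_sigma, f_final, sigma_final, q_temps, q_trials,
             abort) = _kernels.anneal_loop(
                (seed + 1_000_003 * (istage + 1)) % 2**31, rho, h, best_sigma,
                rho_min, rho_max, smin, smax, free_rho, free_h, p_rho, p_h,
                local_frac, width, 0.0, schedule.trials_per_layer * N, 0.5,
                schedule.quench_rejections, -1.0, schedule.max_trials,
                0, *fine_args,
                best_rho, best_h, q_T, q_fcur, q_fbest, q_acc,
            )
            if abort:
                raise FloatingPointError(
                    f"non-finite score during quench (seed={seed})"
                )
            traces.append((np.zeros(q_temps), q_fcur[:q_temps].copy(),
                           q_fbest[:q_temps].copy(), q_acc[:q_temps].copy()))
            n_trials += q_trials
            n_temps += q_temps
            if best_f > schedule.quench_gate:
                break
        # translation degeneracy: a leading region indistinguishable from
        # the substrate (dry, substrate SLD) shifts the whole structure
        # without changing any curve; report the representative flush
        # against the wall and re-relax.  A fixed-SLD constraint anchors
        # the absolute position (such runs are left as found); a
        # fixed-hydration constraint of a dry region does not.
        anchored = any(kind == "fix_sld" for _, kind, _ in applied)
        for _ in range(0 if anchored else 3):
            if best_f > schedule.quench_gate:
                break
            shift = _leading_invisible(best_rho, best_h, best_sigma, D,
                                       ws_fine.rho_fronting)
            if shift <= 0:
                break
            best_rho = np.concatenate([best_rho[shift:],
                                       np.full(shift, best_rho[-1])])
            best_h = np.concatenate([best_h[shift:], np.ones(shift)])
            for idxc, kind, value in applied:
                if kind == "fix_sld":
                    best_rho[idxc] = value
                else:
                    best_h[idxc] = value
            for width in (0.02,):
                rho[:] = best_rho
                h[:] = best_h
                q_T = np.empty(qb)
                q_fcur = np.empty(qb)
                q_fbest = np.empty(qb)
                q_acc = np.zeros(qb, dtype=np.int64)
                (best_f, best_sigma, f_final, sigma_final, q_temps, q_trials,
                 abort) = _kernels.anneal_loop(
                    (seed + 7_368_787) % 2**31, rho, h, best_sigma,
                    rho_min, rho_max, smin, smax, free_rho, free_h, p_rho,
                    p_h, local_frac, width, 0.0,
                    schedule.trials_per_layer * N, 0.5,
                    schedule.quench_rejections, -1.0, schedule.max_trials,
                    0, *fine_args,
                    best_rho, best_h, q_T, q_fcur, q_fbest, q_acc,
                )
                if abort:
                    raise FloatingPointError(
                        f"non-finite score during re-relaxation (seed={seed})"
                    )
                # canonicalization is a reporting convention, not part of
                # the stochastic search: it does not enter the trace
                n_trials += q_trials
    trace = {
        "T": np.concatenate([t[0] for t in traces]),
        "f_current": np.concatenate([t[1] for t in traces]),
        "f_best": np.concatenate([t[2] for t in traces]),
        "accepted": np.concatenate([t[3] for t in traces]),
        "trials_per_T": np.full(n_temps, schedule.trials_per_layer * N),
    }
    logger.info(
        "anneal seed=%d: f_best=%.3e sigma=%.2f A, %d trials over %d "
        "temperature/quench blocks",
        seed, best_f, best_sigma, n_trials, n_temps,
    )
    return AnnealResult(
        model=_build_model(ws, best_rho, best_h, best_sigma, rho_min, rho_max),
        final_model=_build_model(ws, rho, h, sigma_final, rho_min, rho_max),
        f=float(best_f),
        f_final=float(f_final),
        seed=seed,
        n_trials=int(n_trials),
        n_temps=int(n_temps),
        trace=trace,
    )


def multi_run(
    config: ScoreConfig,
    D: float,
    constraints: Sequence[Constraint] = (),
    schedule: Optional[AnnealSchedule] = None,
    n_runs: int = 10,
    seeds: Optional[Sequence[int]] = None,
    **kwargs,
) -> tuple[AnnealResult, list[AnnealResult]]:
    """Independent annealing runs with distinct seeds; the run with the best
    (lowest) score is the final solution, all runs are retained for
    averaging."""
    if seeds is None:
        seeds = list(range(n_runs))
    seeds = list(seeds)
    if len(seeds) < 1:
        raise ValueError("need at least one run")
    results = [
        anneal_run(config, D, constraints, schedule, seed=s, **kwargs) for s in seeds
    ]
    best = min(results, key=lambda r: r.f)
    return best, results


@dataclass
class ProfileAverage:
    """Pointwise mean and spread of low-score reconstructions."""

    z: np.ndarray
    rho_mean: np.ndarray
    rho_std: np.ndarray
    h_mean: np.ndarray
    h_std: np.ndarray
    composite_mean: dict[str, np.ndarray]
    composite_std: dict[str, np.ndarray]
    included_seeds: list[int]
    excluded_seeds: list[int]


def average_profiles(
    results: Sequence[AnnealResult],
    contrasts: Sequence[ContrastCurve],
    f_threshold: float = 0.2,
    z_grid: Optional[np.ndarray] = None,
) -> ProfileAverage:
    """Average the reconstructions whose score lies within ``f_threshold``
    (relative) of the best run; reduces truncation rippling and estimates the
    profile variance.  With fewer than two qualifying runs the single best
    profile is returned with a warning."""
    if not results:
        raise ValueError("no annealing results given")
    fbest = min(r.f for r in results)
    keep = [r for r in results if r.f <= fbest * (1.0 + f_threshold)]
    keep_ids = {id(r) for r in keep}
    excluded = [r.seed for r in results if id(r) not in keep_ids]
    if len(keep) < 2:
        logger.warning(
            "only %d run(s) within %.0f%% of the best score; returning the "
            "single best profile without spread",
            len(keep), 100 * f_threshold,
        )
    ref = keep[0].model
    if z_grid is None:
        z_grid = np.arange(-20.0, ref.D + 20.0 + 0.5, 1.0)
    front = contrasts[0].rho_fronting
    rhos = np.array(
        [
            smeared_component(r.model, z_grid, "sld", rho_fronting=front)
            for r in keep
        ]
    )
    hs = np.array([smeared_component(r.model, z_grid, "hydration") for r in keep])
    comp_mean: dict[str, np.ndarray] = {}
    comp_std: dict[str, np.ndarray] = {}
    for c in contrasts:
        comps = np.array(
            [
                composite_sld(r.model, z_grid, c.rho_solvent, c.rho_fronting)
                for r in keep
            ]
        )
        name = c.label or f"solvent_{c.rho_solvent:g}"
        comp_mean[name] = comps.mean(axis=0)
        comp_std[name] = comps.std(axis=0)
    return ProfileAverage(
        z=z_grid,
        rho_mean=rhos.mean(axis=0),
        rho_std=rhos.std(axis=0),
        h_mean=hs.mean(axis=0),
        h_std=hs.std(axis=0),
        composite_mean=comp_mean,
        composite_std=comp_std,
        included_seeds=[r.seed for r in keep],
        excluded_seeds=excluded,
    )
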