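"""Inverting the diffusion-kurtosis representation: SDE degeneracy and the
DDE resolution.

At O(b^2) an SDE acquisition determines only the axially symmetric DK
quintuple (D_par, D_perp, W_par, W_perp, W_mean).  Substituting

    alpha = f Da + (1-f) De_anis,       beta    = (1-f) De_perp,
    gamma = f Da^2 + (1-f) De_anis^2,   delta   = (1-f) De_anis De_perp,
    epsilon = (1-f) De_perp^2,

turns the five moment equations into two linear systems — a 2x2 system L
for (alpha, beta) and a 3x3 system M for (gamma, delta, epsilon) — whose
coefficients depend only on kappa (det L = p2, det M = -p2 p4 / 2, so both
are invertible whenever kappa > 0).  The five auxiliaries derive from just
four kernel parameters, giving one scalar *coupling equation*

    gamma (epsilon - beta^2) = alpha^2 epsilon + delta^2 - 2 alpha beta delta,

whose real roots in kappa enumerate every biophysical parameter set sharing
the DK representation — the SDE degeneracy.  Empirically the root count is
1, 2 or 4.

A DDE acquisition additionally measures the covariance invariants zeta1,
zeta2, which single out kappa as the unique root of

    h4(1,k)/h4(0,k) = [W_par Dbar^2/3 - (3/2)(zeta1+zeta2) + (D_par-D_perp)^2]
                      / [W_perp Dbar^2/3 - (3/2) zeta2],

the left-hand side being strictly increasing in kappa.  With kappa fixed the
back-map f = 1 - beta^2/epsilon, Da = (alpha epsilon - beta delta)/(epsilon -
beta^2), De_anis = delta/beta, De_perp = epsilon/beta is single-valued, so
the DDE inverse problem is injective (except the fully isotropic kappa = 0,
a proper degeneracy of the model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cumulants import XI_MEAN, AxisymDK, CInvariants, axisym_dk
from .forward_model import ModelParams
from .watson import c2_of_kappa, h2, h4, kappa_of_c2

__all__ = [
    "ReparamVars",
    "CandidateSolution",
    "SolutionSet",
    "reparam",
    "solve_dk_systems",
    "coupling_residual",
    "enumerate_sde_solutions",
    "recover_bp",
    "unique_kappa_dde",
    "census_solution_counts",
    "sample_feasible_params",
    "BoundaryCaseError",
]

KAPPA_MAX_DEFAULT = 1e3
_SCAN_POINTS = 4000


class BoundaryCaseError(ValueError):
    """Back-map hit the apparent-degeneracy boundary f = 0 or f = 1."""


@dataclass(frozen=True)
class ReparamVars:
    """The five auxiliary variables (alpha, beta: um^2/ms; rest um^4/ms^2)."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float

    def coupling_residual(self) -> float:
        a, b, g, d, e = self.alpha, self.beta, self.gamma, self.delta, self.epsilon
        return g * (e - b * b) - (a * a * e + d * d - 2.0 * a * b * d)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta, self.epsilon])


@dataclass(frozen=True)
class CandidateSolution:
    params: ModelParams
    kappa: float
    feasible: bool
    dk_residual: float


@dataclass
class SolutionSet:
    source: AxisymDK
    candidates: list[CandidateSolution]
    kappa_roots: list[float]

    @property
    def n_solutions(self) -> int:
        return len(self.kappa_roots)

    @property
    def n_feasible(self) -> int:
        return sum(c.feasible for c in self.candidates)

    def thetas(self) -> np.ndarray:
        return np.stack([c.params.theta() for c in self.candidates]) if self.candidates else np.empty((0, 5))


def reparam(params: ModelParams) -> ReparamVars:
    """Definitional map from biophysical parameters to the auxiliaries."""
    f, da, de = params.f, params.Da, params.delta_e
    det = params.De_perp
    return ReparamVars(
        alpha=f * da + (1 - f) * de,
        beta=(1 - f) * det,
        gamma=f * da**2 + (1 - f) * de**2,
        delta=(1 - f) * de * det,
        epsilon=(1 - f) * det**2,
    )


def _dk_rhs(dk: AxisymDK) -> tuple[np.ndarray, np.ndarray]:
    dbar2 = dk.D_mean**2
    rhs_l = np.array([dk.D_par, dk.D_perp])
    rhs_m = np.array(
        [
            dk.W_par * dbar2 / 3.0 + dk.D_par**2,
            dk.W_perp * dbar2 / 3.0 + dk.D_perp**2,
            (5.0 / 8.0) * dk.W_mean * dbar2
            - 0.25 * dk.W_perp * dbar2
            - dk.W_par * dbar2 / 24.0
            + 0.25 * (dk.D_par + dk.D_perp) ** 2,
        ]
    )
    return rhs_l, rhs_m


def system_matrices(kappa) -> tuple[np.ndarray, np.ndarray]:
    """L (2x2) and M (3x3) coefficient matrices at concentration kappa.

    Rows evaluate the projection moments at xi = 1, 0 (and 1/sqrt(2) for M).
    Vectorized: a kappa array of shape (n,) yields (n,2,2) and (n,3,3).
    """
    k = np.asarray(kappa, float)
    xi = np.array([1.0, 0.0, XI_MEAN])
    h2v = np.stack([np.broadcast_to(h2(x, k), k.shape) for x in xi], axis=-1)
    h4v = np.stack([np.broadcast_to(h4(x, k), k.shape) for x in xi], axis=-1)
    ones = np.ones_like(h2v[..., 0])
    L = np.stack(
        [
            np.stack([h2v[..., 0], ones], axis=-1),
            np.stack([h2v[..., 1], ones], axis=-1),
        ],
        axis=-2,
    )
    M = np.stack(
        [
            np.stack([h4v[..., i], 2.0 * h2v[..., i], ones], axis=-1)
            for i in range(3)
        ],
        axis=-2,
    )
    return L, M


def solve_dk_systems(dk: AxisymDK, kappa: float) -> ReparamVars:
    """Solve the decoupled linear systems for the auxiliaries at given kappa."""
    if kappa <= 0:
        raise ValueError("the linear systems are singular at kappa = 0")
    L, M = system_matrices(float(kappa))
    rhs_l, rhs_m = _dk_rhs(dk)
    ab = np.linalg.solve(L, rhs_l)
    gde = np.linalg.solve(M, rhs_m)
    return ReparamVars(ab[0], ab[1], gde[0], gde[1], gde[2])


def _vars_on_grid(dk: AxisymDK, kappas: np.ndarray) -> np.ndarray:
    """(n, 5) array of (alpha..epsilon) across a kappa grid, via Cramer."""
    h21 = h2(1.0, kappas)
    h20 = h2(0.0, kappas)
    h2m = h2(XI_MEAN, kappas)
    h41 = h4(1.0, kappas)
    h40 = h4(0.0, kappas)
    h4m = h4(XI_MEAN, kappas)
    rhs_l, rhs_m = _dk_rhs(dk)
    det_l = h21 - h20
    alpha = (rhs_l[0] - rhs_l[1]) / det_l
    beta = (rhs_l[1] * h21 - rhs_l[0] * h20) / det_l
    # Cramer for the 3x3 system with columns (h4, 2 h2, 1)
    a1, a2, a3 = h41, h40, h4m
    b1, b2, b3 = 2 * h21, 2 * h20, 2 * h2m
    r1, r2, r3 = rhs_m
    det_m = a1 * (b2 - b3) - b1 * (a2 - a3) + (a2 * b3 - a3 * b2)
    gamma = (r1 * (b2 - b3) - b1 * (r2 - r3) + (r2 * b3 - r3 * b2)) / det_m
    delta = (a1 * (r2 - r3) - r1 * (a2 - a3) + (a2 * r3 - a3 * r2)) / det_m
    eps = (a1 * (b2 * r3 - b3 * r2) - b1 * (a2 * r3 - a3 * r2) + r1 * (a2 * b3 - a3 * b2)) / det_m
    return np.stack([alpha, beta, gamma, delta, eps], axis=-1)


def coupling_residual(kappa, dk: AxisymDK):
    """Residual of the coupling equation at trial kappa (um^6/ms^3 scale).

    Zero exactly at kappa values whose auxiliaries are consistent with some
    biophysical parameter set; vectorized over kappa.
    """
    k = np.atleast_1d(np.asarray(kappa, float))
    if np.any(k <= 0):
        raise ValueError("coupling residual requires kappa > 0")
    v = _vars_on_grid(dk, k)
    a, b, g, d, e = (v[..., i] for i in range(5))
    r = g * (e - b * b) - (a * a * e + d * d - 2.0 * a * b * d)
    return r if np.ndim(kappa) else float(r[0])


def recover_bp(
    dk: AxisymDK,
    kappa: float,
    mu=(0.0, 0.0, 1.0),
    S0: float = 1.0,
    clip: bool = True,
) -> ModelParams:
    """Back-map auxiliaries at a kappa root to biophysical parameters.

    Raises :class:`BoundaryCaseError` for epsilon <= 0 or epsilon = beta^2,
    which correspond to the apparent degeneracies f = 0 / f = 1.  With
    ``clip`` (default) small negative round-off in f, Da is clamped to the
    physical boundary; genuinely infeasible values are preserved so callers
    can flag them.
    """
    v = solve_dk_systems(dk, kappa)
    a, b, g, d, e = v.alpha, v.beta, v.gamma, v.delta, v.epsilon
    if e <= 0 or abs(e - b * b) < 1e-14 * max(1.0, e):
        raise BoundaryCaseError(
            "epsilon <= 0 or epsilon = beta^2: apparent degeneracy f = 0 or f = 1"
        )
    if abs(b) < 1e-14:
        raise BoundaryCaseError("beta = 0: single-compartment boundary f = 1")
    f = 1.0 - b * b / e
    da = (a * e - b * d) / (e - b * b)
    de_anis = d / b
    de_perp = e / b
    de_par = de_anis + de_perp
    if clip:
        tol = 1e-9
        if -tol < f < 0:
            f = 0.0
        if 1 < f < 1 + tol:
            f = 1.0
        if -tol < da < 0:
            da = 0.0
    return _raw_params(f, da, de_par, de_perp, kappa, mu, S0)


def _raw_params(f, da, de_par, de_perp, kappa, mu, S0) -> ModelParams:
    """ModelParams that may violate feasibility bounds (validation bypassed)."""
    p = object.__new__(ModelParams)
    mu_v = np.asarray(mu, float)
    mu_v = mu_v / np.linalg.norm(mu_v)
    for name, val in (
        ("f", float(f)),
        ("Da", float(da)),
        ("De_par", float(de_par)),
        ("De_perp", float(de_perp)),
        ("kappa", float(kappa)),
        ("mu", mu_v),
        ("S0", float(S0)),
    ):
        object.__setattr__(p, name, val)
    return p


def _is_feasible(p: ModelParams) -> bool:
    return 0.0 < p.f < 1.0 and p.Da >= 0.0 and p.De_par >= 0.0 and p.De_perp >= 0.0


_grid_cache: dict = {}


def _kappa_grid(kappa_max: float, n: int) -> np.ndarray:
    """Grid uniform in c2 on (1/3, c2(kappa_max)), mapped back to kappa."""
    key = (kappa_max, n)
    if key not in _grid_cache:
        table_k = np.geomspace(1e-8, kappa_max, 30000)
        table_c2 = c2_of_kappa(table_k)
        c2_hi = float(table_c2[-1])
        c2g = np.linspace(1.0 / 3.0 + 1e-9, c2_hi, n)
        _grid_cache[key] = np.interp(c2g, table_c2, table_k)
    return _grid_cache[key]


def enumerate_sde_solutions(
    dk: AxisymDK,
    kappa_max: float = KAPPA_MAX_DEFAULT,
    n_grid: int = _SCAN_POINTS,
    mu=(0.0, 0.0, 1.0),
    S0: float = 1.0,
) -> SolutionSet:
    """All biophysical parameter sets sharing one DK representation.

    Scans the coupling residual on a grid uniform in c2, brackets sign
    changes, polishes each root with Brent's method, deduplicates (1e-4
    relative in kappa) and back-maps each root, flagging feasibility.
    Tangential (double) roots where the residual touches zero without a
    sign change — the generic situation as De_perp -> 0 — are located as
    local minima of |residual| and accepted only if the back-mapped
    parameters reproduce the source DK values.  Boundary roots (f = 0 /
    f = 1 apparent degeneracies) are skipped.
    """
    from scipy.optimize import minimize_scalar

    grid = _kappa_grid(kappa_max, n_grid)
    res = coupling_residual(grid, dk)
    sign = np.sign(res)
    roots: list[float] = []
    idx = np.flatnonzero((sign[:-1] * sign[1:]) < 0)
    for i in idx:
        r = brentq(
            lambda k: coupling_residual(k, dk),
            grid[i],
            grid[i + 1],
            xtol=1e-14,
            rtol=1e-12,
        )
        roots.append(float(r))
    roots.extend(float(grid[i]) for i in np.flatnonzero(res == 0.0))

    # tangential candidates: interior local minima of |residual|
    tangential: list[float] = []
    absr = np.abs(res)
    local_min = np.flatnonzero((absr[1:-1] <= absr[:-2]) & (absr[1:-1] <= absr[2:])) + 1
    for i in local_min:
        if sign[i - 1] * sign[i + 1] < 0:
            continue  # already captured as a sign change
        opt = minimize_scalar(
            lambda k: float(coupling_residual(k, dk)) ** 2,
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        tangential.append(float(opt.x))

    bracketed = set(roots)
    roots_all = sorted(roots + tangential)
    dedup: list[float] = []
    for r in roots_all:
        if not dedup or abs(r - dedup[-1]) > 1e-4 * max(1.0, abs(dedup[-1])):
            dedup.append(r)

    candidates = []
    kept_roots = []
    dk_arr = dk.as_array()
    dk_scale = max(1.0, float(np.max(np.abs(dk_arr))))
    for r in dedup:
        try:
            p = recover_bp(dk, r, mu=mu, S0=S0)
        except BoundaryCaseError:
            continue
        if not np.isfinite(p.theta()).all():
            continue
        try:
            back = axisym_dk(p)
        except ValueError:
            continue
        resid = float(np.max(np.abs(back.as_array() - dk_arr)))
        # tangential candidates are only minima of |residual|: accept them
        # solely when the back-map closes; bracketed sign changes are true
        # zeros and are kept regardless of round-off in the closure check
        if r not in bracketed and resid > 1e-6 * dk_scale:
            continue
        kept_roots.append(r)
        candidates.append(
            CandidateSolution(params=p, kappa=r, feasible=_is_feasible(p), dk_residual=resid)
        )
    return SolutionSet(source=dk, candidates=candidates, kappa_roots=kept_roots)


def unique_kappa_dde(
    dk: AxisymDK,
    inv: CInvariants,
    kappa_min: float = 1e-6,
    kappa_max: float = 1e6,
) -> float:
    """The unique concentration consistent with DK values plus C invariants.

    Solves h4(1,k)/h4(0,k) = target by monotone bracketing; the target is
    built from the DK quintuple and the two invariants.  Raises on fully
    isotropic input (D_par = D_perp), the proper degeneracy where the
    orientation concentration is undetermined.
    """
    dbar2 = dk.D_mean**2
    if abs(dk.D_par - dk.D_perp) < 1e-12 * max(1.0, abs(dk.D_par)):
        raise ValueError(
            "isotropic DK input: kappa is undetermined (proper model degeneracy)"
        )
    num = (
        dk.W_par * dbar2 / 3.0
        - 1.5 * (inv.zeta1 + inv.zeta2)
        + (dk.D_par - dk.D_perp) ** 2
    )
    den = dk.W_perp * dbar2 / 3.0 - 1.5 * inv.zeta2
    if den == 0.0:
        raise ValueError("degenerate invariant combination (zero denominator)")
    target = num / den

    def g(k: float) -> float:
        return float(h4(1.0, k) / h4(0.0, k)) - target

    lo, hi = kappa_min, kappa_max
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ValueError("target ratio outside the attainable range of h4(1)/h4(0)")
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=1e-13))


def sample_feasible_params(
    n: int,
    seed: int,
    diff_max: float = 3.0,
    c2_range: tuple[float, float] = (1.0 / 3.0 + 1e-3, 0.98),
) -> list[ModelParams]:
    """Uniform sampler over the feasible biophysical region.

    f ~ U(0,1), each diffusivity ~ U(0, diff_max) um^2/ms, and kappa drawn
    via c2 uniform on ``c2_range`` (matching the dispersion range spanned by
    the in-silico experiments).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xCE25]))
    out = []
    for _ in range(n):
        f = rng.uniform(0.0, 1.0)
        da, de_par, de_perp = rng.uniform(0.0, diff_max, size=3)
        kappa = kappa_of_c2(rng.uniform(*c2_range))
        out.append(ModelParams(f=f, Da=da, De_par=de_par, De_perp=de_perp, kappa=kappa))
    return out


def census_solution_counts(
    n: int,
    seed: int,
    kappa_max: float = KAPPA_MAX_DEFAULT,
    n_grid: int = _SCAN_POINTS,
    sampler=sample_feasible_params,
) -> dict:
    """Distribution of SDE solution counts over random feasible parameters.

    Returns proportions keyed by root count for all real roots and for the
    feasibility-filtered subset, plus raw tallies.
    """
    params = sampler(n, seed)
    counts_all: dict[int, int] = {}
    counts_feas: dict[int, int] = {}
    anomalies: list[dict] = []
    for p in params:
        sols = enumerate_sde_solutions(axisym_dk(p), kappa_max=kappa_max, n_grid=n_grid)
        counts_all[sols.n_solutions] = counts_all.get(sols.n_solutions, 0) + 1
        counts_feas[sols.n_feasible] = counts_feas.get(sols.n_feasible, 0) + 1
        if sols.n_solutions not in (1, 2, 4):
            # theory expects 1/2/4; other counts arise from merged (double)
            # roots at the f -> 0 / De_perp -> 0 boundaries and are logged
            anomalies.append(
                {"theta": p.theta().tolist(), "n_solutions": sols.n_solutions,
                 "kappa_roots": sols.kappa_roots}
            )
    return {
        "n": n,
        "proportions": {k: v / n for k, v in sorted(counts_all.items())},
        "proportions_feasible": {k: v / n for k, v in sorted(counts_feas.items())},
        "counts": dict(sorted(counts_all.items())),
        "anomalies": anomalies,
    }
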