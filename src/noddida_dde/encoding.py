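"""Diffusion-encoding b-tensors and acquisition schemes.

A double diffusion encoding (DDE) measurement applies two gradient pairs
with individual weightings ``b1, b2`` along directions ``n1, n2``.  For
multi-Gaussian tissue the acquisition is fully described by the symmetric
b-tensor

    B = b1 n1 (x) n1 + b2 n2 (x) n2,      b = tr(B).

Parallel pairs (n1 = n2) give rank-1 *linear* tensors, identical to a single
diffusion encoding (SDE) at the summed b; perpendicular pairs with equal
weightings give axially symmetric *planar* tensors (b/2)(I - v v^T), fully
determined by their normal ``v = n1 x n2``.

The protocol families DDEa+b mix ``a`` parallel and ``b`` perpendicular
direction pairs (a + b = 60) over two shells at b = 1 and 2 ms/um^2, plus
five b = 0 measurements.  DDE60+0 is therefore an ordinary two-shell SDE
protocol and DDE0+60 is purely planar.

Directions are spread by electrostatic-repulsion minimization on
antipodally symmetrized point sets, seeded and deterministic; the achieved
minimum (antipodal) pairwise angle is recorded on the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BTensor",
    "Measurement",
    "AcquisitionScheme",
    "btensor_from_pair",
    "uniform_directions",
    "min_antipodal_angle",
    "build_scheme",
    "PROTOCOL_NAMES",
]

PROTOCOL_NAMES = ("DDE60+0", "DDE40+20", "DDE30+30", "DDE20+40", "DDE0+60")

_Shape = Literal["linear", "planar", "zero", "general"]


def _unit(v, tol=1e-6, what="direction"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ValueError(f"{what} must be a unit vector (|v| = {n!r})")
    return v / n


def _classify(matrix: np.ndarray, tol: float = 1e-10) -> _Shape:
    b = float(np.trace(matrix))
    if b <= tol:
        return "zero"
    ev = np.linalg.eigvalsh(matrix)  # ascending
    if ev[0] < -tol:
        raise ValueError("b-tensor must be positive semidefinite")
    if ev[1] <= tol * max(1.0, b):
        return "linear"
    if ev[0] <= tol * max(1.0, b) and abs(ev[1] - ev[2]) <= tol * max(1.0, b):
        return "planar"
    return "general"


@dataclass(frozen=True)
class BTensor:
    """Symmetric 3x3 diffusion-encoding tensor, units ms/um^2."""

    matrix: np.ndarray
    shape: _Shape = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("b-tensor matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-14, rtol=0.0):
            raise ValueError("b-tensor matrix must be symmetric")
        m = 0.5 * (m + m.T)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        if self.shape is None:
            object.__setattr__(self, "shape", _classify(m))

    @property
    def b(self) -> float:
        """Total diffusion weighting tr(B)."""
        return float(np.trace(self.matrix))

    @property
    def principal_axis(self) -> np.ndarray:
        """Eigenvector of the largest eigenvalue (linear axis)."""
        w, v = np.linalg.eigh(self.matrix)
        return v[:, -1]

    @property
    def planar_normal(self) -> np.ndarray:
        """For planar tensors, the unit normal of the encoding plane."""
        if self.shape != "planar":
            raise ValueError("planar_normal is defined for planar tensors only")
        w, v = np.linalg.eigh(self.matrix)
        return v[:, 0]

    @classmethod
    def zero(cls) -> "BTensor":
        return cls(np.zeros((3, 3)), shape="zero")

    @classmethod
    def linear(cls, b: float, axis) -> "BTensor":
        axis = _unit(axis)
        return cls(b * np.outer(axis, axis), shape="linear")

    @classmethod
    def planar(cls, b: float, normal) -> "BTensor":
        normal = _unit(normal)
        return cls(0.5 * b * (np.eye(3) - np.outer(normal, normal)), shape="planar")


def btensor_from_pair(b1: float, n1, b2: float, n2) -> BTensor:
    """b-tensor of a DDE gradient pair, B = b1 n1(x)n1 + b2 n2(x)n2."""
    if b1 < 0 or b2 < 0:
        raise ValueError("individual weightings must be non-negative")
    if b1 + b2 == 0.0:
        return BTensor.zero()
    n1 = _unit(n1, what="n1")
    n2 = _unit(n2, what="n2")
    return BTensor(b1 * np.outer(n1, n1) + b2 * np.outer(n2, n2))


@dataclass(frozen=True)
class Measurement:
    """One acquisition: a b-tensor plus its (optional) gradient-pair provenance."""

    btensor: BTensor
    pair: tuple[float, np.ndarray, float, np.ndarray] | None = None
    shell: int = 0

    def __post_init__(self):
        if self.pair is not None:
            b1, n1, b2, n2 = self.pair
            ref = btensor_from_pair(b1, n1, b2, n2)
            if not np.allclose(ref.matrix, self.btensor.matrix, atol=1e-12):
                raise ValueError("pair provenance inconsistent with b-tensor")


@dataclass
class AcquisitionScheme:
    """Ordered list of measurements defining one protocol."""

    measurements: list[Measurement]
    name: str = ""
    min_angle_deg: float | None = None

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def btensors(self) -> np.ndarray:
        """(N, 3, 3) stack of b-tensor matrices."""
        return np.stack([m.btensor.matrix for m in self.measurements])

    @property
    def bvalues(self) -> np.ndarray:
        return np.array([m.btensor.b for m in self.measurements])

    def counts(self) -> dict:
        """Number of measurements per shape per shell."""
        out: dict = {}
        for m in self.measurements:
            key = (m.btensor.shape, m.shell)
            out[key] = out.get(key, 0) + 1
        return out

    def rotated(self, rot: np.ndarray) -> "AcquisitionScheme":
        """Scheme with every b-tensor conjugated by the rotation matrix."""
        ms = []
        for m in self.measurements:
            bt = BTensor(rot @ m.btensor.matrix @ rot.T, shape=m.btensor.shape)
            ms.append(Measurement(bt, pair=None, shell=m.shell))
        return AcquisitionScheme(ms, name=self.name, min_angle_deg=self.min_angle_deg)


def min_antipodal_angle(directions: np.ndarray) -> float:
    """Minimum pairwise angle in degrees, identifying u with -u."""
    d = np.asarray(directions, float)
    if len(d) < 2:
        return 180.0
    dots = np.abs(d @ d.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))


def _repulsion_energy_grad(flat: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """Electrostatic (1/d^2) energy over points and antipodes, with gradient."""
    x = flat.reshape(n, 3)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / norms
    e = 0.0
    g_u = np.zeros_like(u)
    iu = np.triu_indices(n, k=1)
    for sign in (1.0, -1.0):
        diff = u[:, None, :] - sign * u[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2, np.inf)
        e += np.sum(1.0 / d2[iu]) if sign > 0 else 0.5 * np.sum(1.0 / d2)
        # d/du_p 1/|u_p -+ u_q|^2 = -2 (u_p -+ u_q)/|.|^4 for both pair types
        w = 1.0 / d2**2
        g_u += -2.0 * np.einsum("ij,ijk->ik", w, diff)
    # project through the normalization u = x / |x|
    g_x = (g_u - np.einsum("ik,ik->i", g_u, u)[:, None] * u) / norms
    return float(e), g_x.ravel()


def uniform_directions(n: int, seed: int = 0) -> np.ndarray:
    """``n`` unit vectors spread by antipodal electrostatic repulsion.

    Points repel both every other point and all antipodes, the standard
    construction for diffusion gradient tables.  Deterministic for a fixed
    seed (fixed random start, deterministic local minimization).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), n, 0x5D]))
    if n == 1:
        x0 = rng.standard_normal((1, 3))
        return x0 / np.linalg.norm(x0)
    best = None
    for _ in range(4):  # few restarts: the energy landscape has local minima
        x0 = rng.standard_normal((n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = minimize(
            _repulsion_energy_grad,
            x0.ravel(),
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x.reshape(n, 3)
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere + stable ordering for reproducible files
    flip = x[:, 2] < 0
    flip |= (x[:, 2] == 0) & (x[:, 1] < 0)
    x[flip] *= -1.0
    order = np.lexsort((x[:, 0], x[:, 1], x[:, 2]))
    return x[order]


def _perp_pair(normal: np.ndarray, seed_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal pair spanning the plane normal to ``normal``."""
    ref = seed_vec if abs(np.dot(seed_vec, normal)) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = ref - np.dot(ref, normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def build_scheme(
    config: str,
    b_values: Sequence[float] = (1.0, 2.0),
    n_dir_per_shell: int = 30,
    n_b0: int = 5,
    seed: int = 0,
) -> AcquisitionScheme:
    """Build one of the DDEa+b protocols (a parallel + b perpendicular pairs).

    Each shell carries ``n_dir_per_shell`` direction pairs with individual
    weightings b1 = b2 = b/2; the parallel:perpendicular split follows the
    protocol name and is applied per shell (e.g. DDE40+20 -> 20 parallel +
    10 perpendicular pairs on each of the two shells).  For DDE30+30 the
    perpendicular normals coincide with the parallel directions; otherwise
    a fresh homogeneous normal set is generated with the same algorithm.
    """
    if config not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol {config!r}; expected one of {PROTOCOL_NAMES}")
    a_total, b_total = (int(s) for s in config[3:].split("+"))
    total = a_total + b_total
    n_shells = len(b_values)
    if (a_total * n_dir_per_shell) % total or (b_total * n_dir_per_shell) % total:
        raise ValueError("per-shell direction count incompatible with protocol split")
    n_par = a_total * n_dir_per_shell // total
    n_perp = b_total * n_dir_per_shell // total

    measurements = [Measurement(BTensor.zero(), pair=None, shell=0) for _ in range(n_b0)]
    min_angles = []
    for i_shell, b in enumerate(b_values, start=1):
        par_dirs = uniform_directions(n_par, seed=seed + 101 * i_shell) if n_par else np.empty((0, 3))
        if n_perp == 0:
            normals = np.empty((0, 3))
        elif n_par == n_perp:
            normals = par_dirs  # perpendicular-pair normals reuse the parallel set
        else:
            normals = uniform_directions(n_perp, seed=seed + 101 * i_shell + 17)
        for d in par_dirs:
            bt = BTensor.linear(b, d)
            measurements.append(Measurement(bt, pair=(b / 2, d, b / 2, d), shell=i_shell))
        for v in normals:
            n1, n2 = _perp_pair(v, np.array([0.0, 0.0, 1.0]))
            bt = BTensor.planar(b, v)
            measurements.append(Measurement(bt, pair=(b / 2, n1, b / 2, n2), shell=i_shell))
        for d in (par_dirs, normals):
            if len(d) > 1:
                min_angles.append(min_antipodal_angle(d))
    return AcquisitionScheme(
        measurements,
        name=config,
        min_angle_deg=min(min_angles) if min_angles else None,
    )
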