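"""Bound-constrained optimizer test suite, CEC2022-style.

Twelve functions on [-100, 100]^d: three shifted/rotated unimodal (F1-F3),
five shifted/rotated multimodal (F4-F8) and four composite functions (F9-F12)
built from >= 3 basic components with distinct shifts, combined with
distance-based normalized weights.  Shifts are drawn uniformly inside the
central 80% of the box and rotations come from QR decompositions of seeded
Gaussian matrices, so the whole suite is reproducible from one seed.

Every function's global optimum value is 0: for F1-F8 the optimum sits at the
shift vector; for composites it sits at the first component's shift (which
carries zero composition bias).  The official competition shift/rotation data
files are deliberately not used; this is a structurally equivalent seeded
suite intended for *relative* algorithm comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["BenchmarkFunction", "make_suite", "evaluate_batch"]

BOUND = 100.0
_SCHWEFEL_OFFSET = 4.209687462275036e2
_SCHWEFEL_CONST = 4.189828872724338e2


# ----------------------------------------------------------------------------
# Basic functions.  Each takes an (n, d) matrix z and returns n values, with
# global minimum 0 at z = 0 (internal offsets handle optima away from origin).
# ----------------------------------------------------------------------------

def _zakharov(z: np.ndarray) -> np.ndarray:
    s1 = (z ** 2).sum(axis=1)
    s2 = (0.5 * np.arange(1, z.shape[1] + 1) * z).sum(axis=1)
    return s1 + s2 ** 2 + s2 ** 4


def _rosenbrock(z: np.ndarray) -> np.ndarray:
    y = z + 1.0  # optimum of the classic form is at (1, ..., 1)
    return (100.0 * (y[:, :-1] ** 2 - y[:, 1:]) ** 2
            + (y[:, :-1] - 1.0) ** 2).sum(axis=1)


def _elliptic(z: np.ndarray) -> np.ndarray:
    d = z.shape[1]
    w = 1e6 ** (np.arange(d) / (d - 1))
    return (w * z ** 2).sum(axis=1)


def _rastrigin(z: np.ndarray) -> np.ndarray:
    return (z ** 2 - 10.0 * np.cos(2.0 * np.pi * z) + 10.0).sum(axis=1)


def _levy(z: np.ndarray) -> np.ndarray:
    w = 1.0 + z / 4.0  # optimum of the classic form is at (1, ..., 1)
    term1 = np.sin(np.pi * w[:, 0]) ** 2
    term3 = (w[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * w[:, -1]) ** 2)
    wi = w[:, :-1]
    mid = ((wi - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * wi + 1.0) ** 2)).sum(axis=1)
    return term1 + mid + term3


def _schaffer_f7(z: np.ndarray) -> np.ndarray:
    d = z.shape[1]
    s = np.sqrt(z[:, :-1] ** 2 + z[:, 1:] ** 2)
    t = np.sqrt(s) + np.sqrt(s) * np.sin(50.0 * s ** 0.2) ** 2
    return (t.sum(axis=1) / (d - 1)) ** 2


def _griewank_rosenbrock(z: np.ndarray) -> np.ndarray:
    y = z + 1.0
    ynext = np.roll(y, -1, axis=1)
    t = 100.0 * (y ** 2 - ynext) ** 2 + (y - 1.0) ** 2
    return (t ** 2 / 4000.0 - np.cos(t) + 1.0).sum(axis=1)


def _schwefel(z: np.ndarray) -> np.ndarray:
    d = z.shape[1]
    w = z + _SCHWEFEL_OFFSET
    g = np.empty_like(w)
    inside = np.abs(w) <= 500.0
    g[inside] = w[inside] * np.sin(np.sqrt(np.abs(w[inside])))
    hi = w > 500.0
    if hi.any():
        m = 500.0 - np.mod(w[hi], 500.0)
        g[hi] = m * np.sin(np.sqrt(np.abs(m))) - (w[hi] - 500.0) ** 2 / (10000.0 * d)
    lo = w < -500.0
    if lo.any():
        m = np.mod(np.abs(w[lo]), 500.0) - 500.0
        g[lo] = m * np.sin(np.sqrt(np.abs(m))) - (w[lo] + 500.0) ** 2 / (10000.0 * d)
    return _SCHWEFEL_CONST * d - g.sum(axis=1)


# (callable, input scale): z is multiplied by scale after shift/rotation so the
# interesting landscape of each classic function fits the [-100, 100] box.
_BASIC: dict[str, tuple[Callable[[np.ndarray], np.ndarray], float]] = {
    "zakharov": (_zakharov, 1.0),
    "rosenbrock": (_rosenbrock, 2.048 / 100.0),
    "elliptic": (_elliptic, 1.0),
    "rastrigin": (_rastrigin, 5.12 / 100.0),
    "levy": (_levy, 5.12 / 100.0),
    "schaffer_f7": (_schaffer_f7, 0.5),
    "griewank_rosenbrock": (_griewank_rosenbrock, 5.0 / 100.0),
    "schwefel": (_schwefel, 10.0),
}


@dataclass(frozen=True)
class _Component:
    base: str
    shift: np.ndarray
    rotation: np.ndarray
    sigma: float = 1.0      # composition locality width
    lam: float = 1.0        # per-component value scaling
    bias: float = 0.0       # composition bias (0 for the optimal component)

    def raw(self, x: np.ndarray) -> np.ndarray:
        fn, scale = _BASIC[self.base]
        z = (x - self.shift) @ self.rotation.T * scale
        return fn(z)


@dataclass(frozen=True)
class BenchmarkFunction:
    """One suite member: ``evaluate`` maps a position vector to a scalar."""

    name: str
    category: str  # unimodal | multimodal | composite
    dim: int
    bounds: tuple[float, float]
    shift: np.ndarray
    rotation: np.ndarray
    f_opt: float
    components: tuple[_Component, ...] = field(default=())

    @property
    def optimum_position(self) -> np.ndarray:
        return self.shift

    def evaluate(self, x: np.ndarray) -> float:
        return float(self._eval_matrix(np.asarray(x, dtype=float)[None, :])[0])

    def _eval_matrix(self, X: np.ndarray) -> np.ndarray:
        if len(self.components) == 1:
            return self.components[0].raw(X) + self.f_opt
        return self._composite(X)

    def _composite(self, X: np.ndarray) -> np.ndarray:
        d = self.dim
        vals = np.stack([c.lam * c.raw(X) + c.bias for c in self.components], axis=1)
        d2 = np.stack(
            [((X - c.shift) ** 2).sum(axis=1) for c in self.components], axis=1
        )
        sig2 = np.array([c.sigma ** 2 for c in self.components])
        with np.errstate(divide="ignore"):
            w = np.exp(-d2 / (2.0 * d * sig2)) / np.sqrt(d2)
        # a query exactly on a component's shift gets that component alone
        exact = d2 == 0.0
        hit = exact.any(axis=1)
        w[hit] = exact[hit].astype(float)
        w /= w.sum(axis=1, keepdims=True)
        return (w * vals).sum(axis=1) + self.f_opt


def _rotation(rng: np.random.Generator, dim: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))  # unique, properly distributed Q


def _shift(rng: np.random.Generator, dim: int) -> np.ndarray:
    return rng.uniform(-0.8 * BOUND, 0.8 * BOUND, size=dim)


def make_suite(dim: int, seed: int = 0) -> list[BenchmarkFunction]:
    """Build the 12-function suite (3 unimodal, 5 multimodal, 4 composite)."""
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    rng = np.random.default_rng(seed)
    suite: list[BenchmarkFunction] = []

    singles = [
        ("F1", "unimodal", "zakharov"),
        ("F2", "unimodal", "rosenbrock"),
        ("F3", "unimodal", "elliptic"),
        ("F4", "multimodal", "rastrigin"),
        ("F5", "multimodal", "levy"),
        ("F6", "multimodal", "schaffer_f7"),
        ("F7", "multimodal", "griewank_rosenbrock"),
        ("F8", "multimodal", "schwefel"),
    ]
    for name, cat, base in singles:
        comp = _Component(base=base, shift=_shift(rng, dim), rotation=_rotation(rng, dim))
        suite.append(
            BenchmarkFunction(
                name=name, category=cat, dim=dim, bounds=(-BOUND, BOUND),
                shift=comp.shift, rotation=comp.rotation, f_opt=0.0,
                components=(comp,),
            )
        )

    composites = [
        ("F9", [("rosenbrock", 10, 1.0), ("elliptic", 20, 1e-6), ("rastrigin", 30, 1.0)]),
        ("F10", [("schwefel", 10, 1.0), ("rastrigin", 20, 1.0),
                 ("griewank_rosenbrock", 30, 1e-2)]),
        ("F11", [("elliptic", 10, 1e-6), ("schwefel", 20, 1.0), ("levy", 30, 1.0),
                 ("zakharov", 40, 1e-1), ("rastrigin", 50, 1.0)]),
        ("F12", [("schaffer_f7", 10, 1.0), ("rastrigin", 20, 1.0),
                 ("levy", 30, 1.0), ("zakharov", 40, 1e-1)]),
    ]
    for name, spec in composites:
        comps = tuple(
            _Component(
                base=base, shift=_shift(rng, dim), rotation=_rotation(rng, dim),
                sigma=sigma, lam=lam, bias=100.0 * i,
            )
            for i, (base, sigma, lam) in enumerate(spec)
        )
        suite.append(
            BenchmarkFunction(
                name=name, category="composite", dim=dim, bounds=(-BOUND, BOUND),
                shift=comps[0].shift, rotation=comps[0].rotation, f_opt=0.0,
                components=comps,
            )
        )
    return suite


def evaluate_batch(f: BenchmarkFunction, positions: np.ndarray) -> np.ndarray:
    """Evaluate a whole (n, dim) position matrix at once."""
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("positions must be finite")
    if X.shape[1] != f.dim:
        raise ValueError(f"expected dim {f.dim}, got {X.shape[1]}")
    return f._eval_matrix(X)
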