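"""B-spline bases on the genomic-position and time domains.

The coefficient surface beta(s, t) linking a genotype function x_i(s) to a
phenotype curve y_i(t) is represented as a tensor product of two marginal
B-spline bases.  This module builds those bases, evaluates tensor surfaces,
and computes the quadrature ingredients the regression engine needs:

* ``genotype_functional_weights`` -- weights W with
  ``integral x_i(s) phi_j(s) ds = sum_l x_il W[l, j]`` under a declared
  genotype-function convention (step function or point mass);
* Gram matrices ``integral phi phi^T`` and second-derivative roughness
  penalties ``integral phi'' phi''^T``, both exact via per-span
  Gauss-Legendre quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class DomainError(ValueError):
    """Evaluation or construction outside the basis domain."""


@dataclass(frozen=True)
class BasisSpec:
    """A univariate B-spline basis on ``[domain_lo, domain_hi]``.

    ``order`` is the spline order (degree + 1, so 4 = cubic); ``n_basis``
    is the number of basis functions.  Knots carry full multiplicity at the
    boundaries with equally spaced interior knots, so the basis forms a
    partition of unity on the domain.
    """

    domain_lo: float
    domain_hi: float
    order: int
    n_basis: int
    knots: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return self.order - 1

    def _check_domain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.size and (x.min() < self.domain_lo - 1e-12 or x.max() > self.domain_hi + 1e-12):
            raise DomainError(
                f"evaluation points outside [{self.domain_lo}, {self.domain_hi}]"
            )
        return np.clip(x, self.domain_lo, self.domain_hi)

    def evaluate(self, x) -> np.ndarray:
        """Design matrix ``B[i, j] = phi_j(x_i)``, shape (len(x), n_basis)."""
        x = self._check_domain(np.atleast_1d(x))
        # design_matrix treats the right boundary as inclusive
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False).toarray()

    def evaluate_derivative(self, x, deriv: int = 2) -> np.ndarray:
        x = self._check_domain(np.atleast_1d(x))
        out = np.empty((x.size, self.n_basis))
        eye = np.eye(self.n_basis)
        for j in range(self.n_basis):
            spl = BSpline(self.knots, eye[j], self.degree, extrapolate=False)
            d = spl.derivative(deriv)
            # derivative splines extrapolate NaN at the right boundary knot
            out[:, j] = d(np.minimum(x, self.domain_hi * (1 - 1e-14) + self.domain_lo * 1e-14))
        return out

    # -- exact integrals -------------------------------------------------

    def _gl_nodes(self, npts: int):
        xg, wg = np.polynomial.legendre.leggauss(npts)
        spans = np.unique(self.knots)
        a, b = spans[:-1], spans[1:]
        mid, half = (a + b) / 2, (b - a) / 2
        nodes = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
        weights = (half[:, None] * wg[None, :]).ravel()
        return nodes, weights

    def gram(self) -> np.ndarray:
        """``M[j, j'] = integral phi_j phi_j' ds`` (exact)."""
        nodes, w = self._gl_nodes(self.order + 1)
        B = self.evaluate(nodes)
        return (B * w[:, None]).T @ B

    def penalty(self) -> np.ndarray:
        """Second-derivative roughness penalty ``integral phi'' phi''^T`` (exact).

        Requires order >= 3 so the second derivative exists.
        """
        if self.order < 3:
            raise ValueError("second-derivative penalty requires spline order >= 3")
        nodes, w = self._gl_nodes(self.order + 1)
        B2 = self.evaluate_derivative(nodes, 2)
        return (B2 * w[:, None]).T @ B2

    def integrate_intervals(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Exact ``integral_{lo_l}^{hi_l} phi_j ds`` for a batch of intervals."""
        lo = self._check_domain(np.atleast_1d(lo))
        hi = self._check_domain(np.atleast_1d(hi))
        out = np.empty((lo.size, self.n_basis))
        eye = np.eye(self.n_basis)
        for j in range(self.n_basis):
            spl = BSpline(self.knots, eye[j], self.degree, extrapolate=False)
            anti = spl.antiderivative()
            out[:, j] = anti(hi) - anti(lo)
        return out


def make_bspline_basis(domain_lo: float, domain_hi: float, n_basis: int, order: int = 4) -> BasisSpec:
    """Build a B-spline basis with equally spaced interior knots.

    Boundary knots carry full multiplicity ``order`` so that exactly
    ``n_basis`` functions live on ``[domain_lo, domain_hi]`` and sum to one
    everywhere on it.
    """
    if domain_hi <= domain_lo:
        raise DomainError("degenerate domain: domain_hi must exceed domain_lo")
    if order < 1:
        raise ValueError("order must be >= 1")
    if n_basis < order:
        raise ValueError(f"n_basis ({n_basis}) must be >= order ({order})")
    n_interior = n_basis - order
    interior = np.linspace(domain_lo, domain_hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(order, domain_lo), interior, np.full(order, domain_hi)]
    )
    return BasisSpec(float(domain_lo), float(domain_hi), int(order), int(n_basis), knots)


@dataclass
class BetaSurface:
    """Tensor-product coefficient surface ``beta(s, t)``.

    ``coef`` has shape (s_basis.n_basis, t_basis.n_basis); the flattened
    row-major vector is the coefficient vector b of length K = m_s * m_t.
    """

    s_basis: BasisSpec
    t_basis: BasisSpec
    coef: np.ndarray

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        expected = (self.s_basis.n_basis, self.t_basis.n_basis)
        if self.coef.shape != expected:
            raise ValueError(f"coef shape {self.coef.shape} != {expected}")

    @property
    def k(self) -> int:
        return self.coef.size

    def flatten(self) -> np.ndarray:
        return self.coef.ravel(order="C").copy()

    @classmethod
    def from_flat(cls, s_basis: BasisSpec, t_basis: BasisSpec, b: np.ndarray) -> "BetaSurface":
        b = np.asarray(b, dtype=float)
        return cls(s_basis, t_basis, b.reshape(s_basis.n_basis, t_basis.n_basis, order="C"))


def eval_surface(surface: BetaSurface, s_grid, t_grid) -> np.ndarray:
    """Evaluate ``beta(s_i, t_q)`` on the grid; bilinear in the coefficients."""
    Bs = surface.s_basis.evaluate(s_grid)
    Bt = surface.t_basis.evaluate(t_grid)
    return Bs @ surface.coef @ Bt.T


def genotype_functional_weights(
    positions, s_basis: BasisSpec, mode: str = "step"
) -> np.ndarray:
    """Quadrature weights turning SNP genotypes into functional inner products.

    Returns W (L x m_s) with ``integral x_i(s) phi_j(s) ds ~= sum_l x_il W[l, j]``.

    mode="step": x_i(s) is a step function, constant at x_il between SNP
    midpoints (boundary intervals clipped to the domain); integrals of the
    basis over each step are exact.
    mode="point": per-SNP point mass, ``W[l, j] = phi_j(s_l) * M / L``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty region: no SNP positions")
    if positions.ndim != 1 or np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be a strictly increasing 1-d vector")
    lo, hi = s_basis.domain_lo, s_basis.domain_hi
    if positions.min() < lo - 1e-12 or positions.max() > hi + 1e-12:
        raise DomainError("SNP positions outside the basis domain")
    if mode == "point":
        delta = (hi - lo) / positions.size
        return s_basis.evaluate(positions) * delta
    if mode != "step":
        raise ValueError(f"unknown genotype-function mode {mode!r}")
    mids = (positions[:-1] + positions[1:]) / 2
    left = np.concatenate([[lo], mids])
    right = np.concatenate([mids, [hi]])
    return s_basis.integrate_intervals(left, right)
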