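"""Penalized function-on-function regression of a longitudinal trait on a
gene region.

The model is

    y_i(t) = mu(t) + integral_0^M x_i(s) beta(s, t) ds + eps_i(t)

with beta(s, t) expanded in a tensor product of B-spline bases.  After
centering both sides, the coefficient vector b solves the penalized normal
equations

    (Psi' Psi + lambda1 R1 + lambda2 R2) b = Psi' y

where R1 and R2 penalize the integrated squared second derivative of the
surface in the position and time directions.  Smoothing parameters are
chosen by leave-one-subject-out cross-validation over a grid.

The public surface follows the statsmodels convention: build a
:class:`FunctionOnFunctionRegression` from data, call :meth:`fit`, and work
with the returned :class:`FofrResults`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import BasisSpec, BetaSurface, genotype_functional_weights, make_bspline_basis
from .data import GenotypeRegion, LongitudinalPhenotype, check_aligned

#: smoothing-parameter grid used by default for leave-one-out selection
DEFAULT_LAMBDA_GRID = (1e2, 1e3, 1e4, 1e5, 1e6)


class SingularSystemError(np.linalg.LinAlgError):
    """Penalized normal equations are numerically singular."""


@dataclass
class PenaltyPair:
    """Roughness penalty matrices for the two directions of the surface.

    For a tensor basis, ``R1 = P_s (x) M_t`` and ``R2 = M_s (x) P_t`` where
    ``P`` is the marginal second-derivative penalty and ``M`` the marginal
    Gram matrix.  R1 annihilates surfaces linear in s, R2 surfaces linear
    in t.
    """

    R1: np.ndarray
    R2: np.ndarray
    lambda1: float = 0.0
    lambda2: float = 0.0


def center_data(geno: GenotypeRegion, pheno: LongitudinalPhenotype):
    """Center genotypes and phenotypes across subjects.

    Returns ``(Xc, Yc, mean_curve, x_mean)`` where ``mean_curve`` is the
    per-time phenotype mean (the estimate of mu(t)) and ``x_mean`` the
    per-SNP genotype mean.  Column means of both centered matrices are zero.
    """
    check_aligned(geno, pheno)
    if geno.n < 2:
        raise ValueError("centering requires at least 2 subjects")
    x_mean = geno.G.mean(axis=0)
    mean_curve = pheno.Y.mean(axis=0)
    return geno.G - x_mean, pheno.Y - mean_curve, mean_curve, x_mean


def build_design(Z: np.ndarray, Phit: np.ndarray) -> np.ndarray:
    """Stack the full design Psi, shape ``n(Q+1) x K``.

    Row order is subject-major, time-minor: row ``i*(Q+1) + q`` belongs to
    subject i at time t_q.  Column ``j*m_t + k`` multiplies coefficient
    ``coef[j, k]``, i.e. ``Psi[(i,q), (j,k)] = Z[i, j] * Phit[q, k]`` with
    ``Z = Xc W`` holding the genotype-basis inner products.
    """
    n, ms = Z.shape
    Q1, mt = Phit.shape
    out = np.einsum("ij,qk->iqjk", Z, Phit)
    return out.reshape(n * Q1, ms * mt)


def build_penalties(s_basis: BasisSpec, t_basis: BasisSpec) -> PenaltyPair:
    """Tensor-product roughness penalties (symmetric positive semidefinite)."""
    if s_basis.order < 3 or t_basis.order < 3:
        raise ValueError("roughness penalties require spline order >= 3 in both directions")
    Ms, Ps = s_basis.gram(), s_basis.penalty()
    Mt, Pt = t_basis.gram(), t_basis.penalty()
    R1 = np.kron(Ps, Mt)
    R2 = np.kron(Ms, Pt)
    return PenaltyPair(R1=R1, R2=R2)


def _solve_sym(A: np.ndarray, rhs: np.ndarray, context: str = "", strict: bool = False) -> np.ndarray:
    """Symmetric positive-definite solve with a one-shot jitter fallback.

    ``strict=True`` (used on the unpenalized path) additionally rejects
    rank-deficient systems instead of silently returning one of infinitely
    many solutions.
    """
    if strict:
        ev = np.linalg.eigvalsh((A + A.T) / 2)
        if ev[0] <= 1e-10 * max(ev[-1], 1e-300):
            raise SingularSystemError(
                "penalized normal equations are singular"
                + (f" ({context})" if context else "")
                + "; raise lambda1/lambda2 or reduce the basis size K"
            )
    try:
        c, low = linalg.cho_factor(A)
        return linalg.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * np.trace(A) / A.shape[0]
    try:
        c, low = linalg.cho_factor(A + jitter * np.eye(A.shape[0]))
        return linalg.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError as err:
        raise SingularSystemError(
            "penalized normal equations are singular"
            + (f" ({context})" if context else "")
            + "; raise lambda1/lambda2 or reduce the basis size K"
        ) from err


def penalized_solve(Psi, y_stacked, R1, R2, lambda1, lambda2) -> np.ndarray:
    """Solve ``(Psi'Psi + l1 R1 + l2 R2) b = Psi'y`` for the coefficient vector."""
    Psi = np.asarray(Psi, float)
    y = np.asarray(y_stacked, float).ravel()
    A = Psi.T @ Psi + lambda1 * np.asarray(R1) + lambda2 * np.asarray(R2)
    return _solve_sym(
        A,
        Psi.T @ y,
        context=f"lambda=({lambda1:g},{lambda2:g})",
        strict=(lambda1 == 0.0 and lambda2 == 0.0),
    )


class FunctionOnFunctionRegression:
    """Function-on-function regression model for a gene region.

    Parameters
    ----------
    geno, pheno
        Matched :class:`GenotypeRegion` and :class:`LongitudinalPhenotype`.
    m_s, m_t
        Marginal B-spline basis sizes for the position and time directions.
    order_s, order_t
        Spline orders (4 = cubic).
    k_test
        Numerator degrees of freedom of the per-time F test.  Defaults to
        15, the nominal count of bivariate basis functions; see the methods
        note for why this differs from the coefficient count ``m_s * m_t``.
    genotype_function
        ``"step"`` (default) or ``"point"`` convention for x_i(s).
    """

    def __init__(
        self,
        geno: GenotypeRegion,
        pheno: LongitudinalPhenotype,
        m_s: int = 15,
        m_t: int = 15,
        order_s: int = 4,
        order_t: int = 4,
        k_test: int = 15,
        genotype_function: str = "step",
    ):
        check_aligned(geno, pheno)
        self.geno = geno
        self.pheno = pheno
        self.k_test = int(k_test)
        self.s_basis = make_bspline_basis(0.0, 1.0, m_s, order_s)
        self.t_basis = make_bspline_basis(0.0, 1.0, m_t, order_t)
        self.Xc, self.Yc, self.mean_curve, self.x_mean = center_data(geno, pheno)
        self.W = genotype_functional_weights(geno.positions, self.s_basis, mode=genotype_function)
        self.Z = self.Xc @ self.W
        self.Phit = self.t_basis.evaluate(pheno.time_norm)
        if order_s >= 3 and order_t >= 3:
            self.penalties = build_penalties(self.s_basis, self.t_basis)
        else:
            # degenerate (e.g. constant time basis) -- penalties only where defined
            Ms = self.s_basis.gram()
            Mt = self.t_basis.gram()
            Ps = self.s_basis.penalty() if order_s >= 3 else np.zeros((m_s, m_s))
            Pt = self.t_basis.penalty() if order_t >= 3 else np.zeros((m_t, m_t))
            self.penalties = PenaltyPair(R1=np.kron(Ps, Mt), R2=np.kron(Ms, Pt))
        self._AtA = np.kron(self.Z.T @ self.Z, self.Phit.T @ self.Phit)
        self._rhs = (self.Z.T @ self.Yc @ self.Phit).ravel()

    # ------------------------------------------------------------------
    @classmethod
    def from_data(cls, geno, pheno, **kwargs) -> "FunctionOnFunctionRegression":
        return cls(geno, pheno, **kwargs)

    @property
    def k(self) -> int:
        """Number of estimated coefficients, K = m_s * m_t."""
        return self.s_basis.n_basis * self.t_basis.n_basis

    def design(self) -> np.ndarray:
        """The explicit stacked design matrix (for inspection/testing)."""
        return build_design(self.Z, self.Phit)

    def _system(self, lambda1: float, lambda2: float) -> np.ndarray:
        return self._AtA + lambda1 * self.penalties.R1 + lambda2 * self.penalties.R2

    def _solve(self, lambda1: float, lambda2: float) -> np.ndarray:
        return _solve_sym(
            self._system(lambda1, lambda2),
            self._rhs,
            context=f"lambda=({lambda1:g},{lambda2:g})",
            strict=(lambda1 == 0.0 and lambda2 == 0.0),
        )

    # -- leave-one-subject-out cross-validation -------------------------

    def loocv_score(self, lambda1: float, lambda2: float) -> float:
        """Leave-one-subject-out prediction error via the block hat identity.

        For a linear smoother, removing all rows of subject i gives deleted
        residuals ``(I - H_ii)^{-1} e_i`` where ``H_ii`` is the subject's
        diagonal block of the hat matrix; no refitting is needed.
        """
        b = self._solve(lambda1, lambda2)
        ms, mt = self.s_basis.n_basis, self.t_basis.n_basis
        B = b.reshape(ms, mt)
        resid = self.Yc - self.Z @ B @ self.Phit.T
        C = _solve_sym(self._system(lambda1, lambda2), np.eye(self.k))
        C4 = C.reshape(ms, mt, ms, mt)
        # G[i] = z_i . C . z_i contracted over the two s-axes
        G = np.einsum("ia,akbl,ib->ikl", self.Z, C4, self.Z, optimize=True)
        H = np.einsum("qk,ikl,rl->iqr", self.Phit, G, self.Phit, optimize=True)
        Q1 = self.Phit.shape[0]
        eye = np.eye(Q1)
        total = 0.0
        for i in range(self.geno.n):
            e_loo = np.linalg.solve(eye - H[i], resid[i])
            total += float(e_loo @ e_loo)
        return total

    def loocv_select(self, grid=DEFAULT_LAMBDA_GRID):
        """Pick (lambda1, lambda2) minimizing the CV score over a Cartesian grid.

        Ties are broken toward the smoother model (larger lambda1+lambda2).
        Returns ``(lambda1, lambda2, cv_table)``.
        """
        grid = tuple(grid)
        if len(grid) == 0:
            raise ValueError("lambda grid must be nonempty")
        if self.geno.n < 3:
            raise ValueError("cross-validation requires at least 3 subjects")
        rows = []
        for l1, l2 in itertools.product(grid, grid):
            rows.append((l1, l2, self.loocv_score(l1, l2)))
        cv_table = pd.DataFrame(rows, columns=["lambda1", "lambda2", "cv_score"])
        best = cv_table.sort_values(
            ["cv_score", "lambda1", "lambda2"],
            ascending=[True, False, False],
            kind="mergesort",
        )
        # exact-tie handling: among minimal scores prefer largest lambda1+lambda2
        smin = best["cv_score"].iloc[0]
        tied = cv_table[np.isclose(cv_table["cv_score"], smin, rtol=1e-12, atol=0.0)]
        pick = tied.loc[(tied["lambda1"] + tied["lambda2"]).idxmax()]
        return float(pick["lambda1"]), float(pick["lambda2"]), cv_table

    # ------------------------------------------------------------------

    def fit(self, lambda1: float = None, lambda2: float = None, cv_grid=DEFAULT_LAMBDA_GRID):
        """Fit the model; if the smoothing parameters are not given, select
        them by leave-one-subject-out cross-validation over ``cv_grid``."""
        cv_table = None
        if lambda1 is None or lambda2 is None:
            lambda1, lambda2, cv_table = self.loocv_select(cv_grid)
        b = self._solve(lambda1, lambda2)
        surface = BetaSurface.from_flat(self.s_basis, self.t_basis, b)
        fitted = self.Z @ surface.coef @ self.Phit.T
        residuals = self.Yc - fitted
        return FofrResults(
            model=self,
            surface=surface,
            mean_curve=self.mean_curve.copy(),
            x_mean=self.x_mean.copy(),
            lambda1=float(lambda1),
            lambda2=float(lambda2),
            fitted=fitted,
            residuals=residuals,
            rss1_by_time=(residuals**2).sum(axis=0),
            rss0_by_time=(self.Yc**2).sum(axis=0),
            k=self.k,
            k_test=self.k_test,
            cv_table=cv_table,
        )


@dataclass
class FofrResults:
    """Fitted function-on-function regression.

    ``fitted + residuals`` equals the centered phenotype matrix exactly;
    ``rss0_by_time``/``rss1_by_time`` are the per-time null and model
    residual sums of squares entering the F test.
    """

    model: FunctionOnFunctionRegression
    surface: BetaSurface
    mean_curve: np.ndarray
    x_mean: np.ndarray
    lambda1: float
    lambda2: float
    fitted: np.ndarray
    residuals: np.ndarray
    rss1_by_time: np.ndarray
    rss0_by_time: np.ndarray
    k: int
    k_test: int
    cv_table: pd.DataFrame = None

    @property
    def nobs(self) -> int:
        return self.fitted.shape[0]

    def predict(self, geno_new: GenotypeRegion) -> np.ndarray:
        """Predicted phenotype curves ``mu(t) + integral x(s) beta(s, t) ds``.

        ``geno_new`` must share the training SNP positions.
        """
        if geno_new.positions.shape != self.model.geno.positions.shape or not np.allclose(
            geno_new.positions, self.model.geno.positions
        ):
            raise ValueError("prediction requires the training SNP positions")
        Z_new = (geno_new.G - self.x_mean) @ self.model.W
        return self.mean_curve + Z_new @ self.surface.coef @ self.model.Phit.T

    def f_test(self, alphas=(0.05, 0.01, 0.001)):
        from .association import f_test_all

        return f_test_all(self, alphas=alphas)

    def beta_grid(self, s_grid=None, t_grid=None) -> np.ndarray:
        """Estimated surface on a grid (defaults: SNP positions x time grid)."""
        from .basis import eval_surface

        s = self.model.geno.positions if s_grid is None else s_grid
        t = self.model.pheno.time_norm if t_grid is None else t_grid
        return eval_surface(self.surface, s, t)

    def summary(self) -> str:
        res = self.f_test()
        lines = [
            "Function-on-function regression (longitudinal gene-region test)",
            "=" * 64,
            f"subjects: {self.model.geno.n}   SNPs: {self.model.geno.L}   "
            f"time points: {self.model.pheno.n_times}",
            f"basis: {self.model.s_basis.n_basis} x {self.model.t_basis.n_basis} "
            f"(order {self.model.s_basis.order}/{self.model.t_basis.order}), "
            f"K = {self.k} coefficients",
            f"smoothing: lambda1 = {self.lambda1:g}, lambda2 = {self.lambda2:g}"
            + ("  (leave-one-subject-out CV)" if self.cv_table is not None else ""),
            f"F reference: F({res.df1}, {res.df2})",
            "-" * 64,
            f"{'time':>8} {'RSS0':>12} {'RSS1':>12} {'F':>10} {'p':>12}",
        ]
        for q, t in enumerate(self.model.pheno.time_grid):
            lines.append(
                f"{t:>8g} {self.rss0_by_time[q]:>12.4f} {self.rss1_by_time[q]:>12.4f} "
                f"{res.f_by_time[q]:>10.4f} {res.p_by_time[q]:>12.4g}"
            )
        lines.append("-" * 64)
        lines.append(f"global (all time points): F = {res.f_global:.4f}, p = {res.p_global:.4g}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        """Serialize coefficients, smoothing parameters and per-time RSS."""
        payload = {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "k": self.k,
            "k_test": self.k_test,
            "coef": self.surface.coef.tolist(),
            "mean_curve": self.mean_curve.tolist(),
            "x_mean": self.x_mean.tolist(),
            "rss0_by_time": self.rss0_by_time.tolist(),
            "rss1_by_time": self.rss1_by_time.tolist(),
            "time_grid": self.model.pheno.time_grid.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def surface_to_csv(self, path, n_s: int = 50, n_t: int = 50) -> None:
        """Export the estimated surface as a gridded (s, t, value) CSV."""
        from .basis import eval_surface

        s = np.linspace(0, 1, n_s)
        t = np.linspace(0, 1, n_t)
        vals = eval_surface(self.surface, s, t)
        df = pd.DataFrame(
            {
                "s": np.repeat(s, n_t),
                "t": np.tile(t, n_s),
                "beta": vals.ravel(),
            }
        )
        df.to_csv(path, index=False)


def fit(
    geno: GenotypeRegion,
    pheno: LongitudinalPhenotype,
    lambda1: float = None,
    lambda2: float = None,
    cv_grid=DEFAULT_LAMBDA_GRID,
    **model_kwargs,
) -> FofrResults:
    """One-call fit: build the model and run :meth:`FunctionOnFunctionRegression.fit`."""
    return FunctionOnFunctionRegression(geno, pheno, **model_kwargs).fit(
        lambda1=lambda1, lambda2=lambda2, cv_grid=cv_grid
    )
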