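"""Fit-quality metrics for simulation studies: ISE0, ISE1 and PMSE.

The integrated squared errors compare the estimated effect surface with the
generating truth on the discrete SNP-by-time grid, split into the null set
S0 (SNPs with no effect) and the non-null set S1 (causal SNPs).  Note the
denominators (|Gamma|-1)(|S|-1) and N-1: they differ from plain means and
are kept deliberately (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricReport:
    ise0: float
    ise1: float
    pmse: float
    s0_size: int
    s1_size: int
    n_test: int


def _ise(beta_true, beta_hat, label):
    beta_true = np.asarray(beta_true, float)
    beta_hat = np.asarray(beta_hat, float)
    if beta_true.shape != beta_hat.shape or beta_true.ndim != 2:
        raise ValueError("beta_true and beta_hat must be matching 2-d grids (sites x times)")
    n_sites, n_times = beta_true.shape
    if n_sites < 2 or n_times < 2:
        raise ValueError(
            f"{label} needs at least 2 sites and 2 time points for its "
            f"(|S|-1)(|Gamma|-1) denominator; got {n_sites} x {n_times}"
        )
    return float(((beta_hat - beta_true) ** 2).sum() / ((n_times - 1) * (n_sites - 1)))


def ise_null(beta_true, beta_hat) -> float:
    """Integrated squared error over the null grid S0 x Gamma."""
    return _ise(beta_true, beta_hat, "ISE0")


def ise_nonnull(beta_true, beta_hat) -> float:
    """Integrated squared error over the causal grid S1 x Gamma."""
    return _ise(beta_true, beta_hat, "ISE1")


def pmse(fit, test_geno, test_pheno) -> float:
    """Prediction mean squared error on held-out subjects (N-1 denominator)."""
    N = test_pheno.Y.shape[0]
    if N < 2:
        raise ValueError("PMSE needs at least 2 test subjects for its N-1 denominator")
    pred = fit.predict(test_geno)
    return float(((test_pheno.Y - pred) ** 2).sum() / (N - 1))


def metric_report(fit, beta_true_grid, causal_indices, test_geno, test_pheno) -> MetricReport:
    """All three metrics for one replicate.

    ``beta_true_grid`` is the generating L x (Q+1) effect grid (zero rows off
    the causal set); the estimated surface is evaluated at the same SNP
    positions and times.
    """
    beta_hat = fit.beta_grid()
    causal = np.zeros(beta_true_grid.shape[0], dtype=bool)
    causal[np.asarray(causal_indices, int)] = True
    return MetricReport(
        ise0=ise_null(beta_true_grid[~causal], beta_hat[~causal]),
        ise1=ise_nonnull(beta_true_grid[causal], beta_hat[causal])
        if causal.sum() >= 2
        else float(
            ((beta_hat[causal] - beta_true_grid[causal]) ** 2).sum()
            / (beta_true_grid.shape[1] - 1)
        ),
        pmse=pmse(fit, test_geno, test_pheno),
        s0_size=int((~causal).sum()),
        s1_size=int(causal.sum()),
        n_test=test_pheno.Y.shape[0],
    )
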