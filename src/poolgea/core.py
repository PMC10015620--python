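"""Omega-corrected core model: standardized allele frequencies, the X^T^X
spatial differentiation statistic, and per-variable Bayes factors (BFdB).

Model.  For SNP j with across-population mean frequency pi_j, the scaled
deviation of population i is

    y_ij = (p_ij - pi_j) / sqrt(pi_j (1 - pi_j)),

and the K-vector y_j is modelled as N(0, Omega), Omega the among-population
covariance induced by shared demographic history.  Whitening with the
Cholesky factor L of Omega (z_j = L^-1 y_j) removes that structure; then

    X^T^X_j   = (K/(K-1)) * z_j' z_j                (null mean K)
    BF_j(e)   = closed-form conjugate Bayes factor for z_j = beta*e~ + eps,
                eps ~ N(0, I), beta ~ N(0, tau), e~ = L^-1 standardized env,
    BFdB_j    = 10 log10 BF_j.

Estimation notes.  Centering p at the sample mean pi makes the columns of y
sum to zero, so the raw moment matrix M = (1/S) sum_j y_j y_j' estimates
H Omega H (H the centering projector) — the component of Omega along the
all-ones vector is unidentifiable from frequency data alone.  We complete
the estimate by fitting additive row effects c so that the typical
(median) between-population covariance is anchored at zero: most pairs of
populations share no drift beyond the global mean.  The lost degree of
freedom is compensated in X^T^X by the K/(K-1) factor, which makes the
null mean exactly K under the self-consistent moment Omega.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_triangular

from .containers import AlleleFreqMatrix

__all__ = [
    "OmegaMatrix",
    "GeaConfig",
    "ScanResult",
    "scaled_deviations",
    "estimate_omega",
    "standardize",
    "xtx",
    "bf_env",
    "run_gea",
]

log = logging.getLogger(__name__)

#: pi clamp for the binomial scale factor, avoids blow-ups at near-fixed sites
PI_CLAMP = (0.01, 0.99)


@dataclass
class OmegaMatrix:
    """K x K symmetric positive-definite covariance with Cholesky factor."""

    matrix: np.ndarray
    chol: np.ndarray
    estimator: str = "moments"

    @classmethod
    def from_matrix(cls, omega: np.ndarray, estimator: str = "given") -> "OmegaMatrix":
        omega = np.asarray(omega, dtype=float)
        omega = 0.5 * (omega + omega.T)
        try:
            chol = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            # rank-deficient or indefinite estimate: lift the spectrum just
            # above zero with a trace-scaled ridge
            floor = 1e-6 * np.trace(omega) / omega.shape[0]
            min_eig = float(np.linalg.eigvalsh(omega)[0])
            ridge = floor + max(0.0, -min_eig)
            log.warning("omega not positive-definite; adding ridge %.3g", ridge)
            omega = omega + ridge * np.eye(omega.shape[0])
            chol = np.linalg.cholesky(omega)
        return cls(matrix=omega, chol=chol, estimator=estimator)

    @property
    def n_pops(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path, pop_labels=None) -> None:
        labels = pop_labels or [f"POP{i + 1:02d}" for i in range(self.n_pops)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path, sep="\t")


@dataclass(frozen=True)
class GeaConfig:
    """Scan configuration (prior variance tau, chunking, tails, local score)."""

    tau: float = 0.1
    n_runs: int = 3
    n_subdatasets: int = 19
    tail_fraction: float = 0.0005
    xi: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0.0 < self.tail_fraction < 0.5):
            raise ValueError("tail_fraction must be in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "GeaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ScanResult:
    """Per-SNP scan track: X^T^X plus one BFdB column per variable."""

    table: pd.DataFrame  # scaffold, pos, xtx, bf_<variable>...
    omega: OmegaMatrix
    variables: list[str]
    config: GeaConfig = field(default_factory=GeaConfig)

    def bf(self, variable: str) -> np.ndarray:
        return self.table[f"bf_{variable}"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def scaled_deviations(freqs: AlleleFreqMatrix) -> np.ndarray:
    """y matrix (n_snps, n_pops): mean-centered, binomial-scale standardized.

    Missing cells are mean-imputed and so contribute exactly zero.  The
    centering uses the unclamped mean, keeping column sums of y at zero;
    only the scale denominator clamps pi to avoid division blow-ups.
    """
    p = freqs.imputed()
    pi = freqs.pi
    pic = np.clip(pi, *PI_CLAMP)
    return (p - pi[:, None]) / np.sqrt(pic * (1.0 - pic))[:, None]


def _median_anchor(m: np.ndarray) -> float:
    """Completion weight gamma for omega = m + gamma * 11'.

    The raw moment matrix only identifies H Omega H; gamma is chosen so the
    median off-diagonal covariance of the completed matrix is zero (the
    typical pair of populations shares no drift beyond the global mean).
    Any gamma > 0 yields a positive-definite completion and leaves every
    whitened-domain statistic of mean-zero vectors unchanged, so the choice
    only affects the reported Omega itself.  Floored at a small positive
    value to guarantee positive-definiteness.
    """
    k = m.shape[0]
    off = m[~np.eye(k, dtype=bool)]
    gamma = float(-np.median(off))
    floor = 1e-6 * float(np.trace(m)) / k
    return max(gamma, floor)


def estimate_omega(
    freqs: AlleleFreqMatrix,
    method: str = "moments",
    shrinkage: float | None = None,
) -> OmegaMatrix:
    """Method-of-moments Omega with median-anchored row-effect completion.

    ``method="shrinkage"`` additionally blends toward the diagonal with a
    Ledoit-style intensity (estimated from the sampling variance of the
    moment matrix unless given explicitly).
    """
    if method not in {"moments", "shrinkage"}:
        raise ValueError(f"unknown method {method!r}")
    y = scaled_deviations(freqs)
    s = y.shape[0]
    if s < 50:
        log.warning("estimating omega from only %d SNPs; expect noise", s)
    m = (y.T @ y) / s
    gamma = _median_anchor(m)
    omega = m + gamma

    if method == "shrinkage":
        target = np.diag(np.diag(omega))
        if shrinkage is None:
            # Ledoit-Wolf style: ratio of summed sampling variances of the
            # off-diagonal entries to their summed squared magnitudes
            y2 = y**2
            var_m = ((y2.T @ y2) / s - m**2) / s
            off = ~np.eye(m.shape[0], dtype=bool)
            denom = float((omega[off] ** 2).sum())
            shrinkage = float(np.clip(var_m[off].sum() / max(denom, 1e-12), 0.0, 1.0))
        log.info("shrinkage intensity %.4f", shrinkage)
        omega = (1.0 - shrinkage) * omega + shrinkage * target

    return OmegaMatrix.from_matrix(omega, estimator=method)


def standardize(
    freqs: AlleleFreqMatrix | np.ndarray,
    omega: OmegaMatrix,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Whitened frequencies z (n_snps, n_pops): z_j = L^-1 y_j per SNP.

    Accepts either an :class:`AlleleFreqMatrix` (y computed internally) or
    a precomputed y matrix.  ``pi`` overrides the stored per-SNP mean when
    standardizing raw frequencies against an external reference.
    """
    if isinstance(freqs, AlleleFreqMatrix):
        if pi is not None:
            pic = np.clip(pi, *PI_CLAMP)
            y = (freqs.imputed() - pi[:, None]) / np.sqrt(pic * (1 - pic))[:, None]
        else:
            y = scaled_deviations(freqs)
    else:
        y = np.asarray(freqs, dtype=float)
    return solve_triangular(omega.chol, y.T, lower=True).T


def xtx(z: np.ndarray, df_correction: bool = True) -> np.ndarray:
    """Per-SNP X^T^X = z_j' z_j, with the K/(K-1) mean-centering correction.

    The correction restores the chi-square_K scale lost by centering the
    frequencies at their sample mean (null expectation K).
    """
    k = z.shape[1]
    stat = np.einsum("jk,jk->j", z, z)
    if df_correction:
        stat = stat * (k / (k - 1.0))
    return stat


def whiten_env(env: np.ndarray, omega: OmegaMatrix) -> np.ndarray:
    """Standardize an environmental covariate and whiten it with L^-1."""
    env = np.asarray(env, dtype=float)
    sd = env.std()
    if sd == 0:
        raise ValueError("environmental variable is constant")
    e = (env - env.mean()) / sd
    return solve_triangular(omega.chol, e, lower=True)


def bf_env(z: np.ndarray, env: np.ndarray, tau: float, omega: OmegaMatrix) -> np.ndarray:
    """Closed-form conjugate Bayes factor, in decibels, per SNP.

    BF_j = (1 + tau e~'e~)^(-1/2) exp( tau (e~'z_j)^2 / (2 (1 + tau e~'e~)) )
    with e~ the whitened standardized covariate.  BFdB = 10 log10 BF.
    """
    et = whiten_env(env, omega)
    ete = float(et @ et)
    etz = z @ et
    log_bf = -0.5 * np.log1p(tau * ete) + tau * etz**2 / (2.0 * (1.0 + tau * ete))
    return 10.0 * log_bf / np.log(10.0)


def run_gea(
    freqs: AlleleFreqMatrix,
    env_table: pd.DataFrame,
    config: GeaConfig | None = None,
    omega: OmegaMatrix | None = None,
) -> ScanResult:
    """Full scan: Omega once, then chunked X^T^X and per-variable BFdB.

    SNPs are split into ``n_subdatasets`` contiguous chunks computed
    independently and merged in genomic order (parallelization structure,
    not re-estimation: Omega is fixed globally).  The closed-form estimator
    is deterministic, so the ``n_runs`` averaging is a logged no-op.
    """
    config = config or GeaConfig()
    missing = set(env_table.index) ^ set(freqs.pop_labels)
    if set(env_table.index) != set(freqs.pop_labels):
        raise ValueError(f"environment table population mismatch: {sorted(missing)}")
    env_table = env_table.loc[freqs.pop_labels]

    if omega is None:
        omega = estimate_omega(freqs)
    y = scaled_deviations(freqs)
    n = y.shape[0]
    bounds = np.linspace(0, n, config.n_subdatasets + 1).astype(int)

    xtx_parts, bf_parts = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        z = standardize(y[lo:hi], omega)
        xtx_parts.append(xtx(z))
        bf_parts.append(
            {v: bf_env(z, env_table[v].to_numpy(), config.tau, omega) for v in env_table}
        )
    log.info(
        "closed-form estimator is deterministic: averaging over %d runs is a no-op",
        config.n_runs,
    )

    table = freqs.snps[["scaffold", "pos"]].reset_index(drop=True)
    table["xtx"] = np.concatenate(xtx_parts)
    for v in env_table:
        table[f"bf_{v}"] = np.concatenate([part[v] for part in bf_parts])
    return ScanResult(
        table=table, omega=omega, variables=list(env_table.columns), config=config
    )
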