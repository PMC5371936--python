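"""λ, R₀, T, eigen-structure, sensitivities and elasticities.

Standard matrix-population-model machinery: the population growth rate
λ is the dominant eigenvalue of the projection matrix A, the stable
stage distribution w and reproductive values v are its right and left
dominant eigenvectors, sensitivities are S_ij = v_i w_j / ⟨v, w⟩, and
elasticities E_ij = (a_ij / λ) S_ij.  The net reproductive rate R₀ is
the dominant eigenvalue of F (I − U)⁻¹, where U holds the survival
transitions and F the fertilities, and the mean generation time is
T = ln R₀ / ln λ projection intervals.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .data_model import DemographyResult, ProjectionMatrix

__all__ = [
    "project",
    "growth_rate",
    "growth_rate_power",
    "stable_distribution",
    "reproductive_value",
    "sensitivity",
    "elasticity",
    "net_reproductive_rate",
    "generation_time",
    "analyze",
    "replicate_summary",
    "split_survival_fertility",
]

_IMAG_TOL = 1e-10


def _as_array(A) -> np.ndarray:
    if isinstance(A, ProjectionMatrix):
        return A.matrix
    return np.asarray(A, dtype=float)


def project(A, N0, steps: int) -> np.ndarray:
    """Iterate N_{t+1} = A N_t and return the (steps+1) × s trajectory."""
    M = _as_array(A)
    N0 = np.asarray(N0, dtype=float)
    if (N0 < 0).any():
        raise ValueError("initial abundances must be non-negative")
    if N0.shape != (M.shape[0],):
        raise ValueError("N0 length must match the number of stages")
    out = np.empty((steps + 1, M.shape[0]))
    out[0] = N0
    for t in range(steps):
        out[t + 1] = M @ out[t]
    return out


def _dominant_pair(M: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant eigenvalue with right and left eigenvectors.

    Non-negative matrix theory guarantees a real non-negative dominant
    root; any imaginary residue beyond numerical noise is an error.
    """
    vals, vecs = np.linalg.eig(M)
    i = int(np.argmax(np.abs(vals)))
    lam = vals[i]
    if abs(lam.imag) > _IMAG_TOL * max(1.0, abs(lam.real)):
        raise ValueError(
            f"dominant eigenvalue has imaginary part {lam.imag:g}; "
            f"matrix is not a valid non-negative projection matrix"
        )
    w = vecs[:, i].real
    # left eigenvector from the transpose, matched to the same eigenvalue
    lvals, lvecs = np.linalg.eig(M.T)
    j = int(np.argmin(np.abs(lvals - lam)))
    v = lvecs[:, j].real
    # orient non-negatively
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    return float(lam.real), w, v


def growth_rate(A) -> float:
    """Per-interval population growth rate λ (dominant eigenvalue)."""
    M = _as_array(A)
    lam, _, _ = _dominant_pair(M)
    return lam


def growth_rate_power(
    A, tol: float = 1e-14, max_iter: int = 200_000
) -> float:
    """λ by power iteration — an independent route to the same quantity.

    Iterates until the normalized iterate stops moving (sup-norm below
    ``tol``), then polishes with a Rayleigh quotient.  Convergence is
    geometric in the gap between the two largest eigenvalue moduli, so
    the iteration cap is generous for near-degenerate spectra.
    """
    M = _as_array(A)
    x = np.ones(M.shape[0])
    x /= np.linalg.norm(x)
    for _ in range(max_iter):
        y = M @ x
        norm = float(np.linalg.norm(y))
        if norm == 0.0:
            return 0.0
        y /= norm
        if float(np.max(np.abs(y - x))) <= tol:
            x = y
            break
        x = y
    y = M @ x
    return float(x @ y / (x @ x))


def _check_irreducible(A) -> None:
    if isinstance(A, ProjectionMatrix):
        if (np.asarray(A.G) <= 0).any() or A.F <= 0:
            warnings.warn(
                "projection matrix is reducible (some G = 0 or F = 0); "
                "eigen-structure refers to its dominant block",
                stacklevel=3,
            )


def stable_distribution(A) -> np.ndarray:
    """Stable stage distribution w (right eigenvector of λ, sums to 1)."""
    _check_irreducible(A)
    _, w, _ = _dominant_pair(_as_array(A))
    w = np.where(np.abs(w) < 1e-14, 0.0, w)
    return w / w.sum()


def reproductive_value(A) -> np.ndarray:
    """Reproductive values v (left eigenvector of λ, scaled so v·w = 1)."""
    _check_irreducible(A)
    _, w, v = _dominant_pair(_as_array(A))
    w = w / w.sum()
    return v / (v @ w)


def sensitivity(A) -> np.ndarray:
    """Sensitivity matrix S_ij = ∂λ/∂a_ij = v_i w_j / ⟨v, w⟩."""
    _, w, v = _dominant_pair(_as_array(A))
    return np.outer(v, w) / (v @ w)


def elasticity(A) -> np.ndarray:
    """Elasticity matrix E_ij = (a_ij / λ) S_ij; entries sum to 1."""
    M = _as_array(A)
    lam, w, v = _dominant_pair(M)
    S = np.outer(v, w) / (v @ w)
    return (M / lam) * S


def split_survival_fertility(A) -> tuple[np.ndarray, np.ndarray]:
    """Split A into survival transitions U and fertilities F.

    For a ``ProjectionMatrix`` the fertility is the configured top-right
    entry; for a bare array the first row above the diagonal is treated
    as fertility (adequate for Lefkovitch-form arrays).
    """
    if isinstance(A, ProjectionMatrix):
        M = A.matrix
        s = A.schema.n_stages
        Fm = np.zeros_like(M)
        Fm[0, s - 1] = A.F
        U = M - Fm
        return U, Fm
    M = np.asarray(A, dtype=float)
    Fm = np.zeros_like(M)
    Fm[0, 1:] = M[0, 1:]
    U = M - Fm
    return U, Fm


def net_reproductive_rate(A) -> float:
    """R₀: expected lifetime offspring per newborn.

    Dominant eigenvalue of F (I − U)⁻¹ with U the survival-transition
    part of A and F its fertility part; requires the spectral radius of
    U to be below 1 (no immortal stage).
    """
    U, Fm = split_survival_fertility(A)
    rho = float(np.max(np.abs(np.linalg.eigvals(U))))
    if rho >= 1.0:
        raise ValueError(
            f"survival part has spectral radius {rho:g} >= 1 (an immortal "
            f"stage); set adult_survival_override < 1"
        )
    R = Fm @ np.linalg.inv(np.eye(U.shape[0]) - U)
    vals = np.linalg.eigvals(R)
    return float(np.max(vals.real))


def generation_time(lam: float, R0: float) -> float:
    """Mean generation time T = ln R₀ / ln λ, in projection intervals."""
    if lam <= 0 or R0 <= 0:
        raise ValueError("generation time requires lambda > 0 and R0 > 0")
    if lam == 1.0:
        raise ValueError("generation time is undefined at lambda = 1")
    return math.log(R0) / math.log(lam)


def analyze(A: ProjectionMatrix) -> DemographyResult:
    """Full demographic summary of one projection matrix."""
    M = A.matrix
    lam, w_raw, v_raw = _dominant_pair(M)
    w = np.where(np.abs(w_raw) < 1e-14, 0.0, w_raw)
    w = w / w.sum()
    v = v_raw / (v_raw @ w)
    S = np.outer(v, w)
    E = (M / lam) * S
    R0 = net_reproductive_rate(A)
    if R0 > 0 and lam > 0 and lam != 1.0:
        T = generation_time(lam, R0)
    else:
        T = math.nan
    k = A.schema.projection_interval_days
    return DemographyResult(
        lam=lam, R0=R0, T_intervals=T, T_days=T * k, w=w, v=v, S=S, E=E
    )


def replicate_summary(results: list[DemographyResult]) -> dict[str, dict]:
    """Mean and standard error of λ, R₀ and T over replicate cohorts.

    T is averaged per cohort (each cohort's own ln R₀ / ln λ), matching
    replicate-structured reporting; with a single replicate the SE is
    returned as NaN.  A cohort whose growth chain is broken (R₀ = 0, so
    T is undefined) is excluded from that parameter's summary, and the
    number of such cohorts is reported as ``n_undefined``.
    """
    if len(results) == 0:
        raise ValueError("no replicates")
    out: dict[str, dict] = {}
    for name, values in [
        ("lambda", [r.lam for r in results]),
        ("R0", [r.R0 for r in results]),
        ("T_intervals", [r.T_intervals for r in results]),
        ("T_days", [r.T_days for r in results]),
    ]:
        x = np.asarray(values, dtype=float)
        finite = x[np.isfinite(x)]
        n = len(finite)
        mean = float(np.mean(finite)) if n else math.nan
        se = float(np.std(finite, ddof=1) / np.sqrt(n)) if n >= 2 else math.nan
        out[name] = {"mean": mean, "se": se, "n": n,
                     "n_undefined": int(len(x) - n)}
    return out
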