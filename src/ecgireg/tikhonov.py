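"""SVD-based zero-order Tikhonov solver.

The forward model of electrocardiology relates heart-surface potentials
``H_t`` (N_H epicardial mesh nodes) to body-surface potentials ``B_t``
(N_B electrodes) through a time-invariant transfer matrix ``A``::

    B_t = A @ H_t

The inverse problem is ill-posed (attenuation in the torso, N_H > N_B),
so the reconstruction minimizes a ridge criterion

    J(H) = ||A H - b||^2 + lambda^2 ||H||^2

whose closed-form solution, in terms of the SVD ``A = U S V^T``, is a
filtered expansion

    H_hat = sum_i  sigma_i / (sigma_i^2 + lambda^2) * (u_i^T b) * v_i .

Everything downstream (all lambda selectors, the L-curve, GCV, CRESO,
zero-crossing and U-curve objectives) is a closed-form function of the
singular values and the data projections ``u_i^T b``, so the SVD is
computed once per transfer matrix and cached in :class:`TransferModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransferModel", "BeatRecording", "EpicardialSolution",
    "decompose", "solve", "reconstruct", "norm_curves",
]


class DegenerateMatrixError(ValueError):
    """Raised when the transfer matrix has no usable singular spectrum."""


@dataclass(frozen=True)
class TransferModel:
    """Transfer matrix ``A`` together with its cached singular system.

    Attributes
    ----------
    A : ndarray, shape (n_body, n_heart)
        Lead-field matrix (dimensionless gains).
    U : ndarray, shape (n_body, k)
        Left singular vectors (thin SVD, k = min(n_body, n_heart)).
    sigma : ndarray, shape (k,)
        Singular values in non-increasing order.
    V : ndarray, shape (n_heart, k)
        Right singular vectors.
    r : int
        Numerical rank: number of singular values above the relative
        threshold used at decomposition time.
    """

    A: np.ndarray
    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    r: int

    @property
    def n_body(self) -> int:
        return self.A.shape[0]

    @property
    def n_heart(self) -> int:
        return self.A.shape[1]

    def projections(self, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(beta, b_perp2)`` for one instant or a whole beat.

        ``beta = U[:, :r].T @ b`` are the data projections onto the
        retained left singular subspace; ``b_perp2`` is the squared norm
        of the component of ``b`` outside it (per column for 2-D input).
        """
        b = np.asarray(b, dtype=float)
        beta = self.U[:, : self.r].T @ b
        b_perp2 = np.sum(b * b, axis=0) - np.sum(beta * beta, axis=0)
        return beta, np.maximum(b_perp2, 0.0)


@dataclass(frozen=True)
class BeatRecording:
    """Body-surface potentials for one beat.

    ``B`` is (n_body, T) in millivolts at sampling rate ``fs`` (Hz).
    ``qrs_window`` and ``t_window`` are half-open index ranges
    ``(start, stop)`` within ``[0, T)`` marking depolarization and
    repolarization; they must not overlap.
    """

    B: np.ndarray
    fs: float
    qrs_window: tuple[int, int]
    t_window: tuple[int, int]

    def __post_init__(self):
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 2 or B.shape[1] < 2:
            raise ValueError("B must be 2-D with at least 2 time samples")
        if not np.all(np.isfinite(B)):
            raise ValueError("B contains non-finite values")
        object.__setattr__(self, "B", B)
        T = B.shape[1]
        for name in ("qrs_window", "t_window"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= T):
                raise ValueError(f"{name} {lo, hi} outside [0, {T})")
        q0, q1 = self.qrs_window
        t0, t1 = self.t_window
        if max(q0, t0) < min(q1, t1):
            raise ValueError("qrs_window and t_window overlap")

    @property
    def n_samples(self) -> int:
        return self.B.shape[1]


@dataclass(frozen=True)
class EpicardialSolution:
    """Reconstructed (or true) heart-surface potentials for one beat."""

    H: np.ndarray          # (n_heart, T), millivolts
    lam: float             # regularization parameter used for the beat

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        if not np.all(np.isfinite(H)):
            raise ValueError("H contains non-finite values")
        object.__setattr__(self, "H", H)


def decompose(A: np.ndarray, rank_tol: float = 1e-12) -> TransferModel:
    """Compute the thin SVD of a transfer matrix and its numerical rank.

    Parameters
    ----------
    A : array_like, shape (n_body, n_heart)
    rank_tol : float
        Relative threshold: singular values above ``rank_tol * sigma_1``
        are retained.

    Notes
    -----
    Singular-vector signs are fixed by forcing the largest-magnitude
    entry of each left singular vector to be non-negative, so a
    serialized model is reproducible across LAPACK builds.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty transfer matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("transfer matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[0] <= 0.0:
        raise DegenerateMatrixError("all-zero transfer matrix")
    # deterministic sign convention
    pivot = np.argmax(np.abs(U), axis=0)
    flip = np.sign(U[pivot, np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U *= flip
    Vt *= flip[:, None]
    r = int(np.count_nonzero(s > rank_tol * s[0]))
    return TransferModel(A=A, U=U, sigma=s, V=Vt.T, r=r)


def solve(tm: TransferModel, b: np.ndarray, lam: float) -> np.ndarray:
    """Tikhonov solution for one time instant (or a whole beat).

    Implements ``H_hat = (A^T A + lam^2 I)^{-1} A^T b`` through the SVD
    filter factors ``sigma_i / (sigma_i^2 + lam^2)`` on the retained
    rank.  ``lam = 0`` is the truncated pseudoinverse (minimum-norm
    least squares on the retained spectrum).

    ``b`` may be a vector (n_body,) or matrix (n_body, T).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    b = np.asarray(b, dtype=float)
    if b.shape[0] != tm.n_body:
        raise ValueError(
            f"b has {b.shape[0]} rows, expected {tm.n_body}"
        )
    s = tm.sigma[: tm.r]
    beta, _ = tm.projections(b)
    filt = s / (s * s + lam * lam) if lam > 0 else 1.0 / s
    if b.ndim == 1:
        return tm.V[:, : tm.r] @ (filt * beta)
    return tm.V[:, : tm.r] @ (filt[:, None] * beta)


def reconstruct(tm: TransferModel, B: np.ndarray, lam: float) -> EpicardialSolution:
    """Reconstruct a whole beat (n_body, T) at one lambda."""
    return EpicardialSolution(H=solve(tm, B, lam), lam=float(lam))


def norm_curves(
    tm: TransferModel, b: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residual norm rho(lam) and solution norm eta(lam) on a lambda grid.

    These are the two axes of the L-curve and the ingredients of every
    selector objective.  With ``beta_i = u_i^T b`` and the component of
    ``b`` outside the retained left subspace ``b_perp``::

        eta(lam)^2 = sum_i [sigma_i beta_i / (sigma_i^2 + lam^2)]^2
        rho(lam)^2 = sum_i [lam^2 beta_i / (sigma_i^2 + lam^2)]^2 + ||b_perp||^2

    Returns ``(rho, eta)`` as 1-D arrays over the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly positive and increasing")
    beta, b_perp2 = tm.projections(np.asarray(b, dtype=float))
    rho2, eta2 = _rho2_eta2(tm.sigma[: tm.r], beta, b_perp2, grid)
    return np.sqrt(rho2), np.sqrt(eta2)


# ---------------------------------------------------------------------------
# Closed-form curve kernels shared with the selectors.  All work on
# x = lam^2 and broadcast a lambda grid (m,) against projections that are
# either (r,) for one instant or (r, T) for a beat.

def _rho2_eta2(s, beta, b_perp2, lam):
    """Squared residual/solution norms; shapes (m,) or (m, T)."""
    x = lam * lam                        # (m,)
    f = beta * beta                      # (r,) or (r, T)
    F = 1.0 / (s[None, :] ** 2 + x[:, None])   # (m, r)
    eta2 = (F * F * s[None, :] ** 2) @ f
    rho2 = ((x[:, None] * F) ** 2) @ f + b_perp2
    return rho2, eta2


def _curve_derivatives(s, beta, b_perp2, lam):
    """rho^2, eta^2 and their first/second derivatives w.r.t. x = lam^2.

    Termwise differentiation of the filter-factor sums::

        eta2   = sum s2 f / (s2+x)^2       d eta2/dx  = -2 sum s2 f/(s2+x)^3
        rho2   = sum x^2 f / (s2+x)^2 + c  d rho2/dx  =  2x sum s2 f/(s2+x)^3
        d2 eta2/dx2 = 6 sum s2 f/(s2+x)^4
        d2 rho2/dx2 = 2 sum s2 f (s2-2x)/(s2+x)^4
    """
    x = lam * lam
    f = beta * beta
    s2 = s[None, :] ** 2
    F = 1.0 / (s2 + x[:, None])
    F2 = F * F
    eta2 = (F2 * s2) @ f
    rho2 = (x[:, None] ** 2 * F2) @ f + b_perp2
    core3 = (F2 * F * s2) @ f           # sum s2 f/(s2+x)^3
    core4 = (F2 * F2 * s2) @ f          # sum s2 f/(s2+x)^4
    deta2 = -2.0 * core3
    drho2 = 2.0 * (x[:, None] * core3 if core3.ndim == 2 else x * core3)
    d2eta2 = 6.0 * core4
    d2rho2 = 2.0 * (((s2 - 2.0 * x[:, None]) * F2 * F2 * s2) @ f)
    return rho2, eta2, drho2, deta2, d2rho2, d2eta2
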