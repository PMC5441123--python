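"""ICA that preserves temporal structure via an autoregressive source model.

Standard ICA treats samples as i.i.d. and ignores the strong temporal
dependence of EEG.  The method here models the estimated sources with a
stationary autoregression, S_t = sum_K A_K S_{t-K} + Phi_t, fits the
regression coefficients by least squares, and applies the independence
criterion to the *residuals* Phi_t rather than the raw samples: the unmixing
matrix is updated by natural-gradient descent on an Infomax-style
negative log-likelihood whose score function is backpropagated through each
component's AR filter.  Because the innovations of distinct sources are
independent, this separates mixtures that sample-wise ICA cannot — including
Gaussian sources distinguishable only by their spectra.

Inside the unmixing loop the AR model is fit per component (diagonal
coefficients): the generative assumption is that *sources* are independent,
so cross-source lag coefficients vanish, and leaving them free would let a
full multivariate AR whiten any invertible remixing of the sources and erase
the very temporal cues that make the problem identifiable.  The unconstrained
multivariate fit remains available as :func:`fit_mvar` and via
``diagonal_ar=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: E[log cosh Z] for Z ~ N(0, 1); Gaussian baseline of the marginal term.
_GAUSS_LOGCOSH = 0.3745672966715523


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class MVARFit:
    """Least-squares multivariate AR fit: coefficients, residuals, diagnostics."""

    coeffs: np.ndarray        # (P, M, M); coeffs[k-1] = A_k
    order: int
    residuals: np.ndarray     # M x (T - P)
    residual_cov: np.ndarray  # M x M

    @property
    def residual_scale(self) -> np.ndarray:
        return np.sqrt(np.diag(self.residual_cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-step-ahead prediction of X[:, P:] from lagged values."""
        X = np.atleast_2d(X)
        P = self.order
        pred = np.zeros((X.shape[0], X.shape[1] - P))
        for k in range(1, P + 1):
            pred += self.coeffs[k - 1] @ X[:, P - k: X.shape[1] - k]
        return pred


def _lag_matrix(X: np.ndarray, order: int) -> np.ndarray:
    """Stack lags 1..P: rows [X_{t-1}; ...; X_{t-P}] for t = P..T-1."""
    M, T = X.shape
    return np.vstack([X[:, order - k: T - k] for k in range(1, order + 1)])


def fit_mvar(X: np.ndarray, order: int) -> MVARFit:
    """Fit S_t = sum_k A_k S_{t-k} + Phi_t by least squares.

    Minimizes sum_t ||V_t - A U_t||^2 over the coefficient matrix
    A = (A_1 .. A_P).  A rank-deficient regressor matrix triggers a ridge
    fallback (lambda = 1e-8 x trace of the Gram matrix) with a warning.
    """
    X = np.atleast_2d(np.asarray(X, float))
    M, T = X.shape
    if order < 0:
        raise ValueError("order must be >= 0")
    if order == 0:
        res = X.copy()
        return MVARFit(np.zeros((0, M, M)), 0, res, np.cov(res) if M > 1
                       else np.atleast_2d(np.var(res)))
    if T <= M * order + M:
        raise ValueError(f"T={T} too short for M={M}, P={order}")
    U = _lag_matrix(X, order)               # (M P) x (T - P)
    V = X[:, order:]
    G = U @ U.T
    rank = np.linalg.matrix_rank(G)
    if rank < M * order:
        lam = 1e-8 * np.trace(G)
        warnings.warn(f"rank-deficient regressors (rank {rank} < {M * order}); "
                      f"ridge fallback lambda={lam:.3g}")
        A_flat = np.linalg.solve(G + lam * np.eye(G.shape[0]), U @ V.T).T
    else:
        A_flat = np.linalg.solve(G, U @ V.T).T
    E = V - A_flat @ U
    coeffs = A_flat.reshape(M, order, M).transpose(1, 0, 2)
    cov = (E @ E.T) / E.shape[1]
    return MVARFit(coeffs, order, E, cov)


def _fit_diagonal_ar(X: np.ndarray, order: int) -> np.ndarray:
    """Per-row univariate AR(P) least-squares coefficients, shape (M, P).

    Solved through the normal equations on the per-row lag matrix (the lag
    Gram matrices are tiny, P x P), equivalent to the least-squares fit.
    """
    M, T = X.shape
    A = np.zeros((M, order))
    if order == 0:
        return A
    for i in range(M):
        u = np.lib.stride_tricks.sliding_window_view(X[i], order)[: T - order]
        u = u[:, ::-1]                      # columns = lags 1..P
        v = X[i, order:]
        G = u.T @ u
        try:
            A[i] = np.linalg.solve(G, u.T @ v)
        except np.linalg.LinAlgError:
            A[i] = np.linalg.lstsq(u, v, rcond=None)[0]
    return A


def residual_mutual_information(E: np.ndarray) -> float:
    """Dependence contrast of residual rows; >= 0, ~0 iff jointly Gaussian
    with uncorrelated rows (under the log-cosh surrogate).

    Sum of the Gaussian mutual information implied by the correlation matrix
    (-1/2 log det R) and a marginal non-Gaussianity surrogate per row,
    (E[log cosh e] - E[log cosh Z])^2 on standardized residuals.
    """
    E = np.atleast_2d(np.asarray(E, float))
    if E.shape[0] < 2:
        raise ValueError("need at least 2 residual rows")
    sd = E.std(axis=1)
    if np.any(sd <= 0):
        raise ValueError("zero-variance residual row")
    Z = (E - E.mean(axis=1, keepdims=True)) / sd[:, None]
    R = (Z @ Z.T) / Z.shape[1]
    eig = np.clip(np.linalg.eigvalsh(R), 1e-12, None)
    gaussian_mi = -0.5 * float(np.sum(np.log(eig)))
    marginal = float(np.sum((np.mean(np.log(np.cosh(Z)), axis=1)
                             - _GAUSS_LOGCOSH) ** 2))
    return gaussian_mi + marginal


@dataclass
class UnmixingModel:
    """Whitening + unmixing learned by temporal ICA, with diagnostics.

    ``transform`` maps channel data to independent components via
    ``unmixing @ whitener @ (data - mean)``.  Rows are scaled to unit residual
    variance, ordered by explained component power (descending) and
    sign-fixed so each component's largest-magnitude mixing entry is positive.
    """

    mean: np.ndarray          # (C,)
    whitener: np.ndarray      # M x C
    unmixing: np.ndarray      # M x M
    mvar: MVARFit             # AR fit on the final components
    history: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def separator(self) -> np.ndarray:
        """Total M x C separating matrix (unmixing @ whitener)."""
        return self.unmixing @ self.whitener

    @property
    def mixing_estimate(self) -> np.ndarray:
        """C x M pseudo-inverse mixing (scalp pattern per component)."""
        return np.linalg.pinv(self.separator)

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.atleast_2d(np.asarray(data, float))
        if data.shape[0] != self.mean.size:
            raise ValueError(
                f"data has {data.shape[0]} channels, model expects {self.mean.size}")
        return self.separator @ (data - self.mean[:, None])


def transform(model: UnmixingModel, data: np.ndarray) -> np.ndarray:
    return model.transform(data)


def _objective(W: np.ndarray, E: np.ndarray) -> float:
    """Negative log-likelihood (up to constants) of the Infomax model."""
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0 or not np.isfinite(logdet):
        return np.inf
    return float(-logdet + np.mean(np.sum(np.log(np.cosh(E)), axis=0)))


def _ar_residuals(S: np.ndarray, A_diag: np.ndarray) -> np.ndarray:
    """Residuals of per-component AR prediction (valid part, t >= P)."""
    M, T = S.shape
    P = A_diag.shape[1]
    if P == 0:
        return S.copy()
    E = S[:, P:].copy()
    for k in range(1, P + 1):
        E -= A_diag[:, k - 1][:, None] * S[:, P - k: T - k]
    return E


def fit_unmixing(X: np.ndarray, order: int = 6, *, lr: float = 0.05,
                 max_iter: int = 500, tol: float = 1e-6, seed: int = 0,
                 refit_every: int = 1, diagonal_ar: bool = True,
                 whiten_tol: float = 1e-9,
                 whiten_var: float = None) -> UnmixingModel:
    """Estimate the unmixing matrix by natural-gradient residual ICA.

    Alternates (a) component extraction S = W x whitened data, (b) AR
    coefficient refit on S by least squares, (c) a natural-gradient step
    W <- W + lr (I - phi(E) Etilde^T / T) W, where E are the AR residuals,
    phi = tanh, and Etilde carries the AR-filtered components so the score
    is propagated through each component's temporal filter.  Steps are
    accepted only if the objective does not increase; on 10 consecutive
    rejections the rate is halved and the search restarts from the best W.

    Parameters follow the usual conventions: ``order`` is the AR order P,
    ``tol`` the relative objective change at which iteration stops.  By
    default whitening keeps the full numerical rank; setting ``whiten_var``
    (e.g. 0.99) truncates the PCA to the leading directions explaining that
    fraction of variance, which turns the unmixing into a denoising
    projection onto the signal subspace — the configuration the EEG
    feature-extraction pipeline uses, since a square invertible transform
    would leave downstream spatial filtering essentially unchanged.
    """
    X = np.atleast_2d(np.asarray(X, float))
    C, T = X.shape
    if C < 2:
        raise ValueError("need at least 2 input components")
    if T <= C * order + C:
        raise ValueError(f"T={T} too short for C={C}, P={order}")
    rng = np.random.default_rng(seed)

    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / T
    eval_, evec = np.linalg.eigh(cov)
    keep = eval_ > whiten_tol * eval_.max()
    eval_, evec = eval_[keep], evec[:, keep]
    if whiten_var is not None:
        order_desc = np.argsort(-eval_)
        cum = np.cumsum(eval_[order_desc]) / eval_.sum()
        m = max(int(np.searchsorted(cum, whiten_var) + 1), 2)
        sel = order_desc[:m]
        eval_, evec = eval_[sel], evec[:, sel]
    Z = (evec / np.sqrt(eval_)).T            # M x C whitener
    M = Z.shape[0]
    Y = Z @ Xc

    W = np.eye(M) + 0.01 * rng.standard_normal((M, M))
    lr0 = lr

    def residual_state(Wc):
        S = Wc @ Y
        if diagonal_ar:
            A = _fit_diagonal_ar(S, order)
            E = _ar_residuals(S, A)
        else:
            fit = fit_mvar(S, order)
            A, E = fit, fit.residuals
        return S, A, E

    S, A, E = residual_state(W)
    J = _objective(W, E)
    history = [J]
    best_W, best_J = W.copy(), J
    bad = 0
    for it in range(max_iter):
        phi = np.tanh(E)
        Tn = E.shape[1]
        if diagonal_ar and order > 0:
            # F_il = mean_t phi(e_i(t)) * (component l filtered by row i's AR)
            #      = C0_il - sum_k a_ik Ck_il with lagged cross-products
            F = (phi @ S[:, order:].T) / Tn
            for k in range(1, order + 1):
                Ck = (phi @ S[:, order - k: S.shape[1] - k].T) / Tn
                F -= A[:, k - 1][:, None] * Ck
        else:
            F = (phi @ E.T) / Tn
        W_new = W + lr * (np.eye(M) - F) @ W

        refit = (it + 1) % max(refit_every, 1) == 0
        S_new = W_new @ Y
        if diagonal_ar:
            A_new = _fit_diagonal_ar(S_new, order) if refit else A
            E_new = _ar_residuals(S_new, A_new)
        else:
            A_new = fit_mvar(S_new, order) if refit else A
            E_new = (S_new[:, order:] - A_new.predict(S_new)) if not refit \
                else A_new.residuals
        J_new = _objective(W_new, E_new)

        if np.isfinite(J_new) and J_new <= best_J + abs(best_J) * 1e-12:
            rel = abs(best_J - J_new) / max(abs(best_J), 1e-12)
            W, S, A, E, J = W_new, S_new, A_new, E_new, J_new
            best_W, best_J = W.copy(), J
            history.append(J)
            bad = 0
            lr = min(lr * 1.05, lr0)
            if rel < tol:
                break
        else:
            bad += 1
            lr *= 0.5
            W = best_W.copy()
            S, A, E = residual_state(W)
            if lr < lr0 / 2 ** 10:
                if bad > 10:
                    raise ConvergenceError(
                        "natural-gradient updates kept increasing the "
                        "objective", history)
                break

    # --- canonical form: unit residual variance, power order, sign fix ----
    S = W @ Y
    final = fit_mvar(S, order) if order > 0 else fit_mvar(S, 0)
    scale = final.residual_scale
    scale[scale <= 0] = 1.0
    W = W / scale[:, None]
    S = W @ Y
    power = S.var(axis=1)
    idx = np.argsort(-power)
    W = W[idx]
    mix = np.linalg.pinv(W @ Z)
    signs = np.sign(mix[np.argmax(np.abs(mix), axis=0), np.arange(M)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    S = W @ Y
    final = fit_mvar(S, order)
    if np.linalg.cond(W) > 1e8:
        warnings.warn("unmixing matrix is ill-conditioned")
    return UnmixingModel(mean, Z, W, final, history,
                         dict(order=order, lr=lr0, max_iter=max_iter, tol=tol,
                              seed=seed, refit_every=refit_every,
                              diagonal_ar=diagonal_ar, whiten_var=whiten_var))


class TemporalICA:
    """Estimator-style wrapper: ``TemporalICA(order=6).fit(X)`` -> model."""

    def __init__(self, order: int = 6, lr: float = 0.05, max_iter: int = 500,
                 tol: float = 1e-6, seed: int = 0, refit_every: int = 1,
                 diagonal_ar: bool = True):
        self.order, self.lr, self.max_iter = order, lr, max_iter
        self.tol, self.seed = tol, seed
        self.refit_every, self.diagonal_ar = refit_every, diagonal_ar

    def fit(self, X: np.ndarray) -> UnmixingModel:
        return fit_unmixing(X, self.order, lr=self.lr, max_iter=self.max_iter,
                            tol=self.tol, seed=self.seed,
                            refit_every=self.refit_every,
                            diagonal_ar=self.diagonal_ar)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of P = W_total @ A_true.

    0 for a scaled permutation matrix; O(1) for a random matrix.
    """
    P = np.abs(np.atleast_2d(P))
    M = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * M * (M - 1)))
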