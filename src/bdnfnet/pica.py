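"""Two-modality parallel independent component analysis (fusion ICA).

Each modality (subjects x features: SNP weighted-genotype values, or in-mask
gray-matter voxels) is PCA-whitened and unmixed by infomax ICA (natural
gradient ascent of the entropy of logistically squashed sources).  After each
epoch a constraint step nudges the currently most-correlated pair of
subject-loading columns across the two modalities up the squared-correlation
gradient, so the decomposition favours components whose expression across
subjects is linked between modalities.  With constraint weight 0 the run is
exactly two independent infomax ICAs.

Model per modality: X (n x m) ~ A S with loadings A (n x k, per-subject
component expression) and sources S (k x m, unit-variance feature patterns).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = ["PICAResult", "estimate_order_mdl", "fit_infomax",
           "fit_parallel_ica", "threshold_component", "correlate_loadings",
           "compare_groups"]


# ---------------------------------------------------------------------------
# MDL model-order selection
# ---------------------------------------------------------------------------

def estimate_order_mdl(X: np.ndarray) -> int:
    """Minimum-description-length choice of the number of components.

    Eigenvalues of the subject-by-subject covariance (features as
    observations) enter the classical criterion: for candidate order k,
    -N (p-k) log(geometric/arithmetic mean of trailing eigenvalues) plus the
    penalty 0.5 k (2p - k) log N.  Returns argmin k, floored at 1 (a
    no-structure warning is emitted when the criterion prefers 0), capped at
    the numerical rank.
    """
    X = np.asarray(X, dtype=float)
    p, m = X.shape
    if p < 3:
        raise ValueError("need at least 3 subjects")
    Xc = X - X.mean(axis=1, keepdims=True)
    lam = np.linalg.eigvalsh(Xc @ Xc.T / m)[::-1]
    rank = int((lam > lam[0] * 1e-10).sum())
    lam = np.maximum(lam, lam[0] * 1e-12)
    N = m
    mdl = np.empty(rank)
    for k in range(rank):
        tail = lam[k:]
        g = np.exp(np.mean(np.log(tail)))
        a = np.mean(tail)
        mdl[k] = -N * (p - k) * np.log(g / a) + 0.5 * k * (2 * p - k) * np.log(N)
    k = int(np.argmin(mdl))
    if k == 0:
        warnings.warn("MDL found no structure; returning order 1", stacklevel=2)
        k = 1
    return k


# ---------------------------------------------------------------------------
# Infomax ICA with optional cross-modality constraint
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PICAResult:
    loadings: list          # per modality: (n_subjects, k)
    sources: list           # per modality: (k, n_features), unit-variance rows
    sources_z: list         # per modality: row-wise z-scored sources
    loading_corr: np.ndarray
    loading_corr_p: np.ndarray
    converged: list
    n_iter: list
    seed: int


class _InfomaxState:
    """One modality's whitening + infomax state; stepped one epoch at a time.

    The state's random stream depends only on (seed, modality index), so a
    parallel run with constraint weight 0 reproduces a solo run bitwise.
    """

    def __init__(self, X: np.ndarray, k: int, seed: int, lr: float | None = None,
                 batch: int = 256):
        X = np.asarray(X, dtype=float)
        self.n, self.m = X.shape
        if not 1 <= k <= self.n - 1:
            raise ValueError("k must be in [1, subjects-1]")
        self.k = k
        self.mean = X.mean(axis=0)
        Xc = X - self.mean
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        self.Y = np.sqrt(self.m) * Vt[:k]              # whitened (k x m)
        self.M = U[:, :k] * s[:k] / np.sqrt(self.m)    # dewhitening (n x k)
        self.W = np.eye(k)
        self.lr = 0.015 / np.log(k + 2) if lr is None else lr
        self.lr0 = self.lr
        self.batch = min(batch, self.m)
        self.rng = np.random.default_rng([seed, self.n, self.m, k])
        self.entropy = -np.inf
        self.last_delta = np.inf
        self._prev_dW = None

    def epoch(self) -> bool:
        """One pass of natural-gradient infomax over shuffled feature batches.

        Returns True when the entropy objective decreased (anneal signal).
        """
        W0 = self.W.copy()
        perm = self.rng.permutation(self.m)
        I = np.eye(self.k)
        for start in range(0, self.m, self.batch):
            idx = perm[start:start + self.batch]
            u = self.W @ self.Y[:, idx]
            y = expit(u)
            grad = (I + ((1 - 2 * y) @ u.T) / len(idx)) @ self.W
            self.W = self.W + self.lr * grad
        dW = (self.W - W0).ravel()
        self.last_delta = float(np.abs(self.W - W0).max())
        # anneal when consecutive updates turn by more than 60 degrees
        if self._prev_dW is not None:
            denom = np.linalg.norm(dW) * np.linalg.norm(self._prev_dW)
            if denom > 0 and dW @ self._prev_dW < 0.5 * denom:
                self.lr *= 0.95
        self._prev_dW = dW
        u = self.W @ self.Y
        ent = float(np.mean(np.log(expit(u) * expit(-u) + 1e-300))
                    + np.linalg.slogdet(self.W)[1])
        decreased = ent < self.entropy
        self.entropy = ent
        return decreased

    def unmix(self) -> tuple[np.ndarray, np.ndarray]:
        """Current (loadings, sources) with unit-variance source rows."""
        S = self.W @ self.Y
        A = self.M @ np.linalg.inv(self.W)
        sd = S.std(axis=1)
        sd[sd == 0] = 1.0
        return A * sd, S / sd[:, None]


def _finalize(state: _InfomaxState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A, S = state.unmix()
    # order by variance explained, fix sign so the largest-|weight| feature is positive
    expl = (A ** 2).sum(axis=0)
    order = np.argsort(-expl, kind="stable")
    A, S = A[:, order], S[order]
    for i in range(S.shape[0]):
        j = int(np.argmax(np.abs(S[i])))
        if S[i, j] < 0:
            S[i] *= -1
            A[:, i] *= -1
    Sz = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    return A, S, Sz


def _corr_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of corr(x, y)^2 with respect to x."""
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return np.zeros_like(x)
    c = float(xc @ yc / (nx * ny))
    dc = (yc / ny - c * xc / nx) / nx
    dc -= dc.mean()
    return 2 * c * dc


def fit_infomax(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 512,
                tol: float = 1e-6, lr: float | None = None):
    """Plain single-modality infomax ICA (the constraint-free reference path)."""
    state = _InfomaxState(X, k, seed, lr=lr)
    n_iter, converged = 0, False
    for n_iter in range(1, max_iter + 1):
        state.epoch()
        if state.last_delta < tol:
            converged = True
            break
    A, S, Sz = _finalize(state)
    return A, S, Sz, converged, n_iter


def fit_parallel_ica(
    X1: np.ndarray,
    X2: np.ndarray,
    k1: int,
    k2: int,
    lam: float = 1.0,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    lr: float | None = None,
) -> PICAResult:
    """Joint infomax over two subject-aligned modalities.

    After every epoch the loading-column pair with the largest absolute
    cross-modality correlation takes a gradient step of size ``lam`` x the
    current learning rate up the squared correlation (applied to the
    unmixing inverses, so sources stay consistent); ``lam`` is halved
    whenever a modality's entropy objective decreases.  ``lam = 0``
    reproduces two independent infomax runs bitwise.
    """
    if lam < 0:
        raise ValueError("constraint weight must be >= 0")
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("modalities must share the subject dimension")
    s1 = _InfomaxState(X1, k1, seed, lr=lr)
    s2 = _InfomaxState(X2, k2, seed, lr=lr)
    lam_t = lam
    n_iter = 0
    if lam == 0:
        # exact reduction: each modality runs and stops as a solo infomax would
        done1 = done2 = False
        for n_iter in range(1, max_iter + 1):
            if not done1:
                s1.epoch()
                done1 = s1.last_delta < tol
            if not done2:
                s2.epoch()
                done2 = s2.last_delta < tol
            if done1 and done2:
                break
    else:
        for n_iter in range(1, max_iter + 1):
            dec1 = s1.epoch()
            dec2 = s2.epoch()
            if dec1 or dec2:
                lam_t *= 0.5
            A1, _ = s1.unmix()
            A2, _ = s2.unmix()
            C = _colwise_corr(A1, A2)
            i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
            B1 = np.linalg.inv(s1.W)
            B2 = np.linalg.inv(s2.W)
            g1 = s1.M.T @ _corr_grad(A1[:, i], A2[:, j])
            g2 = s2.M.T @ _corr_grad(A2[:, j], A1[:, i])
            B1[:, i] += lam_t * s1.lr0 * g1
            B2[:, j] += lam_t * s2.lr0 * g2
            s1.W = np.linalg.inv(B1)
            s2.W = np.linalg.inv(B2)
            if s1.last_delta < tol and s2.last_delta < tol:
                break
    A1, S1, Sz1 = _finalize(s1)
    A2, S2, Sz2 = _finalize(s2)
    corr, pval = correlate_loadings(A1, A2)
    return PICAResult(
        loadings=[A1, A2], sources=[S1, S2], sources_z=[Sz1, Sz2],
        loading_corr=corr, loading_corr_p=pval,
        converged=[s1.last_delta < tol, s2.last_delta < tol],
        n_iter=[n_iter, n_iter], seed=seed,
    )


# ---------------------------------------------------------------------------
# Post-hoc statistics
# ---------------------------------------------------------------------------

def threshold_component(weights: np.ndarray, z_thresh: float = 2.5) -> np.ndarray:
    """Indices of features whose |z-scored weight| strictly exceeds the cut.

    z is computed over the component's own feature weights; a weight at
    exactly the threshold is excluded.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size < 2:
        raise ValueError("need at least 2 features")
    sd = weights.std()
    if sd == 0:
        raise ValueError("zero-variance component weights")
    z = (weights - weights.mean()) / sd
    return np.flatnonzero(np.abs(z) > z_thresh)


def _colwise_corr(A1: np.ndarray, A2: np.ndarray) -> np.ndarray:
    a = A1 - A1.mean(axis=0)
    b = A2 - A2.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    na[na == 0] = np.nan
    nb[nb == 0] = np.nan
    return (a.T @ b) / np.outer(na, nb)


def correlate_loadings(A1: np.ndarray, A2: np.ndarray):
    """Pearson correlation of every loading-column pair, with two-sided p.

    p-values come from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom;
    a constant column yields NaN entries (flagged undefined).
    """
    n = A1.shape[0]
    if A2.shape[0] != n or n < 4:
        raise ValueError("need equal subject counts of at least 4")
    r = _colwise_corr(A1, A2)
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def compare_groups(A: np.ndarray, groups, welch: bool = False):
    """Student's t comparison of per-component mean loadings between groups.

    Default is the classical pooled-variance test with df = n1 + n2 - 2;
    Welch's unequal-variance variant is available behind the flag.  Returns a
    list of dicts (component, mean_low/high by label order, t, p, df).
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    g1, g2 = (A[groups == lab] for lab in labels)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    out = []
    for c in range(A.shape[1]):
        x, y = g1[:, c], g2[:, c]
        n1, n2 = len(x), len(y)
        if welch:
            v1, v2 = x.var(ddof=1), y.var(ddof=1)
            se2 = v1 / n1 + v2 / n2
            if se2 == 0:
                raise ValueError("zero variance in both groups")
            t = (x.mean() - y.mean()) / np.sqrt(se2)
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
            if sp2 == 0:
                raise ValueError("zero pooled variance")
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
        p = 2 * stats.t.sf(abs(t), df=df)
        out.append({"component": c, f"mean_{labels[0]}": float(x.mean()),
                    f"mean_{labels[1]}": float(y.mean()), "t": float(t),
                    "p": float(p), "df": float(df)})
    return out
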