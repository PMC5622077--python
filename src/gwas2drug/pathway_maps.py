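"""Kernel-GTM pathway maps.

Gene-sets encoded as binary gene-content vectors are compared with the
Tanimoto (Jaccard) similarity, embedded via kernel PCA, and summarized by a
generative topographic map (GTM): a constrained Gaussian mixture whose
component means are the image of a regular 2D latent grid under a smooth
RBF mapping, trained by EM.  Each gene-set projects to the posterior mean of
its responsibilities over the latent grid, giving 2D map coordinates; the
map is colored by association strength (-log10 p) interpolated with
ordinary kriging.

Hyperparameters follow the square-root rules: k = sqrt(N) grid nodes per
side, m = sqrt(k) RBF centers per side, regularization l = 1, RBF width
factor w = 1, and feature dimension D = number of kernel principal
components explaining 99.5% of the variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import logsumexp

__all__ = [
    "MembershipMatrix",
    "tanimoto_matrix",
    "feature_dim",
    "kernel_pca_embedding",
    "GtmModel",
    "kgtm_fit",
    "MapProjection",
    "project",
    "ordinary_kriging",
    "krige_surface",
    "select_top_sets",
]


def membership_matrix(sets: dict[str, set[str]], universe: list[str] | None = None):
    """Binary sets-by-genes matrix from a gene-set collection."""
    if universe is None:
        universe = sorted(set().union(*sets.values()))
    idx = {g: j for j, g in enumerate(universe)}
    M = np.zeros((len(sets), len(universe)), dtype=np.int8)
    ids = list(sets)
    for i, sid in enumerate(ids):
        for g in sets[sid]:
            if g in idx:
                M[i, idx[g]] = 1
    return ids, M


MembershipMatrix = np.ndarray  # sets x genes, binary, no all-zero row


def tanimoto_matrix(M: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity K_ij = |Ai ∩ Aj| / |Ai ∪ Aj|."""
    M = np.asarray(M, dtype=float)
    sizes = M.sum(axis=1)
    empty = np.flatnonzero(sizes == 0)
    if empty.size:
        raise ValueError(f"empty gene-set(s) at rows {empty.tolist()}")
    inter = M @ M.T
    union = sizes[:, None] + sizes[None, :] - inter
    return inter / union


def _centered_spectrum(K: np.ndarray):
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    Kc = (Kc + Kc.T) / 2.0
    lam, V = np.linalg.eigh(Kc)
    order = np.argsort(lam)[::-1]
    return lam[order], V[:, order]


def feature_dim(K: np.ndarray, variance_fraction: float = 0.995) -> int:
    """Number of kernel principal components explaining the given variance
    fraction of the double-centered kernel (D >= 1)."""
    lam, _ = _centered_spectrum(K)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 1e-12:
        warnings.warn("all gene-sets identical: zero variance, D = 1")
        return 1
    csum = np.cumsum(lam)
    D = int(np.searchsorted(csum, variance_fraction * total - 1e-12) + 1)
    return max(1, D)


def kernel_pca_embedding(K: np.ndarray, D: int | None = None, variance_fraction: float = 0.995):
    """Kernel-PCA coordinates X (N x D) such that ||x_i - x_j||^2 reproduces
    the kernel-induced squared distance K_ii + K_jj - 2 K_ij (at full D)."""
    if D is None:
        D = feature_dim(K, variance_fraction)
    lam, V = _centered_spectrum(K)
    lam = np.clip(lam[:D], 0.0, None)
    return V[:, :D] * np.sqrt(lam)[None, :]


@dataclass
class GtmModel:
    nodes: np.ndarray          # K x 2 latent grid in [-1, 1]^2
    centers: np.ndarray        # M x 2 RBF centers
    sigma: float               # RBF width
    W: np.ndarray              # (M+1) x D mapping weights (with bias row)
    beta: float                # noise precision
    responsibilities: np.ndarray  # K x N
    loglik_trace: list[float] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)  # penalized LL
    X: np.ndarray | None = None   # N x D embedded data
    converged: bool = False


def _grid(side: int) -> np.ndarray:
    g = np.linspace(-1.0, 1.0, side) if side > 1 else np.array([0.0])
    xx, yy = np.meshgrid(g, g)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _phi(nodes: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((nodes[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    Phi = np.exp(-d2 / (2.0 * sigma**2))
    return np.column_stack([Phi, np.ones(len(nodes))])  # bias column


def kgtm_fit(
    K: np.ndarray,
    l: float = 1.0,
    w: float = 1.0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GtmModel:
    """Fit a GTM to the kernel-PCA embedding of a Tanimoto kernel.

    Grid side k = round(sqrt(N)), RBF side m = round(sqrt(k)), both floored
    at 2.  Initialization maps the latent grid through the first two
    principal components of the embedding, so the fit is deterministic; the
    seed only covers residual randomness (none in the default path).

    EM maximizes the penalized log-likelihood (log-likelihood minus
    (l/2)||W||^2, the MAP objective for a Gaussian weight prior); the
    penalized objective is guaranteed non-decreasing and is used for the
    convergence test.
    """
    K = np.asarray(K, dtype=float)
    N = K.shape[0]
    if N < 4:
        raise ValueError("need at least 4 gene-sets")
    lam_k = np.linalg.eigvalsh((K + K.T) / 2.0)
    if lam_k.min() < -1e-6 * max(1.0, lam_k.max()):
        raise ValueError("kernel is not positive semidefinite")
    D = feature_dim(K)
    X = kernel_pca_embedding(K, D)

    k_side = max(2, round(np.sqrt(N)))
    m_side = max(2, round(np.sqrt(k_side)))
    nodes = _grid(k_side)
    centers = _grid(m_side)
    spacing = 2.0 / (m_side - 1)
    sigma = w * spacing
    Phi = _phi(nodes, centers, sigma)
    Kn, M1 = Phi.shape

    # PCA init: latent axes -> first two principal directions of X.
    # X columns are already principal axes (kernel PCA), scaled by sqrt(eig);
    # map node coords onto the first two columns at matching scale.
    sd = X.std(axis=0, ddof=0)
    Y_target = np.zeros((Kn, D))
    Y_target[:, 0] = nodes[:, 0] * (sd[0] if sd[0] > 0 else 1.0)
    if D > 1:
        Y_target[:, 1] = nodes[:, 1] * (sd[1] if sd[1] > 0 else 1.0)
    W, *_ = np.linalg.lstsq(Phi, Y_target, rcond=None)
    Y = Phi @ W
    d2 = ((Y[:, None, :] - X[None, :, :]) ** 2).sum(-1)  # K x N
    beta = 1.0 / max(d2.mean(), 1e-12)

    model = GtmModel(nodes, centers, sigma, W, beta, np.full((Kn, N), 1.0 / Kn), X=X)
    prev_obj = -np.inf
    for _ in range(max_iter):
        # E-step
        log_r = -0.5 * beta * d2
        log_norm = logsumexp(log_r, axis=0)
        R = np.exp(log_r - log_norm)
        ll = float(np.sum(log_norm) + N * (0.5 * D * np.log(beta / (2 * np.pi)) - np.log(Kn)))
        obj = ll - 0.5 * l * float((W[:-1] ** 2).sum())
        model.loglik_trace.append(ll)
        model.objective_trace.append(obj)
        if obj < prev_obj - 1e-9 * max(1.0, abs(prev_obj)):
            raise RuntimeError("EM objective decreased: internal error")
        if prev_obj > -np.inf and abs(obj - prev_obj) < tol * max(1.0, abs(prev_obj)):
            model.converged = True
            break
        prev_obj = obj
        # M-step: weights (ridge on non-bias rows), then noise precision
        G = R.sum(axis=1)
        A = Phi.T @ (Phi * G[:, None])
        reg = (l / beta) * np.eye(M1)
        reg[-1, -1] = 0.0  # bias unpenalized
        W = np.linalg.solve(A + reg, Phi.T @ (R @ X))
        Y = Phi @ W
        d2 = ((Y[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        beta = N * D / max(float((R * d2).sum()), 1e-300)
        model.W, model.beta = W, beta

    # final responsibilities at the last parameters
    log_r = -0.5 * beta * d2
    R = np.exp(log_r - logsumexp(log_r, axis=0))
    model.responsibilities = R
    return model


@dataclass
class MapProjection:
    set_ids: list[str]
    coords: np.ndarray      # N x 2 posterior-mean positions in [-1, 1]^2
    colors: np.ndarray      # -log10(p_competitive) per set

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": self.set_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "neglog10p": self.colors,
            }
        )


def project(model: GtmModel, set_ids=None, colors=None) -> MapProjection:
    """Posterior-mean 2D coordinates: coords_n = sum_a R_an u_a."""
    coords = model.responsibilities.T @ model.nodes
    n = coords.shape[0]
    if set_ids is None:
        set_ids = [str(i) for i in range(n)]
    if colors is None:
        colors = np.zeros(n)
    return MapProjection(list(set_ids), coords, np.asarray(colors, dtype=float))


def _exp_variogram(h, nugget, sill, rng):
    return nugget + sill * (1.0 - np.exp(-h / np.maximum(rng, 1e-12)))


def _fit_variogram(points: np.ndarray, values: np.ndarray, n_bins: int = 12):
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(points), 1)
    h = d[iu]
    gamma = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    edges = np.linspace(0, h.max(), n_bins + 1)
    hc, gc, wc = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (h > a) & (h <= b)
        if mask.sum() > 0:
            hc.append(h[mask].mean())
            gc.append(gamma[mask].mean())
            wc.append(mask.sum())
    hc, gc, wc = map(np.asarray, (hc, gc, wc))
    p0 = [0.0, max(gc.max(), 1e-12), max(h.max() / 3.0, 1e-6)]
    popt, _ = curve_fit(
        _exp_variogram, hc, gc, p0=p0, sigma=1.0 / np.sqrt(wc),
        bounds=([0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]), maxfev=5000,
    )
    return popt  # nugget, sill, range


def ordinary_kriging(
    points: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    variogram: tuple[float, float, float],
) -> np.ndarray:
    """Ordinary-kriging prediction at target locations.

    Solves the standard system with the Lagrange multiplier enforcing unit
    weight sum; exact interpolator at data points when the nugget is zero.
    Accepts any n >= 1 (a single point predicts its own value everywhere).
    """
    points = np.atleast_2d(points)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(targets)
    n = len(points)
    if n == 1:
        return np.full(len(targets), values[0])
    nugget, sill, rng = variogram
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    G = _exp_variogram(d, nugget, sill, rng)
    np.fill_diagonal(G, 0.0)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[n, :n] = A[:n, n] = 1.0
    dt = np.sqrt(((targets[:, None] - points[None, :]) ** 2).sum(-1))
    B = np.column_stack([_exp_variogram(dt, nugget, sill, rng), np.ones(len(targets))])
    try:
        lam = np.linalg.solve(A, B.T)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(A, B.T, rcond=None)[0]
    return lam[:n].T @ values


def krige_surface(
    projection: MapProjection, grid_resolution: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Ordinary-kriging color surface over the [-1, 1]^2 map.

    Returns (grid_x, grid_y, surface, meta).  The exponential variogram is
    fitted by weighted least squares to the binned empirical semivariogram;
    when fitting fails the surface falls back to inverse-distance weighting,
    flagged in ``meta['method']``.
    """
    pts_all = np.asarray(projection.coords, dtype=float)
    vals_all = np.asarray(projection.colors, dtype=float)
    # average duplicated locations
    uniq, inv = np.unique(np.round(pts_all, 12), axis=0, return_inverse=True)
    vals = np.array([vals_all[inv == i].mean() for i in range(len(uniq))])
    pts = uniq
    if len(pts) < 3:
        raise ValueError("kriging requires at least 3 distinct points")
    g = np.linspace(-1, 1, grid_resolution)
    gx, gy = np.meshgrid(g, g)
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    if np.ptp(vals) < 1e-12:
        return gx, gy, np.full(gx.shape, vals[0]), {"method": "constant"}
    try:
        variogram = _fit_variogram(pts, vals)
        surf = ordinary_kriging(pts, vals, targets, tuple(variogram))
        meta = {"method": "ordinary_kriging",
                "variogram": {"nugget": variogram[0], "sill": variogram[1], "range": variogram[2]}}
    except Exception as exc:  # variogram fit failure -> documented fallback
        d = np.sqrt(((targets[:, None] - pts[None, :]) ** 2).sum(-1))
        wgt = 1.0 / np.maximum(d, 1e-12) ** 2
        surf = (wgt @ vals) / wgt.sum(axis=1)
        exactly = d.min(axis=1) < 1e-12
        if exactly.any():
            surf[exactly] = vals[d.argmin(axis=1)[exactly]]
        meta = {"method": "idw", "reason": str(exc)}
    return gx, gy, surf.reshape(gx.shape), meta


def select_top_sets(set_results: pd.DataFrame, n: int = 50) -> pd.DataFrame:
    """The n gene-sets with smallest competitive p; ties broken by set_id."""
    df = set_results.sort_values(["p_competitive", "set_id"], kind="stable")
    if len(df) < n:
        warnings.warn(f"only {len(df)} sets available; requested {n}")
        return df.reset_index(drop=True)
    return df.head(n).reset_index(drop=True)
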