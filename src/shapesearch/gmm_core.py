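"""Gaussian mixture shape models: fitting, analytic overlap and superposition.

A density map is summarized by a K-component 3D Gaussian mixture fitted by
weighted expectation-maximization on voxel centers.  Shape similarity between
two mixtures A and B is the normalized overlap

    CC = <f_A, f_B> / sqrt(<f_A, f_A> <f_B, f_B>)

where the inner product has the closed form

    <f_A, f_B> = sum_kl w_k w_l N(mu_k - mu_l; 0, Sigma_k + Sigma_l).

Superposition maximizes CC over proper rigid transforms of the second
mixture with a multi-start local search (principal-axis alignments plus
seeded random rotations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from shapesearch.errors import InfeasibleFitError, NumericalDegeneracyError

#: Floor on covariance eigenvalues (A^2) to prevent component collapse.
COVARIANCE_FLOOR = 0.25

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianComponent:
    """One weighted 3D Gaussian: positive weight, mean (A), covariance (A^2)."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        self.covariance = np.asarray(self.covariance, dtype=np.float64).reshape(3, 3)


class GaussianMixture:
    """A normalized mixture of 3D Gaussian components.

    Weights are renormalized to sum to 1 at construction.  Components are
    exposed both as a list of :class:`GaussianComponent` and as packed
    arrays ``weights`` (K,), ``means`` (K, 3), ``covariances`` (K, 3, 3).
    """

    def __init__(self, components, name: str = ""):
        comps = list(components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        w = np.array([c.weight for c in comps], dtype=np.float64)
        if np.any(w <= 0):
            raise ValueError("component weights must be positive")
        w = w / w.sum()
        self.weights = w
        self.means = np.stack([c.mean for c in comps])
        self.covariances = np.stack([c.covariance for c in comps])
        self.name = name

    @property
    def components(self) -> list[GaussianComponent]:
        return [
            GaussianComponent(float(w), m.copy(), c.copy())
            for w, m, c in zip(self.weights, self.means, self.covariances)
        ]

    def __len__(self) -> int:
        return len(self.weights)

    # -- evaluation ---------------------------------------------------------

    def density(self, points: np.ndarray) -> np.ndarray:
        """Mixture density at an (N, 3) array of points."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = np.zeros(len(points))
        for w, mu, cov in zip(self.weights, self.means, self.covariances):
            out += w * _gauss3(points - mu, cov)
        return out

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Overall mean and covariance of the mixture distribution."""
        m = self.weights @ self.means
        dev = self.means - m
        cov = np.einsum("k,kij->ij", self.weights, self.covariances)
        cov += np.einsum("k,ki,kj->ij", self.weights, dev, dev)
        return m, cov

    # -- serialization ------------------------------------------------------

    _COLS = (
        "weight mean_x mean_y mean_z cov_xx cov_yy cov_zz cov_xy cov_xz cov_yz"
    ).split()

    def to_table(self, path) -> None:
        """Write one component per row: weight, mean xyz, 6 covariance entries."""
        with open(path, "w") as fh:
            fh.write("# " + "\t".join(self._COLS) + "\n")
            for w, mu, c in zip(self.weights, self.means, self.covariances):
                vals = [w, *mu, c[0, 0], c[1, 1], c[2, 2], c[0, 1], c[0, 2], c[1, 2]]
                fh.write("\t".join(f"{v:.17g}" for v in vals) + "\n")

    @classmethod
    def from_table(cls, path, name: str = "") -> "GaussianMixture":
        rows = np.loadtxt(path, ndmin=2)
        comps = []
        for r in rows:
            cov = np.array(
                [[r[4], r[7], r[8]], [r[7], r[5], r[9]], [r[8], r[9], r[6]]]
            )
            comps.append(GaussianComponent(r[0], r[1:4], cov))
        return cls(comps, name=name)

    def to_json_obj(self) -> dict:
        return {
            "name": self.name,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "GaussianMixture":
        comps = [
            GaussianComponent(w, m, c)
            for w, m, c in zip(obj["weights"], obj["means"], obj["covariances"])
        ]
        return cls(comps, name=obj.get("name", ""))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(), fh)

    @classmethod
    def from_json(cls, path) -> "GaussianMixture":
        with open(path) as fh:
            return cls.from_json_obj(json.load(fh))


@dataclass
class RigidTransform:
    """A proper rigid transform: unit quaternion (x, y, z, w) + translation (A)."""

    quaternion: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=np.float64).reshape(4)
        n = np.linalg.norm(q)
        if n == 0:
            raise ValueError("zero quaternion")
        self.quaternion = q / n
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3))

    @classmethod
    def from_rotation(cls, rot: Rotation, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(rot.as_quat(), np.asarray(translation, dtype=np.float64))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation) + self.translation
        return RigidTransform(r.as_quat(), t)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform(rinv.as_quat(), -rinv.apply(self.translation))


@dataclass
class Superposition3DResult:
    """Best rigid transform of the second mixture and the CC it attains."""

    transform: RigidTransform
    cc: float


# ---------------------------------------------------------------------------
# evaluation helpers


def _gauss3(dev: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """N(dev; 0, cov) for an (N, 3) array of deviations."""
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise NumericalDegeneracyError("singular covariance matrix")
    sol = np.linalg.solve(cov, dev.T).T
    maha = np.einsum("ni,ni->n", dev, sol)
    return np.exp(-0.5 * (maha + 3.0 * _LOG_2PI + logdet))


def transform_mixture(gmm: GaussianMixture, transform: RigidTransform) -> GaussianMixture:
    """Apply a rigid transform to every component of a mixture."""
    R = transform.matrix
    comps = [
        GaussianComponent(float(w), R @ mu + transform.translation, R @ cov @ R.T)
        for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covariances)
    ]
    return GaussianMixture(comps, name=gmm.name)


# ---------------------------------------------------------------------------
# fitting


def _downsample_to(grid: np.ndarray, max_dim: int) -> tuple[np.ndarray, float]:
    """Downsample so no axis exceeds max_dim; returns (grid, linear factor)."""
    from scipy import ndimage

    biggest = max(grid.shape)
    if biggest <= max_dim:
        return grid, 1.0
    factor = max_dim / biggest
    out = ndimage.zoom(grid, factor, order=1)
    return np.clip(out, 0.0, None), factor


def _kmeanspp_centers(points, weights, k, rng):
    """Weighted k-means++ seeding."""
    n = len(points)
    centers = np.empty((k, 3))
    probs = weights / weights.sum()
    idx = rng.choice(n, p=probs)
    centers[0] = points[idx]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        p = weights * d2
        total = p.sum()
        if total <= 0:
            idx = rng.choice(n, p=probs)
        else:
            idx = rng.choice(n, p=p / total)
        centers[j] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _floor_covariance(cov: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def fit_gmm(
    dmap,
    K: int,
    seed: int = 0,
    max_voxels_per_dim: int = 64,
    tol: float = 1e-6,
    max_iter: int = 500,
    density_threshold: float = 1e-6,
) -> GaussianMixture:
    """Fit a K-component mixture to a density map by weighted EM.

    Voxel-center positions are the data, densities the sample weights.
    Maps larger than ``max_voxels_per_dim`` per axis are downsampled first
    (mirroring the voxel cap used when mixtures are built by existing EM
    fitting tools).  Initialization is weighted k-means++ from ``seed``;
    iteration stops when the relative log-likelihood change drops below
    ``tol`` or after ``max_iter`` rounds.  Covariance eigenvalues are
    floored at 0.25 A^2.

    Raises
    ------
    InfeasibleFitError
        If K exceeds the number of occupied voxels.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    grid = np.asarray(dmap.grid, dtype=np.float64)
    spacing = np.asarray(dmap.spacing, dtype=np.float64)
    origin = np.asarray(dmap.origin, dtype=np.float64)

    grid_ds, factor = _downsample_to(grid, max_voxels_per_dim)
    spacing_ds = spacing / factor

    mask = grid_ds > density_threshold * grid_ds.max()
    n_occ = int(mask.sum())
    if n_occ < K:
        raise InfeasibleFitError(
            f"K = {K} exceeds the {n_occ} occupied voxels of map {dmap.name!r}"
        )
    idx = np.argwhere(mask)
    pts = origin + (idx + 0.5) * spacing_ds
    w = grid_ds[mask]
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(pts, w, K, rng)

    # hard-assignment initialization of the mixture parameters
    assign = np.argmin(
        ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    weights = np.empty(K)
    means = np.empty((K, 3))
    covs = np.empty((K, 3, 3))
    for k in range(K):
        sel = assign == k
        wk = w[sel].sum()
        if wk <= 0:
            weights[k] = 1.0 / len(pts)
            means[k] = centers[k]
            covs[k] = np.eye(3)
            continue
        weights[k] = wk
        means[k] = (w[sel, None] * pts[sel]).sum(axis=0) / wk
        dev = pts[sel] - means[k]
        covs[k] = _floor_covariance((w[sel, None] * dev).T @ dev / wk, COVARIANCE_FLOOR)
    weights /= weights.sum()

    prev_ll = -np.inf
    log_w = np.log(weights)
    for _ in range(max_iter):
        # E step: log N(x; mu_k, Sigma_k) via Cholesky per component
        logp = np.empty((len(pts), K))
        for k in range(K):
            L = np.linalg.cholesky(covs[k])
            dev = pts - means[k]
            sol = np.linalg.solve(L, dev.T)
            maha = np.einsum("in,in->n", sol, sol)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            logp[:, k] = log_w[k] - 0.5 * (maha + 3.0 * _LOG_2PI + logdet)
        mx = logp.max(axis=1)
        lse = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
        ll = float((w * lse).sum())
        resp = np.exp(logp - lse[:, None])

        # M step with sample weights
        wr = resp * w[:, None]
        nk = wr.sum(axis=0)
        nk = np.clip(nk, 1e-300, None)
        weights = nk / nk.sum()
        means = (wr.T @ pts) / nk[:, None]
        for k in range(K):
            dev = pts - means[k]
            covs[k] = _floor_covariance(
                (wr[:, k, None] * dev).T @ dev / nk[k], COVARIANCE_FLOOR
            )
        log_w = np.log(weights)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll

    comps = [
        GaussianComponent(float(weights[k]), means[k], covs[k]) for k in range(K)
    ]
    return GaussianMixture(comps, name=dmap.name)


# ---------------------------------------------------------------------------
# analytic overlap


def _pairwise_gauss_sum(A: GaussianMixture, B: GaussianMixture) -> float:
    """sum_kl w_k w_l N(mu_k - mu_l; 0, Sigma_k + Sigma_l), fully vectorized."""
    dev = A.means[:, None, :] - B.means[None, :, :]  # (Ka, Kb, 3)
    cov = A.covariances[:, None, :, :] + B.covariances[None, :, :, :]
    sign, logdet = np.linalg.slogdet(cov)
    if np.any(sign <= 0):
        raise NumericalDegeneracyError("singular summed covariance in overlap")
    sol = np.linalg.solve(cov, dev[..., None])[..., 0]
    maha = np.einsum("abi,abi->ab", dev, sol)
    vals = np.exp(-0.5 * (maha + 3.0 * _LOG_2PI + logdet))
    return float(np.einsum("a,b,ab->", A.weights, B.weights, vals))


def gmm_inner_product(A: GaussianMixture, B: GaussianMixture) -> float:
    """Closed-form integral of the product of two mixture densities."""
    return _pairwise_gauss_sum(A, B)


def gmm_overlap_cc(A: GaussianMixture, B: GaussianMixture) -> float:
    """Normalized overlap of two mixtures; 1 means identical shapes."""
    num = gmm_inner_product(A, B)
    return num / np.sqrt(gmm_inner_product(A, A) * gmm_inner_product(B, B))


# ---------------------------------------------------------------------------
# superposition


def _proper_axes(cov: np.ndarray) -> np.ndarray:
    """Eigenvector basis of a covariance as a proper rotation (columns)."""
    _, vecs = np.linalg.eigh(cov)
    if np.linalg.det(vecs) < 0:
        vecs = vecs.copy()
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def _cc_transformed(A, B, R: np.ndarray, t: np.ndarray, self_a: float, self_b: float) -> float:
    """CC between A and B after applying rotation R + translation t to B."""
    meansB = B.means @ R.T + t
    covsB = np.einsum("ij,kjl,ml->kim", R, B.covariances, R)
    dev = A.means[:, None, :] - meansB[None, :, :]
    cov = A.covariances[:, None, :, :] + covsB[None, :, :, :]
    sign, logdet = np.linalg.slogdet(cov)
    sol = np.linalg.solve(cov, dev[..., None])[..., 0]
    maha = np.einsum("abi,abi->ab", dev, sol)
    vals = np.exp(-0.5 * (maha + 3.0 * _LOG_2PI + logdet))
    num = float(np.einsum("a,b,ab->", A.weights, B.weights, vals))
    return num / np.sqrt(self_a * self_b)


def superpose_gmms(
    A: GaussianMixture,
    B: GaussianMixture,
    n_starts: int = 24,
    seed: int = 0,
) -> Superposition3DResult:
    """Maximize the overlap CC of A with a rigidly transformed B.

    Multi-start local optimization: the identity, the 4 proper sign
    alignments of the principal axes of the two mixtures, and
    ``n_starts - 4`` seeded random rotations, each refined by L-BFGS-B on a
    (rotation-vector increment, translation) parameterization.  The
    returned CC is never below the unaligned (identity) CC.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    self_a = gmm_inner_product(A, A)
    self_b = gmm_inner_product(B, B)

    mA, covA = A.moments()
    mB, covB = B.moments()
    EA = _proper_axes(covA)
    EB = _proper_axes(covB)

    starts: list[np.ndarray] = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        D = np.diag([sx, sy, sx * sy])  # det +1
        starts.append(EA @ D @ EB.T)
    n_random = max(0, n_starts - 4)
    if n_random:
        starts.extend(Rotation.random(n_random, random_state=rng).as_matrix())
    starts = starts[:max(n_starts, 4)]

    best_cc = _cc_transformed(A, B, np.eye(3), np.zeros(3), self_a, self_b)
    best = (np.eye(3), np.zeros(3), best_cc)

    def objective(params, R0):
        R = Rotation.from_rotvec(params[:3]).as_matrix() @ R0
        return -_cc_transformed(A, B, R, params[3:], self_a, self_b)

    for R0 in starts:
        t0 = mA - R0 @ mB
        x0 = np.concatenate([np.zeros(3), t0])
        res = minimize(
            objective,
            x0,
            args=(R0,),
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10},
        )
        R = Rotation.from_rotvec(res.x[:3]).as_matrix() @ R0
        cc = -res.fun
        if cc > best[2]:
            best = (R, res.x[3:].copy(), cc)

    R, t, cc = best
    transform = RigidTransform.from_rotation(Rotation.from_matrix(R), t)
    return Superposition3DResult(transform=transform, cc=float(cc))


def pairwise_cc_matrix(
    mixtures: list[GaussianMixture], seed: int = 0, n_starts: int = 24
) -> np.ndarray:
    """Symmetric matrix of superposed CCs; each pair computed once (i < j)."""
    if len(mixtures) < 2:
        raise ValueError("need at least 2 mixtures")
    n = len(mixtures)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            res = superpose_gmms(
                mixtures[i], mixtures[j], n_starts=n_starts, seed=seed + 1000 * i + j
            )
            M[i, j] = M[j, i] = res.cc
    return M
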