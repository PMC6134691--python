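"""Independent oracles used by the test suite.

Each oracle is written from the definition it checks, not from the package
implementation: numeric quadrature for the analytic Gaussian overlap, a
step-by-step Lance-Williams agglomeration for Ward clustering, and a direct
Gram-matrix eigendecomposition for classical MDS.
"""

import numpy as np


def riemann_inner_product(A, B, n_grid: int = 64, pad_sigma: float = 6.0) -> float:
    """3D quadrature of integral f_A(r) f_B(r) dr on an n_grid^3 lattice."""
    means = np.vstack([A.means, B.means])
    sig = np.sqrt(
        np.concatenate(
            [
                np.linalg.eigvalsh(A.covariances)[:, -1],
                np.linalg.eigvalsh(B.covariances)[:, -1],
            ]
        )
    )
    lo = (means - pad_sigma * sig[:, None]).min(axis=0)
    hi = (means + pad_sigma * sig[:, None]).max(axis=0)
    axes = [np.linspace(lo[d], hi[d], n_grid) for d in range(3)]
    h = np.prod([(ax[1] - ax[0]) for ax in axes])
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    return float((A.density(pts) * B.density(pts)).sum() * h)


def random_mixture(rng: np.random.Generator, k: int = 3, spread: float = 5.0):
    """A random well-conditioned mixture for overlap tests."""
    from shapesearch.gmm_core import GaussianComponent, GaussianMixture

    comps = []
    for _ in range(k):
        w = rng.uniform(0.5, 2.0)
        mu = rng.uniform(-spread, spread, size=3)
        M = rng.normal(size=(3, 3)) * 0.4
        cov = M @ M.T + np.diag(rng.uniform(1.5, 3.0, size=3)) ** 2
        comps.append(GaussianComponent(w, mu, cov))
    return GaussianMixture(comps)


def lance_williams_ward(D: np.ndarray):
    """Naive O(n^3) ward.D agglomeration; returns [(id_a, id_b, height, new_id)].

    Ties broken by the lowest pair of positions in creation order, matching
    the documented determinism contract.
    """
    n = len(D)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    merges = []
    nxt = n
    for _ in range(n - 1):
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                key = (min(a, b), max(a, b))
                d = dist[key]
                if best is None or d < best[0]:
                    best = (d, ai, active.index(b))
        h, pi, pj = best
        a, b = active[pi], active[pj]
        for c in active:
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            na, nb, nc = size[a], size[b], size[c]
            d_new = ((na + nc) * dist[ka] + (nb + nc) * dist[kb] - nc * h) / (
                na + nb + nc
            )
            dist[(min(nxt, c), max(nxt, c))] = d_new
        merges.append((a, b, h, nxt))
        size[nxt] = size[a] + size[b]
        active[pi] = nxt
        del active[pj]
        nxt += 1
    return merges


def mds_oracle(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical MDS coordinates by explicit Gram construction + scipy eigh."""
    from scipy.linalg import eigh

    D = np.asarray(D, dtype=float)
    n = len(D)
    D2 = D**2
    row = D2.mean(axis=1)
    B = -0.5 * (D2 - row[:, None] - row[None, :] + D2.mean())
    vals, vecs = eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def pairwise_dists(X: np.ndarray) -> np.ndarray:
    return np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
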