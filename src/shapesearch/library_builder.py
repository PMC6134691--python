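"""Non-redundant shape library construction.

Pairwise 3D overlap CCs become distances d = sqrt(1 - CC^2); models are
clustered with Ward's method applied directly to those (unsquared)
distances ("ward.D" semantics -- note most library defaults implement
ward.D2 on squared distances); the tree is cut at the median merge height
and each cluster contributes its medoid, whose projections populate the
searchable library.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from shapesearch import gmm_core, projections, volumes

logger = logging.getLogger(__name__)


def cc_to_distance(cc):
    """d = sqrt(1 - CC^2); accepts scalars or arrays, CC in [-1, 1]."""
    cc = np.asarray(cc, dtype=np.float64)
    if np.any(np.abs(cc) > 1.0 + 1e-9):
        raise ValueError(f"|CC| > 1: {cc[np.abs(cc) > 1 + 1e-9]}")
    d = np.sqrt(np.clip(1.0 - np.clip(cc, -1.0, 1.0) ** 2, 0.0, None))
    return float(d) if d.ndim == 0 else d


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists (id_a, id_b, height, new_id) in merge order; leaves are
    ids 0..n-1 and merge i creates id n+i.  ``labels`` names the leaves.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix (for plotting/cutting tools)."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        out = np.empty((len(self.merges), 4))
        for row, (a, b, h, new) in enumerate(self.merges):
            sizes[new] = sizes[a] + sizes[b]
            out[row] = (a, b, h, sizes[new])
        return out


def ward_cluster(D: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Ward agglomeration on the given distances (ward.D semantics).

    The Lance-Williams update

        d(k, i+j) = ((n_i + n_k) d_ki + (n_j + n_k) d_kj - n_k d_ij)
                    / (n_i + n_j + n_k)

    is applied directly to the input distances, which are NOT squared
    first.  Deterministic: on exact ties the pair with the lowest indices
    merges first.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix with >= 2 items")
    if labels is None:
        labels = [str(i) for i in range(n)]

    # active cluster ids in creation order; work matrix indexed by position
    ids = list(range(n))
    sizes = [1] * n
    work = D.astype(np.float64).copy()
    np.fill_diagonal(work, np.inf)

    merges = []
    next_id = n
    for _ in range(n - 1):
        m = len(ids)
        # lowest-index tie-breaking: first occurrence in row-major upper triangle
        iu = np.triu_indices(m, k=1)
        flat = work[iu]
        best = int(np.argmin(flat))
        i, j = int(iu[0][best]), int(iu[1][best])
        h = float(work[i, j])

        ni, nj = sizes[i], sizes[j]
        nk = np.array(sizes, dtype=np.float64)
        new_row = ((ni + nk) * work[i, :] + (nj + nk) * work[j, :] - nk * h) / (
            ni + nj + nk
        )

        merges.append((ids[i], ids[j], h, next_id))
        # replace position i with the merged cluster, drop position j
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        keep = [p for p in range(m) if p != j]
        work = work[np.ix_(keep, keep)]
        ids[i] = next_id
        sizes[i] = ni + nj
        del ids[j], sizes[j]
        next_id += 1
    return Dendrogram(merges=merges, labels=list(labels))


def cut_tree(tree: Dendrogram, cutoff: float) -> list[list[int]]:
    """Leaf clusters after applying all merges with height <= cutoff."""
    members: dict[int, list[int]] = {i: [i] for i in range(tree.n_leaves)}
    for a, b, h, new in tree.merges:
        if h <= cutoff:
            members[new] = members.pop(a) + members.pop(b)
    return sorted(members.values(), key=lambda c: min(c))


def median_height(tree: Dendrogram) -> float:
    """Median merge height -- the default dedup cutoff."""
    return float(np.median(tree.heights))


def select_representatives(
    tree: Dendrogram, D: np.ndarray, cutoff: float | None = None
) -> list[str]:
    """Cut the tree and pick each cluster's medoid.

    ``cutoff`` defaults to the median merge height.  The medoid is the
    member minimizing summed distance to its co-members (lowest leaf index
    on ties).
    """
    D = np.asarray(D, dtype=np.float64)
    if cutoff is None:
        cutoff = median_height(tree)
    reps = []
    for cluster in cut_tree(tree, cutoff):
        sub = D[np.ix_(cluster, cluster)]
        medoid = cluster[int(np.argmin(sub.sum(axis=1)))]
        reps.append(tree.labels[medoid])
    return reps


@dataclass
class ProjectionLibrary:
    """A searchable projection-image library with its provenance."""

    stack: projections.ImageStack
    gmms: dict[str, gmm_core.GaussianMixture] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def model_ids(self) -> list[str]:
        seen = []
        for m in self.stack.model_ids:
            if m not in seen:
                seen.append(m)
        return seen

    def image_model_index(self) -> list[str]:
        return self.stack.model_ids

    # -- persistence -------------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dirs = None
        n_images = self.provenance.get("n_images")
        if n_images:
            dirs = projections.sample_directions(n_images)
        self.stack.save(out / "images.mrcs", out / "index.tsv", directions=dirs)
        gmm_dir = out / "gmms"
        gmm_dir.mkdir(exist_ok=True)
        for name, gmm in self.gmms.items():
            gmm.to_table(gmm_dir / f"{name}.tsv")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, out_dir) -> "ProjectionLibrary":
        out = Path(out_dir)
        stack = projections.ImageStack.load(out / "images.mrcs", out / "index.tsv")
        gmms = {}
        gmm_dir = out / "gmms"
        if gmm_dir.is_dir():
            for p in sorted(gmm_dir.glob("*.tsv")):
                gmms[p.stem] = gmm_core.GaussianMixture.from_table(p, name=p.stem)
        with open(out / "provenance.json") as fh:
            prov = json.load(fh)
        return cls(stack=stack, gmms=gmms, provenance=prov)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("images", data=self.stack.as_array())
            fh.create_dataset(
                "model_ids",
                data=np.array(self.stack.model_ids, dtype=h5py.string_dtype()),
            )
            fh.create_dataset(
                "direction_ids",
                data=np.array([im.direction_id for im in self.stack]),
            )
            fh.attrs["pixel_size"] = self.stack[0].pixel_size
            fh.attrs["provenance"] = json.dumps(self.provenance, sort_keys=True)
            g = fh.create_group("gmms")
            for name, gmm in self.gmms.items():
                sub = g.create_group(name)
                sub.create_dataset("weights", data=gmm.weights)
                sub.create_dataset("means", data=gmm.means)
                sub.create_dataset("covariances", data=gmm.covariances)

    @classmethod
    def load_hdf5(cls, path) -> "ProjectionLibrary":
        import h5py

        with h5py.File(path, "r") as fh:
            arr = fh["images"][...]
            models = [m.decode() for m in fh["model_ids"][...]]
            dir_ids = fh["direction_ids"][...]
            pixel_size = float(fh.attrs["pixel_size"])
            prov = json.loads(fh.attrs["provenance"])
            stack = projections.ImageStack()
            for pix, m, d in zip(arr, models, dir_ids):
                stack.append(
                    projections.ProjectionImage(
                        pixels=pix, pixel_size=pixel_size, model=m, direction_id=int(d)
                    )
                )
            gmms = {}
            for name, sub in fh["gmms"].items():
                comps = [
                    gmm_core.GaussianComponent(w, mu, c)
                    for w, mu, c in zip(
                        sub["weights"][...], sub["means"][...], sub["covariances"][...]
                    )
                ]
                gmms[name] = gmm_core.GaussianMixture(comps, name=name)
        return cls(stack=stack, gmms=gmms, provenance=prov)


def prepare_model(dmap, K: int, seed: int) -> tuple[volumes.DensityMap, gmm_core.GaussianMixture, float]:
    """normalize -> fit -> estimate volume -> resize -> refit for one map."""
    norm = volumes.normalize_grid(dmap)
    gmm0 = gmm_core.fit_gmm(norm, K=K, seed=seed)
    v_old = volumes.estimate_volume(gmm0)
    resized = volumes.resize_to_common_volume(norm, v_old)
    gmm = gmm_core.fit_gmm(resized, K=K, seed=seed)
    return resized, gmm, v_old


def build_library(
    maps,
    K: int = 20,
    n_images: int = 91,
    cutoff_policy="median",
    seed: int = 0,
    n_starts: int = 24,
) -> ProjectionLibrary:
    """Run the full library pipeline on a list of density maps.

    Per map: grid normalization, mixture fit, volume estimate, common-volume
    resize and a refit on the resized map.  Pairwise superposed CCs are then
    converted to distances, Ward-clustered and cut (``cutoff_policy``:
    ``"median"``, ``"none"`` to keep every model, or a float height);
    cluster medoids are the representatives whose projections make up the
    library.  Maps that fail any stage are logged and skipped; fewer than 2
    surviving maps aborts.

    With ``cutoff_policy="none"`` the clustering stages are skipped
    entirely (every model is its own representative), which avoids the
    pairwise superposition cost.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")

    resized: dict[str, volumes.DensityMap] = {}
    gmms: dict[str, gmm_core.GaussianMixture] = {}
    volumes_est: dict[str, float] = {}
    for i, dmap in enumerate(maps):
        try:
            rmap, gmm, v_old = prepare_model(dmap, K=K, seed=seed + i)
        except Exception:  # per-map failures must not sink the build
            logger.exception("skipping map %r after a pipeline failure", dmap.name)
            continue
        resized[dmap.name] = rmap
        gmms[dmap.name] = gmm
        volumes_est[dmap.name] = v_old
    if len(resized) < 2:
        raise ValueError(f"only {len(resized)} maps survived preparation; need >= 2")

    names = list(resized)
    cc_matrix = None
    cutoff = None
    if cutoff_policy == "none":
        reps = names
    else:
        cc_matrix = gmm_core.pairwise_cc_matrix(
            [gmms[n] for n in names], seed=seed, n_starts=n_starts
        )
        # nonnegative mixtures cannot produce negative overlap; floor at 0
        cc_matrix = np.clip(cc_matrix, 0.0, 1.0)
        D = cc_to_distance(cc_matrix)
        np.fill_diagonal(D, 0.0)
        tree = ward_cluster(D, labels=names)
        if cutoff_policy == "median":
            cutoff = median_height(tree)
        else:
            cutoff = float(cutoff_policy)
        reps = select_representatives(tree, D, cutoff=cutoff)

    stack = projections.ImageStack()
    for name in reps:
        stack.extend(projections.build_projection_set(resized[name], n_images=n_images))

    provenance = {
        "K": K,
        "n_images": n_images,
        "cutoff_policy": str(cutoff_policy),
        "cutoff": cutoff,
        "seed": seed,
        "n_starts": n_starts,
        "input_models": names,
        "representatives": reps,
        "estimated_volumes": volumes_est,
        "cc_matrix": None if cc_matrix is None else cc_matrix.tolist(),
    }
    return ProjectionLibrary(
        stack=stack,
        gmms={n: gmms[n] for n in reps},
        provenance=provenance,
    )
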