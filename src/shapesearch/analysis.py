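"""Diagnostics of image-space structure: PCC model clustering, classical MDS
and grid-cell binning of the embedding."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from shapesearch.errors import DegenerateGeometryError, DegenerateProfileError
from shapesearch.library_builder import Dendrogram, cc_to_distance, ward_cluster


@dataclass
class MDSEmbedding:
    """Classical MDS result: centered coordinates plus eigen-spectrum."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    goodness_of_fit: float


@dataclass
class CellSummary:
    """One occupied 0.1 x 0.1 cell of the binned embedding."""

    cell: tuple[int, int]
    count: int
    mean_cc: float | None
    representative_image: int
    representative_model: str


def model_pcc_matrix(cc_full: np.ndarray, index: list[str]) -> tuple[np.ndarray, list[str]]:
    """Pearson correlations between per-model CC profiles.

    A model's profile is the column-wise mean of its images' rows of the
    all-pairs CC matrix (a length-N vector over every library image); the
    PCC is computed between profiles.  Returns (matrix, model order).
    """
    cc_full = np.asarray(cc_full, dtype=np.float64)
    n = cc_full.shape[0]
    if cc_full.shape != (n, n):
        raise ValueError("cc_full must be square")
    if len(index) != n:
        raise ValueError("index must cover all images")
    models: list[str] = []
    for m in index:
        if m not in models:
            models.append(m)
    profiles = np.stack(
        [cc_full[[i for i, m in enumerate(index) if m == name]].mean(axis=0) for name in models]
    )
    sds = profiles.std(axis=1)
    bad = [models[i] for i in np.where(sds == 0)[0]]
    if bad:
        raise DegenerateProfileError(f"constant CC profile for model(s) {bad}")
    pcc = np.corrcoef(profiles)
    np.fill_diagonal(pcc, 1.0)
    return pcc, models


def classical_mds(D: np.ndarray, k: int = 2) -> MDSEmbedding:
    """Torgerson's classical multidimensional scaling.

    Double-centers -D^2/2, eigendecomposes, and scales the top-k
    eigenvectors by the square roots of their (positive) eigenvalues.
    Goodness of fit is the top-k positive eigenvalue mass over all
    positive eigenvalue mass.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("need a square distance matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    vals, vecs = vals[::-1], vecs[:, ::-1]  # non-increasing
    pos = vals > 0
    if not pos.any():
        raise DegenerateGeometryError("no positive eigenvalues: degenerate geometry")
    coords = np.zeros((n, k))
    take = min(k, int(pos.sum()))
    coords[:, :take] = vecs[:, :take] * np.sqrt(vals[:take])
    gof = float(vals[:k][vals[:k] > 0].sum() / vals[pos].sum())
    coords -= coords.mean(axis=0)  # numerically exact centering
    return MDSEmbedding(coordinates=coords, eigenvalues=vals, goodness_of_fit=gof)


def grid_bin_embedding(
    emb: MDSEmbedding,
    cc_full: np.ndarray,
    index: list[str],
    cell: float = 0.1,
) -> list[CellSummary]:
    """Bin embedded images into half-open square cells and summarize each.

    Per occupied cell: image count, the mean pairwise CC over within-cell
    image pairs (omitted -- ``None`` -- for singleton cells), and a
    representative image drawn from the most frequent model in the cell
    (lowest model id on frequency ties, then lowest image index).
    """
    if cell <= 0:
        raise ValueError("cell must be positive")
    coords = emb.coordinates[:, :2]
    cc_full = np.asarray(cc_full, dtype=np.float64)
    keys = np.floor(coords / cell).astype(int)
    cells: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(map(tuple, keys)):
        cells.setdefault(key, []).append(i)

    out = []
    for key in sorted(cells):
        members = cells[key]
        if len(members) > 1:
            sub = cc_full[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            mean_cc = float(sub[iu].mean())
        else:
            mean_cc = None
        counts: dict[str, int] = {}
        for i in members:
            counts[index[i]] = counts.get(index[i], 0) + 1
        top_model = min(counts, key=lambda m: (-counts[m], m))
        rep = min(i for i in members if index[i] == top_model)
        out.append(
            CellSummary(
                cell=key,
                count=len(members),
                mean_cc=mean_cc,
                representative_image=rep,
                representative_model=top_model,
            )
        )
    return out


def cluster_models(sim: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Ward-cluster a model similarity matrix (3D CC or 2D PCC).

    The similarity is converted elementwise with d = sqrt(1 - sim^2) and
    passed to the same Ward implementation used for library deduplication.
    """
    sim = np.asarray(sim, dtype=np.float64)
    D = cc_to_distance(np.clip(sim, -1.0, 1.0))
    np.fill_diagonal(D, 0.0)
    return ward_cluster(D, labels=labels)
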