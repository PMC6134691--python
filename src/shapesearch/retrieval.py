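"""Match scoring of library models against query images.

For query image i and library image j, the alignment CCs are standardized
per query row,

    Z(i, j) = (CC_ij - mu_i) / sigma_i          (population SD)

so every query image contributes equally regardless of its contrast.  Per
model n the top-k Z-scores of each row are summed into X_i^n, rows are
summed into S_n, and the final match score is the standardized

    T_n = (S_n - mu_S) / sigma_S.

Models are ranked by T_n descending (ties broken by model id).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from shapesearch import align2d
from shapesearch.errors import DegenerateRowError, InsufficientLibraryError

logger = logging.getLogger(__name__)

#: Number of top Z-scores summed per model per query image.
TOP_K = 10


@dataclass
class ZScoreMatrix:
    """Row-standardized CC matrix with the row statistics retained."""

    z: np.ndarray
    row_means: np.ndarray
    row_sds: np.ndarray


@dataclass
class ModelScore:
    """Scores of one library model: per-image X_i^n, their sum S_n, and T_n."""

    model: str
    x_per_image: np.ndarray
    s: float
    t: float = float("nan")


@dataclass
class MatchReport:
    """Ranked models with per-query-image score contributions."""

    scores: list[ModelScore]
    query_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        return [s.model for s in self.scores]

    def consecutive_gaps(self) -> np.ndarray:
        """Differences between consecutive ranked T_n (match-quality hint)."""
        t = np.array([s.t for s in self.scores])
        return -np.diff(t)

    def to_tsv(self, path) -> None:
        x_cols = len(self.scores[0].x_per_image) if self.scores else 0
        with open(path, "w") as fh:
            header = ["rank", "model_id", "T_n", "S_n"] + [
                f"X_{i + 1}" for i in range(x_cols)
            ]
            fh.write("\t".join(header) + "\n")
            for rank, sc in enumerate(self.scores, start=1):
                row = [str(rank), sc.model, f"{sc.t:.9g}", f"{sc.s:.9g}"] + [
                    f"{x:.9g}" for x in sc.x_per_image
                ]
                fh.write("\t".join(row) + "\n")

    def to_json(self, path) -> None:
        obj = {
            "query_ids": self.query_ids,
            "provenance": self.provenance,
            "ranking": [
                {
                    "rank": rank,
                    "model_id": sc.model,
                    "T_n": sc.t,
                    "S_n": sc.s,
                    "X_per_image": sc.x_per_image.tolist(),
                }
                for rank, sc in enumerate(self.scores, start=1)
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def zscore_rows(cc: np.ndarray, sample_sd: bool = False) -> ZScoreMatrix:
    """Standardize each row of a CC matrix (population SD by default).

    Raises
    ------
    DegenerateRowError
        If a row is constant (zero SD); the message names the row.
    """
    cc = np.asarray(cc, dtype=np.float64)
    if cc.ndim != 2 or cc.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 columns")
    mu = cc.mean(axis=1)
    sd = cc.std(axis=1, ddof=1 if sample_sd else 0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise DegenerateRowError(f"constant CC row for query image(s) {bad.tolist()}")
    z = (cc - mu[:, None]) / sd[:, None]
    return ZScoreMatrix(z=z, row_means=mu, row_sds=sd)


def per_model_topk_sum(z_row: np.ndarray, index: list[str], k: int = TOP_K) -> dict[str, float]:
    """Sum of the k largest Z-scores per model for one query row.

    Models with fewer than k images contribute the sum of all their
    Z-scores (with a logged warning).  Within a model, ties in Z are
    resolved by column index (stable), which cannot change the sum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    z_row = np.asarray(z_row, dtype=np.float64)
    if len(z_row) != len(index):
        raise ValueError("index must cover all columns")
    out: dict[str, float] = {}
    cols: dict[str, list[int]] = {}
    for j, n in enumerate(index):
        cols.setdefault(n, []).append(j)
    for n, js in cols.items():
        vals = z_row[js]
        if len(vals) < k:
            logger.warning(
                "model %r has only %d images (< k = %d); summing all", n, len(vals), k
            )
            out[n] = float(vals.sum())
        else:
            out[n] = float(np.sort(vals)[-k:].sum())
    return out


def aggregate_scores(x: np.ndarray) -> np.ndarray:
    """S_n = sum over query images of X_i^n; x has shape (n_images, n_models)."""
    x = np.asarray(x, dtype=np.float64)
    return x.sum(axis=0)


def final_scores(s: np.ndarray, sample_sd: bool = False) -> np.ndarray:
    """T_n = (S_n - mu_S) / sigma_S over models; all-equal S gives all-zero T."""
    s = np.asarray(s, dtype=np.float64)
    if s.size < 2:
        raise InsufficientLibraryError("need >= 2 library models for final scores")
    mu = s.mean()
    sd = s.std(ddof=1 if sample_sd else 0)
    if sd == 0:
        logger.warning("all S_n equal; returning all-zero final scores")
        return np.zeros_like(s)
    return (s - mu) / sd


def search(
    queries,
    library,
    k: int = TOP_K,
    psi_step: float = 2.0,
    max_shift: int = 10,
    sample_sd: bool = False,
) -> MatchReport:
    """Rank library models against a stack of query images.

    Each query image is aligned against every library image
    (:func:`align2d.align_stack_to_reference`), rows are standardized and
    fed through the top-k / sum / standardize chain.  A query whose CC row
    is degenerate is dropped with a warning; the search proceeds while at
    least one valid row remains.
    """
    if len(queries) < 1:
        raise ValueError("need at least one query image")
    index = library.image_model_index()
    models = library.model_ids
    if len(models) < 2:
        raise InsufficientLibraryError("library holds fewer than 2 models")

    rows = []
    kept = []
    for qi, q in enumerate(queries):
        cc_row = align2d.align_stack_to_reference(
            q, library.stack, psi_step=psi_step, max_shift=max_shift
        )
        cc_row = np.nan_to_num(cc_row, nan=-1.0)
        if np.std(cc_row) == 0:
            logger.warning("query image %d has a constant CC row; dropping it", qi)
            continue
        rows.append(cc_row)
        kept.append(qi)
    if not rows:
        raise DegenerateRowError("every query image produced a constant CC row")

    zmat = zscore_rows(np.stack(rows), sample_sd=sample_sd)
    x = np.empty((len(rows), len(models)))
    for r, z_row in enumerate(zmat.z):
        per_model = per_model_topk_sum(z_row, index, k=k)
        x[r] = [per_model[m] for m in models]
    s = aggregate_scores(x)
    t = final_scores(s, sample_sd=sample_sd)

    order = sorted(range(len(models)), key=lambda i: (-t[i], models[i]))
    scores = [
        ModelScore(model=models[i], x_per_image=x[:, i].copy(), s=float(s[i]), t=float(t[i]))
        for i in order
    ]
    return MatchReport(
        scores=scores,
        query_ids=[str(i) for i in kept],
        provenance={
            "k": k,
            "psi_step": psi_step,
            "max_shift": max_shift,
            "sample_sd": sample_sd,
            "n_queries_used": len(kept),
        },
    )
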