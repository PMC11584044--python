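"""PCA morphospace of aligned leaf configurations and inverse PCA.

Aligned configurations are flattened to row vectors (x0, y0, x1, y1, ...)
and decomposed with an ordinary covariance-basis PCA.  The inverse map,
``mean + sum_j score_j * loading_j``, turns any point of the PC plane back
into a theoretical ("eigen") leaf, which is how the morphospace grid of
theoretical shapes is drawn behind the scatter of real leaves.

Loading signs are fixed so the largest-magnitude element of each loading is
positive, making scores reproducible across runs and library versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ParameterError
from .landmarking import LandmarkConfiguration
from .procrustes import AlignedSet

__all__ = ["Morphospace", "MorphospaceGrid", "fit_pca", "inverse_pca", "morphospace_grid"]


@dataclass
class Morphospace:
    """A fitted PC decomposition of aligned shapes."""

    ids: list[str]
    scores: np.ndarray  # (n_leaves, n_components)
    loadings: np.ndarray  # (n_components, 4S), orthonormal rows
    explained_variance_ratio: np.ndarray
    mean_vector: np.ndarray  # (4S,)
    n_components: int
    S: int

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=pd.Index(self.ids, name="id"), columns=cols)


def _flatten(config: LandmarkConfiguration) -> np.ndarray:
    return config.points.ravel()


def _unflatten(vec: np.ndarray, S: int, id: str) -> LandmarkConfiguration:
    return LandmarkConfiguration(id=id, points=vec.reshape(2 * S, 2), S=S)


def fit_pca(aligned: AlignedSet, n_components: int | None = None) -> Morphospace:
    """Fit a PCA morphospace to GPA-aligned configurations.

    ``n_components`` defaults to the full rank ``min(n - 1, 4S)``.  With all
    components retained, ``scores @ loadings + mean`` reconstructs every
    input exactly (to floating point).
    """
    configs = aligned.configurations
    if len(configs) < 3:
        raise ParameterError("morphospace needs at least 3 aligned configurations")
    S = configs[0].S
    X = np.array([_flatten(c) for c in configs])
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if not (1 <= n_components <= max_rank):
        raise ParameterError(
            f"n_components={n_components} outside [1, {max_rank}] for {n} leaves, {p} coordinates"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # Deterministic sign: largest-magnitude element of each loading positive.
    flip = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return Morphospace(
        ids=[c.id for c in configs],
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean_vector=pca.mean_.copy(),
        n_components=n_components,
        S=S,
    )


def inverse_pca(
    space: Morphospace, pc_scores: np.ndarray, id: str = "theoretical"
) -> LandmarkConfiguration:
    """Map PC coordinates back to a theoretical leaf configuration.

    ``pc_scores`` may be shorter than the retained components; the missing
    trailing scores are taken as zero.
    """
    pc_scores = np.asarray(pc_scores, dtype=float).ravel()
    if pc_scores.size > space.n_components:
        raise ParameterError(
            f"{pc_scores.size} scores given but only {space.n_components} components retained"
        )
    vec = space.mean_vector + pc_scores @ space.loadings[: pc_scores.size]
    return _unflatten(vec, space.S, id)


@dataclass
class MorphospaceGrid:
    """A grid of theoretical leaves spanning the observed PC1/PC2 cloud."""

    pc1_values: np.ndarray  # (ncols,) column positions
    pc2_values: np.ndarray  # (nrows,) row positions
    leaves: list[list[LandmarkConfiguration]]  # [row][col]

    @property
    def n_cells(self) -> int:
        return len(self.pc1_values) * len(self.pc2_values)


def morphospace_grid(
    space: Morphospace, ncols: int = 5, nrows: int = 5, span_sd: float | None = None
) -> MorphospaceGrid:
    """Build the grid of theoretical leaves behind the PC1-PC2 scatter.

    Column positions are evenly spaced between the observed min and max PC1
    scores (rows likewise on PC2); each cell is the inverse-PCA leaf at that
    (PC1, PC2) with all other scores zero.  ``span_sd`` switches the span to
    plus/minus that many score standard deviations instead.
    """
    if space.n_components < 2:
        raise ParameterError("morphospace grid needs at least 2 retained components")
    if span_sd is None:
        lo1, hi1 = space.scores[:, 0].min(), space.scores[:, 0].max()
        lo2, hi2 = space.scores[:, 1].min(), space.scores[:, 1].max()
    else:
        s1, s2 = space.scores[:, 0].std(), space.scores[:, 1].std()
        lo1, hi1 = -span_sd * s1, span_sd * s1
        lo2, hi2 = -span_sd * s2, span_sd * s2
    pc1 = np.linspace(lo1, hi1, ncols)
    pc2 = np.linspace(lo2, hi2, nrows)
    leaves = [
        [
            inverse_pca(space, np.array([p1, p2]), id=f"grid_r{i}_c{j}")
            for j, p1 in enumerate(pc1)
        ]
        for i, p2 in enumerate(pc2)
    ]
    return MorphospaceGrid(pc1_values=pc1, pc2_values=pc2, leaves=leaves)


def plot_morphospace(space: Morphospace, grid: MorphospaceGrid, path: str) -> None:
    """Render the theoretical-leaf grid with the real score cloud overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    span1 = grid.pc1_values[-1] - grid.pc1_values[0] or 1.0
    span2 = grid.pc2_values[-1] - grid.pc2_values[0] or 1.0
    cell = 0.35 * min(span1 / max(len(grid.pc1_values) - 1, 1),
                      span2 / max(len(grid.pc2_values) - 1, 1))
    for i, p2 in enumerate(grid.pc2_values):
        for j, p1 in enumerate(grid.pc1_values):
            pts = grid.leaves[i][j].points
            scale = cell / max(np.abs(pts).max(), 1e-12)
            closed = np.vstack([pts, pts[:1]]) * scale + [p1, p2]
            ax.plot(closed[:, 0], closed[:, 1], color="gray", lw=0.8)
    ax.scatter(space.scores[:, 0], space.scores[:, 1], s=8, color="tab:blue", alpha=0.6)
    ax.set_xlabel(f"PC1 ({space.explained_variance_ratio[0]:.1%})")
    ax.set_ylabel(f"PC2 ({space.explained_variance_ratio[1]:.1%})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
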