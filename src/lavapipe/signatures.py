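"""PCA and loading-based expression signatures.

Used for two analyses: ranking genes by their contribution (|loading|) to the
first principal component of a pluripotency time course, and extracting the
top-10 positive and top-10 negative TE loadings on PC1 and PC2, whose union
(with cross-component duplicates counted once) defines the TE signature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pca", "top_loading_features", "loading_set_union"]


@dataclass
class PCAResult:
    """Scores are sample x component, loadings feature x component
    (orthonormal feature weights); explained_variance_ratio is per component,
    non-increasing."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(
    expression: pd.DataFrame,
    transform: Literal["log2p1", "none"] = "log2p1",
    center: bool = True,
) -> PCAResult:
    """Principal component analysis of a feature x sample expression matrix.

    Samples are observations.  The default transform is log2(x + 1); features
    are mean-centered.  Components come from the SVD of the centered
    sample-by-feature matrix.  Sign convention: each loading column's
    largest-magnitude entry is positive, so ranked loading lists are
    reproducible across linear-algebra backends.
    """
    if expression.shape[0] < 2 or expression.shape[1] < 2:
        raise ValueError("PCA needs >= 2 features and >= 2 samples")
    if transform == "log2p1":
        x = np.log2(expression.to_numpy(dtype=float) + 1.0)
    elif transform == "none":
        x = expression.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if np.allclose(x, x.flat[0]):
        raise ValueError("constant expression matrix: no variance to decompose")
    xt = x.T  # samples x features
    if center:
        xt = xt - xt.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xt, full_matrices=False)
    # deterministic sign: largest-|.| loading entry positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expression.columns, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=expression.index, columns=comp_names),
        explained_variance_ratio=evr,
    )


def top_loading_features(
    result: PCAResult,
    component: int,
    k: int,
    mode: Literal["signed_top", "signed_bottom", "absolute"] = "absolute",
) -> list[str]:
    """The k features contributing most to one component.

    ``signed_top`` ranks by largest loading, ``signed_bottom`` by most
    negative, ``absolute`` by |loading|.  Ties break lexicographically by
    feature id.  ``component`` is 1-based (component 1 = PC1).
    """
    if not 1 <= component <= result.n_components:
        raise ValueError(f"component {component} out of range 1..{result.n_components}")
    col = result.loadings.iloc[:, component - 1]
    if k > len(col):
        raise ValueError(f"k={k} exceeds feature count {len(col)}")
    items = list(zip(col.index.astype(str), col.to_numpy(dtype=float)))
    if mode == "signed_top":
        items.sort(key=lambda fv: (-fv[1], fv[0]))
    elif mode == "signed_bottom":
        items.sort(key=lambda fv: (fv[1], fv[0]))
    elif mode == "absolute":
        items.sort(key=lambda fv: (-abs(fv[1]), fv[0]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [f for f, _ in items[:k]]


def loading_set_union(lists: Sequence[Iterable[str]]) -> tuple[set, int]:
    """Union of ranked loading lists with the cross-list overlap count.

    Returns (unique feature set, overlap) where overlap = sum of list
    lengths minus the union size — e.g. four top-10 lists sharing four
    features across components give (36 unique features, 4 overlapping).
    """
    lists = [list(l) for l in lists]
    if not lists or any(len(l) == 0 for l in lists):
        raise ValueError("loading lists must be non-empty")
    union: set = set()
    total = 0
    for l in lists:
        total += len(l)
        union |= set(l)
    return union, total - len(union)
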