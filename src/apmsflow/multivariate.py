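"""z-transformation and PCA of the protein × sample SI_GI matrix.

Samples (band-replicate runs) are the observations and proteins the
variables, so loadings read as protein contributions. Each protein row is
standardized across samples before decomposition; zero-variance proteins
are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from apmsflow.errors import ValidationError


@dataclass
class ZMatrix:
    """Standardized proteins × samples matrix with the dropped-row list."""

    data: pd.DataFrame
    dropped_proteins: list[str] = field(default_factory=list)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # proteins × components
    variance_explained: np.ndarray  # percent per component
    dropped_proteins: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path, prefix: str = "pca") -> None:
        outdir = Path(outdir)
        self.scores.to_csv(outdir / f"{prefix}_scores.tsv", sep="\t")
        self.loadings.to_csv(outdir / f"{prefix}_loadings.tsv", sep="\t")
        pd.DataFrame(
            {"component": self.scores.columns, "percent_variance": self.variance_explained}
        ).to_csv(outdir / f"{prefix}_variance.tsv", sep="\t", index=False)


def z_transform(matrix: pd.DataFrame) -> ZMatrix:
    """Standardize each protein row across samples (mean 0, sd 1, ddof=1).

    Zero-variance rows cannot be standardized; they are dropped and listed
    in ``dropped_proteins``. Requires at least 2 samples.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("z_transform needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [str(p) for p in matrix.index[~keep]]
    kept = values[keep]
    z = (kept - kept.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return ZMatrix(pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns), dropped)


def pca(z: ZMatrix | pd.DataFrame) -> PCAResult:
    """PCA of samples-as-observations via SVD of the z-matrix.

    Components carry a deterministic sign convention (the largest-magnitude
    loading of each component is made positive) so output is bit-stable.
    ``variance_explained`` is in percent and sums to 100 over the retained
    components.
    """
    if isinstance(z, ZMatrix):
        frame, dropped = z.data, z.dropped_proteins
    else:
        frame, dropped = z, []
    if frame.shape[0] < 1 or frame.shape[1] < 2:
        raise ValidationError("pca needs >=1 protein and >=2 samples")
    X = frame.to_numpy(dtype=float).T  # samples × proteins
    if not np.any(X):
        raise ValidationError("pca: degenerate all-zero matrix")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: flip each component so its largest |loading| is positive
    for j in range(len(S)):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    var = S**2
    percent = 100.0 * var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=frame.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=frame.index, columns=comps),
        variance_explained=percent,
        dropped_proteins=dropped,
    )
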