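"""PCA fingerprinting of TE-composition profiles across samples.

Samples are rows, TE super-families are columns, values are
UCOS-normalized abundances. Columns are natural-log transformed,
centered and scaled to unit variance (the prcomp(scale=TRUE)
convention), and the components come from an eigen-decomposition of the
covariance of the transformed matrix. Subsample replicates are compared
to the full-data ordination by sign-aligned correlation of PC1/PC2
scores, so no Procrustes rotation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["assemble_matrix", "PCAResult", "run_pca", "replicate_pca"]


def assemble_matrix(tables: dict[str, pd.Series]) -> pd.DataFrame:
    """Stack per-sample super-family abundances into a samples x superfamilies matrix.

    All samples must share the same super-family set. Zero cells are
    floored at half the smallest positive value in their column so the
    subsequent log transform is defined; the floor values used are
    recorded in ``df.attrs["zero_floor"]``.
    """
    keys = None
    for sample, s in tables.items():
        k = frozenset(s.index)
        if keys is None:
            keys = k
        elif k != keys:
            raise ValueError(f"sample {sample} has a different superfamily set")
    df = pd.DataFrame({sample: s for sample, s in tables.items()}).T.sort_index(axis=1)
    df.index.name = "sample"
    floors = {}
    for col in df.columns:
        v = df[col]
        if (v == 0).any():
            positive = v[v > 0]
            if len(positive):
                floor = positive.min() / 2.0
                df.loc[v == 0, col] = floor
                floors[col] = floor
    df.attrs["zero_floor"] = floors
    return df


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_variance: np.ndarray  # proportions, non-increasing, sum 1

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(matrix: pd.DataFrame, log_transform: bool = True, scale: bool = True) -> PCAResult:
    """Principal components of the (log-)transformed abundance matrix.

    Zero-variance columns are dropped with a warning. The sign of each
    component is fixed so its largest-magnitude loading is positive,
    making results comparable across runs and replicates.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.astype(float)
    if log_transform:
        if (X <= 0).any().any():
            raise ValueError("log transform requires strictly positive abundances")
        X = np.log(X)
    var = X.var(axis=0, ddof=1)
    keep = var > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        X = X.loc[:, keep]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / Xc.std(axis=0, ddof=1)
    cov = np.cov(Xc.to_numpy(), rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = Xc.to_numpy() @ eigvec
    comp_names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(eigvec, index=X.columns, columns=comp_names),
        explained_variance=eigval / eigval.sum(),
    )


def replicate_pca(
    replicate_matrices: list[pd.DataFrame],
    full_matrix: pd.DataFrame,
    log_transform: bool = True,
    scale: bool = True,
) -> tuple[list[PCAResult], pd.DataFrame]:
    """PCA per replicate plus a stability summary against the full data.

    The summary holds, per replicate, the sign-aligned Pearson
    correlation of PC1 and PC2 sample scores with the full-data PCA
    (max over the sign flip, since component orientation is arbitrary up
    to the tie behaviour of the sign convention).
    """
    full = run_pca(full_matrix, log_transform, scale)
    results = []
    rows = []
    for i, m in enumerate(replicate_matrices, start=1):
        r = run_pca(m, log_transform, scale)
        results.append(r)
        row = {"replicate": i}
        for pc in ("PC1", "PC2"):
            if pc in r.scores.columns and pc in full.scores.columns:
                a = r.scores[pc].reindex(full.scores.index)
                b = full.scores[pc]
                c = float(np.corrcoef(a, b)[0, 1])
                row[f"{pc.lower()}_score_correlation"] = max(c, -c)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("replicate") if len(rows) > 1 else pd.DataFrame()
    return results, summary


def plot_biplot(result: PCAResult, path: str) -> None:
    """Minimal PC1/PC2 biplot for visual inspection (numbers are the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    s = result.scores
    ax.scatter(s["PC1"], s["PC2"])
    for name, row in s.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=8)
    ev = result.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.0f}%)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
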