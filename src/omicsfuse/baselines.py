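"""PCA-family fusion baselines (PCA, kernel PCA, sparse PCA).

Linear and regularised linear alternatives to the autoencoder embedding,
run through the identical clustering + survival machinery for comparison.
For plain PCA the component count is the smallest explaining the target
cumulative variance (0.90 by default); kernel and sparse PCA use a fixed
component count matching the autoencoders' latent width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA, KernelPCA, SparsePCA

__all__ = ["BaselineConfig", "pca_embed", "kpca_embed", "spca_embed", "embed"]


@dataclass
class BaselineConfig:
    method: str = "pca"  # pca | kpca | spca
    variance_retained: float = 0.90
    n_components: int = 100
    kernel: str = "rbf"
    gamma: float | None = None  # None -> median pairwise distance heuristic
    sparsity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pca", "kpca", "spca"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must lie in (0, 1]")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with more than one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains non-finite entries")
    if np.ptp(x) == 0:
        raise ValueError("degenerate all-constant matrix")
    return x


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Make each component's largest-magnitude loading positive."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None], scores * signs[None, :]


def pca_embed(fused, config: BaselineConfig | None = None) -> np.ndarray:
    """Scores on the leading components covering ``variance_retained``."""
    config = config or BaselineConfig(method="pca")
    x = _check_input(np.asarray(fused, dtype=float))
    model = PCA(svd_solver="full")
    scores = model.fit_transform(x)
    cum = np.cumsum(model.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, config.variance_retained - 1e-12) + 1)
    n_comp = min(n_comp, scores.shape[1])
    _, scores = _fix_signs(model.components_[:n_comp], scores[:, :n_comp])
    return scores


def _median_heuristic_gamma(x: np.ndarray) -> float:
    med = np.median(pdist(x))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med * med)


def kpca_embed(fused, config: BaselineConfig | None = None) -> np.ndarray:
    """Kernel PCA scores (RBF by default, bandwidth by median heuristic)."""
    config = config or BaselineConfig(method="kpca")
    x = _check_input(np.asarray(fused, dtype=float))
    n_comp = min(config.n_components, x.shape[0] - 1)
    gamma = config.gamma
    if gamma is None and config.kernel == "rbf":
        gamma = _median_heuristic_gamma(x)
    model = KernelPCA(
        n_components=n_comp,
        kernel=config.kernel,
        gamma=gamma,
        random_state=config.seed,
    )
    return model.fit_transform(x)


def spca_embed(fused, config: BaselineConfig | None = None) -> np.ndarray:
    """Sparse PCA scores via l1-penalised component estimation."""
    config = config or BaselineConfig(method="spca")
    x = _check_input(np.asarray(fused, dtype=float))
    n_comp = min(config.n_components, min(x.shape))
    model = SparsePCA(
        n_components=n_comp,
        alpha=config.sparsity,
        random_state=config.seed,
        max_iter=200,
    )
    return model.fit_transform(x - x.mean(axis=0))


def embed(fused, config: BaselineConfig) -> np.ndarray:
    """Dispatch to the configured baseline method."""
    fn = {"pca": pca_embed, "kpca": kpca_embed, "spca": spca_embed}[config.method]
    return fn(fused, config)
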