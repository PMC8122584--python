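"""End-to-end orchestration: preprocess → embed → cluster → survival → pick.

For each of the four autoencoder variants the fused matrix is embedded,
both clustering pairings are swept over k = 3..6, and every solution is
scored by mean silhouette and log-rank p-value. The subtype number is the
k at which most configurations reach a silhouette above 0.80 (ties to the
smaller k); the final model is the configuration at that k with the
smallest log-rank p among those above the silhouette bar.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import autoencoders, cluster
from .autoencoders import EncoderConfig, LatentEmbedding, VARIANTS, default_config
from .preprocess import (
    ClinicalTable,
    MultiOmicsDataset,
    NormalizedBlock,
    OmicsBlock,
    fuse,
    minmax_normalize,
    restrict,
    select_by_cox,
    select_by_variance,
)
from .survival import logrank

__all__ = [
    "SILHOUETTE_BAR",
    "GridCell",
    "SubtypeReport",
    "load_omics_block",
    "load_clinical",
    "load_dataset",
    "prepare_fused",
    "run_all",
    "choose_optimal_k",
    "choose_final",
]

logger = logging.getLogger("omicsfuse")

#: silhouette threshold a configuration must exceed to count as confident
SILHOUETTE_BAR = 0.80

#: default per-omic feature counts for variance selection (mRNA, methylation,
#: miRNA) — fused width 1000 at full scale
DEFAULT_SELECT_COUNTS = (500, 400, 100)


# ---------------------------------------------------------------------------
# loaders (the synthetic writer round-trips through these)
# ---------------------------------------------------------------------------

def load_omics_block(path: str | Path, omic_name: str) -> OmicsBlock:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, float_precision="round_trip"
    )
    return OmicsBlock.from_frame(frame, omic_name)


def load_clinical(path: str | Path) -> ClinicalTable:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, float_precision="round_trip"
    )
    return ClinicalTable(
        sample_ids=list(frame.index.astype(str)),
        time_days=frame["time_days"].to_numpy(dtype=float),
        event=frame["event"].to_numpy(dtype=int),
    )


def load_dataset(
    directory: str | Path,
    omic_files: dict[str, str] | None = None,
    clinical_file: str = "clinical.tsv",
) -> MultiOmicsDataset:
    """Load the TSV file set produced by :func:`omicsfuse.synthetic.write_dataset`
    (or user-supplied matrices following the same layout)."""
    directory = Path(directory)
    if omic_files is None:
        omic_files = {
            name: f"{name}.tsv"
            for name in ("mrna", "methylation", "mirna")
            if (directory / f"{name}.tsv").exists()
        }
    if not omic_files:
        raise FileNotFoundError(f"no omic matrices found under {directory}")
    blocks = {
        name: load_omics_block(directory / fname, name)
        for name, fname in omic_files.items()
    }
    clinical = load_clinical(directory / clinical_file)
    return MultiOmicsDataset(blocks=blocks, clinical=clinical)


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    """One (variant, pairing, k) configuration's scores."""

    variant: str
    algorithm: str
    metric: str
    k: int
    mean_silhouette: float
    logrank_p: float
    labels: np.ndarray = field(repr=False)

    @property
    def pairing(self) -> str:
        return f"{self.algorithm}/{self.metric}"


@dataclass
class SubtypeReport:
    """The full configuration grid plus the selected subtype model."""

    cells: list[GridCell]
    optimal_k: int
    counts: dict[int, int]  # per k: configurations above the silhouette bar
    confident: bool  # False when no configuration cleared the bar
    final: GridCell | None
    selection_method: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant": c.variant,
                    "algorithm": c.algorithm,
                    "metric": c.metric,
                    "k": c.k,
                    "mean_silhouette": c.mean_silhouette,
                    "logrank_p": c.logrank_p,
                }
                for c in self.cells
            ]
        )

    def silhouette_table(self) -> pd.DataFrame:
        """k x (variant, pairing) grid of mean silhouettes."""
        frame = self.to_frame()
        frame["pairing"] = frame["algorithm"] + "/" + frame["metric"]
        return frame.pivot_table(
            index="k", columns=["variant", "pairing"], values="mean_silhouette"
        )

    def pvalue_table(self) -> pd.DataFrame:
        """k x (variant, pairing) grid of log-rank p-values."""
        frame = self.to_frame()
        frame["pairing"] = frame["algorithm"] + "/" + frame["metric"]
        return frame.pivot_table(
            index="k", columns=["variant", "pairing"], values="logrank_p"
        )

    def summary(self) -> dict:
        out = {
            "optimal_k": self.optimal_k,
            "confident": self.confident,
            "counts_above_bar": {str(k): v for k, v in sorted(self.counts.items())},
            "selection_method": self.selection_method,
            "seed": self.seed,
        }
        if self.final is not None:
            out["final"] = {
                "variant": self.final.variant,
                "pairing": self.final.pairing,
                "k": self.final.k,
                "mean_silhouette": self.final.mean_silhouette,
                "logrank_p": self.final.logrank_p,
                "labels": [int(x) for x in self.final.labels],
            }
        else:
            out["final"] = None
        return out

    def to_json(self) -> str:
        return json.dumps(self.summary(), sort_keys=True, indent=2)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "grid.tsv", sep="\t", index=False)
        self.silhouette_table().to_csv(directory / "silhouette_table.tsv", sep="\t")
        self.pvalue_table().to_csv(directory / "pvalue_table.tsv", sep="\t")
        (directory / "summary.json").write_text(self.to_json() + "\n")


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def choose_optimal_k(
    cells: list[GridCell], bar: float = SILHOUETTE_BAR
) -> tuple[int, dict[int, int], bool]:
    """Pick the k at which most configurations exceed the silhouette bar.

    Returns ``(optimal_k, counts, confident)``. Ties break to the smallest
    k. When no configuration clears the bar anywhere, ``confident`` is
    False and the k of the best raw mean silhouette is reported instead.
    """
    if not cells:
        raise ValueError("empty configuration grid")
    ks = sorted({c.k for c in cells})
    counts = {
        k: sum(1 for c in cells if c.k == k and c.mean_silhouette > bar) for k in ks
    }
    if all(v == 0 for v in counts.values()):
        best = max(cells, key=lambda c: (c.mean_silhouette, -c.k))
        return best.k, counts, False
    optimal = max(ks, key=lambda k: (counts[k], -k))
    return optimal, counts, True


_VARIANT_RANK = {v: i for i, v in enumerate(VARIANTS)}
_PAIRING_RANK = {p: i for i, p in enumerate(cluster.DEFAULT_PAIRINGS)}


def choose_final(
    cells: list[GridCell], optimal_k: int, bar: float = SILHOUETTE_BAR
) -> GridCell:
    """At the optimal k, pick the above-bar cell with the lowest log-rank p.

    Ties break to the higher silhouette, then to variant order (vanilla,
    denoising, sparse, variational), then pairing order (PAM/Spearman
    first). Raises when no cell at ``optimal_k`` clears the bar — callers
    should fall back to reporting the grid without a final model.
    """
    eligible = [
        c for c in cells if c.k == optimal_k and c.mean_silhouette > bar
    ]
    if not eligible:
        raise ValueError(
            f"no configuration at k={optimal_k} exceeds silhouette {bar}; "
            "report the grid and fall back to the best raw silhouette"
        )
    return min(
        eligible,
        key=lambda c: (
            c.logrank_p,
            -c.mean_silhouette,
            _VARIANT_RANK.get(c.variant, len(_VARIANT_RANK)),
            _PAIRING_RANK.get((c.algorithm, c.metric), len(_PAIRING_RANK)),
        ),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def prepare_fused(
    dataset: MultiOmicsDataset,
    selection: str = "variance",
    select_counts=DEFAULT_SELECT_COUNTS,
    cox_alpha: float = 0.05,
) -> pd.DataFrame:
    """Normalize, select features per omic, and fuse into one matrix."""
    blocks = dataset.ordered_blocks()
    normalized: list[NormalizedBlock] = [minmax_normalize(b) for b in blocks]
    reduced = []
    for block, count in zip(normalized, list(select_counts) + [None] * 99):
        if selection == "variance":
            k = min(count or block.n_features, block.n_features)
            sel = select_by_variance(block, k)
        elif selection == "cox":
            sel = select_by_cox(block, dataset.clinical, alpha=cox_alpha)
            if not sel.kept_ids:  # degenerate screen: keep everything
                sel = select_by_variance(block, block.n_features)
        else:
            raise ValueError(f"unknown selection method {selection!r}")
        reduced.append(restrict(block, sel))
    return fuse(reduced)


def run_all(
    dataset: MultiOmicsDataset,
    configs: dict[str, EncoderConfig] | None = None,
    selection: str = "variance",
    seed: int = 0,
    k_range=range(3, 7),
    select_counts=DEFAULT_SELECT_COUNTS,
    cox_alpha: float = 0.05,
    epochs: int | None = None,
) -> tuple[SubtypeReport, dict[str, LatentEmbedding]]:
    """Run the whole analysis and return the report plus the embeddings.

    ``configs`` defaults to the four variants' standard configurations;
    per-variant training seeds and the k-means seed are derived
    deterministically from ``seed``, so identical inputs and seed yield a
    byte-identical serialized report.
    """
    t0 = time.perf_counter()
    fused = prepare_fused(
        dataset, selection=selection, select_counts=select_counts,
        cox_alpha=cox_alpha,
    )
    logger.info(
        "fused matrix: %d samples x %d features (%.1fs)",
        fused.shape[0], fused.shape[1], time.perf_counter() - t0,
    )

    seed_rng = np.random.default_rng(seed)
    derived = seed_rng.integers(0, 2**31 - 1, size=len(VARIANTS) + 1)
    if configs is None:
        configs = {v: default_config(v) for v in VARIANTS}
    missing = [v for v in VARIANTS if v not in configs]
    if missing:
        raise ValueError(f"configs missing variants: {missing}")

    cells: list[GridCell] = []
    embeddings: dict[str, LatentEmbedding] = {}
    for i, variant in enumerate(VARIANTS):
        cfg = configs[variant] or autoencoders.default_config(variant)
        overrides: dict = {"seed": int(derived[i])}
        if epochs is not None:
            overrides["epochs"] = epochs
        cfg = replace(cfg, **overrides)
        t1 = time.perf_counter()
        try:
            emb = autoencoders.train(cfg, fused)
        except Exception as exc:
            raise RuntimeError(f"training failed for variant '{variant}': {exc}")
        embeddings[variant] = emb
        logger.info(
            "%s: trained %d epochs (%.1fs)", variant, cfg.epochs,
            time.perf_counter() - t1,
        )
        try:
            solutions = cluster.sweep(
                emb.coordinates, k_range=k_range, seed=int(derived[-1])
            )
        except Exception as exc:
            raise RuntimeError(f"clustering failed for variant '{variant}': {exc}")
        for sol in solutions:
            try:
                lr = logrank(
                    dataset.clinical.time_days, dataset.clinical.event, sol.labels
                )
            except Exception as exc:
                raise RuntimeError(
                    f"log-rank failed for ({variant}, {sol.algorithm}/"
                    f"{sol.metric}, k={sol.k}): {exc}"
                )
            cells.append(
                GridCell(
                    variant=variant,
                    algorithm=sol.algorithm,
                    metric=sol.metric,
                    k=sol.k,
                    mean_silhouette=float(sol.mean_silhouette),
                    logrank_p=lr.p_value,
                    labels=sol.labels,
                )
            )

    optimal_k, counts, confident = choose_optimal_k(cells)
    final: GridCell | None
    if confident:
        final = choose_final(cells, optimal_k)
    else:
        final = None
        logger.warning(
            "no configuration exceeded silhouette %.2f; reporting grid "
            "without a final model", SILHOUETTE_BAR,
        )
    logger.info("run_all finished in %.1fs", time.perf_counter() - t0)
    return (
        SubtypeReport(
            cells=cells,
            optimal_k=optimal_k,
            counts=counts,
            confident=confident,
            final=final,
            selection_method=selection,
            seed=seed,
        ),
        embeddings,
    )
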