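"""Synthetic multi-omics datasets with planted subtypes and survival.

Emulates the shape of a TCGA-style cohort — three omic blocks (mRNA,
methylation, miRNA) over one patient set plus right-censored survival —
with a known ground truth: a minority of features per omic carries a
subtype-specific mean shift, and each subtype has its own exponential
event hazard, so both the clustering stages and the survival stages of the
pipeline have a planted signal to recover.

Three geometries are available. ``"blobs"`` (default) plants
mean-separable Gaussian blocks. ``"lognormal"`` plants the same blobs on
the log scale and exponentiates the whole block, giving multiplicative
noise with the heavy-tailed marginals of raw expression data — structure
a linear projection handles poorly but a saturating encoder compresses.
``"shells"`` places subtypes on concentric hyperspheres in the
informative subspace; note that purely radial structure is not
recoverable by centroid/medoid clustering in any pointwise embedding
(opposite poles of one shell stay maximally distant), so this geometry
exercises the generator, not the subtype-recovery pipeline.

Within the blob geometry two signal modes exist. ``"signatures"``
(default) elevates a disjoint third of the informative features per
subtype by ``effect_size`` noise-SDs, the way real subtypes carry distinct
marker panels; each subtype then has its own cross-feature rank pattern,
visible to both Euclidean and Spearman-correlation similarity.
``"ladder"`` instead shifts every informative feature by
``s × effect_size`` for subtype *s* — a one-directional separation that is
mean-separable but rank-identical across non-zero subtypes, and therefore
invisible to scale-invariant (Spearman) similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ClinicalTable, MultiOmicsDataset, OmicsBlock, OMIC_ORDER

__all__ = ["SimulationSpec", "GroundTruth", "simulate_multiomics", "write_dataset"]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort.

    Defaults are the scaled-down study conditions used throughout the test
    suite: 3 subtypes × 50 patients and raw block widths 2500/2000/500 —
    about a seventh of a real cohort's mRNA/methylation dimensions — from
    which the pipeline's variance selection keeps its usual 500/400/100,
    so selection stays a real (signal-enriching) step. Subtype markers are
    shifted by 6 noise-SDs on 20% of features, and per-subtype exponential
    hazards span a 10× range with light independent censoring.
    """

    n_subtypes: int = 3
    samples_per_subtype: tuple[int, ...] = (50, 50, 50)
    omic_widths: tuple[int, int, int] = (2500, 2000, 500)
    informative_fraction: float = 0.2
    effect_size: float = 6.0
    noise_sd: float = 1.0
    hazards: tuple[float, ...] = (0.01, 0.004, 0.001)  # events per day
    censoring_rate: float = 5e-4  # per day; 0 disables censoring
    seed: int = 0
    geometry: str = "blobs"  # blobs | lognormal | shells
    lognormal_tau: float = 2.0  # log-scale multiplier for geometry="lognormal"
    signal_mode: str = "signatures"  # or "ladder"
    methylation_beta: bool = False  # squash methylation block into (0, 1)

    def validate(self) -> None:
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be positive")
        if len(self.samples_per_subtype) != self.n_subtypes:
            raise ValueError("samples_per_subtype must have n_subtypes entries")
        if any(c < 1 for c in self.samples_per_subtype):
            raise ValueError("samples_per_subtype entries must be positive")
        if any(w < 1 for w in self.omic_widths):
            raise ValueError("omic_widths entries must be positive")
        if not 0 < self.informative_fraction <= 1:
            raise ValueError("informative_fraction must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.hazards) != self.n_subtypes:
            raise ValueError("hazards must have n_subtypes entries")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be strictly positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        if self.geometry not in ("blobs", "lognormal", "shells"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.lognormal_tau <= 0:
            raise ValueError("lognormal_tau must be positive")
        if self.signal_mode not in ("signatures", "ladder"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


@dataclass
class GroundTruth:
    """Planted labels and the identity of the informative features."""

    subtype_label: np.ndarray
    informative_feature_ids: dict[str, list[str]]
    sample_ids: list[str] = field(default_factory=list)


def _informative_block(
    rng: np.random.Generator,
    labels: np.ndarray,
    n_inf: int,
    spec: SimulationSpec,
) -> np.ndarray:
    n = labels.size
    if spec.geometry in ("blobs", "lognormal"):
        x = rng.normal(0.0, spec.noise_sd, size=(n, n_inf))
        shift = spec.effect_size * spec.noise_sd
        if spec.signal_mode == "ladder":
            x += labels[:, None] * shift
        else:
            # each informative feature is a marker of one subtype
            # (round-robin assignment), elevated only in that subtype
            owner = np.arange(n_inf) % spec.n_subtypes
            x += shift * (labels[:, None] == owner[None, :])
        return x
    # shells: radius grows with subtype; direction uniform on the sphere.
    # Radius scales with sqrt(dim) so the per-feature RMS displacement is
    # effect_size*(s+1)/2 noise-SDs regardless of the block width.
    g = rng.normal(size=(n, n_inf))
    u = g / np.linalg.norm(g, axis=1, keepdims=True)
    radius = (
        0.5 * spec.effect_size * spec.noise_sd * np.sqrt(n_inf) * (labels + 1.0)
    )
    return radius[:, None] * u + rng.normal(0.0, spec.noise_sd, size=(n, n_inf))


def simulate_multiomics(
    spec: SimulationSpec,
) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one cohort; identical spec (incl. seed) → bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = np.asarray(spec.samples_per_subtype)
    labels = np.repeat(np.arange(spec.n_subtypes), counts)
    n = int(counts.sum())
    sample_ids = [f"PT-{i + 1:04d}" for i in range(n)]

    blocks: dict[str, OmicsBlock] = {}
    informative: dict[str, list[str]] = {}
    for omic, width in zip(OMIC_ORDER, spec.omic_widths):
        n_inf = max(1, int(round(spec.informative_fraction * width)))
        n_inf = min(n_inf, width)
        inf_idx = np.sort(rng.choice(width, size=n_inf, replace=False))
        x = rng.normal(0.0, spec.noise_sd, size=(n, width))
        x[:, inf_idx] = _informative_block(rng, labels, n_inf, spec)
        if spec.geometry == "lognormal":
            x = np.exp(spec.lognormal_tau * x)
        if omic == "methylation" and spec.methylation_beta:
            # logistic squash gives a beta-like bounded marginal
            x = 1.0 / (1.0 + np.exp(-x))
        feature_ids = [f"{omic}_f{j:05d}" for j in range(width)]
        blocks[omic] = OmicsBlock(
            values=x, sample_ids=sample_ids, feature_ids=feature_ids, omic_name=omic
        )
        informative[omic] = [feature_ids[j] for j in inf_idx]

    hazards = np.asarray(spec.hazards)[labels]
    event_time = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = ClinicalTable(
        sample_ids=sample_ids, time_days=observed, event=event
    )

    dataset = MultiOmicsDataset(blocks=blocks, clinical=clinical)
    truth = GroundTruth(
        subtype_label=labels,
        informative_feature_ids=informative,
        sample_ids=sample_ids,
    )
    return dataset, truth


def write_dataset(
    dataset: MultiOmicsDataset, truth: GroundTruth, directory: str | Path
) -> list[Path]:
    """Write one TSV per omic plus clinical and truth tables.

    Matrices are written with full float repr and round-trip exactly
    through :func:`omicsfuse.pipeline.load_dataset`.
    """
    if dataset.n_samples == 0:
        raise ValueError("refusing to write an empty dataset (0 samples)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, block in dataset.blocks.items():
        path = directory / f"{name}.tsv"
        frame = block.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(path, sep="\t", float_format="%.17g")  # exact round trip
        written.append(path)
    clin_path = directory / "clinical.tsv"
    dataset.clinical.to_frame().to_csv(clin_path, sep="\t", float_format="%.17g")
    written.append(clin_path)
    truth_path = directory / "truth.tsv"
    pd.DataFrame(
        {"subtype": truth.subtype_label},
        index=pd.Index(truth.sample_ids or dataset.sample_ids, name="sample_id"),
    ).to_csv(truth_path, sep="\t")
    written.append(truth_path)
    return written
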