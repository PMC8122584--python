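"""Per-omic normalisation, feature selection and fusion.

Each omic (mRNA expression, DNA methylation, miRNA expression) arrives as a
sample-by-feature matrix sharing one patient set. Features are min-max
scaled to [0, 1] per feature, then reduced either by largest sample
variance or by univariate Cox proportional-hazards screening against the
patients' survival, and finally the reduced blocks are concatenated
column-wise into the fused matrix fed to the autoencoders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OMIC_ORDER",
    "OmicsBlock",
    "NormalizedBlock",
    "ClinicalTable",
    "MultiOmicsDataset",
    "FeatureSelection",
    "minmax_normalize",
    "select_by_variance",
    "select_by_cox",
    "cox_univariate",
    "fuse",
]

#: canonical concatenation order for the fused matrix
OMIC_ORDER = ("mrna", "methylation", "mirna")


@dataclass
class OmicsBlock:
    """One omic's sample-by-feature matrix with row/column identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omic_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample-by-feature matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{self.omic_name}: {len(self.sample_ids)} sample_ids for {n} rows"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{self.omic_name}: {len(self.feature_ids)} feature_ids for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"{self.omic_name}: duplicate sample_ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError(f"{self.omic_name}: duplicate feature_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"{self.omic_name}: matrix contains missing/non-finite values; "
                "resolve missingness before loading"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omic_name: str) -> "OmicsBlock":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=list(frame.index),
            feature_ids=list(frame.columns),
            omic_name=omic_name,
        )


@dataclass
class NormalizedBlock(OmicsBlock):
    """An :class:`OmicsBlock` after per-feature min-max scaling.

    ``feature_min``/``feature_max`` retain the per-feature extremes of the
    raw matrix so the affine map is recoverable.
    """

    feature_min: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_max: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError(f"{self.omic_name}: normalized entries outside [0, 1]")


@dataclass
class ClinicalTable:
    """Per-patient right-censored survival: time in days and event flag."""

    sample_ids: list[str]
    time_days: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time_days.shape != (n,) or self.event.shape != (n,):
            raise ValueError("clinical columns must have one entry per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids in clinical table")
        if np.any(self.time_days < 0):
            raise ValueError("survival times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.time_days, "event": self.event},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def reindex(self, sample_ids: list[str]) -> "ClinicalTable":
        """Return the table restricted/reordered to ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples missing from clinical table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(
            sample_ids=list(sample_ids),
            time_days=self.time_days[idx],
            event=self.event[idx],
        )


@dataclass
class MultiOmicsDataset:
    """Aligned omic blocks plus the clinical table for one patient set."""

    blocks: dict[str, OmicsBlock]
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        ids = None
        for name, block in self.blocks.items():
            if ids is None:
                ids = block.sample_ids
            elif block.sample_ids != ids:
                raise ValueError(
                    f"omic '{name}' sample ids differ from the first block; "
                    "align patients before constructing the dataset"
                )
        if ids is not None and self.clinical.sample_ids != ids:
            raise ValueError("clinical sample ids differ from the omic blocks")

    @property
    def sample_ids(self) -> list[str]:
        first = next(iter(self.blocks.values()))
        return first.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def ordered_blocks(self) -> list[OmicsBlock]:
        """Blocks in canonical (mRNA, methylation, miRNA) order; unknown
        omic names follow in insertion order."""
        known = [self.blocks[n] for n in OMIC_ORDER if n in self.blocks]
        other = [b for n, b in self.blocks.items() if n not in OMIC_ORDER]
        return known + other


@dataclass
class FeatureSelection:
    """Kept features of one block plus the per-feature score used."""

    method: str  # "variance" or "cox"
    omic_name: str
    kept_ids: list[str]
    scores: pd.Series  # variance, or Cox Wald p-value, indexed by feature id
    threshold: float
    skipped_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("variance", "cox"):
            raise ValueError(f"unknown selection method {self.method!r}")


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def minmax_normalize(block: OmicsBlock) -> NormalizedBlock:
    """Scale each feature to [0, 1] via (x - xmin) / (xmax - xmin).

    Constant features (xmax == xmin) map to all-zeros rather than raising:
    flat probes are common in methylation/expression matrices and a zero
    column is a harmless input node downstream.
    """
    if block.n_samples < 1:
        raise ValueError("cannot normalize an empty block")
    x = block.values
    xmin = x.min(axis=0)
    xmax = x.max(axis=0)
    span = xmax - xmin
    flat = span == 0
    safe_span = np.where(flat, 1.0, span)
    scaled = (x - xmin) / safe_span
    scaled[:, flat] = 0.0
    return NormalizedBlock(
        values=scaled,
        sample_ids=list(block.sample_ids),
        feature_ids=list(block.feature_ids),
        omic_name=block.omic_name,
        feature_min=xmin,
        feature_max=xmax,
    )


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_by_variance(block: OmicsBlock, k: int) -> FeatureSelection:
    """Keep the ``k`` features of largest sample variance.

    Ties break deterministically in favour of the earlier feature id; kept
    ids preserve the block's original feature order.
    """
    p = block.n_features
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")
    var = block.values.var(axis=0, ddof=1) if block.n_samples > 1 else np.zeros(p)
    order = np.argsort(-var, kind="stable")  # stable → ties by feature order
    top = np.sort(order[:k])
    threshold = float(var[order[k - 1]])
    return FeatureSelection(
        method="variance",
        omic_name=block.omic_name,
        kept_ids=[block.feature_ids[i] for i in top],
        scores=pd.Series(var, index=block.feature_ids, name="variance"),
        threshold=threshold,
    )


def cox_univariate(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Fit hazard(t) = h0(t)·exp(beta·x) by Newton–Raphson on the Breslow
    partial likelihood and return ``(beta, se, wald_p)``.

    Raises ``ArithmeticError`` when the likelihood is degenerate or Newton
    fails to converge (e.g. monotone likelihood under perfect separation).
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="stable")  # descending time
    x, time, event = x[order], time[order], event[order]

    def derivatives(beta: float) -> tuple[float, float, float]:
        # risk set of an event at t = all subjects with time >= t; with the
        # descending sort these are prefixes, so cumulative sums suffice
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        ll = u = info = 0.0
        # group tied event times (Breslow: shared risk-set denominator)
        ev_idx = np.flatnonzero(event == 1)
        if ev_idx.size == 0:
            raise ArithmeticError("no events in Cox fit")
        i = 0
        while i < ev_idx.size:
            j = i
            t = time[ev_idx[i]]
            while j < ev_idx.size and time[ev_idx[j]] == t:
                j += 1
            tied = ev_idx[i:j]
            d = tied.size
            # last subject entering the risk set (largest index with time >= t)
            r = np.searchsorted(-time, -t, side="right") - 1
            m0, m1, m2 = s0[r], s1[r], s2[r]
            xb = x[tied].sum()
            ll += beta * xb - d * np.log(m0)
            u += xb - d * m1 / m0
            info += d * (m2 / m0 - (m1 / m0) ** 2)
            i = j
        return ll, u, info

    beta = 0.0
    ll, u, info = derivatives(beta)
    for _ in range(max_iter):
        if info <= 0 or not np.isfinite(info):
            raise ArithmeticError("singular information in Cox fit")
        step = u / info
        new_beta = beta + step
        if abs(new_beta) > 500:
            raise ArithmeticError("Cox fit diverged (monotone likelihood?)")
        new_ll, new_u, new_info = derivatives(new_beta)
        # step-halving keeps the partial likelihood non-decreasing
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            new_beta = (beta + new_beta) / 2
            new_ll, new_u, new_info = derivatives(new_beta)
            halvings += 1
        converged = abs(new_beta - beta) < tol or abs(new_u) < 1e-9
        beta, ll, u, info = new_beta, new_ll, new_u, new_info
        if converged:
            se = 1.0 / np.sqrt(info)
            z = beta / se
            return beta, se, 2.0 * stats.norm.sf(abs(z))
    raise ArithmeticError("Cox Newton iteration did not converge")


def select_by_cox(
    block: OmicsBlock,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    max_features: int | None = None,
) -> FeatureSelection:
    """Keep features whose univariate Cox Wald p-value is below ``alpha``.

    Constant features have an undefined hazard effect and are skipped (and
    reported in ``skipped_ids``); features whose fit fails to converge are
    likewise skipped with a warning. ``max_features`` optionally caps the
    selection at the smallest p-values (off by default: the screening rule
    is a raw p cutoff).
    """
    if block.sample_ids != clinical.sample_ids:
        raise ValueError("block and clinical table are not sample-aligned")
    if clinical.event.sum() == 0:
        raise ValueError("Cox screening requires at least one observed event")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    pvals = np.full(block.n_features, np.nan)
    skipped: list[str] = []
    for j in range(block.n_features):
        col = block.values[:, j]
        if np.ptp(col) == 0:
            skipped.append(block.feature_ids[j])
            continue
        try:
            _, _, p = cox_univariate(col, clinical.time_days, clinical.event)
        except ArithmeticError as exc:
            warnings.warn(
                f"Cox fit failed for feature {block.feature_ids[j]!r}: {exc}; "
                "feature excluded from screening",
                RuntimeWarning,
                stacklevel=2,
            )
            skipped.append(block.feature_ids[j])
            continue
        pvals[j] = p
    keep = np.flatnonzero(pvals < alpha)
    if max_features is not None and keep.size > max_features:
        best = keep[np.argsort(pvals[keep], kind="stable")[:max_features]]
        keep = np.sort(best)
    return FeatureSelection(
        method="cox",
        omic_name=block.omic_name,
        kept_ids=[block.feature_ids[i] for i in keep],
        scores=pd.Series(pvals, index=block.feature_ids, name="cox_p"),
        threshold=alpha,
        skipped_ids=skipped,
    )


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def restrict(block: OmicsBlock, selection: FeatureSelection) -> OmicsBlock:
    """Subset a block to a selection's kept features (order-stable)."""
    if selection.omic_name != block.omic_name:
        raise ValueError("selection belongs to a different omic")
    pos = {f: i for i, f in enumerate(block.feature_ids)}
    idx = [pos[f] for f in selection.kept_ids]
    return type(block)(
        **{
            **{
                "values": block.values[:, idx],
                "sample_ids": list(block.sample_ids),
                "feature_ids": list(selection.kept_ids),
                "omic_name": block.omic_name,
            },
            **(
                {
                    "feature_min": block.feature_min[idx],
                    "feature_max": block.feature_max[idx],
                }
                if isinstance(block, NormalizedBlock)
                else {}
            ),
        }
    )


def fuse(blocks: list[OmicsBlock]) -> pd.DataFrame:
    """Concatenate sample-aligned blocks column-wise into the fused matrix.

    Blocks are taken in the order given (canonically mRNA, methylation,
    miRNA); feature ids are prefixed with the omic name to stay unique.
    """
    if not blocks:
        raise ValueError("no blocks to fuse")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            bad = sorted(set(b.sample_ids).symmetric_difference(ref))[:5]
            detail = f"; differing ids e.g. {bad}" if bad else " (order differs)"
            raise ValueError(
                f"omic '{b.omic_name}' is not sample-aligned with "
                f"'{blocks[0].omic_name}'{detail}"
            )
    columns = [f"{b.omic_name}:{f}" for b in blocks for f in b.feature_ids]
    values = np.hstack([b.values for b in blocks])
    return pd.DataFrame(values, index=list(ref), columns=columns)
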