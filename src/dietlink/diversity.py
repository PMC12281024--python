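"""Diversity indices and read-depth normalisation.

Hill numbers of order q (effective numbers of taxa), Shannon entropy,
the Chao1 richness estimator, common scaling of a 16S ASV table to the
smallest sample read depth, and the arcsine square-root transform used
for proportion responses in linear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "MicrobiomeCountTable",
    "hill_number",
    "shannon",
    "chao1",
    "common_scale",
    "arcsine_transform",
    "sample_diversity",
]


class DiversityError(ValueError):
    pass


@dataclass
class MicrobiomeCountTable:
    """Integer 16S ASV read counts, ASVs as rows, samples as columns.

    ``taxonomy`` (optional) is indexed by ASV id with ``phylum`` and
    ``family`` columns; partially missing assignments are allowed.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise DiversityError("duplicate ASV id")
        if self.counts.columns.duplicated().any():
            raise DiversityError("duplicate sample id")
        if (self.counts.to_numpy() < 0).any():
            raise DiversityError("negative counts")
        if self.taxonomy is not None:
            missing = self.counts.index.difference(self.taxonomy.index)
            if len(missing):
                raise DiversityError(
                    f"ASV(s) without taxonomy rows: {list(missing)[:5]}"
                )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _as_proportions(values, kind: str = "auto") -> np.ndarray:
    p = np.asarray(values, dtype=float).ravel()
    if p.size == 0:
        raise DiversityError("empty abundance vector")
    if (p < 0).any():
        raise DiversityError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise DiversityError("abundance vector has no positive entry")
    if kind == "proportions" and not np.isclose(total, 1.0, atol=1e-9):
        raise DiversityError(f"proportions sum to {total}, not 1")
    return p / total


def hill_number(p, q: float) -> float:
    """Hill number of order ``q``: the effective number of taxa.

    ``(sum_i p_i^q)^(1/(1-q))`` for q != 1, with the continuity limit
    ``exp(-sum_i p_i ln p_i)`` at q = 1. q = 0 gives observed richness.
    Zero-abundance categories are ignored; counts are normalised first.
    """
    if q < 0:
        raise DiversityError("Hill order q must be non-negative")
    p = _as_proportions(p)
    p = p[p > 0]
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    # log-domain evaluation keeps q near 1 numerically stable
    return float(np.exp(logsumexp(q * np.log(p)) / (1.0 - q)))


def shannon(p) -> float:
    """Shannon entropy ``-sum_i p_i ln p_i`` over non-zero categories."""
    p = _as_proportions(p)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def chao1(counts) -> float:
    """Chao1 richness: ``S_obs + F1^2 / (2 F2)``.

    F1 and F2 are the numbers of singleton and doubleton taxa. When no
    doubleton exists the bias-corrected form
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is used, which avoids the
    division by zero and is the standard small-sample correction.
    Requires integer counts — common-scaled tables should be rounded.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0:
        raise DiversityError("empty count vector")
    if (c < 0).any():
        raise DiversityError("negative counts")
    if not np.allclose(c, np.round(c), atol=1e-9):
        raise DiversityError(
            "Chao1 needs integer counts; round the table (e.g. the rounded "
            "common-scaled counts) or pass unscaled counts"
        )
    c = np.round(c)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def common_scale(
    table: MicrobiomeCountTable, round_counts: bool = True
) -> MicrobiomeCountTable:
    """Scale every sample to the smallest sample read depth.

    Each sample's counts are multiplied by ``min_depth / depth``; by
    default the scaled values are rounded half-to-even back to integers
    (``round_counts=False`` keeps them fractional for sensitivity
    checks). The minimum-depth sample is returned bit-identical.
    """
    depths = table.depths()
    zero = depths.index[depths == 0]
    if len(zero):
        raise DiversityError(f"zero-depth sample(s): {list(zero)[:5]}")
    min_depth = depths.min()
    factors = min_depth / depths
    scaled = table.counts * factors
    if round_counts:
        scaled = pd.DataFrame(
            np.round(scaled.to_numpy()),  # numpy rounds half-to-even
            index=scaled.index, columns=scaled.columns,
        )
    # scale factor 1 must be an exact no-op
    min_cols = depths.index[depths == min_depth]
    scaled[min_cols] = table.counts[min_cols]
    return MicrobiomeCountTable(counts=scaled, taxonomy=table.taxonomy)


def arcsine_transform(p) -> float | np.ndarray:
    """Arcsine square-root transform ``arcsin(sqrt(p))`` in radians."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise DiversityError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def sample_diversity(table: MicrobiomeCountTable) -> pd.DataFrame:
    """Per-sample Shannon, Hill q=1 and Chao1, as a tidy frame.

    Chao1 is computed on the (integer) counts as given; apply
    :func:`common_scale` first to put samples on a common depth.
    """
    rows = []
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        rows.append({"sample_id": s, "metric": "shannon", "value": shannon(c)})
        rows.append({"sample_id": s, "metric": "hill_q1",
                     "value": hill_number(c, 1.0)})
        rows.append({"sample_id": s, "metric": "chao1", "value": chao1(c)})
    return pd.DataFrame(rows, columns=["sample_id", "metric", "value"])
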