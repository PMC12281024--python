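"""Curation of replicate-level metabarcoding count tables.

The curation chain turns raw per-PCR MOTU read counts into per-sample
relative read abundance (RRA) profiles:

1. :func:`basic_motu_filter` — drop MOTUs with implausibly short sequences
   (< 10 bp) or trivially low dataset-wide read totals (<= 10 reads).
2. :func:`replicate_outlier_filter` — iteratively discard failed PCR
   replicates whose profile lies further from their own sample average
   than typical *between*-sample dissimilarities.
3. :func:`collapse_replicates` — average surviving replicates (each first
   normalised to proportions, so every replicate carries equal weight).
4. :func:`rra_identity_filter` — drop MOTUs that never reach 1% RRA in any
   sample, and MOTUs whose best reference-database identity is below 94%.
5. :func:`aggregate_taxonomy` — sum RRA within plant families or
   functional groups.

All tables are plain pandas DataFrames wrapped in light dataclasses that
enforce the structural invariants (unique ids, matching dimensions,
rows-sum-to-one for compositions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

logger = logging.getLogger("dietlink.curation")

__all__ = [
    "ReplicateCountTable",
    "MotuMeta",
    "SampleCompositionTable",
    "CurationResult",
    "basic_motu_filter",
    "replicate_outlier_filter",
    "collapse_replicates",
    "rra_identity_filter",
    "aggregate_taxonomy",
    "density_intersection",
]

#: Default curation thresholds.
MIN_SEQ_LENGTH = 10        # bp; sequences shorter than this are artefacts
MIN_TOTAL_READS = 10       # dataset-wide; MOTUs at <= this many reads dropped
MIN_RRA = 0.01             # a MOTU must reach 1% RRA in at least one sample
MIN_IDENTITY = 0.94        # best-identity match against the reference database

ROW_SUM_TOL = 1e-9


class CurationError(ValueError):
    """Raised when a curation pre-condition is violated."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ReplicateCountTable:
    """Integer read counts per MOTU (rows) x PCR replicate (columns).

    Parameters
    ----------
    counts
        DataFrame with MOTU ids as index and replicate ids as columns.
    replicate_to_sample
        Mapping from every replicate id to its biological sample id.
    """

    counts: pd.DataFrame
    replicate_to_sample: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise CurationError(f"duplicate MOTU id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise CurationError(f"duplicate replicate id: {dup!r}")
        missing = [c for c in self.counts.columns if c not in self.replicate_to_sample]
        if missing:
            raise CurationError(
                f"replicates without a sample mapping: {missing[:5]}"
            )
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise CurationError("negative read counts")

    @property
    def motu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rep in self.counts.columns:
            seen.setdefault(self.replicate_to_sample[rep], None)
        return list(seen)

    def replicates_of(self, sample_id: str) -> list[str]:
        return [r for r in self.counts.columns
                if self.replicate_to_sample[r] == sample_id]

    def proportions(self) -> pd.DataFrame:
        """Column-wise read proportions; errors on a zero-read replicate."""
        depths = self.counts.sum(axis=0)
        zero = depths.index[depths == 0]
        if len(zero):
            raise CurationError(f"zero-read replicate(s): {list(zero)[:5]}")
        return self.counts / depths

    def subset_replicates(self, keep: Sequence[str]) -> "ReplicateCountTable":
        keep = [r for r in self.counts.columns if r in set(keep)]
        return ReplicateCountTable(
            counts=self.counts[keep].copy(),
            replicate_to_sample={r: self.replicate_to_sample[r] for r in keep},
        )

    def subset_motus(self, keep: Sequence[str]) -> "ReplicateCountTable":
        return ReplicateCountTable(
            counts=self.counts.loc[list(keep)].copy(),
            replicate_to_sample=dict(self.replicate_to_sample),
        )


@dataclass
class MotuMeta:
    """Per-MOTU metadata driving the filters and taxonomic aggregation.

    ``table`` is indexed by MOTU id with columns ``seq_length`` (bp),
    ``total_reads`` (dataset-wide count), ``best_identity`` (fraction in
    [0, 1]), ``family`` and ``functional_group``.
    """

    table: pd.DataFrame

    REQUIRED = ("seq_length", "total_reads", "best_identity",
                "family", "functional_group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise CurationError(f"MotuMeta missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise CurationError("duplicate MOTU id in metadata")
        ident = self.table["best_identity"]
        if ((ident < 0) | (ident > 1)).any():
            raise CurationError("best_identity outside [0, 1]")
        for col in ("family", "functional_group"):
            bad = self.table.index[
                self.table[col].isna() | (self.table[col].astype(str) == "")
            ]
            if len(bad):
                raise CurationError(f"empty {col} label for MOTU {bad[0]!r}")

    def require_covers(self, motu_ids: Sequence[str]) -> None:
        missing = [m for m in motu_ids if m not in self.table.index]
        if missing:
            raise CurationError(
                f"MOTU(s) present in count table but absent from metadata: "
                f"{missing[:5]}"
            )

    def subset(self, motu_ids: Sequence[str]) -> "MotuMeta":
        return MotuMeta(self.table.loc[list(motu_ids)].copy())


@dataclass
class SampleCompositionTable:
    """Per-sample relative read abundances over MOTUs/families/groups.

    Rows are samples, columns taxa; each row sums to one unless
    ``normalised`` is explicitly False.
    """

    rra: pd.DataFrame
    level: Literal["motu", "family", "functional_group"] = "motu"
    normalised: bool = True
    #: free-form provenance (e.g. per-sample RRA mass discarded by a filter)
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rra.index.duplicated().any():
            raise CurationError("duplicate sample id")
        if self.rra.columns.duplicated().any():
            raise CurationError("duplicate taxon id")
        if (self.rra.to_numpy() < -ROW_SUM_TOL).any():
            raise CurationError("negative relative abundance")
        if self.normalised and len(self.rra.columns):
            sums = self.rra.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.rra.index[np.argmax(np.abs(sums - 1.0))]
                raise CurationError(
                    f"row sum != 1 for sample {bad!r} ({sums.max():.6f})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rra.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rra.columns)


@dataclass
class CurationResult:
    """Audit trail of the iterative replicate-outlier filter."""

    kept: ReplicateCountTable
    removed_replicates: list[tuple[str, int, float]]   # (replicate, iteration, dw)
    removed_samples: list[str]
    thresholds: list[float]                            # one per iteration
    iterations: int

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise CurationError("iterations must be >= 1")
        if len(self.thresholds) != self.iterations:
            raise CurationError("one threshold per iteration required")
        removed = {r for r, _, _ in self.removed_replicates}
        still = removed & set(self.kept.replicate_ids)
        if still:
            raise CurationError(f"removed replicates reappear in kept: {still}")

    def audit_frame(self) -> pd.DataFrame:
        """Tidy per-removal log (replicate_id, sample_id, iteration, dw)."""
        rows = [
            {"replicate_id": rep, "iteration": it, "dw": dw}
            for rep, it, dw in self.removed_replicates
        ]
        return pd.DataFrame(rows, columns=["replicate_id", "iteration", "dw"])


# ---------------------------------------------------------------------------
# 1. basic MOTU filter
# ---------------------------------------------------------------------------

def basic_motu_filter(
    table: ReplicateCountTable,
    meta: MotuMeta,
    min_length: int = MIN_SEQ_LENGTH,
    min_reads: int = MIN_TOTAL_READS,
) -> tuple[ReplicateCountTable, list[str]]:
    """Drop MOTUs shorter than ``min_length`` bp or at <= ``min_reads`` reads.

    The read-count rule is dataset-wide (``MotuMeta.total_reads``), applied
    before any sample-wise step. Boundary semantics: a 10 bp sequence is
    kept, a MOTU at exactly 10 total reads is removed.
    """
    meta.require_covers(table.motu_ids)
    sub = meta.table.loc[table.motu_ids]
    bad = (sub["seq_length"] < min_length) | (sub["total_reads"] <= min_reads)
    removed = list(sub.index[bad])
    kept = table.subset_motus(list(sub.index[~bad]))
    logger.info("basic_motu_filter removed %d MOTU(s)", len(removed))
    return kept, removed


# ---------------------------------------------------------------------------
# 2. iterative replicate-outlier filter
# ---------------------------------------------------------------------------

def _silverman_bandwidth(x: np.ndarray) -> float:
    sigma = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
    return 0.9 * spread * len(x) ** (-0.2)


def density_intersection(dw: np.ndarray, db: np.ndarray) -> float:
    """Threshold separating within- from between-sample distances.

    Both distance sets are smoothed with a Gaussian kernel using one
    shared Silverman bandwidth computed on the pooled values; the
    threshold is the first crossing point of the two density curves
    between the two distribution means. The shared bandwidth makes the
    crossing a genuine decision boundary between the two clusters: with
    per-set bandwidths a nearly degenerate within-sample distribution
    gets a needle-thin kernel and the crossing collapses onto its own
    tail, flagging good replicates. If either set is (numerically)
    constant, or no crossing exists in the interval, the midpoint of the
    two means is used — a deterministic fallback robust at small n.
    """
    dw = np.asarray(dw, dtype=float)
    db = np.asarray(db, dtype=float)
    m_w, m_b = float(np.mean(dw)), float(np.mean(db))
    lo, hi = (m_w, m_b) if m_w <= m_b else (m_b, m_w)
    midpoint = 0.5 * (m_w + m_b)
    if hi - lo < 1e-12:
        return midpoint
    if len(dw) < 2 or len(db) < 2:
        return midpoint
    h = _silverman_bandwidth(np.concatenate([dw, db]))
    if h < 1e-12:
        return midpoint

    def density(points: np.ndarray, x: np.ndarray) -> np.ndarray:
        z = (x[:, None] - points[None, :]) / h
        return np.exp(-0.5 * z * z).mean(axis=1) / (h * np.sqrt(2 * np.pi))

    grid = np.linspace(lo, hi, 512)
    diff = density(dw, grid) - density(db, grid)
    sign = np.sign(diff)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        return midpoint
    i = crossings[0]
    # linear interpolation of the zero of `diff` between grid[i], grid[i+1]
    x0, x1, y0, y1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
    if y1 == y0:
        return float(0.5 * (x0 + x1))
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def replicate_outlier_filter(
    table: ReplicateCountTable,
    max_iterations: int | None = None,
) -> CurationResult:
    """Iteratively discard PCR replicates unlike their own sample.

    Per iteration, on read-proportion profiles:

    1. average each sample's current replicates;
    2. ``dw`` — Euclidean distance of each replicate to its sample average;
    3. ``db`` — all pairwise Euclidean distances between sample averages;
    4. threshold — crossing of the two distance densities
       (:func:`density_intersection`);
    5. remove every replicate with ``dw`` strictly above the threshold.

    Iterate until no replicate is removed, then drop samples left with a
    single replicate. The expectation motivating the rule is that
    replicates of one sample should resemble each other more than two
    different samples do (dw < db); replicates violating it are failed
    PCRs.
    """
    n_reps = len(table.replicate_ids)
    if max_iterations is None:
        max_iterations = max(n_reps, 1)

    samples = table.sample_ids
    if sum(1 for s in samples if len(table.replicates_of(s)) >= 2) < 2:
        raise CurationError(
            "need >= 2 samples with >= 2 replicates for the outlier filter"
        )

    current = table
    removed_replicates: list[tuple[str, int, float]] = []
    thresholds: list[float] = []
    iteration = 0

    while True:
        iteration += 1
        if iteration > max_iterations:
            raise CurationError(
                f"replicate_outlier_filter failed to converge within "
                f"{max_iterations} iterations; removals so far: "
                f"{[r for r, _, _ in removed_replicates]}"
            )
        props = current.proportions()
        rep_samples = pd.Series(
            [current.replicate_to_sample[r] for r in props.columns],
            index=props.columns,
        )
        means = props.T.groupby(rep_samples).mean().T  # MOTU x sample
        if means.shape[1] < 2:
            raise CurationError(
                "fewer than 2 sample averages; between-sample distances undefined"
            )
        dw = pd.Series(
            np.linalg.norm(
                props.to_numpy() - means[rep_samples].to_numpy(), axis=0
            ),
            index=props.columns,
        )
        db = pdist(means.T.to_numpy(), metric="euclidean")
        thr = density_intersection(dw.to_numpy(), db)
        thresholds.append(thr)
        flagged = dw.index[dw.to_numpy() > thr]
        if len(flagged) == 0:
            break
        # Remove at most the worst replicate per sample per iteration: an
        # outlier inflates its own sample average and with it the dw of
        # its good siblings, so simultaneous removal would discard those
        # too. After recomputation the siblings' dw falls back below the
        # threshold.
        worst: dict[str, str] = {}
        for rep in flagged:
            s = current.replicate_to_sample[rep]
            if s not in worst or dw[rep] > dw[worst[s]]:
                worst[s] = rep
        out = list(worst.values())
        for rep in out:
            removed_replicates.append((rep, iteration, float(dw[rep])))
        current = current.subset_replicates(
            [r for r in current.replicate_ids if r not in set(out)]
        )

    # drop samples reduced to < 2 replicates, only after convergence
    removed_samples = [
        s for s in current.sample_ids if len(current.replicates_of(s)) < 2
    ]
    if removed_samples:
        keep = [
            r for r in current.replicate_ids
            if current.replicate_to_sample[r] not in set(removed_samples)
        ]
        current = current.subset_replicates(keep)

    logger.info(
        "replicate_outlier_filter: %d iteration(s), removed %d replicate(s), "
        "%d sample(s)", iteration, len(removed_replicates), len(removed_samples)
    )
    return CurationResult(
        kept=current,
        removed_replicates=removed_replicates,
        removed_samples=removed_samples,
        thresholds=thresholds,
        iterations=iteration,
    )


# ---------------------------------------------------------------------------
# 3. replicate averaging
# ---------------------------------------------------------------------------

def collapse_replicates(table: ReplicateCountTable) -> SampleCompositionTable:
    """Average each sample's replicates into one RRA profile.

    Replicates are first normalised to proportions so that sequencing
    depth differences between replicates carry no weight; the per-sample
    profile is the unweighted mean of its replicate proportion vectors.
    """
    props = table.proportions()
    rep_samples = pd.Series(
        [table.replicate_to_sample[r] for r in props.columns],
        index=props.columns,
    )
    rra = props.T.groupby(rep_samples, sort=False).mean()
    rra = rra.loc[table.sample_ids]  # preserve first-appearance sample order
    rra.index.name = "sample_id"
    return SampleCompositionTable(rra=rra, level="motu")


# ---------------------------------------------------------------------------
# 4. abundance / identity filter
# ---------------------------------------------------------------------------

def rra_identity_filter(
    table: SampleCompositionTable,
    meta: MotuMeta,
    min_rra: float = MIN_RRA,
    min_identity: float = MIN_IDENTITY,
) -> tuple[SampleCompositionTable, list[str]]:
    """Drop MOTUs never reaching ``min_rra`` in any sample, or with
    best-identity below ``min_identity``; renormalise the survivors.

    A MOTU is retained iff ``max_s RRA(s) >= min_rra`` *and*
    ``best_identity >= min_identity``. The RRA mass discarded from each
    sample is recorded in the returned table's ``log`` under
    ``"discarded_mass"`` so the un-renormalised profile is recoverable.
    """
    if table.level != "motu":
        raise CurationError("rra_identity_filter expects a MOTU-level table")
    meta.require_covers(table.taxon_ids)
    sub = meta.table.loc[table.taxon_ids]
    max_rra = table.rra.max(axis=0)
    keep = (max_rra >= min_rra) & (sub["best_identity"] >= min_identity)
    removed = list(max_rra.index[~keep])
    kept = table.rra.loc[:, keep.index[keep]]
    sums = kept.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise CurationError(
            f"sample {bad!r} lost all RRA mass in the abundance/identity filter"
        )
    discarded = 1.0 - sums
    rra = kept.div(sums, axis=0)
    logger.info(
        "rra_identity_filter removed %d MOTU(s); max discarded mass %.4f",
        len(removed), float(discarded.max()) if len(discarded) else 0.0,
    )
    return (
        SampleCompositionTable(
            rra=rra, level="motu",
            log={"discarded_mass": discarded},
        ),
        removed,
    )


# ---------------------------------------------------------------------------
# 5. taxonomic aggregation
# ---------------------------------------------------------------------------

def aggregate_taxonomy(
    table: SampleCompositionTable,
    meta: MotuMeta,
    level: Literal["family", "functional_group"],
) -> SampleCompositionTable:
    """Sum RRA within plant families or functional groups.

    Group columns are ordered lexicographically; row sums are conserved.
    """
    if level not in ("family", "functional_group"):
        raise CurationError(f"unknown aggregation level {level!r}")
    meta.require_covers(table.taxon_ids)
    labels = meta.table.loc[table.taxon_ids, level]
    bad = labels.index[labels.isna() | (labels.astype(str) == "")]
    if len(bad):
        raise CurationError(f"missing {level} label for MOTU {bad[0]!r}")
    agg = table.rra.T.groupby(labels).sum().T
    agg = agg[sorted(agg.columns)]
    return SampleCompositionTable(
        rra=agg, level=level, normalised=table.normalised
    )
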