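"""Synthetic Svalbard-reindeer-style studies with known ground truth.

The generator emulates the sampling design of a multi-year rumen survey:
female reindeer culled in October across four valleys over seven years
(~97 animals, unequal cell sizes), each rumen sample amplified in three
PCR replicates, a 39-MOTU plant diet spread over 14 families and eight
functional groups, a 16S rumen microbiome whose composition and
diversity covary with the dietary *Salix* fraction, and autumn body mass
generated from known direct and microbiome-mediated path coefficients.

Everything downstream can therefore be scored against a
:class:`TruthRegistry`: which PCR replicates were planted failures,
which MOTUs are artefacts (and which filter should catch them), the true
per-sample diet compositions, and the structural coefficients behind
body mass.

Randomness is organised as one seed per study with fixed per-stage
sub-streams (design, diet, replicates, outliers, artefacts, microbiome,
host), so adding a stage never perturbs the draws of earlier stages and
identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curation import MotuMeta, ReplicateCountTable
from .diversity import MicrobiomeCountTable

__all__ = [
    "StudyConfig",
    "PathTruth",
    "TruthRegistry",
    "HostMetadata",
    "generate_study",
    "spike_artefacts",
    "default_config",
    "recovery_config",
    "VALLEYS",
    "VALLEY_SALIX_MEAN",
]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Study-design constants (the emulated survey)
# ---------------------------------------------------------------------------

VALLEYS = ("Colesdalen", "Eskerdalen", "Sassendalen", "Semmeldalen")

#: Mean dietary Salix RRA per valley, the dominant spatial contrast.
VALLEY_SALIX_MEAN = {
    "Colesdalen": 0.745,
    "Eskerdalen": 0.245,
    "Sassendalen": 0.468,
    "Semmeldalen": 0.915,
}

GRASS_MEAN = 0.045          # overall mean grass RRA
FIRST_YEAR = 1998

#: Annual max NDVI: mean 0.226, increasing over the span, with the warm
#: first summer having the second-lowest value.
NDVI_BY_YEAR = (0.19, 0.18, 0.21, 0.23, 0.24, 0.26, 0.27)
#: Mean July temperature (deg C): mean 6.93, sd ~0.8, no trend, first
#: year warmest.
JULY_TEMP_BY_YEAR = (8.1, 6.5, 6.0, 7.3, 6.6, 7.6, 6.4)

#: 14 plant families with the number of diet MOTUs each contributes
#: (sums to 39) and a relative base weight for the non-Salix, non-grass
#: remainder of the diet.
FAMILY_PLAN = (
    # (family, functional group, n MOTUs, base weight)
    ("Salicaceae",      "deciduous_shrub", 2, 0.0),   # driven by NDVI
    ("Poaceae",         "grass",           6, 0.0),   # driven by July temp
    ("Cyperaceae",      "sedge",           4, 0.080),
    ("Juncaceae",       "rush",            2, 0.030),
    ("Betulaceae",      "deciduous_shrub", 1, 0.020),
    ("Ericaceae",       "evergreen_shrub", 3, 0.050),
    ("Rosaceae",        "evergreen_shrub", 2, 0.035),
    ("Saxifragaceae",   "small_forb",      5, 0.055),
    ("Polygonaceae",    "large_forb",      2, 0.050),
    ("Brassicaceae",    "large_forb",      3, 0.030),
    ("Caryophyllaceae", "small_forb",      3, 0.025),
    ("Asteraceae",      "large_forb",      2, 0.020),
    ("Ranunculaceae",   "small_forb",      3, 0.025),
    ("Equisetaceae",    "horsetail",       1, 0.020),
)

ARTEFACT_REASONS = ("short", "low_reads", "low_identity", "sub1pct")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathTruth:
    """Structural coefficients behind synthetic body mass.

    ``a_true`` (Salix -> diversity), ``b_true`` (diversity -> mass) and
    ``c_direct_true`` (Salix -> mass) are standardised: they act on
    z-scored Salix and a unit-variance latent diversity, in units of the
    structural mass scale. ``valley_mass_offsets`` and the age terms are
    in kg; ``noise_sd_mass`` is the residual sd on the structural scale.
    """

    a_true: float = 0.3
    b_true: float = -0.25
    c_direct_true: float = 0.4
    lactation_interaction: float = 0.1
    valley_mass_offsets: tuple[float, ...] = (1.0, -2.0, -0.5, 1.5)
    noise_sd_mass: float = 0.9
    age_linear_kg: float = 1.6      # per year above 2, quadratic peak ~8 yr
    age_quadratic_kg: float = -0.13
    mass_base_kg: float = 49.0
    mass_scale_kg: float = 5.0      # kg per structural (sd) unit

    def __post_init__(self) -> None:
        if self.noise_sd_mass <= 0:
            raise SimulationError("noise_sd_mass must be > 0")


@dataclass(frozen=True)
class StudyConfig:
    """Full description of one synthetic study."""

    n_valleys: int = 4
    n_years: int = 7
    n_samples: int = 97
    samples_per_cell: int | None = None   # overrides n_samples when set
    n_replicates: int = 3
    n_motus: int = 39
    n_families: int = 14
    n_functional_groups: int = 8
    read_depth_mean: int = 60_000
    overdispersion: float = 8.0           # family-level Dirichlet concentration
    within_family_concentration: float = 60.0
    outlier_replicate_rate: float = 0.10
    outlier_concentration: float = 0.15  # sparse: failed PCRs are spiky junk
    artefact_motu_count: int = 6
    ndvi_by_year: tuple[float, ...] = NDVI_BY_YEAR
    july_temp_by_year: tuple[float, ...] = JULY_TEMP_BY_YEAR
    ndvi_salix_slope: float = 0.5         # logit-scale slope on z(NDVI)
    temp_grass_slope: float = 0.4         # logit-scale slope on z(July T)
    n_asvs: int = 300
    microbiome_depth_mean: int = 45_000
    microbiome_depth_sd: int = 9_000
    microbiome_concentration: float = 2000.0
    salix_response_scale: float = 0.3   # per-ASV log-fold response to z(Salix)
    lactating_fraction: float = 0.5
    path_truth: PathTruth = field(default_factory=PathTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_valleys", "n_years", "n_samples", "n_replicates",
                     "n_motus", "n_families", "n_functional_groups",
                     "read_depth_mean", "n_asvs", "microbiome_depth_mean"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in ("outlier_replicate_rate", "lactating_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.artefact_motu_count < 0:
            raise SimulationError("artefact_motu_count must be >= 0")
        if len(self.ndvi_by_year) != self.n_years:
            raise SimulationError(
                f"ndvi_by_year has length {len(self.ndvi_by_year)}, "
                f"expected n_years={self.n_years}"
            )
        if len(self.july_temp_by_year) != self.n_years:
            raise SimulationError(
                f"july_temp_by_year has length {len(self.july_temp_by_year)}, "
                f"expected n_years={self.n_years}"
            )
        if any(not -1.0 <= v <= 1.0 for v in self.ndvi_by_year):
            raise SimulationError("ndvi_by_year values must lie in [-1, 1]")
        if len(self.path_truth.valley_mass_offsets) != self.n_valleys:
            raise SimulationError(
                f"valley_mass_offsets has length "
                f"{len(self.path_truth.valley_mass_offsets)}, "
                f"expected n_valleys={self.n_valleys}"
            )


def default_config(seed: int = 0, **overrides) -> StudyConfig:
    """The study-scale default configuration."""
    return replace(StudyConfig(), seed=seed, **overrides) if overrides else \
        StudyConfig(seed=seed)


def recovery_config(
    seed: int = 0,
    a: float = 0.3,
    b: float = -0.25,
    c_direct: float = 0.4,
) -> StudyConfig:
    """Configuration for structural-coefficient recovery simulations.

    Uses n = 96 (4 valleys x 6 years x 4 samples) and strips the
    nuisance mass structure (valley offsets, age curve, lactation
    interaction) so that body mass follows the two-equation path model
    exactly with unit variance; the residual sd is solved from the
    coefficients. Under this configuration the standardised estimates of
    (a, b, c') are unbiased and directly comparable with the truth.
    """
    resid_var = 1.0 - (c_direct ** 2 + b ** 2 + 2 * a * b * c_direct)
    if resid_var <= 0:
        raise SimulationError("path coefficients imply variance > 1")
    truth = PathTruth(
        a_true=a, b_true=b, c_direct_true=c_direct,
        lactation_interaction=0.0,
        valley_mass_offsets=(0.0, 0.0, 0.0, 0.0),
        noise_sd_mass=math.sqrt(resid_var),
        age_linear_kg=0.0, age_quadratic_kg=0.0,
        mass_base_kg=49.0, mass_scale_kg=1.0,
    )
    return StudyConfig(
        n_years=6,
        samples_per_cell=4,
        n_samples=96,
        ndvi_by_year=NDVI_BY_YEAR[:6],
        july_temp_by_year=JULY_TEMP_BY_YEAR[:6],
        outlier_replicate_rate=0.0,
        artefact_motu_count=0,
        salix_response_scale=0.0,   # diversity is the only microbiome channel
        path_truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class HostMetadata:
    """Per-animal covariates and body mass."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "valley", "year", "age", "lactating",
                "body_mass", "ndvi_max", "july_temp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SimulationError(f"HostMetadata missing columns: {missing}")
        if (self.table["age"] < 2).any():
            raise SimulationError("ages below 2 (only adults are sampled)")
        if (self.table["body_mass"] <= 0).any():
            raise SimulationError("non-positive body mass")


@dataclass
class TruthRegistry:
    """Everything a recovery test needs to score the pipeline."""

    true_compositions: pd.DataFrame            # samples x diet MOTUs
    outlier_replicates: set[str] = field(default_factory=set)
    artefact_motus: dict[str, str] = field(default_factory=dict)
    #: per-sample latent variables: salix_true, diversity_latent,
    #: mixing_weight, shannon_expected, mass_structural
    sample_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sums = self.true_compositions.sum(axis=1).to_numpy()
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise SimulationError("true composition rows must sum to 1")
        for reason in self.artefact_motus.values():
            if reason not in ARTEFACT_REASONS:
                raise SimulationError(f"unknown artefact reason {reason!r}")

    def validate_against(
        self, table: ReplicateCountTable, meta: MotuMeta
    ) -> None:
        reps = set(table.replicate_ids)
        dangling = self.outlier_replicates - reps
        if dangling:
            raise SimulationError(
                f"registered outlier replicates missing from table: "
                f"{sorted(dangling)[:5]}"
            )
        motus = set(table.motu_ids)
        dangling = set(self.artefact_motus) - motus
        if dangling:
            raise SimulationError(
                f"registered artefact MOTUs missing from table: "
                f"{sorted(dangling)[:5]}"
            )
        if set(self.artefact_motus) - set(meta.table.index):
            raise SimulationError("artefact MOTUs missing from metadata")

    def merge(self, other: "TruthRegistry") -> "TruthRegistry":
        return TruthRegistry(
            true_compositions=self.true_compositions,
            outlier_replicates=self.outlier_replicates
            | other.outlier_replicates,
            artefact_motus={**self.artefact_motus, **other.artefact_motus},
            sample_truth=self.sample_truth
            if self.sample_truth is not None else other.sample_truth,
        )

    def long_frame(self) -> pd.DataFrame:
        """Tidy (id, category, reason) view of the planted defects."""
        rows = [{"id": r, "category": "outlier_replicate", "reason": "planted"}
                for r in sorted(self.outlier_replicates)]
        rows += [{"id": m, "category": "artefact_motu", "reason": why}
                 for m, why in sorted(self.artefact_motus.items())]
        return pd.DataFrame(rows, columns=["id", "category", "reason"])


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, order-stable sub-streams of the study seed."""
    children = np.random.SeedSequence(seed).spawn(8)
    names = ("design", "diet", "replicates", "outliers", "artefacts",
             "microbiome", "host", "reserved")
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def _motu_catalogue(config: StudyConfig, rng: np.random.Generator):
    """MOTU ids, family/functional labels and base mean weights."""
    if (config.n_motus, config.n_families, config.n_functional_groups) != (
            39, 14, 8):
        # Non-default sizes recycle the family plan, one MOTU at a time.
        fams = list(FAMILY_PLAN)[:config.n_families] or list(FAMILY_PLAN)
        plan = [
            (f, g, 1, max(w, 0.01))
            for f, g, _n, w in (fams[i % len(fams)]
                                for i in range(config.n_motus))
        ]
    else:
        plan = list(FAMILY_PLAN)

    motu_ids, families, groups, within = [], [], [], []
    k = 0
    for fam, group, n_m, _w in plan:
        decay = 0.75 ** np.arange(n_m)
        decay = decay / decay.sum()
        for j in range(n_m):
            k += 1
            motu_ids.append(f"MOTU{k:03d}")
            families.append(fam)
            groups.append(group)
            within.append(decay[j])
    base_family_weight = {fam: w for fam, _g, _n, w in plan}
    return motu_ids, families, groups, np.array(within), base_family_weight


def _allocate_samples(config: StudyConfig, rng: np.random.Generator):
    """Assign samples to valley x year cells (unequal cells allowed)."""
    valleys = [VALLEYS[i % len(VALLEYS)] if i < len(VALLEYS)
               else f"Valley{i + 1}" for i in range(config.n_valleys)]
    cells = [(v, y) for v in valleys for y in range(config.n_years)]
    if config.samples_per_cell is not None:
        counts = {cell: config.samples_per_cell for cell in cells}
    else:
        base = config.n_samples // len(cells)
        extra = config.n_samples - base * len(cells)
        counts = {cell: base for cell in cells}
        order = rng.permutation(len(cells))
        for i in order[:extra]:
            counts[cells[i]] += 1
    assignments = []
    for v, y in cells:
        for _ in range(counts[(v, y)]):
            assignments.append((v, y))
    return valleys, assignments


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_study(config: StudyConfig) -> tuple[
    ReplicateCountTable, MotuMeta, MicrobiomeCountTable, HostMetadata,
    TruthRegistry,
]:
    """Generate one complete synthetic study from ``config``.

    The causal chain is: annual NDVI raises the valley's mean dietary
    *Salix* fraction (logistic-linear on the Dirichlet mean) and July
    temperature raises the grass fraction; each animal's true diet is a
    Dirichlet draw around its valley/year mean; PCR replicates are
    multinomial reads of the true diet, except planted outliers which
    are reads of an unrelated symmetric-Dirichlet composition; a latent
    microbiome diversity equals ``a * z(Salix) + noise`` and sets the
    mixing weight between an even and an uneven community archetype;
    body mass combines valley offsets, a quadratic age curve, the direct
    Salix path ``c'``, a Salix x lactation interaction, the diversity
    path ``b`` and Gaussian noise.
    """
    rngs = _streams(config.seed)
    truth = config.path_truth

    motu_ids, families, groups, within, fam_weight = _motu_catalogue(
        config, rngs["design"]
    )
    motu_fam = pd.Series(families, index=motu_ids)
    valleys, assignments = _allocate_samples(config, rngs["design"])
    n = len(assignments)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    ndvi = np.asarray(config.ndvi_by_year, dtype=float)
    temp = np.asarray(config.july_temp_by_year, dtype=float)
    z_ndvi = _zscore(ndvi) if config.n_years > 1 else np.zeros(1)
    z_temp = _zscore(temp) if config.n_years > 1 else np.zeros(1)

    # --- true diet compositions -------------------------------------------
    # Two-level composition model: family fractions vary strongly between
    # individuals (low-concentration Dirichlet around the valley/year
    # mean) while within-family MOTU ratios are comparatively stable
    # (higher concentration). Diets are hierarchical in exactly this way,
    # and it is what lets every genuine MOTU clear the 1%-RRA rule in at
    # least one sample of a ~97-animal study, as the emulated survey's
    # MOTU set did.
    rng_diet = rngs["diet"]
    fam_order = list(dict.fromkeys(families))
    fam_motu_idx = {
        f: np.array([k for k, g in enumerate(families) if g == f])
        for f in fam_order
    }
    is_salix = motu_fam == "Salicaceae"
    comps = np.empty((n, len(motu_ids)))
    for i, (valley, year) in enumerate(assignments):
        base = VALLEY_SALIX_MEAN.get(valley, 0.5)
        salix_mean = float(_sigmoid(
            _logit(base) + config.ndvi_salix_slope * z_ndvi[year]
        ))
        grass_mean = float(_sigmoid(
            _logit(GRASS_MEAN) + config.temp_grass_slope * z_temp[year]
        ))
        if salix_mean + grass_mean > 0.97:
            scale = 0.97 / (salix_mean + grass_mean)
            salix_mean *= scale
            grass_mean *= scale
        fam_mean = np.empty(len(fam_order))
        for j, f in enumerate(fam_order):
            if f == "Salicaceae":
                fam_mean[j] = salix_mean
            elif f == "Poaceae":
                fam_mean[j] = grass_mean
            else:
                fam_mean[j] = fam_weight[f]
        other = [j for j, f in enumerate(fam_order)
                 if f not in ("Salicaceae", "Poaceae")]
        if other:
            fam_mean[other] *= (1.0 - salix_mean - grass_mean) \
                / fam_mean[other].sum()
        fam_frac = rng_diet.dirichlet(
            np.maximum(config.overdispersion * fam_mean, 1e-3)
        )
        comp = np.zeros(len(motu_ids))
        for j, f in enumerate(fam_order):
            idx = fam_motu_idx[f]
            if len(idx) == 1:
                comp[idx] = fam_frac[j]
            else:
                w = within[idx] / within[idx].sum()
                comp[idx] = fam_frac[j] * rng_diet.dirichlet(
                    config.within_family_concentration * w
                )
        comps[i] = comp
    true_comps = pd.DataFrame(comps, index=sample_ids, columns=motu_ids)
    salix_true = true_comps.loc[:, is_salix.to_numpy()].sum(axis=1).to_numpy()

    # --- PCR replicates (with planted outliers) ---------------------------
    rng_rep = rngs["replicates"]
    rng_out = rngs["outliers"]
    rep_ids: list[str] = []
    rep_to_sample: dict[str, str] = {}
    outliers: set[str] = set()
    cols = []
    for i, sid in enumerate(sample_ids):
        for j in range(config.n_replicates):
            rid = f"{sid}_r{j + 1}"
            rep_ids.append(rid)
            rep_to_sample[rid] = sid
            depth = max(
                1000,
                int(round(rng_rep.normal(config.read_depth_mean,
                                         0.2 * config.read_depth_mean))),
            )
            if rng_out.random() < config.outlier_replicate_rate:
                outliers.add(rid)
                comp = rng_out.dirichlet(
                    np.full(len(motu_ids), config.outlier_concentration)
                )
            else:
                comp = comps[i]
            cols.append(rng_rep.multinomial(depth, comp))
    counts = pd.DataFrame(
        np.column_stack(cols), index=motu_ids, columns=rep_ids
    )
    counts.index.name = "motu_id"
    table = ReplicateCountTable(counts=counts,
                                replicate_to_sample=rep_to_sample)

    # --- MOTU metadata ----------------------------------------------------
    rng_design = rngs["design"]
    meta_frame = pd.DataFrame(
        {
            "seq_length": rng_design.integers(20, 121, size=len(motu_ids)),
            "total_reads": counts.sum(axis=1).to_numpy(),
            "best_identity": np.round(
                rng_design.uniform(0.945, 1.0, size=len(motu_ids)), 3
            ),
            "family": families,
            "functional_group": groups,
        },
        index=pd.Index(motu_ids, name="motu_id"),
    )
    meta = MotuMeta(meta_frame)

    # --- artefact MOTUs ---------------------------------------------------
    registry = TruthRegistry(
        true_compositions=true_comps, outlier_replicates=outliers
    )
    if config.artefact_motu_count > 0:
        table, meta, art_registry = spike_artefacts(table, meta, config)
        registry = registry.merge(art_registry)

    # --- microbiome -------------------------------------------------------
    rng_mb = rngs["microbiome"]
    a = truth.a_true
    z_salix = _zscore(salix_true)
    div_latent = a * z_salix + math.sqrt(max(0.0, 1.0 - a * a)) \
        * rng_mb.standard_normal(n)
    mix_w = np.clip(0.5 + 0.17 * div_latent, 0.02, 0.98)

    k_asv = config.n_asvs
    p_even = rng_mb.dirichlet(np.full(k_asv, 8.0))
    skew = 0.85 ** np.arange(k_asv)
    p_skew = skew[rng_mb.permutation(k_asv)]
    p_skew = p_skew / p_skew.sum()

    # fixed per-ASV log-fold response to dietary Salix: taxa that wax or
    # wane with the Salix fraction, giving the composition a direct
    # covariation with diet beyond the diversity channel
    salix_loading = rng_mb.standard_normal(k_asv)

    asv_ids = [f"ASV{i + 1:04d}" for i in range(k_asv)]
    mb_cols = []
    shannon_expected = np.empty(n)
    for i in range(n):
        p_mix = mix_w[i] * p_even + (1.0 - mix_w[i]) * p_skew
        p_mix = p_mix * np.exp(
            config.salix_response_scale * z_salix[i] * salix_loading
        )
        p_mix = p_mix / p_mix.sum()
        p_i = rng_mb.dirichlet(config.microbiome_concentration * p_mix)
        pos = p_i[p_i > 0]
        shannon_expected[i] = float(-np.sum(pos * np.log(pos)))
        depth = max(
            5000,
            int(round(rng_mb.normal(config.microbiome_depth_mean,
                                    config.microbiome_depth_sd))),
        )
        mb_cols.append(rng_mb.multinomial(depth, p_i))
    mb_counts = pd.DataFrame(
        np.column_stack(mb_cols), index=asv_ids, columns=sample_ids
    )
    mb_counts.index.name = "asv_id"

    phyla = ("Bacteroidota", "Firmicutes", "Proteobacteria",
             "Spirochaetota", "Fibrobacterota", "Verrucomicrobiota")
    phylum = rng_mb.choice(
        phyla, size=k_asv, p=(0.385, 0.428, 0.08, 0.05, 0.03, 0.027)
    )
    fam_idx = rng_mb.integers(1, 139, size=k_asv)
    assigned = rng_mb.random(k_asv) < 0.6
    asv_family = np.where(
        assigned, np.char.add("Family_", fam_idx.astype(str)), ""
    )
    taxonomy = pd.DataFrame(
        {"phylum": phylum, "family": asv_family},
        index=pd.Index(asv_ids, name="asv_id"),
    )
    microbiome = MicrobiomeCountTable(counts=mb_counts, taxonomy=taxonomy)

    # --- host traits ------------------------------------------------------
    rng_host = rngs["host"]
    ages = rng_host.integers(2, 14, size=n)
    lactating = rng_host.random(n) < config.lactating_fraction
    offsets = dict(zip(valleys, truth.valley_mass_offsets))
    structural = (
        truth.c_direct_true * z_salix
        + truth.lactation_interaction * z_salix * lactating
        + truth.b_true * div_latent
        + truth.noise_sd_mass * rng_host.standard_normal(n)
    )
    age_rel = ages - 2.0
    mass = (
        truth.mass_base_kg
        + np.array([offsets[v] for v, _y in assignments])
        + truth.age_linear_kg * age_rel
        + truth.age_quadratic_kg * age_rel ** 2
        + truth.mass_scale_kg * structural
    )
    host = HostMetadata(pd.DataFrame({
        "sample_id": sample_ids,
        "valley": [v for v, _y in assignments],
        "year": [FIRST_YEAR + y for _v, y in assignments],
        "age": ages,
        "lactating": lactating,
        "body_mass": np.round(mass, 2).clip(min=1.0),
        "ndvi_max": [ndvi[y] for _v, y in assignments],
        "july_temp": [temp[y] for _v, y in assignments],
    }))

    registry.sample_truth = pd.DataFrame(
        {
            "salix_true": salix_true,
            "diversity_latent": div_latent,
            "mixing_weight": mix_w,
            "shannon_expected": shannon_expected,
            "mass_structural": structural,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    registry.validate_against(table, meta)
    return table, meta, microbiome, host, registry


# ---------------------------------------------------------------------------
# Artefact spiking
# ---------------------------------------------------------------------------

def spike_artefacts(
    table: ReplicateCountTable,
    meta: MotuMeta,
    config: StudyConfig,
) -> tuple[ReplicateCountTable, MotuMeta, TruthRegistry]:
    """Plant artefact MOTUs, each targeted at one curation rule.

    Cycles through the four reasons: ``short`` (8 bp but abundant),
    ``low_reads`` (<= 10 reads dataset-wide), ``low_identity`` (best
    identity 0.90 but abundant) and ``sub1pct`` (well sequenced but
    never reaching 1% RRA in any sample). Each artefact is registered
    with its reason; the reason names the first pipeline rule that
    should remove it.
    """
    if config.artefact_motu_count == 0:
        return table, meta, TruthRegistry(
            true_compositions=pd.DataFrame(
                index=pd.Index([], name="sample_id"), columns=[]
            )
        )
    rng = _streams(config.seed)["artefacts"]
    depths = table.counts.sum(axis=0).to_numpy()
    n_rep = len(table.replicate_ids)
    new_rows = {}
    new_meta = {}
    artefacts: dict[str, str] = {}
    for i in range(config.artefact_motu_count):
        reason = ARTEFACT_REASONS[i % len(ARTEFACT_REASONS)]
        mid = f"ART{i + 1:02d}"
        row = np.zeros(n_rep, dtype=int)
        if reason == "short":
            present = rng.random(n_rep) < 0.5
            row[present] = np.round(0.02 * depths[present]).astype(int)
            length, ident = 8, 0.99
        elif reason == "low_reads":
            hit = rng.choice(n_rep, size=min(4, n_rep), replace=False)
            row[hit] = rng.integers(1, 3, size=len(hit))  # total <= 8
            length, ident = 64, 0.99
        elif reason == "low_identity":
            present = rng.random(n_rep) < 0.5
            row[present] = np.round(0.02 * depths[present]).astype(int)
            length, ident = 72, 0.90
        else:  # sub1pct
            present = rng.random(n_rep) < 0.8
            row[present] = np.maximum(
                np.round(0.002 * depths[present]).astype(int), 1
            )
            length, ident = 48, 0.99
        new_rows[mid] = row
        new_meta[mid] = {
            "seq_length": length,
            "total_reads": int(row.sum()),
            "best_identity": ident,
            "family": "Salicaceae",       # plausible but irrelevant
            "functional_group": "deciduous_shrub",
        }
        artefacts[mid] = reason
    add = pd.DataFrame.from_dict(
        new_rows, orient="index", columns=table.counts.columns
    )
    add.index.name = table.counts.index.name
    counts = pd.concat([table.counts, add])
    meta_add = pd.DataFrame.from_dict(new_meta, orient="index")
    meta_add.index.name = meta.table.index.name
    meta_frame = pd.concat([meta.table, meta_add])
    registry = TruthRegistry(
        true_compositions=pd.DataFrame(
            index=pd.Index([], name="sample_id"), columns=[]
        ),
        artefact_motus=artefacts,
    )
    return (
        ReplicateCountTable(counts=counts,
                            replicate_to_sample=dict(table.replicate_to_sample)),
        MotuMeta(meta_frame),
        registry,
    )
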