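"""Tab-separated table I/O, run configuration and the pipeline driver.

All tables move as plain TSV with a header row and the id in the first
column; writes are byte-reproducible for identical inputs (fixed float
format, fixed column order). The pipeline stages run in the fixed order
simulate -> curate -> diversity -> associate -> path, and every removal
decision is written once to a plain-text audit log plus a
machine-readable TSV summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, curation, diversity, simulate

logger = logging.getLogger("dietlink.io")

__all__ = [
    "RunConfig",
    "read_count_table",
    "read_replicate_table",
    "read_motu_meta",
    "read_microbiome_table",
    "read_host_metadata",
    "write_table",
    "write_study",
    "run_pipeline",
]

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count/abundance table (first column = id).

    Rejects ragged rows, non-numeric cells and duplicate ids, reporting
    the offending line number (1-based, header = line 1).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header needs an id and >= 1 column")
        n_cols = len(header)
        ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} fields, "
                    f"got {len(parts)}"
                )
            rid = parts[0]
            if rid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate id {rid!r}")
            seen.add(rid)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell "
                                 f"({exc})") from None
            ids.append(rid)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name=header[0]),
                         columns=header[1:])
    return frame


def read_replicate_table(
    counts_path: str | Path, mapping_path: str | Path
) -> curation.ReplicateCountTable:
    counts = read_count_table(counts_path)
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    if list(mapping.columns[:2]) != ["replicate_id", "sample_id"]:
        raise ParseError(
            f"{mapping_path}: expected columns replicate_id, sample_id"
        )
    if mapping["replicate_id"].duplicated().any():
        dup = mapping.loc[mapping["replicate_id"].duplicated(),
                          "replicate_id"].iloc[0]
        raise ParseError(f"{mapping_path}: replicate {dup!r} mapped twice")
    return curation.ReplicateCountTable(
        counts=counts.round().astype(int),
        replicate_to_sample=dict(
            zip(mapping["replicate_id"], mapping["sample_id"])
        ),
    )


def read_motu_meta(path: str | Path) -> curation.MotuMeta:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return curation.MotuMeta(frame)


def read_microbiome_table(
    counts_path: str | Path, taxonomy_path: str | Path | None = None
) -> diversity.MicrobiomeCountTable:
    counts = read_count_table(counts_path).round().astype(int)
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0,
                               keep_default_na=False)
    return diversity.MicrobiomeCountTable(counts=counts, taxonomy=taxonomy)


def read_host_metadata(path: str | Path) -> simulate.HostMetadata:
    frame = pd.read_csv(path, sep="\t")
    if "lactating" in frame.columns:
        frame["lactating"] = frame["lactating"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    return simulate.HostMetadata(frame)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path,
                index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index_label=index_label or frame.index.name or "id",
                 lineterminator="\n")


def write_study(
    out_dir: str | Path,
    table: curation.ReplicateCountTable,
    meta: curation.MotuMeta,
    microbiome: diversity.MicrobiomeCountTable,
    host: simulate.HostMetadata,
    registry: simulate.TruthRegistry,
    config: simulate.StudyConfig,
) -> dict[str, Path]:
    """Write every generated table as TSV; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "diet_counts": out / "diet_replicate_counts.tsv",
        "replicate_map": out / "replicate_to_sample.tsv",
        "motu_meta": out / "motu_metadata.tsv",
        "microbiome_counts": out / "microbiome_counts.tsv",
        "microbiome_taxonomy": out / "microbiome_taxonomy.tsv",
        "host": out / "host_metadata.tsv",
        "truth": out / "truth_registry.tsv",
        "truth_compositions": out / "truth_compositions.tsv",
        "config": out / "study_config.yaml",
    }
    write_table(table.counts, paths["diet_counts"], "motu_id")
    mapping = pd.DataFrame(
        {"replicate_id": table.replicate_ids,
         "sample_id": [table.replicate_to_sample[r]
                       for r in table.replicate_ids]}
    )
    mapping.to_csv(paths["replicate_map"], sep="\t", index=False,
                   lineterminator="\n")
    write_table(meta.table, paths["motu_meta"], "motu_id")
    write_table(microbiome.counts, paths["microbiome_counts"], "asv_id")
    if microbiome.taxonomy is not None:
        write_table(microbiome.taxonomy, paths["microbiome_taxonomy"],
                    "asv_id")
    host.table.to_csv(paths["host"], sep="\t", index=False,
                      float_format=FLOAT_FORMAT, lineterminator="\n")
    registry.long_frame().to_csv(paths["truth"], sep="\t", index=False,
                                 lineterminator="\n")
    write_table(registry.true_compositions, paths["truth_compositions"],
                "sample_id")
    cfg = dataclasses.asdict(config)
    cfg["path_truth"] = dataclasses.asdict(config.path_truth)
    with paths["config"].open("w") as fh:
        yaml.safe_dump(_yaml_clean(cfg), fh, sort_keys=True)
    return paths


def _yaml_clean(obj):
    if isinstance(obj, dict):
        return {k: _yaml_clean(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_yaml_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat pipeline configuration with the published default thresholds."""

    min_len: int = curation.MIN_SEQ_LENGTH
    min_reads: int = curation.MIN_TOTAL_READS
    min_rra: float = curation.MIN_RRA
    min_identity: float = curation.MIN_IDENTITY
    n_perm: int = 10_000
    mantel_method: str = "pearson"
    permanova_terms: tuple[str, ...] = ("valley", "year", "salix")
    seed: int = 0
    out_dir: str = "dietlink_out"
    log_level: str = "INFO"
    simulate: bool = True
    diet_counts: str = ""
    replicate_map: str = ""
    motu_meta: str = ""
    microbiome_counts: str = ""
    microbiome_taxonomy: str = ""
    host: str = ""

    def __post_init__(self) -> None:
        for name in ("min_rra", "min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParseError(f"{name}={v} outside [0, 1]")
        if not self.out_dir:
            raise ParseError("out_dir must be non-empty")
        if not self.simulate:
            for name in ("diet_counts", "replicate_map", "motu_meta",
                         "microbiome_counts", "host"):
                if not getattr(self, name):
                    raise ParseError(
                        f"input path {name!r} required when simulate=false"
                    )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "permanova_terms" in raw and isinstance(raw["permanova_terms"],
                                                   list):
            raw["permanova_terms"] = tuple(raw["permanova_terms"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> curate -> diversity -> associate -> path.

    Writes all stage outputs and an audit log under ``config.out_dir``
    and returns a summary dict (removal counts, headline statistics,
    output paths). Identical config and seed give byte-identical output
    tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: list[str] = []
    summary_rows: list[dict] = []

    def note(stage: str, message: str) -> None:
        audit.append(f"[{stage}] {message}")
        logger.log(getattr(logging, config.log_level.upper(), logging.INFO),
                   "[%s] %s", stage, message)

    # -- simulate / load ---------------------------------------------------
    registry = None
    if config.simulate:
        study_cfg = simulate.default_config(seed=config.seed)
        table, meta, microbiome, host, registry = simulate.generate_study(
            study_cfg
        )
        write_study(out / "study", table, meta, microbiome, host,
                    registry, study_cfg)
        note("simulate",
             f"seed={config.seed} samples={len(host.table)} "
             f"replicates={len(table.replicate_ids)} "
             f"motus={len(table.motu_ids)} "
             f"planted_outliers={len(registry.outlier_replicates)} "
             f"artefact_motus={len(registry.artefact_motus)}")
    else:
        table = read_replicate_table(config.diet_counts, config.replicate_map)
        meta = read_motu_meta(config.motu_meta)
        microbiome = read_microbiome_table(
            config.microbiome_counts, config.microbiome_taxonomy or None
        )
        host = read_host_metadata(config.host)
        note("load", f"loaded {len(table.replicate_ids)} replicates, "
                     f"{len(table.motu_ids)} MOTUs")

    # -- curate ------------------------------------------------------------
    table1, removed_basic = curation.basic_motu_filter(
        table, meta, config.min_len, config.min_reads
    )
    for m in removed_basic:
        summary_rows.append({"stage": "curate", "rule": "basic_filter",
                             "id": m})
    note("curate", f"basic_motu_filter removed {len(removed_basic)} "
                   f"MOTU(s): {removed_basic}")

    result = curation.replicate_outlier_filter(table1)
    for rep, it, dw in result.removed_replicates:
        summary_rows.append({"stage": "curate", "rule": "replicate_outlier",
                             "id": rep, "iteration": it, "dw": dw})
    for s in result.removed_samples:
        summary_rows.append({"stage": "curate", "rule": "single_replicate",
                             "id": s})
    note("curate",
         f"replicate_outlier_filter: {result.iterations} iteration(s), "
         f"removed {len(result.removed_replicates)} replicate(s), "
         f"{len(result.removed_samples)} sample(s); "
         f"thresholds={[round(t, 4) for t in result.thresholds]}")

    composition = curation.collapse_replicates(result.kept)
    composition, removed_rra = curation.rra_identity_filter(
        composition, meta, config.min_rra, config.min_identity
    )
    for m in removed_rra:
        summary_rows.append({"stage": "curate", "rule": "rra_identity",
                             "id": m})
    note("curate", f"rra_identity_filter removed {len(removed_rra)} "
                   f"MOTU(s): {removed_rra}")

    families = curation.aggregate_taxonomy(composition, meta, "family")
    groups = curation.aggregate_taxonomy(composition, meta,
                                         "functional_group")
    write_table(composition.rra, out / "diet_rra_motu.tsv", "sample_id")
    write_table(families.rra, out / "diet_rra_family.tsv", "sample_id")
    write_table(groups.rra, out / "diet_rra_functional_group.tsv",
                "sample_id")

    # -- diversity ---------------------------------------------------------
    diet_div = pd.DataFrame({
        "sample_id": families.sample_ids,
        "metric": "hill_q1_family",
        "value": [diversity.hill_number(families.rra.loc[s], 1.0)
                  for s in families.sample_ids],
    })
    scaled = diversity.common_scale(microbiome)
    mb_div = diversity.sample_diversity(scaled)
    div_tidy = pd.concat([diet_div, mb_div], ignore_index=True)
    div_tidy.to_csv(out / "diversity.tsv", sep="\t", index=False,
                    float_format=FLOAT_FORMAT, lineterminator="\n")
    note("diversity",
         f"common scaling to min depth {int(microbiome.depths().min())}; "
         f"{len(mb_div['sample_id'].unique())} samples")

    # -- associate ---------------------------------------------------------
    shared = [s for s in composition.sample_ids
              if s in set(scaled.sample_ids)]
    diet_d = association.bray_curtis(
        curation.SampleCompositionTable(
            rra=composition.rra.loc[shared], level="motu"
        )
    )
    mb_sub = diversity.MicrobiomeCountTable(
        counts=scaled.counts[shared], taxonomy=scaled.taxonomy
    )
    mb_d = association.bray_curtis(mb_sub)
    mantel = association.mantel_test(
        diet_d, mb_d, method=config.mantel_method,
        n_perm=config.n_perm, seed=config.seed,
    )
    note("associate",
         f"mantel ({config.mantel_method}) r={mantel.statistic:.4f} "
         f"p={mantel.p_value:.4g} n_perm={config.n_perm}")

    host_idx = host.table.set_index("sample_id").loc[shared]
    salix_cols = [
        c for c in composition.rra.columns
        if meta.table.loc[c, "family"] == "Salicaceae"
    ]
    salix = composition.rra.loc[shared, salix_cols].sum(axis=1)
    design = pd.DataFrame({
        "valley": host_idx["valley"].astype(str),
        "year": host_idx["year"].astype(str),
        "salix": salix,
    }, index=shared)
    perma = association.permanova_sequential(
        mb_d, design, terms=list(config.permanova_terms),
        n_perm=config.n_perm, seed=config.seed,
    )
    perma.to_csv(out / "permanova.tsv", sep="\t", index_label="term",
                 float_format=FLOAT_FORMAT, lineterminator="\n")
    note("associate",
         "permanova terms " + "->".join(config.permanova_terms) + "; "
         + "; ".join(
             f"{t}: F={perma.loc[t, 'pseudo_f']:.3f} "
             f"R2={perma.loc[t, 'r2']:.4f} p={perma.loc[t, 'p_value']:.4g}"
             for t in config.permanova_terms))

    # -- path --------------------------------------------------------------
    shannon_vals = (
        mb_div[mb_div["metric"] == "shannon"]
        .set_index("sample_id").loc[shared, "value"]
    )
    chao1_vals = (
        mb_div[mb_div["metric"] == "chao1"]
        .set_index("sample_id").loc[shared, "value"]
    )
    mass = host_idx["body_mass"].to_numpy(dtype=float)
    paths_out = {}
    for metric, vals in (("shannon", shannon_vals), ("chao1", chao1_vals)):
        pm = association.path_decomposition(
            salix.to_numpy(), vals.to_numpy(), mass, metric=metric
        )
        paths_out[metric] = pm
        note("path",
             f"{metric}: a={pm.a:.3f} b={pm.b:.3f} c_direct={pm.c_direct:.3f} "
             f"indirect={pm.indirect:.3f} total={pm.total:.3f} "
             f"direct_exceeds_indirect={pm.direct_exceeds_indirect}")
    path_frame = pd.DataFrame([
        {"metric": m, "a": pm.a, "b": pm.b, "c_direct": pm.c_direct,
         "indirect": pm.indirect, "total": pm.total}
        for m, pm in paths_out.items()
    ])
    path_frame.to_csv(out / "path_model.tsv", sep="\t", index=False,
                      float_format=FLOAT_FORMAT, lineterminator="\n")

    # -- logs --------------------------------------------------------------
    (out / "audit.log").write_text("\n".join(audit) + "\n")
    pd.DataFrame(
        summary_rows, columns=["stage", "rule", "id", "iteration", "dw"]
    ).to_csv(out / "removals.tsv", sep="\t", index=False,
             float_format=FLOAT_FORMAT, lineterminator="\n")

    return {
        "n_samples": len(composition.sample_ids),
        "removed_motus_basic": removed_basic,
        "removed_motus_rra_identity": removed_rra,
        "removed_replicates": [r for r, _, _ in result.removed_replicates],
        "removed_samples": result.removed_samples,
        "mantel": mantel,
        "permanova": perma,
        "paths": paths_out,
        "registry": registry,
        "out_dir": str(out),
    }
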