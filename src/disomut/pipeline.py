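"""Stage orchestration behind the command-line interface.

Each stage reads/writes plain TSV/JSON artifacts in an output directory and
logs the exact parameters applied (including the boundary convention
"ps ≥ 0.5 ⇒ disordered", so the call threshold is auditable from the log).
The ``report`` stage aggregates counts into one JSON whose percentages and
folds are all recomputable from the counts it also contains.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import curation, io, simulate, stats
from .disorder import PropensityPredictor, PropensityScale
from .morf import classify_morf_impact, scan_candidates
from .transitions import (
    D_TO_D,
    D_TO_O,
    DatasetClassification,
    KLASSES,
    O_TO_D,
    O_TO_O,
    classify_dataset,
)

logger = logging.getLogger("disomut")


@dataclass
class RunConfig:
    """All tunables of a pipeline run, loadable from a YAML key-value file."""

    seed: int = 0
    out_dir: str = "disomut_out"
    # predictor
    predictor_window: int = 21
    predictor_steepness: float = 8.0
    predictor_scale_file: str | None = None
    # curation
    cluster_identity: float = 40.0
    nes_identity: float = 95.0
    outlier_method: str = "top_k"
    outlier_k: int = 4
    # statistics
    bootstrap_reps: int = 10_000
    delta_ps_cutoffs: tuple[float, ...] = (0.2,)
    # MoRF scan
    morf_min_len: int = 5
    morf_max_len: int = 25
    morf_min_flank: int = 10
    # simulation
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim_kwargs = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        if sim_kwargs:
            config.sim = dataclasses.replace(config.sim, **sim_kwargs)
        return config

    def predictor(self) -> PropensityPredictor:
        scale = (
            PropensityScale.from_file(self.predictor_scale_file)
            if self.predictor_scale_file
            else PropensityScale.top_idp()
        )
        return PropensityPredictor(
            scale, self.predictor_window, self.predictor_steepness
        )

    def echo(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["call_rule"] = "ps >= 0.5 => disordered; ps < 0.5 => ordered"
        return payload


def _ensure_out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def stage_simulate(config: RunConfig) -> dict:
    """Generate synthetic proteins, mutation datasets and annotations."""
    out = _ensure_out(config)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    synthetic, mutations, annotations = simulate.simulate_all(sim)
    io.write_fasta(synthetic.proteins, out / "proteins.fasta")
    all_mutations = [m for records in mutations.datasets.values() for m in records]
    io.write_mutations(all_mutations, out / "mutations.tsv")
    io.write_annotations(annotations.annotations, out / "annotations.tsv")
    mutations.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    summary = {
        "n_proteins": len(synthetic.proteins),
        "n_mutations": {k: len(v) for k, v in mutations.datasets.items()},
        "n_annotations": len(annotations.annotations),
        "n_unsatisfiable_flips": mutations.n_unsatisfiable,
        "parameters": config.echo(),
    }
    _write_json(out / "simulate.json", summary)
    logger.info("simulate: %d proteins, %s mutations", len(synthetic.proteins),
                summary["n_mutations"])
    return summary


def stage_predict(config: RunConfig, fasta: str | Path) -> dict:
    """Score every protein with the built-in predictor; write the track TSV."""
    out = _ensure_out(config)
    predictor = config.predictor()
    proteins = io.read_fasta(fasta)
    profiles = [predictor.predict(p) for p in proteins]
    io.write_score_track(profiles, out / "profiles.tsv")
    from .disorder import disorder_content

    summary = {
        "predictor": predictor.name,
        "n_proteins": len(proteins),
        "mean_disorder_content": float(
            sum(disorder_content(p) for p in profiles) / len(profiles)
        ),
        "parameters": config.echo(),
    }
    _write_json(out / "predict.json", summary)
    return summary


def stage_classify(
    config: RunConfig, fasta: str | Path, mutations_tsv: str | Path
) -> DatasetClassification:
    """Transition-classify all mutations; write per-mutation TSV + counts."""
    out = _ensure_out(config)
    predictor = config.predictor()
    proteins = io.read_fasta(fasta)
    report = io.read_mutations(mutations_tsv, proteins)
    if report.n_rejected:
        logger.warning(
            "classify: rejected %d mutation rows with wild-type mismatch",
            report.n_rejected,
        )
    classification = classify_dataset(report.records, proteins, predictor)
    classification.to_frame().to_csv(out / "transitions.tsv", sep="\t", index=False)
    counts = classification.counts()
    payload = {
        "counts": {ds: {k: int(row[k]) for k in KLASSES} for ds, row in counts.iterrows()},
        "n_rejected_wt_mismatch": report.n_rejected,
        "parameters": config.echo(),
    }
    _write_json(out / "classify.json", payload)
    return classification


def stage_morf(
    config: RunConfig, fasta: str | Path, mutations_tsv: str | Path | None = None
) -> dict:
    """Stage-1 MoRF scan for every protein; impact calls if mutations given."""
    out = _ensure_out(config)
    predictor = config.predictor()
    proteins = io.read_fasta(fasta)
    rows = []
    profiles = {}
    morfs = {}
    for protein in proteins:
        profile = predictor.predict(protein)
        profiles[protein.id] = profile
        regions = scan_candidates(
            profile, config.morf_min_len, config.morf_max_len, config.morf_min_flank
        )
        morfs[protein.id] = regions
        for r in regions:
            rows.append(
                (r.protein_id, r.start, r.end, r.left_flank_len, r.right_flank_len)
            )
    io._write_tsv(
        out / "morf_regions.tsv",
        ("protein_id", "start", "end", "left_flank_len", "right_flank_len"),
        rows,
    )
    summary = {"n_regions": len(rows), "parameters": config.echo()}
    if mutations_tsv is not None:
        by_id = {p.id: p for p in proteins}
        report = io.read_mutations(mutations_tsv, by_id.values())
        impact_rows = []
        impact_counts: dict[str, int] = {}
        for m in report.records:
            mut_profile = predictor.predict_mutant(by_id[m.protein_id], m)
            mut_regions = scan_candidates(
                mut_profile,
                config.morf_min_len,
                config.morf_max_len,
                config.morf_min_flank,
            )
            impact = classify_morf_impact(
                morfs[m.protein_id], mut_regions, m.position
            )
            impact_counts[impact] = impact_counts.get(impact, 0) + 1
            impact_rows.append(
                (m.protein_id, m.position, m.wt_aa, m.mut_aa, m.dataset, impact)
            )
        io._write_tsv(
            out / "morf_impact.tsv",
            ("protein_id", "position", "wt_aa", "mut_aa", "dataset", "impact"),
            impact_rows,
        )
        summary["impact_counts"] = impact_counts
    _write_json(out / "morf.json", summary)
    return summary


def stage_curate(
    config: RunConfig, fasta: str | Path, mutations_tsv: str | Path
) -> dict:
    """Redundancy-cluster proteins, flag outliers, write filtered mutations."""
    out = _ensure_out(config)
    proteins = io.read_fasta(fasta)
    report = io.read_mutations(mutations_tsv, proteins)
    clusters = curation.cluster_redundant(
        proteins, config.cluster_identity, seed=config.seed
    )
    kept, n_discarded = clusters.filter_mutations(report.records)
    outliers = curation.flag_outliers(kept, config.outlier_method, config.outlier_k)
    final = outliers.filter_mutations(kept)
    io.write_mutations(final, out / "mutations_curated.tsv")
    io._write_tsv(
        out / "clusters.tsv",
        ("protein_id", "cluster", "representative"),
        (
            (pid, cluster, clusters.representatives[cluster])
            for pid, cluster in sorted(clusters.cluster_of.items())
        ),
    )
    summary = {
        "n_clusters": len(clusters.representatives),
        "n_discarded_redundant": n_discarded,
        "outliers": outliers.flagged,
        "outlier_removed_fraction": outliers.removed_fraction,
        "n_mutations_final": len(final),
        "parameters": config.echo(),
    }
    _write_json(out / "curate.json", summary)
    return summary


def stage_nes(
    config: RunConfig,
    fasta: str | Path,
    alignment_files: Sequence[str | Path],
    disease_tsv: str | Path | None = None,
) -> dict:
    """Build the NES control from aligned-FASTA ortholog files.

    Each aligned FASTA must contain the human protein first (its id must
    match a record in ``fasta``) followed by ortholog rows.
    """
    out = _ensure_out(config)
    proteins = {p.id: p for p in io.read_fasta(fasta)}
    disease = (
        io.read_mutations(disease_tsv, proteins.values()).records
        if disease_tsv
        else []
    )
    all_records = []
    for path in alignment_files:
        aligned = io.read_aligned_fasta(path)
        ids = list(aligned)
        human_id = ids[0]
        if human_id not in proteins:
            raise io.FormatError(f"{path}: human id {human_id!r} not in FASTA")
        pairs = {}
        for oid in ids[1:]:
            pair_h, pair_o = _project_pair(aligned[human_id], aligned[oid])
            pairs[oid] = (pair_h, pair_o)
        all_records.extend(
            curation.extract_nes(
                proteins[human_id],
                ortholog_alignments=pairs,
                min_identity=config.nes_identity,
                disease_mutations=disease,
            )
        )
    io.write_mutations(all_records, out / "nes_mutations.tsv")
    summary = {"n_nes": len(all_records), "parameters": config.echo()}
    _write_json(out / "nes.json", summary)
    return summary


def _project_pair(aligned_a: str, aligned_b: str) -> tuple[str, str]:
    """Drop columns where both rows are gapped (pairwise projection of an MSA)."""
    kept = [(x, y) for x, y in zip(aligned_a, aligned_b) if not (x == "-" and y == "-")]
    return "".join(x for x, _ in kept), "".join(y for _, y in kept)


def stage_enrich(
    config: RunConfig,
    fasta: str | Path,
    mutations_tsv: str | Path,
    annotations_tsv: str | Path,
    dataset: str | None = None,
) -> list[stats.EnrichmentResult]:
    """Feature enrichment of IDR vs OR mutations (within one dataset).

    Features are normalized (qualifier drop, prefix strip, rare-feature
    filter against the ``DM`` dataset when present), then each label is
    tested with a 2×2 Fisher comparison of mutations at disordered vs
    ordered wild-type sites.
    """
    out = _ensure_out(config)
    predictor = config.predictor()
    proteins = io.read_fasta(fasta)
    report = io.read_mutations(mutations_tsv, proteins)
    annotations = io.read_annotations(annotations_tsv)
    classification = classify_dataset(report.records, proteins, predictor)
    calls = classification.calls
    dataset_names = sorted({c.mutation.dataset for c in calls})
    if dataset is None:
        dataset = "DM" if "DM" in dataset_names else dataset_names[0]
    rare_filter_dataset = "DM" if "DM" in dataset_names else dataset
    dm_mutations = [
        c.mutation for c in calls if c.mutation.dataset == rare_filter_dataset
    ]
    features = stats.normalize_ft(annotations, dm_mutations)
    idr = [c.mutation for c in calls if c.mutation.dataset == dataset and c.in_idr]
    orm = [c.mutation for c in calls if c.mutation.dataset == dataset and not c.in_idr]
    results = stats.ft_enrichment(features, idr, orm, level=1, labels=("IDR", "OR"))
    io._write_tsv(
        out / "enrichment.tsv",
        ("feature", "a", "b", "c", "d", "fold", "fold_se", "p_raw", "p_adjusted"),
        (
            (
                r.label,
                r.table[0][0],
                r.table[0][1],
                r.table[1][0],
                r.table[1][1],
                f"{r.fold:.4g}",
                f"{r.fold_se:.4g}",
                f"{r.p_raw:.4g}",
                f"{r.p_adjusted:.4g}",
            )
            for r in results
        ),
    )
    return results


def build_report(
    classification: DatasetClassification, reference: str = "DM"
) -> dict:
    """Aggregate transition counts into a table-style JSON report.

    Every percentage and fold in the report is recomputable from the counts
    present in the same JSON (self-consistency is asserted in the tests).
    """
    counts = classification.counts()
    report: dict = {"datasets": {}, "comparisons": {}}
    for ds, row in counts.iterrows():
        n_idr = int(row[D_TO_O] + row[D_TO_D])
        n_or = int(row[O_TO_D] + row[O_TO_O])
        n = n_idr + n_or
        report["datasets"][ds] = {
            "n": n,
            "idr": {"n": n_idr, "pct": 100.0 * n_idr / n if n else 0.0},
            "or": {"n": n_or, "pct": 100.0 * n_or / n if n else 0.0},
            "transitions": {k: int(row[k]) for k in KLASSES},
            "do_share_of_idr_pct": 100.0 * row[D_TO_O] / n_idr if n_idr else 0.0,
            "od_share_of_or_pct": 100.0 * row[O_TO_D] / n_or if n_or else 0.0,
        }
    controls = [ds for ds in counts.index if ds != reference]
    if reference in counts.index:
        for control in controls:
            entry = {}
            for region, table_fn in (("idr", classification.idr_table),
                                     ("or", classification.or_table)):
                table = table_fn(reference, control)
                p = stats.fisher_exact_2x2(table)
                try:
                    fold, se = stats.fold_difference(table)
                except ValueError:
                    fold, se = float("nan"), float("nan")
                entry[region] = {
                    "table": table.tolist(),
                    "fisher_p": p,
                    "fold": fold,
                    "fold_se": se,
                }
            report["comparisons"][f"{reference}_vs_{control}"] = entry
    return report


def stage_report(
    config: RunConfig, fasta: str | Path, mutations_tsv: str | Path
) -> dict:
    out = _ensure_out(config)
    classification = stage_classify(config, fasta, mutations_tsv)
    report = build_report(classification)
    report["parameters"] = config.echo()
    _write_json(out / "report.json", report)
    return report


def run_all(config: RunConfig) -> dict:
    """simulate → predict → classify → morf → enrich → report on one seed."""
    out = _ensure_out(config)
    stage_simulate(config)
    fasta = out / "proteins.fasta"
    mutations = out / "mutations.tsv"
    stage_predict(config, fasta)
    stage_morf(config, fasta)
    stage_enrich(config, fasta, mutations, out / "annotations.tsv")
    return stage_report(config, fasta, mutations)
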