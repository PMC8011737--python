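"""The two end-to-end workflows and project persistence.

``run_annotate`` goes from a genome FASTA to a curated EMBL file: ORF
prediction, queue-driven search + selection + resize, the three pre-curation
passes, RNA annotation, and export. ``run_reannotate`` starts instead from an
existing EMBL/GenBank annotation: the imported CDS coordinates are trusted,
prediction is skipped, and each feature is searched, selected, resized and
filtered the same way.

A project directory holds the config snapshot, the per-ORF hit lists (JSON),
the removed-feature log and the final EMBL, so a run is inspectable and
re-loadable without re-searching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from .engine import AnnotatedFeature, AnnotationState, process_queue
from .errors import FormatError
from .genetics import (
    DEFAULT_START_CODONS,
    FULL_VAL_LEU_START_CODONS,
    GeneticCode,
)
from .orfs import Orf, find_orfs
from .precuration import low_accuracy_filter, overlap_filter, reduce_intergenic
from .rna import annotate_rna, read_rna_refs
from .scoring import Thresholds
from .search import FixtureSearchProvider, LocalSearchProvider
from .seqio import (
    FeatureKind,
    FeatureRecord,
    GenomeRecord,
    read_fasta,
    read_flatfile,
    read_protein_db,
    write_embl,
)

DEFAULT_CONFIG: dict = {
    "genetic_code_table": 11,
    "start_codons": "default",  # default | full_val_leu | explicit list
    "search": {
        "provider": "local",
        "max_hits": 10,
        "min_identity": 0.3,
        "matrix": "BLOSUM62",
        "gap_open": 11,
        "gap_extend": 1,
    },
    "thresholds": {},  # overrides of Thresholds fields
    "filters": {"low_accuracy": True, "overlaps": True, "intergenic": True},
    "rna": {"min_identity": 0.9, "min_cov": 0.9},
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config: Union[None, dict, str, Path]) -> dict:
    if config is None:
        return dict(DEFAULT_CONFIG)
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, config)


def _build_code(cfg: dict) -> GeneticCode:
    starts = cfg["start_codons"]
    if starts == "default":
        start_set = DEFAULT_START_CODONS
    elif starts == "full_val_leu":
        start_set = FULL_VAL_LEU_START_CODONS
    else:
        start_set = frozenset(str(c).upper() for c in starts)
    return GeneticCode.from_table(cfg["genetic_code_table"], start_set)


def _build_provider(cfg: dict, db):
    scfg = cfg["search"]
    if scfg["provider"] == "local":
        return LocalSearchProvider(
            db,
            matrix=scfg["matrix"],
            gap_open=scfg["gap_open"],
            gap_extend=scfg["gap_extend"],
            min_identity=scfg["min_identity"],
        )
    if scfg["provider"] == "fixture":
        return FixtureSearchProvider(scfg.get("table", {}))
    raise FormatError(f"unknown search provider {scfg['provider']!r}")


def _apply_filters(
    confirmed: list[AnnotatedFeature],
    thresholds: Thresholds,
    genomes: dict,
    code: GeneticCode,
    cfg: dict,
) -> tuple[list[AnnotatedFeature], list[AnnotatedFeature]]:
    removed: list[AnnotatedFeature] = []
    fcfg = cfg["filters"]
    kept = list(confirmed)
    if fcfg.get("low_accuracy", True):
        kept, dropped = low_accuracy_filter(kept, thresholds.low_accuracy_cutoff)
        removed += dropped
    if fcfg.get("overlaps", True):
        kept, dropped = overlap_filter(kept, thresholds, genomes, code)
        removed += dropped
    if fcfg.get("intergenic", True):
        kept = reduce_intergenic(kept, thresholds, genomes, code)
    return kept, removed


def _persist(
    out_dir: Path,
    cfg: dict,
    genomes: list[GenomeRecord],
    kept: list[AnnotatedFeature],
    removed_features: list,
    rna_features: list[FeatureRecord],
    state: AnnotationState,
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    hits_dir = out_dir / "hits"
    hits_dir.mkdir(exist_ok=True)
    for feat in kept:
        name = f"{feat.orf.contig_id}_{feat.orf.start}_{feat.orf.end}_{'fwd' if feat.orf.strand == '+' else 'rev'}.json"
        payload = {
            "orf": {
                "contig": feat.orf.contig_id,
                "start": feat.orf.start,
                "end": feat.orf.end,
                "strand": feat.orf.strand,
            },
            "selected": asdict(feat.entry) if feat.entry else None,
            "candidates": [asdict(c) for c in feat.candidates],
            "flags": feat.flags,
        }
        with open(hits_dir / name, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    log = {
        "removed_in_engine": [
            {"start": o.start, "end": o.end, "strand": o.strand,
             "reason": o.qualifiers.get("removed_reason", "")}
            for o in state.removed
        ],
        "removed_in_filters": [
            {"start": f.orf.start, "end": f.orf.end, "strand": f.orf.strand,
             "reason": f.orf.qualifiers.get("removed_reason", "low_accuracy")}
            for f in removed_features
        ],
        "unresolved": [
            {"start": o.start, "end": o.end, "strand": o.strand}
            for o in state.unresolved
        ],
    }
    with open(out_dir / "log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    embl_path = out_dir / "annotation.embl"
    write_embl(genomes, list(kept) + list(rna_features), embl_path)
    summary = report_from_features(kept, rna_features)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run_annotate(
    genome_path: Union[str, Path],
    db_path: Union[str, Path],
    out_dir: Union[str, Path],
    config: Union[None, dict, str, Path] = None,
    rna_refs_path: Union[str, Path, None] = None,
) -> dict:
    """Annotate a genome FASTA against a protein database; returns the report."""
    cfg = load_config(config)
    code = _build_code(cfg)
    thresholds = Thresholds(**cfg["thresholds"])
    genomes = read_fasta(genome_path)
    db = read_protein_db(db_path)
    provider = _build_provider(cfg, db)
    genome_map = {g.id: g for g in genomes}

    orfs: list[Orf] = []
    for g in genomes:
        orfs += find_orfs(g, code, thresholds.min_orf_nt)
    state = AnnotationState.from_orfs(
        orfs, provider, thresholds=thresholds, max_hits=cfg["search"]["max_hits"]
    )
    process_queue(state, genome_map, code)
    kept, removed = _apply_filters(state.confirmed, thresholds, genome_map, code, cfg)

    rna_features: list[FeatureRecord] = []
    if rna_refs_path is not None:
        refs = read_rna_refs(rna_refs_path)
        for g in genomes:
            rna_features += annotate_rna(
                g, refs, cfg["rna"]["min_identity"], cfg["rna"]["min_cov"]
            )
    return _persist(Path(out_dir), cfg, genomes, kept, removed, rna_features, state)


def run_reannotate(
    flatfile_path: Union[str, Path],
    db_path: Union[str, Path],
    out_dir: Union[str, Path],
    config: Union[None, dict, str, Path] = None,
    dialect: Optional[str] = None,
) -> dict:
    """Re-annotate an existing EMBL/GenBank file: keep its coordinates, redo
    search, selection, resize and filters."""
    cfg = load_config(config)
    code = _build_code(cfg)
    thresholds = Thresholds(**cfg["thresholds"])
    if dialect is None:
        suffix = str(flatfile_path).lower()
        dialect = "genbank" if suffix.endswith((".gb", ".gbk", ".genbank")) else "embl"
    genomes, features = read_flatfile(flatfile_path, dialect)
    db = read_protein_db(db_path)
    provider = _build_provider(cfg, db)
    genome_map = {g.id: g for g in genomes}

    orfs: list[Orf] = []
    passthrough_rna: list[FeatureRecord] = []
    for f in features:
        if f.kind is not FeatureKind.CDS:
            passthrough_rna.append(f)
            continue
        if f.length % 3 != 0:
            warnings.warn(
                f"skipping CDS [{f.start},{f.end}) on {f.contig_id}: "
                "length not divisible by 3",
                stacklevel=2,
            )
            continue
        frame = (
            f.start % 3 if f.strand == "+" else (len(genome_map[f.contig_id]) - f.end) % 3
        )
        orfs.append(Orf(f.contig_id, f.start, f.end, f.strand, frame))
    state = AnnotationState.from_orfs(
        orfs,
        provider,
        thresholds=thresholds,
        max_hits=cfg["search"]["max_hits"],
        retain_no_hit=True,
    )
    process_queue(state, genome_map, code)
    kept, removed = _apply_filters(state.confirmed, thresholds, genome_map, code, cfg)
    return _persist(Path(out_dir), cfg, genomes, kept, removed, passthrough_rna, state)


def report_from_features(
    kept: list[AnnotatedFeature], rna_features: list[FeatureRecord]
) -> dict:
    """Summary counts and mean accuracy (percent, two decimals)."""
    cds = [f for f in kept]
    accs = [f.accuracy for f in cds]
    return {
        "n_cds": len(cds),
        "n_trna": sum(1 for f in rna_features if f.kind is FeatureKind.tRNA),
        "n_rrna": sum(1 for f in rna_features if f.kind is FeatureKind.rRNA),
        "n_gene_acronym": sum(1 for f in cds if f.has_gene),
        "n_hypothetical": sum(1 for f in cds if f.is_hypothetical),
        "mean_accuracy_pct": round(100 * sum(accs) / len(accs), 2) if accs else 0.0,
    }


def load_project(project_dir: Union[str, Path]):
    """Rebuild (genomes, features, config) from a saved project directory."""
    from .scoring import HitEntry

    project_dir = Path(project_dir)
    cfg = load_config(project_dir / "config.yaml")
    genomes, _ = read_flatfile(project_dir / "annotation.embl", "embl")
    features: list[AnnotatedFeature] = []
    for path in sorted((project_dir / "hits").glob("*.json")):
        with open(path) as fh:
            payload = json.load(fh)
        o = payload["orf"]
        orf = Orf(
            o["contig"],
            o["start"],
            o["end"],
            o["strand"],
            o["start"] % 3 if o["strand"] == "+" else 0,
            status="confirmed",
        )
        entry = HitEntry(**payload["selected"]) if payload["selected"] else None
        cands = [HitEntry(**c) for c in payload["candidates"]]
        features.append(AnnotatedFeature(orf, entry, cands, dict(payload["flags"])))
    return genomes, features, cfg


def refilter(
    project_dir: Union[str, Path],
    low_accuracy: Optional[float] = None,
    overlaps: bool = False,
    intergenic: bool = False,
) -> dict:
    """Re-apply a subset of pre-curation passes to a saved project in place."""
    project_dir = Path(project_dir)
    genomes, features, cfg = load_project(project_dir)
    code = _build_code(cfg)
    thresholds = Thresholds(**cfg["thresholds"])
    genome_map = {g.id: g for g in genomes}
    removed: list[AnnotatedFeature] = []
    if low_accuracy is not None:
        features, dropped = low_accuracy_filter(features, low_accuracy)
        removed += dropped
    if overlaps:
        features, dropped = overlap_filter(features, thresholds, genome_map, code)
        removed += dropped
    if intergenic:
        features = reduce_intergenic(features, thresholds, genome_map, code)
    _, rna_feats = read_flatfile(project_dir / "annotation.embl", "embl")
    rna_only = [f for f in rna_feats if f.kind is not FeatureKind.CDS]
    state = AnnotationState(thresholds=thresholds)
    return _persist(project_dir, cfg, genomes, features, removed, rna_only, state)


def report(project_dir: Union[str, Path]) -> dict:
    """Load the summary of a completed project directory."""
    path = Path(project_dir) / "report.json"
    if not path.exists():
        raise FormatError(f"{project_dir} is not a completed project (no report.json)")
    with open(path) as fh:
        return json.load(fh)
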