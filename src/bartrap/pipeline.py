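"""End-to-end screen deconvolution: count → group → link → map → filter →
annotate → test → genes, with a run manifest and per-stage logging."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .barcodes import (
    DEFAULT_FLANK_5P,
    DEFAULT_FLANK_MISMATCH,
    DEFAULT_MAX_EDIT,
    FlankSpec,
    build_count_matrix,
    extract_barcodes,
    group_barcodes,
)
from .differential import DEFAULT_PRIOR_COUNT, run_screen_test
from .genes import (
    DEFAULT_FC_CUTOFF,
    DEFAULT_MIN_INSERTIONS,
    DEFAULT_P_CUTOFF,
    call_gene_hits,
    join_results,
)
from .io import read_sample_sheet, sha256_of, write_tsv
from .sites import (
    DEFAULT_JUNCTION_START,
    DEFAULT_MERGE_WINDOW,
    DEFAULT_MIN_GENOMIC,
    DEFAULT_MIN_LINK_READS,
    DEFAULT_MIN_RPM,
    annotate_sites,
    call_sites,
    filter_and_merge_sites,
    link_barcodes_to_sites,
    load_gene_annotations,
    map_junctions,
    parse_invpcr_pairs,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys in a config file are rejected
    and every default equals its module's documented value."""

    sample_sheet: str = ""
    reference: str = ""
    gtf: str = ""
    invpcr: dict = field(default_factory=dict)  # library -> [barcode_fq, junction_fq]
    out_dir: str = "bartrap_out"
    seed: int = 0
    # barcode extraction / grouping
    flank_5p: str = DEFAULT_FLANK_5P
    flank_3p: str = ""
    flank_mismatch: int = DEFAULT_FLANK_MISMATCH
    max_edit: int = DEFAULT_MAX_EDIT
    # inverse PCR parsing / mapping
    junction_start: str = DEFAULT_JUNCTION_START
    start_mismatch: int = 1
    min_genomic: int = DEFAULT_MIN_GENOMIC
    mapping_mode: str = "builtin"
    sam_paths: dict = field(default_factory=dict)  # library -> SAM path
    # site filtering / linking
    min_rpm: float = DEFAULT_MIN_RPM
    merge_window: int = DEFAULT_MERGE_WINDOW
    min_link_reads: int = DEFAULT_MIN_LINK_READS
    # differential testing
    condition_drug: str = "drug"
    condition_vehicle: str = "dmso"
    dispersion: float | None = None
    prior: float = DEFAULT_PRIOR_COUNT
    # gene aggregation
    fc_cutoff: float = DEFAULT_FC_CUTOFF
    p_cutoff: float = DEFAULT_P_CUTOFF
    min_insertions: int = DEFAULT_MIN_INSERTIONS

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not str(path) or not p.exists():
        raise FileNotFoundError(f"{what} not found: {path!r}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full deconvolution and write per-stage TSVs plus a run
    manifest.  All inputs are validated before any compute; any stage error
    aborts with the stage name attached."""
    sheet_path = _require(config.sample_sheet, "sample sheet")
    gtf_path = _require(config.gtf, "GTF gene models")
    if config.mapping_mode == "builtin":
        ref_path = _require(config.reference, "reference FASTA")
    else:
        ref_path = Path(config.reference) if config.reference else None
    for library, pair in config.invpcr.items():
        for p in pair:
            _require(p, f"inverse-PCR FASTQ for library {library}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flank = FlankSpec(config.flank_5p, config.flank_3p)
    manifest: dict = {"version": __version__, "parameters": asdict(config), "inputs": {}}
    for p in [sheet_path, gtf_path] + ([ref_path] if ref_path else []):
        manifest["inputs"][str(p)] = sha256_of(p)

    stage = "count"
    try:
        sheet = read_sample_sheet(sheet_path)
        raw_counts, discard_rows = [], []
        for row in sheet.itertuples(index=False):
            counts, discards = extract_barcodes(
                row.fastq_path, flank, sample=row.sample, max_mismatch=config.flank_mismatch
            )
            raw_counts.extend(counts)
            for reason, n in discards.items():
                discard_rows.append({"sample": row.sample, "reason": reason, "reads": n})
        write_tsv(pd.DataFrame(discard_rows), out / "discards.tsv")
        log.info("count: %d raw barcode records", len(raw_counts))

        stage = "group"
        groups = group_barcodes(raw_counts, max_edit=config.max_edit)
        canonical_map = {m: g.canonical for g in groups for m in g.members}
        matrix = build_count_matrix(groups, sheet)
        write_tsv(matrix.reset_index(), out / "counts.tsv")
        log.info("group: %d barcode groups", len(groups))

        stage = "link"
        all_pairs = []
        for library, (bc_fq, jn_fq) in sorted(config.invpcr.items()):
            pairs, pair_discards = parse_invpcr_pairs(
                bc_fq,
                jn_fq,
                expected_start=config.junction_start,
                flank=flank,
                library=library,
                start_mismatch=config.start_mismatch,
                flank_mismatch=config.flank_mismatch,
                min_genomic=config.min_genomic,
            )
            log.info("link[%s]: %d pairs kept, discards %s", library, len(pairs), pair_discards)
            all_pairs.append((library, pairs))

        stage = "map"
        mapped_frames = []
        for library, pairs in all_pairs:
            mapped, tally = map_junctions(
                pairs,
                reference=str(ref_path) if ref_path else None,
                mode=config.mapping_mode,
                sam_path=config.sam_paths.get(library),
            )
            log.info("map[%s]: %d mapped, %s", library, len(mapped), tally)
            mapped_frames.append(mapped)
        mapped = pd.concat(mapped_frames, ignore_index=True) if mapped_frames else pd.DataFrame()

        stage = "filter"
        sites = call_sites(mapped)
        merged, site_map = filter_and_merge_sites(
            sites, min_rpm=config.min_rpm, window=config.merge_window, return_map=True
        )
        log.info("filter: %d sites -> %d after rpm>=%g filter and %d bp merge",
                 len(sites), len(merged), config.min_rpm, config.merge_window)

        stage = "annotate"
        genes_df = load_gene_annotations(gtf_path)
        annotated_sites = annotate_sites(merged, genes_df)
        links = link_barcodes_to_sites(
            mapped, site_map, canonical_map=canonical_map, min_link_reads=config.min_link_reads
        )
        mapping_table = links.merge(
            annotated_sites[
                ["library", "end_label", "chrom", "strand", "pos", "rpm", "gene_id", "gene_name"]
            ],
            on=["library", "end_label", "chrom", "strand", "pos"],
            how="left",
        )[
            ["barcode", "chrom", "pos", "strand", "end_label", "library",
             "reads", "rpm", "gene_id", "gene_name", "ambiguous"]
        ]
        write_tsv(mapping_table, out / "mapping.tsv")

        stage = "test"
        results = run_screen_test(
            matrix,
            sheet,
            condition_a=config.condition_drug,
            condition_b=config.condition_vehicle,
            dispersion=config.dispersion,
            prior=config.prior,
        )
        write_tsv(results, out / "results.tsv")
        log.info("test: %d barcodes tested, dispersion %.4g",
                 len(results), results.attrs["dispersion"])

        stage = "genes"
        annotated, orphans = join_results(results, links, annotated_sites)
        gene_hits = call_gene_hits(
            annotated,
            fc_cutoff=config.fc_cutoff,
            p_cutoff=config.p_cutoff,
            min_insertions=config.min_insertions,
        )
        write_tsv(annotated, out / "insertions.tsv")
        write_tsv(orphans, out / "orphans.tsv")
        write_tsv(gene_hits, out / "genes.tsv")
        log.info("genes: %d gene hits", len(gene_hits))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "matrix": matrix,
        "links": links,
        "mapping": mapping_table,
        "results": results,
        "annotated": annotated,
        "gene_hits": gene_hits,
        "out_dir": out,
    }
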