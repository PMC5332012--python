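"""Linking barcodes to transposon integration sites via inverse PCR.

Inverse-PCR amplicons carry the random barcode at one end and the
transposon–genome junction at the other; paired-end sequencing of those
amplicons lets each barcode be tied to the genomic position its transposon
disrupted.  This module parses the read pairs, maps the junction sequences
(with a built-in exact-seed aligner or by importing external SAM
alignments), applies the site-level filters — discard sites below 10
reads/million within their mapping run, combine same-library sites within
5 bp — and annotates surviving sites with overlapping gene bodies.

Coordinates are 1-based throughout; a site's ``pos`` is the first genomic
base flanking the transposon end (for minus-strand junctions, the rightmost
base of the aligned window).
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .barcodes import FlankSpec, hamming
from .io import read_fasta, read_fastq

log = logging.getLogger(__name__)

#: Transposon terminal sequence expected to open every junction-side read
#: (synthetic inverse-PCR construct; real data supplies its own).
DEFAULT_JUNCTION_START = "TTAACCCTAGAAAGATA"
DEFAULT_MIN_GENOMIC = 20
DEFAULT_MIN_RPM = 10.0
DEFAULT_MERGE_WINDOW = 5
DEFAULT_MIN_LINK_READS = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_KEY = ["library", "end_label", "chrom", "strand", "pos"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class InvPcrPair:
    """One inverse-PCR read pair reduced to barcode + trimmed junction."""

    pair_id: int
    barcode: str
    junction_seq: str
    library: str
    end_label: str


def _strip_mate_suffix(read_id: str) -> str:
    return re.sub(r"/[12]$", "", read_id)


def parse_invpcr_pairs(
    barcode_fastq,
    junction_fastq,
    expected_start: str = DEFAULT_JUNCTION_START,
    flank: FlankSpec | None = None,
    library: str = "L1",
    end_label: str = "PB3",
    start_mismatch: int = 1,
    flank_mismatch: int = 2,
    min_genomic: int = DEFAULT_MIN_GENOMIC,
) -> tuple[list[InvPcrPair], dict[str, int]]:
    """Reduce paired inverse-PCR FASTQs to (barcode, junction) records.

    The junction-side read must open with ``expected_start`` (the transposon
    terminal sequence) within ``start_mismatch`` Hamming mismatches and must
    retain at least ``min_genomic`` bases after trimming it; the barcode is
    recovered from the mate using the amplicon flank logic.  Reads failing
    either test are discarded and tallied by reason; mismatched or ragged
    read ids are a hard error.
    """
    if not expected_start:
        raise ValueError("expected_start must be a non-empty transposon terminal sequence")
    flank = flank or FlankSpec()
    bc_reads = read_fastq(barcode_fastq) if isinstance(barcode_fastq, (str, Path)) else iter(barcode_fastq)
    jn_reads = read_fastq(junction_fastq) if isinstance(junction_fastq, (str, Path)) else iter(junction_fastq)
    pairs: list[InvPcrPair] = []
    discards = {"truncated": 0, "wrong-start": 0, "barcode-fail": 0}
    f5, blen = flank.five_prime, flank.barcode_length
    n = 0
    while True:
        b = next(bc_reads, None)
        j = next(jn_reads, None)
        if b is None and j is None:
            break
        if b is None or j is None:
            raise ValueError("unpaired inverse-PCR streams: files differ in read count")
        bid, bseq = _strip_mate_suffix(b[0]), b[1].upper()
        jid, jseq = _strip_mate_suffix(j[0]), j[1].upper()
        if bid != jid:
            raise ValueError(f"unpaired inverse-PCR reads at record {n}: {bid!r} vs {jid!r}")
        n += 1
        if len(jseq) < len(expected_start) + min_genomic:
            discards["truncated"] += 1
            continue
        if hamming(jseq[: len(expected_start)], expected_start) > start_mismatch:
            discards["wrong-start"] += 1
            continue
        if len(bseq) < len(f5) + blen:
            discards["barcode-fail"] += 1
            continue
        if hamming(bseq[: len(f5)], f5) > flank_mismatch:
            discards["barcode-fail"] += 1
            continue
        barcode = bseq[len(f5) : len(f5) + blen]
        if "N" in barcode:
            discards["barcode-fail"] += 1
            continue
        pairs.append(InvPcrPair(n - 1, barcode, jseq[len(expected_start) :], library, end_label))
    return pairs, discards


# ---------------------------------------------------------------------------
# junction mapping


def _build_seed_index(genome: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((chrom, i))
    return index


def _evaluate(qs: str, ref: str, start: int) -> tuple[int, int]:
    """Ungapped comparison of ``qs`` placed at 0-based ``start``; returns
    (matching bases, compared bases) over the on-contig overlap."""
    a = max(0, -start)
    b = min(len(qs), len(ref) - start)
    if b <= a:
        return 0, 0
    seg = ref[start + a : start + b]
    matches = sum(x == y for x, y in zip(qs[a:b], seg))
    return matches, b - a


def map_junctions(
    pairs: list[InvPcrPair],
    reference=None,
    mode: str = "builtin",
    sam_path: str | Path | None = None,
    seed_k: int = 16,
    min_identity: float = 0.95,
    min_len: int = 20,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map junction sequences to the reference and derive integration sites.

    ``builtin`` mode uses an exact-seed (k=16) + ungapped-extension aligner:
    a junction maps iff it has a unique best hit with ≥95% identity over
    ≥20 compared bases.  ``sam-import`` mode ingests pre-computed alignments
    whose read names encode the pair index (an integer, optionally after a
    final ``:``).  Returns one row per mapped pair (pair_id, barcode,
    library, end_label, chrom, pos, strand) plus a tally of unmapped and
    multimapping pairs.
    """
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    rows: list[dict] = []
    tally = {"unmapped": 0, "multimapping": 0}
    if mode == "builtin":
        if reference is None:
            raise ValueError("builtin mapping mode requires a reference FASTA")
        index = _build_seed_index(reference, seed_k)
        for pair in pairs:
            hit = _map_one(pair.junction_seq, reference, index, seed_k, min_identity, min_len)
            if hit is None:
                tally["unmapped"] += 1
            elif hit == "multi":
                tally["multimapping"] += 1
            else:
                chrom, pos, strand = hit
                rows.append(_row(pair, chrom, pos, strand))
    elif mode in ("sam-import", "sam"):
        if sam_path is None:
            raise ValueError("sam-import mode requires sam_path")
        rows, tally = _import_sam(pairs, sam_path, reference)
    else:
        raise ValueError(f"unknown mapping mode: {mode!r}")
    mapped = pd.DataFrame(
        rows, columns=["pair_id", "barcode", "library", "end_label", "chrom", "pos", "strand"]
    )
    log.info("mapped %d/%d junction pairs (%s)", len(mapped), len(pairs), tally)
    return mapped, tally


def _row(pair: InvPcrPair, chrom: str, pos: int, strand: str) -> dict:
    return {
        "pair_id": pair.pair_id,
        "barcode": pair.barcode,
        "library": pair.library,
        "end_label": pair.end_label,
        "chrom": chrom,
        "pos": pos,
        "strand": strand,
    }


def _map_one(query, genome, index, k, min_identity, min_len):
    candidates: set[tuple[str, int, str]] = set()
    for strand, qs in (("+", query), ("-", revcomp(query))):
        if len(qs) < k:
            continue
        for i in range(len(qs) - k + 1):
            for chrom, off in index.get(qs[i : i + k], ()):
                candidates.add((chrom, off - i, strand))
    scored = []
    for chrom, start, strand in candidates:
        qs = query if strand == "+" else revcomp(query)
        matches, complen = _evaluate(qs, genome[chrom], start)
        if complen >= min_len and matches / complen >= min_identity:
            pos = start + 1 if strand == "+" else start + len(qs)
            if 1 <= pos <= len(genome[chrom]):
                scored.append((matches, chrom, start, strand, pos))
    if not scored:
        return None
    scored.sort(key=lambda t: -t[0])
    if len(scored) > 1 and scored[1][0] == scored[0][0]:
        return "multi"
    _, chrom, _, strand, pos = scored[0]
    return chrom, pos, strand


def _import_sam(pairs, sam_path, reference):
    import pysam

    by_id = {p.pair_id: p for p in pairs}
    ref_names = set(reference) if reference is not None else None
    rows, tally = [], {"unmapped": 0, "multimapping": 0}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            token = aln.query_name.rsplit(":", 1)[-1]
            try:
                pid = int(token)
            except ValueError as exc:
                raise ValueError(
                    f"SAM read name {aln.query_name!r} does not encode a pair index"
                ) from exc
            pair = by_id.get(pid)
            if pair is None:
                raise ValueError(f"SAM pair index {pid} not present in parsed pairs")
            if aln.is_unmapped:
                tally["unmapped"] += 1
                continue
            if ref_names is not None and aln.reference_name not in ref_names:
                raise ValueError(
                    f"SAM references {aln.reference_name!r} absent from the reference FASTA"
                )
            if aln.mapping_quality == 0:
                tally["multimapping"] += 1
                continue
            cig = aln.cigartuples or []
            lead = sum(l for op, l in _leading_clips(cig))
            tail = sum(l for op, l in _leading_clips(cig[::-1]))
            if not aln.is_reverse:
                pos = aln.reference_start + 1 - lead
                strand = "+"
            else:
                # query start corresponds to the rightmost reference base
                pos = aln.reference_end + tail
                strand = "-"
            rows.append(_row(pair, aln.reference_name, pos, strand))
    return rows, tally


def _leading_clips(cigartuples):
    for op, length in cigartuples:
        if op in (4, 5):  # S, H
            yield op, length
        else:
            break


# ---------------------------------------------------------------------------
# site calling, filtering, merging


def call_sites(mapped: pd.DataFrame) -> pd.DataFrame:
    """Aggregate mapped pairs into integration sites with read support.

    Reads-per-million is computed within each (library, end_label) mapping
    run, i.e. the denominator is the total mapped reads of that run.
    """
    if mapped.empty:
        return pd.DataFrame(columns=SITE_KEY + ["reads", "rpm"])
    sites = mapped.groupby(SITE_KEY, as_index=False).size().rename(columns={"size": "reads"})
    totals = sites.groupby(["library", "end_label"])["reads"].transform("sum")
    sites["rpm"] = sites["reads"] / totals * 1e6
    return sites.sort_values(["chrom", "pos", "strand", "library", "end_label"]).reset_index(
        drop=True
    )


def filter_and_merge_sites(
    sites: pd.DataFrame,
    min_rpm: float = DEFAULT_MIN_RPM,
    window: int = DEFAULT_MERGE_WINDOW,
    return_map: bool = False,
):
    """Apply the site-level read filter and proximity merge.

    Sites with ``rpm`` strictly below ``min_rpm`` are discarded.  Surviving
    sites from the same library (and same chromosome, strand and transposon
    end) whose positions lie within ``window`` bp of each other are combined
    transitively; the merged site takes the position of its most-supported
    member (ties: smallest position) and the summed read count and rpm.
    The operation is idempotent and conserves the reads of surviving sites.

    With ``return_map=True`` also returns a dict mapping each surviving raw
    site key ``(library, end_label, chrom, strand, pos)`` to its merged key.
    """
    kept = sites[sites["rpm"] >= min_rpm].copy()
    out_rows: list[dict] = []
    member_map: dict[tuple, tuple] = {}
    for (library, end_label, chrom, strand), grp in kept.groupby(
        ["library", "end_label", "chrom", "strand"], sort=True
    ):
        grp = grp.sort_values("pos")
        cluster: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cluster and row["pos"] - cluster[-1]["pos"] > window:
                out_rows.append(_merge_cluster(cluster, member_map))
                cluster = []
            cluster.append(row)
        if cluster:
            out_rows.append(_merge_cluster(cluster, member_map))
    merged = pd.DataFrame(out_rows, columns=SITE_KEY + ["reads", "rpm"])
    merged = merged.sort_values(["chrom", "pos", "strand", "library", "end_label"]).reset_index(
        drop=True
    )
    if return_map:
        return merged, member_map
    return merged


def _merge_cluster(cluster: list[pd.Series], member_map: dict) -> dict:
    rep = min(cluster, key=lambda r: (-r["reads"], r["pos"]))
    merged_key = (rep["library"], rep["end_label"], rep["chrom"], rep["strand"], int(rep["pos"]))
    for r in cluster:
        member_map[(r["library"], r["end_label"], r["chrom"], r["strand"], int(r["pos"]))] = (
            merged_key
        )
    return {
        "library": rep["library"],
        "end_label": rep["end_label"],
        "chrom": rep["chrom"],
        "strand": rep["strand"],
        "pos": int(rep["pos"]),
        "reads": int(sum(r["reads"] for r in cluster)),
        "rpm": float(sum(r["rpm"] for r in cluster)),
    }


def link_barcodes_to_sites(
    mapped: pd.DataFrame,
    site_map: dict[tuple, tuple],
    canonical_map: dict[str, str] | None = None,
    min_link_reads: int = DEFAULT_MIN_LINK_READS,
) -> pd.DataFrame:
    """Build the barcode → merged-site association table.

    ``site_map`` comes from :func:`filter_and_merge_sites(..., return_map=True)`;
    pairs whose raw site failed the rpm filter are dropped.  ``canonical_map``
    translates raw barcodes to canonical group representatives (identity when
    omitted).  Links supported by fewer than ``min_link_reads`` pairs are
    discarded, and a barcode still linked to more than one merged site is
    flagged ambiguous.
    """
    support: dict[tuple, int] = defaultdict(int)
    for row in mapped.itertuples(index=False):
        raw_key = (row.library, row.end_label, row.chrom, row.strand, int(row.pos))
        merged_key = site_map.get(raw_key)
        if merged_key is None:
            continue
        barcode = (canonical_map or {}).get(row.barcode, row.barcode)
        support[(barcode,) + merged_key] += 1
    records = [
        {
            "barcode": k[0],
            "library": k[1],
            "end_label": k[2],
            "chrom": k[3],
            "strand": k[4],
            "pos": k[5],
            "reads": n,
        }
        for k, n in support.items()
        if n >= min_link_reads
    ]
    links = pd.DataFrame(
        records, columns=["barcode", "library", "end_label", "chrom", "strand", "pos", "reads"]
    )
    n_sites = links.groupby("barcode")[["chrom", "strand", "pos"]].apply(
        lambda d: len(d.drop_duplicates())
    )
    links["ambiguous"] = links["barcode"].map(n_sites > 1).fillna(False).astype(bool)
    return links.sort_values(["barcode", "chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation


def load_gene_annotations(gtf_path: str | Path) -> pd.DataFrame:
    """Parse a GTF into gene-body spans (1-based, closed intervals).

    A gene's body runs from the minimum start to the maximum end over all of
    its records; quoted and unquoted ``gene_id`` attributes are both
    accepted, and a record without ``gene_id`` is a parse error.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    spans: dict[str, dict] = {}
    for feat in db.all_features():
        gid_attr = feat.attributes.get("gene_id")
        if not gid_attr:
            raise ValueError(f"{gtf_path}: GTF record without gene_id attribute: {feat}")
        gid = gid_attr[0]
        name = feat.attributes.get("gene_name", [gid])[0]
        rec = spans.setdefault(
            gid,
            {
                "gene_id": gid,
                "gene_name": name,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            },
        )
        rec["start"] = min(rec["start"], feat.start)
        rec["end"] = max(rec["end"], feat.end)
    genes = pd.DataFrame(
        spans.values(), columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"]
    )
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


def annotate_sites(sites: pd.DataFrame, genes: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Assign every overlapping gene body to each site (strand-agnostic).

    A site is assigned each gene whose body span contains its position;
    sites overlapping no gene are labelled ``gene_id = "none"``.  Sites
    inside several overlapping genes yield one output row per gene.
    """
    if isinstance(genes, (str, Path)):
        genes = load_gene_annotations(genes)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes.itertuples(index=False):
        trees[g.chrom][g.start : g.end + 1] = (g.gene_id, g.gene_name)
    rows = []
    for _, site in sites.iterrows():
        hits = sorted(iv.data for iv in trees[site["chrom"]][int(site["pos"])])
        if not hits:
            hits = [("none", "none")]
        for gid, gname in hits:
            rec = dict(site)
            rec["gene_id"] = gid
            rec["gene_name"] = gname
            rows.append(rec)
    return pd.DataFrame(rows, columns=list(sites.columns) + ["gene_id", "gene_name"])
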