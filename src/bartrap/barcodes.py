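"""Barcode extraction, error-aware grouping and count-matrix assembly.

Each transposon carries a random 25-bp barcode at either end (PB5/"Sims" and
PB3/"West"); sequencing the barcode amplicons yields per-sample read counts
proportional to the abundance of each mutant.  PCR and sequencing errors
scatter reads into near-identical barcode variants, so raw barcodes are
clustered by edit distance and counted together under a canonical
representative before any downstream comparison.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .io import read_fastq

log = logging.getLogger(__name__)

BARCODE_LENGTH = 25

#: Fixed vector sequence immediately 5' of the random 25-mer in barcode
#: amplicon reads (synthetic construct; any real flank can be supplied).
DEFAULT_FLANK_5P = "ACCTCGAGATGTCACGCGTA"
#: Optional fixed sequence immediately 3' of the barcode.
DEFAULT_FLANK_3P = ""
DEFAULT_FLANK_MISMATCH = 2
DEFAULT_MAX_EDIT = 2

END_LABELS = ("PB3", "PB5")  # analysis-file aliases: West and Sims


@dataclass(frozen=True)
class FlankSpec:
    """Constant sequences bracketing the 25-mer in an amplicon read."""

    five_prime: str = DEFAULT_FLANK_5P
    three_prime: str = DEFAULT_FLANK_3P
    barcode_length: int = BARCODE_LENGTH

    def __post_init__(self):
        if not self.five_prime:
            raise ValueError("flank spec requires a non-empty 5' flank")


@dataclass
class BarcodeGroup:
    """A cluster of near-identical barcodes counted as one mutant tag.

    ``canonical`` is the most abundant member (ties: lexicographically
    smallest); ``sample_reads`` sums the raw per-sample counts over all
    members, so grouping conserves reads.
    """

    canonical: str
    members: set[str]
    sample_reads: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.sample_reads.values())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def extract_barcodes(
    reads,
    flank: FlankSpec | None = None,
    sample: str = "sample",
    max_mismatch: int = DEFAULT_FLANK_MISMATCH,
) -> tuple[list[dict], dict[str, int]]:
    """Count 25-mer barcodes in single-end amplicon reads.

    ``reads`` is a FASTQ path or an iterable of ``(read_id, sequence, qual)``
    tuples.  The 5' flank is matched at the start of the read by Hamming
    distance over a fixed window (no indel alignment), so extraction is O(1)
    per read; the 25-mer immediately following the flank is counted.  Reads
    are discarded — and tallied by reason — when they are shorter than
    flank+barcode (+3' flank), when the flank exceeds ``max_mismatch``
    mismatches, or when the barcode window contains an N.

    Returns ``(counts, discards)`` where ``counts`` is a list of raw-count
    records ``{"barcode", "sample", "reads"}`` and ``discards`` maps a
    discard reason to its read tally.
    """
    flank = flank or FlankSpec()
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    f5, f3, blen = flank.five_prime, flank.three_prime, flank.barcode_length
    min_len = len(f5) + blen + len(f3)
    counter: Counter[str] = Counter()
    discards: dict[str, int] = {"too-short": 0, "flank-mismatch": 0, "barcode-N": 0}
    n_reads = 0
    for _rid, seq, _qual in reads:
        n_reads += 1
        seq = seq.upper()
        if len(seq) < min_len:
            discards["too-short"] += 1
            continue
        if hamming(seq[: len(f5)], f5) > max_mismatch:
            discards["flank-mismatch"] += 1
            continue
        if f3 and hamming(seq[len(f5) + blen : min_len], f3) > max_mismatch:
            discards["flank-mismatch"] += 1
            continue
        barcode = seq[len(f5) : len(f5) + blen]
        if "N" in barcode:
            discards["barcode-N"] += 1
            continue
        counter[barcode] += 1
    if n_reads == 0:
        log.warning("extract_barcodes: empty input for sample %s", sample)
    counts = [
        {"barcode": bc, "sample": sample, "reads": n}
        for bc, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return counts, discards


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _candidate_pairs(barcodes: list[str], max_edit: int):
    """Generate candidate index pairs guaranteed to cover all pairs within
    ``max_edit`` Levenshtein distance.

    Pigeonhole over ``max_edit + 1`` contiguous pieces of each barcode: two
    strings within edit distance e share at least one piece exactly, shifted
    by at most e positions, so indexing each piece's content over a ±e
    position window is a sound (never-missing) prefilter.
    """
    n = len(barcodes)
    if n <= 300:  # brute force is cheaper than indexing at small n
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j
        return
    length = len(barcodes[0])
    k = max_edit + 1
    piece = length // k
    starts = [p * piece for p in range(k)]
    index: dict[tuple[int, str], list[int]] = defaultdict(list)
    for idx, bc in enumerate(barcodes):
        for p, s in enumerate(starts):
            for d in range(-max_edit, max_edit + 1):
                o = s + d
                if 0 <= o and o + piece <= len(bc):
                    index[(p, bc[o : o + piece])].append(idx)
    seen: set[tuple[int, int]] = set()
    for idx, bc in enumerate(barcodes):
        for p, s in enumerate(starts):
            for j in index.get((p, bc[s : s + piece]), ()):
                if j == idx:
                    continue
                pair = (min(idx, j), max(idx, j))
                if pair not in seen:
                    seen.add(pair)
                    yield pair


def group_barcodes(counts: list[dict], max_edit: int = DEFAULT_MAX_EDIT) -> list[BarcodeGroup]:
    """Cluster barcodes by single-linkage under Levenshtein distance.

    Clustering is computed across the pooled barcode universe (all samples),
    not per sample, so that the same error cloud collapses identically
    everywhere.  The canonical barcode of each cluster is its most abundant
    member, ties broken by lexicographic order; per-sample counts are summed
    over members.  Output is sorted by total reads descending (canonical as
    tie-break), and with ``max_edit=0`` the grouping is the identity.
    """
    if max_edit < 0:
        raise ValueError("max_edit must be >= 0")
    per_barcode: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for rec in counts:
        bc = rec["barcode"]
        if len(bc) != BARCODE_LENGTH:
            raise ValueError(f"barcode {bc!r} is not {BARCODE_LENGTH} bp")
        per_barcode[bc][rec["sample"]] += int(rec["reads"])
    barcodes = sorted(per_barcode)
    uf = _UnionFind(len(barcodes))
    if max_edit > 0:
        for i, j in _candidate_pairs(barcodes, max_edit):
            if (
                edlib.align(barcodes[i], barcodes[j], mode="NW", task="distance", k=max_edit)[
                    "editDistance"
                ]
                != -1
            ):
                uf.union(i, j)
    clusters: dict[int, list[str]] = defaultdict(list)
    for i, bc in enumerate(barcodes):
        clusters[uf.find(i)].append(bc)
    groups: list[BarcodeGroup] = []
    for members in clusters.values():
        totals = {bc: sum(per_barcode[bc].values()) for bc in members}
        canonical = min(members, key=lambda bc: (-totals[bc], bc))
        sample_reads: dict[str, int] = defaultdict(int)
        for bc in members:
            for smp, n in per_barcode[bc].items():
                sample_reads[smp] += n
        groups.append(BarcodeGroup(canonical, set(members), dict(sample_reads)))
    groups.sort(key=lambda g: (-g.total_reads, g.canonical))
    return groups


def build_count_matrix(groups: list[BarcodeGroup], sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Assemble the dense barcode-group × sample count matrix.

    Rows are canonical barcodes, columns are every sample in the sheet (in
    sheet order); absent (group, sample) pairs are zero.  A sample present
    in the counts but missing from the sheet is a hard error.
    """
    samples = list(sample_sheet["sample"])
    known = set(samples)
    seen = {s for g in groups for s in g.sample_reads}
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(
            "sample(s) present in counts but absent from sample sheet: " + ", ".join(unknown)
        )
    data = np.zeros((len(groups), len(samples)), dtype=np.int64)
    col = {s: j for j, s in enumerate(samples)}
    for i, g in enumerate(groups):
        for s, n in g.sample_reads.items():
            data[i, col[s]] = n
    matrix = pd.DataFrame(data, index=[g.canonical for g in groups], columns=samples)
    matrix.index.name = "barcode"
    log.info(
        "count matrix: %d groups x %d samples; column sums: %s",
        *matrix.shape,
        dict(matrix.sum(axis=0)),
    )
    return matrix
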