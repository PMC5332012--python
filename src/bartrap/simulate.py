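"""Synthetic barcoded-transposon screens with machine-readable ground truth.

The generator mirrors the structure of the real experiment: a reference
genome with non-overlapping gene bodies, mutant libraries built by piggyBac
insertion at TTAA tetranucleotides (mainly single-copy, with a small
multi-copy fraction), random 25-bp barcodes at the transposon ends drawn
from a finite plasmid pool (so barcode collisions occur), exponential
drug/vehicle selection calibrated so a neutral mutant loses 50% of its
cells over the screening window, and FASTQ emission for both the barcode
amplicons and the paired inverse-PCR products, with a per-base substitution
error model and optional PCR jackpotting.  Every emitted read carries its
truth id in the read name for traceability; production parsers must not
rely on those names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import BARCODE_LENGTH, DEFAULT_FLANK_5P
from .io import write_fasta, write_fastq, write_tsv
from .sites import DEFAULT_JUNCTION_START, revcomp

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Knobs of the synthetic screen; defaults emulate the real study's
    structure at its stated scale (ten pools of ~10,000 mutants, a finite
    barcode plasmid pool, 50% wild-type kill over the selection window)."""

    seed: int = 0
    # genome / annotation
    n_chroms: int = 3
    chrom_length: int = 500_000
    n_genes: int = 60
    gene_length: int = 8_000
    # library structure
    n_pools: int = 10
    n_mutants_per_pool: int = 10_000
    barcode_pool_size: int | None = 1_000_000
    multi_copy_fraction: float = 0.05
    min_site_spacing: int = 6
    # selection
    generations: float = 8.0
    selection_sigma: float = 0.1
    cells_per_mutant: int = 200
    n_replicates: int = 2
    fitness: dict = field(default_factory=dict)  # mutant_id -> (f_drug, f_vehicle)
    # sequencing
    reads_per_sample: int = 500_000
    invpcr_reads_per_site: float = 100.0
    junction_length: int = 40
    error_rate: float = 0.01
    pcr_jackpot_shape: float | None = None
    flank_5p: str = DEFAULT_FLANK_5P
    read_tail: str = "TGTTAGCCATGGACCGTAAC"
    junction_start: str = DEFAULT_JUNCTION_START

    def __post_init__(self):
        if self.barcode_pool_size is not None and self.barcode_pool_size < 1:
            raise ValueError("barcode_pool_size must be >= 1")
        for name in ("error_rate", "multi_copy_fraction", "selection_sigma", "generations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown simulator config key(s): {', '.join(unknown)}")
        return cls(**d)

    @property
    def neutral_drug_fitness(self) -> float:
        """Relative growth rate that halves a mutant's final abundance over
        the screen relative to vehicle — the 50%-kill calibration."""
        return 1.0 - 1.0 / self.generations

    def mutant_fitness(self, mutant_id: str) -> tuple[float, float]:
        return self.fitness.get(mutant_id, (self.neutral_drug_fitness, 1.0))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


# ---------------------------------------------------------------------------
# genome and gene models


def simulate_genome_and_genes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random reference with non-overlapping gene bodies.

    TTAA tetranucleotides occur at their natural random-sequence density
    (~1/256 bp); each gene span is additionally guaranteed to contain at
    least one.  Raises if the requested genes do not fit the genome.
    """
    if config.chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    slot = config.chrom_length // per_chrom if per_chrom else config.chrom_length
    if per_chrom and slot < config.gene_length + 200:
        raise ValueError(
            f"{config.n_genes} genes of {config.gene_length} bp do not fit "
            f"{config.n_chroms} x {config.chrom_length} bp"
        )
    genome: dict[str, str] = {}
    gene_rows = []
    gi = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        seq = np.array(list(_random_seq(rng, config.chrom_length)))
        for s in range(per_chrom):
            if gi >= config.n_genes:
                break
            start0 = s * slot + 100  # 0-based
            end0 = start0 + config.gene_length - 1
            span = "".join(seq[start0 : end0 + 1])
            if "TTAA" not in span:
                mid = start0 + config.gene_length // 2
                seq[mid : mid + 4] = list("TTAA")
            gi += 1
            gene_rows.append(
                {
                    "gene_id": f"gene{gi:04d}",
                    "gene_name": f"Gene{gi:04d}",
                    "chrom": chrom,
                    "start": start0 + 1,
                    "end": end0 + 1,
                    "strand": "+" if gi % 2 else "-",
                }
            )
        genome[chrom] = "".join(seq)
    return genome, pd.DataFrame(gene_rows)


def write_gtf(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\tbartrap_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def ttaa_positions(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """0-based start positions of every TTAA occurrence per chromosome."""
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        hits = (
            (arr[:-3] == b"T") & (arr[1:-2] == b"T") & (arr[2:-1] == b"A") & (arr[3:] == b"A")
        )
        out[chrom] = np.flatnonzero(hits)
    return out


# ---------------------------------------------------------------------------
# library construction


def _draw_barcode(rng: np.random.Generator, config: SimConfig, used: dict) -> str:
    """Draw one barcode from the finite plasmid pool (collisions possible)
    or, with an unlimited pool, a fresh unique random 25-mer."""
    if config.barcode_pool_size is None:
        while True:
            bc = _random_seq(rng, BARCODE_LENGTH)
            if bc not in used:
                used[bc] = True
                return bc
    idx = int(rng.integers(0, config.barcode_pool_size))
    bc = used.get(idx)
    if bc is None:
        # pool member sequences derive deterministically from (seed, index)
        bc = _random_seq(np.random.default_rng([config.seed % (2**31), idx]), BARCODE_LENGTH)
        used[idx] = bc
    return bc


def simulate_library(
    config: SimConfig,
    genome: dict[str, str],
    genes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    n_pools: int | None = None,
) -> pd.DataFrame:
    """Generate mutants and their integrations; returns the truth table.

    One row per integration: most mutants are single copy, a configurable
    fraction carry a second insertion.  Integration positions are uniform
    over TTAA sites, subject to a minimum spacing between chosen sites on
    the same chromosome and strand so that distinct mutants remain distinct
    after the pipeline's 5-bp site merge (on a genome this small, unspaced
    sampling would conflate mutants far more often than the real genome
    ever would).  PB3 (West) and PB5 (Sims) barcodes are independent draws
    from the same pool.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ttaa = ttaa_positions(genome)
    # keep sites at least a junction-read length away from contig edges so
    # every junction window lies fully on the contig (real chromosomes are
    # vastly larger than any read; only toy genomes hit their edges)
    margin = config.junction_length + 4
    ttaa = {
        c: p[(p >= margin) & (p <= len(genome[c]) - margin)] for c, p in ttaa.items()
    }
    ttaa = {c: p for c, p in ttaa.items() if len(p)}
    chroms = sorted(ttaa)
    weights = np.array([len(ttaa[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    gene_index = _gene_interval_index(genes) if genes is not None else {}
    used_bc: dict = {}
    taken: dict[tuple[str, str], list[int]] = {}
    rows = []
    for pool_i in range(n_pools if n_pools is not None else config.n_pools):
        library = f"L{pool_i + 1}"
        for m in range(config.n_mutants_per_pool):
            mutant_id = f"{library}_m{m + 1:05d}"
            bc3 = _draw_barcode(rng, config, used_bc)
            bc5 = _draw_barcode(rng, config, used_bc)
            f_drug, f_veh = config.mutant_fitness(mutant_id)
            n_copies = 2 if rng.random() < config.multi_copy_fraction else 1
            for copy in range(n_copies):
                chrom, pos, strand = _place_integration(rng, config, ttaa, chroms, weights, taken)
                rows.append(
                    {
                        "mutant_id": mutant_id,
                        "library": library,
                        "barcode": bc3,
                        "barcode_pb5": bc5,
                        "end_label": "PB3",
                        "copy": copy,
                        "n_copies": n_copies,
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "gene_id": _lookup_gene(gene_index, chrom, pos),
                        "fitness_drug": f_drug,
                        "fitness_vehicle": f_veh,
                    }
                )
    truth = pd.DataFrame(rows)
    log.info("simulated %d integrations in %d mutants", len(truth), truth["mutant_id"].nunique())
    return truth


def _place_integration(rng, config, ttaa, chroms, weights, taken):
    for _ in range(1000):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        s = int(ttaa[chrom][rng.integers(0, len(ttaa[chrom]))])
        strand = "+" if rng.random() < 0.5 else "-"
        pos = s + 1 if strand == "+" else s + 4  # 1-based first flanking base
        near = taken.setdefault((chrom, strand), [])
        if all(abs(pos - q) >= config.min_site_spacing for q in near):
            near.append(pos)
            return chrom, pos, strand
    raise RuntimeError("could not place integration with required spacing")


def _gene_interval_index(genes: pd.DataFrame):
    idx: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes.itertuples(index=False):
        idx.setdefault(g.chrom, []).append((g.start, g.end, g.gene_id))
    return idx


def _lookup_gene(index, chrom: str, pos: int) -> str:
    for start, end, gid in index.get(chrom, ()):
        if start <= pos <= end:
            return gid
    return "none"


# ---------------------------------------------------------------------------
# selection and sequencing


def simulate_selection(
    truth: pd.DataFrame,
    condition: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Final cell count per mutant after exponential growth under one
    condition: cells₀ · 2^(g·f) with multiplicative lognormal noise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    col = "fitness_drug" if condition == "drug" else "fitness_vehicle"
    mutants = truth.drop_duplicates("mutant_id").set_index("mutant_id")
    growth = config.cells_per_mutant * 2.0 ** (config.generations * mutants[col])
    noise = np.exp(rng.normal(0.0, config.selection_sigma, len(growth)))
    return (growth * noise).rename("cells")


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        arr[i] = "ACGT"[(("ACGT".find(arr[i]) + int(rng.integers(1, 4))) % 4)]
    return "".join(arr)


def sample_read_counts(
    cells: pd.Series, total_reads: int, config: SimConfig, rng: np.random.Generator
) -> pd.Series:
    """Multinomial read sampling proportional to cell abundance, optionally
    gamma-weighted per mutant to emulate PCR jackpotting."""
    weights = cells.to_numpy(dtype=float)
    if config.pcr_jackpot_shape is not None:
        weights = weights * rng.gamma(config.pcr_jackpot_shape, 1.0 / config.pcr_jackpot_shape, len(weights))
    probs = weights / weights.sum()
    return pd.Series(rng.multinomial(total_reads, probs), index=cells.index, name="reads")


def simulate_count_matrix(
    config: SimConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug/vehicle replicate barcode counts without FASTQ emission.

    Collapses directly to true per-barcode read counts (mutants sharing a
    barcode pool up); returns ``(matrix, design)`` ready for
    :func:`bartrap.differential.run_screen_test`.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mutant_bc = truth.drop_duplicates("mutant_id").set_index("mutant_id")["barcode"]
    columns, design_rows = {}, []
    for condition in ("drug", "dmso"):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_{rep}"
            cells = simulate_selection(truth, "drug" if condition == "drug" else "vehicle", config, rng)
            reads = sample_read_counts(cells, config.reads_per_sample, config, rng)
            columns[sample] = reads.groupby(mutant_bc).sum()
            design_rows.append({"sample": sample, "condition": condition, "replicate": rep})
    matrix = pd.DataFrame(columns).fillna(0).astype(int)
    matrix.index.name = "barcode"
    return matrix, pd.DataFrame(design_rows)


def emit_barcode_fastq(
    truth: pd.DataFrame,
    reads_per_mutant: pd.Series,
    path: str | Path,
    config: SimConfig,
    rng: np.random.Generator,
) -> int:
    """Write one sample's barcode amplicon FASTQ (flank + barcode + tail)."""
    mutant_bc = truth.drop_duplicates("mutant_id").set_index("mutant_id")["barcode"]

    def records():
        i = 0
        for mutant_id, n in reads_per_mutant.items():
            template = config.flank_5p + mutant_bc[mutant_id] + config.read_tail
            for _ in range(int(n)):
                i += 1
                seq = _mutate(template, rng, config.error_rate)
                yield f"bc:{mutant_id}:{i}", seq, "I" * len(seq)

    return write_fastq(path, records())


def emit_invpcr_fastq(
    truth: pd.DataFrame,
    genome: dict[str, str],
    out_prefix: str | Path,
    config: SimConfig,
    rng: np.random.Generator,
    library: str | None = None,
) -> tuple[Path, Path]:
    """Write the paired inverse-PCR FASTQs for one library.

    R1 carries the barcode amplicon, R2 the transposon terminal sequence
    followed by ``junction_length`` genomic bases read off the integration
    site in insertion orientation.  Per-site read depth is Poisson around
    ``invpcr_reads_per_site``.
    """
    sub = truth if library is None else truth[truth["library"] == library]
    r1, r2 = [], []
    glen = config.junction_length
    for row in sub.itertuples(index=False):
        if row.strand == "+":
            flankseq = genome[row.chrom][row.pos - 1 : row.pos - 1 + glen]
        else:
            flankseq = revcomp(genome[row.chrom][row.pos - glen : row.pos])
        n = max(1, rng.poisson(config.invpcr_reads_per_site))
        for k in range(n):
            rid = f"inv:{row.mutant_id}:{row.copy}:{k}"
            s1 = _mutate(config.flank_5p + row.barcode + config.read_tail, rng, config.error_rate)
            s2 = _mutate(config.junction_start + flankseq, rng, config.error_rate)
            r1.append((rid, s1, "I" * len(s1)))
            r2.append((rid, s2, "I" * len(s2)))
    p1 = Path(f"{out_prefix}_R1.fastq")
    p2 = Path(f"{out_prefix}_R2.fastq")
    write_fastq(p1, r1)
    write_fastq(p2, r2)
    return p1, p2


def simulate_screen(config: SimConfig, out_dir: str | Path) -> dict:
    """Full synthetic screen: genome, GTF, truth table, barcode FASTQs for
    drug/vehicle replicates and paired inverse-PCR FASTQs per library, plus
    a sample sheet.  Returns the paths and in-memory truth objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, genes = simulate_genome_and_genes(config, rng)
    fasta = out / "genome.fa"
    gtf = out / "genes.gtf"
    write_fasta(fasta, genome)
    write_gtf(genes, gtf)
    truth = simulate_library(config, genome, genes, rng)
    write_tsv(truth, out / "truth.tsv")
    sheet_rows = []
    for condition in ("drug", "dmso"):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_{rep}"
            fq = out / f"{sample}.fastq"
            cells = simulate_selection(
                truth, "drug" if condition == "drug" else "vehicle", config, rng
            )
            reads = sample_read_counts(cells, config.reads_per_sample, config, rng)
            emit_barcode_fastq(truth, reads, fq, config, rng)
            sheet_rows.append(
                {
                    "sample": sample,
                    "fastq_path": str(fq),
                    "condition": condition,
                    "replicate": rep,
                    "library": "all",
                    "end_label": "PB3",
                }
            )
    invpcr = {}
    for library in sorted(truth["library"].unique()):
        invpcr[library] = emit_invpcr_fastq(
            truth, genome, out / f"invpcr_{library}", config, rng, library
        )
    sheet = pd.DataFrame(sheet_rows)
    write_tsv(sheet, out / "samples.tsv")
    return {
        "fasta": fasta,
        "gtf": gtf,
        "truth": truth,
        "genome": genome,
        "genes": genes,
        "sample_sheet": sheet,
        "invpcr": invpcr,
        "out_dir": out,
    }
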