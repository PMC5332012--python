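"""Computational validation experiments for the screen pipeline.

Each function builds a synthetic experiment with known truth and measures
how the pipeline behaves on it: the null type-I error of the exact test,
recovery of a drug-hypersensitive spike-in mixed at 1:10,000, end-to-end
truth recovery through the full FASTQ pipeline, and gene-level ranking of
a gene carrying several depleted insertions.  They are used by the test
suite and by the reproduction script, and are deliberately cheap enough to
run on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import run_screen_test
from .genes import call_gene_hits, join_results
from .pipeline import PipelineConfig, run_pipeline
from .simulate import SimConfig, simulate_count_matrix, simulate_screen

TWO_BY_TWO = pd.DataFrame(
    {
        "sample": ["drug_1", "drug_2", "dmso_1", "dmso_2"],
        "condition": ["drug", "drug", "dmso", "dmso"],
        "replicate": [1, 2, 1, 2],
    }
)


def null_nb_matrix(
    seed: int, n_barcodes: int = 1000, phi: float = 0.1, mean: float = 100.0
) -> pd.DataFrame:
    """2-vs-2 negative-binomial counts with no true abundance differences."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean), 0.7, n_barcodes)
    size = 1.0 / phi
    counts = np.vstack(
        [rng.negative_binomial(size, size / (size + mu), n_barcodes) for _ in range(4)]
    ).T
    m = pd.DataFrame(counts, columns=TWO_BY_TWO["sample"])
    m.index = [f"bc{i:05d}" for i in range(n_barcodes)]
    m.index.name = "barcode"
    return m


def null_type_i_fraction(seed: int, alpha: float = 0.05, **kwargs) -> float:
    """Fraction of null barcodes with exact-test P below ``alpha``."""
    res = run_screen_test(null_nb_matrix(seed, **kwargs), TWO_BY_TWO)
    return float((res["PValue"] < alpha).mean())


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    bases = np.array(list("ACGT"))
    return ["".join(rng.choice(bases, 25)) for _ in range(n)]


def spike_in_experiment(seed: int, n_library: int = 10_000) -> dict:
    """The drug-hypersensitive spike-in mixing experiment.

    One mutant that cannot grow under drug (relative rate 0) is mixed with
    an otherwise neutral 10,000-mutant library at 1:10,000 (200 cells into
    2 million library cells) and screened 2-vs-2.  Returns whether the
    spike barcode is the most depleted (rank 1 among negative fold changes
    by P-value), plus its log2 fold change and P-value.
    """
    cfg = SimConfig(
        seed=seed,
        n_pools=1,
        n_mutants_per_pool=n_library,
        barcode_pool_size=None,
        reads_per_sample=1_000_000,
    )
    rng = np.random.default_rng(seed)
    ids = [f"L1_m{i:05d}" for i in range(n_library)] + ["spike"]
    barcodes = _random_barcodes(rng, n_library + 1)
    f0 = cfg.neutral_drug_fitness
    truth = pd.DataFrame(
        {
            "mutant_id": ids,
            "barcode": barcodes,
            "fitness_drug": [f0] * n_library + [0.0],
            "fitness_vehicle": 1.0,
        }
    )
    matrix, design = simulate_count_matrix(cfg, truth, rng)
    res = run_screen_test(matrix, design)
    depleted = res[res["logFC"] < 0].reset_index(drop=True)
    spike_rows = depleted.index[depleted["barcode"] == barcodes[-1]]
    rank = int(spike_rows[0]) + 1 if len(spike_rows) else None
    spike = res[res["barcode"] == barcodes[-1]]
    return {
        "top_depleted": rank == 1,
        "rank": rank,
        "spike_logfc": float(spike["logFC"].iloc[0]) if len(spike) else float("nan"),
        "spike_p": float(spike["PValue"].iloc[0]) if len(spike) else float("nan"),
        "n_barcodes": len(res),
    }


def gene_ranking_experiment(
    seed: int,
    n_genes: int = 40,
    insertions_per_gene: int = 4,
    depletion_fold: float = 8.0,
) -> dict:
    """One gene carries several independently depleted insertions.

    Every gene gets ``insertions_per_gene`` single-copy mutants; the target
    gene's mutants are depleted ``depletion_fold``-fold under drug relative
    to neutral mutants, everything else is null.  Returns whether the
    target ranks first among gene hits.
    """
    cfg = SimConfig(
        seed=seed, n_pools=1, barcode_pool_size=None, reads_per_sample=200_000
    )
    rng = np.random.default_rng(seed)
    n_mutants = n_genes * insertions_per_gene
    barcodes = _random_barcodes(rng, n_mutants)
    f0 = cfg.neutral_drug_fitness
    f_dep = f0 - np.log2(depletion_fold) / cfg.generations
    rows, links_rows, annot_rows = [], [], []
    target = "gene0001"
    for g in range(n_genes):
        gene = f"gene{g + 1:04d}"
        for k in range(insertions_per_gene):
            i = g * insertions_per_gene + k
            rows.append(
                {
                    "mutant_id": f"L1_m{i:05d}",
                    "barcode": barcodes[i],
                    "fitness_drug": f_dep if gene == target else f0,
                    "fitness_vehicle": 1.0,
                }
            )
            pos = 10_000 * i + 1
            links_rows.append(
                {
                    "barcode": barcodes[i], "library": "L1", "end_label": "PB3",
                    "chrom": "chr1", "strand": "+", "pos": pos, "reads": 50,
                    "ambiguous": False,
                }
            )
            annot_rows.append(
                {
                    "library": "L1", "end_label": "PB3", "chrom": "chr1", "strand": "+",
                    "pos": pos, "gene_id": gene, "gene_name": gene.capitalize(),
                }
            )
    truth = pd.DataFrame(rows)
    matrix, design = simulate_count_matrix(cfg, truth, rng)
    res = run_screen_test(matrix, design)
    annotated, _ = join_results(res, pd.DataFrame(links_rows), pd.DataFrame(annot_rows))
    hits = call_gene_hits(annotated)
    top = hits.iloc[0] if len(hits) else None
    return {
        "target_first": top is not None
        and top["gene_id"] == target
        and top["direction"] == "depleted",
        "n_hits": len(hits),
        "target_n_significant": int(
            hits.set_index("gene_id")["n_significant"].get(target, 0)
        ),
    }


def end_to_end_truth_recovery(seed: int, out_dir, n_mutants: int = 500) -> dict:
    """Full FASTQ-level pipeline on an error-free screen vs its truth table.

    Simulates a screen with per-base error rate 0 and unique barcodes, runs
    count → group → link → map → filter → annotate, and compares the
    resulting barcode → site → gene table with the simulator truth.
    """
    cfg = SimConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=150_000,
        n_genes=30,
        gene_length=5_000,
        n_pools=1,
        n_mutants_per_pool=n_mutants,
        barcode_pool_size=None,
        reads_per_sample=100_000,
        invpcr_reads_per_site=50,
        error_rate=0.0,
    )
    sim = simulate_screen(cfg, out_dir)
    pcfg = PipelineConfig(
        sample_sheet=str(sim["out_dir"] / "samples.tsv"),
        reference=str(sim["fasta"]),
        gtf=str(sim["gtf"]),
        invpcr={"L1": [str(p) for p in sim["invpcr"]["L1"]]},
        out_dir=str(sim["out_dir"] / "pipeline"),
    )
    res = run_pipeline(pcfg)
    truth = sim["truth"]
    key = ["barcode", "chrom", "pos", "strand"]
    merged = truth.merge(
        res["mapping"], on=key, how="outer", indicator=True, suffixes=("_truth", "")
    )
    both = merged["_merge"] == "both"
    gene_ok = (merged.loc[both, "gene_id_truth"] == merged.loc[both, "gene_id"]).all()
    multi = set(truth.loc[truth["n_copies"] > 1, "barcode"])
    links = res["links"]
    flags_ok = set(links.loc[links["ambiguous"], "barcode"]) == multi
    return {
        "recovered_fraction": float(both.sum() / len(truth)),
        "spurious_links": int((merged["_merge"] == "right_only").sum()),
        "gene_assignment_correct": bool(gene_ok),
        "ambiguity_flags_correct": bool(flags_ok),
        "n_integrations": len(truth),
    }
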