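"""Inverse-PCR parsing, junction mapping, site filtering and annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bartrap.barcodes import DEFAULT_FLANK_5P
from bartrap.sites import (
    DEFAULT_JUNCTION_START,
    InvPcrPair,
    annotate_sites,
    call_sites,
    filter_and_merge_sites,
    link_barcodes_to_sites,
    load_gene_annotations,
    map_junctions,
    parse_invpcr_pairs,
    revcomp,
)

from _oracles import brute_best_hits, brute_filter_merge

BC = "ACGT" * 6 + "A"
START = DEFAULT_JUNCTION_START


def _pair(rid, bc_seq, jn_seq):
    q = "I"
    return (rid, bc_seq, q * len(bc_seq)), (rid, jn_seq, q * len(jn_seq))


class TestParsePairs:
    def test_exact_prefix_kept_and_trimmed(self):
        genomic = "G" * 60
        b, j = _pair("p1", DEFAULT_FLANK_5P + BC + "TT", START + genomic)
        pairs, discards = parse_invpcr_pairs([b], [j])
        assert len(pairs) == 1
        assert pairs[0].junction_seq == genomic and pairs[0].barcode == BC
        assert sum(discards.values()) == 0

    def test_wrong_start_discarded(self):
        bad_start = "G" + START[1:]
        b, j = _pair("p1", DEFAULT_FLANK_5P + BC, bad_start + "G" * 60)
        pairs, discards = parse_invpcr_pairs([b], [j], start_mismatch=0)
        assert pairs == [] and discards["wrong-start"] == 1

    def test_truncated_junction_discarded(self):
        b, j = _pair("p1", DEFAULT_FLANK_5P + BC, START + "G" * 19)  # < 20 genomic bases
        pairs, discards = parse_invpcr_pairs([b], [j], min_genomic=20)
        assert pairs == [] and discards["truncated"] == 1

    def test_unpaired_ids_hard_error(self):
        b1, j1 = _pair("p1", DEFAULT_FLANK_5P + BC, START + "G" * 30)
        _, j2 = _pair("p2", "", START + "G" * 30)
        with pytest.raises(ValueError, match="unpaired"):
            parse_invpcr_pairs([b1], [j2])
        with pytest.raises(ValueError, match="unpaired"):
            parse_invpcr_pairs([b1], [j1, j2])

    def test_empty_expected_start_is_config_error(self):
        with pytest.raises(ValueError, match="expected_start"):
            parse_invpcr_pairs([], [], expected_start="")

    def test_mate_suffixes_tolerated(self):
        b, j = _pair("p1", DEFAULT_FLANK_5P + BC, START + "G" * 30)
        pairs, _ = parse_invpcr_pairs([(b[0] + "/1", b[1], b[2])], [(j[0] + "/2", j[1], j[2])])
        assert len(pairs) == 1


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(42)
    return {
        "chr1": "".join(rng.choice(list("ACGT"), 12_000)),
        "chr2": "".join(rng.choice(list("ACGT"), 8_000)),
    }


def _jpair(i, seq, library="L1"):
    return InvPcrPair(i, BC, seq, library, "PB3")


class TestBuiltinMapper:
    def test_perfect_forward_match(self, genome):
        p0 = 4999  # 0-based
        mapped, tally = map_junctions([_jpair(0, genome["chr1"][p0 : p0 + 40])], genome)
        row = mapped.iloc[0]
        assert (row.chrom, row.pos, row.strand) == ("chr1", p0 + 1, "+")
        assert tally == {"unmapped": 0, "multimapping": 0}

    def test_reverse_complement_maps_to_window_right_edge(self, genome):
        p0 = 3000
        window = genome["chr2"][p0 : p0 + 40]
        mapped, _ = map_junctions([_jpair(0, revcomp(window))], genome)
        row = mapped.iloc[0]
        assert (row.chrom, row.pos, row.strand) == ("chr2", p0 + 40, "-")

    def test_duplicated_junction_is_multimapping(self, genome):
        dup = genome["chr1"][100:140]
        doctored = dict(genome)
        doctored["chr2"] = genome["chr2"] + dup
        mapped, tally = map_junctions([_jpair(0, dup)], doctored)
        assert len(mapped) == 0 and tally["multimapping"] == 1

    def test_unmappable_junction_tallied(self, genome):
        mapped, tally = map_junctions([_jpair(0, "A" * 40)], genome)
        assert len(mapped) == 0 and tally["unmapped"] == 1

    def test_agrees_with_bruteforce_scan(self, genome):
        rng = np.random.default_rng(7)
        pairs = []
        for i in range(30):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            p0 = int(rng.integers(0, len(genome[chrom]) - 40))
            seq = genome[chrom][p0 : p0 + 40]
            # up to 2 substitutions (identity >= 95% of 40)
            seq = list(seq)
            for _ in range(int(rng.integers(0, 3))):
                k = int(rng.integers(0, 40))
                seq[k] = "ACGT"[(("ACGT".find(seq[k]) + 1) % 4)]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            pairs.append(_jpair(i, seq))
        mapped, _ = map_junctions(pairs, genome)
        mapped = mapped.set_index("pair_id")
        for p in pairs:
            hits = brute_best_hits(p.junction_seq, genome)
            best = hits[0]
            unique = len(hits) < 2 or hits[1][0] < best[0]
            passes = best[0] / 40 >= 0.95 and unique
            if passes:
                matches, chrom, start0, strand = best
                pos = start0 + 1 if strand == "+" else start0 + 40
                row = mapped.loc[p.pair_id]
                assert (row.chrom, row.pos, row.strand) == (chrom, pos, strand)
            else:
                assert p.pair_id not in mapped.index


class TestSamImport:
    def _write_sam(self, path, genome, records):
        lines = ["@HD\tVN:1.6\tSO:unknown"]
        for chrom, seq in genome.items():
            lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
        lines.extend(records)
        path.write_text("\n".join(lines) + "\n")

    def test_clipped_positions_match_bruteforce(self, genome, tmp_path):
        p0 = 2000
        fwd = genome["chr1"][p0 : p0 + 40]
        rev = revcomp(genome["chr2"][500:540])
        pairs = [_jpair(0, fwd), _jpair(1, rev)]
        # forward read soft-clipped 5 bases at query start: POS shifts +5
        rec0 = f"inv:0\t0\tchr1\t{p0 + 6}\t60\t5S35M\t*\t0\t0\t{fwd}\t*"
        # reverse read: query-leading clip appears at the cigar tail (3S)
        rev_sam_seq = revcomp(rev)  # full query; last 3 bases soft-clipped
        rec1 = f"inv:1\t16\tchr2\t501\t60\t37M3S\t*\t0\t0\t{rev_sam_seq}\t*"
        sam = tmp_path / "aln.sam"
        self._write_sam(sam, genome, [rec0, rec1])
        mapped, _ = map_junctions(pairs, genome, mode="sam-import", sam_path=sam)
        got = {r.pair_id: (r.chrom, r.pos, r.strand) for r in mapped.itertuples()}
        # brute-force oracle on the untrimmed junctions gives the truth
        for pid, query in [(0, fwd), (1, rev)]:
            matches, chrom, start0, strand = brute_best_hits(query, genome)[0]
            pos = start0 + 1 if strand == "+" else start0 + len(query)
            assert got[pid] == (chrom, pos, strand)

    def test_unknown_reference_is_hard_error(self, genome, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@SQ\tSN:chrX\tLN:1000\ninv:0\t0\tchrX\t10\t60\t40M\t*\t0\t0\t" + "A" * 40 + "\t*\n"
        )
        with pytest.raises(ValueError, match="chrX"):
            map_junctions([_jpair(0, "A" * 40)], genome, mode="sam-import", sam_path=sam)

    def test_mapq_zero_counts_as_multimapping(self, genome, tmp_path):
        sam = tmp_path / "aln.sam"
        self._write_sam(
            sam, genome, [f"inv:0\t0\tchr1\t10\t0\t40M\t*\t0\t0\t{'A' * 40}\t*"]
        )
        mapped, tally = map_junctions([_jpair(0, "A" * 40)], genome, mode="sam-import", sam_path=sam)
        assert len(mapped) == 0 and tally["multimapping"] == 1


def _site(pos, reads, rpm, chrom="chr1", strand="+", library="L1"):
    return {
        "library": library, "end_label": "PB3", "chrom": chrom, "strand": strand,
        "pos": pos, "reads": reads, "rpm": rpm,
    }


class TestFilterMerge:
    def test_rpm_filter_is_strictly_less_than(self):
        sites = pd.DataFrame([_site(100, 9, 9.0), _site(500, 10, 10.0)])
        out = filter_and_merge_sites(sites)
        assert out["pos"].tolist() == [500]

    def test_rpm_boundary_from_read_counts(self):
        # 9 and 10 reads in a 1,000,000-read mapping run: rpm 9 vs rpm 10
        rows = [{"pair_id": i, "barcode": BC, "library": "L1", "end_label": "PB3",
                 "chrom": "chr1", "pos": 100, "strand": "+"} for i in range(9)]
        rows += [{"pair_id": 9 + i, "barcode": BC, "library": "L1", "end_label": "PB3",
                  "chrom": "chr1", "pos": 5000, "strand": "+"} for i in range(10)]
        rows += [{"pair_id": 19 + i, "barcode": BC, "library": "L1", "end_label": "PB3",
                  "chrom": "chr2", "pos": 1, "strand": "+"} for i in range(1_000_000 - 19)]
        sites = call_sites(pd.DataFrame(rows))
        assert sites.set_index("pos").loc[100, "rpm"] == pytest.approx(9.0)
        out = filter_and_merge_sites(sites)
        assert 100 not in out["pos"].tolist() and 5000 in out["pos"].tolist()

    def test_merge_takes_supported_position_and_sums_reads(self):
        sites = pd.DataFrame([_site(100, 30, 30.0), _site(104, 5, 5.0)])
        out = filter_and_merge_sites(sites, min_rpm=0)
        assert len(out) == 1
        assert out.iloc[0]["pos"] == 100 and out.iloc[0]["reads"] == 35

    def test_gap_above_window_not_merged(self):
        sites = pd.DataFrame([_site(100, 10, 10.0), _site(106, 10, 10.0)])
        assert len(filter_and_merge_sites(sites)) == 2

    def test_different_strand_or_library_never_merged(self):
        sites = pd.DataFrame(
            [_site(100, 10, 10.0, strand="+"), _site(102, 10, 10.0, strand="-"),
             _site(103, 10, 10.0, library="L2")]
        )
        assert len(filter_and_merge_sites(sites)) == 3

    @given(st.integers(0, 5_000))
    def test_matches_bruteforce_and_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 25))
        sites = pd.DataFrame(
            [
                _site(
                    int(rng.integers(1, 60)),
                    int(rng.integers(1, 50)),
                    float(rng.choice([5.0, 9.999, 10.0, 20.0])),
                    chrom=str(rng.choice(["chr1", "chr2"])),
                    strand=str(rng.choice(["+", "-"])),
                    library=str(rng.choice(["L1", "L2"])),
                )
                for _ in range(n)
            ]
        ).drop_duplicates(["library", "end_label", "chrom", "strand", "pos"])
        mine = filter_and_merge_sites(sites)
        ref = brute_filter_merge(sites, 10.0, 5)
        pd.testing.assert_frame_equal(mine, ref, check_dtype=False)
        # idempotence and read conservation
        again = filter_and_merge_sites(mine)
        pd.testing.assert_frame_equal(again, mine, check_dtype=False)
        assert mine["reads"].sum() == sites[sites["rpm"] >= 10.0]["reads"].sum()


class TestLinks:
    def _mapped(self, rows):
        return pd.DataFrame(
            rows, columns=["pair_id", "barcode", "library", "end_label", "chrom", "pos", "strand"]
        )

    def _map_for(self, mapped):
        sites = call_sites(mapped)
        return filter_and_merge_sites(sites, min_rpm=0, return_map=True)[1]

    def test_single_site_unambiguous(self):
        mapped = self._mapped([(i, BC, "L1", "PB3", "chr1", 100, "+") for i in range(3)])
        links = link_barcodes_to_sites(mapped, self._map_for(mapped))
        assert len(links) == 1 and not links.iloc[0]["ambiguous"]

    def test_two_sites_flagged_ambiguous(self):
        mapped = self._mapped(
            [(0, BC, "L1", "PB3", "chr1", 100, "+"), (1, BC, "L1", "PB3", "chr2", 900, "+"),
             (2, BC, "L1", "PB3", "chr1", 100, "+"), (3, BC, "L1", "PB3", "chr2", 900, "+")]
        )
        links = link_barcodes_to_sites(mapped, self._map_for(mapped))
        assert len(links) == 2 and links["ambiguous"].all()

    def test_weak_second_link_dropped_restores_unambiguity(self):
        mapped = self._mapped(
            [(0, BC, "L1", "PB3", "chr1", 100, "+"), (1, BC, "L1", "PB3", "chr1", 100, "+"),
             (2, BC, "L1", "PB3", "chr2", 900, "+")]  # support 1 < 2
        )
        links = link_barcodes_to_sites(mapped, self._map_for(mapped), min_link_reads=2)
        assert len(links) == 1 and not links.iloc[0]["ambiguous"]

    def test_canonical_map_applied(self):
        variant = BC[:-1] + "G"
        mapped = self._mapped(
            [(0, BC, "L1", "PB3", "chr1", 100, "+"), (1, variant, "L1", "PB3", "chr1", 100, "+")]
        )
        links = link_barcodes_to_sites(mapped, self._map_for(mapped), canonical_map={variant: BC})
        assert links["barcode"].tolist() == [BC] and links.iloc[0]["reads"] == 2


GTF = """\
chr1\tsrc\tgene\t100\t500\t.\t+\t.\tgene_id "g1"; gene_name "Alpha";
chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g1"; gene_name "Alpha";
chr1\tsrc\tgene\t400\t900\t.\t-\t.\tgene_id g2
chr2\tsrc\tgene\t50\t80\t.\t+\t.\tgene_id "g3";
"""


class TestAnnotation:
    @pytest.fixture()
    def gtf(self, tmp_path):
        p = tmp_path / "genes.gtf"
        p.write_text(GTF)
        return p

    def test_gene_spans_and_quoting(self, gtf):
        genes = load_gene_annotations(gtf)
        g1 = genes.set_index("gene_id").loc["g1"]
        assert (g1["start"], g1["end"], g1["gene_name"]) == (100, 500, "Alpha")
        assert "g2" in genes["gene_id"].tolist()  # unquoted attribute accepted

    def test_single_overlap_both_overlaps_and_intergenic(self, gtf):
        sites = pd.DataFrame(
            [_site(150, 5, 5.0), _site(450, 5, 5.0), _site(901, 5, 5.0)]
        )
        out = annotate_sites(sites, gtf)
        by_pos = out.groupby("pos")["gene_id"].apply(sorted).to_dict()
        assert by_pos[150] == ["g1"]
        assert by_pos[450] == ["g1", "g2"]  # overlapping genes both reported
        assert by_pos[901] == ["none"]  # 1 bp outside g2's span

    def test_missing_gene_id_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tsrc\tgene\t1\t10\t.\t+\t.\ttranscript_id "t1";\n')
        with pytest.raises(ValueError, match="gene_id"):
            load_gene_annotations(p)
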