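"""Variant filtering, parental subtraction, parallelism, and I/O round-trips."""

import itertools
import textwrap

import numpy as np
import pytest

from evofit.simulate import VariantSimParams, simulate_variant_tables
from evofit.variants import (
    VariantRecord,
    filter_by_frequency,
    normalize_variant,
    parallel_genes,
    read_variants,
    subtract_parental,
    venn_regions,
    write_variants,
)


def rec(chrom="chrI", pos=100, ref="A", alt="T", freq=1.0, gene="GENE1", clone="c1"):
    return VariantRecord(chrom, pos, ref, alt, freq, gene, "missense", clone)


class TestNormalize:
    def test_snv_unchanged(self):
        r = rec()
        assert normalize_variant(r) is r

    def test_suffix_then_prefix_trim_advances_position(self):
        # CAG>CTG at 100: suffix G trimmed, prefix C trimmed -> A>T at 101
        r = rec(ref="CAG", alt="CTG")
        n = normalize_variant(r)
        assert (n.pos, n.ref_allele, n.alt_allele) == (101, "A", "T")

    def test_padded_insertion_minimalised(self):
        # ATT>ATTT == AT>ATT after suffix trim keeps one anchor base
        a = rec(ref="AT", alt="ATT")
        b = rec(ref="ATT", alt="ATTT")
        assert a.key() == b.key()

    def test_distinct_alleles_stay_distinct(self):
        assert rec(alt="T").key() != rec(alt="G").key()


class TestFrequencyFilter:
    def test_cutoff_is_inclusive(self):
        vs = [rec(pos=p, freq=f) for p, f in ((1, 0.49), (2, 0.50), (3, 0.99))]
        kept = filter_by_frequency(vs)
        assert [v.frequency for v in kept] == [0.50, 0.99]

    def test_empty_and_fixed_inputs(self):
        assert filter_by_frequency([]) == []
        vs = [rec(pos=p, freq=1.0) for p in range(1, 6)]
        assert filter_by_frequency(vs) == vs

    def test_size_non_increasing_in_threshold(self):
        rng = np.random.default_rng(7)
        vs = [rec(pos=i + 1, freq=float(f)) for i, f in enumerate(rng.random(50))]
        sizes = [len(filter_by_frequency(vs, t)) for t in np.linspace(0, 1, 11)]
        assert sizes == sorted(sizes, reverse=True)


def brute_force_subtract(child, parental, position_only=False):
    """Independent oracle: quadratic scan over normalised records."""
    out = []
    for c in child:
        cn = normalize_variant(c)
        hit = False
        for p in parental:
            pn = normalize_variant(p)
            same_site = (cn.chrom, cn.pos) == (pn.chrom, pn.pos)
            same_allele = (cn.ref_allele, cn.alt_allele) == (pn.ref_allele, pn.alt_allele)
            if same_site and (position_only or same_allele):
                hit = True
                break
        if not hit:
            out.append(c)
    return out


class TestSubtractParental:
    def test_identity_and_annihilation(self):
        child = [rec(pos=p) for p in (10, 20, 30)]
        assert subtract_parental(child, []) == child
        assert subtract_parental(child, child) == []

    def test_idempotent(self):
        child = [rec(pos=p) for p in (10, 20, 30, 40)]
        parental = [rec(pos=20), rec(pos=40)]
        once = subtract_parental(child, parental)
        assert subtract_parental(once, parental) == once

    def test_alt_mismatch_is_retained(self):
        """Same site, different alt: not a parental polymorphism."""
        child = [rec(pos=p, alt="T") for p in range(1, 11)]
        parental = [rec(pos=p, alt="T") for p in range(1, 8)] + [rec(pos=8, alt="G")]
        kept = subtract_parental(child, parental)
        assert len(kept) == 3
        assert {v.pos for v in kept} == {8, 9, 10}
        # position-only mode drops the co-located distinct allele too
        assert len(subtract_parental(child, parental, position_only=True)) == 2

    def test_unknown_contig_policy(self):
        child = [rec(chrom="chrX")]
        parental = [rec(chrom="chrI", pos=999)]
        with pytest.raises(ValueError, match="chrX"):
            subtract_parental(child, parental, on_unknown_contig="error")
        assert subtract_parental(child, parental, on_unknown_contig="ignore") == child

    @pytest.mark.parametrize("position_only", [False, True])
    def test_matches_brute_force_oracle_on_random_tables(self, position_only):
        """200 random parent/child tables incl. padded-indel spellings."""
        rng = np.random.default_rng(42)
        spellings = [
            ("A", "T"), ("A", "G"), ("CAG", "CTG"), ("AT", "ATT"),
            ("ATT", "ATTT"), ("GCC", "GC"), ("TGCC", "TGC"),
        ]
        for _ in range(200):
            def table(n):
                return [
                    VariantRecord(
                        chrom=f"chr{int(rng.integers(1, 4))}",
                        pos=int(rng.integers(1, 30)),
                        ref_allele=s[0],
                        alt_allele=s[1],
                    )
                    for s in (spellings[int(i)] for i in rng.integers(0, len(spellings), n))
                ]
            child, parental = table(int(rng.integers(1, 15))), table(int(rng.integers(0, 15)))
            got = subtract_parental(child, parental,
                                    position_only=position_only, on_unknown_contig="ignore")
            want = brute_force_subtract(child, parental, position_only)
            assert got == want

    def test_recovers_planted_de_novo_set(self):
        parental, child, truth = simulate_variant_tables(
            VariantSimParams(n_parental_polymorphisms=500, n_de_novo=12, seed=3)
        )
        got = subtract_parental(child, parental)
        assert len(got) == 12
        assert {v.key() for v in got} == {v.key() for v in truth}


class TestParallelGenes:
    def _clones(self):
        return {
            "P1c": [rec(gene="ATH1", clone="P1c"), rec(pos=2, gene="CYR1", clone="P1c")],
            "P2c": [rec(gene="ATH1", clone="P2c"), rec(pos=3, gene="CYR1", clone="P2c")],
            "P3c": [rec(gene="ATH1", clone="P3c"), rec(pos=4, gene="PTR2", clone="P3c")],
            "P4c": [rec(pos=5, gene="PTR2", clone="P4c"), rec(pos=6, gene="BUD3", clone="P4c")],
        }

    def test_three_way_intersection_member(self):
        gene_to_clones, parallel = parallel_genes(self._clones())
        assert gene_to_clones["ATH1"] == frozenset({"P1c", "P2c", "P3c"})
        assert set(parallel) == {"ATH1", "CYR1", "PTR2"}

    def test_disjoint_gene_sets_have_no_parallelism(self):
        clones = {"a": [rec(gene="G1")], "b": [rec(pos=2, gene="G2")]}
        _, parallel = parallel_genes(clones)
        assert parallel == {}

    def test_intergenic_excluded_by_default(self):
        clones = {"a": [rec(gene="intergenic")], "b": [rec(pos=2, gene="intergenic")]}
        gene_to_clones, _ = parallel_genes(clones)
        assert gene_to_clones == {}
        gene_to_clones, _ = parallel_genes(clones, include_intergenic=True)
        assert gene_to_clones["intergenic"] == frozenset({"a", "b"})

    def test_single_clone_rejected(self):
        with pytest.raises(ValueError):
            parallel_genes({"only": [rec()]})

    def test_venn_regions_match_exhaustive_enumeration(self):
        """Region counts equal brute-force enumeration over all 2^4-1 patterns."""
        rng = np.random.default_rng(11)
        clone_ids = ["c1", "c2", "c3", "c4"]
        genes = [f"G{i}" for i in range(30)]
        membership = {g: {c for c in clone_ids if rng.random() < 0.4} for g in genes}
        membership = {g: m for g, m in membership.items() if m}
        clones = {c: [] for c in clone_ids}
        pos = itertools.count(1)
        for g, members in membership.items():
            for c in members:
                clones[c].append(rec(pos=next(pos), gene=g, clone=c))
        gene_to_clones, _ = parallel_genes(clones)
        regions = venn_regions(gene_to_clones)
        # oracle: count genes per pattern over every non-empty clone subset
        for r in range(1, 5):
            for subset in itertools.combinations(clone_ids, r):
                expected = {g for g, m in membership.items() if m == set(subset)}
                got = regions.get(frozenset(subset), set())
                assert got == expected
        assert sum(len(v) for v in regions.values()) == len(membership)


MINI_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chrI,length=230218>
    ##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    chrI\t100\t.\tA\tT\t.\t.\tAF=0.98;GENE=ATH1
    chrI\t250\t.\tG\tC,A\t.\t.\tAF=0.60,0.35;GENE=CYR1
    """
)


class TestIO:
    def test_vcf_multiallelic_rows_split(self, tmp_path):
        path = tmp_path / "mini.vcf"
        path.write_text(MINI_VCF)
        records = read_variants(path, clone_id="P1c")
        assert len(records) == 3
        biallelic = [r for r in records if r.pos == 250]
        got = sorted((r.alt_allele, r.frequency) for r in biallelic)
        assert [a for a, _ in got] == ["A", "C"]
        assert [f for _, f in got] == pytest.approx([0.35, 0.6], abs=1e-6)
        assert all(r.clone_id == "P1c" for r in records)

    def test_vcf_without_frequency_source_errors(self, tmp_path):
        path = tmp_path / "noaf.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chrI>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\nchrI\t5\t.\tA\tT\t.\t.\t.\n"
        )
        with pytest.raises(ValueError, match="AF"):
            read_variants(path)

    def test_tsv_round_trip_exact(self, tmp_path):
        _, child, _ = simulate_variant_tables(VariantSimParams(n_parental_polymorphisms=20, n_de_novo=5, seed=1))
        path = tmp_path / "child.tsv"
        write_variants(child, path)
        assert read_variants(path) == child

    def test_malformed_tsv_strict_names_line_lenient_skips(self, tmp_path):
        lines = ["chrom\tpos\tref\talt\tfrequency\tgene\teffect\tclone_id"]
        for i in range(1, 6):
            pos = "oops" if i == 3 else str(i * 10)
            lines.append(f"chrI\t{pos}\tA\tT\t1.0\tG{i}\tmissense\tc1")
        path = tmp_path / "t.tsv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 4"):
            read_variants(path, strict=True)
        records = read_variants(path, strict=False)
        assert len(records) == 4

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\n")
        with pytest.raises(ValueError, match="ref"):
            read_variants(path)
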