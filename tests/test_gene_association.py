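import numpy as np
import pandas as pd
import pytest

from fourc_rdna.contact_calling import ContactFragment
from fourc_rdna.gene_association import (
    AssociationParams,
    RegionClassAnnotation,
    build_count_matrix,
    classify_contact_sites,
    count_reads_per_gene,
    extend_fragment,
    filter_viewpoint_proximity,
    log2fc_table,
    select_contact_genes,
)
from fourc_rdna.io_genomics import GeneRecord, GenomicInterval


def _frag(s, e, n1, n2, chrom="chr1", fid=""):
    return ContactFragment(
        GenomicInterval(chrom, s, e), {"rep1": n1, "rep2": n2}, (n1 + n2) / 2, fid
    )


def _gene(gid, s, e, chrom="chr1"):
    return GeneRecord(gid, gid, GenomicInterval(chrom, s, e))


class TestExtendFragment:
    def test_symmetric_extension(self):
        ext = extend_fragment(_frag(10_000, 10_400, 1, 1), 2500, 10**7)
        assert (ext.start, ext.end) == (7_500, 12_900)

    def test_clipped_at_chromosome_bounds(self):
        ext = extend_fragment(_frag(1_000, 1_200, 1, 1), 2500, 3_700)
        assert (ext.start, ext.end) == (0, 3_700)

    def test_zero_extension_identity(self):
        ext = extend_fragment(_frag(500, 600, 1, 1), 0, 10**6)
        assert (ext.start, ext.end) == (500, 600)

    def test_fixed_window_semantics(self):
        ext = extend_fragment(_frag(10_000, 10_400, 1, 1), 2500, 10**7, fixed_window=True)
        assert ext.end - ext.start == 5000
        assert (ext.start + ext.end) // 2 == 10_200


class TestViewpointFilter:
    def test_within_radius_excluded(self):
        frags = [_frag(4_000_000, 4_001_000, 50, 50)]  # 1 Mb from viewpoint
        kept, excluded = filter_viewpoint_proximity(frags, [("chr1", 5_000_000)], 5_000_000)
        assert not kept and len(excluded) == 1

    def test_other_chromosome_kept(self):
        frags = [_frag(5_000_000, 5_001_000, 50, 50, chrom="chr9")]
        kept, excluded = filter_viewpoint_proximity(frags, [("chr1", 5_000_000)], 5_000_000)
        assert len(kept) == 1 and not excluded

    def test_zero_radius_excludes_only_covering_fragment(self):
        vp = [("chr1", 1000)]
        covering = _frag(990, 1010, 1, 1)
        nearby = _frag(1011, 1020, 1, 1)
        kept, excluded = filter_viewpoint_proximity([covering, nearby], vp, 0)
        assert excluded == [covering] and kept == [nearby]

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        frags = [
            _frag(int(s), int(s) + 100, 1, 1, chrom=f"chr{c}")
            for s, c in zip(rng.integers(0, 10**7, 100), rng.integers(1, 4, 100))
        ]
        kept, excluded = filter_viewpoint_proximity(frags, [("chr1", 5_000_000)], 10**6)
        assert len(kept) + len(excluded) == len(frags)
        assert {id(f) for f in kept}.isdisjoint({id(f) for f in excluded})


def brute_force_counts(frags, genes, extension, chrom_len):
    """Quadratic per-(fragment, gene) oracle."""
    totals = {}
    for f in frags:
        lo = max(0, f.interval.start - extension)
        hi = min(chrom_len, f.interval.end + extension)
        for g in genes:
            if g.interval.chrom == f.interval.chrom and g.interval.start < hi and lo < g.interval.end:
                totals[g.gene_id] = totals.get(g.gene_id, 0) + f.total_reads
    return totals


class TestCountReadsPerGene:
    def test_fragment_counts_toward_every_overlapped_gene(self):
        frag = _frag(10_000, 10_500, 60, 50)
        genes = [_gene("A", 8_000, 9_000), _gene("B", 11_000, 12_000)]
        counts = {c.gene_id: c.total_reads for c in count_reads_per_gene([frag], genes, chrom_lengths={"chr1": 10**6})}
        assert counts == {"A": 110, "B": 110}

    def test_gene_beyond_extension_not_associated(self):
        frag = _frag(10_000, 10_500, 60, 50)
        gene = _gene("far", 13_500, 14_000)  # 3,000 nt downstream > 2,500
        assert count_reads_per_gene([frag], [gene], chrom_lengths={"chr1": 10**6}) == []

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n_f, n_g = int(rng.integers(1, 100)), int(rng.integers(1, 100))
            frags = [
                _frag(int(s), int(s) + int(l), int(a), int(b), fid=f"f{i}")
                for i, (s, l, a, b) in enumerate(
                    zip(
                        rng.integers(0, 80_000, n_f),
                        rng.integers(1, 2_000, n_f),
                        rng.integers(1, 80, n_f),
                        rng.integers(1, 80, n_f),
                    )
                )
            ]
            genes = [
                _gene(f"g{i}", int(s), int(s) + int(l))
                for i, (s, l) in enumerate(
                    zip(rng.integers(0, 80_000, n_g), rng.integers(100, 5_000, n_g))
                )
            ]
            got = {
                c.gene_id: c.total_reads
                for c in count_reads_per_gene(frags, genes, chrom_lengths={"chr1": 10**6})
            }
            assert got == brute_force_counts(frags, genes, 2500, 10**6)

    def test_extension_monotonicity(self):
        rng = np.random.default_rng(4)
        frags = [
            _frag(int(s), int(s) + 200, 10, 10)
            for s in rng.integers(0, 50_000, 30)
        ]
        genes = [_gene(f"g{i}", int(s), int(s) + 1000) for i, s in enumerate(rng.integers(0, 50_000, 30))]
        prev: dict = {}
        for ext in [0, 500, 2500, 10_000]:
            params = AssociationParams(extension_nt=ext)
            got = {
                c.gene_id: c.total_reads
                for c in count_reads_per_gene(frags, genes, params, {"chr1": 10**6})
            }
            for gid, t in prev.items():
                assert got.get(gid, 0) >= t
            prev = got


class TestSelectContactGenes:
    def _counts(self, totals):
        from fourc_rdna.gene_association import GeneContactCount

        return [GeneContactCount(g, t) for g, t in totals.items()]

    def test_threshold_is_strict(self):
        sel = select_contact_genes(self._counts({"A": 110, "B": 100, "C": 101}), 100)
        assert [c.gene_id for c in sel] == ["A", "C"]  # B: 100 does not exceed 100

    def test_ranking_and_ties(self):
        sel = select_contact_genes(self._counts({"b": 200, "a": 200, "z": 300}), 100)
        assert [c.gene_id for c in sel] == ["z", "a", "b"]

    def test_zero_threshold_and_empty(self):
        assert len(select_contact_genes(self._counts({"A": 1, "B": 5}), 0)) == 2
        assert select_contact_genes([], 100) == []

    def test_threshold_monotonicity(self):
        counts = self._counts({f"g{i}": i * 7 for i in range(40)})
        prev = None
        for t in [0, 50, 100, 200]:
            sel = {c.gene_id for c in select_contact_genes(counts, t)}
            if prev is not None:
                assert sel <= prev
            prev = sel


class TestCountMatrix:
    def test_column_sums_conserve_sample_reads(self):
        genes = [_gene("A", 1_000, 2_000), _gene("B", 50_000, 51_000)]
        frags = {
            "s1": [_frag(1_200, 1_400, 30, 0, fid="f1")],
            "s2": [_frag(1_100, 1_300, 0, 45, fid="f1"), _frag(50_100, 50_200, 5, 5, fid="f2")],
            "s3": [],
        }
        m = build_count_matrix(frags, genes, chrom_lengths={"chr1": 10**6})
        df = m.to_frame()
        assert df["s1"].sum() == 30 and df["s2"].sum() == 55
        assert (df["s3"] == 0).all()

    def test_log2fc_identical_conditions_zero(self):
        genes = [_gene("A", 1_000, 2_000)]
        frags = {
            "c_r1": [_frag(1_000, 1_200, 40, 0)],
            "h_r1": [_frag(1_000, 1_200, 40, 0)],
        }
        m = build_count_matrix(frags, genes, chrom_lengths={"chr1": 10**6})
        fc = log2fc_table(m, {"c_r1": "ctrl", "h_r1": "hs"})
        assert fc["log2fc"].abs().max() == 0.0

    def test_log2fc_arithmetic(self):
        genes = [_gene("A", 1_000, 2_000), _gene("B", 9_000, 9_500)]
        frags = {
            "c": [_frag(1_000, 1_200, 100, 0), _frag(9_000, 9_100, 100, 0)],
            "h": [_frag(1_000, 1_200, 400, 0), _frag(9_000, 9_100, 100, 0)],
        }
        m = build_count_matrix(frags, genes, chrom_lengths={"chr1": 10**6})
        # equal library normalization off, zero pseudocount: 400/100 -> 2.0
        fc = log2fc_table(m, {"c": "c", "h": "h"}, pseudocount=0, normalize=False)
        assert fc.loc["A", "log2fc"] == pytest.approx(2.0)

    def test_single_condition_rejected(self):
        genes = [_gene("A", 0, 100)]
        m = build_count_matrix({"s1": []}, genes, chrom_lengths={"chr1": 10**6})
        with pytest.raises(ValueError):
            log2fc_table(m, {"s1": "only"})


class TestClassifyContactSites:
    def _annotation(self):
        return RegionClassAnnotation(
            (
                ("exon", (GenomicInterval("chr1", 100, 200),)),
                ("LINE", (GenomicInterval("chr1", 150, 400),)),
            )
        )

    def test_precedence(self):
        assert self._annotation().classify("chr1", 160) == "exon"
        assert self._annotation().classify("chr1", 250) == "LINE"

    def test_fallback_intergenic(self):
        assert self._annotation().classify("chr1", 5000) == "intergenic"
        assert self._annotation().classify("chr2", 160) == "intergenic"

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        centers = [("chr1", int(p)) for p in rng.integers(0, 1000, 100)]
        comp = classify_contact_sites(centers, self._annotation())
        assert sum(comp.values()) == pytest.approx(1.0)
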