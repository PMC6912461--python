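import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from fourc_rdna.contact_calling import (
    CallingParams,
    ContactFragment,
    MergedFragment,
    call_contacts,
    intersect_replicates,
    merge_overlapping_reads,
    score_and_filter,
)
from fourc_rdna.io_genomics import GenomicInterval, ReadAlignment


def _reads(spans, chrom="chr1", rep=""):
    return [
        ReadAlignment(GenomicInterval(chrom, s, e), f"r{i}", rep)
        for i, (s, e) in enumerate(spans)
    ]


def brute_force_merge(reads):
    """Independent oracle: pairwise-overlap graph + connected components."""
    if not reads:
        return []
    out = []
    by_chrom = {}
    for r in reads:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = by_chrom[chrom]
        n = len(rs)
        s = np.array([r.interval.start for r in rs])
        e = np.array([r.interval.end for r in rs])
        adj = (s[:, None] < e[None, :]) & (s[None, :] < e[:, None])
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for c in range(n_comp):
            idx = np.flatnonzero(labels == c)
            out.append(
                (chrom, int(s[idx].min()), int(e[idx].max()), int(sum(rs[i].weight for i in idx)))
            )
    return sorted(out)


class TestMerge:
    def test_one_nucleotide_intersection_merges(self):
        frags = merge_overlapping_reads(_reads([(100, 150), (149, 200), (300, 350)]))
        assert [(f.interval.start, f.interval.end, f.n_reads) for f in frags] == [
            (100, 200, 2),
            (300, 350, 1),
        ]

    def test_bookended_reads_stay_separate(self):
        frags = merge_overlapping_reads(_reads([(100, 150), (150, 200)]))
        assert len(frags) == 2
        # opt-in flag flips the behaviour
        assert len(merge_overlapping_reads(_reads([(100, 150), (150, 200)]), merge_bookended=True)) == 1

    def test_empty_input(self):
        assert merge_overlapping_reads([]) == []

    def test_matches_brute_force_on_random_reads(self):
        rng = np.random.default_rng(7)
        reads = []
        for i in range(500):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 50_000))
            reads.append(
                ReadAlignment(GenomicInterval(chrom, s, s + int(rng.integers(1, 400))), f"r{i}")
            )
        ours = sorted(
            (f.interval.chrom, f.interval.start, f.interval.end, f.n_reads)
            for f in merge_overlapping_reads(reads)
        )
        assert ours == brute_force_merge(reads)


class TestIntersectReplicates:
    def _frag(self, s, e, n, rep, chrom="chr1"):
        return MergedFragment(GenomicInterval(chrom, s, e), n, rep)

    def test_union_of_overlapping_spans(self):
        (cand,) = intersect_replicates(
            [self._frag(100, 200, 30, "rep1")], [self._frag(150, 250, 60, "rep2")]
        )
        assert (cand.interval.start, cand.interval.end) == (100, 250)
        assert cand.reads_per_replicate == {"rep1": 30, "rep2": 60}
        assert cand.mean_coverage == 45.0

    def test_single_replicate_fragment_dropped(self):
        assert intersect_replicates([self._frag(0, 100, 50, "rep1")], []) == []
        assert (
            intersect_replicates(
                [self._frag(0, 100, 50, "rep1")], [self._frag(500, 600, 50, "rep2")]
            )
            == []
        )

    def test_chained_overlap_forms_single_candidate(self):
        # rep1 A overlaps rep2 B; B overlaps rep1 C -> one candidate A∪B∪C
        (cand,) = intersect_replicates(
            [self._frag(0, 100, 10, "rep1"), self._frag(150, 250, 20, "rep1")],
            [self._frag(90, 160, 5, "rep2")],
        )
        assert (cand.interval.start, cand.interval.end) == (0, 250)
        assert cand.reads_per_replicate == {"rep1": 30, "rep2": 5}

    def test_identical_labels_rejected(self):
        with pytest.raises(ValueError):
            intersect_replicates([], [], rep1_label="a", rep2_label="a")

    def test_matches_bipartite_component_oracle(self):
        rng = np.random.default_rng(3)
        def random_merged(rep):
            reads = [
                ReadAlignment(
                    GenomicInterval("chr1", int(s), int(s) + int(l)), f"{rep}{i}", rep
                )
                for i, (s, l) in enumerate(
                    zip(rng.integers(0, 30_000, 150), rng.integers(1, 600, 150))
                )
            ]
            return merge_overlapping_reads(reads)

        f1, f2 = random_merged("rep1"), random_merged("rep2")
        ours = intersect_replicates(f1, f2)
        # oracle: connected components of the full overlap graph
        all_frags = [(f, "rep1") for f in f1] + [(f, "rep2") for f in f2]
        s = np.array([f.interval.start for f, _ in all_frags])
        e = np.array([f.interval.end for f, _ in all_frags])
        adj = (s[:, None] < e[None, :]) & (s[None, :] < e[:, None])
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        expected = []
        for c in range(n_comp):
            idx = np.flatnonzero(labels == c)
            reps = {all_frags[i][1] for i in idx}
            if reps == {"rep1", "rep2"}:
                counts = {"rep1": 0, "rep2": 0}
                for i in idx:
                    counts[all_frags[i][1]] += all_frags[i][0].n_reads
                expected.append((int(s[idx].min()), int(e[idx].max()), counts["rep1"], counts["rep2"]))
        got = sorted(
            (c.interval.start, c.interval.end, c.reads_per_replicate["rep1"], c.reads_per_replicate["rep2"])
            for c in ours
        )
        assert got == sorted(expected)


class TestScoreAndFilter:
    def _cand(self, n1, n2):
        return ContactFragment(
            GenomicInterval("chr1", 0, 100), {"rep1": n1, "rep2": n2}, (n1 + n2) / 2
        )

    def test_threshold_is_inclusive_mean_of_replicates(self):
        kept = score_and_filter([self._cand(50, 34), self._cand(50, 20)], CallingParams())
        assert len(kept) == 1 and kept[0].mean_coverage == 42.0
        # exactly at threshold is retained
        assert len(score_and_filter([self._cand(40, 40)], CallingParams())) == 1

    def test_zero_threshold_keeps_all(self):
        cands = [self._cand(1, 1), self._cand(100, 2)]
        assert len(score_and_filter(cands, CallingParams(min_mean_coverage=0))) == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        cands = [self._cand(int(a), int(b)) for a, b in rng.integers(1, 120, (50, 2))]
        prev = None
        for t in [0, 10, 40, 80, 200]:
            kept = {
                (c.interval.start, c.mean_coverage)
                for c in score_and_filter(cands, CallingParams(min_mean_coverage=t))
            }
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestCallContacts:
    def test_empty_and_singleton_inputs_give_no_contacts(self):
        assert call_contacts({"rep1": [], "rep2": []}) == []
        noise = {
            "rep1": _reads([(100, 250)], rep="rep1"),
            "rep2": _reads([(5000, 5150)], rep="rep2"),
        }
        assert call_contacts(noise) == []

    def test_two_replicates_required(self):
        with pytest.raises(ValueError, match="two replicates"):
            call_contacts({"rep1": []})

    def test_fragment_ids_deterministic_sorted(self):
        reads = {
            "rep1": _reads([(100, 300)] * 50 + [(9000, 9200)] * 50, rep="rep1"),
            "rep2": _reads([(200, 400)] * 50 + [(9100, 9300)] * 50, rep="rep2"),
        }
        frags = call_contacts(reads)
        assert [f.fragment_id for f in frags] == ["frag00001", "frag00002"]
        assert frags[0].interval.start < frags[1].interval.start

    def test_read_conservation_through_merge(self):
        rng = np.random.default_rng(9)
        spans = [(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 10_000, 200), rng.integers(1, 300, 200))]
        merged = merge_overlapping_reads(_reads(spans))
        assert sum(f.n_reads for f in merged) == 200
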