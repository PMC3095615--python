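import numpy as np
import pytest

from mirseek.genome_scan import (
    GenomeHit, LocusSet, excise_windows, filter_repeats, map_tags,
)
from mirseek.io import revcomp
from mirseek.preprocess import UniqueTag


def numpy_sliding_window_hits(genome: dict, tag: str):
    """Independent oracle: vectorised window-equality scan on both strands."""
    hits = set()
    k = len(tag)
    tag_arr = np.frombuffer(tag.encode(), dtype=np.uint8)
    rc_arr = np.frombuffer(revcomp(tag).encode(), dtype=np.uint8)
    for name, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        for pos in np.nonzero((windows == tag_arr).all(axis=1))[0]:
            hits.add((name, int(pos) + 1, "+"))
        for pos in np.nonzero((windows == rc_arr).all(axis=1))[0]:
            if tag == revcomp(tag) and (name, int(pos) + 1, "+") in hits:
                continue
            hits.add((name, int(pos) + 1, "-"))
    return hits


class TestMapTags:
    GENOME = {"s1": "AAAA" + "ACGGTTCAGGCATTACGGATCAC" + "TTTT"}
    TAG = "ACGGTTCAGGCATTACGGATCAC"

    def test_single_plus_strand_hit(self):
        (ls,) = map_tags([UniqueTag(self.TAG, 1)], self.GENOME)
        assert ls.n_loci == 1
        hit = ls.hits[0]
        assert (hit.scaffold, hit.start, hit.end, hit.strand) == ("s1", 5, 27, "+")

    def test_tag_and_revcomp_planted_give_opposite_strands(self):
        genome = {"s1": "AA" + self.TAG + "CCGG" + revcomp(self.TAG) + "TT"}
        (ls,) = map_tags([UniqueTag(self.TAG, 1)], genome)
        assert ls.n_loci == 2
        assert sorted(h.strand for h in ls.hits) == ["+", "-"]

    def test_matches_sliding_window_oracle(self, rng):
        bases = np.array(list("ACGT"))
        genome = {
            f"s{i}": "".join(rng.choice(bases, size=3000)) for i in range(3)
        }
        tags = []
        for _ in range(60):
            if rng.random() < 0.5:  # genome-derived, guaranteed hits
                seq = genome[f"s{rng.integers(3)}"]
                pos = rng.integers(0, len(seq) - 24)
                t = seq[pos : pos + 24]
                if rng.random() < 0.5:
                    t = revcomp(t)
            else:
                t = "".join(rng.choice(bases, size=20))
            tags.append(t)
        tags = [UniqueTag(t, 1) for t in sorted(set(tags))]
        for ls in map_tags(tags, genome):
            got = {(h.scaffold, h.start, h.strand) for h in ls.hits}
            assert got == numpy_sliding_window_hits(genome, ls.tag.seq)

    def test_strand_symmetry_under_genome_revcomp(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=2000))
        genome_f = {"s": seq}
        genome_r = {"s": revcomp(seq)}
        tag = UniqueTag(seq[100:124], 1)
        fwd = map_tags([tag], genome_f)[0]
        rev = map_tags([tag], genome_r)[0]
        assert fwd.n_loci == rev.n_loci
        mirrored = {
            (h.scaffold, len(seq) - h.end + 1, {"+": "-", "-": "+"}[h.strand])
            for h in fwd.hits
        }
        assert mirrored == {(h.scaffold, h.start, h.strand) for h in rev.hits}


class TestFilterRepeats:
    def _locus_set(self, n_loci):
        tag = UniqueTag("A" * 10 + "C" * 14, 1)
        hits = tuple(
            GenomeHit(tag, "s1", 100 * i + 1, 100 * i + 24, "+") for i in range(n_loci)
        )
        return LocusSet(tag, hits)

    def test_51_loci_excluded_50_kept(self):
        kept, excluded = filter_repeats([self._locus_set(51), self._locus_set(50)])
        assert [ls.n_loci for ls in kept] == [50]
        assert [ls.n_loci for ls in excluded] == [51]

    def test_partition_is_exact(self):
        sets = [self._locus_set(n) for n in (1, 50, 51, 60)]
        kept, excluded = filter_repeats(sets)
        assert sorted(kept + excluded, key=id) == sorted(sets, key=id)
        assert not (set(map(id, kept)) & set(map(id, excluded)))

    def test_synthetic_repeat_family_fully_excluded(self, small_bundle):
        from mirseek.preprocess import collapse, length_filter

        _, genome, truth, reads = small_bundle
        tags = length_filter(collapse(reads))
        _, excluded = filter_repeats(map_tags(tags, genome))
        excluded_seqs = {ls.tag.seq for ls in excluded}
        assert {s for s, _ in truth.repeat.tags} <= excluded_seqs


class TestExciseWindows:
    def test_window_clipped_at_scaffold_start(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=400))
        tag = seq[5:29]
        hit = GenomeHit(UniqueTag(tag, 1), "s", 6, 29, "+")
        windows = excise_windows(hit, {"s": seq}, flank_lengths=[100])
        assert all(w.start >= 1 for w in windows)
        assert any(w.start == 1 for w in windows)

    def test_tag_verbatim_in_every_window(self, small_bundle):
        _, genome, truth, _ = small_bundle
        for mir in truth.mirs[:4]:
            (ls,) = map_tags([UniqueTag(mir.mature_seq, 1)], genome)
            for hit in ls.hits:
                for w in excise_windows(hit, genome):
                    assert w.seq[w.tag_offset : w.tag_offset + len(mir.mature_seq)] \
                        == mir.mature_seq

    def test_minus_strand_window_contains_tag_not_complement(self, rng):
        bases = np.array(list("ACGT"))
        tag = "ACCGTTAGGCATCCATGGTCAAGT"
        seq = "".join(rng.choice(bases, size=200)) + revcomp(tag) + \
            "".join(rng.choice(bases, size=200))
        (ls,) = map_tags([UniqueTag(tag, 1)], {"s": seq})
        (hit,) = ls.hits
        assert hit.strand == "-"
        for w in excise_windows(hit, {"s": seq}):
            assert tag in w.seq

    def test_planted_precursor_contained_in_some_window(self, small_bundle):
        _, genome, truth, _ = small_bundle
        for mir in truth.mirs:
            (ls,) = map_tags([UniqueTag(mir.mature_seq, 1)], genome)
            hit = next(h for h in ls.hits
                       if (h.scaffold, h.start) == (mir.scaffold_id, mir.start))
            precursor = mir.precursor_seq
            found = any(precursor in w.seq for h in ls.hits
                        for w in excise_windows(h, genome))
            assert found, f"no window holds the precursor of {mir.scaffold_id}:{mir.start}"

    def test_nonpositive_flank_rejected(self):
        hit = GenomeHit(UniqueTag("A" * 24, 1), "s", 1, 24, "+")
        with pytest.raises(ValueError):
            excise_windows(hit, {"s": "A" * 100}, flank_lengths=[0])
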