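"""Control-region element detection: repeats, hairpins, homopolymers, tiling."""
import numpy as np
import pytest

from mitokit.control_region import (HairpinHit, find_hairpins, find_homopolymers,
                                    find_tandem_repeats,
                                    hairpins_outside_repeats, partition_cr)

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_RC)[::-1]


def random_dna(rng, n, p=(0.31, 0.124, 0.168, 0.398)):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _pairs(x, y, allow_gu=True):
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    return (x, y) in wc or (allow_gu and (x, y) in gu)


def oracle_hairpins(seq, min_stem=4, loop_range=(3, 30), max_mismatches=0,
                    allow_gu=True):
    """Exhaustive all-placements scan: every (arm1 start, stem, loop) triple
    satisfying the hit predicate."""
    n = len(seq)
    lmin, lmax = loop_range
    hits = set()
    for a1 in range(n):
        for s in range(min_stem, n):
            for l in range(lmin, lmax + 1):
                a2 = a1 + s + l
                end = a2 + s
                if end > n:
                    break
                arm1 = seq[a1:a1 + s]
                arm2 = seq[a2:end]
                mism = sum(not _pairs(arm1[k], arm2[s - 1 - k], allow_gu)
                           for k in range(s))
                if mism > max_mismatches:
                    continue
                if not _pairs(arm1[0], arm2[-1], allow_gu):
                    continue  # outermost pair must pair
                if not _pairs(arm1[-1], arm2[0], allow_gu):
                    continue  # innermost pair must pair
                # outward maximality
                if a1 > 0 and end < n and _pairs(seq[a1 - 1], seq[end], allow_gu):
                    continue
                # inward maximality
                if l - 2 >= lmin and _pairs(seq[a1 + s], seq[a2 - 1], allow_gu):
                    continue
                hits.add((a1 + 1, s, l, mism))
    return hits


class TestHomopolymers:
    def test_simple_run(self):
        assert find_homopolymers("AATTTTA", "T", 3) == [(3, 4)]

    def test_no_run_long_enough(self):
        assert find_homopolymers("ATATAT", "T", 3) == []

    def test_run_at_end(self):
        assert find_homopolymers("ACGTTTT", "T", 4) == [(4, 4)]

    def test_planted_polyt_recovered_exactly(self, synthetic_cr, synthetic_genome):
        plan = synthetic_genome.spec.cr_plan
        runs = find_homopolymers(synthetic_cr, "T", 15)
        assert runs == [(plan.gc_region_len + 1, plan.polyt_len)]


class TestHairpins:
    def test_planted_perfect_hairpin(self):
        rng = np.random.default_rng(8)
        arm = "GCAGTCAGGC"
        hp = arm + "TTTCA" + revcomp(arm)
        left, right = random_dna(rng, 150), random_dna(rng, 150)
        seq = left + "C" + hp + "C" + right  # C flanks cannot pair with G/ G... guard
        hits = find_hairpins(seq, min_stem=8, loop_range=(3, 10))
        top = hits[0]
        assert top.span >= 25
        assert top.mismatches == 0
        planted = [h for h in hits if h.arm1_start == len(left) + 2 + 0
                   or h.span == 25]
        assert planted

    def test_homopolymer_has_no_hairpin(self):
        assert find_hairpins("AAAAAAAA", min_stem=4) == []

    def test_oracle_equality_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for trial in range(8):
            n = int(rng.integers(60, 200))
            seq = random_dna(rng, n)
            for max_mm in (0, 1):
                got = {(h.arm1_start, h.stem_len, h.loop_len, h.mismatches)
                       for h in find_hairpins(seq, min_stem=4, loop_range=(3, 12),
                                              max_mismatches=max_mm)}
                want = oracle_hairpins(seq, min_stem=4, loop_range=(3, 12),
                                       max_mismatches=max_mm)
                assert got == want, (trial, max_mm, seq)

    def test_min_stem_validated(self):
        with pytest.raises(ValueError):
            find_hairpins("ACGT", min_stem=2)


class TestTandemRepeats:
    def test_planted_exact_repeat(self):
        rng = np.random.default_rng(12)
        unit = "ACGTT"
        seq = random_dna(rng, 100) + unit * 4 + random_dna(rng, 100)
        hits = find_tandem_repeats(seq, (3, 20), min_copies=3, min_identity=0.9)
        spanning = [h for h in hits if h.period == 5 and h.copies >= 3.5]
        assert spanning, hits
        assert max(h.per_copy_identity[0] for h in spanning) == 1.0

    def test_random_sequence_negative_control(self):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 500)
        assert find_tandem_repeats(seq, (20, 100), 2, 0.9) == []

    def test_pmax_validated(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGTACGT", (2, 10))

    def test_planted_cr_arrays_recovered(self, synthetic_cr, synthetic_genome):
        plan = synthetic_genome.spec.cr_plan
        hits = find_tandem_repeats(synthetic_cr, (20, 150), 2, 0.8)
        periods = sorted(h.period for h in hits)
        assert periods == sorted([plan.long_repeat_period, plan.short_repeat_period])
        long_hit = next(h for h in hits if h.period == plan.long_repeat_period)
        short_hit = next(h for h in hits if h.period == plan.short_repeat_period)
        assert long_hit.copies == pytest.approx(plan.long_repeat_copies, abs=0.5)
        assert short_hit.copies == pytest.approx(plan.short_repeat_copies, abs=0.5)
        # the internally deleted third copy shows identity < 1
        assert min(short_hit.per_copy_identity) < 1.0
        assert short_hit.per_copy_identity[:2] == [1.0, 1.0]

    def test_recovery_of_planted_arrays_across_seeds(self):
        """Planted perfect arrays are recovered with period ±1, copies ±0.5."""
        rng = np.random.default_rng(99)
        recovered = 0
        trials = 40
        for _ in range(trials):
            p = int(rng.integers(3, 41))
            copies = int(rng.integers(2, 6))
            while True:
                unit = random_dna(rng, p)
                if len(set(unit)) > 1:
                    break
            seq = random_dna(rng, 120) + unit * copies + random_dna(rng, 120)
            hits = find_tandem_repeats(seq, (max(2, p - 5), p + 5),
                                       min_copies=2, min_identity=0.9)
            ok = any(abs(h.period - p) <= 1 and abs(h.copies - copies) <= 0.5
                     for h in hits)
            recovered += ok
        assert recovered == trials


class TestPartition:
    def test_hit_free_uniform_sequence_is_one_spacer(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 200)
        rep = partition_cr(seq)
        assert [s.cls for s in rep.segments] == ["spacer"]
        assert rep.segments[0].length == 200

    def test_whole_sequence_repeat_array(self):
        seq = "ACGTTA" * 20
        hits = find_tandem_repeats(seq, (3, 12), 2, 0.95)
        rep = partition_cr(seq, repeats=hits)
        assert [s.cls for s in rep.segments] == ["repeat-array"]

    def test_tiling_invariant(self, synthetic_cr):
        hits = find_tandem_repeats(synthetic_cr, (20, 150), 2, 0.8)
        hps = hairpins_outside_repeats(find_hairpins(synthetic_cr, min_stem=10), hits)
        pts = find_homopolymers(synthetic_cr, "T", 15)
        rep = partition_cr(synthetic_cr, repeats=hits, hairpins=hps[:1],
                           homopolymers=pts)
        assert sum(s.length for s in rep.segments) == len(synthetic_cr)
        for s1, s2 in zip(rep.segments, rep.segments[1:]):
            assert s2.start == s1.end + 1

    def test_five_part_plan_recovered(self, synthetic_cr):
        hits = find_tandem_repeats(synthetic_cr, (20, 150), 2, 0.8)
        hps = hairpins_outside_repeats(find_hairpins(synthetic_cr, min_stem=10), hits)
        pts = find_homopolymers(synthetic_cr, "T", 15)
        rep = partition_cr(synthetic_cr, repeats=hits, hairpins=hps[:1],
                           homopolymers=pts)
        element_classes = [s.cls for s in rep.segments if s.cls != "spacer"]
        assert element_classes == ["gc-elevated", "poly-T", "stem-loop",
                                   "repeat-array", "repeat-array"]
        # an intervening spacer separates the two repeat arrays
        idx = [i for i, s in enumerate(rep.segments) if s.cls == "repeat-array"]
        between = rep.segments[idx[0] + 1:idx[1]]
        assert any(s.cls == "spacer" and s.length > 80 for s in between)
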