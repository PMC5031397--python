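"""Paired-read processing: stripping, merging, screening, chimera flagging
and pooled-sample profiling."""

import numpy as np
import pytest

from minicoi import readpipe as rp
from minicoi.classify import train_bayes
from minicoi.primers import UNIVERSAL_TAIL_F, UNIVERSAL_TAIL_R, builtin_pair
from minicoi.seqcore import NucRecord, expand_degenerate, reverse_complement


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _pair(fwd_seq, rev_seq, fq=None, rq=None, rid="p1"):
    return rp.ReadPair(
        id=rid,
        fwd=NucRecord(id=rid, sequence=fwd_seq,
                      quality=fq or [30] * len(fwd_seq)),
        rev=NucRecord(id=rid, sequence=rev_seq,
                      quality=rq or [30] * len(rev_seq)))


@pytest.fixture(scope="module")
def pair_sites():
    fwd, rev = builtin_pair()
    return (fwd, rev,
            next(expand_degenerate(fwd.sequence)),
            next(expand_degenerate(rev.sequence)))


class TestStripPrimersTails:
    def test_tail_and_primer_removed_preserving_insert(self, pair_sites):
        fwd, rev, fsite, rsite = pair_sites
        rng = np.random.default_rng(0)
        insert = _rand_seq(rng, 60)
        read_f = UNIVERSAL_TAIL_F + fsite + insert
        read_r = UNIVERSAL_TAIL_R + rsite + reverse_complement(insert)
        stripped, reason = rp.strip_primers_tails(_pair(read_f, read_r), fwd, rev)
        assert reason is None
        assert stripped.fwd.sequence == insert
        assert stripped.rev.sequence == reverse_complement(insert)
        assert len(stripped.fwd.quality) == len(insert)

    def test_read_without_primer_rejected(self, pair_sites):
        fwd, rev, fsite, rsite = pair_sites
        rng = np.random.default_rng(1)
        read_f = _rand_seq(rng, 100)
        read_r = UNIVERSAL_TAIL_R + rsite + _rand_seq(rng, 60)
        stripped, reason = rp.strip_primers_tails(_pair(read_f, read_r), fwd, rev)
        assert stripped is None and reason == "no_primer_fwd"

    def test_small_offset_tolerated(self, pair_sites):
        fwd, rev, fsite, rsite = pair_sites
        rng = np.random.default_rng(2)
        insert = _rand_seq(rng, 50)
        read_f = "GT" + UNIVERSAL_TAIL_F + fsite + insert
        read_r = UNIVERSAL_TAIL_R + rsite + reverse_complement(insert)
        stripped, reason = rp.strip_primers_tails(_pair(read_f, read_r), fwd, rev)
        assert reason is None and stripped.fwd.sequence == insert


class TestMergePairs:
    def test_error_free_overlap_reconstructs_template(self):
        rng = np.random.default_rng(3)
        template = _rand_seq(rng, 150)
        fwd_read = template[:100]
        rev_read = reverse_complement(template[50:])
        merged = rp.merge_pairs(_pair(fwd_read, rev_read))
        assert merged is not None
        assert merged.sequence == template
        assert merged.overlap_length == 50
        assert merged.overlap_mismatches == 0

    def test_conflict_resolves_to_higher_quality_base(self):
        rng = np.random.default_rng(4)
        template = _rand_seq(rng, 120)
        conflict_pos = 60
        fwd_read = template[:80]
        mutated = list(template)
        mutated[conflict_pos] = {"A": "C", "C": "G",
                                 "G": "T", "T": "A"}[mutated[conflict_pos]]
        rev_read = reverse_complement("".join(mutated)[40:])
        fq = [40] * 80
        rq = [10] * 80
        merged = rp.merge_pairs(_pair(fwd_read, rev_read, fq=fq, rq=rq))
        assert merged.sequence[conflict_pos] == template[conflict_pos]  # Q40 wins
        assert merged.quality[conflict_pos] == 30  # |Q1 - Q2|
        agree_pos = 50
        assert merged.quality[agree_pos] == 45  # min(Q1+Q2, 45)

    def test_overlap_below_minimum_fails(self):
        rng = np.random.default_rng(5)
        template = _rand_seq(rng, 200)
        fwd_read = template[:100]
        rev_read = reverse_complement(template[190:])  # 10 nt overlap only
        assert rp.merge_pairs(_pair(fwd_read, rev_read), min_overlap=20) is None


class TestScreenDereplicate:
    def _merged(self, seq, rid):
        return rp.MergedRead(id=rid, sequence=seq, quality=[30] * len(seq),
                             overlap_length=30, overlap_mismatches=0)

    def test_ambiguous_removed_duplicates_collapse_lengths_screened(self):
        rng = np.random.default_rng(6)
        good = _rand_seq(rng, 154)
        reads = [self._merged(good, f"a{i}") for i in range(3)]
        reads.append(self._merged(good[:80] + "N" + good[81:], "amb"))
        reads.append(self._merged(good + _rand_seq(rng, 40), "long"))
        uniques, rejects = rp.screen_dereplicate(reads, expected_length=154)
        assert len(uniques) == 1
        assert uniques[0].abundance == 3 and uniques[0].rep_id == "a0"
        assert sorted(r[0] for r in rejects) == ["amb", "long"]
        assert dict(rejects)["amb"] == "ambiguous"

    def test_accounting_conserved(self):
        rng = np.random.default_rng(7)
        reads = [self._merged(_rand_seq(rng, 154), f"r{i}") for i in range(10)]
        reads += [self._merged(_rand_seq(rng, 200), "bad")]
        uniques, rejects = rp.screen_dereplicate(reads, expected_length=154)
        assert sum(u.abundance for u in uniques) + len(rejects) == len(reads)


class TestFlagChimeras:
    def _uniques(self):
        rng = np.random.default_rng(8)
        a = _rand_seq(rng, 202)
        b = _rand_seq(rng, 202)
        bimera = a[:100] + b[100:]
        return [rp.UniqueSeq(sequence=a, abundance=50, rep_id="A"),
                rp.UniqueSeq(sequence=b, abundance=40, rep_id="B"),
                rp.UniqueSeq(sequence=bimera, abundance=2, rep_id="X")]

    def test_constructed_bimera_flagged_with_correct_parents(self):
        flags = {f.rep_id: f for f in rp.flag_chimeras(self._uniques())}
        assert flags["X"].is_chimera
        assert set(flags["X"].parents) == {"A", "B"}

    def test_most_abundant_unique_never_flagged(self):
        flags = {f.rep_id: f for f in rp.flag_chimeras(self._uniques())}
        assert not flags["A"].is_chimera

    def test_clean_divergent_sequence_not_flagged(self):
        rng = np.random.default_rng(9)
        uniques = [rp.UniqueSeq(sequence=_rand_seq(rng, 202),
                                abundance=n, rep_id=f"u{i}")
                   for i, n in enumerate([50, 40, 2])]
        flags = rp.flag_chimeras(uniques)
        assert not any(f.is_chimera for f in flags)


class TestProfilePool:
    def test_single_species_pool_has_proportion_one(self, small_world,
                                                    trained_model):
        rec = small_world.library_inserts()[0]
        uniques = [rp.UniqueSeq(sequence=rec.sequence, abundance=120,
                                rep_id="u0")]
        profile = rp.profile_pool(uniques, trained_model)
        sp = rec.lineage.species
        assert profile.species_counts == {sp: 120}
        assert profile.detected == [sp]
        assert profile.proportions[sp] == 1.0

    def test_detection_rule_thresholds(self, small_world, trained_model):
        lib = small_world.library_inserts()
        a, b = lib[0], lib[-1]
        uniques = [
            rp.UniqueSeq(sequence=a.sequence, abundance=5000, rep_id="u0"),
            rp.UniqueSeq(sequence=b.sequence, abundance=4, rep_id="u1"),
        ]
        profile = rp.profile_pool(uniques, trained_model,
                                  detection=rp.DetectionRule(min_reads=10,
                                                             min_fraction=0.001))
        assert profile.detected == [a.lineage.species]  # b fails min_reads

    def test_detection_monotone_in_depth(self, small_world, trained_model):
        lib = small_world.library_inserts()
        a, b = lib[0], lib[-1]
        detected = []
        for depth in (1, 10, 100):
            uniques = [
                rp.UniqueSeq(sequence=a.sequence, abundance=900 * depth,
                             rep_id="u0"),
                rp.UniqueSeq(sequence=b.sequence, abundance=12 * depth,
                             rep_id="u1"),
            ]
            profile = rp.profile_pool(uniques, trained_model)
            detected.append(set(profile.detected))
        assert detected[0] <= detected[1] <= detected[2]


class TestEndToEnd:
    def test_zero_error_pool_reproduces_templates_exactly(self, small_world):
        from minicoi.synthdata import PoolSpec, simulate_pooled_reads
        model = train_bayes(small_world.library_inserts())
        species = small_world.species()
        mix = {species[0]: 0.5, species[3]: 0.3, species[6]: 0.2}
        pairs, truth = simulate_pooled_reads(
            small_world,
            PoolSpec(proportions=mix, n_pairs=600, quality=93, seed=17))
        fwd, rev = builtin_pair()
        profile, acct, flags = rp.run_pipeline(
            pairs, fwd, rev, model,
            expected_insert_length=small_world.insert_length)
        # conservation at every stage
        assert acct["input_pairs"] == (acct.get("strip_rejected", 0)
                                       + acct.get("merge_failed", 0)
                                       + acct["merged"])
        assert acct["merged"] == acct["screened_kept"] + acct["screen_rejected"]
        # with no sequencing error the counts equal the template draws and
        # nothing is flagged as chimeric
        assert acct.get("strip_rejected", 0) == 0
        assert acct["chimera_flagged"] == 0
        truth_counts = dict(zip(truth["source"], truth["n_reads"]))
        assert profile.species_counts == truth_counts
        assert profile.unclassified == 0
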