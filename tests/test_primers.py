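"""Degenerate primer scoring, scanning, in-silico PCR and design."""

import itertools

import numpy as np
import pytest

from minicoi import primers as pr
from minicoi.seqcore import NucRecord, TaxonLineage, expand_degenerate, \
    iupac_match, reverse_complement


def brute_force_best_score(primer: pr.DegeneratePrimer, sequence: str,
                           params: pr.ScoringParams):
    """Independent oracle: minimum weighted score over every concrete
    primer variant at every gapless offset (strand per orientation).

    Returns (best score, set of offsets within float fuzz of it)."""
    w = params.weights(len(primer))
    variants = list(expand_degenerate(primer.sequence))
    scores = []
    for off in range(len(sequence) - len(primer) + 1):
        window = sequence[off: off + len(primer)]
        cmp_window = window if primer.orientation == "forward" \
            else reverse_complement(window)
        scores.append(min(
            sum(w[i] for i in range(len(primer)) if cmp_window[i] != v[i])
            for v in variants))
    best = min(scores)
    ties = {off for off, s in enumerate(scores) if abs(s - best) < 1e-9}
    return best, ties


class TestScoreSite:
    def test_perfect_degenerate_match_scores_zero(self):
        p = pr.DegeneratePrimer(name="p", sequence="GTHACHGCYCAYGCHTTYG",
                                orientation="forward")
        window = next(expand_degenerate(p.sequence))
        site = pr.score_site(p, window)
        assert site.weighted_score == 0.0
        assert not site.terminal_mismatch

    def test_single_mismatch_outside_three_prime_window(self):
        p = pr.DegeneratePrimer(name="p", sequence="A" * 20, orientation="forward")
        window = "C" + "A" * 19
        assert pr.score_site(p, window).weighted_score == pytest.approx(0.4)

    def test_terminal_mismatch_weight(self):
        p = pr.DegeneratePrimer(name="p", sequence="A" * 20, orientation="forward")
        window = "A" * 19 + "C"
        site = pr.score_site(p, window)
        assert site.weighted_score == pytest.approx(3.0)
        assert site.terminal_mismatch and site.mismatches_3 == 1

    def test_three_prime_window_nonterminal_weight(self):
        p = pr.DegeneratePrimer(name="p", sequence="A" * 20, orientation="forward")
        window = "A" * 17 + "C" + "A" * 2
        assert pr.score_site(p, window).weighted_score == pytest.approx(1.0)

    def test_score_decomposition_invariant(self):
        params = pr.ScoringParams()
        p = pr.DegeneratePrimer(name="p", sequence="ACGTACGTACGTACGTACGT",
                                orientation="forward")
        rng = np.random.default_rng(0)
        for _ in range(20):
            window = "".join(rng.choice(list("ACGT"), size=len(p)))
            s = pr.score_site(p, window, params)
            expected = (params.w_non3 * s.mismatches_non3
                        + params.w_3 * (s.mismatches_3 - s.terminal_mismatch)
                        + params.w_terminal * s.terminal_mismatch)
            assert s.weighted_score == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        p = pr.DegeneratePrimer(name="p", sequence="A" * 20, orientation="forward")
        with pytest.raises(ValueError):
            pr.score_site(p, "A" * 19)

    def test_reverse_primer_three_prime_end_is_leftmost_on_plus_strand(self):
        # plus strand carries rc(primer); the primer's terminal 3' base maps
        # to the first plus-strand position of the footprint
        p = pr.DegeneratePrimer(name="r", sequence="ACGTACGTACGTACGTACGT",
                                orientation="reverse")
        site_rc = reverse_complement(p.sequence)
        mismatched = ("T" if site_rc[0] != "T" else "G") + site_rc[1:]
        site = pr.score_site(p, mismatched)
        assert site.terminal_mismatch
        assert site.weighted_score == pytest.approx(3.0)


class TestScanBestSite:
    def test_embedded_primer_found_at_offset(self):
        p = pr.DegeneratePrimer(name="p", sequence="GTCACTGCTCATGCATTCG",
                                orientation="forward")
        rec = NucRecord(id="t", sequence="AAAA" + p.sequence + "GGGG")
        site = pr.scan_best_site(p, rec)
        assert site.start == 4 and site.weighted_score == 0.0

    def test_reverse_primer_found_via_reverse_complement(self):
        p = pr.DegeneratePrimer(name="r", sequence="CTCCAGCATGAGCAAGATTTCC",
                                orientation="reverse")
        rec = NucRecord(id="t",
                        sequence="TTTT" + reverse_complement(p.sequence) + "AA")
        site = pr.scan_best_site(p, rec)
        assert site.start == 4 and site.weighted_score == 0.0
        assert site.strand == "-"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        params = pr.ScoringParams()
        for i in range(15):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            primer_seq = "".join(
                rng.choice(["A", "C", "G", "T", "R", "Y", "H"], size=18,
                           p=[.2, .2, .2, .2, .07, .07, .06]))
            orientation = "forward" if i % 2 == 0 else "reverse"
            p = pr.DegeneratePrimer(name="p", sequence=primer_seq,
                                    orientation=orientation)
            site = pr.scan_best_site(p, NucRecord(id="t", sequence=seq), params)
            score, offsets = brute_force_best_score(p, seq, params)
            assert site.weighted_score == pytest.approx(score)
            assert site.start in offsets


class TestInsilicoPcr:
    def test_constructed_template_yields_202bp_product(self, default_pair):
        fwd, rev = default_pair
        rng = np.random.default_rng(1)
        insert = "".join(rng.choice(list("ACGT"), size=154))
        fwd_site = next(expand_degenerate(fwd.sequence))
        rev_site = reverse_complement(next(expand_degenerate(rev.sequence)))
        template = "GG" + fwd_site + insert + rev_site + "CC"
        hits = pr.insilico_pcr(fwd, rev, [NucRecord(id="t", sequence=template)])
        assert len(hits) == 1
        h = hits[0]
        assert h.product_length == 202 == 26 + 154 + 22
        assert h.insert_sequence == insert
        assert h.product_sequence == fwd_site + insert + rev_site

    def test_template_without_reverse_site_gives_no_amplicon(self, default_pair):
        fwd, rev = default_pair
        rng = np.random.default_rng(2)
        template = ("GG" + next(expand_degenerate(fwd.sequence))
                    + "".join(rng.choice(list("ACGT"), size=200)))
        assert pr.insilico_pcr(fwd, rev, [NucRecord(id="t", sequence=template)]) == []

    def test_product_length_invariant(self, small_world, default_pair):
        fwd, rev = default_pair
        hits = pr.insilico_pcr(fwd, rev, [r.record for r in small_world.records])
        assert hits, "planted pair must amplify the world"
        for h in hits:
            assert h.product_length == len(fwd) + len(h.insert_sequence) + len(rev)
            assert h.fwd.end <= h.rev.start


def _planted_design_world(seed=4, n=30, site=None):
    rng = np.random.default_rng(seed)
    site = site or "GTCACTGCTCATGCATTCGTAATAA"  # invariant 25-nt footprint
    records = []
    for i in range(n):
        left = "".join(rng.choice(list("ACGT"), size=40))
        right = "".join(rng.choice(list("ACGT"), size=120))
        records.append(NucRecord(id=f"t{i}", sequence=left + site + right))
    return site, records


class TestDesignPrimers:
    def test_recovers_planted_invariant_site(self):
        site, records = _planted_design_world()
        cands = pr.design_primers(records,
                                  design=pr.DesignParams(primer_length=len(site)))
        assert cands
        best = cands[0]
        assert best.target_coverage == 1.0
        footprints = {c.primer.sequence for c in cands if c.target_coverage == 1.0}
        assert site in footprints

    def test_exclusion_hits_rank_candidates_lower(self):
        site, targets = _planted_design_world(seed=5)
        # exclusion set carries the same planted site
        _, exclusions = _planted_design_world(seed=6, site=site)
        with_exc = pr.design_primers(targets, exclusions,
                                     design=pr.DesignParams(primer_length=len(site)))
        covs = [(c.target_coverage, c.exclusion_coverage) for c in with_exc]
        # ranking: coverage desc, then exclusion coverage asc
        assert covs == sorted(covs, key=lambda x: (-x[0], x[1]))

    def test_degeneracy_cap_respected(self):
        _, records = _planted_design_world(seed=8)
        cands = pr.design_primers(
            records, design=pr.DesignParams(primer_length=20, degeneracy_cap=64))
        for c in cands:
            assert c.degeneracy <= 64

    def test_no_conserved_seed_gives_empty_list(self):
        rng = np.random.default_rng(9)
        records = [NucRecord(id=f"t{i}",
                             sequence="".join(rng.choice(list("ACGT"), size=80)))
                   for i in range(20)]
        cands = pr.design_primers(
            records, design=pr.DesignParams(seed_fraction=0.95, primer_length=20))
        assert cands == []


class TestTaxonCoverage:
    def _lineages(self):
        return {
            "a1": TaxonLineage(order="O", family="F", genus="Myotis"),
            "a2": TaxonLineage(order="O", family="F", genus="Myotis"),
            "b1": TaxonLineage(order="O", family="F", genus="Tadarida"),
        }

    def _hit(self, rid):
        fake = pr.SiteMatch(ref_id=rid, start=0, strand="+", length=20,
                            weighted_score=0.0, mismatches_non3=0,
                            mismatches_3=0, terminal_mismatch=False)
        return pr.AmpliconHit(ref_id=rid, fwd=fake, rev=fake,
                              product_sequence="A" * 60, insert_sequence="A" * 20)

    def test_all_amplified(self):
        lin = self._lineages()
        df, overall = pr.taxon_coverage([self._hit(r) for r in lin], lin, "genus")
        assert (df["coverage"] == 1.0).all() and overall == 1.0

    def test_none_amplified(self):
        lin = self._lineages()
        df, overall = pr.taxon_coverage([], lin, "genus")
        assert (df["coverage"] == 0.0).all() and overall == 0.0

    def test_partial_coverage_fractions(self):
        lin = self._lineages()
        df, overall = pr.taxon_coverage([self._hit("a1")], lin, "genus")
        by = df.set_index("taxon")["coverage"]
        assert by["Myotis"] == 0.5 and by["Tadarida"] == 0.0
        assert overall == pytest.approx(1 / 3)


class TestBuiltinPrimers:
    def test_published_pair_loads_with_correct_sequences(self):
        fwd, rev = pr.builtin_pair()
        assert fwd.sequence == "GTHACHGCYCAYGCHTTYGTAATAAT"
        assert rev.sequence == "CTCCWGCRTGDGCWAGRTTTCC"
        assert (fwd.orientation, rev.orientation) == ("forward", "reverse")

    def test_full_set_present(self):
        names = set(pr.builtin_primers())
        assert {"SFF_145f", "SFF_210f", "SFF_348f", "SFF_351f", "SFF_348r",
                "SFF_351r", "SFF_492r", "BEGLCOIf", "BEGLCOIr"} <= names
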