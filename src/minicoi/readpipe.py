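"""Pooled-sample amplicon read processing.

Stages, in order: universal-tail/primer stripping, pair merging, ambiguity
and length screening, dereplication, two-parent chimera flagging, and
classification into a per-species sample profile.  Read accounting is
conserved at every stage: input pairs = stripped-rejected + merged +
merge-failures; merged = screened-kept + screened-rejected; the summed
abundance of the unique sequences equals the screened-kept count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .classify import Call, NaiveBayesKmerClassifier
from .primers import (
    DegeneratePrimer,
    ScoringParams,
    UNIVERSAL_TAIL_F,
    UNIVERSAL_TAIL_R,
    score_site,
)
from .seqcore import NucRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "ReadPair",
    "MergedRead",
    "UniqueSeq",
    "ChimeraFlag",
    "DetectionRule",
    "SampleProfile",
    "strip_primers_tails",
    "merge_pairs",
    "screen_dereplicate",
    "flag_chimeras",
    "profile_pool",
    "run_pipeline",
]


@dataclass
class ReadPair:
    """Forward and reverse mate of one fragment (Phred+33 qualities)."""

    id: str
    fwd: NucRecord
    rev: NucRecord

    def __post_init__(self) -> None:
        if self.fwd.quality is None or self.rev.quality is None:
            raise ValueError(f"{self.id}: both mates need quality scores")


@dataclass
class MergedRead:
    id: str
    sequence: str
    quality: list
    overlap_length: int
    overlap_mismatches: int


@dataclass
class UniqueSeq:
    sequence: str
    abundance: int
    rep_id: str


@dataclass
class ChimeraFlag:
    rep_id: str
    is_chimera: bool
    parents: Optional[tuple] = None  # (left rep_id, right rep_id)
    improvement: int = 0


@dataclass(frozen=True)
class DetectionRule:
    """A species is reported as detected when its classified read count
    reaches ``min_reads`` AND its proportion of all screened reads reaches
    ``min_fraction``.  Defaults (10 reads, 0.1%) are explicit stand-ins for
    the 'small proportions' reported informally by field studies."""

    min_reads: int = 10
    min_fraction: float = 0.001


@dataclass
class SampleProfile:
    """Per-taxon read counts and proportions for one pooled sample."""

    sample_id: str
    species_counts: dict            # species -> summed abundance
    genus_counts: dict              # genus-level acceptances only
    unclassified: int
    total: int
    detected: list                  # species meeting the detection rule
    off_target: dict = field(default_factory=dict)  # screen name -> hit count

    @property
    def proportions(self) -> dict:
        if self.total == 0:
            return {}
        out = {sp: c / self.total for sp, c in self.species_counts.items()}
        out.update({g: c / self.total for g, c in self.genus_counts.items()})
        out["unclassified"] = self.unclassified / self.total
        return out


# ---------------------------------------------------------------------------
# Stage 1: tail + primer stripping
# ---------------------------------------------------------------------------

def _strip_one(rec: NucRecord, pattern: str, params: ScoringParams,
               search_window: int) -> Optional[NucRecord]:
    """Remove a leading tail+primer pattern found within the first
    ``search_window`` offsets at weighted score <= hit_threshold."""
    plen = len(pattern)
    probe = DegeneratePrimer(name="strip", sequence=pattern, orientation="forward")
    best = None
    for off in range(0, search_window + 1):
        window = rec.sequence[off: off + plen]
        if len(window) < plen:
            break
        site = score_site(probe, window, params)
        if best is None or site.weighted_score < best[1]:
            best = (off, site.weighted_score)
        if site.weighted_score == 0:
            break
    if best is None or best[1] > params.hit_threshold:
        return None
    cut = best[0] + plen
    return NucRecord(id=rec.id, sequence=rec.sequence[cut:],
                     description=rec.description,
                     quality=None if rec.quality is None else rec.quality[cut:])


def strip_primers_tails(pair: ReadPair, fwd: DegeneratePrimer,
                        rev: DegeneratePrimer,
                        tails=(UNIVERSAL_TAIL_F, UNIVERSAL_TAIL_R),
                        params: ScoringParams = ScoringParams(),
                        search_window: int = 3,
                        require_primer: bool = True):
    """Strip the leading universal tail + primer from each mate.

    Both patterns are given in read orientation (the reverse mate reads the
    minus strand, so it begins with tail2 + reverse primer as written).
    Returns (trimmed ReadPair, None) or (None, reason).
    """
    fpat = tails[0] + fwd.sequence
    rpat = tails[1] + rev.sequence
    new_f = _strip_one(pair.fwd, fpat, params, search_window)
    new_r = _strip_one(pair.rev, rpat, params, search_window)
    if require_primer and (new_f is None or new_r is None):
        side = "fwd" if new_f is None else "rev"
        return None, f"no_primer_{side}"
    new_f = new_f if new_f is not None else pair.fwd
    new_r = new_r if new_r is not None else pair.rev
    if len(new_f.sequence) == 0 or len(new_r.sequence) == 0:
        return None, "empty_after_trim"
    return ReadPair(id=pair.id, fwd=new_f, rev=new_r), None


# ---------------------------------------------------------------------------
# Stage 2: pair merging
# ---------------------------------------------------------------------------

def merge_pairs(pair: ReadPair, min_overlap: int = 20,
                max_mismatch_rate: float = 0.10) -> Optional[MergedRead]:
    """Assemble mates into a contig via their best 3' overlap.

    The overlap offset maximizes matching positions between the forward read
    and the reverse complement of the reverse read, subject to the minimum
    overlap and maximum mismatch rate.  Overlap disagreements resolve to the
    higher-quality base with consensus quality |Q1-Q2|; agreements get
    min(Q1+Q2, 45).
    """
    f = np.frombuffer(pair.fwd.sequence.encode(), dtype="S1")
    rseq = reverse_complement(pair.rev.sequence)
    r = np.frombuffer(rseq.encode(), dtype="S1")
    fq = np.asarray(pair.fwd.quality)
    rq = np.asarray(pair.rev.quality)[::-1]

    best = None  # (matches, overlap, mismatches)
    for o in range(min_overlap, min(len(f), len(r)) + 1):
        a = f[len(f) - o:]
        b = r[:o]
        mm = int(np.count_nonzero(a != b))
        if mm > o * max_mismatch_rate:
            continue
        matches = o - mm
        if best is None or (matches, o) > (best[0], best[1]):
            best = (matches, o, mm)
    if best is None:
        return None
    _, o, mm = best
    fa, fb = f[: len(f) - o], f[len(f) - o:]
    ra, rb = r[:o], r[o:]
    qa = fq[len(f) - o:]
    qb = rq[:o]
    agree = fb == ra
    cons = np.where(agree | (qa >= qb), fb, ra)
    consq = np.where(agree, np.minimum(qa + qb, 45), np.abs(qa - qb))
    seq = (fa.tobytes() + cons.tobytes() + rb.tobytes()).decode()
    qual = list(fq[: len(f) - o]) + [int(q) for q in consq] + list(rq[o:])
    return MergedRead(id=pair.id, sequence=seq, quality=qual,
                      overlap_length=o, overlap_mismatches=mm)


# ---------------------------------------------------------------------------
# Stage 3: screening + dereplication
# ---------------------------------------------------------------------------

def screen_dereplicate(merged: Iterable[MergedRead], expected_length: int,
                       length_delta: int = 10):
    """Drop ambiguous or off-length contigs, collapse exact duplicates.

    Returns (uniques sorted by abundance desc then sequence, rejects) where
    rejects is a list of (id, reason).
    """
    counts: Counter = Counter()
    rep: dict = {}
    rejects: list = []
    lo, hi = expected_length - length_delta, expected_length + length_delta
    for m in merged:
        if any(c not in "ACGT" for c in m.sequence):
            rejects.append((m.id, "ambiguous"))
            continue
        if not lo <= len(m.sequence) <= hi:
            rejects.append((m.id, f"length:{len(m.sequence)}"))
            continue
        counts[m.sequence] += 1
        rep.setdefault(m.sequence, m.id)
    uniques = [UniqueSeq(sequence=s, abundance=c, rep_id=rep[s])
               for s, c in counts.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques, rejects


# ---------------------------------------------------------------------------
# Stage 4: chimera flagging
# ---------------------------------------------------------------------------

def flag_chimeras(uniques: Sequence[UniqueSeq], skew: float = 2.0,
                  min_diff: int = 3, min_identity: float = 0.99,
                  max_parents: int = 20) -> list:
    """Two-parent (bimera) flagging with an abundance-skew parent filter.

    For each query, candidate parents are same-length uniques at abundance
    >= skew x the query's (capped at the ``max_parents`` most abundant, as
    reference chimera detectors do).  Over ordered parent pairs and
    crossover points, the best chimeric model must beat the best single
    parent by at least ``min_diff`` matching positions and reach
    ``min_identity`` to flag.  This is a deliberate simplification of
    reference chimera detectors, validated on constructed bimeras.
    """
    seq_arrays = [np.frombuffer(u.sequence.encode(), dtype="S1") for u in uniques]
    flags = []
    for qi, q in enumerate(uniques):
        cand = [i for i, u in enumerate(uniques)
                if i != qi and u.abundance >= skew * q.abundance
                and len(u.sequence) == len(q.sequence)]
        cand = sorted(cand, key=lambda i: (-uniques[i].abundance,
                                           uniques[i].sequence))[:max_parents]
        if len(cand) < 2:
            flags.append(ChimeraFlag(rep_id=q.rep_id, is_chimera=False))
            continue
        qa = seq_arrays[qi]
        L = len(qa)
        match = {i: np.cumsum(np.concatenate([[0], (seq_arrays[i] == qa).astype(int)]))
                 for i in cand}
        best_single = max(int(match[i][L]) for i in cand)
        best_chim, best_pair = -1, None
        for i in cand:
            for j in cand:
                if i == j:
                    continue
                # matches of i-prefix + j-suffix over all crossovers
                comb = match[i][1:L] + (match[j][L] - match[j][1:L])
                x = int(np.argmax(comb))
                if int(comb[x]) > best_chim:
                    best_chim = int(comb[x])
                    best_pair = (uniques[i].rep_id, uniques[j].rep_id)
        improvement = best_chim - best_single
        is_chim = (improvement >= min_diff and best_chim / L >= min_identity)
        flags.append(ChimeraFlag(rep_id=q.rep_id, is_chimera=is_chim,
                                 parents=best_pair if is_chim else None,
                                 improvement=max(improvement, 0)))
    return flags


# ---------------------------------------------------------------------------
# Stage 5: profiling
# ---------------------------------------------------------------------------

def profile_pool(uniques: Sequence[UniqueSeq],
                 model: NaiveBayesKmerClassifier,
                 confidence: Optional[float] = None,
                 detection: DetectionRule = DetectionRule(),
                 off_target_models: Optional[Mapping[str, NaiveBayesKmerClassifier]] = None,
                 chimera_flags: Optional[Sequence[ChimeraFlag]] = None,
                 sample_id: str = "sample") -> SampleProfile:
    """Classify unique sequences and build the per-species profile.

    Chimera-flagged sequences are excluded before classification.  Species
    counts sum the abundances of uniques accepted at species rank; calls
    accepted only at genus accrue to ``genus_counts``; everything else is
    unclassified.  Each off-target model (exclusion screens, e.g. arthropod
    classes) reports the summed abundance of uniques it would accept at
    genus rank or deeper -- an order-level forced-choice call against an
    exclusion-only library carries no evidence and is not counted.
    """
    c = model.confidence if confidence is None else confidence
    flagged = {f.rep_id for f in (chimera_flags or []) if f.is_chimera}
    kept = [u for u in uniques if u.rep_id not in flagged]
    total = sum(u.abundance for u in kept)
    species_counts: Counter = Counter()
    genus_counts: Counter = Counter()
    unclassified = 0
    calls = model.predict_calls([u.sequence for u in kept],
                                ids=[u.rep_id for u in kept])
    for u, call in zip(kept, calls):
        rank, taxon = call.accepted(c)
        if rank == "species":
            species_counts[taxon] += u.abundance
        elif rank == "genus":
            genus_counts[taxon] += u.abundance
        else:
            unclassified += u.abundance

    detected = sorted(sp for sp, n in species_counts.items()
                      if n >= detection.min_reads
                      and total > 0 and n / total >= detection.min_fraction)

    off_target: dict = {}
    for name, ot_model in (off_target_models or {}).items():
        ot_c = ot_model.confidence
        hits = 0
        ot_calls = ot_model.predict_calls([u.sequence for u in kept],
                                          ids=[u.rep_id for u in kept])
        for u, call in zip(kept, ot_calls):
            rank, _ = call.accepted(ot_c)
            if rank in ("species", "genus"):
                hits += u.abundance
        off_target[name] = hits

    return SampleProfile(sample_id=sample_id,
                         species_counts=dict(species_counts),
                         genus_counts=dict(genus_counts),
                         unclassified=unclassified, total=total,
                         detected=detected, off_target=off_target)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def run_pipeline(pairs: Iterable[ReadPair], fwd: DegeneratePrimer,
                 rev: DegeneratePrimer, model: NaiveBayesKmerClassifier,
                 expected_insert_length: int,
                 tails=(UNIVERSAL_TAIL_F, UNIVERSAL_TAIL_R),
                 scoring: ScoringParams = ScoringParams(),
                 detection: DetectionRule = DetectionRule(),
                 off_target_models=None,
                 min_overlap: int = 20, max_mismatch_rate: float = 0.10,
                 length_delta: int = 10,
                 chimera_skew: float = 2.0, chimera_min_diff: int = 3,
                 sample_id: str = "sample"):
    """All stages in order; returns (SampleProfile, accounting dict,
    chimera flags)."""
    accounting = Counter()
    merged = []
    for pair in pairs:
        accounting["input_pairs"] += 1
        stripped, reason = strip_primers_tails(pair, fwd, rev, tails, scoring)
        if stripped is None:
            accounting["strip_rejected"] += 1
            continue
        m = merge_pairs(stripped, min_overlap=min_overlap,
                        max_mismatch_rate=max_mismatch_rate)
        if m is None:
            accounting["merge_failed"] += 1
            continue
        merged.append(m)
    accounting["merged"] = len(merged)
    uniques, rejects = screen_dereplicate(merged, expected_insert_length,
                                          length_delta=length_delta)
    accounting["screen_rejected"] = len(rejects)
    accounting["screened_kept"] = sum(u.abundance for u in uniques)
    flags = flag_chimeras(uniques, skew=chimera_skew, min_diff=chimera_min_diff)
    accounting["chimera_flagged"] = sum(f.is_chimera for f in flags)
    profile = profile_pool(uniques, model, detection=detection,
                           off_target_models=off_target_models,
                           chimera_flags=flags, sample_id=sample_id)
    return profile, dict(accounting), flags
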