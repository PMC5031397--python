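"""Degenerate primers: representation, weighted-mismatch scoring, in-silico
PCR, de novo design, and per-taxon coverage reports.

Scoring follows the weighted-mismatch scheme used by microbial primer
analysis tools: mismatches in the last ``three_prime_window`` bases of the
primer (its 3' end) are penalized more than 5' mismatches, and a mismatch at
the terminal 3' base carries an extra penalty.  A site is a "hit" when its
weighted score is at or below ``hit_threshold``.  Matching is gapless; COI
shows no length variation across the mini-barcode region in mammals, so
insertions/deletions are treated as non-hits.

Reverse primers are stored 5'->3' in their own sense and matched through
their reverse complement on the plus strand; all coordinates are reported on
the plus strand, 0-based.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    IUPAC_SETS,
    NucRecord,
    TaxonLineage,
    degeneracy as seq_degeneracy,
    normalize_sequence,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DegeneratePrimer",
    "ScoringParams",
    "SiteMatch",
    "AmpliconHit",
    "DesignParams",
    "PrimerCandidate",
    "score_site",
    "scan_best_site",
    "insilico_pcr",
    "design_primers",
    "taxon_coverage",
    "builtin_primers",
    "builtin_pair",
    "load_primer_tsv",
    "UNIVERSAL_TAIL_F",
    "UNIVERSAL_TAIL_R",
]

#: Universal tails prepended to the target primers for two-step indexed
#: amplification (forward / reverse, 5'->3').
UNIVERSAL_TAIL_F = "ACCCAACTGAATGGAGC"
UNIVERSAL_TAIL_R = "ACGCACTTGACTTGTCTTC"

# Bitmask encoding: A=1, C=2, G=4, T=8; a degenerate code is the OR of its
# bases.  Two codes are compatible iff their masks intersect.
_MASK = {code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases)
         for code, bases in IUPAC_SETS.items()}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_MASK[c] for c in seq), dtype=np.uint8, count=len(seq))


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC primer, 5'->3' in its own sense.

    ``degeneracy_cap`` is enforced only when given: de novo design applies a
    cap to its candidates, while published primers of any degeneracy are
    accepted as-is.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    degeneracy_cap: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")
        if len(self.sequence) < 15:
            raise ValueError(f"{self.name}: primer length {len(self.sequence)} < 15")
        if self.degeneracy_cap is not None and self.degeneracy > self.degeneracy_cap:
            raise ValueError(f"{self.name}: degeneracy {self.degeneracy} exceeds "
                             f"cap {self.degeneracy_cap}")

    @property
    def degeneracy(self) -> int:
        return seq_degeneracy(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringParams:
    """Weighted-mismatch scoring parameters.

    Defaults emulate the defaults of the microbial primer-analysis tools this
    scheme derives from: a 5-nt 3' window, weight 0.4 for 5' mismatches, 1.0
    inside the 3' window, an extra-penalized terminal base (3.0), and a hit
    threshold of 1.0 ("allows for some primer mismatch").
    """

    three_prime_window: int = 5
    w_non3: float = 0.4
    w_3: float = 1.0
    w_terminal: float = 3.0
    hit_threshold: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_non3, self.w_3, self.w_terminal) < 0 or self.hit_threshold < 0:
            raise ValueError("weights and hit_threshold must be >= 0")

    def weights(self, primer_length: int) -> np.ndarray:
        """Per-position weight vector in the primer's own 5'->3' sense."""
        w = np.full(primer_length, self.w_non3)
        win = min(self.three_prime_window, primer_length)
        if win > 0:
            w[primer_length - win:] = self.w_3
            w[primer_length - 1] = self.w_terminal
        return w


@dataclass(frozen=True)
class SiteMatch:
    """A primer placed at one position of a reference, with its mismatch
    statistics.  ``start`` is the 0-based plus-strand position of the
    footprint's first (leftmost) base."""

    ref_id: str
    start: int
    strand: str  # "+" for forward primers, "-" for reverse primers
    length: int
    weighted_score: float
    mismatches_non3: int
    mismatches_3: int
    terminal_mismatch: bool

    @property
    def end(self) -> int:
        """Exclusive plus-strand end of the footprint."""
        return self.start + self.length


@dataclass(frozen=True)
class AmpliconHit:
    """An in-silico PCR product: forward and reverse footprints plus the
    extracted product (inclusive of both footprints) and insert."""

    ref_id: str
    fwd: SiteMatch
    rev: SiteMatch
    product_sequence: str
    insert_sequence: str

    @property
    def product_length(self) -> int:
        return len(self.product_sequence)


def _primer_arrays(primer: DegeneratePrimer, params: ScoringParams):
    """Plus-strand mask and per-plus-position weights/classes for a primer.

    For reverse primers the plus strand carries the reverse complement of the
    primer, so the mask is rc'ed and the weight vector reversed (the primer's
    3' end sits at the leftmost plus-strand position).
    """
    w = params.weights(len(primer))
    if primer.orientation == "forward":
        mask = _encode(primer.sequence)
    else:
        mask = _encode(reverse_complement(primer.sequence))
        w = w[::-1].copy()
    win = min(params.three_prime_window, len(primer))
    in3 = np.zeros(len(primer), dtype=bool)
    in3[len(primer) - win:] = True
    term = np.zeros(len(primer), dtype=bool)
    term[len(primer) - 1] = True
    if primer.orientation == "reverse":
        in3, term = in3[::-1].copy(), term[::-1].copy()
    return mask, w, in3, term


def _site_from_mismatch(primer, ref_id, start, mism, w, in3, term) -> SiteMatch:
    n3 = int(np.count_nonzero(mism & in3))
    nterm = bool(np.any(mism & term))
    nnon = int(np.count_nonzero(mism & ~in3))
    return SiteMatch(
        ref_id=ref_id, start=int(start),
        strand="+" if primer.orientation == "forward" else "-",
        length=len(primer),
        weighted_score=float(mism @ w),
        mismatches_non3=nnon, mismatches_3=n3, terminal_mismatch=nterm,
    )


def score_site(primer: DegeneratePrimer, window_sequence: str,
               params: ScoringParams = ScoringParams(),
               ref_id: str = "", start: int = 0) -> SiteMatch:
    """Score one gapless placement of a primer against a same-length window.

    The window is given in plus-strand orientation; reverse primers are
    compared as their reverse complement.
    """
    window = normalize_sequence(window_sequence)
    if len(window) != len(primer):
        raise ValueError(f"window length {len(window)} != primer length {len(primer)}")
    mask, w, in3, term = _primer_arrays(primer, params)
    obs = _encode(window)
    mism = (obs & mask) == 0
    return _site_from_mismatch(primer, ref_id, start, mism, w, in3, term)


def _scan_scores(primer: DegeneratePrimer, sequence: str, params: ScoringParams):
    """Weighted score at every gapless offset; returns (scores, mism matrix)."""
    mask, w, in3, term = _primer_arrays(primer, params)
    obs = _encode(sequence)
    if len(obs) < len(primer):
        return None
    windows = np.lib.stride_tricks.sliding_window_view(obs, len(primer))
    mism = (windows & mask) == 0
    return mism @ w, mism, (mask, w, in3, term)


def scan_best_site(primer: DegeneratePrimer, record: NucRecord,
                   params: ScoringParams = ScoringParams()) -> Optional[SiteMatch]:
    """Best (minimum weighted score) gapless placement on a record.

    Ties break to the smallest start position.  Returns None when the record
    is shorter than the primer.  The caller decides hit-ness by comparing
    ``weighted_score`` to ``params.hit_threshold``.
    """
    res = _scan_scores(primer, record.sequence, params)
    if res is None:
        return None
    scores, mism, (mask, w, in3, term) = res
    best = int(np.argmin(scores))
    return _site_from_mismatch(primer, record.id, best, mism[best], w, in3, term)


def insilico_pcr(fwd: DegeneratePrimer, rev: DegeneratePrimer,
                 records: Iterable[NucRecord],
                 params: ScoringParams = ScoringParams(),
                 max_candidates: int = 50) -> list:
    """Extract in-silico PCR products for a primer pair over records.

    Both primers must hit (weighted score <= hit_threshold) with the forward
    footprint strictly upstream of (and not overlapping) the reverse
    footprint; at most one amplicon per record is reported, the best-scoring
    compatible site pair (ties to the leftmost forward, then leftmost reverse
    position).  The product runs from the first base of the forward footprint
    through the last base of the reverse footprint, inclusive.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("insilico_pcr needs a forward and a reverse primer")
    hits = []
    for rec in records:
        fres = _scan_scores(fwd, rec.sequence, params)
        rres = _scan_scores(rev, rec.sequence, params)
        if fres is None or rres is None:
            continue
        fscores, fmism, fctx = fres
        rscores, rmism, rctx = rres
        fidx = np.flatnonzero(fscores <= params.hit_threshold)
        ridx = np.flatnonzero(rscores <= params.hit_threshold)
        if fidx.size == 0 or ridx.size == 0:
            continue
        # keep the best few candidates per side; ample for real templates
        fidx = fidx[np.argsort(fscores[fidx], kind="stable")][:max_candidates]
        ridx = ridx[np.argsort(rscores[ridx], kind="stable")][:max_candidates]
        best = None
        for fs in sorted(fidx):
            for rs in sorted(ridx):
                if fs + len(fwd) > rs:
                    continue
                key = (float(fscores[fs] + rscores[rs]), fs, rs)
                if best is None or key < best[0]:
                    best = (key, int(fs), int(rs))
        if best is None:
            logger.info("insilico_pcr: %s has hits but footprints overlap or "
                        "are misordered; no amplicon", rec.id)
            continue
        _, fs, rs = best
        fsite = _site_from_mismatch(fwd, rec.id, fs, fmism[fs], *fctx[1:])
        rsite = _site_from_mismatch(rev, rec.id, rs, rmism[rs], *rctx[1:])
        product = rec.sequence[fs: rs + len(rev)]
        insert = rec.sequence[fs + len(fwd): rs]
        hits.append(AmpliconHit(ref_id=rec.id, fwd=fsite, rev=rsite,
                                product_sequence=product, insert_sequence=insert))
    return hits


# ---------------------------------------------------------------------------
# De novo design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignParams:
    """Parameters for conserved-region primer design.

    Candidate footprints are seeded on exact k-mers shared by at least
    ``seed_fraction`` of the targets within a +/- ``position_band`` window of
    their median location, extended to ``primer_length`` by accumulating
    per-position base frequencies, and emitted as the IUPAC code covering all
    bases with per-position frequency >= ``min_base_freq``.
    """

    primer_length: int = 20
    seed_k: int = 5
    seed_fraction: float = 0.6
    position_band: int = 10
    min_base_freq: float = 0.05
    degeneracy_cap: int = 512
    max_seeds: int = 50
    orientation: str = "forward"


@dataclass(frozen=True)
class PrimerCandidate:
    primer: DegeneratePrimer
    target_coverage: float
    exclusion_coverage: float
    mean_target_score: float

    @property
    def degeneracy(self) -> int:
        return self.primer.degeneracy


def _coverage(primer, records, params: ScoringParams):
    """(fraction of records hit, mean best score) for a primer."""
    n = hit = 0
    scores = []
    for rec in records:
        site = scan_best_site(primer, rec, params)
        n += 1
        if site is not None:
            scores.append(site.weighted_score)
            if site.weighted_score <= params.hit_threshold:
                hit += 1
    if n == 0:
        return 0.0, float("nan")
    return hit / n, float(np.mean(scores)) if scores else float("nan")


def design_primers(target_records: Sequence[NucRecord],
                   exclusion_records: Sequence[NucRecord] = (),
                   design: DesignParams = DesignParams(),
                   scoring: ScoringParams = ScoringParams()) -> list:
    """Design degenerate primers against targets while avoiding exclusions.

    Returns PrimerCandidates ranked by (target coverage desc, exclusion
    coverage asc, degeneracy asc).  Empty when no sufficiently conserved seed
    k-mer exists.
    """
    targets = list(target_records)
    if not targets:
        return []
    seqs = [t.sequence if design.orientation == "forward"
            else reverse_complement(t.sequence) for t in targets]
    k = design.seed_k
    # document frequency of exact k-mers across targets
    df: Counter = Counter()
    first_pos: list[dict] = []
    for s in seqs:
        pos: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if w not in pos:
                pos[w] = i
        first_pos.append(pos)
        df.update(pos.keys())
    n = len(seqs)
    seeds = [w for w, c in df.items() if c / n >= design.seed_fraction]
    if not seeds:
        logger.warning("design_primers: no seed %d-mer reaches fraction %.2f",
                       k, design.seed_fraction)
        return []
    seeds.sort(key=lambda w: (-df[w], w))
    seeds = seeds[: design.max_seeds]

    candidates: dict[str, PrimerCandidate] = {}
    for seed in seeds:
        anchors = [pos.get(seed) for pos in first_pos]
        present = [a for a in anchors if a is not None]
        med = int(np.median(present))
        windows = []
        for s, a in zip(seqs, anchors):
            if a is None or abs(a - med) > design.position_band:
                continue
            win = s[a: a + design.primer_length]
            if len(win) == design.primer_length:
                windows.append(win)
        if len(windows) / n < design.seed_fraction:
            continue
        # per-position base frequencies -> covering IUPAC code
        cols = np.array([list(w) for w in windows])
        consensus = []
        for j in range(design.primer_length):
            col = cols[:, j]
            counts = Counter(b for b in col if b in "ACGT")
            total = sum(counts.values())
            if total == 0:
                consensus = None
                break
            keep = frozenset(b for b, c in counts.items()
                             if c / total >= design.min_base_freq)
            if not keep:
                keep = frozenset([counts.most_common(1)[0][0]])
            consensus.append({v: k_ for k_, v in IUPAC_SETS.items()}[keep])
        if consensus is None:
            continue
        seq = "".join(consensus)
        if seq in candidates or seq_degeneracy(seq) > design.degeneracy_cap:
            continue
        if len(seq) < 15:
            continue
        primer = DegeneratePrimer(
            name=f"cand_{len(candidates):03d}", sequence=seq,
            orientation="forward", degeneracy_cap=design.degeneracy_cap)
        if design.orientation == "reverse":
            primer = DegeneratePrimer(
                name=primer.name, sequence=reverse_complement(seq),
                orientation="reverse", degeneracy_cap=design.degeneracy_cap)
        tcov, tscore = _coverage(primer, targets, scoring)
        ecov, _ = _coverage(primer, exclusion_records, scoring)
        candidates[seq] = PrimerCandidate(
            primer=primer, target_coverage=tcov,
            exclusion_coverage=ecov, mean_target_score=tscore)

    ranked = sorted(candidates.values(),
                    key=lambda c: (-c.target_coverage, c.exclusion_coverage,
                                   c.degeneracy, c.primer.sequence))
    return ranked


def taxon_coverage(hits: Iterable[AmpliconHit],
                   lineages: Mapping[str, TaxonLineage],
                   rank: str = "genus"):
    """Per-taxon amplification coverage at a rank.

    ``lineages`` must cover every record considered (hit or not); coverage is
    amplified records / total records per taxon.  Records without a lineage
    entry at the rank are counted under "unassigned".  Returns (DataFrame
    with columns rank, taxon, n_total, n_amplified, coverage; overall
    fraction).
    """
    hit_ids = {h.ref_id for h in hits}
    totals: Counter = Counter()
    amplified: Counter = Counter()
    for rid, lin in lineages.items():
        taxon = lin.get(rank) or "unassigned"
        totals[taxon] += 1
        if rid in hit_ids:
            amplified[taxon] += 1
    rows = [{"rank": rank, "taxon": t, "n_total": totals[t],
             "n_amplified": amplified.get(t, 0),
             "coverage": amplified.get(t, 0) / totals[t]}
            for t in sorted(totals)]
    df = pd.DataFrame(rows, columns=["rank", "taxon", "n_total", "n_amplified",
                                     "coverage"])
    overall = (sum(amplified.values()) / sum(totals.values())) if totals else 0.0
    return df, overall


# ---------------------------------------------------------------------------
# Bundled primer set
# ---------------------------------------------------------------------------

def load_primer_tsv(path_or_text) -> dict:
    """Load a primer TSV (name<TAB>sequence<TAB>orientation) into a dict."""
    primers = {}
    if hasattr(path_or_text, "read"):
        lines = path_or_text.read().splitlines()
    elif "\n" in str(path_or_text) or "\t" in str(path_or_text):
        lines = str(path_or_text).splitlines()
    else:
        with open(path_or_text) as fh:
            lines = fh.read().splitlines()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        name, seq, orient = line.split("\t")[:3]
        primers[name] = DegeneratePrimer(name=name, sequence=seq, orientation=orient)
    return primers


def builtin_primers() -> dict:
    """The bundled COI mini-barcode primer set (SFF_* plus BEGLCOI pair)."""
    text = resources.files("minicoi").joinpath("data/primers_table.tsv").read_text()
    return load_primer_tsv(text)


def builtin_pair(fwd_name: str = "SFF_145f", rev_name: str = "SFF_351r"):
    prim = builtin_primers()
    return prim[fwd_name], prim[rev_name]
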