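"""Seeded generation of COI-like reference worlds and pooled amplicon reads.

The generator emulates the features of real COI barcode data that the rest
of the toolkit depends on: protein-coding sequences that are stop-free in
frame 0 under the vertebrate mitochondrial code, a rank hierarchy
(order -> family -> genus -> species) with low within-species and high
between-species divergence, conserved primer footprints, and paired reads
with a Phred substitution-error model.  Everything is deterministic per
seed.

It also builds the synthetic stand-in fixtures the test suite uses in place
of external barcode collections (a 186-sequence / 54-species validation
set, a 430-species mini-barcode panel of known resolution composition, and
a mixed bat/arthropod primer-design set); these are constructions with the
published structural properties, not real data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .primers import (
    DegeneratePrimer,
    UNIVERSAL_TAIL_F,
    UNIVERSAL_TAIL_R,
    builtin_pair,
)
from .readpipe import ReadPair
from .seqcore import (
    IUPAC_SETS,
    MITO_STOPS,
    NucRecord,
    RefRecord,
    TaxonLineage,
    reverse_complement,
)

__all__ = [
    "WorldParams",
    "ReferenceWorld",
    "PoolSpec",
    "simulate_reference_world",
    "simulate_pooled_reads",
    "mutate_sequence",
    "random_coding_root",
    "divergence_summary",
    "synthetic_validation_set",
    "synthetic_species_panel",
    "synthetic_design_set",
    "synthetic_arthropod_reference",
    "write_pool_fastq",
]

_BASES = np.array(list("ACGT"))
_ALLOWED_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                   if "".join(c) not in MITO_STOPS]


@dataclass(frozen=True)
class WorldParams:
    """Parameters of a simulated reference world.

    Divergence targets are expected per-site substitution fractions on the
    path from the shared ancestor at each level: ``d_genus`` root->genus,
    ``d_species`` genus->species, ``d_within`` species->individual.
    Defaults (0.12 / 0.05 / 0.005 over a 658 nt coding root) reproduce the
    low intraspecific variation and high interspecific divergence that make
    COI usable as a barcode.
    """

    n_genera: int = 4
    species_per_genus: int = 3
    seqs_per_species: int = 3
    root_length: int = 658
    d_genus: float = 0.12
    d_species: float = 0.05
    d_within: float = 0.005
    fwd_primer: Optional[DegeneratePrimer] = None   # default SFF_145f
    rev_primer: Optional[DegeneratePrimer] = None   # default SFF_351r
    fwd_start: int = 99
    product_length: int = 202
    protect_footprints: bool = True
    order_name: str = "Chiroptera"
    genera_per_family: int = 2
    genus_prefix: str = "Genus"
    family_prefix: str = "Family"
    root: Optional[str] = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not (self.d_within < self.d_species < self.d_genus):
            raise ValueError("need d_within < d_species < d_genus")


@dataclass
class ReferenceWorld:
    """A simulated world: full-length records plus planted-footprint
    coordinates, so the product/insert of any record can be sliced
    directly."""

    params: WorldParams
    records: list                      # RefRecords, full length
    root: str
    fwd_start: int
    fwd_len: int
    rev_start: int
    rev_len: int

    @property
    def insert_length(self) -> int:
        return self.rev_start - (self.fwd_start + self.fwd_len)

    def product(self, rec: RefRecord) -> str:
        return rec.sequence[self.fwd_start: self.rev_start + self.rev_len]

    def insert(self, rec: RefRecord) -> str:
        return rec.sequence[self.fwd_start + self.fwd_len: self.rev_start]

    def library_inserts(self) -> list:
        """Records trimmed to the insert (classifier training region)."""
        return [r.with_sequence(self.insert(r)) for r in self.records]

    def library_products(self) -> list:
        return [r.with_sequence(self.product(r)) for r in self.records]

    def species(self) -> list:
        return sorted({r.lineage.species for r in self.records})

    def records_of(self, species: str) -> list:
        return sorted((r for r in self.records if r.lineage.species == species),
                      key=lambda r: r.id)


def random_coding_root(length: int, rng: np.random.Generator) -> str:
    """A random sequence of ``length`` nt, stop-free in frame 0."""
    n_codons, rem = divmod(length, 3)
    codons = rng.choice(_ALLOWED_CODONS, size=n_codons)
    tail = "".join(rng.choice(_BASES, size=rem)) if rem else ""
    return "".join(codons) + tail


def _creates_stop(seq: list, site: int, base: str) -> bool:
    c0 = (site // 3) * 3
    if c0 + 3 > len(seq):
        return False
    codon = seq[c0:c0 + 3]
    codon[site - c0] = base
    return "".join(codon) in MITO_STOPS


def mutate_sequence(sequence: str, d: float, rng: np.random.Generator,
                    protect: Sequence[tuple] = (),
                    third_position_bias: float = 3.0) -> str:
    """Apply random substitutions at expected per-site fraction ``d``.

    Sites inside ``protect`` intervals (half-open, e.g. primer footprints)
    are never touched; substitutions that would create a frame-0 stop codon
    of the vertebrate mitochondrial code are resampled or skipped.  Third
    codon positions are ``third_position_bias`` times as likely to mutate as
    first/second positions (coding realism).
    """
    seq = list(sequence)
    protected = np.zeros(len(seq), dtype=bool)
    for a, b in protect:
        protected[a:b] = True
    mutable = np.flatnonzero(~protected)
    if mutable.size == 0 or d <= 0:
        return sequence
    n_mut = rng.binomial(mutable.size, min(d, 1.0))
    if n_mut == 0:
        return sequence
    w = np.where(mutable % 3 == 2, third_position_bias, 1.0)
    w /= w.sum()
    sites = rng.choice(mutable, size=min(n_mut, mutable.size), replace=False, p=w)
    for site in sites:
        cur = seq[site]
        options = [b for b in "ACGT" if b != cur]
        rng.shuffle(options)
        for b in options:
            if not _creates_stop(seq, int(site), b):
                seq[site] = b
                break
    return "".join(seq)


def _plant_footprints(root: str, fwd: DegeneratePrimer, rev: DegeneratePrimer,
                      fwd_start: int, product_length: int,
                      rng: np.random.Generator, max_tries: int = 200):
    """Write concrete primer resolutions into the root; returns the planted
    root and footprint coordinates.  Raises if no stop-free planting exists
    within the attempt budget (infeasible parameters)."""
    rev_start = fwd_start + product_length - len(rev)
    if fwd_start < 0 or fwd_start + len(fwd) > rev_start \
            or rev_start + len(rev) > len(root):
        raise ValueError(
            f"infeasible footprint layout: fwd_start={fwd_start}, "
            f"product_length={product_length}, root_length={len(root)}")

    def resolve(degenerate: str) -> str:
        return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in degenerate)

    for _ in range(max_tries):
        seq = list(root)
        seq[fwd_start:fwd_start + len(fwd)] = resolve(fwd.sequence)
        seq[rev_start:rev_start + len(rev)] = reverse_complement(resolve(rev.sequence))
        # repair stop codons in/around the footprints using free positions
        protected = np.zeros(len(seq), dtype=bool)
        protected[fwd_start:fwd_start + len(fwd)] = True
        protected[rev_start:rev_start + len(rev)] = True
        ok = True
        for c0 in range(0, len(seq) - 2, 3):
            if "".join(seq[c0:c0 + 3]) not in MITO_STOPS:
                continue
            free = [i for i in range(c0, c0 + 3) if not protected[i]]
            fixed = False
            for i in free:
                for b in "ACGT":
                    if b != seq[i] and not _creates_stop(seq, i, b):
                        seq[i] = b
                        fixed = True
                        break
                if fixed:
                    break
            if not fixed:
                ok = False
                break
        if ok:
            return "".join(seq), fwd_start, len(fwd), rev_start, len(rev)
    raise ValueError("infeasible parameters: cannot plant stop-free primer "
                     "footprints into the root")


def simulate_reference_world(params: WorldParams = WorldParams()) -> ReferenceWorld:
    """Generate a reference world by hierarchical mutation from a stop-free
    coding root with planted primer footprints."""
    rng = np.random.default_rng(params.seed)
    fwd, rev = params.fwd_primer, params.rev_primer
    if fwd is None or rev is None:
        bf, br = builtin_pair()
        fwd = fwd or bf
        rev = rev or br
    root = params.root or random_coding_root(params.root_length, rng)
    if len(root) != params.root_length:
        raise ValueError("root length does not match root_length")
    root, fs, fl, rs, rl = _plant_footprints(
        root, fwd, rev, params.fwd_start, params.product_length, rng)
    protect = ((fs, fs + fl), (rs, rs + rl)) if params.protect_footprints else ()

    records = []
    for g in range(params.n_genera):
        genus = f"{params.genus_prefix}{g + 1:02d}"
        family = f"{params.family_prefix}{g // params.genera_per_family + 1:02d}"
        genus_anc = mutate_sequence(root, params.d_genus, rng, protect)
        for s in range(params.species_per_genus):
            species = f"{genus} sp{s + 1:02d}"
            sp_anc = mutate_sequence(genus_anc, params.d_species, rng, protect)
            lineage = TaxonLineage(order=params.order_name, family=family,
                                   genus=genus, species=species)
            for i in range(params.seqs_per_species):
                seq = mutate_sequence(sp_anc, params.d_within, rng, protect)
                rid = f"{params.genus_prefix[:1]}{g + 1:02d}S{s + 1:02d}I{i + 1:02d}"
                records.append(RefRecord(
                    record=NucRecord(id=rid, sequence=seq,
                                     description=species),
                    lineage=lineage, marker="COI-5P"))
    return ReferenceWorld(params=params, records=records, root=root,
                          fwd_start=fs, fwd_len=fl, rev_start=rs, rev_len=rl)


def divergence_summary(world: ReferenceWorld, max_pairs: int = 500) -> dict:
    """Mean realized pairwise divergence within species, between congeneric
    species, and between genera (Hamming fraction on full-length records)."""
    rng = np.random.default_rng(0)
    arrs = {r.id: np.frombuffer(r.sequence.encode(), dtype="S1")
            for r in world.records}
    buckets = {"within_species": [], "between_species": [], "between_genus": []}
    recs = world.records
    pairs = [(i, j) for i in range(len(recs)) for j in range(i + 1, len(recs))]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    for i, j in pairs:
        a, b = recs[i], recs[j]
        d = float(np.mean(arrs[a.id] != arrs[b.id]))
        if a.lineage.species == b.lineage.species:
            buckets["within_species"].append(d)
        elif a.lineage.genus == b.lineage.genus:
            buckets["between_species"].append(d)
        else:
            buckets["between_genus"].append(d)
    return {k: (float(np.mean(v)) if v else float("nan"))
            for k, v in buckets.items()}


# ---------------------------------------------------------------------------
# Pooled-read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolSpec:
    """A mock pooled sample: species template proportions, sequencing depth
    and error model.  The default quality (constant Q33, substitutions only)
    matches the average read quality of real pooled-guano runs."""

    proportions: Mapping[str, float] = field(default_factory=dict)
    n_pairs: int = 20000
    read_length: int = 150
    quality: int = 33
    chimera_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {total}, expected 1")


def _apply_errors(seq: str, p_err: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(arr.size) < p_err
    for i in np.flatnonzero(mask):
        cur = arr[i].decode()
        arr[i] = rng.choice([b for b in "ACGT" if b != cur]).encode()
    return arr.tobytes().decode()


def simulate_pooled_reads(world: ReferenceWorld, pool: PoolSpec):
    """Simulate paired reads from a pooled sample.

    One template individual (the first record, by id) represents each
    species; the sequencing construct is tail1 + product + rc(tail2); the
    forward read covers its 5' end and the reverse read the 3' end of the
    opposite strand.  Read counts are multinomial in the template
    proportions; substitution errors occur per base at the rate implied by
    the constant Phred quality.  Returns (list of ReadPair, truth
    DataFrame).
    """
    rng = np.random.default_rng(pool.seed)
    species = sorted(pool.proportions)
    missing = [sp for sp in species if sp not in set(world.species())]
    if missing:
        raise ValueError(f"species not in world: {missing}")
    constructs = {}
    for sp in species:
        template = world.records_of(sp)[0]
        constructs[sp] = (UNIVERSAL_TAIL_F + world.product(template)
                          + reverse_complement(UNIVERSAL_TAIL_R))
    n_chim = int(round(pool.chimera_rate * pool.n_pairs))
    n_real = pool.n_pairs - n_chim
    counts = rng.multinomial(n_real, [pool.proportions[sp] for sp in species])
    p_err = 10 ** (-pool.quality / 10)
    R = pool.read_length

    sources = []
    for sp, c in zip(species, counts):
        sources.extend([sp] * int(c))
    for _ in range(n_chim):
        sources.append("chimera")
    order = rng.permutation(len(sources))

    pairs, truth_rows = [], []
    chim_products = []
    if n_chim:
        for _ in range(n_chim):
            a, b = rng.choice(species, size=2, replace=False)
            prod_a = constructs[a][len(UNIVERSAL_TAIL_F):-len(UNIVERSAL_TAIL_R)]
            prod_b = constructs[b][len(UNIVERSAL_TAIL_F):-len(UNIVERSAL_TAIL_R)]
            x = int(rng.integers(30, len(prod_a) - 30))
            chim_products.append(UNIVERSAL_TAIL_F + prod_a[:x] + prod_b[x:]
                                 + reverse_complement(UNIVERSAL_TAIL_R))
    chim_i = 0
    for k, src_i in enumerate(order):
        src = sources[src_i]
        if src == "chimera":
            construct = chim_products[chim_i]
            chim_i += 1
        else:
            construct = constructs[src]
        fwd_seq = _apply_errors(construct[:R], p_err, rng)
        rev_seq = _apply_errors(reverse_complement(construct)[:R], p_err, rng)
        rid = f"read{k:06d}"
        qual = [pool.quality] * R
        pairs.append(ReadPair(
            id=rid,
            fwd=NucRecord(id=rid, sequence=fwd_seq, description="1", quality=qual),
            rev=NucRecord(id=rid, sequence=rev_seq, description="2", quality=list(qual)),
        ))
        truth_rows.append({"read_id": rid, "source": src})
    truth = pd.DataFrame(truth_rows)
    summary = truth.groupby("source").size().rename("n_reads").reset_index()
    summary["proportion"] = summary["n_reads"] / pool.n_pairs
    return pairs, summary


def write_pool_fastq(pairs: Sequence[ReadPair], fwd_path, rev_path) -> None:
    from .seqcore import write_fastq
    write_fastq((p.fwd for p in pairs), fwd_path)
    write_fastq((p.rev for p in pairs), rev_path)


# ---------------------------------------------------------------------------
# Synthetic stand-in fixtures
# ---------------------------------------------------------------------------

def synthetic_validation_set(seed: int = 1):
    """Synthetic stand-in for a Sanger validation set: 186 mini-barcode
    sequences (full 202 bp products) from 54 species, all stop-free by
    construction.  Returns a list of RefRecords."""
    params = WorldParams(n_genera=18, species_per_genus=3, seqs_per_species=4,
                         genera_per_family=3, seed=seed)
    world = simulate_reference_world(params)
    products = world.library_products()
    # 54 species x 4 = 216; drop the 4th individual of the last 30 species
    species = sorted({r.lineage.species for r in products})
    drop_species = set(species[-30:])
    out, seen_4th = [], set()
    for rec in sorted(products, key=lambda r: r.id):
        if rec.lineage.species in drop_species and rec.id.endswith("I04"):
            continue
        out.append(rec)
    assert len(out) == 186
    return out


def synthetic_species_panel(seed: int = 1):
    """Synthetic stand-in for a 430-species mini-barcode panel of known
    resolution composition: 394 species-resolved, 11 congeneric pairs (22
    species) sharing a barcode within a genus, and 7 cross-genus pairs (14
    species) sharing a barcode across genera -- 36 shared species in all.

    Returns (records, truth) where records are full-length RefRecords (one
    per species, footprints included, trimmable with the default pair) and
    truth is a dict of planted category counts.
    """
    params = WorldParams(n_genera=86, species_per_genus=5, seqs_per_species=1,
                         genera_per_family=4, seed=seed)
    world = simulate_reference_world(params)
    rng = np.random.default_rng(seed + 1)
    records = sorted(world.records, key=lambda r: r.id)
    assert len(records) == 430
    lo, hi = world.fwd_start, world.rev_start + world.rev_len

    by_genus: dict = {}
    for i, r in enumerate(records):
        by_genus.setdefault(r.lineage.genus, []).append(i)
    genera = sorted(by_genus)

    def share(i, j):
        donor = records[i].sequence
        rec = records[j]
        seq = rec.sequence[:lo] + donor[lo:hi] + rec.sequence[hi:]
        records[j] = rec.with_sequence(seq)

    congener, cross = [], []
    for g in genera[:11]:
        i, j = by_genus[g][0], by_genus[g][1]
        share(i, j)
        congener.extend([records[i].id, records[j].id])
    for k in range(7):
        i = by_genus[genera[11 + k]][0]
        j = by_genus[genera[40 + k]][0]
        share(i, j)
        cross.extend([records[i].id, records[j].id])

    # enforce product uniqueness among the intended species-resolved panel
    shared_ids = set(congener) | set(cross)
    seen: dict = {}
    for idx, rec in enumerate(records):
        if rec.id in shared_ids:
            continue
        prod = rec.sequence[lo:hi]
        guard = 0
        while prod in seen:
            seq = mutate_sequence(rec.sequence, 1.0 / len(rec.sequence), rng,
                                  protect=((world.fwd_start,
                                            world.fwd_start + world.fwd_len),
                                           (world.rev_start,
                                            world.rev_start + world.rev_len)))
            records[idx] = rec = rec.with_sequence(seq)
            prod = rec.sequence[lo:hi]
            guard += 1
            if guard > 50:
                raise RuntimeError("could not de-duplicate panel products")
        seen[prod] = rec.id
    truth = {"n_species": 430, "species_resolved": 430 - len(shared_ids),
             "congener_shared": len(congener), "cross_genus_shared": len(cross)}
    return records, truth


def synthetic_design_set(seed: int = 1):
    """Synthetic stand-in for a primer-design input set: target-order COI
    records with conserved planted footprints plus arthropod-like exclusion
    records diverged without footprint protection (so the planted primers
    mostly miss them).  Returns a list of RefRecords spanning the orders
    Chiroptera, Insecta and Arachnida."""
    rng = np.random.default_rng(seed)
    bats = simulate_reference_world(WorldParams(
        n_genera=8, species_per_genus=3, seqs_per_species=1,
        order_name="Chiroptera", seed=seed))
    out = list(bats.records)
    for k, (order, div, prefix) in enumerate(
            [("Insecta", 0.25, "Insgen"), ("Arachnida", 0.30, "Aragen")]):
        off_root = mutate_sequence(bats.root, div, rng)
        w = simulate_reference_world(WorldParams(
            n_genera=4, species_per_genus=2, seqs_per_species=1,
            order_name=order, genus_prefix=prefix,
            family_prefix=f"{order[:4]}fam",
            protect_footprints=False, root=off_root, seed=seed + 10 + k))
        out.extend(w.records)
    return out


def synthetic_arthropod_reference(seed: int = 1,
                                  root: Optional[str] = None):
    """Synthetic stand-in for arthropod-class exclusion libraries: insert
    region records spanning four arthropod classes (as orders of the rank
    hierarchy), derived from a shared ancestral COI so realistic word
    overlap with other worlds exists.  Returns a list of RefRecords trimmed
    to the insert region."""
    rng = np.random.default_rng(seed)
    if root is None:
        root = random_coding_root(658, rng)
    out = []
    for k, order in enumerate(["Insecta", "Arachnida", "Chilopoda", "Diplopoda"]):
        off_root = mutate_sequence(root, 0.20, rng)
        w = simulate_reference_world(WorldParams(
            n_genera=3, species_per_genus=2, seqs_per_species=2,
            order_name=order, genus_prefix=f"{order[:3]}gen",
            family_prefix=f"{order[:3]}fam", root=off_root, seed=seed + 20 + k))
        out.extend(w.library_inserts())
    return out
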