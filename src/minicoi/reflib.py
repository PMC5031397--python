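"""Reference-library construction and curation.

Filters barcode records by marker label, length, ambiguity and taxonomic
depth; clusters them by greedy centroid selection at an identity threshold;
and trims them to the mini-barcode amplicon region by anchoring on the
primer footprints (records lacking footprints are excluded rather than
imputed).

Pairwise identity is matching columns / alignment length of a unit-cost
global alignment (edlib); length-equal near-identical inputs align
gaplessly under this metric.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib

from .primers import DegeneratePrimer, ScoringParams, insilico_pcr
from .seqcore import RefRecord, TaxonLineage, read_fasta, read_taxonomy, \
    attach_lineages, write_fasta, write_taxonomy, RANKS

__all__ = [
    "CurationParams",
    "ClusterParams",
    "ReferenceLibrary",
    "sequence_identity",
    "curate",
    "greedy_cluster",
    "ClusterResult",
    "trim_to_minibarcode",
    "load_library",
    "save_library",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def sequence_identity(a: str, b: str) -> float:
    """Matching columns / alignment columns of a global (NW) alignment."""
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    aln_len = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return 1.0 - res["editDistance"] / aln_len


@dataclass(frozen=True)
class CurationParams:
    """Reference curation filters, applied in the fixed order
    marker -> length -> ambiguity -> taxonomy."""

    min_len: int = 0
    max_len: Optional[int] = None
    require_marker: Optional[str] = None
    min_rank_depth: Optional[str] = None  # "genus" | "species"
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.max_len is not None and self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.min_rank_depth not in (None, "genus", "species"):
            raise ValueError("min_rank_depth must be genus or species")

    @classmethod
    def design_preset(cls) -> "CurationParams":
        """Primer-design curation: 500-700 nt, drop ambiguous characters."""
        return cls(min_len=500, max_len=700, drop_ambiguous=True)

    @classmethod
    def reference_preset(cls) -> "CurationParams":
        """Reference-library curation: >=500 nt COI-5P identified to genus
        or deeper, ambiguous characters dropped."""
        return cls(min_len=500, require_marker="COI-5P",
                   min_rank_depth="genus", drop_ambiguous=True)


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class ReferenceLibrary:
    """Curated, lineage-annotated barcode records with a provenance log.

    The provenance log records every rejection or trim as (id, action,
    reason) tuples.
    """

    records: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in library")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lineages(self) -> dict:
        return {r.id: r.lineage for r in self.records}

    def species(self) -> list:
        return sorted({r.lineage.species for r in self.records if r.lineage.species})

    def log(self, rid: str, action: str, reason: str) -> None:
        self.provenance.append((rid, action, reason))


def _first_failure(rec: RefRecord, p: CurationParams) -> Optional[str]:
    if p.require_marker and rec.marker != p.require_marker:
        return f"marker:{rec.marker or 'missing'}"
    n = len(rec.sequence)
    if n < p.min_len:
        return f"length:{n}<{p.min_len}"
    if p.max_len is not None and n > p.max_len:
        return f"length:{n}>{p.max_len}"
    if p.drop_ambiguous and rec.record.has_ambiguous():
        return "ambiguity"
    if p.min_rank_depth and not rec.lineage.get(p.min_rank_depth):
        return f"taxonomy:no_{p.min_rank_depth}"
    return None


def curate(records: Iterable[RefRecord],
           params: CurationParams) -> ReferenceLibrary:
    """Apply curation filters; the provenance log records one reason per
    rejection (the first failing filter)."""
    lib = ReferenceLibrary()
    for rec in records:
        reason = _first_failure(rec, params)
        if reason is None:
            lib.records.append(rec)
        else:
            lib.log(rec.id, "rejected", reason)
    return lib


@dataclass
class ClusterResult:
    centroids: list                 # RefRecords, in centroid creation order
    membership: dict                # record id -> centroid id
    sizes: dict                     # centroid id -> member count (incl. self)


def greedy_cluster(records: Sequence[RefRecord],
                   params: ClusterParams = ClusterParams()) -> ClusterResult:
    """Greedy centroid clustering at an identity threshold.

    Records are visited longest-first (ties by id); each joins the first
    existing centroid at identity >= t, else becomes a centroid itself.
    """
    t = params.identity_threshold
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    centroids: list = []
    membership: dict = {}
    sizes: dict = {}
    for rec in order:
        assigned = None
        for cen in centroids:
            if sequence_identity(rec.sequence, cen.sequence) >= t:
                assigned = cen
                break
        if assigned is None:
            centroids.append(rec)
            membership[rec.id] = rec.id
            sizes[rec.id] = 1
        else:
            membership[rec.id] = assigned.id
            sizes[assigned.id] += 1
    return ClusterResult(centroids=centroids, membership=membership, sizes=sizes)


def trim_to_minibarcode(records: Iterable[RefRecord],
                        fwd: DegeneratePrimer, rev: DegeneratePrimer,
                        scoring: ScoringParams = ScoringParams(),
                        keep_primers: bool = True) -> ReferenceLibrary:
    """Trim records to the mini-barcode amplicon via primer anchoring.

    ``keep_primers=True`` keeps the full product (both footprints included);
    ``False`` keeps only the insert between them.  Records the pair does not
    hit are excluded and logged.
    """
    records = list(records)
    hits = {h.ref_id: h for h in
            insilico_pcr(fwd, rev, [r.record for r in records], scoring)}
    lib = ReferenceLibrary()
    for rec in records:
        hit = hits.get(rec.id)
        if hit is None:
            lib.log(rec.id, "excluded", "no_amplicon")
            continue
        seq = hit.product_sequence if keep_primers else hit.insert_sequence
        lib.records.append(rec.with_sequence(seq))
        if len(seq) != len(rec.sequence):
            lib.log(rec.id, "trimmed", f"{len(rec.sequence)}->{len(seq)}")
    return lib


def load_library(fasta_path, taxonomy_path=None, marker: str = "COI-5P") -> list:
    """Load FASTA (+ optional taxonomy TSV) into RefRecords."""
    recs = read_fasta(fasta_path)
    lineages = read_taxonomy(taxonomy_path) if taxonomy_path else {}
    return attach_lineages(recs, lineages, marker=marker)


def save_library(lib: ReferenceLibrary, fasta_path, taxonomy_path=None,
                 provenance_path=None) -> None:
    write_fasta((r.record for r in lib.records), fasta_path)
    if taxonomy_path:
        write_taxonomy(lib.lineages, taxonomy_path)
    if provenance_path:
        with open(provenance_path, "w") as fh:
            fh.write("id\taction\treason\n")
            for rid, action, reason in lib.provenance:
                fh.write(f"{rid}\t{action}\t{reason}\n")
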