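"""IUPAC-aware sequence primitives and I/O.

Record types shared across the toolkit, FASTA/FASTQ reading and writing,
tab-separated taxonomy files, and a stop-codon (NUMT/pseudogene) screen
under the vertebrate mitochondrial genetic code.

Sequences are stored uppercase in DNA space (U is normalized to T) over the
full IUPAC nucleotide alphabet.  Taxonomy is restricted to the four ranks the
toolkit evaluates (order, family, genus, species); a BOLD-style subfamily
column is accepted on input and dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "MITO_STOPS",
    "RANKS",
    "NucRecord",
    "TaxonLineage",
    "RefRecord",
    "FastaParseError",
    "normalize_sequence",
    "iupac_match",
    "reverse_complement",
    "degeneracy",
    "expand_degenerate",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "parse_bold_lineage",
    "read_taxonomy",
    "write_taxonomy",
    "attach_lineages",
    "PseudogeneScreen",
    "pseudogene_screen",
]

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SET_TO_CODE = {s: c for c, s in IUPAC_SETS.items()}

#: Per-code complement derived from the base sets (R<->Y, W<->W, D<->H, ...).
IUPAC_COMPLEMENT: Mapping[str, str] = {
    code: _SET_TO_CODE[frozenset(_BASE_COMP[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}

#: Stop codons of the vertebrate mitochondrial genetic code.
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: Taxonomic ranks handled by the toolkit, deepest first.
RANKS = ("species", "genus", "family", "order")


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line number."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in IUPAC_SETS:
            raise ValueError(f"non-IUPAC symbol {ch!r} at position {i}")
    return s


def iupac_match(observed_base: str, code: str) -> bool:
    """True iff the observed base's set intersects the code's set.

    Both arguments may be degenerate; N matches everything.
    """
    try:
        a = IUPAC_SETS[observed_base.upper()]
        b = IUPAC_SETS[code.upper()]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol {exc.args[0]!r}") from None
    return bool(a & b)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the full IUPAC alphabet (an involution)."""
    s = normalize_sequence(sequence)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(s))


def degeneracy(sequence: str) -> int:
    """Product of per-position code cardinalities."""
    d = 1
    for c in normalize_sequence(sequence):
        d *= len(IUPAC_SETS[c])
    return d


def expand_degenerate(sequence: str) -> Iterable[str]:
    """Yield every concrete ACGT resolution of a degenerate sequence."""
    sets = [sorted(IUPAC_SETS[c]) for c in normalize_sequence(sequence)]
    for combo in itertools.product(*sets):
        yield "".join(combo)


@dataclass
class NucRecord:
    """A nucleotide sequence with optional per-base Phred quality."""

    id: str
    sequence: str
    description: str = ""
    quality: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.sequence = normalize_sequence(self.sequence)
        if self.quality is not None:
            self.quality = list(self.quality)
            if len(self.quality) != len(self.sequence):
                raise ValueError(
                    f"{self.id}: quality length {len(self.quality)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if any(q < 0 for q in self.quality):
                raise ValueError(f"{self.id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)

    def has_ambiguous(self) -> bool:
        """True if any position is a non-ACGT IUPAC code."""
        return any(c not in "ACGT" for c in self.sequence)


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered ranks order -> family -> genus -> species (binomial)."""

    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.species and not self.genus:
            raise ValueError(f"species {self.species!r} set without genus")
        for rank in RANKS:
            name = getattr(self, rank)
            if name is not None and "\t" in name:
                raise ValueError(f"{rank} name contains a tab: {name!r}")

    def get(self, rank: str) -> Optional[str]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    @property
    def deepest_rank(self) -> Optional[str]:
        for rank in RANKS:
            if getattr(self, rank):
                return rank
        return None

    def is_complete(self) -> bool:
        return all(getattr(self, r) for r in RANKS)

    def to_string(self) -> str:
        return ";".join(getattr(self, r) or "" for r in reversed(RANKS))


@dataclass
class RefRecord:
    """A reference barcode: sequence + lineage + marker label."""

    record: NucRecord
    lineage: TaxonLineage
    marker: str = "COI-5P"

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def with_sequence(self, sequence: str) -> "RefRecord":
        return RefRecord(
            record=replace(self.record, sequence=sequence, quality=None),
            lineage=self.lineage,
            marker=self.marker,
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into NucRecords (order-preserving, ids unique).

    Parsing is line-based so that malformed headers and empty sequences can
    be reported with their line number, which the toolkit's provenance logs
    rely on.
    """
    path = Path(path)
    records: list[NucRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}: empty sequence for header at line {header_line}")
        fields = header.split(None, 1)
        rid = fields[0]
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate id {rid!r} at line {header_line}")
        seen.add(rid)
        records.append(NucRecord(id=rid, sequence=seq,
                                 description=fields[1] if len(fields) > 1 else ""))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                if len(line) == 1:
                    raise FastaParseError(f"{path}: empty header at line {i}")
                header = line[1:].strip()
                header_line = i
            else:
                if header is None:
                    raise FastaParseError(f"{path}: sequence before header at line {i}")
                chunks.append(line)
        flush(-1)
    return records


def write_fasta(records: Iterable[NucRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path) -> list:
    """Read Phred+33 FASTQ via Biopython."""
    records = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fastq"):
        if sr.id in seen:
            raise ValueError(f"{path}: duplicate id {sr.id!r}")
        seen.add(sr.id)
        records.append(NucRecord(
            id=sr.id, sequence=str(sr.seq),
            description=sr.description[len(sr.id):].strip(),
            quality=sr.letter_annotations["phred_quality"],
        ))
    return records


def write_fastq(records: Iterable[NucRecord], path) -> None:
    out = []
    for rec in records:
        if rec.quality is None:
            raise ValueError(f"{rec.id}: FASTQ output requires quality scores")
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        sr.letter_annotations["phred_quality"] = list(rec.quality)
        out.append(sr)
    SeqIO.write(out, str(path), "fastq")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def parse_bold_lineage(row: str, colmap: Optional[Sequence[str]] = None,
                       sep: str = ";") -> TaxonLineage:
    """Parse a delimiter-separated lineage string into a TaxonLineage.

    Default column order is order;family;genus;species.  A five-field
    BOLD-style row (order;family;subfamily;genus;species) is accepted and the
    subfamily dropped.  ``colmap`` overrides the column->rank assignment
    (entries not in RANKS are ignored).
    """
    fields = [f.strip() for f in row.split(sep)]
    if colmap is None:
        if len(fields) == 5:
            colmap = ("order", "family", "subfamily", "genus", "species")
        else:
            colmap = ("order", "family", "genus", "species")[: len(fields)]
    kwargs = {}
    for rank, value in zip(colmap, fields):
        if rank in RANKS and value:
            kwargs[rank] = value
    return TaxonLineage(**kwargs)


def read_taxonomy(path, sep: str = ";") -> dict:
    """Read a taxonomy TSV: ``seq_id<TAB>order;family;genus;species``."""
    lineages: dict[str, TaxonLineage] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                rid, lin = line.split("\t", 1)
            except ValueError:
                raise ValueError(f"{path}: line {i} is not 'id<TAB>lineage'") from None
            lineages[rid.strip()] = parse_bold_lineage(lin, sep=sep)
    return lineages


def write_taxonomy(lineages: Mapping[str, TaxonLineage], path) -> None:
    with open(path, "w") as fh:
        for rid, lin in lineages.items():
            fh.write(f"{rid}\t{lin.to_string()}\n")


def attach_lineages(records: Iterable[NucRecord],
                    lineages: Mapping[str, TaxonLineage],
                    marker: str = "COI-5P") -> list:
    """Pair FASTA records with their taxonomy rows into RefRecords.

    Records without a taxonomy entry get an empty lineage (curation rejects
    them later if a rank depth is required).
    """
    out = []
    for rec in records:
        out.append(RefRecord(record=rec,
                             lineage=lineages.get(rec.id, TaxonLineage()),
                             marker=marker))
    return out


# ---------------------------------------------------------------------------
# Pseudogene (NUMT) screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudogeneScreen:
    status: str            # "pass" | "flagged"
    stop_count: int
    chosen_frame: int


def _codon_is_stop(codon: str) -> bool:
    # A degenerate codon counts as a stop only when every resolution is a
    # stop; curation removes ambiguous references, so this path matters for
    # reads only.
    if all(c in "ACGT" for c in codon):
        return codon in MITO_STOPS
    return all(res in MITO_STOPS for res in expand_degenerate(codon))


def _count_stops(seq: str, frame: int) -> int:
    n = 0
    for i in range(frame, len(seq) - 2, 3):
        if _codon_is_stop(seq[i:i + 3]):
            n += 1
    return n


def pseudogene_screen(sequence: str, frame="auto") -> PseudogeneScreen:
    """Flag putative nuclear pseudogenes via in-frame mitochondrial stops.

    Translation follows the vertebrate mitochondrial code, whose stops are
    TAA, TAG, AGA and AGG.  With ``frame="auto"`` the reading frame (0, 1, 2)
    minimizing the internal stop count is chosen (ties to the lowest frame);
    the sequence is flagged iff that minimal count is positive.
    """
    seq = normalize_sequence(sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if frame == "auto":
        counts = [_count_stops(seq, f) for f in (0, 1, 2)]
        chosen = int(min(range(3), key=lambda f: counts[f]))
        stops = counts[chosen]
    else:
        frame = int(frame)
        if frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1, 2 or 'auto'")
        chosen, stops = frame, _count_stops(seq, frame)
    return PseudogeneScreen(status="flagged" if stops > 0 else "pass",
                            stop_count=stops, chosen_frame=chosen)
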