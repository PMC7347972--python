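"""Reading, writing and per-base classification of annotated plastid genomes.

Internal coordinates are 0-based half-open everywhere; GenBank's 1-based
inclusive coordinates are converted at the I/O boundary.  Circular genomes
are linearized at the record's given origin; a feature spanning the origin
is stored as two intervals with ``wraps=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._codon import revcomp

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "pseudogene")
_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file."""


class AlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/T/N."""


class CoordinateError(ValueError):
    """Interval outside the genome."""


@dataclass(frozen=True)
class Feature:
    """One annotated locus.

    ``parts`` are 0-based half-open intervals stored in reading order:
    ascending genome order on the plus strand, descending on the minus
    strand.  ``codon_start`` is the 0-based phase offset (GenBank's
    /codon_start minus one).
    """

    name: str
    kind: str
    strand: str
    parts: tuple[tuple[int, int], ...]
    codon_start: int = 0
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.codon_start not in (0, 1, 2):
            raise ValueError("codon_start must be 0, 1 or 2")
        if not self.parts:
            raise ValueError("feature needs at least one interval")
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"empty/inverted interval [{s},{e}) in {self.name}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def genome_order_parts(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.parts))

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)


@dataclass
class PlastomeRecord:
    """One annotated (possibly circular) plastid genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise AlphabetError(f"{self.id}: non-DNA characters {sorted(bad)!r}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < e <= n):
                    raise CoordinateError(
                        f"{self.id}:{f.name} interval [{s},{e}) outside [0,{n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_named(self, name: str) -> list[Feature]:
        return [f for f in self.features if f.name == name]


# ---------------------------------------------------------------------------
# I/O


def _feature_from_biopython(bf) -> Feature | None:
    kind = bf.type
    if kind not in ("CDS", "tRNA", "rRNA"):
        return None
    quals = bf.qualifiers
    if "pseudo" in quals or "pseudogene" in quals:
        kind = "pseudogene"
    name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
    codon_start = int(quals.get("codon_start", [1])[0]) - 1
    strand = "-" if bf.location.strand == -1 else "+"
    parts = [(int(p.start), int(p.end)) for p in bf.location.parts]
    parts.sort(reverse=(strand == "-"))
    wraps = len(parts) > 1 and bf.location.parts[0].start > bf.location.parts[-1].start
    return Feature(
        name=name,
        kind=kind,
        strand=strand,
        parts=tuple(parts),
        codon_start=codon_start,
        wraps=wraps,
    )


def read_annotated_genome(path, format: str = "genbank") -> PlastomeRecord:
    """Read one GenBank or FASTA record into a :class:`PlastomeRecord`.

    GenBank locations (1-based inclusive, join()/complement()) become
    0-based half-open multi-part features with strand.
    """
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        rec = next(SeqIO.parse(str(path), format))
    except StopIteration:
        raise ParseError(f"{path}: no records found")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    circular = True
    if format == "genbank":
        circular = rec.annotations.get("topology", "circular") == "circular"
    feats = []
    if format == "genbank":
        for bf in rec.features:
            f = _feature_from_biopython(bf)
            if f is not None:
                feats.append(f)
    return PlastomeRecord(
        id=rec.id,
        sequence=str(rec.seq),
        circular=circular,
        features=feats,
        source=f"{format}:{path}",
    )


def write_genome(record: PlastomeRecord, path, format: str = "genbank") -> None:
    """Write a record back to GenBank or FASTA."""
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, description=record.source)
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.genome_order_parts()]
        if f.strand == "-":
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = "CDS" if f.kind == "pseudogene" else f.kind
        quals = {"gene": [f.name]}
        if f.kind in ("CDS", "pseudogene"):
            quals["codon_start"] = [str(f.codon_start + 1)]
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([seqrec], str(path), format)


# ---------------------------------------------------------------------------
# Per-base statistics


def gc_content(record: PlastomeRecord, interval: tuple[int, int] | None = None) -> float:
    """GC fraction (G+C)/(A+C+G+T) over ``interval`` (whole genome if None).

    N bases are excluded from numerator and denominator.  On circular
    records an interval with start > end wraps through the origin.
    """
    n = len(record)
    if interval is None:
        seq = record.sequence
    else:
        s, e = interval
        if not (0 <= s <= n and 0 <= e <= n):
            raise CoordinateError(f"interval [{s},{e}) outside genome")
        if s == e:
            raise ValueError("empty interval")
        if s < e:
            seq = record.sequence[s:e]
        else:
            if not record.circular:
                raise CoordinateError("wrapped interval on a linear record")
            seq = record.sequence[s:] + record.sequence[:e]
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("interval contains no unambiguous bases")
    return gc / acgt


def extract_feature_sequence(record: PlastomeRecord, feature: Feature) -> str:
    """Feature sequence in reading direction.

    Parts are concatenated in reading order; minus-strand parts are
    reverse-complemented.  For CDS features the ``codon_start`` phase
    bases are trimmed.
    """
    n = len(record)
    chunks = []
    for s, e in feature.parts:
        if not (0 <= s < e <= n):
            raise CoordinateError(f"interval [{s},{e}) outside genome")
        piece = record.sequence[s:e]
        if feature.strand == "-":
            piece = revcomp(piece)
        chunks.append(piece)
    seq = "".join(chunks)
    if feature.kind == "CDS" and feature.codon_start:
        seq = seq[feature.codon_start :]
    return seq


# ---------------------------------------------------------------------------
# Region classification

CLASS_IGS = "IGS"
CLASS_INTRON = "intron"
CLASS_CDS = "CDS"


@dataclass
class RegionClassMap:
    """Per-base CDS/intron/IGS classification of one genome.

    ``intervals`` tile the genome: (start, end, class, locus).  IGS names
    are "geneA-geneB" from the flanking loci in genome order.  Overlaps
    between features are resolved by precedence CDS > intron > IGS and
    recorded in ``overlaps``.
    """

    seq_id: str
    length: int
    intervals: list[tuple[int, int, str, str]]
    overlaps: list[tuple[int, int, str]] = field(default_factory=list)

    def class_at(self, pos: int) -> tuple[str, str]:
        for s, e, cls, locus in self.intervals:
            if s <= pos < e:
                return cls, locus
        raise CoordinateError(f"position {pos} outside [0,{self.length})")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tstart\tend\tclass\tlocus\n")
            for s, e, cls, locus in self.intervals:
                fh.write(f"{self.seq_id}\t{s}\t{e}\t{cls}\t{locus}\n")


def region_class_map(record: PlastomeRecord) -> RegionClassMap:
    """Classify every base as CDS (any exon), intron, or IGS.

    Bases inside any CDS/tRNA/rRNA/pseudogene exon are CDS-class, owned
    by that gene; bases between consecutive parts of one feature are
    intron; everything else is IGS named by its flanking genes.
    """
    n = len(record)
    # 0 = IGS, 1 = intron, 2 = exon; higher wins
    cls = np.zeros(n, dtype=np.int8)
    owner = np.full(n, "", dtype=object)
    overlaps: list[tuple[int, int, str]] = []

    def paint(s: int, e: int, level: int, name: str) -> None:
        seg_cls = cls[s:e]
        clash = (seg_cls >= level) & (seg_cls > 0)
        if clash.any():
            overlaps.append((s, e, name))
        take = seg_cls < level
        seg_cls[take] = level
        owner_seg = owner[s:e]
        owner_seg[take] = name
        cls[s:e] = seg_cls
        owner[s:e] = owner_seg

    for f in record.features:
        gparts = f.genome_order_parts()
        for s, e in gparts:
            paint(s, e, 2, f.name)
        if len(gparts) > 1 and not f.wraps:
            for (s1, e1), (s2, _) in zip(gparts, gparts[1:]):
                if e1 < s2:
                    paint(e1, s2, 1, f.name)

    # name IGS runs by flanking genes (genome order, circular wrap)
    intervals: list[tuple[int, int, str, str]] = []
    boundaries = [0]
    for i in range(1, n):
        if cls[i] != cls[i - 1] or owner[i] != owner[i - 1]:
            boundaries.append(i)
    boundaries.append(n)
    runs = [
        (boundaries[i], boundaries[i + 1], int(cls[boundaries[i]]), owner[boundaries[i]])
        for i in range(len(boundaries) - 1)
    ]
    # merge circular wrap of an IGS split across the origin: kept as two
    # intervals (tiling), but they share one name.
    names = []
    for idx, (s, e, c, o) in enumerate(runs):
        if c == 0:
            left = right = "?"
            for j in range(1, len(runs) + 1):
                cand = runs[(idx - j) % len(runs)]
                if cand[2] > 0:
                    left = cand[3]
                    break
            for j in range(1, len(runs) + 1):
                cand = runs[(idx + j) % len(runs)]
                if cand[2] > 0:
                    right = cand[3]
                    break
            name = f"{left}-{right}" if left != "?" else "genome"
            names.append((s, e, CLASS_IGS, name))
        elif c == 1:
            names.append((s, e, CLASS_INTRON, o))
        else:
            names.append((s, e, CLASS_CDS, o))
    intervals = names
    return RegionClassMap(record.id, n, intervals, overlaps)
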