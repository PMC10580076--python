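"""Core DNA record model and GenBank/FASTA I/O.

A :class:`DnaMolecule` is an annotated double-stranded sequence, circular or
linear, represented by its top strand 5'->3'.  All coordinates are 0-based,
half-open, on the top strand; GenBank's 1-based inclusive convention is
converted at the I/O boundary only.  On circular molecules a feature may span
the origin, in which case its ``end`` exceeds the molecule length and wraps
(``end <= start + length`` always holds).

I/O goes through Biopython's ``SeqIO``; this module only translates between
``SeqRecord`` and the internal types.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, TopologyError, ValidationError

ALPHABET = set("ACGTN")

#: Controlled vocabulary for feature kinds (the part categories of a Golden
#: Gate kit: promoters, fluorescent proteins, tags/linkers, ORFs, 3' UTRs,
#: selection markers, recombination and enzyme recognition sites).
FEATURE_KINDS = (
    "promoter",
    "CDS",
    "fluorophore",
    "linker",
    "utr3",
    "selection_marker",
    "recombination_site",
    "recognition_site",
    "misc",
)

# GenBank feature keys with a 1:1 kind mapping; everything else round-trips
# through misc_feature with a ``/note="ggkit_kind: ..."`` qualifier.
_KIND_TO_GB = {"promoter": "promoter", "CDS": "CDS", "utr3": "3'UTR"}
_GB_TO_KIND = {v: k for k, v in _KIND_TO_GB.items()}
_KIND_NOTE = "ggkit_kind: "

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp_seq(s: str) -> str:
    """Reverse complement of a plain top-strand string."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """An annotated interval: 0-based half-open, strand +1/-1.

    ``end`` may exceed the molecule length on circular records (origin wrap).
    """

    label: str
    kind: str
    start: int
    end: int
    strand: int = 1

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.start >= self.end:
            raise ValidationError(
                f"feature {self.label!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in (1, -1):
            raise ValidationError(f"feature {self.label!r}: strand must be +1/-1")

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class DnaMolecule:
    """Double-stranded DNA given by its top strand, with typed features."""

    id: str
    sequence: str
    topology: str = "linear"  # "circular" | "linear"
    features: list[Feature] = field(default_factory=list)
    source_kind: str = "plasmid"  # "plasmid" | "pcr_product" | "oligo_duplex"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"{self.id}: disallowed characters {sorted(bad)}; only A/C/G/T/N "
                "are accepted (other ambiguity codes are rejected)"
            )
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"{self.id}: topology must be circular or linear")
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < n):
                raise ValidationError(
                    f"{self.id}: feature {f.label!r} start {f.start} outside [0,{n})"
                )
            if f.end > f.start + n or (self.topology == "linear" and f.end > n):
                raise ValidationError(
                    f"{self.id}: feature {f.label!r} interval [{f.start},{f.end}) "
                    f"invalid for {self.topology} length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def subseq(self, start: int, end: int) -> str:
        """Top-strand slice [start, end); wraps on circular molecules.

        The span length ``end - start`` must lie in [0, length]; ``start`` is
        taken modulo the length on circular records.
        """
        n = len(self.sequence)
        span = end - start
        if not 0 <= span <= n:
            raise ValidationError(f"{self.id}: slice span {span} outside [0,{n}]")
        if self.is_circular:
            start %= n
            return (self.sequence + self.sequence)[start : start + span]
        if start < 0 or end > n:
            raise ValidationError(f"{self.id}: slice [{start},{end}) outside linear record")
        return self.sequence[start:end]


def revcomp(mol: DnaMolecule) -> DnaMolecule:
    """Reverse-complement a molecule, remapping features to the new top strand."""
    n = len(mol)
    feats = []
    for f in mol.features:
        length = len(f)
        new_start = (n - f.end) % n
        feats.append(
            Feature(f.label, f.kind, new_start, new_start + length, -f.strand)
        )
    feats.sort(key=lambda f: (f.start, f.end))
    return DnaMolecule(
        id=mol.id,
        sequence=revcomp_seq(mol.sequence),
        topology=mol.topology,
        features=feats,
        source_kind=mol.source_kind,
    )


def rotate(mol: DnaMolecule, new_origin: int) -> DnaMolecule:
    """Move the origin of a circular molecule to ``new_origin``."""
    if not mol.is_circular:
        raise TopologyError(f"{mol.id}: rotate is only defined on circular molecules")
    n = len(mol)
    k = new_origin % n
    seq = mol.sequence[k:] + mol.sequence[:k]
    feats = []
    for f in mol.features:
        start = (f.start - k) % n
        feats.append(Feature(f.label, f.kind, start, start + len(f), f.strand))
    feats.sort(key=lambda f: (f.start, f.end))
    return DnaMolecule(mol.id, seq, "circular", feats, mol.source_kind)


# ---------------------------------------------------------------------------
# SeqRecord conversion


def _feature_from_seqfeature(sf: SeqFeature, length: int, topology: str) -> Feature | None:
    kind = _GB_TO_KIND.get(sf.type)
    label = ""
    for key in ("label", "gene", "product", "standard_name"):
        if key in sf.qualifiers:
            label = str(sf.qualifiers[key][0])
            break
    if kind is None:
        kind = "misc"
        for note in sf.qualifiers.get("note", []):
            if note.startswith(_KIND_NOTE):
                cand = note[len(_KIND_NOTE) :].strip()
                if cand in FEATURE_KINDS:
                    kind = cand
    loc = sf.location
    if loc is None:
        return None
    strand = -1 if loc.strand == -1 else 1
    if isinstance(loc, CompoundLocation) and topology == "circular":
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # join(a..length, 1..b) -> unwrapped interval spanning the origin
        if (
            len(parts) == 2
            and int(parts[1].end) == length
            and int(parts[0].start) == 0
        ):
            start = int(parts[1].start)
            end = length + int(parts[0].end)
            return Feature(label, kind, start, end, strand)
    start, end = int(loc.start), int(loc.end)
    return Feature(label, kind, start, end, strand)


def _seqfeature_from_feature(f: Feature, length: int) -> SeqFeature:
    gb_type = _KIND_TO_GB.get(f.kind, "misc_feature")
    quals: dict = {"label": [f.label]}
    if gb_type == "misc_feature":
        quals["note"] = [f"{_KIND_NOTE}{f.kind}"]
    if f.end <= length:
        loc = SimpleLocation(f.start, f.end, strand=f.strand)
    else:  # origin-spanning: emit join(start..length, 0..end-length)
        p1 = SimpleLocation(f.start, length, strand=f.strand)
        p2 = SimpleLocation(0, f.end - length, strand=f.strand)
        parts = [p1, p2] if f.strand == 1 else [p2, p1]
        loc = CompoundLocation(parts)
    return SeqFeature(loc, type=gb_type, qualifiers=quals)


def to_seqrecord(mol: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(Seq(mol.sequence), id=mol.id, name=mol.id[:16] or "record", description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    rec.annotations["date"] = "01-JAN-2000"  # fixed so outputs are byte-reproducible
    rec.features = [_seqfeature_from_feature(f, len(mol)) for f in mol.features]
    return rec


def from_seqrecord(rec: SeqRecord, source_kind: str = "plasmid") -> DnaMolecule:
    topo = rec.annotations.get("topology", "linear")
    if topo not in ("circular", "linear"):
        warnings.warn(f"{rec.id}: unknown topology token {topo!r}; treating as linear")
        topo = "linear"
    feats = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        f = _feature_from_seqfeature(sf, len(rec.seq), topo)
        if f is not None:
            feats.append(f)
    return DnaMolecule(
        id=rec.id, sequence=str(rec.seq), topology=topo, features=feats,
        source_kind=source_kind,
    )


# ---------------------------------------------------------------------------
# File I/O


def read_record(path, format: str = "genbank") -> DnaMolecule:
    """Read a single GenBank/FASTA record into a :class:`DnaMolecule`."""
    return _one(read_records(path, format))


def read_records(path, format: str = "genbank") -> list[DnaMolecule]:
    if format not in ("genbank", "fasta"):
        raise FormatError(f"unsupported format {format!r}")
    try:
        recs = list(SeqIO.parse(str(path), format))
    except (ValueError, Exception) as exc:  # Biopython raises bare ValueError
        raise FormatError(f"{path}: failed to parse as {format}: {exc}") from exc
    if not recs:
        raise FormatError(f"{path}: no records found ({format})")
    return [from_seqrecord(r) for r in recs]


def _one(mols: list[DnaMolecule]) -> DnaMolecule:
    if len(mols) != 1:
        raise FormatError(f"expected exactly one record, found {len(mols)}")
    return mols[0]


def write_record(mol: DnaMolecule, path, format: str = "genbank") -> None:
    """Write one molecule; the write is atomic (temp file + rename)."""
    write_records([mol], path, format)


def write_records(mols, path, format: str = "genbank") -> None:
    if format not in ("genbank", "fasta"):
        raise FormatError(f"unsupported format {format!r}")
    path = str(path)
    recs = [to_seqrecord(m) for m in mols]
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            SeqIO.write(recs, fh, format)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
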