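"""Type IIS enzyme definitions, site finding and digestion.

A type IIS enzyme (SapI, BsaI, ...) recognises a short non-palindromic
sequence and cuts *outside* it at a fixed offset, leaving a short 5' overhang
whose sequence is unconstrained by the recognition site.  Cut geometry for a
top-strand site ``REC`` is::

    5'-R E C n t . . b-3'        t = rec_end + cut_offset_top
    3'-r e c n n n n b-5'        b = rec_end + cut_offset_bottom

so the single-stranded extension is the top-strand window ``[t, b)`` — a 5'
overhang of ``cut_offset_bottom - cut_offset_top`` nucleotides.  A site on the
bottom strand mirrors this arithmetic to the left of the top-strand match.

Junction-label convention: the *label* of a sticky end is the top-strand
sequence of the duplex that the overhang will form once ligated.  Two ends are
ligatable iff their labels are EQUAL (not reverse complements); the
reverse-complement pairing is absorbed when a fragment is flipped, which swaps
the ends and reverse-complements both labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, ValidationError
from .seq_model import DnaMolecule, Feature, revcomp_seq

# ---------------------------------------------------------------------------
# Enzymes


@dataclass(frozen=True)
class EnzymeSpec:
    """A type IIS enzyme: recognition sequence plus downstream cut offsets."""

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self):
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if not rec or set(rec) - set("ACGT"):
            raise ConfigError(f"{self.name}: recognition must be plain A/C/G/T")

    @property
    def overhang_len(self) -> int:
        return self.cut_offset_bottom - self.cut_offset_top

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp_seq(self.recognition)

    def validate_for_assembly(self) -> None:
        if self.is_palindromic:
            raise ConfigError(
                f"{self.name}: assembly enzymes must have a non-palindromic "
                "recognition sequence"
            )
        if not 2 <= self.overhang_len <= 4:
            raise ConfigError(
                f"{self.name}: assembly enzymes must leave 2-4 nt 5' overhangs "
                f"(got {self.overhang_len})"
            )


#: Built-in enzyme table.  Offsets cross-checked against the public
#: restriction-enzyme registry (REBASE, as shipped with Biopython):
#: SapI GCTCTTC(1/4), BsaI GGTCTC(1/5); LguI is a SapI isoschizomer.
SAPI = EnzymeSpec("SapI", "GCTCTTC", 1, 4)
LGUI = EnzymeSpec("LguI", "GCTCTTC", 1, 4)
BSAI = EnzymeSpec("BsaI", "GGTCTC", 1, 5)

ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (SAPI, LGUI, BSAI)}


def get_enzyme(name: str | EnzymeSpec) -> EnzymeSpec:
    if isinstance(name, EnzymeSpec):
        return name
    try:
        return ENZYMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown enzyme {name!r}; known: {', '.join(sorted(ENZYMES))}"
        ) from None


def load_enzyme_table(path) -> dict[str, EnzymeSpec]:
    """Load a plain-text enzyme table: name, recognition, top offset, bottom offset.

    Tab- or whitespace-delimited, ``#`` comments allowed.  Entries are merged
    into (and returned with) the built-in table.
    """
    table = dict(ENZYMES)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ConfigError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            name, rec, top, bottom = fields
            try:
                spec = EnzymeSpec(name, rec, int(top), int(bottom))
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: {exc}") from exc
            table[name] = spec
    return table


# ---------------------------------------------------------------------------
# Site finding


@dataclass(frozen=True)
class SiteMatch:
    """One recognition-site occurrence with its implied cut positions.

    ``cut_top``/``cut_bottom`` are top-strand indices (bond before the index);
    on circular molecules ``cut_top`` is normalised to [0, n) and
    ``cut_bottom = cut_top + overhang_len``.  On linear molecules the cuts may
    fall outside [0, n] when the site sits too close to an end to be cut.
    """

    enzyme: str
    strand: int  # +1 site read on top strand, -1 on bottom
    recognition_start: int
    cut_top: int
    cut_bottom: int


def _scan(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_sites(mol: DnaMolecule, enzyme: str | EnzymeSpec) -> list[SiteMatch]:
    """All occurrences of the recognition sequence on either strand.

    Circular wrap is handled by scanning the sequence extended with a prefix
    of length ``len(recognition) - 1`` and de-duplicating modulo length.
    """
    enz = get_enzyme(enzyme)
    rec = enz.recognition
    if "N" in rec:
        raise ValidationError("recognition sequences may not contain N")
    n = len(mol)
    seq = mol.sequence
    hay = seq + seq[: len(rec) - 1] if mol.is_circular else seq
    matches: list[SiteMatch] = []
    seen: set[tuple[int, int]] = set()
    for strand, needle in ((1, rec), (-1, revcomp_seq(rec))):
        for r in _scan(hay, needle):
            r0 = r % n if mol.is_circular else r
            if (strand, r0) in seen:
                continue
            seen.add((strand, r0))
            if strand == 1:
                t = r0 + len(rec) + enz.cut_offset_top
            else:
                t = r0 - enz.cut_offset_bottom
            if mol.is_circular:
                t %= n
            matches.append(
                SiteMatch(enz.name, strand, r0, t, t + enz.overhang_len)
            )
    matches.sort(key=lambda m: (m.recognition_start, m.strand))
    return matches


def count_sites_in_str(seq: str, enzyme: str | EnzymeSpec) -> int:
    """Recognition occurrences (both strands) in a plain linear string."""
    enz = get_enzyme(enzyme)
    return len(_scan(seq, enz.recognition)) + len(_scan(seq, revcomp_seq(enz.recognition)))


@dataclass
class DomesticationReport:
    """Per-enzyme internal recognition-site counts for a molecule."""

    molecule_id: str
    counts: dict[str, int]

    @property
    def ok(self) -> bool:
        return all(c == 0 for c in self.counts.values())


def is_domesticated(mol: DnaMolecule, enzymes) -> DomesticationReport:
    """Count recognition sites per enzyme; all-zero means the part is usable."""
    counts = {}
    for e in enzymes:
        enz = get_enzyme(e)
        counts[enz.name] = len(find_sites(mol, enz))
    return DomesticationReport(mol.id, counts)


# ---------------------------------------------------------------------------
# Fragments


@dataclass(frozen=True)
class End:
    """End chemistry of a fragment: blunt, or a 5' overhang with its label."""

    kind: str  # "blunt" | "five_prime"
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("blunt", "five_prime"):
            raise ValidationError(f"unknown end kind {self.kind!r}")
        if self.kind == "five_prime":
            if not self.label or "N" in self.label:
                raise ValidationError("overhang labels must be N-free and non-empty")

    @property
    def is_sticky(self) -> bool:
        return self.kind == "five_prime"


BLUNT = End("blunt")


def sticky(label: str) -> End:
    return End("five_prime", label)


@dataclass
class StickyFragment:
    """A linear duplex with explicit end chemistry.

    ``sequence`` is the top-strand string of the *full fragment span*: it
    includes the left overhang and, at the right end, the top-strand sequence
    of the duplex the right overhang will form (physically contributed by the
    protruding bottom strand).  With this convention, ligating A to B yields
    ``A.sequence + B.sequence[overhang:]`` and a circular closure of n
    fragments has length ``sum(len) - n * overhang_len``.

    ``top_strand`` is the physical top strand (the span minus the right
    junction region) — the multiset of these across a digest equals the
    input's top strand.
    """

    sequence: str
    left_end: End = BLUNT
    right_end: End = BLUNT
    source_id: str = ""
    provenance: list[tuple] = field(default_factory=list)  # (source_id, start, end, strand)
    features: list[Feature] = field(default_factory=list)  # fragment coordinates
    circular: bool = False  # an uncut circular input passed through digest
    precut: bool = False  # supplied with ends already formed (oligo duplex)
    directional: bool = False  # may not be flipped during assembly

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.left_end.is_sticky and self.sequence[: len(self.left_end.label)] != self.left_end.label:
            raise ValidationError("left overhang label must prefix the span sequence")
        if self.right_end.is_sticky and self.sequence[-len(self.right_end.label):] != self.right_end.label:
            raise ValidationError("right overhang label must suffix the span sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def left_label(self) -> str | None:
        return self.left_end.label if self.left_end.is_sticky else None

    @property
    def right_label(self) -> str | None:
        return self.right_end.label if self.right_end.is_sticky else None

    @property
    def top_strand(self) -> str:
        if self.right_end.is_sticky:
            return self.sequence[: len(self.sequence) - len(self.right_end.label)]
        return self.sequence

    def rc(self) -> "StickyFragment":
        """The same physical fragment written in the flipped orientation."""
        m = len(self.sequence)
        new_left = (
            sticky(revcomp_seq(self.right_end.label)) if self.right_end.is_sticky else BLUNT
        )
        new_right = (
            sticky(revcomp_seq(self.left_end.label)) if self.left_end.is_sticky else BLUNT
        )
        feats = [
            Feature(f.label, f.kind, m - f.end, m - f.start, -f.strand)
            for f in self.features
        ]
        feats.sort(key=lambda f: (f.start, f.end))
        prov = [(sid, s, e, -st) for (sid, s, e, st) in reversed(self.provenance)]
        return StickyFragment(
            sequence=revcomp_seq(self.sequence),
            left_end=new_left,
            right_end=new_right,
            source_id=self.source_id,
            provenance=prov,
            features=feats,
            circular=self.circular,
            precut=self.precut,
            directional=self.directional,
        )

    def internal_site_count(self, enzyme: str | EnzymeSpec) -> int:
        return count_sites_in_str(self.sequence, enzyme)


# ---------------------------------------------------------------------------
# Digestion


def _carry_features(mol: DnaMolecule, span_start: int, span_len: int) -> list[Feature]:
    """Source features fully contained in the span, shifted to span coordinates."""
    n = len(mol)
    out = []
    for f in mol.features:
        if mol.is_circular:
            fs = span_start + ((f.start - span_start) % n)
        else:
            fs = f.start
        fe = fs + len(f)
        if fs >= span_start and fe <= span_start + span_len:
            out.append(Feature(f.label, f.kind, fs - span_start, fe - span_start, f.strand))
    out.sort(key=lambda f: (f.start, f.end))
    return out


def digest(mol: DnaMolecule, enzyme: str | EnzymeSpec) -> list[StickyFragment]:
    """Digest to completion with one type IIS enzyme.

    Returns the sticky-ended fragments in top-strand order.  A molecule with
    no cuttable site passes through as a single fragment (flagged ``circular``
    if the input was circular).
    """
    enz = get_enzyme(enzyme)
    if enz.overhang_len < 1:
        raise ConfigError(f"{enz.name}: digestion requires a positive 5' overhang")
    n = len(mol)
    sites = find_sites(mol, enz)
    if mol.is_circular:
        cuts = sorted({(s.cut_top, s.cut_bottom) for s in sites})
    else:
        cuts = sorted(
            {(s.cut_top, s.cut_bottom) for s in sites if s.cut_top >= 0 and s.cut_bottom <= n}
        )
    for t, b in cuts:
        if not mol.is_circular and not (0 <= t and b <= n):
            raise ConfigError(f"{enz.name}: cut [{t},{b}) outside sequence of length {n}")

    if not cuts:
        return [
            StickyFragment(
                sequence=mol.sequence,
                left_end=BLUNT,
                right_end=BLUNT,
                source_id=mol.id,
                provenance=[(mol.id, 0, n, 1)],
                features=_carry_features(mol, 0, n),
                circular=mol.is_circular,
            )
        ]

    # span slices may reach t + n + overhang, past the doubled sequence
    doubled = mol.sequence * 2 + mol.sequence[: enz.overhang_len]
    frags: list[StickyFragment] = []
    if mol.is_circular:
        k = len(cuts)
        for i in range(k):
            t_i, _ = cuts[i]
            t_j, b_j = cuts[(i + 1) % k]
            core = n if k == 1 else (t_j - t_i) % n
            span = core + enz.overhang_len
            seq = doubled[t_i : t_i + span]
            frags.append(
                StickyFragment(
                    sequence=seq,
                    left_end=sticky(seq[: enz.overhang_len]),
                    right_end=sticky(seq[-enz.overhang_len :]),
                    source_id=mol.id,
                    provenance=[(mol.id, t_i, t_i + span, 1)],
                    features=_carry_features(mol, t_i, span),
                )
            )
    else:
        bounds = [(0, None)] + [(t, b) for (t, b) in cuts] + [(n, None)]
        for i in range(len(bounds) - 1):
            t_i = bounds[i][0]
            t_next, b_next = bounds[i + 1]
            span_end = b_next if b_next is not None else t_next
            seq = mol.sequence[t_i:span_end]
            left = sticky(seq[: enz.overhang_len]) if bounds[i][1] is not None else BLUNT
            right = sticky(seq[-enz.overhang_len :]) if b_next is not None else BLUNT
            frags.append(
                StickyFragment(
                    sequence=seq,
                    left_end=left,
                    right_end=right,
                    source_id=mol.id,
                    provenance=[(mol.id, t_i, span_end, 1)],
                    features=_carry_features(mol, t_i, span_end - t_i),
                )
            )
    return frags
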