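"""Design of inputs that create new parts.

Four routes into the kit are covered:

* **BsaI-tailed primers** that amplify an insert for ligation into an empty
  KanR entry vector, yielding a new SapI entry clone (the toolkit's standard
  route for novel parts).
* **SapI-tailed primers** whose PCR product is used directly in an assembly,
  skipping the intermediate clone.
* **Annealed oligo duplexes** supplied pre-cut with the scheme's overhangs.
* **Domestication plans** that remove internal SapI/BsaI sites by fragmenting
  the insert at each site, lesioning one base per site (synonymously when a
  reading frame is supplied), and reassembling the sub-amplicons with BsaI.

Primer tail anatomy (5'->3'): 2-nt spacer, recognition site, offset base(s),
junction label, template homology.  The melting-temperature rule is the
deliberately crude Wallace rule (2 degC per A/T, 4 per G/C) on the homology
region, with the homology extended from 18 nt until Tm >= 55 degC, capped at
35 nt.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from Bio.Seq import Seq

from . import fixtures
from .errors import (
    AnnealError,
    ConfigError,
    DomesticationRequired,
    GGError,
    NoSilentLesion,
    SynthesisRecommended,
    ValidationError,
)
from .seq_model import DnaMolecule, Feature, revcomp_seq
from .slots import SlotScheme, Span, classify_part, get_scheme
from .typeiis import (
    BSAI,
    SAPI,
    EnzymeSpec,
    StickyFragment,
    count_sites_in_str,
    digest,
    find_sites,
    get_enzyme,
    is_domesticated,
    sticky,
)

SPACER = "AA"  # cutting-efficiency padding ahead of the recognition site
MIN_HOMOLOGY = 18
MAX_HOMOLOGY = 35
TM_MIN = 55.0
MIN_ANNEAL = 12  # shortest primer 3' match accepted by the PCR simulator


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C) degC."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def _choose_homology(region: str) -> str:
    """Extend from the 5' end of ``region`` until the Tm rule is satisfied."""
    n = min(len(region), MAX_HOMOLOGY)
    if len(region) < MIN_HOMOLOGY:
        raise ValidationError(f"template too short for a {MIN_HOMOLOGY}-nt homology region")
    length = MIN_HOMOLOGY
    while length < n and wallace_tm(region[:length]) < TM_MIN:
        length += 1
    return region[:length]


@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str
    fwd_homology_len: int
    rev_homology_len: int

    @property
    def fwd_tm(self) -> float:
        return wallace_tm(self.forward[-self.fwd_homology_len:])

    @property
    def rev_tm(self) -> float:
        return wallace_tm(self.reverse[-self.rev_homology_len:])


# ---------------------------------------------------------------------------
# PCR simulation


def _anchor(primer: str, hay: str) -> tuple[int, int]:
    """(match start in hay, matched suffix length) for the longest primer
    suffix with a unique exact occurrence."""
    for length in range(len(primer), MIN_ANNEAL - 1, -1):
        suffix = primer[-length:]
        first = hay.find(suffix)
        if first == -1:
            continue
        if hay.find(suffix, first + 1) != -1:
            raise ValidationError("primer anneals at multiple template positions")
        return first, length
    raise ValidationError(
        "primer 3' end does not match the template exactly "
        f"(no suffix of >= {MIN_ANNEAL} nt found)"
    )


def _reject_internal_mismatch(primer: str, hay: str, a: int, h: int) -> None:
    """Reject a primer whose homology region continues matching upstream of a
    mismatch — an enzyme tail diverges from the template, a typo does not."""
    tail_len = len(primer) - h
    if a == 0 or tail_len == 0:
        return
    k_max = min(8, a - 1, tail_len - 1)
    if k_max < 3:
        return
    matches = sum(
        primer[tail_len - 1 - k] == hay[a - 1 - k] for k in range(1, k_max + 1)
    )
    if matches >= max(3, (3 * k_max) // 4):
        raise ValidationError(
            "primer mismatches the template inside its homology region "
            f"(alignment resumes upstream of template position {a})"
        )


def simulate_pcr(template: DnaMolecule, forward: str, reverse: str,
                 product_id: str = "pcr") -> DnaMolecule:
    """Exact-homology PCR: tails are carried through, mismatches are rejected."""
    if template.is_circular:
        raise ValidationError("PCR simulation expects a linear template")
    top = template.sequence
    forward, reverse = forward.upper(), reverse.upper()
    a, hf = _anchor(forward, top)
    _reject_internal_mismatch(forward, top, a, hf)
    b_rc, hr = _anchor(reverse, revcomp_seq(top))
    _reject_internal_mismatch(reverse, revcomp_seq(top), b_rc, hr)
    b = len(top) - b_rc  # rightmost template position covered by the reverse primer
    if a + hf > b - hr:
        raise ValidationError("primers overlap on the template")
    seq = forward + top[a + hf : b - hr] + revcomp_seq(reverse)
    return DnaMolecule(product_id, seq, "linear", source_kind="pcr_product")


# ---------------------------------------------------------------------------
# Entry-clone and direct-PCR primer design


@dataclass
class EntryDesign:
    """Primer pair plus the matching empty vector and the predicted clone."""

    primers: PrimerPair
    vector: DnaMolecule | None
    pcr_product: DnaMolecule
    predicted_clone: DnaMolecule | None
    span: Span


def _require_domesticated(insert: DnaMolecule, enzymes) -> None:
    report = is_domesticated(insert, enzymes)
    if not report.ok:
        raise DomesticationRequired(
            f"{insert.id}: internal recognition sites {report.counts}; "
            "run plan_domestication first",
            site_counts=report.counts,
        )


def design_entry_primers(
    insert: DnaMolecule,
    span: Span | str,
    scheme: SlotScheme | str,
    tail_enzyme: EnzymeSpec | str = BSAI,
    *,
    vector_seed: int = 0,
) -> EntryDesign:
    """BsaI-tailed primers creating a new SapI entry clone for ``span``.

    The full round trip is simulated at design time — PCR, tail-enzyme
    assembly into a generated empty KanR vector, classification of the
    resulting clone — and the offset pad bases are varied deterministically
    until the predicted clone digests to exactly one clean insert.
    """
    scheme = get_scheme(scheme)
    if isinstance(span, str):
        span = (span, span)
    tail = get_enzyme(tail_enzyme)
    senz = scheme.enzyme
    _require_domesticated(insert, [senz, tail])
    left, right = scheme.span_labels(span)
    hf = _choose_homology(insert.sequence)
    hr = _choose_homology(revcomp_seq(insert.sequence))

    rng = random.Random(vector_seed)
    backbone = fixtures._scrub(fixtures._rand_seq(rng, 260), [senz, tail])
    stuffer = fixtures._scrub(fixtures._rand_seq(rng, 90), [senz, tail])

    last_error = None
    for lp in "ACGT":
        for rp in "TGCA":
            bl = lp * senz.cut_offset_top + left
            br = right + rp * senz.cut_offset_top
            labels = {bl, br}
            if len(labels) < 2 or any(l == revcomp_seq(l) for l in labels) \
                    or bl == revcomp_seq(br):
                continue
            fwd = SPACER + tail.recognition + fixtures._pad(tail, "A") + bl + hf
            rev = SPACER + tail.recognition + fixtures._pad(tail, "A") + revcomp_seq(br) + hr
            pair = PrimerPair(f"{insert.id}_{span[0]}", fwd, rev, len(hf), len(hr))
            try:
                vector = fixtures.make_empty_entry_vector(
                    f"pENTRY_{span[0]}_{span[1]}", left, right, senz, tail,
                    backbone, stuffer, left_pad=lp, right_pad=rp,
                )
                product = simulate_pcr(insert, fwd, rev, f"{insert.id}_amp")
                from .assembly import assemble  # local import avoids a cycle

                clone = assemble(vector, [product], tail,
                                 product_id=f"p{insert.id}_{span[0]}").molecule
                got_span, _, orient = classify_part(clone, scheme)
                if got_span != span or orient != 1:
                    raise ValidationError(f"clone classifies as {got_span} ({orient})")
            except GGError as exc:
                last_error = exc
                continue
            return EntryDesign(pair, vector, product, clone, span)
    raise ValidationError(
        f"{insert.id}: no tail design yields a clean entry clone for span {span} "
        f"(a recognition site is created across a junction); last failure: {last_error}"
    )


def design_direct_pcr_part(
    insert: DnaMolecule,
    span: Span | str,
    scheme: SlotScheme | str,
) -> EntryDesign:
    """SapI-tailed primers whose PCR product drops straight into an assembly.

    The released fragment is sequence-identical to what an entry clone built
    from the same insert would release, so plasmid and PCR delivery give the
    same final construct.
    """
    scheme = get_scheme(scheme)
    if isinstance(span, str):
        span = (span, span)
    senz = scheme.enzyme
    _require_domesticated(insert, [senz])
    left, right = scheme.span_labels(span)
    hf = _choose_homology(insert.sequence)
    hr = _choose_homology(revcomp_seq(insert.sequence))
    fwd = SPACER + senz.recognition + fixtures._pad(senz, "A") + left + hf
    rev = SPACER + senz.recognition + fixtures._pad(senz, "A") + revcomp_seq(right) + hr
    pair = PrimerPair(f"{insert.id}_{span[0]}_direct", fwd, rev, len(hf), len(hr))
    product = simulate_pcr(insert, fwd, rev, f"{insert.id}_amp")
    frags = [
        f for f in digest(product, senz)
        if f.internal_site_count(senz) == 0 and f.left_end.is_sticky and f.right_end.is_sticky
    ]
    if len(frags) != 1 or (frags[0].left_label, frags[0].right_label) != (left, right):
        raise ValidationError(
            f"{insert.id}: tailed product does not release a clean ({left},{right}) "
            "fragment — a recognition site spans a junction"
        )
    return EntryDesign(pair, None, product, None, span)


# ---------------------------------------------------------------------------
# Oligo duplexes


def oligo_duplex(
    top: str,
    bottom: str,
    overhang_len: int,
    source_id: str = "oligo_duplex",
) -> StickyFragment:
    """Build a pre-cut fragment from two annealed 5'-phosphorylated strands.

    Both strands are given 5'->3'.  The duplex must be perfectly
    complementary over its core, with 5' extensions of ``overhang_len`` on the
    top strand (left end) and bottom strand (right end); ``overhang_len`` 0
    means blunt.  The fragment is flagged pre-cut and is exempt from digestion
    during assembly.
    """
    top, bottom = top.upper(), bottom.upper()
    k = overhang_len
    if k < 0 or (k and (len(top) <= k or len(bottom) <= k)):
        raise ValidationError("extension length inconsistent with strand lengths")
    if len(top) != len(bottom):
        raise AnnealError(
            f"strand lengths differ ({len(top)} vs {len(bottom)}); symmetric "
            f"{k}-nt 5' extensions require equal lengths"
        )
    span = top + revcomp_seq(bottom)[-k:] if k else top
    expected_bottom_rc = span[k:]
    got = revcomp_seq(bottom)
    for i, (x, y) in enumerate(zip(got, expected_bottom_rc)):
        if x != y:
            raise AnnealError(
                f"duplex mismatch at top-strand position {i + k}", position=i + k
            )
    if k and ("N" in span[:k] or "N" in span[-k:]):
        raise ValidationError("overhang extensions may not contain N")
    left = sticky(span[:k]) if k else None
    right = sticky(span[-k:]) if k else None
    from .typeiis import BLUNT

    return StickyFragment(
        sequence=span,
        left_end=left or BLUNT,
        right_end=right or BLUNT,
        source_id=source_id,
        provenance=[(source_id, 0, len(span), 1)],
        precut=True,
    )


def duplex_for_span(core: str, scheme: SlotScheme | str, span: Span | str,
                    source_id: str = "oligo_duplex") -> tuple[str, str]:
    """Convenience: the two strand sequences that anneal into a ``span`` part."""
    scheme = get_scheme(scheme)
    if isinstance(span, str):
        span = (span, span)
    left, right = scheme.span_labels(span)
    k = scheme.enzyme.overhang_len
    full = left + core + right
    top = full[:-k]
    bottom = revcomp_seq(full[k:])
    return top, bottom


# ---------------------------------------------------------------------------
# Domestication


@dataclass
class Lesion:
    position: int  # 0-based coordinate in the insert
    ref: str
    alt: str
    enzyme: str
    synonymous: str  # "yes" | "unknown"


@dataclass
class DomesticationPlan:
    """n internal sites -> n+1 sub-amplicons, 2(n+1) primers, n junction labels.

    ``fragments`` hold the tailed amplicon sequences; ``target`` is the
    insert with all lesions applied.  ``simulate()`` digests every amplicon
    with the tail enzyme and chain-ligates the released pieces, returning the
    reconstructed sequence (which must equal ``target.sequence``).
    """

    insert_id: str
    lesions: list[Lesion]
    junction_labels: list[str]
    fragments: list[str]
    primer_pairs: list[PrimerPair]
    target: DnaMolecule
    tail_enzyme: EnzymeSpec = BSAI

    def simulate(self) -> str:
        pieces = []
        for i, seq in enumerate(self.fragments):
            amp = DnaMolecule(f"{self.insert_id}_f{i}", seq, "linear")
            for frag in digest(amp, self.tail_enzyme):
                if frag.internal_site_count(self.tail_enzyme) == 0 and (
                    frag.left_end.is_sticky or frag.right_end.is_sticky
                    or len(self.fragments) == 1
                ):
                    # keep only pieces containing template (not tail scraps)
                    if len(frag.sequence) > len(SPACER) + len(self.tail_enzyme.recognition) + 8:
                        pieces.append(frag)
        start = [p for p in pieces if not p.left_end.is_sticky]
        if len(start) != 1:
            raise ValidationError("reassembly: expected exactly one 5'-terminal piece")
        chain = [start[0]]
        used = {id(start[0])}
        while chain[-1].right_end.is_sticky:
            nxt = [
                p for p in pieces
                if id(p) not in used and p.left_label == chain[-1].right_label
            ]
            if len(nxt) != 1:
                raise ValidationError(
                    f"reassembly: junction {chain[-1].right_label} matched {len(nxt)} pieces"
                )
            chain.append(nxt[0])
            used.add(id(nxt[0]))
        out = []
        for p in chain:
            oh = len(p.right_end.label) if p.right_end.is_sticky else 0
            out.append(p.sequence[: len(p.sequence) - oh] if oh else p.sequence)
        return "".join(out)


def _translation(seq: str, frame: int) -> str:
    trimmed = seq[frame:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    return str(Seq(trimmed).translate())


def _internal_sites(seq: str, enzymes):
    mol = DnaMolecule("tmp", seq, "linear")
    out = []
    for e in enzymes:
        enz = get_enzyme(e)
        for m in find_sites(mol, enz):
            out.append((enz, m))
    out.sort(key=lambda em: em[1].recognition_start)
    return out


def _site_footprint(enz, match) -> range:
    return range(match.recognition_start, match.recognition_start + len(enz.recognition))


def plan_domestication(
    insert: DnaMolecule,
    enzymes=(SAPI, BSAI),
    frame: int | None = None,
    *,
    tail_enzyme: EnzymeSpec | str = BSAI,
    max_sites: int = 4,
    allow_no_op: bool = False,
) -> DomesticationPlan:
    """Plan removal of every internal recognition site by lesioned re-assembly.

    One base substitution per site: with ``frame`` given (0-based offset of
    the reading frame), only synonymous substitutions are accepted, preferring
    third-codon positions; without a frame the first site-destroying
    substitution in coordinate order is taken.  More than ``max_sites`` sites
    raises :class:`SynthesisRecommended` (ordering a synthetic fragment is the
    practical route at that point).
    """
    if insert.is_circular:
        raise ValidationError("domestication planning expects a linear insert")
    tail = get_enzyme(tail_enzyme)
    enzymes = [get_enzyme(e) for e in enzymes]
    seq = insert.sequence
    initial = _internal_sites(seq, enzymes)
    if not initial:
        if allow_no_op:
            return DomesticationPlan(insert.id, [], [], [seq], [], insert, tail)
        raise ValidationError(f"{insert.id}: no internal sites; nothing to domesticate")
    if len(initial) > max_sites:
        raise SynthesisRecommended(
            f"{insert.id}: {len(initial)} internal sites (> {max_sites}); "
            "synthesis of a lesioned fragment is recommended"
        )

    work = list(seq)
    lesions: list[Lesion] = []
    for _ in range(len(initial) + 4):
        sites = _internal_sites("".join(work), enzymes)
        if not sites:
            break
        enz, match = sites[0]
        footprint = _site_footprint(enz, match)
        if frame is not None:
            positions = sorted(footprint, key=lambda p: ((p - frame) % 3 != 2, p))
        else:
            positions = list(footprint)
        placed = False
        for p in positions:
            ref = work[p]
            for alt in "ACGT":
                if alt == ref:
                    continue
                if frame is not None:
                    cstart = p - (p - frame) % 3
                    if cstart < frame or cstart + 3 > len(work):
                        continue
                    codon = work[cstart : cstart + 3]
                    mutated = list(codon)
                    mutated[p - cstart] = alt
                    if str(Seq("".join(codon)).translate()) != str(
                        Seq("".join(mutated)).translate()
                    ):
                        continue
                trial = list(work)
                trial[p] = alt
                w0 = max(0, min(footprint) - 7)
                w1 = min(len(work), max(footprint) + 8)
                window = "".join(trial[w0:w1])
                if any(count_sites_in_str(window, e) for e in enzymes):
                    continue
                work = trial
                lesions.append(
                    Lesion(p, ref, alt, enz.name,
                           "yes" if frame is not None else "unknown")
                )
                placed = True
                break
            if placed:
                break
        if not placed:
            raise NoSilentLesion(
                f"{insert.id}: no {'synonymous ' if frame is not None else ''}"
                f"substitution removes the {enz.name} site at {match.recognition_start}",
                position=match.recognition_start,
            )
    lesioned = "".join(work)
    if _internal_sites(lesioned, enzymes):
        raise NoSilentLesion(f"{insert.id}: residual sites after lesioning")
    if frame is not None and _translation(seq, frame) != _translation(lesioned, frame):
        raise NoSilentLesion(f"{insert.id}: lesions change the translation")

    # junction windows: native 4-mer at each lesion, slid downstream on
    # collision or self-complementarity
    oh = tail.overhang_len
    labels: list[str] = []
    for les in sorted(lesions, key=lambda l: l.position):
        chosen = None
        for w in range(les.position, min(les.position + 9, len(lesioned) - oh)):
            if w < 1:
                continue
            cand = lesioned[w : w + oh]
            if cand == revcomp_seq(cand):
                continue
            if any(cand in (l, revcomp_seq(l)) for l in labels):
                continue
            chosen = (w, cand)
            break
        if chosen is None:
            raise ConfigError(f"{insert.id}: no usable junction overhang near {les.position}")
        labels.append(chosen[1])
        les._window = chosen[0]  # type: ignore[attr-defined]
    windows = sorted(l._window for l in lesions)  # type: ignore[attr-defined]
    label_by_window = {l._window: lab for l, lab in  # type: ignore[attr-defined]
                       zip(sorted(lesions, key=lambda l: l.position), labels)}

    fragments: list[str] = []
    pairs: list[PrimerPair] = []
    bounds = [0] + windows + [len(lesioned)]
    tail5 = SPACER + tail.recognition + fixtures._pad(tail, "A")
    for k in range(len(windows) + 1):
        start, end = bounds[k], bounds[k + 1]
        core = lesioned[start : (end + oh if k < len(windows) else end)]
        if k == 0:
            fwd = _choose_homology(lesioned[start:])
        else:
            fwd = tail5 + lesioned[start : start + oh + len(_choose_homology(lesioned[start + oh:]))]
        if k == len(windows):
            rev = _choose_homology(revcomp_seq(lesioned))
        else:
            w = bounds[k + 1]
            hom = _choose_homology(revcomp_seq(lesioned[:w]))
            rev = tail5 + revcomp_seq(lesioned[w : w + oh]) + hom
        amp = ("" if k == 0 else tail5) + core + (
            "" if k == len(windows) else fixtures._pad(tail, "T") + revcomp_seq(tail.recognition) + "TT"
        )
        fragments.append(amp)
        hfl = len(fwd) if k == 0 else len(fwd) - len(tail5)
        hrl = len(rev) if k == len(windows) else len(rev) - len(tail5) - oh
        pairs.append(PrimerPair(f"{insert.id}_dom{k + 1}", fwd, rev, hfl, hrl))

    target = DnaMolecule(
        f"{insert.id}_dom", lesioned, "linear",
        [Feature(f.label, f.kind, f.start, f.end, f.strand) for f in insert.features],
        source_kind=insert.source_kind,
    )
    plan = DomesticationPlan(
        insert.id, sorted(lesions, key=lambda l: l.position),
        [label_by_window[w] for w in windows], fragments, pairs, target, tail,
    )
    recon = plan.simulate()
    if recon != lesioned:
        raise ConfigError(f"{insert.id}: domestication simulation mismatch")
    return plan


# ---------------------------------------------------------------------------
# Frame checking


@dataclass
class FrameReport:
    cds_label: str
    length: int
    in_frame: bool
    internal_stops: list[int]  # codon indices

    @property
    def ok(self) -> bool:
        return self.in_frame and not self.internal_stops


def check_frame(mol: DnaMolecule, cds_span=None) -> list[FrameReport]:
    """Check fused CDS features for frame breaks and internal stop codons.

    ``cds_span`` may be ``(start, end, strand)`` to check an explicit span;
    otherwise every CDS feature on the molecule is checked.  A fusion whose
    junctions insert non-multiple-of-3 spacing shows up as ``in_frame=False``
    on the downstream CDS or as internal stops.
    """
    targets = []
    if cds_span is not None:
        targets.append(("span", *cds_span))
    else:
        for f in mol.features:
            if f.kind == "CDS":
                targets.append((f.label, f.start, f.end, f.strand))
    reports = []
    for label, start, end, strand in targets:
        seq = mol.subseq(start, end)
        if strand == -1:
            seq = revcomp_seq(seq)
        in_frame = len(seq) % 3 == 0
        aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
        stops = [i for i, c in enumerate(aa[:-1]) if c == "*"]
        reports.append(FrameReport(label, len(seq), in_frame, stops))
    return reports
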