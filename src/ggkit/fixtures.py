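"""Deterministic synthetic-kit generator.

Every other module is tested against kits built here: a circular destination
vector (AmpR marker, two inward-facing sites releasing a stuffer), entry
clones (KanR marker, insert flanked by inward-cutting sites that release it
with slot-specific overhangs), empty entry vectors for the BsaI
clone-creation route, and stress sets of up to 20 chained inserts.

All sequences are random but *screened*: part cores carry no recognition site
for the assembly enzymes, and every junction that can occur in a predicted
product is checked for sites created by ligation across the boundary
(offending cores are deterministically resampled).  Same seed, byte-identical
kit.  Marker features are short symbolic placeholder ORFs labelled KanR/AmpR;
marker logic downstream is annotation-driven, not homology-driven.
"""

from __future__ import annotations

import itertools
import os
import random
from dataclasses import dataclass, field

from .errors import ConfigError, ValidationError
from .seq_model import DnaMolecule, Feature, revcomp_seq, write_record
from .slots import PartRecord, SlotScheme, Span, save_scheme, write_registry
from .typeiis import BSAI, SAPI, EnzymeSpec, count_sites_in_str, find_sites, get_enzyme

MAX_STRESS_INSERTS = 20  # largest co-assembly the generator supports (one backbone + 20)

_BASES = "ACGT"
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

_SLOT_KINDS = {
    "5arm": "promoter", "CT": "linker", "FP": "fluorophore",
    "SEC": "linker", "NT": "CDS", "3arm": "utr3",
}
_KIND_CYCLE = ["promoter", "linker", "fluorophore", "CDS", "utr3"]


def _rand_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _first_site(seq: str, enzymes, from_pos: int = 0) -> tuple[int, int] | None:
    """Leftmost recognition occurrence at/after ``from_pos`` as (start, length)."""
    best = None
    for e in enzymes:
        enz = get_enzyme(e)
        for needle in (enz.recognition, revcomp_seq(enz.recognition)):
            i = seq.find(needle, from_pos)
            if i != -1 and (best is None or i < best[0]):
                best = (i, len(needle))
    return best


def _scrub(seq: str, enzymes, protected=frozenset(), max_iter: int = 10000) -> str:
    """Mutate bases until no forbidden recognition site remains.

    Positions in ``protected`` are never touched, so planted sites survive;
    occurrences lying entirely inside a protected region are skipped.
    """
    s = list(seq)
    for it in range(max_iter):
        mutable = None
        pos = 0
        while True:
            hit = _first_site("".join(s), enzymes, pos)
            if hit is None:
                break
            start, length = hit
            candidates = [p for p in range(start, start + length) if p not in protected]
            if candidates:
                mutable = (candidates, length)
                break
            pos = start + 1  # occurrence inside a planted site: leave it
        if mutable is None:
            return "".join(s)
        candidates, length = mutable
        p = candidates[(length // 2 + it) % len(candidates)]
        s[p] = _NEXT_BASE[s[p]]
    raise ValidationError("site scrubbing did not converge")


def make_random_insert(
    length: int,
    seed: int,
    forbid=(SAPI, BSAI),
    plant=None,
    id: str = "insert",
) -> DnaMolecule:
    """Random linear insert free of the forbidden sites, optionally with
    planted recognition sites at exact positions.

    ``plant`` is a list of ``(enzyme, position)``: the recognition sequence is
    written on the top strand starting at ``position``.
    """
    forbid = [get_enzyme(e) for e in forbid]
    longest = max((len(e.recognition) for e in forbid), default=0)
    if length < longest:
        raise ValidationError(f"length {length} shorter than longest recognition ({longest})")
    rng = random.Random(seed)
    seq = _rand_seq(rng, length)
    protected: set[int] = set()
    if plant:
        s = list(seq)
        for e, pos in plant:
            enz = get_enzyme(e)
            if pos < 0 or pos + len(enz.recognition) > length:
                raise ValidationError(f"planted {enz.name} site at {pos} outside sequence")
            s[pos : pos + len(enz.recognition)] = enz.recognition
            protected.update(range(pos, pos + len(enz.recognition)))
        seq = "".join(s)
    seq = _scrub(seq, forbid, frozenset(protected))
    return DnaMolecule(id, seq, "linear", source_kind="pcr_product")


# ---------------------------------------------------------------------------
# Labels


def generate_labels(n: int, overhang_len: int, seed: int) -> list[str]:
    """n pairwise-distinct overhang labels, none self-complementary, none the
    reverse complement of another."""
    pool = ["".join(p) for p in itertools.product(_BASES, repeat=overhang_len)]
    pool = [l for l in pool if l != revcomp_seq(l)]
    rng = random.Random(seed)
    rng.shuffle(pool)
    chosen: list[str] = []
    taken: set[str] = set()
    for lab in pool:
        if lab in taken or revcomp_seq(lab) in taken:
            continue
        chosen.append(lab)
        taken.add(lab)
        if len(chosen) == n:
            return chosen
    raise ConfigError(
        f"overhang alphabet exhausted: cannot draw {n} collision-free "
        f"{overhang_len}-mers"
    )


# ---------------------------------------------------------------------------
# Molecule builders


def _pad(enz: EnzymeSpec, base: str = "A") -> str:
    return base * enz.cut_offset_top


def make_entry_clone(
    part_id: str,
    core: str,
    left_label: str,
    right_label: str,
    enzyme: EnzymeSpec,
    backbone_core: str,
    core_kind: str = "misc",
) -> DnaMolecule:
    """Circular KanR entry clone: digestion releases ``label+core+label``.

    Layout (top strand): KanR backbone, recognition site cutting rightward
    into the insert, insert, mirrored site cutting leftward, wrap.
    """
    rec = enzyme.recognition
    seq = (
        backbone_core
        + rec + _pad(enzyme, "A")
        + left_label + core + right_label
        + _pad(enzyme, "T") + revcomp_seq(rec)
    )
    nb = len(backbone_core)
    insert_start = nb + len(rec) + enzyme.cut_offset_top + len(left_label)
    feats = [
        Feature(f"KanR_{part_id}", "selection_marker", 10, min(nb - 10, 10 + 150), 1),
        Feature(part_id, core_kind, insert_start, insert_start + len(core), 1),
    ]
    return DnaMolecule(part_id, seq, "circular", feats)


def make_destination_vector(
    vec_id: str,
    left_label: str,
    right_label: str,
    enzyme: EnzymeSpec,
    backbone_core: str,
    stuffer_core: str,
) -> DnaMolecule:
    """Circular AmpR destination vector.

    The recognition sites sit inside the stuffer and cut outward, so the
    opened backbone is site-free with its right end labelled ``left_label``
    (meets the first slot) and its left end ``right_label`` (meets the last).
    """
    rec = enzyme.recognition
    seq = (
        backbone_core
        + left_label + _pad(enzyme, "A") + revcomp_seq(rec)
        + stuffer_core
        + rec + _pad(enzyme, "A") + right_label
    )
    nb = len(backbone_core)
    feats = [
        Feature(f"AmpR_{vec_id}", "selection_marker", 10, min(nb - 10, 10 + 150), 1),
        Feature("FRT_L", "recombination_site", max(nb - 60, 0), max(nb - 26, 34), 1),
        Feature(
            f"{vec_id}_stuffer", "misc",
            nb + len(left_label) + enzyme.cut_offset_top + len(rec),
            nb + len(left_label) + enzyme.cut_offset_top + len(rec) + len(stuffer_core),
            1,
        ),
    ]
    return DnaMolecule(vec_id, seq, "circular", feats)


def make_empty_entry_vector(
    vec_id: str,
    left_label: str,
    right_label: str,
    scheme_enzyme: EnzymeSpec,
    tail_enzyme: EnzymeSpec,
    backbone_core: str,
    stuffer_core: str,
    left_pad: str = "A",
    right_pad: str = "T",
) -> DnaMolecule:
    """Empty KanR vector for creating new entry clones via a second enzyme.

    A ``tail_enzyme`` (BsaI) reaction opens the vector between its two
    strategically placed scheme-enzyme (SapI) flanks; ligating in a tailed PCR
    product yields an entry clone whose scheme-enzyme digestion releases the
    insert with ``(left_label, right_label)`` overhangs.  The tail-enzyme
    junction labels are ``pad + left_label`` and ``right_label + pad`` — the
    scheme enzyme's offset base is shared with the tail junction.
    """
    srec, trec = scheme_enzyme.recognition, tail_enzyme.recognition
    bl = _pad(scheme_enzyme, left_pad) + left_label
    br = right_label + _pad(scheme_enzyme, right_pad)
    if len(bl) != tail_enzyme.overhang_len or len(br) != tail_enzyme.overhang_len:
        raise ConfigError(
            "scheme offset + overhang must equal the tail enzyme's overhang length"
        )
    seq = (
        backbone_core
        + srec + bl + _pad(tail_enzyme, "A") + revcomp_seq(trec)
        + stuffer_core
        + trec + _pad(tail_enzyme, "A") + br + revcomp_seq(srec)
    )
    nb = len(backbone_core)
    feats = [
        Feature(f"KanR_{vec_id}", "selection_marker", 10, min(nb - 10, 10 + 150), 1),
    ]
    return DnaMolecule(vec_id, seq, "circular", feats)


# ---------------------------------------------------------------------------
# Junction-window screening


def _window_clean(left_tail: str, label: str, right_head: str, enzymes) -> bool:
    window = left_tail + label + right_head
    return all(count_sites_in_str(window, e) == 0 for e in enzymes)


def _margin(enzymes) -> int:
    return max(len(get_enzyme(e).recognition) for e in enzymes) - 1


# ---------------------------------------------------------------------------
# Kits


@dataclass
class FixtureKit:
    """A synthetic Golden Gate kit: scheme, destination vector, entry parts."""

    scheme: SlotScheme
    vector: DnaMolecule
    parts: dict[Span, list[DnaMolecule]]
    seed: int
    kinds: dict[Span, str] = field(default_factory=dict)

    def options(self, span: Span) -> list[DnaMolecule]:
        return self.parts[span]

    def default_selection(self) -> dict[Span, str]:
        """One single-slot part per slot (the canonical full build)."""
        sel = {}
        for s in self.scheme.slots:
            span = (s, s)
            sel[span] = self.parts[span][0].id
        return sel

    def registry(self) -> list[PartRecord]:
        records = []
        for span, mols in sorted(self.parts.items(),
                                 key=lambda kv: (self.scheme.slot_index(kv[0][0]),
                                                 self.scheme.slot_index(kv[0][1]))):
            for mol in mols:
                records.append(
                    PartRecord(
                        id=mol.id, slot_first=span[0], slot_last=span[1],
                        kind=self.kinds.get(span, "misc"),
                        path=f"{mol.id}.gb", molecule=mol,
                    )
                )
        return records

    def write(self, outdir) -> str:
        """Write vector + parts as GenBank and the registry TSV; returns the
        registry path."""
        os.makedirs(outdir, exist_ok=True)
        write_record(self.vector, os.path.join(outdir, f"{self.vector.id}.gb"))
        records = self.registry()
        for rec in records:
            write_record(rec.molecule, os.path.join(outdir, rec.path))
        reg_path = os.path.join(outdir, "registry.tsv")
        write_registry(records, reg_path)
        save_scheme(self.scheme, os.path.join(outdir, "scheme.json"))
        return reg_path


def _slot_kind(slot: str, index: int) -> str:
    return _SLOT_KINDS.get(slot, _KIND_CYCLE[index % len(_KIND_CYCLE)])


def make_kit(
    scheme_size: int = 6,
    parts_per_slot: int | dict = 1,
    seed: int = 0,
    *,
    enzyme: EnzymeSpec = SAPI,
    combined_spans: bool = True,
    core_length: tuple[int, int] = (150, 400),
) -> FixtureKit:
    """Generate a validated synthetic kit.

    ``scheme_size`` slots (2-8; size 6 reuses the RMCE slot names),
    ``parts_per_slot`` options per slot (int, or a dict slot -> count), all
    labels drawn fresh from the seed.  When ``combined_spans`` is set and the
    scheme has >= 4 slots, one slot-skipping part is added for the first two
    slots and one for the last three (the "simpler clone" patterns).
    """
    if not 2 <= scheme_size <= 8:
        raise ConfigError("scheme_size must be in 2..8")
    if isinstance(parts_per_slot, int) and not 1 <= parts_per_slot <= 8:
        raise ConfigError("parts_per_slot must be in 1..8")
    # junction screening can hit an unfixable backbone-adjacent window for an
    # unlucky label draw; redraw everything deterministically in that case
    last = None
    for outer in range(20):
        try:
            return _make_kit(scheme_size, parts_per_slot, seed + 1_000_003 * outer,
                             enzyme=enzyme, combined_spans=combined_spans,
                             core_length=core_length)
        except ConfigError as exc:
            last = exc
    raise ConfigError(f"kit generation failed for seed {seed}: {last}")


def _make_kit(scheme_size, parts_per_slot, seed, *, enzyme, combined_spans, core_length):
    rng = random.Random(seed)
    if scheme_size == 6:
        slot_names = ["5arm", "CT", "FP", "SEC", "NT", "3arm"]
    else:
        slot_names = [f"slot{i + 1}" for i in range(scheme_size)]
    labels = generate_labels(scheme_size + 1, enzyme.overhang_len, rng.randrange(2**31))
    scheme = SlotScheme(f"fixture{scheme_size}", slot_names, labels, enzyme)

    if isinstance(parts_per_slot, int):
        counts = {s: parts_per_slot for s in slot_names}
    else:
        counts = {s: parts_per_slot.get(s, 1) for s in slot_names}
    for s, c in counts.items():
        if not 1 <= c <= 8:
            raise ConfigError(f"slot {s}: parts_per_slot must be in 1..8")

    spans: list[Span] = [(s, s) for s in slot_names]
    if combined_spans and scheme_size >= 4:
        spans.append((slot_names[0], slot_names[1]))
        spans.append((slot_names[-3], slot_names[-1]))

    forbidden = [SAPI, BSAI]  # parts stay domesticated for both assembly enzymes
    margin = _margin(forbidden)

    backbone_core = _scrub(_rand_seq(rng, 320), forbidden)
    stuffer_core = _scrub(_rand_seq(rng, 120), forbidden)
    vector = make_destination_vector(
        "pDEST_fix", labels[0], labels[-1], enzyme, backbone_core, stuffer_core
    )

    def gen_core(base_seed: int, attempt: int, lo: int, hi: int) -> str:
        r = random.Random(base_seed + 7919 * attempt)
        return _scrub(_rand_seq(r, r.randint(lo, hi)), forbidden)

    kit_parts: dict[Span, list[DnaMolecule]] = {}
    kinds: dict[Span, str] = {}
    cores: dict[tuple[Span, int], str] = {}
    seeds: dict[tuple[Span, int], int] = {}
    for span in spans:
        n = counts[span[0]] if span[0] == span[1] else 1
        for i in range(n):
            seeds[(span, i)] = rng.randrange(2**31)
            cores[(span, i)] = gen_core(seeds[(span, i)], 0, *core_length)
        kinds[span] = _slot_kind(span[0], scheme.slot_index(span[0]))

    # Screen every junction that can occur in a product: for junction k, the
    # product reads ...left_core  labels[k]  right_core...  A site spanning
    # that window would make the closure unstable, so the right-hand core is
    # resampled until all pairings are clean.
    def left_candidates(k: int):
        if k == 0:
            yield ("vector", 0), backbone_core[-margin:]
        for (span, i), core in cores.items():
            if scheme.slot_index(span[1]) + 1 == k:
                yield (span, i), core[-margin:]

    def right_keys(k: int):
        for (span, i) in cores:
            if scheme.slot_index(span[0]) == k:
                yield (span, i)

    n_slots = len(slot_names)
    for _round in range(50):
        dirty = False
        for k in range(n_slots + 1):
            lefts = list(left_candidates(k))
            if k == n_slots:
                # last junction: right-hand side is always the vector backbone,
                # so the left-hand core is the one to resample
                for key, tail in lefts:
                    if _window_clean(tail, labels[k], backbone_core[:margin], forbidden):
                        continue
                    for attempt in range(1, 200):
                        cores[key] = gen_core(seeds[key], attempt, *core_length)
                        if _window_clean(cores[key][-margin:], labels[k],
                                         backbone_core[:margin], forbidden):
                            break
                    dirty = True
                continue
            for rkey in right_keys(k):
                head = cores[rkey][:margin]
                if all(_window_clean(tail, labels[k], head, forbidden)
                       for _, tail in lefts):
                    continue
                for attempt in range(1, 200):
                    cores[rkey] = gen_core(seeds[rkey], attempt, *core_length)
                    head = cores[rkey][:margin]
                    if all(_window_clean(tail, labels[k], head, forbidden)
                           for _, tail in lefts):
                        break
                dirty = True
        if not dirty:
            break
    else:
        raise ConfigError("junction screening did not converge")

    for span in spans:
        n = counts[span[0]] if span[0] == span[1] else 1
        mols = []
        left, right = scheme.span_labels(span)
        for i in range(n):
            pid = (span[0] if span[0] == span[1] else f"{span[0]}-{span[1]}") + f"_p{i + 1}"
            kb_seed = rng.randrange(2**31)
            for attempt in range(50):
                kanr = _scrub(_rand_seq(random.Random(kb_seed + attempt), 260), forbidden)
                mol = make_entry_clone(
                    pid, cores[(span, i)], left, right, enzyme, kanr, kinds[span]
                )
                if len(find_sites(mol, enzyme)) == 2:
                    break
            else:
                raise ConfigError(f"{pid}: could not build a two-site entry clone")
            mols.append(mol)
        kit_parts[span] = mols

    kit = FixtureKit(scheme, vector, kit_parts, seed, kinds)
    if len(find_sites(vector, enzyme)) != 2:
        raise ConfigError("destination vector does not carry exactly two sites")
    return kit


def make_stress_set(n_inserts: int = MAX_STRESS_INSERTS, seed: int = 0,
                    enzyme: EnzymeSpec = SAPI):
    """Vector plus ``n_inserts`` chained entry clones with n+1 distinct labels.

    Models the "up to 20 inserts" co-assembly: the unique stable closure
    incorporates every insert.  Returns ``(vector, inserts, labels)``.
    """
    if not 1 <= n_inserts <= MAX_STRESS_INSERTS:
        raise ConfigError(f"n_inserts must be in 1..{MAX_STRESS_INSERTS}")
    # junction screening can hit an unfixable backbone-adjacent window for an
    # unlucky label draw; redraw everything deterministically in that case
    last = None
    for outer in range(20):
        try:
            return _make_stress_set(n_inserts, seed + 1_000_003 * outer, enzyme)
        except ConfigError as exc:
            last = exc
    raise ConfigError(f"stress-set generation failed for seed {seed}: {last}")


def _make_stress_set(n_inserts: int, seed: int, enzyme: EnzymeSpec):
    rng = random.Random(seed)
    labels = generate_labels(n_inserts + 1, enzyme.overhang_len, rng.randrange(2**31))
    forbidden = [SAPI, BSAI]
    margin = _margin(forbidden)
    backbone_core = _scrub(_rand_seq(rng, 320), forbidden)
    stuffer_core = _scrub(_rand_seq(rng, 100), forbidden)
    vector = make_destination_vector(
        "pDEST_stress", labels[0], labels[-1], enzyme, backbone_core, stuffer_core
    )
    cores, seeds = [], []
    for i in range(n_inserts):
        seeds.append(rng.randrange(2**31))
        cores.append(_scrub(_rand_seq(random.Random(seeds[i]), 90 + (i % 5) * 20), forbidden))
    neighbours = [backbone_core] + cores + [backbone_core]
    for i in range(n_inserts):
        for attempt in range(1, 200):
            left_tail = neighbours[i][-margin:]
            right_head = neighbours[i + 2][:margin] if i + 1 < n_inserts else backbone_core[:margin]
            ok_l = _window_clean(left_tail, labels[i], cores[i][:margin], forbidden)
            ok_r = _window_clean(cores[i][-margin:], labels[i + 1], right_head, forbidden)
            if ok_l and ok_r:
                break
            r = random.Random(seeds[i] + 7919 * attempt)
            cores[i] = _scrub(_rand_seq(r, 90 + (i % 5) * 20), forbidden)
            neighbours[i + 1] = cores[i]
        else:
            raise ConfigError("stress-set junction screening did not converge")
    inserts = []
    for i, core in enumerate(cores):
        kb_seed = rng.randrange(2**31)
        for attempt in range(50):
            kanr = _scrub(_rand_seq(random.Random(kb_seed + attempt), 220), forbidden)
            mol = make_entry_clone(
                f"stress_{i + 1:02d}", core, labels[i], labels[i + 1], enzyme, kanr, "misc"
            )
            if len(find_sites(mol, enzyme)) == 2:
                break
        else:
            raise ConfigError(f"stress insert {i + 1}: entry clone screening failed")
        inserts.append(mol)
    return vector, inserts, labels


def make_insert_for_span(
    scheme: SlotScheme,
    span: Span,
    length: int,
    seed: int,
    forbid=(SAPI, BSAI),
) -> DnaMolecule:
    """Random insert sequence screened for use in ``span``: domesticated AND
    free of sites spanning its future junctions.

    The screening contexts are the fixed entry-clone flanks of the scheme
    enzyme (recognition + offset pad on the left, mirrored on the right), so
    an entry clone built around this insert always digests to exactly one
    site-free insert fragment.
    """
    left, right = scheme.span_labels(span)
    enz = scheme.enzyme
    left_ctx = (enz.recognition + _pad(enz, "A"))[-_margin(forbid):]
    right_ctx = (_pad(enz, "T") + revcomp_seq(enz.recognition))[: _margin(forbid)]
    for attempt in range(200):
        mol = make_random_insert(length, seed + 7919 * attempt, forbid,
                                 id=f"ins_{span[0]}_{span[1]}")
        released = left_ctx + left + mol.sequence + right + right_ctx
        if all(count_sites_in_str(released, e) == 0 for e in forbid):
            return mol
    raise ConfigError("could not generate a junction-compatible insert")
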