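"""Slot architecture and the registry-driven construct builder.

The kit arranges entry clones in an ordered series of *slots* — by default
the six-slot series 5'arm, CT, FP, SEC, NT, 3'arm used for RMCE targeting
vectors — delimited by seven pairwise-distinct junction overhangs.  A part
may occupy a single slot or a *combined span* of consecutive slots (slot
skipping), in which case it carries the outer labels of its span.  A
construct selection must tile the scheme exactly once; building then reduces
to one Golden Gate assembly.

The registry is a plain delimited table (id, slot_first, slot_last, kind,
path, notes) — the software twin of a parts spreadsheet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import seq_model
from .assembly import AssemblyProduct, assemble
from .errors import ConfigError, MultiInsertPart, SlotCoverage, UnassignablePart
from .seq_model import DnaMolecule, revcomp_seq
from .typeiis import SAPI, EnzymeSpec, StickyFragment, digest, get_enzyme

Span = tuple[str, str]  # (first slot name, last slot name)


@dataclass
class SlotScheme:
    """Ordered slot names plus the junction label between each adjacent pair.

    ``junction_labels`` has length ``len(slots) + 1``: vector-left, one per
    internal junction, vector-right.  All labels must be pairwise distinct,
    of the scheme enzyme's overhang length, and free of reverse-complement
    collisions (a label equal to another's reverse complement would permit a
    flipped ligation and break product uniqueness).
    """

    name: str
    slots: list[str]
    junction_labels: list[str]
    enzyme: EnzymeSpec = SAPI
    role_notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.junction_labels) != len(self.slots) + 1:
            raise ConfigError(
                f"scheme {self.name}: need {len(self.slots) + 1} junction labels, "
                f"got {len(self.junction_labels)}"
            )
        self.junction_labels = [l.upper() for l in self.junction_labels]
        oh = self.enzyme.overhang_len
        seen = set()
        for lab in self.junction_labels:
            if len(lab) != oh or set(lab) - set("ACGT"):
                raise ConfigError(
                    f"scheme {self.name}: label {lab!r} is not a clean {oh}-mer"
                )
            if lab in seen or revcomp_seq(lab) in seen:
                raise ConfigError(
                    f"scheme {self.name}: label {lab!r} collides (identity or "
                    "reverse complement) with another junction label"
                )
            if lab == revcomp_seq(lab):
                raise ConfigError(f"scheme {self.name}: label {lab!r} is self-complementary")
            seen.add(lab)

    def __len__(self) -> int:
        return len(self.slots)

    def slot_index(self, slot: str) -> int:
        try:
            return self.slots.index(slot)
        except ValueError:
            raise ConfigError(f"scheme {self.name}: unknown slot {slot!r}") from None

    def span_labels(self, span: Span) -> tuple[str, str]:
        """(left, right) junction labels of a (possibly combined) slot span."""
        i, j = self.slot_index(span[0]), self.slot_index(span[1])
        if i > j:
            raise ConfigError(f"scheme {self.name}: inverted span {span}")
        return self.junction_labels[i], self.junction_labels[j + 1]

    def all_spans(self) -> list[Span]:
        return [
            (self.slots[i], self.slots[j])
            for i in range(len(self.slots))
            for j in range(i, len(self.slots))
        ]

    @property
    def vector_labels(self) -> tuple[str, str]:
        """Labels of the opened destination backbone: (right end, left end).

        The backbone's right end meets the first slot (label 0) and its left
        end meets the last slot (label n).
        """
        return self.junction_labels[0], self.junction_labels[-1]


#: Default six-slot RMCE scheme.  The junction 3-mers are toolkit defaults
#: (pairwise distinct, no reverse-complement collisions); schemes read from
#: config may override them freely.
RMCE6 = SlotScheme(
    name="rmce6",
    slots=["5arm", "CT", "FP", "SEC", "NT", "3arm"],
    junction_labels=["AAC", "TCC", "GGT", "CAT", "GCA", "TGG", "CTG"],
    enzyme=SAPI,
    role_notes={
        "5arm": "promoter (or 5' homology arm in CRISPR-oriented schemes)",
        "CT": "C-terminal tag or linker",
        "FP": "fluorescent protein / protein tag",
        "SEC": "short peptide linker (selection cassette in CRISPR schemes)",
        "NT": "gene of interest (N-terminal fusion partner)",
        "3arm": "3' UTR (or 3' homology arm)",
    },
)

SCHEMES: dict[str, SlotScheme] = {RMCE6.name: RMCE6}


def get_scheme(name: str | SlotScheme) -> SlotScheme:
    if isinstance(name, SlotScheme):
        return name
    try:
        return SCHEMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown scheme {name!r}; known: {', '.join(sorted(SCHEMES))}"
        ) from None


def save_scheme(scheme: SlotScheme, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "name": scheme.name,
                "slots": scheme.slots,
                "junction_labels": scheme.junction_labels,
                "enzyme": scheme.enzyme.name,
                "role_notes": scheme.role_notes,
            },
            fh, indent=2,
        )


def load_scheme(path) -> SlotScheme:
    """Read a scheme definition from JSON (round-trips with save_scheme)."""
    import json

    with open(path) as fh:
        data = json.load(fh)
    try:
        return SlotScheme(
            name=data["name"],
            slots=list(data["slots"]),
            junction_labels=list(data["junction_labels"]),
            enzyme=get_enzyme(data.get("enzyme", "SapI")),
            role_notes=dict(data.get("role_notes", {})),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: scheme file missing key {exc}") from exc


# ---------------------------------------------------------------------------
# Part classification


def _usable_inserts(mol_or_frag, enz) -> list[StickyFragment]:
    if isinstance(mol_or_frag, StickyFragment):
        frags = [mol_or_frag]
    else:
        frags = digest(mol_or_frag, enz)
    return [
        f for f in frags
        if f.internal_site_count(enz) == 0
        and f.left_end.is_sticky
        and f.right_end.is_sticky
        and not f.circular
    ]


def classify_part(mol, scheme: str | SlotScheme, enzyme=None):
    """Assign a part to the unique slot span its insert labels match.

    Returns ``(span, fragment, orientation)`` where orientation is +1 when the
    insert matches the scheme in its digested orientation and -1 when only the
    flipped fragment matches.  The entry backbone (which retains the
    recognition sites) is excluded automatically.
    """
    scheme = get_scheme(scheme)
    enz = get_enzyme(enzyme) if enzyme is not None else scheme.enzyme
    inserts = _usable_inserts(mol, enz)
    pid = mol.source_id if isinstance(mol, StickyFragment) else mol.id
    span_by_labels = {scheme.span_labels(s): s for s in scheme.all_spans()}
    hits = []
    for frag in inserts:
        for orient, f in ((1, frag), (-1, frag.rc())):
            span = span_by_labels.get((f.left_label, f.right_label))
            if span is not None:
                hits.append((span, f, orient))
    if not hits:
        raise UnassignablePart(
            f"{pid}: no slot span of scheme {scheme.name} matches any released "
            f"insert fragment"
        )
    if len(hits) > 1:
        raise MultiInsertPart(
            f"{pid}: {len(hits)} released fragments match slot spans "
            f"({[h[0] for h in hits]})"
        )
    return hits[0]


# ---------------------------------------------------------------------------
# Registry


@dataclass
class PartRecord:
    id: str
    slot_first: str
    slot_last: str
    kind: str
    path: str
    notes: str = ""
    molecule: DnaMolecule | None = None
    status: str = "unverified"

    @property
    def span(self) -> Span:
        return (self.slot_first, self.slot_last)


REGISTRY_COLUMNS = ["id", "slot_first", "slot_last", "kind", "path", "notes"]


def read_registry(path, base_dir=None, load: bool = True) -> list[PartRecord]:
    """Read a TSV/CSV parts registry; relative paths resolve against the table."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: registry missing columns {missing}")
    base = base_dir if base_dir is not None else os.path.dirname(str(path))
    records = []
    for row in df.itertuples(index=False):
        rec = PartRecord(
            id=row.id, slot_first=row.slot_first, slot_last=row.slot_last,
            kind=row.kind, path=row.path, notes=getattr(row, "notes", ""),
        )
        if load:
            p = rec.path if os.path.isabs(rec.path) else os.path.join(base, rec.path)
            fmt = "fasta" if p.endswith((".fa", ".fasta")) else "genbank"
            rec.molecule = seq_model.read_record(p, fmt)
        records.append(rec)
    return records


def write_registry(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id, "slot_first": r.slot_first, "slot_last": r.slot_last,
                "kind": r.kind, "path": r.path, "notes": r.notes,
            }
            for r in records
        ],
        columns=REGISTRY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Construct building


def _check_tiling(scheme: SlotScheme, spans) -> None:
    covered: list[int] = []
    for span in spans:
        i, j = scheme.slot_index(span[0]), scheme.slot_index(span[1])
        if i > j:
            raise SlotCoverage(f"inverted span {span}")
        covered.extend(range(i, j + 1))
    counts = {s: covered.count(i) for i, s in enumerate(scheme.slots)}
    uncovered = [s for s, c in counts.items() if c == 0]
    overlapping = [s for s, c in counts.items() if c > 1]
    if uncovered or overlapping:
        raise SlotCoverage(
            f"selection does not tile scheme {scheme.name}: "
            f"uncovered={uncovered} overlapping={overlapping}",
            uncovered=uncovered,
            overlapping=overlapping,
        )


def build_construct(
    vector: DnaMolecule,
    selection: dict,
    registry,
    scheme: str | SlotScheme,
    *,
    product_id: str | None = None,
) -> AssemblyProduct:
    """Assemble a construct from a slot-span -> part-id selection.

    ``selection`` maps spans (``(first, last)`` tuples, or a bare slot name
    for a single-slot span) to part ids found in ``registry`` (a list of
    :class:`PartRecord` with molecules loaded).  Spans must tile the scheme
    exactly once.  The product records the selection in its metadata; use
    :func:`ggkit.seq_model.write_record` for the annotated GenBank and plain
    FASTA outputs.
    """
    scheme = get_scheme(scheme)
    by_id = {r.id: r for r in registry}
    norm: dict[Span, str] = {}
    for span, pid in selection.items():
        if isinstance(span, str):
            span = (span, span)
        norm[span] = pid
    _check_tiling(scheme, norm.keys())
    # assemble parts in slot order for a deterministic, readable parts list
    ordered = sorted(norm.items(), key=lambda kv: scheme.slot_index(kv[0][0]))
    parts = []
    for span, pid in ordered:
        if pid not in by_id:
            raise ConfigError(f"part id {pid!r} not in registry")
        rec = by_id[pid]
        if rec.molecule is None:
            raise ConfigError(f"part {pid!r}: molecule not loaded")
        parts.append(rec.molecule)
    product = assemble(
        vector, parts, scheme.enzyme,
        product_id=product_id or f"{vector.id}_build",
    )
    product.selection = {f"{s[0]}-{s[1]}" if s[0] != s[1] else s[0]: pid
                         for s, pid in ordered}
    return product


# ---------------------------------------------------------------------------
# Kit validation


@dataclass
class Finding:
    part_id: str
    code: str
    message: str


@dataclass
class KitReport:
    findings: list[Finding] = field(default_factory=list)
    compatibility: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.findings

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"part_id": f.part_id, "code": f.code, "message": f.message}
             for f in self.findings],
            columns=["part_id", "code", "message"],
        )


def validate_kit(registry, scheme: str | SlotScheme, enzyme=None,
                 entry_marker: str = "KanR") -> KitReport:
    """Report-only audit of a parts registry against its scheme.

    Per part: the insert must release cleanly, its labels must match the
    declared span, it must carry no internal recognition site, and the entry
    backbone must carry the expected selection marker.  Kit-wide, a pairwise
    junction-compatibility matrix is produced (which part can ligate to
    which).
    """
    scheme = get_scheme(scheme)
    enz = get_enzyme(enzyme) if enzyme is not None else scheme.enzyme
    report = KitReport()
    label_pairs: dict[str, tuple[str, str]] = {}
    for rec in registry:
        mol = rec.molecule
        if mol is None:
            report.findings.append(Finding(rec.id, "unloaded", "molecule not loaded"))
            continue
        try:
            span, frag, orient = classify_part(mol, scheme, enz)
        except (UnassignablePart, MultiInsertPart) as exc:
            report.findings.append(Finding(rec.id, type(exc).__name__, str(exc)))
            continue
        if span != rec.span:
            report.findings.append(
                Finding(
                    rec.id, "SpanMismatch",
                    f"declared span {rec.span} but insert labels match {span}",
                )
            )
            continue
        if orient == -1:
            report.findings.append(
                Finding(rec.id, "FlippedInsert",
                        "insert matches its span only in reverse orientation")
            )
        label_pairs[rec.id] = (frag.left_label, frag.right_label)
        markers = [f.label for f in mol.features if f.kind == "selection_marker"]
        if not any(entry_marker in m for m in markers):
            report.findings.append(
                Finding(rec.id, "BackboneMarker",
                        f"entry backbone lacks a {entry_marker} selection marker")
            )
        rec.status = "verified" if not any(f.part_id == rec.id for f in report.findings) \
            else "unverified"
    ids = sorted(label_pairs)
    mat = pd.DataFrame(
        [[label_pairs[a][1] == label_pairs[b][0] for b in ids] for a in ids],
        index=ids, columns=ids,
    )
    report.compatibility = mat
    return report
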