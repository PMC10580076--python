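"""Golden Gate product prediction.

The one-pot repetitive digestion-ligation reaction is modelled as its fixed
point: every molecule is digested to completion, the sticky fragments are
joined wherever end labels match, and only *stable* circular closures — those
whose ligated sequence contains no residual recognition site for the assembly
enzyme — survive (anything still carrying a site is re-cut on the next
thermocycle).  The contract mirrors the bench reality that the desired clone
is "the only circular plasmid product": exactly one stable closure containing
the destination backbone must exist, otherwise assembly fails loudly.

Fragments are orientation-blind: each may enter a closure as-is or flipped
(unless flagged directional); direction comes only from the overhang design.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import AmbiguousAssembly, ConfigError, MissingJunction, SlotHeterogeneity
from .seq_model import DnaMolecule, Feature, revcomp_seq
from .typeiis import EnzymeSpec, StickyFragment, digest, find_sites, get_enzyme

__all__ = [
    "AssemblyDiagnostics",
    "AssemblyProduct",
    "assemble",
    "build_ligation_graph",
    "multiplex_assemble",
    "verify_product",
]


def _label_class(label: str) -> str:
    """Canonical representative of {label, revcomp(label)}."""
    return min(label, revcomp_seq(label))


@dataclass
class AssemblyDiagnostics:
    residual_sites: int = 0
    unused_inputs: list[str] = field(default_factory=list)
    duplicate_labels: list[str] = field(default_factory=list)
    self_complementary_labels: list[str] = field(default_factory=list)
    non_backbone_closures: int = 0
    unstable_closures: int = 0
    backbone_marker_ok: bool | None = None

    @property
    def clean(self) -> bool:
        return (
            self.residual_sites == 0
            and not self.unused_inputs
            and not self.duplicate_labels
        )


@dataclass
class AssemblyProduct:
    """A predicted circular clone plus bookkeeping about how it was built."""

    molecule: DnaMolecule
    parts_used: list[tuple[str, int]]  # (source id, orientation +1/-1) in ligation order
    diagnostics: AssemblyDiagnostics = field(default_factory=AssemblyDiagnostics)
    selection: dict = field(default_factory=dict)  # slot span -> part id (builder metadata)

    @property
    def insert_ids(self) -> list[str]:
        return [pid for pid, _ in self.parts_used[1:]]

    @property
    def n_inserts(self) -> int:
        return len(self.parts_used) - 1


# ---------------------------------------------------------------------------
# Fragment pool assembly


def _digest_inputs(vector, parts, enz):
    """Digest plasmid inputs; pass pre-cut fragments through.

    Returns (backbone fragment, list of candidate insert fragments,
    diagnostics seeded with inert inputs).
    """
    diags = AssemblyDiagnostics()

    vec_frags = digest(vector, enz)
    if len(vec_frags) < 2 and vec_frags[0].circular:
        raise ConfigError(
            f"vector {vector.id}: no {enz.name} site; the backbone cannot be opened"
        )
    backbone_cands = [
        f for f in vec_frags
        if f.internal_site_count(enz) == 0 and f.left_end.is_sticky and f.right_end.is_sticky
    ]
    if len(backbone_cands) != 1:
        raise ConfigError(
            f"vector {vector.id}: expected exactly one site-free backbone fragment "
            f"after {enz.name} digestion, found {len(backbone_cands)}"
        )
    backbone = backbone_cands[0]

    inserts: list[StickyFragment] = []
    for part in parts:
        if isinstance(part, StickyFragment):
            frags = [part]
            pid = part.source_id or "<fragment>"
        else:
            frags = digest(part, enz)
            pid = part.id
        usable = [
            f for f in frags
            if f.internal_site_count(enz) == 0
            and f.left_end.is_sticky
            and f.right_end.is_sticky
            and not f.circular
        ]
        if not usable:
            warnings.warn(f"InertInput: {pid} contributes no ligatable fragment")
            diags.unused_inputs.append(pid)
        inserts.extend(usable)
    return backbone, inserts, diags


def build_ligation_graph(backbone: StickyFragment, inserts) -> nx.DiGraph:
    """Directed graph over oriented fragments; edge A->B iff A.right == B.left.

    Nodes are ``(fragment_index, orientation)`` with index 0 = backbone (kept
    in its digested orientation); fragment data hangs off the node.  Also
    records a duplicate-label registry in ``graph.graph``.
    """
    g = nx.DiGraph()
    oriented: dict[tuple[int, int], StickyFragment] = {(0, 1): backbone}
    for i, frag in enumerate(inserts, start=1):
        oriented[(i, 1)] = frag
        if not frag.directional:
            oriented[(i, -1)] = frag.rc()
    for node, frag in oriented.items():
        g.add_node(node, fragment=frag)
    for a, fa in oriented.items():
        for b, fb in oriented.items():
            if a[0] != b[0] and fa.right_label == fb.left_label:
                g.add_edge(a, b, label=fa.right_label)
    # label bookkeeping over canonical orientations only
    class_counts: dict[str, int] = {}
    selfcomp = set()
    for frag in [backbone] + list(inserts):
        for lab in (frag.left_label, frag.right_label):
            if lab is None:
                continue
            if lab == revcomp_seq(lab):
                selfcomp.add(lab)
            cls = _label_class(lab)
            class_counts[cls] = class_counts.get(cls, 0) + 1
    g.graph["duplicate_labels"] = sorted(c for c, k in class_counts.items() if k > 2)
    g.graph["unpaired_labels"] = sorted(c for c, k in class_counts.items() if k == 1)
    g.graph["self_complementary_labels"] = sorted(selfcomp)
    return g


def _enumerate_closures(backbone: StickyFragment, inserts):
    """All circular chains backbone -> inserts... -> backbone (label-matched).

    Yields lists of (source_id, orientation, fragment) starting with the
    backbone.  Each underlying insert fragment is used at most once; both
    orientations are explored unless the fragment is directional.
    """
    variants: list[list[tuple[int, StickyFragment]]] = []
    for frag in inserts:
        v = [(1, frag)]
        if not frag.directional:
            v.append((-1, frag.rc()))
        variants.append(v)
    target = backbone.left_label
    closures = []

    def extend(path, used, right_label):
        if right_label == target:
            closures.append(list(path))
        for i, opts in enumerate(variants):
            if i in used:
                continue
            for orient, frag in opts:
                if frag.left_label == right_label:
                    path.append((frag.source_id, orient, frag))
                    used.add(i)
                    extend(path, used, frag.right_label)
                    used.remove(i)
                    path.pop()

    extend([(backbone.source_id, 1, backbone)], set(), backbone.right_label)
    return closures


def _closure_sequence(chain) -> str:
    parts = []
    for _, _, frag in chain:
        oh = len(frag.right_end.label)
        parts.append(frag.sequence[: len(frag.sequence) - oh])
    return "".join(parts)


def _canonical_circular(seq: str) -> str:
    doubled = seq + seq
    best = min(doubled[i : i + len(seq)] for i in range(len(seq)))
    rc = revcomp_seq(seq)
    doubled = rc + rc
    best_rc = min(doubled[i : i + len(seq)] for i in range(len(seq)))
    return min(best, best_rc)


def _count_circular_sites(seq: str, enz: EnzymeSpec) -> int:
    return len(find_sites(DnaMolecule("tmp", seq, "circular"), enz))


def _product_molecule(chain, product_id: str) -> DnaMolecule:
    seq = _closure_sequence(chain)
    feats: list[Feature] = []
    offset = 0
    total = len(seq)
    for _, _, frag in chain:
        for f in frag.features:
            start = (f.start + offset) % total
            feats.append(Feature(f.label, f.kind, start, start + len(f), f.strand))
        feats.sort(key=lambda f: (f.start, f.end))
        offset += len(frag.sequence) - len(frag.right_end.label)
    feats.sort(key=lambda f: (f.start, f.end))
    return DnaMolecule(product_id, seq, "circular", feats)


def assemble(
    vector: DnaMolecule,
    parts,
    enzyme: str | EnzymeSpec,
    *,
    allow_self_complementary: bool = False,
    product_id: str | None = None,
) -> AssemblyProduct:
    """Predict the unique circular Golden Gate product.

    ``parts`` may mix plasmids (digested in place), pre-cut
    :class:`StickyFragment` inputs (annealed oligo duplexes) and PCR products
    carrying appended sites (plain linear molecules).  Raises
    :class:`MissingJunction` when no stable closure exists and
    :class:`AmbiguousAssembly` when more than one does.
    """
    enz = get_enzyme(enzyme)
    enz.validate_for_assembly()
    parts = list(parts)
    if not parts and vector.is_circular and not find_sites(vector, enz):
        # a finished product with no remaining sites is a fixed point
        return AssemblyProduct(molecule=vector, parts_used=[(vector.id, 1)])
    backbone, inserts, diags = _digest_inputs(vector, parts, enz)

    graph = build_ligation_graph(backbone, inserts)
    diags.duplicate_labels = graph.graph["duplicate_labels"]
    diags.self_complementary_labels = graph.graph["self_complementary_labels"]
    if diags.self_complementary_labels and not allow_self_complementary:
        raise AmbiguousAssembly(
            "self-complementary overhang label(s) permit inverted ligation: "
            + ", ".join(diags.self_complementary_labels),
            colliding_labels=diags.self_complementary_labels,
        )

    closures = _enumerate_closures(backbone, inserts)
    stable, seen = [], set()
    for chain in closures:
        seq = _closure_sequence(chain)
        if _count_circular_sites(seq, enz) > 0:
            diags.unstable_closures += 1
            continue
        key = _canonical_circular(seq)
        if key in seen:
            continue
        seen.add(key)
        stable.append(chain)

    if not stable:
        unmatched = graph.graph["unpaired_labels"]
        raise MissingJunction(
            f"no stable circular closure; unmatched overhang label(s): "
            f"{', '.join(unmatched) if unmatched else '(none unpaired — sites remain)'}",
            unmatched_labels=unmatched,
        )
    if len(stable) > 1:
        raise AmbiguousAssembly(
            f"{len(stable)} distinct stable circular closures found"
            + (
                "; colliding labels: " + ", ".join(diags.duplicate_labels)
                if diags.duplicate_labels
                else ""
            ),
            colliding_labels=diags.duplicate_labels,
            closures=[tuple(pid for pid, _, _ in c) for c in stable],
        )

    chain = stable[0]
    used_ids = {pid for pid, _, _ in chain}
    supplied = []
    for part in parts:
        pid = part.source_id if isinstance(part, StickyFragment) else part.id
        supplied.append(pid)
    for pid in supplied:
        if pid not in used_ids and pid not in diags.unused_inputs:
            diags.unused_inputs.append(pid)

    pid = product_id or f"{vector.id}_product"
    mol = _product_molecule(chain, pid)
    diags.residual_sites = _count_circular_sites(mol.sequence, enz)
    product = AssemblyProduct(
        molecule=mol,
        parts_used=[(sid, orient) for sid, orient, _ in chain],
        diagnostics=diags,
    )
    return product


# ---------------------------------------------------------------------------
# Multiplexing


def _insert_label_pair(part, enz):
    if isinstance(part, StickyFragment):
        frags = [part]
    else:
        frags = digest(part, enz)
    usable = [
        f for f in frags
        if f.internal_site_count(enz) == 0
        and f.left_end.is_sticky
        and f.right_end.is_sticky
        and not f.circular
    ]
    if len(usable) != 1:
        pid = part.source_id if isinstance(part, StickyFragment) else part.id
        raise SlotHeterogeneity(
            f"{pid}: expected exactly one ligatable insert fragment, found {len(usable)}"
        )
    f = usable[0]
    pair = (f.left_label, f.right_label)
    flipped = (revcomp_seq(f.right_label), revcomp_seq(f.left_label))
    return min(pair, flipped)


def multiplex_assemble(
    vector: DnaMolecule,
    slot_options: dict,
    enzyme: str | EnzymeSpec,
    **kwargs,
) -> list[AssemblyProduct]:
    """Cartesian assembly over alternative parts per slot.

    ``slot_options`` maps slot name -> ordered list of parts; every option in
    a slot must expose the same (orientation-normalised) end-label pair.
    Products are returned sorted by slot-option index tuple — the full
    Cartesian set, one clone per combination.
    """
    enz = get_enzyme(enzyme)
    for slot, options in slot_options.items():
        if not options:
            raise SlotHeterogeneity(f"slot {slot!r}: empty option list")
        pairs = {_insert_label_pair(p, enz) for p in options}
        if len(pairs) != 1:
            raise SlotHeterogeneity(
                f"slot {slot!r}: options expose differing end labels: {sorted(pairs)}"
            )
    slots = list(slot_options)
    products = []
    for combo in itertools.product(*(range(len(slot_options[s])) for s in slots)):
        parts = [slot_options[s][i] for s, i in zip(slots, combo)]
        suffix = "_".join(str(i) for i in combo)
        prod = assemble(
            vector, parts, enz, product_id=f"{vector.id}_mx{suffix}", **kwargs
        )
        prod.selection = {s: getattr(p, "id", getattr(p, "source_id", "?"))
                          for s, p in zip(slots, parts)}
        products.append(prod)
    return products


# ---------------------------------------------------------------------------
# Verification


def verify_product(
    product: AssemblyProduct | DnaMolecule,
    enzyme: str | EnzymeSpec,
    *,
    dest_marker: str = "AmpR",
    entry_marker: str = "KanR",
) -> AssemblyDiagnostics:
    """Report-only re-check: residual sites and backbone-marker logic.

    The destination backbone's selection marker (AmpR in the reference kit)
    must be present and no entry-backbone marker (KanR) may have leaked in.
    """
    mol = product.molecule if isinstance(product, AssemblyProduct) else product
    enz = get_enzyme(enzyme)
    diags = AssemblyDiagnostics()
    diags.residual_sites = len(find_sites(mol, enz))
    markers = [f.label for f in mol.features if f.kind == "selection_marker"]
    diags.backbone_marker_ok = (
        any(dest_marker in m for m in markers)
        and not any(entry_marker in m for m in markers)
    )
    return diags
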