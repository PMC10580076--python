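"""Closure uniqueness, conservation, and the brute-force assembly oracle."""

import itertools
import random

import pytest

from ggkit import fixtures
from ggkit.assembly import (
    assemble,
    build_ligation_graph,
    multiplex_assemble,
    verify_product,
)
from ggkit.errors import AmbiguousAssembly, MissingJunction, SlotHeterogeneity
from ggkit.seq_model import DnaMolecule, revcomp_seq
from ggkit.typeiis import SAPI, digest, find_sites


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every ordering x orientation of every subset


def _chain_seq(frags):
    out = []
    for f in frags:
        out.append(f.sequence[: len(f.sequence) - len(f.right_end.label)])
    return "".join(out)


def _canon(seq):
    doubled = seq + seq
    fwd = min(doubled[i : i + len(seq)] for i in range(len(seq)))
    rc = revcomp_seq(seq)
    doubled = rc + rc
    return min(fwd, min(doubled[i : i + len(seq)] for i in range(len(seq))))


def oracle_closures(backbone, inserts, enz):
    """Canonical sequences of every stable circular closure through the backbone."""
    found = set()
    idx = range(len(inserts))
    for k in range(len(inserts) + 1):
        for subset in itertools.permutations(idx, k):
            for orients in itertools.product((1, -1), repeat=k):
                chain = [backbone]
                for i, o in zip(subset, orients):
                    chain.append(inserts[i] if o == 1 else inserts[i].rc())
                ok = all(
                    chain[j].right_label == chain[j + 1].left_label
                    for j in range(len(chain) - 1)
                ) and chain[-1].right_label == chain[0].left_label
                if not ok:
                    continue
                seq = _chain_seq(chain)
                mol = DnaMolecule("t", seq, "circular")
                if find_sites(mol, enz):
                    continue
                found.add(_canon(seq))
    return found


def _insert_frags(mols, enz):
    out = []
    for m in mols:
        for f in digest(m, enz):
            if f.internal_site_count(enz) == 0 and f.left_end.is_sticky and f.right_end.is_sticky:
                out.append(f)
    return out


def _backbone_frag(vector, enz):
    return next(
        f for f in digest(vector, enz)
        if f.internal_site_count(enz) == 0 and f.left_end.is_sticky and f.right_end.is_sticky
    )


@pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
def test_closures_match_exhaustive_enumeration(n):
    """The library's closure set equals the permutation/orientation oracle."""
    vector, inserts, _ = fixtures.make_stress_set(n, seed=n * 31)
    enz = SAPI
    oracle = oracle_closures(_backbone_frag(vector, enz), _insert_frags(inserts, enz), enz)
    prod = assemble(vector, inserts, enz)
    assert len(oracle) == 1
    assert _canon(prod.molecule.sequence) in oracle
    assert prod.n_inserts == n


def test_duplicate_label_found_by_both_routes():
    """Two parts sharing a label pair: oracle sees two closures, assemble raises."""
    kitB = fixtures.make_kit(4, 2, seed=1)
    parts = [kitB.parts[(s, s)][0] for s in kitB.scheme.slots]
    twin = kitB.parts[("slot2", "slot2")][1]  # same labels as the slot2 part present
    enz = kitB.scheme.enzyme
    oracle = oracle_closures(
        _backbone_frag(kitB.vector, enz), _insert_frags(parts + [twin], enz), enz
    )
    assert len(oracle) == 2
    with pytest.raises(AmbiguousAssembly):
        assemble(kitB.vector, parts + [twin], enz)


def test_six_part_assembly_contains_all_inserts(kit6):
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots]
    prod = assemble(kit6.vector, parts, "SapI")
    assert prod.n_inserts == 6
    assert prod.diagnostics.clean
    assert find_sites(prod.molecule, SAPI) == []
    labels = {f.label for f in prod.molecule.features}
    for p in parts:
        assert p.id in labels  # annotation propagated from every donor


def test_product_length_formula(kit6):
    """len(product) = sum of fragment span lengths - junctions * overhang."""
    enz = kit6.scheme.enzyme
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots]
    prod = assemble(kit6.vector, parts, enz)
    frags = [_backbone_frag(kit6.vector, enz)] + _insert_frags(parts, enz)
    n_junctions = len(frags)
    assert len(prod.molecule) == sum(len(f.sequence) for f in frags) - \
        n_junctions * enz.overhang_len


@pytest.mark.parametrize("n", [1, 8, 20])
def test_stress_scaling(n):
    vector, inserts, labels = fixtures.make_stress_set(n, seed=2)
    assert len(set(labels)) == n + 1
    prod = assemble(vector, inserts, "SapI")
    assert prod.n_inserts == n
    assert find_sites(prod.molecule, SAPI) == []


def test_empty_vector_self_closure():
    """A vector whose two overhang labels are equal re-circularises alone."""
    rng = random.Random(9)
    bb = fixtures._scrub("".join(rng.choice("ACGT") for _ in range(200)), [SAPI])
    st = fixtures._scrub("".join(rng.choice("ACGT") for _ in range(80)), [SAPI])
    vec = fixtures.make_destination_vector("selfv", "ACT", "ACT", SAPI, bb, st)
    prod = assemble(vec, [], "SapI")
    assert prod.n_inserts == 0
    assert find_sites(prod.molecule, SAPI) == []
    assert prod.molecule.is_circular


def test_idempotence_of_finished_product(kit6):
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots]
    prod = assemble(kit6.vector, parts, "SapI")
    again = assemble(prod.molecule, [], "SapI")
    assert again.molecule.sequence == prod.molecule.sequence


def test_missing_junction_names_labels(kit6):
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots if s != "NT"]
    with pytest.raises(MissingJunction) as exc:
        assemble(kit6.vector, parts, "SapI")
    left, right = kit6.scheme.span_labels(("NT", "NT"))
    classes = {min(l, revcomp_seq(l)) for l in (left, right)}
    assert classes <= set(exc.value.unmatched_labels)


def test_ligation_graph_edges(kit6):
    enz = kit6.scheme.enzyme
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots]
    g = build_ligation_graph(_backbone_frag(kit6.vector, enz), _insert_frags(parts, enz))
    # 7 fragments, canonical + flipped insert orientations
    assert g.number_of_nodes() == 1 + 2 * 6
    assert not g.graph["duplicate_labels"]
    # the designed chain is present as a directed path of canonical nodes
    for a, b in zip(range(0, 6), range(1, 7)):
        assert g.has_edge((a, 1), (b, 1)) or a == 0 and g.has_edge((0, 1), (1, 1))


def test_multiplex_counts(kit6_multi):
    opts = {s: kit6_multi.parts[(s, s)] for s in kit6_multi.scheme.slots}
    prods = multiplex_assemble(kit6_multi.vector, opts, "SapI")
    assert len(prods) == 4
    assert len({p.molecule.sequence for p in prods}) == 4


def test_multiplex_two_by_three():
    kit = fixtures.make_kit(4, {"slot1": 2, "slot3": 3}, seed=3)
    opts = {s: kit.parts[(s, s)] for s in kit.scheme.slots}
    prods = multiplex_assemble(kit.vector, opts, kit.scheme.enzyme)
    assert len(prods) == 6
    assert len({p.molecule.sequence for p in prods}) == 6


def test_multiplex_singleton_equals_assemble(kit6):
    opts = {s: kit6.parts[(s, s)] for s in kit6.scheme.slots}
    (prod,) = [p for p in multiplex_assemble(kit6.vector, opts, "SapI")]
    direct = assemble(kit6.vector, [kit6.parts[(s, s)][0] for s in kit6.scheme.slots],
                      "SapI")
    assert prod.molecule.sequence == direct.molecule.sequence


def test_multiplex_heterogeneous_slot_rejected(kit6, kit4):
    opts = {s: kit6.parts[(s, s)] for s in kit6.scheme.slots}
    opts["FP"] = opts["FP"] + [kit4.parts[("slot1", "slot1")][0]]
    with pytest.raises(SlotHeterogeneity):
        multiplex_assemble(kit6.vector, opts, "SapI")


def test_verify_product_clean_and_planted(kit6):
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots]
    prod = assemble(kit6.vector, parts, "SapI")
    diags = verify_product(prod, "SapI")
    assert diags.residual_sites == 0
    assert diags.backbone_marker_ok
    # plant a residual site
    bad = DnaMolecule(
        "bad", prod.molecule.sequence + SAPI.recognition, "circular",
        prod.molecule.features,
    )
    assert verify_product(bad, "SapI").residual_sites >= 1


def test_verify_product_roundtrip_stable(tmp_path, kit6):
    from ggkit.seq_model import read_record, write_record

    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots]
    prod = assemble(kit6.vector, parts, "SapI")
    path = tmp_path / "prod.gb"
    write_record(prod.molecule, path)
    back = read_record(path)
    d1, d2 = verify_product(prod, "SapI"), verify_product(back, "SapI")
    assert (d1.residual_sites, d1.backbone_marker_ok) == \
        (d2.residual_sites, d2.backbone_marker_ok)


def test_self_complementary_overhang_rejected_by_default():
    """A self-complementary 4-nt BsaI overhang permits inverted ligation and
    is an error unless explicitly allowed."""
    from ggkit.typeiis import BSAI

    rng = random.Random(4)
    bb = fixtures._scrub("".join(rng.choice("ACGT") for _ in range(200)),
                         [fixtures.SAPI, BSAI])
    st = fixtures._scrub("".join(rng.choice("ACGT") for _ in range(80)),
                         [fixtures.SAPI, BSAI])
    vec = fixtures.make_destination_vector("scv", "GATC", "AACC", BSAI, bb, st)
    with pytest.raises(AmbiguousAssembly) as exc:
        assemble(vec, [], "BsaI")
    assert "GATC" in exc.value.colliding_labels
    with pytest.raises(MissingJunction):  # allowed, but the ends cannot meet
        assemble(vec, [], "BsaI", allow_self_complementary=True)
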