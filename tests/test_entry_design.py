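"""Primer design, PCR simulation, oligo duplexes, domestication planning."""

import pytest

from ggkit import fixtures
from ggkit.assembly import assemble
from ggkit.entry_design import (
    check_frame,
    design_direct_pcr_part,
    design_entry_primers,
    duplex_for_span,
    oligo_duplex,
    plan_domestication,
    simulate_pcr,
    wallace_tm,
    MIN_HOMOLOGY,
    MAX_HOMOLOGY,
    TM_MIN,
)
from ggkit.errors import (
    AnnealError,
    DomesticationRequired,
    MissingJunction,
    SynthesisRecommended,
    ValidationError,
)
from ggkit.seq_model import DnaMolecule, Feature, revcomp_seq
from ggkit.slots import classify_part
from ggkit.typeiis import BSAI, SAPI, find_sites


# ---------------------------------------------------------------------------
# Entry-clone primers (BsaI route)


@pytest.mark.parametrize("seed", range(25))
def test_entry_primer_round_trip(kit6, seed):
    """PCR + BsaI assembly + classification recovers the requested span."""
    scheme = kit6.scheme
    span = scheme.all_spans()[seed % len(scheme.all_spans())]
    span = (span[0], span[0])  # single-slot spans for variety across seeds
    insert = fixtures.make_insert_for_span(scheme, span, 300 + 37 * seed, seed=seed)
    design = design_entry_primers(insert, span, scheme, vector_seed=seed)
    got, frag, orient = classify_part(design.predicted_clone, scheme)
    assert got == span and orient == 1
    # the released insert is exactly label + insert + label
    left, right = scheme.span_labels(span)
    assert frag.sequence == left + insert.sequence + right


def test_entry_primers_require_domestication(kit6):
    dirty = fixtures.make_random_insert(500, seed=1, plant=[("SapI", 100)])
    with pytest.raises(DomesticationRequired):
        design_entry_primers(dirty, ("NT", "NT"), kit6.scheme)


def test_homology_respects_tm_rule(kit6):
    insert = fixtures.make_insert_for_span(kit6.scheme, ("NT", "NT"), 400, seed=5)
    design = design_entry_primers(insert, ("NT", "NT"), kit6.scheme)
    p = design.primers
    for hom_len, tm in ((p.fwd_homology_len, p.fwd_tm), (p.rev_homology_len, p.rev_tm)):
        assert MIN_HOMOLOGY <= hom_len <= MAX_HOMOLOGY
        assert tm >= TM_MIN or hom_len == MAX_HOMOLOGY


# ---------------------------------------------------------------------------
# Direct SapI-tailed PCR parts


def test_plasmid_and_pcr_routes_identical_product(kit6):
    """The same part delivered as plasmid or PCR gives one final sequence."""
    scheme = kit6.scheme
    span = ("NT", "NT")
    insert = fixtures.make_insert_for_span(scheme, span, 450, seed=21)
    entry = design_entry_primers(insert, span, scheme)
    direct = design_direct_pcr_part(insert, span, scheme)
    others = {s: kit6.parts[(s, s)][0] for s in scheme.slots if s != "NT"}
    via_plasmid = assemble(
        kit6.vector, list(others.values()) + [entry.predicted_clone], "SapI"
    )
    via_pcr = assemble(
        kit6.vector, list(others.values()) + [direct.pcr_product], "SapI"
    )
    assert via_plasmid.molecule.sequence == via_pcr.molecule.sequence


def test_pcr_mismatch_rejected(kit6):
    insert = fixtures.make_insert_for_span(kit6.scheme, ("FP", "FP"), 300, seed=8)
    design = design_direct_pcr_part(insert, ("FP", "FP"), kit6.scheme)
    # mutate the template under the forward primer's 3' end
    seq = list(insert.sequence)
    seq[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[5]]
    mutated = DnaMolecule("mut", "".join(seq), "linear")
    with pytest.raises(ValidationError):
        simulate_pcr(mutated, design.primers.forward, design.primers.reverse)


# ---------------------------------------------------------------------------
# Oligo duplexes


def test_duplex_supplies_a_slot(kit6):
    """An annealed linker duplex stands in for the SEC-slot plasmid."""
    scheme = kit6.scheme
    core = "GGAGGTGGAAGCGGAGGTTCAGGCGGTAGTGGAGGA"  # flexible linker, site-free
    top, bottom = duplex_for_span(core, scheme, ("SEC", "SEC"), "linkerA")
    frag = oligo_duplex(top, bottom, scheme.enzyme.overhang_len, "linkerA")
    left, right = scheme.span_labels(("SEC", "SEC"))
    assert (frag.left_label, frag.right_label) == (left, right)
    assert frag.precut
    parts = [kit6.parts[(s, s)][0] for s in scheme.slots if s != "SEC"] + [frag]
    prod = assemble(kit6.vector, parts, "SapI")
    assert core in prod.molecule.sequence


def test_blunt_duplex_cannot_close_sticky_assembly(kit6):
    core = "GGAGGTGGAAGCGGAGGT"
    frag = oligo_duplex(core, revcomp_seq(core), 0, "blunt_linker")
    assert not frag.left_end.is_sticky and not frag.right_end.is_sticky
    parts = [kit6.parts[(s, s)][0] for s in kit6.scheme.slots if s != "SEC"] + [frag]
    with pytest.raises(MissingJunction):
        assemble(kit6.vector, parts, "SapI")


def test_duplex_mismatch_and_length_errors():
    top, bottom = duplex_for_span("GGAGGTGGAAGCGGAGGT", "rmce6", ("SEC", "SEC"))
    bad = bottom[:10] + {"A": "C", "C": "G", "G": "T", "T": "A"}[bottom[10]] + bottom[11:]
    with pytest.raises(AnnealError) as exc:
        oligo_duplex(top, bad, 3)
    assert exc.value.position is not None
    with pytest.raises(AnnealError):
        oligo_duplex(top, bottom[:-2], 3)  # unequal strand lengths


# ---------------------------------------------------------------------------
# Domestication


@pytest.mark.parametrize("n_sites", [1, 2, 3])
def test_domestication_plan(n_sites):
    """n sites -> n+1 fragments, 2(n+1) primers, faithful lesioned rebuild."""
    plant = [("SapI", 150 + 160 * i) if i % 2 == 0 else ("BsaI", 150 + 160 * i)
             for i in range(n_sites)]
    insert = fixtures.make_random_insert(720, seed=40 + n_sites, plant=plant, id="dom")
    plan = plan_domestication(insert, frame=0)
    assert len(plan.fragments) == n_sites + 1
    assert len(plan.primer_pairs) == n_sites + 1
    assert len(plan.lesions) >= n_sites
    lesioned = plan.target.sequence
    assert len(lesioned) == len(insert.sequence)
    diffs = [i for i, (a, b) in enumerate(zip(insert.sequence, lesioned)) if a != b]
    assert diffs == [l.position for l in plan.lesions]
    assert not find_sites(plan.target, SAPI) and not find_sites(plan.target, BSAI)
    assert plan.simulate() == lesioned


def test_domestication_preserves_translation():
    from Bio.Seq import Seq

    insert = fixtures.make_random_insert(600, seed=77, plant=[("SapI", 201)], id="orf")
    plan = plan_domestication(insert, frame=0)
    assert all(l.synonymous == "yes" for l in plan.lesions)
    assert str(Seq(insert.sequence).translate()) == str(Seq(plan.target.sequence).translate())


def test_domestication_without_frame():
    insert = fixtures.make_random_insert(500, seed=13, plant=[("BsaI", 250)])
    plan = plan_domestication(insert, frame=None)
    assert plan.lesions[0].synonymous == "unknown"
    assert not find_sites(plan.target, BSAI)


def test_domestication_no_sites_and_too_many():
    clean = fixtures.make_random_insert(400, seed=2)
    with pytest.raises(ValidationError):
        plan_domestication(clean)
    noop = plan_domestication(clean, allow_no_op=True)
    assert noop.fragments == [clean.sequence]
    many = fixtures.make_random_insert(
        1200, seed=3, plant=[("SapI", 100 + 180 * i) for i in range(5)]
    )
    with pytest.raises(SynthesisRecommended):
        plan_domestication(many, max_sites=4)


# ---------------------------------------------------------------------------
# Frame checking


def _cds_molecule(seq: str) -> DnaMolecule:
    return DnaMolecule("fusion", seq, "linear",
                       [Feature("fusion_cds", "CDS", 0, len(seq), 1)])


def test_check_frame_clean_and_broken():
    clean = _cds_molecule("ATG" + "GCT" * 30 + "TAA")
    assert all(r.ok for r in check_frame(clean))
    shifted = _cds_molecule("ATG" + "GCT" * 30 + "A" + "TAA")  # 1-nt junction slip
    assert not check_frame(shifted)[0].in_frame
    stopped = _cds_molecule("ATG" + "GCT" * 10 + "TGA" + "GCT" * 10 + "TAA")
    rep = check_frame(stopped)[0]
    assert rep.internal_stops


def test_wallace_rule_values():
    assert wallace_tm("ATAT") == 8
    assert wallace_tm("GCGC") == 16
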