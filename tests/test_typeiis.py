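"""Site finding and digestion against independent oracles.

The primary oracle is a naive literal-substring scanner with its own cut
arithmetic; Bio.Restriction provides an external cross-check of top-strand
cut positions on linear records.
"""

import random

import pytest
from Bio.Restriction import BsaI as BioBsaI
from Bio.Restriction import SapI as BioSapI
from Bio.Seq import Seq

from ggkit import fixtures
from ggkit.seq_model import DnaMolecule, revcomp, revcomp_seq, rotate
from ggkit.typeiis import (
    BSAI,
    SAPI,
    EnzymeSpec,
    digest,
    find_sites,
    is_domesticated,
)

# ---------------------------------------------------------------------------
# Oracle: naive scan + cut arithmetic written independently of the library


def oracle_sites(seq: str, circular: bool, enz: EnzymeSpec):
    """(strand, recognition_start) pairs by literal scanning of every offset."""
    rec, rc = enz.recognition, str(Seq(enz.recognition).reverse_complement())
    n = len(seq)
    doubled = seq + seq if circular else seq
    limit = n if circular else n - len(rec) + 1
    out = set()
    for i in range(max(limit, 0)):
        window = doubled[i : i + len(rec)]
        if window == rec:
            out.add((1, i % n))
        if window == rc:
            out.add((-1, i % n))
    return out


def oracle_cut_tops(seq: str, circular: bool, enz: EnzymeSpec):
    cuts = set()
    n = len(seq)
    for strand, r in oracle_sites(seq, circular, enz):
        if strand == 1:
            t = r + len(enz.recognition) + enz.cut_offset_top
        else:
            t = r - enz.cut_offset_bottom
        if circular:
            t %= n
        elif not (0 <= t and t + enz.overhang_len <= n):
            continue
        cuts.add(t)
    return cuts


def random_mol(seed, lo=50, hi=2000, planted=2):
    rng = random.Random(seed)
    n = rng.randint(lo, hi)
    s = list("".join(rng.choice("ACGT") for _ in range(n)))
    enz = rng.choice([SAPI, BSAI])
    for _ in range(rng.randint(0, planted)):
        rec = enz.recognition if rng.random() < 0.5 else revcomp_seq(enz.recognition)
        p = rng.randrange(n - len(rec))
        s[p : p + len(rec)] = rec
    return DnaMolecule(f"r{seed}", "".join(s), rng.choice(["linear", "circular"])), enz


@pytest.mark.parametrize("seed", range(60))
def test_find_sites_matches_literal_scan(seed):
    mol, enz = random_mol(seed)
    got = {(m.strand, m.recognition_start) for m in find_sites(mol, enz)}
    assert got == oracle_sites(mol.sequence, mol.is_circular, enz)


def test_simple_site_and_mirror():
    mol = DnaMolecule("x", "AAGCTCTTCAAAA", "linear")
    (m,) = find_sites(mol, SAPI)
    assert (m.strand, m.recognition_start) == (1, 2)
    (mr,) = find_sites(revcomp(mol), SAPI)
    assert mr.strand == -1
    assert mr.recognition_start == len(mol) - 2 - len(SAPI.recognition)


def test_origin_split_recognition_found():
    core = "GCTCTTC"
    seq = core[3:] + "ACGTACGTACGTA" + core[:3]  # site wraps the origin
    mol = DnaMolecule("wrap", seq, "circular")
    hits = [m for m in find_sites(mol, SAPI) if m.strand == 1]
    assert len(hits) == 1
    assert hits[0].recognition_start == len(seq) - 3


@pytest.mark.parametrize("seed", range(40))
def test_cut_positions_match_bio_restriction(seed):
    """Top-strand cut indices equal Bio.Restriction's 1-based search - 1."""
    mol, enz = random_mol(seed)
    if mol.is_circular:
        mol = DnaMolecule(mol.id, mol.sequence, "linear")
    bio = BioSapI if enz.name == "SapI" else BioBsaI
    expected = {p - 1 for p in bio.search(Seq(mol.sequence))}
    got = {
        m.cut_top for m in find_sites(mol, enz)
        if 0 <= m.cut_top and m.cut_bottom <= len(mol)
    }
    assert got == expected


@pytest.mark.parametrize("seed", range(40))
def test_digest_conservation_and_overhangs(seed):
    """Top-strand conservation; every overhang has the enzyme's length."""
    mol, enz = random_mol(seed)
    frags = digest(mol, enz)
    joined = "".join(f.top_strand for f in frags)
    if mol.is_circular and not frags[0].circular:
        t0 = min(oracle_cut_tops(mol.sequence, True, enz))
        assert joined == mol.sequence[t0:] + mol.sequence[:t0]
    else:
        assert joined == mol.sequence
    for f in frags:
        for end in (f.left_end, f.right_end):
            if end.is_sticky:
                assert len(end.label) == enz.overhang_len
                assert 2 <= len(end.label) <= 4


def _canon_frag(f):
    # an uncut circular fragment keeps the input origin; compare rotation-free
    if f.circular:
        doubled = f.sequence + f.sequence
        seq = min(doubled[i : i + len(f.sequence)] for i in range(len(f.sequence)))
    else:
        seq = f.sequence
    return (seq, f.left_label, f.right_label)


@pytest.mark.parametrize("seed", range(15))
def test_rotation_invariance_of_fragments(seed):
    mol, enz = random_mol(seed * 7 + 3)
    if not mol.is_circular:
        mol = DnaMolecule(mol.id, mol.sequence, "circular")
    base = sorted(_canon_frag(f) for f in digest(mol, enz))
    rng = random.Random(seed)
    for _ in range(3):
        rot = rotate(mol, rng.randrange(len(mol)))
        got = sorted(_canon_frag(f) for f in digest(rot, enz))
        assert got == base


@pytest.mark.parametrize("seed", range(15))
def test_strand_invariance(seed):
    """Digesting the reverse complement yields the flipped fragment multiset."""
    mol, enz = random_mol(seed * 13 + 1)
    fwd = sorted((f.sequence, f.left_label, f.right_label) for f in digest(mol, enz))
    rev = sorted(
        (g.sequence, g.left_label, g.right_label)
        for f in digest(revcomp(mol), enz)
        for g in [f.rc()]
    )
    assert fwd == rev


def test_single_site_circular_gives_one_linear_fragment():
    rng = random.Random(0)
    body = fixtures._scrub("".join(rng.choice("ACGT") for _ in range(93)), [SAPI])
    seq = body + SAPI.recognition  # one + site; cuts wrap past the origin
    mol = DnaMolecule("c1", seq, "circular")
    (frag,) = digest(mol, SAPI)
    assert not frag.circular
    assert len(frag.top_strand) == 100
    assert len(frag.sequence) == 100 + SAPI.overhang_len
    assert frag.left_label == frag.right_label  # same cut seen from both ends
    (t,) = oracle_cut_tops(seq, True, SAPI)
    assert frag.left_label == (seq + seq)[t : t + 3]


def test_zero_site_passthrough():
    mol = DnaMolecule("plain", "ACGT" * 30, "circular")
    (frag,) = digest(mol, SAPI)
    assert frag.circular and frag.sequence == mol.sequence
    assert not frag.left_end.is_sticky and not frag.right_end.is_sticky


def test_entry_clone_digests_to_insert_plus_backbone(kit6):
    """Two inward sites: insert carries no recognition, backbone carries both."""
    part = kit6.parts[("FP", "FP")][0]
    frags = digest(part, SAPI)
    assert len(frags) == 2
    by_sites = sorted(frags, key=lambda f: f.internal_site_count(SAPI))
    insert, backbone = by_sites
    assert insert.internal_site_count(SAPI) == 0
    assert backbone.internal_site_count(SAPI) == 2
    left, right = kit6.scheme.span_labels(("FP", "FP"))
    assert (insert.left_label, insert.right_label) == (left, right)


def test_is_domesticated_planted_truth():
    clean = fixtures.make_random_insert(1000, seed=4)
    assert is_domesticated(clean, [SAPI, BSAI]).ok
    planted = fixtures.make_random_insert(1000, seed=4, plant=[("BsaI", 300)])
    rep = is_domesticated(planted, [SAPI, BSAI])
    assert rep.counts["BsaI"] == 1 and rep.counts["SapI"] == 0
    sites = find_sites(planted, BSAI)
    assert sites[0].recognition_start == 300
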