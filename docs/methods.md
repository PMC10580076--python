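# Methods

## Sequence model and coordinates

All sequences are double-stranded DNA represented by the top strand 5'→3'
over `{A,C,G,T,N}`. Coordinates are 0-based, half-open, top-strand
throughout; GenBank's 1-based inclusive convention is converted only at the
I/O boundary (Biopython `SeqIO`). Circular records have a defined origin but
every site/fragment computation is rotation-invariant; a feature may span the
origin, stored unwrapped as `[start, end)` with `end > length` and emitted as
a `join(...)` location. Ambiguity codes other than `N` are rejected, and `N`
is forbidden inside recognition sites and overhangs, because overhang
identity must be unambiguous for ligation prediction.

## Cut geometry and the junction-label convention

A type IIS enzyme is `(recognition, o_top, o_bot)`; for a top-strand site
ending at position `e` the top strand is cut at `e + o_top` and the bottom at
`e + o_bot`, a 5' overhang of `o_bot − o_top` nt (bottom-strand sites mirror
this to the left). Shipped geometry — SapI `GCTCTTC(1/4)`, LguI as its
isoschizomer, BsaI `GGTCTC(1/5)` — was checked against the public
restriction-enzyme registry as distributed with Biopython, which also serves
as an independent oracle for cut positions in the test suite.

A fragment's `sequence` is the top strand of its **full span**, including
both junction regions; its left/right **labels** are the first/last
`overhang_len` characters. The label of an end is defined as the top-strand
sequence of the duplex the overhang will form, so ligatable ends have *equal*
labels and ligation is string concatenation with the junction counted once:
`A + B[overhang:]`. Flipping a fragment swaps the ends and
reverse-complements both labels, which is where the physical
reverse-complement pairing is absorbed. The physical top strand of a fragment
(`top_strand`, the span minus the right junction region) is what the
conservation invariant uses: the top strands of a digest tile the input
exactly once.

## Assembly semantics

The repetitive digestion–ligation reaction is modelled as its fixed point:
digest every input to completion, then enumerate circular closures in the
label-matching graph. Design choices:

- Fragments are orientation-blind (each may enter as-is or flipped) unless
  flagged directional; direction comes only from overhang design.
- Only *stable* closures count: any closure whose ligated circular sequence
  still contains a recognition site for the assembly enzyme — including
  sites created across a junction by ligation itself — would be re-cut and
  is discarded (counted in diagnostics). This also removes entry-backbone
  by-products naturally, since they retain their recognition sites.
- The backbone is the unique site-free fragment of the digested destination
  vector; exactly one stable closure through it must exist. Zero closures
  raise `MissingJunction` (naming unpaired label classes); two or more —
  including vector self-closure next to real products — raise
  `AmbiguousAssembly`. Wrong products are invisible on the bench only
  because of marker selection; in silico they are surfaced as errors.
- Self-complementary overhangs (possible at 4 nt) permit inverted ligation
  and are rejected by default (`allow_self_complementary` overrides).
- Closures not containing the backbone are not reported (not selectable
  states) but are countable for debugging; linear concatemers are not
  modelled.
- Everything is deterministic: no randomness exists anywhere in assembly,
  and multiplex products are ordered by slot-option index tuple.

Marker logic is annotation-driven: the destination backbone must contribute
a `selection_marker` feature labelled AmpR and no KanR entry marker may
appear in a product. Feature propagation carries every donor feature that is
fully contained in a placed fragment; features truncated by a cut are
dropped rather than emitted as partial intervals.

## Slot schemes and the builder

A scheme is an ordered slot list plus `n+1` junction labels (vector-left,
internal junctions, vector-right), all pairwise distinct, of the enzyme's
overhang length, with no reverse-complement collisions and no
self-complementary labels — conditions under which a validated kit cannot
produce an ambiguous build (property-tested). Combined spans ("slot
skipping") use the outer labels of their span. The default `rmce6` scheme
ships a toolkit-chosen 3-mer table; published kits do not fix these values in
any source available here, so correctness never depends on the defaults —
every test uses fixture-generated labels, and schemes round-trip through a
JSON config. CRISPR-style schemes (homology arms in the outer slots) are
just another `SlotScheme`; no special-case code exists. The registry is a
plain TSV (`id, slot_first, slot_last, kind, path, notes`) — the software
twin of a parts spreadsheet.

## Primer design and domestication

Tail anatomy is `AA` spacer + recognition + offset base(s) + junction label +
homology; the spacer is fixed for determinism and configurable. The melting
temperature rule is deliberately crude and stated: Wallace (2·AT + 4·GC) on
the homology region, extended from 18 nt until ≥ 55 °C, capped at 35 nt. The
entry-clone route shares the scheme enzyme's offset base with the tail
enzyme's 4-nt junction (`pad+label` / `label+pad`), and the designer
simulates the entire round trip (PCR → BsaI assembly → classification) at
design time, varying the pad bases deterministically until the predicted
clone digests cleanly; if no variant works, the insert/span juxtaposition
itself creates a site and the design fails with that diagnosis. The PCR
simulator anchors each primer by its longest uniquely matching 3' suffix and
rejects primers whose homology region mismatches internally (alignment
resuming upstream of a mismatch distinguishes a typo from an enzyme tail).

Domestication removes each internal site with one substitution. With a
reading frame supplied, only synonymous substitutions are accepted,
preferring third-codon positions, ties broken by lowest coordinate; without
a frame, the first site-destroying substitution in coordinate order is taken.
Every candidate is also screened against creating a new site for any assembly
enzyme in a ±7 nt window. Junction overhangs for the sub-amplicons start at
the native 4-mer at the lesion and slide downstream on collision or
self-complementarity; with 18+ nt homology the lesion always falls inside the
upstream fragment's mutagenic reverse primer. `n` sites yield `n+1` amplicons
and `2(n+1)` primers, and each plan re-simulates digestion and chain ligation
of its own amplicons before it is returned. More than `max_sites` (default 4)
sites raises a recommendation to order a synthetic fragment instead.

## The synthetic kit generator

Fixture kits emulate the reference kit's architecture, not its sequences:
circular destination vectors (AmpR feature, stuffer carrying both recognition
sites so the opened backbone is site-free), entry clones (KanR feature,
insert flanked by inward-cutting sites), empty entry vectors for the BsaI
route, and stress sets of up to 20 chained inserts (21 distinct overhangs,
the largest co-assembly supported). Part cores are random sequence scrubbed
of SapI/BsaI sites (default 150–400 bp, backbone cores ~220–320 bp — sizes
chosen to keep whole-kit simulations comfortable while exercising every code
path; marker features are short symbolic placeholder ORFs because marker
logic is annotation-driven, not homology-driven). Every junction that can
occur in any predicted product — including all multiplex pairings — is
screened for recognition sites created across the boundary, with offending
cores resampled deterministically; an unlucky label draw adjacent to a fixed
backbone flank triggers a deterministic full redraw. Same seed, byte-identical
output files (GenBank dates are pinned).

What the generator does **not** emulate: real marker/replicon sequences,
primer-dimer contamination, ligase fidelity on near-cognate overhangs,
partial digestion, methylation, or stoichiometry. Passing tests therefore
demonstrate the combinatorial and sequence-arithmetic correctness of the
design logic, not wet-lab success rates; bench efficiencies (e.g. colony
fractions) are outside what simulation can reproduce.

## Numerical/degenerate-input choices

- Zero-site molecules pass through digestion unchanged (flagged circular if
  the input was circular); a single-site circular molecule yields one linear
  fragment whose two end labels are the same cut's 3-mers.
- Linear molecules with a site too close to an end report the occurrence but
  cannot be cut there.
- A vector with no site, or without exactly one site-free backbone fragment,
  is a configuration error, except that re-assembling a finished site-free
  product with no parts is the identity (idempotence).
- Closure enumeration deduplicates by canonical circular sequence (minimum
  over rotations and reflection), so the same physical molecule reached by
  different orderings counts once.

## Known limitations

- Closure enumeration is exponential in principle; it is exercised to the
  supported 20-insert scale, where distinct labels keep the search linear.
  Heavily duplicated labels in large sets would slow it (they are an error
  condition anyway).
- The frame checker reports length-mod-3 and internal stops on annotated CDS
  spans; it does not infer fusion frames from junction positions.
- `N` bases are carried through sequences but any operation needing exact
  overhang identity rejects them.
- Only 5'-overhang type IIS chemistry is modelled; blunt and 3'-overhang
  cutters are out of scope (presence/absence checks still work for any
  recognition sequence).
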