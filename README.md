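# ggkit

In-silico Golden Gate assembly for slot-based cloning kits: a type IIS
(SapI/BsaI) digestion–ligation simulator, a registry-driven construct
builder, an entry-clone primer designer, and a domestication planner.

## The problem

Golden Gate (GG) cloning assembles a plasmid from many parts in one tube.
Type IIS restriction enzymes such as SapI and BsaI recognise a short
**non-palindromic** sequence and cut *outside* it, leaving a 2–4 nt 5'
overhang whose sequence is freely designable. Because every junction overhang
can be made distinct, a backbone plus up to ~20 inserts chain together in a
single defined order, and — since the recognition sites are designed to leave
with the discarded fragments — the desired clone is the only stable circular
species a repetitive digestion–ligation reaction can produce.

Kits built on this chemistry (notably the SapTrap-derived toolkits used for
*C. elegans* transgenesis) arrange entry clones in an ordered series of
**slots** — here the six-slot series `5arm, CT, FP, SEC, NT, 3arm` delimited
by seven distinct 3-nt SapI overhangs. Entry clones live on KanR backbones;
the destination (targeting) vector is AmpR, so only correctly assembled
clones survive selection. A part may skip slots by spanning several
consecutive positions, one slot can be fed several alternative parts to
multiplex a reaction, and new entry clones are made by PCR with BsaI-tailed
primers into empty KanR vectors — after *domesticating* (removing) any
internal SapI/BsaI sites.

`ggkit` simulates all of this before a single tube is touched: it predicts
the unique circular product (or explains exactly why there isn't one),
propagates annotations from every donor, validates whole kits, designs tailed
primers, and plans site-removal mutagenesis.

## The model in brief

A cut for a top-strand site `REC` at position *r* is the index pair
`t = r + |REC| + o_top`, `b = r + |REC| + o_bot` (mirrored for bottom-strand
sites); the 5' overhang is the top-strand window `[t, b)`. The **label** of a
sticky end is the top-strand sequence of the duplex its overhang will form;
two ends ligate iff their labels are **equal** (flipping a fragment swaps and
reverse-complements its labels). Assembly is the fixed point of
digest-to-completion + ligation: closures are simple cycles through the
backbone in the label-matching graph, and any closure whose circular sequence
retains a recognition site is discarded as unstable. Exactly one stable
closure must remain; zero raises `MissingJunction`, more than one raises
`AmbiguousAssembly`.

Enzyme geometry ships as a config table (SapI `GCTCTTC` 1/4 → 3-nt overhangs,
its isoschizomer LguI, BsaI `GGTCTC` 1/5 → 4-nt overhangs), verified against
the public restriction-enzyme registry.

## Worked example

No external sequences are needed — the fixture generator emits a complete
synthetic kit (destination vector, one entry clone per slot, two slot-skipping
clones, registry and scheme files):

```console
$ ggkit make-fixtures --out demo --slots 6 --seed 1
kit seed=1: vector + 8 parts -> demo/registry.tsv

$ ggkit digest demo/pDEST_fix.gb --enzyme SapI
id                        length  left    right
pDEST_fix_frag1              142  CGT     ACA
pDEST_fix_frag2              326  ACA     CGT

$ ggkit assemble --vector demo/pDEST_fix.gb \
    --part demo/5arm_p1.gb --part demo/CT_p1.gb --part demo/FP_p1.gb \
    --part demo/SEC_p1.gb --part demo/NT_p1.gb --part demo/3arm_p1.gb \
    --enzyme SapI -o demo/reporter.gb
pDEST_fix_product: 1991 bp, 6 inserts -> demo/reporter.gb

$ ggkit validate-kit --registry demo/registry.tsv --scheme demo/scheme.json
kit OK: 8 parts, zero findings
```

The digest table shows the vector opening into a 142 bp stuffer (which keeps
both SapI recognition sites) and a 326 bp AmpR backbone whose ends carry the
scheme's outer overhangs (`ACA`/`CGT`). The assembly joins the backbone and
all six inserts into one 1991 bp circular clone with zero residual SapI
sites; the product GenBank carries every donor's features in slot order.
`ggkit build --pick FP=FP_p1 ...` does the same from a registry selection,
and `ggkit design-entry` / `ggkit domesticate` emit primer order sheets for
creating new parts. The same functionality is available as a library
(`ggkit.assemble`, `ggkit.multiplex_assemble`, `ggkit.plan_domestication`,
...).

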