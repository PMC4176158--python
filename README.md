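# gcweld

A desk-scale design engine for **GC-adaptor combinatorial plasmid assembly** —
the modular scheme used to build cyanobacterial shuttle and suicide plasmids
from a library of reusable DNA devices.

## The problem

Genetic work in cyanobacteria needs many different vectors: autonomously
replicating shuttle plasmids (strain-specific or broad-host-range),
neutral-site knock-in vectors, and non-replicating knockout (suicide)
plasmids. Building each one by bespoke cloning is slow. In the GC-adaptor
scheme, every reusable **device** (a replicon, an *E. coli* origin, an
antibiotic-resistance marker, an expression/reporter/cloning cassette, …)
lives in an *E. coli* donor plasmid flanked by standardized 30-nt adaptor
flanks:

```
release site (6) | G/C core (15) | GAT (3) | secondary site (6)
   EcoRV/ZraI        pure G+C       EcoRV       XbaI/SacI/MfeI/
                                   half-site      NheI/AgeI
```

Blunt digestion with EcoRV (GAT^ATC) or ZraI (GAC^GTC) releases the device
with a 21-nt **GC-adaptor** at each end — half-site (ATC or GTC) + 15-bp G/C
core + GAT. Four core classes exist (G5C5, C3G3, GC, C2G); categories of
devices carry fixed class pairs, so the facing ends of adjacent devices
expose *identical* 21-mers. Pooled digests are then joined in one
isothermal (Gibson-style) reaction at 50 °C: the overlaps dictate fragment
order and orientation, and because the cores are 15/15 G+C every junction
melts far above the reaction temperature (Wallace Tm 76–78 °C). When a
ZraI-released end meets an EcoRV-released end the overlap carries a single
tolerated half-site mismatch.

`gcweld` implements this system in silico: it catalogs devices and donor
plasmids, validates them against the grammar, simulates restriction release
and overlap-guided assembly into a unique circle, designs adaptor-tailed
primers and knockout vectors, handles the SwaI/ccdB cloning-cassette
replacement path, annotates products from a parts database, exports GenBank,
and prints bench protocols.

## Worked example

Generate the seeded synthetic device kit (8 devices + donors + parts DB),
plan a strain-specific shuttle vector from four of them, and assemble it:

```sh
$ gcweld fixtures generate --seed 1 --out kit1
wrote 8 devices, 8 donors, 10 parts -> kit1/manifest.json

$ gcweld plan self_replicating_strain_specific --catalog kit1 \
    --slot cyano_replicon=repA7120 --slot ecoli_origin_paired=oriEc1 \
    --slot antibiotic_marker=aadA1 --slot expression_cassette=exprGFP1 \
    --out plan.json

$ gcweld assemble plan.json --catalog kit1 --out asm.gb --junctions j.json
assembled 532 nt circle with 4 junctions -> asm.gb
```

Each synthetic device has a 100-nt payload, so each released fragment is
100 + 54 = 154 nt (two 21-mer adaptors plus two 6-nt secondary sites), and
the circle is 4×154 − 4×21 = **532 nt**. The junction report shows the
overlap geometry — the replicon is ZraI-released (its payload carries an
internal EcoRV site), so its two junctions each carry the single half-site
mismatch, at overlap position 1 on one side and 21 on the other:

```
aadA1    -> exprGFP1  C2G   21 nt  0 mismatches  Tm 76 C
exprGFP1 -> repA7120  G5C5  21 nt  1 mismatch @1  Tm 76 C
repA7120 -> oriEc1    C3G3  21 nt  1 mismatch @21 Tm 76 C
oriEc1   -> aadA1     GC    21 nt  0 mismatches  Tm 76 C
```

`gcweld protocol plan.json --catalog kit1` prints the bench protocol: donors
pooled into an EcoRV pool and a ZraI pool, digestion at 5 U enzyme per µg
plasmid for 3–5 h in ≥ 50× the enzyme volume, cleanup, then isothermal
assembly. `gcweld plan knockout … --homology-up up.fa --homology-down
down.fa` additionally emits the 50-nt adaptor-tailed primers for the two
homology arms.

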