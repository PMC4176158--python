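# Methods

## The assembly model

`gcweld` simulates the GC-adaptor scheme as exact string algebra on A/C/G/T
sequences. The model rests on three assumptions:

1. **Blunt release is exact.** EcoRV (GAT^ATC), ZraI (GAC^GTC) and SwaI
   (ATTT^AAAT) cut both strands at the stated offset at every occurrence of
   their palindromic recognition sites; star activity, methylation
   sensitivity and partial digestion are not modeled. On a circular donor,
   *n* sites yield exactly *n* linear fragments whose lengths sum to the
   donor length.
2. **Overlap identity determines joining.** Two fragments join when the
   upstream fragment's terminal top-strand sequence equals the downstream
   fragment's leading top-strand sequence over the full overlap, allowing at
   most one mismatch for 21-mer adaptor overlaps and none for free-form
   (custom/cassette) overlaps. Exonuclease kinetics, misassembly rates and
   concatemer formation are not modeled: assembly succeeds exactly when the
   junction graph admits one Hamiltonian cycle over all fragments.
3. **Every junction must melt above the 50 °C reaction temperature**,
   checked with the configured melting estimator.

### Adaptor anatomy and face bookkeeping

A device's flank is `release site (6) + G/C core (15) + GAT (3) + secondary
site (6)`. The four core classes are G5C5 (`GGGGGCCCCCGGGGG`), C3G3
(`GGGCCCGGGCCCGGG`), GC (`CGCGCGCGCGCGCGC`) and C2G (`CGGCGGCGGCGGCGG`);
each is used in both orientations, and orientation is part of a face's
identity. A device's *right* flank is stored as the bundled string located
on the bottom strand, so on the device's top strand it reads as the reverse
complement with the release site distal to the payload. This is the only
arrangement under which a released fragment's right terminal 21-mer is the
reverse complement of `junction_21mer(right_face)`, making adjacent
fragments with opposite-orientation cores of one class expose *identical*
facing 21-mers. Face pairing therefore reduces to: same class, opposite
stored orientation.

Category → flank-class assignments: strain-specific replicons and knockout
*E. coli* origins are (G5C5, C3G3); *E. coli* origins paired with a
cyanobacterial replicon are (C3G3, GC); broad-host-range replicons and
neutral sites are (G5C5, GC); antibiotic markers are (GC, C2G); all
functional modules are (C2G, G5C5). The bundled flank table lists one string
per distinct printed flank (8 labels); neutral sites list only their right
flank in the source table, so their G5C5 left face is taken from the class
assignment above. Table strings are printed in one enzyme dialect per row; a
device released with the other enzyme swaps only the 6-nt prefix.

### Release-enzyme choice

EcoRV is the default; ZraI is substituted when the payload contains an
internal EcoRV site; a payload carrying both sites is rejected as
unreleasable. Both payload strands are screened even though the bundled
sites are palindromic (no behavioral difference today; future-proofing).

### Mixed-dialect junctions and normalization

A ZraI end contributes GTC/GAC half-sites where an EcoRV end contributes
ATC/GAT, so a ZraI↔EcoRV junction carries exactly one mismatch, at overlap
position 1 (a G/A top-strand pair) or 21 (C/T). The physical heteroduplex
resolves unpredictably on repair, so for deterministic output every
*mismatched* position is written in the EcoRV dialect (A at position 1, T at
position 21); the ambiguity is retained in the junction report. Matched
positions are never rewritten — a junction between two ZraI-released ends
would be a matched GTC/GAC duplex, but note that such a junction differs
from its partner's leading 21-mer at *two* half-site positions and is
therefore rejected by the one-mismatch rule: the engine flags adjacent
ZraI/ZraI devices as an open assembly rather than assuming the chemistry
tolerates a doubly wobbled overlap. Under this normalization, re-releasing
any device with the other enzyme (where its neighbours are EcoRV) leaves the
assembled sequence byte-identical.

### Vector grammars

Four templates fix the slot order around the circle (the cycle closes from
the last slot to the first); users choose devices, the grammar orders them:

| template | slots |
|---|---|
| self_replicating_strain_specific | cyano replicon · *E. coli* origin · marker · functional (4 devices) |
| broad_host_range | BHR replicon · marker · functional (3) |
| neutral_site_integration | neutral site · marker · functional (3) |
| knockout | backbone · upstream arm\* · marker · downstream arm\* (2 devices + 2 custom PCR fragments) |

Exactly one functional slot exists per template; extra or unplaceable
devices are rejected. Knockout homology arms get their face classes from the
slot they bridge (C3G3|GC upstream, C2G|G5C5 downstream) with the enzyme
dialect chosen per-arm by the payload rule, and must be at least 100 nt
(configurable) — a floor chosen as the practical minimum for homologous
recombination in cyanobacteria.

### Custom PCR fragments and primer tails

Tailed primers carry the full 30-nt flank at their 5′ ends (50 nt total with
a 20-nt target-specific core), the same design used to build devices into
donors. Before junction finding, the simulated amplicon is digested with its
tail release enzymes, trimming the outer 9 nt per end and leaving standard
21-mer adaptor ends; in the wet reaction the equivalent trimming is done by
the 5′-exonuclease chew-back and the proofreading polymerase's removal of
unannealed 3′ bases.

### The SwaI/ccdB cloning cassette

The cassette payload is `adaptor-1 · AAAT · ccdB stuffer · ATTT ·
revcomp(adaptor-2)`, where the two 25-nt adaptors
(`TAGTCGGCCAATAACCCAGGGATTT`, `CTCCTGCCGGGGAGCTCCTTCATTT`) each end in the
ATTT half of a SwaI site, so SwaI digestion drops the toxic stuffer and
leaves the adaptors terminal on the opened backbone. An insert tailed with
adaptor-1 and the reverse complement of adaptor-2 joins through two exact
25-nt overlaps (Wallace Tm 74 and 80 °C); the ccdB part is absent from the
product by construction.

## Melting temperature

Default: the Wallace rule, 4 °C per G/C + 2 °C per A/T — deterministic
integer arithmetic, and for 15/15 G+C cores any standard formula clears the
50 °C bound (adaptor 21-mers sit at 76 °C EcoRV-dialect / 78 °C ZraI). A
nearest-neighbor option (SantaLucia unified parameters via Biopython, 50 mM
monovalent salt, 250 nM strands) is available behind
`MeltingParams(method="nearest_neighbor")`; all shipped checks use Wallace.

## Hairpin screen

The single-strand screen is combinatorial, not thermodynamic: it fails a
sequence iff two reverse-complementary substrings of ≥ `min_stem` bases are
separated by ≥ `min_loop` intervening bases, and reports every seed stem.
Defaults are `min_stem=5, min_loop=3`. The stem threshold is calibrated to
the 50 °C reaction: a 4-bp stem cannot nucleate a stable hairpin there, and
the printed cassette adaptors — designed to be structure-free — do contain
one 4-bp self-complementary pair (CTCC/GGAG, 6-nt loop) while containing no
5-bp pair. A stricter screen is one argument away.

## Synthetic fixtures

The generator fabricates what the real donor library provides: categorized
devices with clean payloads (no EcoRV/ZraI/SwaI sites, resampled with a
bounded retry budget), small synthetic parts embedded at recorded
coordinates, and ~2.7-kb donor backbones (pUC19-scale) carrying a marker
part. Payloads default to 100 nt — convenient desk-scale arithmetic
(154-nt released fragments, a 532-nt four-device circle) — and the
strain-specific replicon carries one planted internal EcoRV site so the kit
exercises the ZraI fallback and the mixed-dialect junctions. The PRNG is
Python's Mersenne Twister seeded with `"<seed>:<stream>"` strings; identical
seeds give byte-identical catalogs.

What passing tests show — and don't: the suite validates the combinatorial
logic (release geometry, overlap uniqueness, grammar enforcement, I/O
round-trips) on sequences two orders of magnitude shorter than real devices.
It says nothing about wet-lab assembly efficiency, enzyme fidelity on real
substrates, repeat-rich payloads (where exact substring annotation and
unique-payload release identification could both become ambiguous), or the
biology of the assembled vectors.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GenBank output is 1-based
  inclusive, origin-spanning features written as `join(a..N,1..b)`.
- Assembled circles are canonicalized to the lexicographically minimal
  rotation (Booth's algorithm) of the strand on which the first planned
  fragment reads forward; permuting or flipping input fragments cannot
  change the output.
- Overlapping/nested recognition sites are each reported and each cut.
- Duplicate part sequences annotate every matching part id at a locus;
  palindromic parts are reported once, on the plus strand.
- Fragments supplied in flipped orientation are auto-reverse-complemented
  with a logged notice.
- Catalog manifests are canonical JSON (sorted keys, schema-checked field by
  field in code); sequences over 200 nt go to sibling GenBank files. GenBank
  output carries a fixed LOCUS date so repeated writes are byte-identical.

## Known limitations

Sticky-end enzymes, methylation, thermodynamic secondary-structure
prediction, PCR thermocycling beyond tail concatenation, multi-functional-
module vectors, and adjacent ZraI/ZraI junctions (see above) are out of
scope. Annotation is exact-match only — no mismatch-tolerant part search.
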