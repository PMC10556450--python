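# Methods

This note documents the models behind `forkpcr`: what is simulated, what
is deliberately simplified, the defaults and why, and the numerical
conventions.

## Sequence model and coordinates

All oligos are strict uppercase ACGT, stored 5′→3′; IUPAC ambiguity
codes, RNA, and modified bases are out of scope. Coordinates are 0-based
half-open everywhere (BED convention); human-readable reports that show
1-based positions say so. A binding site is keyed by the template base
paired with the primer's 3′ terminus.

## Fork-set geometry and design rules

A fork set obeys: |PFP| = |SFP| = 41 nt, stem 21 nt, branch = |BP| =
20 nt, PFP = branch + stem, SFP = BP + stem. The *designed* decomposition
is authoritative: the literal 3′ identity between PFP and SFP may exceed
21 nt when branch-terminal bases coincide by chance (the bundled fork
set 2 shares 22 nt), so the decomposition check uses ≥ 21. Branches are
"heterologous" when their longest shared substring is ≤ 10 nt — half the
branch — which also blocks the bridging-PCR failure mode in which a PFP
site elongates along SFP.

Per-oligo rules: homopolymer runs ≤ 3; per-base frequency within
[0.05, 0.50] for validation (the tightest window every bundled reference
primer satisfies — the universal BP is half C), tightened to [0.10, 0.40]
in the de-novo designer; role-specific length windows (fork primers
fixed, NSPs 20–32 nt). One bundled NSP (gadR iNSP) contains an AAAA run
and is deliberately reported as failing the run rule rather than
special-cased.

The designer is rejection sampling over random 20/21-mers — matching the
"random oligomer" character of the primers — with per-rule rejection
accounting and a candidate budget (default 10⁵) so unsatisfiable
constraints fail loudly, naming the dominant rejecting rule. Stems are
additionally screened for ≤ 10 nt of 3′ identity with BP, and stems
differ across parallel sets. NSP triples are selected from the strand
pointing toward the unknown flank, nesting successively closer to the
junction without overlap (gap ≥ 0), so every inner primer lies inside the
previous round's product and never sits on carried-over primer dimers.

## Melting temperature

Tm is nearest-neighbor with the unified 2004 parameter set and the
Owczarzy divalent correction, as implemented by Biopython's
`MeltingTemp.Tm_NN` (`DNA_NN4`, `saltcorr=7`), under the walking recipe's
conditions: 50 mM monovalent, 2.5 mM Mg²⁺, 1.6 mM total dNTP, 0.2 µM
primer. Results are rounded to 0.01 °C for determinism. Design windows
are 60–65 °C for stems/branches/NSPs; acceptance windows widen by ±3 °C
(57–68 °C for segments, 71–79 °C for the ~75 °C full-length primers)
because reported Tm figures for such primers typically come from vendor calculators with
systematic offsets, and exact reproduction of those tools is not
attempted. The test suite cross-checks the engine against an
independently hand-coded NN sum to within 1.5 °C.

## Structure screens

Hairpin and dimer detection is combinatorial — maximal Watson-Crick
pairable windows — not free-energy folding. This suffices for the
method's logic, which is length-threshold based, and keeps every verdict
exact. Design-time "severe" thresholds: hairpin stem ≥ 5 bp, 3′-anchored
duplex ≥ 4 bp, internal duplex ≥ 8 bp (conventional practice; tunable).
The terminal-inverted-repeat scan returns the largest k with
`seq[:k] == revcomp(seq[-k:])`.

## Annealing stringency

Both annealing regimes are rule thresholds on the primer's 3′ alignment:

| regime | exact 3′ run | identity over 3′ window (21 nt) | models |
|---|---|---|---|
| low (25 °C) | ≥ 7 | ≥ 0.6 | the permissive seeding cycle |
| high (65 °C) | ≥ 18 | ≥ 0.6 | designed matches only |

18 nt is the smallest round number that separates every designed 3′ match
(full NSPs ≥ 20 nt; the 21-nt stem priming a PFP site; the 20-nt BP
priming an SFP/BP site) from partial ones; 7 nt with 60% window identity
is the loosest setting that keeps low-stringency site counts tractable on
large templates. All primers present in round 1 get the low-stringency
treatment symmetrically — the existence of category I products implies
oNSP can mis-prime too. Site discovery anchors on the exact 3′ seed, so
it is provably exhaustive for these rules and is tested against a
position-by-position oracle.

Extension incorporates the full primer, unhybridized 5′ tail included —
this is what converts a partial site into a perfect primer site for the
next round — and truncates products at 5 000 nt (from the observed
product ceiling and a 2-minute extension; a kinetic simplification).
Polymerase errors, partial extension, and template switching are not
modeled.

## Product classification and abundance

Abundance is class-based (exponential / linear / suppressed), not
copy-number kinetics: the method's selection argument is qualitative, and
classes make every assertion exact. Band intensities (the SFP titration
experiment) are correspondingly out of scope; the SFP concentration
appears as a parameter default (0.02 µM, 1/10 of BP) and as the modeling
rule that SFP acts only once, as the round-2 bridge, never as an
amplifier.

A paired product is exponential because both ends are exact primer
copies; unpaired first strands are retained as linear and categorized by
their sole primer (oNSP alone → I, PFP alone → III). A paired oNSP–PFP
product is the *target* when its oNSP site is the designed full-length
match, category II otherwise.

Suppression requires both conditions: terminal inverted repeat ≥ 41 nt
("more than 40") **and** the best competing primer 3′ match onto the
repeat shorter than the repeat. A full-length-matching primer would still
amplify; the 21-nt stem against a 41-nt repeat loses. Suppressed products
leave the template set and never appear on the gel. Carryover (diluted)
products are simply non-amplified; the bench-side 10–1 000× dilution is
not modeled. Primer-dimer products are excluded by construction since
sites must lie on genome-derived template.

The secondary target's walking-side terminus follows this convention: the
bridging copy, anchored at the PFP site's 3′ terminus, rewrites the whole
terminal primer copy into revcomp(SFP) = stem remnant + BP tail. The
product's provenance note records this convention. Consequently the
secondary length equals the primary length minus the oNSP→mNSP nesting
offset, and the tertiary shrinks by the mNSP→iNSP offset — exact
arithmetic asserted in tests.

## Synthetic fixtures

`make_fixture` emulates a walking experiment: a random genome with a
300-nt known locus (25-mer NSPs at offsets 0/40/80), a planted partial
PFP site (10 nt exact 3′ run, ~76% window identity — low- but not
high-stringency) at the requested distance beyond the junction, and
optional decoy pairs forcing one product per unwanted category. Truth
metadata enumerates every expected product by coordinate arithmetic. To
make truth exhaustive, the generator scrubs the background: it re-scans
the genome with every primer and mutates the 3′ seed of any unplanned
site (a ~10-kb random genome would otherwise carry on the order of one
spurious low-stringency site). Real genomes are *not* scrubbed, of
course: passing fixture tests shows the selection logic is correct, not
that real walks are background-free — on real templates the low-stringency
cycle produces many more linear strands and category I–III products,
which is precisely what the suppression/dilution machinery is for.
Repeat-rich or low-complexity genomic regions, which the fixtures'
uniform random background does not emulate, are the main unmodeled risk.

## Problem sizes and determinism

Test and acceptance sweeps use 8–10 kb genomes, walk distances 500–4 500
nt, 100 designer seeds, and 100 simulation fixtures — sizes at which
every property is checked exhaustively against oracles while the whole
suite stays interactive. All randomness flows through a single seeded
NumPy generator per run; the CLI requires `--seed` on stochastic
subcommands and echoes it into every report. Config precedence is CLI
flag > config file > built-in default.

## Known limitations

- No thermodynamic binding probabilities or annealing competition: a site
  either satisfies a regime or it does not.
- The hairpin model has no loop-energy term, so unusually stable short
  hairpins and unstable long ones are treated alike.
- Amplicon length is capped rather than drawn from an extension-time
  distribution.
- Multi-template competition, polymerase processivity, and band
  intensities are out of scope.
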