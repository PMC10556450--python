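# forkpcr

In-silico **fork PCR genome walking**: design the walking primers, predict
what the three PCR rounds will amplify on any template, and print the
bench protocol.

## The problem and the method

Genome walking recovers unknown DNA flanking a known locus without
building a genome library. Fork PCR does it with a *fork primer set* of
three random oligomers plus three nested site-specific primers (NSPs):

- **PFP** (primary fork primer) and **SFP** (secondary fork primer) are
  41-mers sharing a 3′ **stem** of 21 nt; their 5′ **branches** (20 nt)
  are unrelated ("heterologous").
- **BP** (branch primer) is identical to SFP's branch and is *universal*:
  one BP serves all parallel fork sets.
- **oNSP → mNSP → iNSP** sit in the known sequence, nesting toward the
  unknown junction; one drives each round.

Round 1 (PFP + oNSP) opens with a single 25 °C low-stringency cycle in
which PFP lands on partially matched sites genome-wide, writing its full
sequence — mismatches included — into the 5′ tails of a batch of first
strands. Thirty 65 °C cycles then exponentially amplify only strands
bounded by a perfect oNSP site and a PFP tail copy. Round 2 (SFP + BP +
mNSP, SFP at 1/10 the BP concentration) uses SFP once as a *bridge*: its
stem primes the PFP site, its branch writes a BP site onto the product,
and BP + mNSP take over as the amplifiers. Round 3 (BP + iNSP) repeats the
selection one nest inward.

Unwanted primary products fall into three categories — **I** (oNSP at
both ends), **II** (mis-primed oNSP + PFP), **III** (PFP at both ends) —
and the design eliminates each: I and II lack a true mNSP site and are
diluted; III carries a 41-nt terminal inverted repeat, so the single
strand folds into a panhandle hairpin that outcompetes SFP's 21-nt stem
match (suppression PCR: repeats over 40 nt suppress; the competing match
is only 21 nt). The simulator implements exactly this logic at the strand
level and reports a per-round *virtual gel*.

## Worked example

Generate a synthetic walking problem — a seeded 8-kb genome with a known
locus and a partial PFP site planted 1 500 nt beyond the junction — and
simulate all three rounds:

```sh
forkpcr fixture  --seed 7 --genome-len 8000 --walk-distance 1500 --out demo
forkpcr simulate --genome demo/genome.fasta --primers demo/primers.tsv --out demo_sim
```

which prints:

```
virtual gel (exponential products only)
lane P (round 1): 1841 nt
lane S (round 2): 1801 nt
lane T (round 3): 1761 nt
```

The primary target is 1841 nt: the 25-nt oNSP, 275 nt of known locus
downstream of it, the 1500-nt unknown flank, and the 41-nt PFP copy.
Each nested round trims the known side to the next NSP (40 nt closer to
the junction here), so the secondary and tertiary bands are 1801 and
1761 nt — matching `demo/truth.json` exactly. `demo_sim/products.json`
lists every product with its category, abundance class, and suppression
flag; `amplicons.fasta` holds the predicted tertiary target, which
`forkpcr verify` confirms overlaps the known region base-for-base.

Primer design for a new locus works the same way:

```sh
forkpcr design --n-sets 2 --seed 7 --known mylocus.fasta --out primers
forkpcr protocol --out protocol
```

`design` emits two fork sets sharing one universal BP plus a nested NSP
triple, as a primer sheet (TSV), FASTA, and a JSON report; `protocol`
prints the three-round thermal programs and reaction recipes.

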