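"""Strand-level simulation of the three fork PCR rounds.

Round 1 (PFP + oNSP): one low-stringency cycle seeds single strands from
partially matched sites on the genome; the following high-stringency
cycles pair them.  Products are classified by their end primers:

* target — oNSP priming its designed (perfect) locus site on one end, PFP
  on the other, i.e. the amplicon spans the known/unknown junction;
* category I — oNSP at both ends (oNSP mis-priming alone);
* category II — a mis-primed oNSP end plus a PFP end;
* category III — PFP at both ends.

Round 2 (SFP + BP + mNSP): SFP, present at 1/10 the BP concentration, acts
once as a bridge — its 21-nt stem primes the PFP site and its 5' branch
writes a BP site onto the product — after which BP and mNSP amplify
exponentially.  Category I/II products lack a true mNSP site and are
carried over unamplified ("diluted"); category III products end in a
terminal inverted repeat of the full 41-nt PFP, which folds into a
panhandle hairpin that outcompetes the 21-nt stem match, so they are
suppressed.  Round 3 (BP + iNSP) repeats the selection one nest inward.

Abundance is class-based (exponential / linear), not copy-number kinetics:
the method's selection argument is qualitative and classes keep every
assertion exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .annealing import (
    HIGH_STRINGENCY,
    LOW_STRINGENCY,
    BindingSite,
    StringencyModel,
    extend_product,
    find_binding_sites,
)
from .oligos import Oligo, longest_common_suffix, revcomp
from .thermo import terminal_inverted_repeat

__all__ = [
    "Amplicon",
    "ProductPool",
    "SimParams",
    "GelReport",
    "RoundOrderError",
    "simulate_primary",
    "simulate_secondary",
    "simulate_tertiary",
    "virtual_gel",
    "verify_walk",
    "WalkVerdict",
]


class RoundOrderError(ValueError):
    """A pool from the wrong round was fed to a simulation stage."""


@dataclass(frozen=True)
class Amplicon:
    """A predicted product, stored with its known-side (NSP) end leftmost."""

    seq: str
    left_primer: str
    right_primer: str | None  # None for unpaired single strands
    category: str  # target | I | II | III | carryover
    abundance: str  # exponential | linear
    suppressed: bool
    round: int
    insert_span: tuple[int, int] | None = None  # genome coords of the insert when known
    note: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def key(self) -> tuple:
        return (self.left_primer, self.right_primer, self.length)

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "left_primer": self.left_primer,
            "right_primer": self.right_primer,
            "category": self.category,
            "abundance": self.abundance,
            "suppressed": self.suppressed,
            "round": self.round,
            "insert_span": list(self.insert_span) if self.insert_span else None,
            "note": self.note,
        }


@dataclass
class ProductPool:
    round: int
    amplicons: list[Amplicon] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def exponential(self) -> list[Amplicon]:
        return [
            a for a in self.amplicons
            if a.abundance == "exponential" and not a.suppressed
        ]

    def add(self, amp: Amplicon, note: str = "") -> None:
        # pools never hold duplicate (left, right, length) triples
        if any(a.key() == amp.key() for a in self.amplicons):
            return
        self.amplicons.append(amp)
        if note:
            self.notes.append(note)


@dataclass(frozen=True)
class SimParams:
    """Stringency, suppression, and concentration settings of the simulation."""

    low_model: StringencyModel = LOW_STRINGENCY
    high_model: StringencyModel = HIGH_STRINGENCY
    suppression_min_repeat: int = 41  # "more than 40 nt"
    sfp_uM: float = 0.02
    bp_uM: float = 0.2
    max_amplicon_len: int = 5000

    def __post_init__(self) -> None:
        if self.suppression_min_repeat < 1:
            raise ValueError("suppression_min_repeat must be >= 1")
        if self.sfp_uM < 0 or self.bp_uM < 0:
            raise ValueError("concentrations must be >= 0")


def _classify_pair(
    left: BindingSite, right: BindingSite, pfp: Oligo, onsp: Oligo
) -> str:
    def kind(site: BindingSite) -> str:
        return "onsp" if site.primer == onsp.name else "pfp"

    lk, rk = kind(left), kind(right)
    if lk == rk == "onsp":
        return "I"
    if lk == rk == "pfp":
        return "III"
    nsp_site = left if lk == "onsp" else right
    # the designed locus site is a perfect full-length match
    exact = nsp_site.matched_run >= len(onsp)
    return "target" if exact else "II"


def simulate_primary(
    genome: dict[str, str] | str,
    pfp: Oligo,
    onsp: Oligo,
    params: SimParams | None = None,
) -> ProductPool:
    """Round 1: low-stringency seeding by PFP and oNSP, then exponential pairing.

    Every ordered (+, -) site pair within the length ceiling yields a
    double-stranded amplicon whose ends are exact copies of the two priming
    primers (full-tail incorporation), hence exponential.  Unpaired sites
    contribute linear single strands, retained because round 2 may still act
    on them.  Returns a warning note (not an error) when oNSP has no site.
    """
    p = params or SimParams()
    records = {"genome": genome} if isinstance(genome, str) else dict(genome)
    pool = ProductPool(round=1)
    onsp_found = False
    for rec_id, seq in records.items():
        seq = seq.upper()
        sites: list[BindingSite] = []
        for oligo in (pfp, onsp):
            sites += find_binding_sites(seq, oligo.seq, p.low_model, rec_id, oligo.name)
        by_primer = {pfp.name: pfp, onsp.name: onsp}
        onsp_found = onsp_found or any(s.primer == onsp.name for s in sites)
        plus = [s for s in sites if s.strand == "+"]
        minus = [s for s in sites if s.strand == "-"]
        paired: set[tuple[str, int, str]] = set()
        for sp in plus:
            lp = by_primer[sp.primer]
            for sm in minus:
                if sm.three_prime_pos <= sp.three_prime_pos:
                    continue
                rp = by_primer[sm.primer]
                interior = seq[sp.three_prime_pos + 1 : sm.three_prime_pos]
                total = len(lp.seq) + len(interior) + len(rp.seq)
                if total > p.max_amplicon_len:
                    continue
                product = lp.seq + interior + revcomp(rp.seq)
                cat = _classify_pair(sp, sm, pfp, onsp)
                left_name, right_name = lp.name, rp.name
                span = (sp.three_prime_pos + 1, sm.three_prime_pos)
                # canonical orientation: NSP end leftmost
                if cat in ("target", "II") and lp.name == pfp.name:
                    product = revcomp(product)
                    left_name, right_name = rp.name, lp.name
                pool.add(
                    Amplicon(
                        product, left_name, right_name, cat, "exponential",
                        suppressed=False, round=1, insert_span=span,
                        note=f"{rec_id}:{sp.three_prime_pos}+/{sm.three_prime_pos}-",
                    ),
                    note=f"pair {lp.name}@{sp.three_prime_pos}+ x {rp.name}@{sm.three_prime_pos}-",
                )
                paired.add((sp.primer, sp.three_prime_pos, "+"))
                paired.add((sm.primer, sm.three_prime_pos, "-"))
        for s in plus + minus:
            if (s.primer, s.three_prime_pos, s.strand) in paired:
                continue
            strand_seq = extend_product(seq, s, by_primer[s.primer].seq, p.max_amplicon_len)
            cat = "I" if s.primer == onsp.name else "III"
            pool.add(
                Amplicon(
                    strand_seq, s.primer, None, cat, "linear", suppressed=False,
                    round=1, note=f"unpaired single strand {rec_id}:{s.three_prime_pos}{s.strand}",
                )
            )
    if not onsp_found:
        pool.notes.append(
            f"warning: no low-stringency {onsp.name} site on the template; "
            "target absent"
        )
    return pool


def _nsp_site(amp_seq: str, nsp: Oligo, model: StringencyModel) -> BindingSite | None:
    """Leftmost '+'-strand high-stringency NSP site on an amplicon top strand."""
    if len(amp_seq) < min(model.window, len(nsp.seq)):
        return None
    sites = [
        s
        for s in find_binding_sites(amp_seq, nsp.seq, model, "amplicon", nsp.name)
        if s.strand == "+"
    ]
    return sites[0] if sites else None


def _suppression(
    amp: Amplicon, primers: list[Oligo], params: SimParams
) -> tuple[bool, int, int]:
    """(suppressed?, repeat length, best competing 3' match) for a product.

    Suppressed when the terminal inverted repeat reaches the threshold AND
    every available primer's 3' match onto the repeat terminus is shorter
    than the repeat — the panhandle fold then wins the competition.
    """
    tir = terminal_inverted_repeat(amp.seq)
    repeat = amp.seq[:tir]
    best = max(
        (longest_common_suffix(pr.seq, repeat) for pr in primers), default=0
    )
    return (tir >= params.suppression_min_repeat and best < tir, tir, best)


def _nested_round(
    pool: ProductPool,
    round_no: int,
    nsp: Oligo,
    bp: Oligo,
    params: SimParams,
    bridge: Oligo | None,
) -> ProductPool:
    """Shared selection logic of rounds 2 and 3.

    ``bridge`` is SFP in round 2 (rewrites the PFP end into a BP end through
    one stem-primed copying event); in round 3 the BP end from round 2 is
    primed directly and no bridge is needed.
    """
    if pool.round != round_no - 1:
        raise RoundOrderError(
            f"round-{round_no} simulation needs a round-{round_no - 1} pool, "
            f"got round {pool.round}"
        )
    out = ProductPool(round=round_no)
    competing = [p for p in (bridge, bp, nsp) if p is not None]
    for amp in pool.amplicons:
        if amp.suppressed:
            continue  # hairpin-locked products leave the template set
        # panhandle suppression is checked before any priming
        if amp.right_primer is not None:
            suppressed, tir, best = _suppression(amp, competing, params)
            if suppressed:
                out.add(
                    replace(
                        amp, round=round_no, suppressed=True, abundance="linear",
                        note=f"suppressed: {tir}-nt terminal inverted repeat vs "
                        f"{best}-nt best primer match",
                    )
                )
                continue
        site = _nsp_site(amp.seq, nsp, params.high_model)
        if site is None or site.matched_run < len(nsp.seq):
            out.add(
                replace(
                    amp, round=round_no, category="carryover", abundance="linear",
                    note=f"diluted: no {nsp.name} site",
                )
            )
            continue
        nsp_start = site.three_prime_pos - len(nsp.seq) + 1
        if bridge is not None:
            # The walking-side end must expose the primary-round primer site
            # the bridge can stem-prime.  The bottom strand's 5' segment is
            # the reverse complement of the top strand's right end, so the
            # bridge's usable 3' match is its common suffix with that segment.
            if len(amp.seq) < len(bridge.seq) + len(nsp.seq):
                out.add(
                    replace(
                        amp, round=round_no, category="carryover", abundance="linear",
                        note="too short to carry both a walking end and an NSP site",
                    )
                )
                continue
            right_end = amp.seq[-len(bridge.seq):]
            stem_match = longest_common_suffix(bridge.seq, revcomp(right_end))
            if stem_match < params.high_model.min_three_prime_run:
                out.add(
                    replace(
                        amp, round=round_no, category="carryover", abundance="linear",
                        note=f"no {bridge.name} stem match on walking end",
                    )
                )
                continue
            # One bridging copy anchored at the site's 3' terminus rewrites
            # the whole walking-end primer copy into the bridge (stem + BP
            # branch); BP then amplifies from the new end.
            new_seq = amp.seq[nsp_start : len(amp.seq) - len(bridge.seq)] + revcomp(
                bridge.seq
            )
            note = (
                f"{bridge.name} bridged the walking end (stem match {stem_match} nt); "
                "convention: stem remnant + BP tail replace the walking-end primer copy"
            )
        else:
            right_end = amp.seq[-len(bp.seq):]
            if longest_common_suffix(bp.seq, revcomp(right_end)) < min(
                params.high_model.min_three_prime_run, len(bp.seq)
            ):
                out.add(
                    replace(
                        amp, round=round_no, category="carryover", abundance="linear",
                        note=f"no {bp.name} site on walking end",
                    )
                )
                continue
            new_seq = amp.seq[nsp_start:]
            note = f"{bp.name} primed the walking end directly"
        out.add(
            Amplicon(
                new_seq, nsp.name, bp.name, amp.category, "exponential",
                suppressed=False, round=round_no, insert_span=amp.insert_span,
                note=note,
            ),
            note=note,
        )
    return out


def simulate_secondary(
    pool: ProductPool, sfp: Oligo, bp: Oligo, mnsp: Oligo, params: SimParams | None = None
) -> ProductPool:
    """Round 2: SFP bridges, BP + mNSP amplify; category III is suppressed."""
    return _nested_round(pool, 2, mnsp, bp, params or SimParams(), bridge=sfp)


def simulate_tertiary(
    pool: ProductPool, bp: Oligo, insp: Oligo, params: SimParams | None = None
) -> ProductPool:
    """Round 3: BP + iNSP repeat the selection one nest inward."""
    return _nested_round(pool, 3, insp, bp, params or SimParams(), bridge=None)


@dataclass(frozen=True)
class GelReport:
    """Virtual agarose gel: per-round lanes of exponential band lengths."""

    lanes: dict[int, list[tuple[int, int]]]  # round -> [(length, multiplicity)]

    def lane(self, round_no: int) -> list[tuple[int, int]]:
        return self.lanes.get(round_no, [])

    def to_dict(self) -> dict:
        return {
            str(r): [{"length": l, "multiplicity": m} for l, m in bands]
            for r, bands in sorted(self.lanes.items())
        }

    def render(self) -> str:
        lines = ["virtual gel (exponential products only)"]
        labels = {1: "P", 2: "S", 3: "T"}
        for r in sorted(self.lanes):
            bands = ", ".join(
                f"{l} nt" + (f" (x{m})" if m > 1 else "") for l, m in self.lanes[r]
            ) or "(empty)"
            lines.append(f"lane {labels.get(r, r)} (round {r}): {bands}")
        return "\n".join(lines)


def virtual_gel(pools: list[ProductPool]) -> GelReport:
    """Band lengths per round, longest first; linear/suppressed products omitted."""
    if not pools:
        raise ValueError("virtual_gel needs at least one pool")
    lanes: dict[int, list[tuple[int, int]]] = {}
    for pool in pools:
        counts: dict[int, int] = {}
        for a in pool.exponential():
            counts[a.length] = counts.get(a.length, 0) + 1
        lanes[pool.round] = sorted(counts.items(), key=lambda x: -x[0])
    return GelReport(lanes)


@dataclass(frozen=True)
class WalkVerdict:
    ok: bool
    detail: str = ""

    def __bool__(self) -> bool:
        return self.ok


def verify_walk(amplicon: Amplicon, known_seq: str, min_anchor: int = 15) -> WalkVerdict:
    """In-silico analog of sequencing validation: the NSP-sided end of a
    walking product must match the known region exactly over the full overlap.

    The amplicon's leading ``min_anchor`` bases are located in the known
    sequence (either strand); the overlap from that point to the junction
    must then match base-for-base.
    """
    known = known_seq.upper()
    amp = amplicon.seq.upper()
    if len(amp) < min_anchor:
        return WalkVerdict(False, f"amplicon shorter than the {min_anchor}-nt anchor window")
    anchor = amp[:min_anchor]
    for strand_seq in (known, revcomp(known)):
        pos = strand_seq.find(anchor)
        if pos < 0:
            continue
        overlap = strand_seq[pos:]
        take = min(len(overlap), len(amp))
        if amp[:take] == overlap[:take]:
            return WalkVerdict(True, f"overlap of {take} nt matches the known region")
        return WalkVerdict(False, "NSP-sided end diverges from the known region")
    return WalkVerdict(False, "anchor not found in the known sequence")
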