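"""Core oligonucleotide types and deterministic string utilities.

Fork PCR walks from a known locus into unknown flanking DNA using a *fork
primer set* of three oligos: the primary fork primer (PFP) and secondary
fork primer (SFP) are 41-mers sharing a 3' *stem* of 21 nt, while their 5'
*branches* (20 nt) are unrelated; the branch primer (BP) is identical to
SFP's branch and is shared ("universal") across parallel fork sets.  Three
nested site-specific primers (oNSP, mNSP, iNSP) anchor the known side of
each of the three PCR rounds.

All sequences are stored 5'->3', uppercase, strict ACGT.  Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq

__all__ = [
    "Oligo",
    "ForkPrimerSet",
    "NSPSet",
    "RuleVerdict",
    "ValidationReport",
    "ValidationConstraints",
    "AlphabetError",
    "StructuralError",
    "revcomp",
    "longest_common_suffix",
    "longest_common_prefix",
    "longest_common_substring",
    "max_homopolymer_run",
    "validate_oligo",
    "decompose_fork",
]

ROLES = ("PFP", "SFP", "BP", "oNSP", "mNSP", "iNSP", "generic")

#: stem / branch geometry of a fork primer set (nt)
STEM_LEN = 21
BRANCH_LEN = 20
FORK_PRIMER_LEN = STEM_LEN + BRANCH_LEN

_ACGT = re.compile(r"^[ACGT]+$")


class AlphabetError(ValueError):
    """Sequence contains characters outside the strict A/C/G/T alphabet."""


class StructuralError(ValueError):
    """A fork-set or NSP-set invariant is violated."""


def _clean(seq: str) -> str:
    """Normalize to uppercase and verify strict ACGT (U and IUPAC codes rejected)."""
    s = seq.strip().upper()
    if not s:
        raise AlphabetError("empty sequence")
    if not _ACGT.fullmatch(s):
        bad = sorted(set(s) - set("ACGT"))
        raise AlphabetError(f"non-ACGT character(s) {bad} in {s[:30]!r}...")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return str(Seq(_clean(seq)).reverse_complement())


def longest_common_suffix(a: str, b: str) -> int:
    """Length of the maximal identical 3'-terminal run of two sequences."""
    k = 0
    n = min(len(a), len(b))
    while k < n and a[-1 - k] == b[-1 - k]:
        k += 1
    return k


def longest_common_prefix(a: str, b: str) -> int:
    """Length of the maximal identical 5'-terminal run of two sequences."""
    k = 0
    n = min(len(a), len(b))
    while k < n and a[k] == b[k]:
        k += 1
    return k


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest substring shared by a and b (classic DP)."""
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b):
            if ca == cb:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best:
                    best = cur[j + 1]
        prev = cur
    return best


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of one base (design rule: runs of 4+ are rejected)."""
    s = _clean(seq)
    return max(len(m.group()) for m in re.finditer(r"(.)\1*", s))


@dataclass(frozen=True)
class Oligo:
    """A named 5'->3' DNA primer with a fork PCR role."""

    name: str
    seq: str
    role: str = "generic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _clean(self.seq))
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if len(self.seq) > 64:
            raise ValueError(f"{self.name}: length {len(self.seq)} exceeds 64 nt sanity bound")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ForkPrimerSet:
    """PFP + SFP + universal BP with their stem/branch decomposition.

    Invariants: |PFP| = |SFP| = 41; PFP = pfp_branch (20) + stem (21);
    SFP = BP (20) + stem; branches mutually heterologous.
    """

    pfp: Oligo
    sfp: Oligo
    bp: Oligo
    stem: str
    pfp_branch: str
    set_id: str = "fork"

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.pfp, self.sfp, self.bp)


@dataclass(frozen=True)
class NSPSet:
    """Three nested site-specific primers with coordinates on the known sequence.

    ``coords[role] = (start, end)`` is 0-based half-open on the known sequence;
    ``walk_end`` ('left' or 'right') names the end of the known sequence that
    abuts the unknown flank.  iNSP lies closest to that junction.
    """

    onsp: Oligo
    mnsp: Oligo
    insp: Oligo
    coords: dict[str, tuple[int, int]] = field(default_factory=dict)
    walk_end: str = "right"

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.onsp, self.mnsp, self.insp)


@dataclass(frozen=True)
class RuleVerdict:
    rule: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    """Per-oligo design-rule verdicts; every rule appears exactly once."""

    name: str
    verdicts: tuple[RuleVerdict, ...]

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def failed_rules(self) -> list[str]:
        return [v.rule for v in self.verdicts if not v.passed]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "passed": self.passed,
            "verdicts": [
                {"rule": v.rule, "passed": v.passed, "detail": v.detail}
                for v in self.verdicts
            ],
        }


# role -> (min_len, max_len).  NSP window reflects observed lengths 21-32.
_ROLE_LENGTHS: dict[str, tuple[int, int]] = {
    "PFP": (FORK_PRIMER_LEN, FORK_PRIMER_LEN),
    "SFP": (FORK_PRIMER_LEN, FORK_PRIMER_LEN),
    "BP": (BRANCH_LEN, BRANCH_LEN),
    "oNSP": (20, 32),
    "mNSP": (20, 32),
    "iNSP": (20, 32),
    "generic": (8, 64),
}


@dataclass(frozen=True)
class ValidationConstraints:
    """Tunable design-rule thresholds.

    ``balance`` is the allowed per-base frequency window operationalizing
    "the four bases should be evenly distributed"; the default is the
    tightest window the bundled reference fork/NSP primers all satisfy.
    """

    max_run: int = 3
    balance: tuple[float, float] = (0.05, 0.50)
    role_lengths: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_ROLE_LENGTHS)
    )


def validate_oligo(
    oligo: Oligo, constraints: ValidationConstraints | None = None
) -> ValidationReport:
    """Apply every primer design rule to one oligo and report each verdict.

    Rules: strict ACGT alphabet; homopolymer runs shorter than 4 (i.e. at most
    ``max_run``); per-base frequency inside the balance window; length within
    the window for the oligo's role.
    """
    c = constraints or ValidationConstraints()
    if oligo.role not in c.role_lengths:
        raise ValueError(f"no length window configured for role {oligo.role!r}")
    verdicts: list[RuleVerdict] = []

    verdicts.append(RuleVerdict("alphabet", _ACGT.fullmatch(oligo.seq) is not None))

    run = max_homopolymer_run(oligo.seq)
    verdicts.append(
        RuleVerdict(
            "run_length",
            run <= c.max_run,
            f"longest homopolymer run {run} (max {c.max_run})",
        )
    )

    lo, hi = c.balance
    freqs = {b: oligo.seq.count(b) / len(oligo.seq) for b in "ACGT"}
    bad = {b: round(f, 3) for b, f in freqs.items() if not lo <= f <= hi}
    verdicts.append(
        RuleVerdict(
            "base_balance",
            not bad,
            f"frequencies outside [{lo}, {hi}]: {bad}" if bad else "balanced",
        )
    )

    nmin, nmax = c.role_lengths[oligo.role]
    verdicts.append(
        RuleVerdict(
            "length",
            nmin <= len(oligo) <= nmax,
            f"length {len(oligo)} for role {oligo.role} (window [{nmin}, {nmax}])",
        )
    )
    return ValidationReport(oligo.name, tuple(verdicts))


#: longest substring shared by the two branches before they count as homologous
HETEROLOGY_CAP = 10


def decompose_fork(
    pfp: Oligo, sfp: Oligo, bp: Oligo, set_id: str = "fork"
) -> ForkPrimerSet:
    """Decompose three oligos into a fork primer set, verifying every invariant.

    The designed decomposition is authoritative: stem := sfp[20:41] and
    pfp_branch := pfp[0:20].  The literal 3' identity between PFP and SFP may
    exceed 21 nt when branch-terminal bases coincide by chance, hence the
    >= 21 check rather than equality.
    """
    def fail(why: str) -> StructuralError:
        return StructuralError(f"fork set {set_id!r}: {why}")

    if len(pfp) != FORK_PRIMER_LEN or len(sfp) != FORK_PRIMER_LEN:
        raise fail(
            f"PFP/SFP must be {FORK_PRIMER_LEN} nt (got {len(pfp)}, {len(sfp)})"
        )
    if len(bp) != BRANCH_LEN:
        raise fail(f"BP must be {BRANCH_LEN} nt (got {len(bp)})")

    stem = sfp.seq[BRANCH_LEN:]
    pfp_branch = pfp.seq[:BRANCH_LEN]

    if pfp.seq != pfp_branch + stem:
        raise fail("PFP stem differs from SFP stem (pfp != pfp_branch + stem)")
    if sfp.seq != bp.seq + stem:
        raise fail("SFP branch differs from BP (sfp != bp + stem)")
    if longest_common_suffix(pfp.seq, sfp.seq) < STEM_LEN:
        raise fail(f"3' identity between PFP and SFP shorter than {STEM_LEN} nt")
    if longest_common_prefix(bp.seq, sfp.seq) != BRANCH_LEN:
        raise fail(f"BP is not the {BRANCH_LEN}-nt 5' branch of SFP")
    shared = longest_common_substring(pfp_branch, bp.seq)
    if shared > HETEROLOGY_CAP:
        raise fail(
            f"branches share a {shared}-nt substring (> {HETEROLOGY_CAP}); "
            "branches must be heterologous"
        )
    return ForkPrimerSet(pfp, sfp, bp, stem=stem, pfp_branch=pfp_branch, set_id=set_id)


def build_nsp_set(
    known_seq: str,
    coords: dict[str, tuple[int, int]],
    walk_end: str = "right",
    name_prefix: str = "nsp",
) -> NSPSet:
    """Construct an NSPSet from coordinates on the known sequence, checking nesting.

    Primers are taken from the strand pointing toward the unknown flank:
    the given (top) strand for ``walk_end='right'``, its reverse complement
    for ``walk_end='left'``.  Coordinates are always on the given sequence.
    """
    if walk_end not in ("left", "right"):
        raise ValueError("walk_end must be 'left' or 'right'")
    seq = _clean(known_seq)
    oligos = {}
    for role in ("oNSP", "mNSP", "iNSP"):
        s, e = coords[role]
        if not (0 <= s < e <= len(seq)):
            raise StructuralError(f"{role} coordinates [{s}, {e}) outside known sequence")
        sub = seq[s:e]
        oligos[role] = Oligo(f"{name_prefix}_{role}", sub if walk_end == "right" else revcomp(sub), role)
    order = [coords["oNSP"], coords["mNSP"], coords["iNSP"]]
    if walk_end == "left":
        order = [(-e, -s) for s, e in order]
    # successive primers approach the unknown junction without overlapping
    for (s0, e0), (s1, e1) in zip(order, order[1:]):
        if s1 < e0:
            raise StructuralError("NSPs must not overlap and must nest toward the junction")
    return NSPSet(oligos["oNSP"], oligos["mNSP"], oligos["iNSP"], dict(coords), walk_end)
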