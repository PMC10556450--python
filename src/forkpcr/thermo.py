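"""Melting temperature and secondary-structure screens.

Tm is nearest-neighbor (SantaLucia 2004 unified parameters) with the
Owczarzy divalent-cation correction, computed by Biopython's MeltingTemp
engine under reaction conditions matching the walking recipe (50 mM
monovalent, 2.5 mM Mg2+, 1.6 mM total dNTP, 0.2 uM primer).  Design
windows carry a +/-3 degC method tolerance because vendor Tm calculators
differ systematically.

Structure screens are combinatorial, not free-energy folding: a hairpin or
dimer hit is a maximal Watson-Crick-pairable window.  That is sufficient
for the rule-based design thresholds and for the length-threshold
suppression logic (a product whose terminal inverted repeat exceeds ~40 nt
snaps into a hairpin faster than any primer can anneal to it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from Bio.SeqUtils import MeltingTemp as _mt

from .oligos import revcomp

__all__ = [
    "ThermoConditions",
    "StructureHit",
    "StructureThresholds",
    "melt_temp",
    "hairpin_scan",
    "dimer_scan",
    "terminal_inverted_repeat",
    "severe_hits",
]

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ThermoConditions:
    """Ionic and primer concentrations used in the Tm calculation."""

    monovalent_mM: float = 50.0
    mg_mM: float = 2.5
    dntp_mM: float = 1.6  # 4 x 0.4 mM
    primer_uM: float = 0.2

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "mg_mM", "dntp_mM", "primer_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_CONDITIONS = ThermoConditions()


def melt_temp(seq: str, conditions: ThermoConditions | None = None) -> float:
    """Nearest-neighbor Tm (degC), deterministic to 0.01 degC.

    Valid for 8-64 nt oligos; shorter/longer sequences are outside the NN
    model's sensible range and raise ``ValueError``.
    """
    c = conditions or DEFAULT_CONDITIONS
    n = len(seq)
    if not 8 <= n <= 64:
        raise ValueError(f"melt_temp requires 8 <= length <= 64, got {n}")
    tm = _mt.Tm_NN(
        seq.upper(),
        nn_table=_mt.DNA_NN4,
        Na=c.monovalent_mM,
        Mg=c.mg_mM,
        dNTPs=c.dntp_mM,
        dnac1=c.primer_uM * 1000.0,  # nM
        dnac2=0,
        saltcorr=7,
    )
    return round(tm, 2)


@dataclass(frozen=True)
class StructureHit:
    """One maximal pairable window (hairpin stem or duplex)."""

    kind: str  # hairpin | self-dimer | cross-dimer | terminal-inverted-repeat
    stem: int  # paired length (bp)
    loop: int = 0  # hairpin only
    three_prime_anchored: bool = False
    positions: tuple[int, ...] = ()  # (i, j) 5' starts of the paired windows

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "stem": self.stem,
            "loop": self.loop,
            "three_prime_anchored": self.three_prime_anchored,
            "positions": list(self.positions),
        }


def _pairs(a: str, b: str) -> bool:
    return _COMP[a] == b


def hairpin_scan(seq: str, min_loop: int = 3) -> list[StructureHit]:
    """All maximal self-complementary stems with loop >= min_loop, longest first.

    A stem of length k pairs seq[i:i+k] with the reverse complement of
    seq[j-k+1:j+1]; the loop is the unpaired stretch between them.  A hit is
    maximal when the stem can be extended neither outward nor inward.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    s = seq.upper()
    n = len(s)
    hits: list[StructureHit] = []
    for i in range(n):
        for j in range(n - 1, i, -1):
            if not _pairs(s[i], s[j]):
                continue
            # outward-maximal start: previous outer pair must not exist
            if i > 0 and j < n - 1 and _pairs(s[i - 1], s[j + 1]):
                continue
            k = 1
            while (
                i + k < j - k
                and _pairs(s[i + k], s[j - k])
                and (j - k) - (i + k) - 1 >= min_loop
            ):
                k += 1
            loop = j - i - 2 * k + 1
            if loop >= min_loop:
                hits.append(
                    StructureHit("hairpin", stem=k, loop=loop, positions=(i, j - k + 1))
                )
    hits.sort(key=lambda h: (-h.stem, h.positions))
    return hits


def dimer_scan(a: str, b: str) -> list[StructureHit]:
    """Maximal complementary duplex windows between two primers.

    ``a[i:i+k]`` pairs antiparallel with ``b[j:j+k]`` when it equals the
    reverse complement of that window.  A hit is 3'-anchored when the duplex
    covers the 3' terminus of either primer — the configuration that seeds
    polymerase extension and therefore the one the design rules punish.
    Self-dimers are reported when both sequences are identical.
    """
    A, B = a.upper(), b.upper()
    kind = "self-dimer" if A == B else "cross-dimer"
    la, lb = len(A), len(B)
    rcB = revcomp(B)
    hits: list[StructureHit] = []
    # window of A at i aligned with window of rcB at p corresponds to
    # b-window start j = lb - (p + k)
    for i in range(la):
        for p in range(lb):
            if A[i] != rcB[p]:
                continue
            if i > 0 and p > 0 and A[i - 1] == rcB[p - 1]:
                continue  # not maximal
            k = 1
            while i + k < la and p + k < lb and A[i + k] == rcB[p + k]:
                k += 1
            j = lb - (p + k)
            if kind == "self-dimer" and i > j:
                continue  # symmetric duplicate
            anchored = (i + k == la) or (j + k == lb)
            hits.append(
                StructureHit(kind, stem=k, three_prime_anchored=anchored, positions=(i, j))
            )
    hits.sort(key=lambda h: (-h.stem, h.positions))
    return hits


def terminal_inverted_repeat(seq: str) -> int:
    """Largest k with seq[:k] equal to the reverse complement of seq[-k:].

    A single strand whose ends form a long inverted repeat folds into a
    panhandle hairpin; products with repeats > 40 nt are suppressed because
    the fold outcompetes primer annealing.
    """
    s = seq.upper()
    if len(s) < 2:
        raise ValueError("terminal_inverted_repeat requires length >= 2")
    rc = revcomp(s)
    # seq[:k] == revcomp(seq[-k:]) is exactly rc[:k] reversed... compare directly
    best = 0
    for k in range(1, len(s) + 1):
        if s[:k] == rc[:k]:
            best = k
    return best


@dataclass(frozen=True)
class StructureThresholds:
    """Design-time rejection thresholds for "severe" structure.

    A candidate is rejected when a hairpin stem reaches ``hairpin_stem``, a
    3'-anchored duplex reaches ``anchored_stem``, or any duplex reaches
    ``internal_stem``.  Conventional primer-design practice; tunable.
    """

    hairpin_stem: int = 5
    anchored_stem: int = 4
    internal_stem: int = 8
    min_loop: int = 3


def severe_hits(
    a: str, b: str | None = None, thresholds: StructureThresholds | None = None
) -> list[StructureHit]:
    """Severe hairpin/dimer hits for one primer (b=None) or a primer pair."""
    t = thresholds or StructureThresholds()
    out: list[StructureHit] = []
    if b is None:
        out += [h for h in hairpin_scan(a, t.min_loop) if h.stem >= t.hairpin_stem]
        b = a
    for h in dimer_scan(a, b):
        if h.stem >= t.internal_stem or (h.three_prime_anchored and h.stem >= t.anchored_stem):
            out.append(h)
    return out
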