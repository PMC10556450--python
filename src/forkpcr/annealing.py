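"""Primer binding-site discovery and single-strand extension.

Fork PCR alternates two annealing regimes.  The low-stringency cycle
(25 degC) lets the primary fork primer land on partially matched sites all
over the genome; the high-stringency cycles (65 degC) only accept sites
with a long exact 3' match.  Both regimes are modelled as rule thresholds
on the primer's 3'-terminal alignment: a minimum exact 3' run plus a
minimum identity over the 3'-terminal window.  The defaults separate the
designed matches (full NSPs >= 20 nt, the 21-nt stem priming a PFP site,
the 20-nt BP priming an SFP site) from anything shorter.

Strand convention: a '+' site means the primer reads as the top strand
(it anneals to the bottom strand and extension proceeds toward higher top
coordinates); a '-' site reads as the bottom strand and extends toward
lower top coordinates.  Site coordinates give the template base paired
with the primer's 3' terminus (0-based, top strand).
"""

from __future__ import annotations

from dataclasses import dataclass

from .oligos import revcomp

__all__ = [
    "StringencyModel",
    "LOW_STRINGENCY",
    "HIGH_STRINGENCY",
    "BindingSite",
    "find_binding_sites",
    "extend_product",
]


@dataclass(frozen=True)
class StringencyModel:
    """Annealing acceptance rule for one regime.

    A primer binds at a position when its 3'-terminal ``min_three_prime_run``
    bases match the template exactly and the identity over the 3'-terminal
    ``window`` bases is at least ``min_identity``.
    """

    regime: str  # "low" | "high"
    min_three_prime_run: int
    min_identity: float = 0.6
    window: int = 21

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_three_prime_run < 1 or self.window < 1:
            raise ValueError("run and window must be positive")


#: 25 degC cycle: partial annealing that seeds the walk
LOW_STRINGENCY = StringencyModel("low", min_three_prime_run=7)
#: 65 degC cycles: designed 3' matches only
HIGH_STRINGENCY = StringencyModel("high", min_three_prime_run=18)


@dataclass(frozen=True)
class BindingSite:
    """One primer/template annealing event."""

    template_id: str
    strand: str  # '+' or '-'
    three_prime_pos: int  # top-strand coordinate paired with the primer's 3' base
    matched_run: int
    identity: float
    regime: str
    primer: str = ""  # primer name

    def satisfies(self, model: StringencyModel) -> bool:
        return (
            self.matched_run >= model.min_three_prime_run
            and self.identity >= model.min_identity
        )


def _scan_plus(
    template: str, primer: str, model: StringencyModel, template_id: str, name: str
) -> list[BindingSite]:
    """Sites where the primer reads as the template top strand."""
    lp = len(primer)
    seed = primer[-model.min_three_prime_run :]
    w = min(model.window, lp)
    sites = []
    start = 0
    while True:
        hit = template.find(seed, start)
        if hit < 0:
            break
        start = hit + 1
        e = hit + len(seed) - 1  # 3'-terminus coordinate
        if e - w + 1 < 0:
            continue  # window runs off the template
        # extend the exact run 5'-ward
        run = len(seed)
        while run < lp and e - run >= 0 and primer[-1 - run] == template[e - run]:
            run += 1
        ident = sum(
            primer[-1 - t] == template[e - t] for t in range(w)
        ) / w
        if run >= model.min_three_prime_run and ident >= model.min_identity:
            sites.append(
                BindingSite(template_id, "+", e, run, round(ident, 4), model.regime, name)
            )
    return sites


def find_binding_sites(
    template: str,
    primer: str,
    model: StringencyModel,
    template_id: str = "template",
    primer_name: str = "",
) -> list[BindingSite]:
    """All sites on both strands satisfying the regime, sorted by coordinate.

    Exhaustive: every position whose 3'-terminal seed matches exactly is
    examined, which is equivalent to a position-by-position scan because the
    regime itself requires that exact seed.
    """
    t = template.upper()
    p = primer.upper()
    w = min(model.window, len(p))
    if len(t) < w:
        raise ValueError("template shorter than the primer's 3' window")
    name = primer_name
    sites = list(_scan_plus(t, p, model, template_id, name))
    L = len(t)
    for s in _scan_plus(revcomp(t), p, model, template_id, name):
        sites.append(
            BindingSite(
                template_id, "-", L - 1 - s.three_prime_pos, s.matched_run,
                s.identity, s.regime, name,
            )
        )
    sites.sort(key=lambda s: (s.three_prime_pos, s.strand))
    return sites


def extend_product(
    template: str, site: BindingSite, primer: str, max_len: int = 5000
) -> str:
    """Polymerase extension of a primer from a binding site, 5'->3'.

    The full primer — including any unhybridized 5' tail — is incorporated,
    then the template is copied from the site's 3' end onward (toward the
    template strand's 5' end), truncating the product at ``max_len`` total.
    Tail incorporation is what turns a partial site into a perfect primer
    site for the next round.
    """
    t = template.upper()
    p = primer.upper()
    e = site.three_prime_pos
    if not 0 <= e < len(t):
        raise IndexError(f"site 3' coordinate {e} outside template of length {len(t)}")
    room = max(0, max_len - len(p))
    if site.strand == "+":
        ext = t[e + 1 : e + 1 + room]
    else:
        ext = revcomp(t[max(0, e - room) : e])
    return (p + ext)[:max_len]
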