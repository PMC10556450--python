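"""Seeded synthetic walking fixtures with closed-form truth metadata.

A fixture is a random genome carrying (1) a known locus whose top strand
contains the three nested NSP sites walking rightward, (2) a partial
reverse-strand PFP site planted ``walk_distance`` beyond the known/unknown
junction that satisfies the low- but not the high-stringency annealing
model, and (3) optional decoy site pairs that force one product of each
requested unwanted category (I: oNSP alone, II: oNSP + PFP off-target,
III: PFP alone).

The truth metadata enumerates, by coordinate arithmetic alone, every
product the three simulated rounds must emit, so it fully determines the
simulator's output.  To make that guarantee hold, the generator *scrubs*
the random background: it re-scans the genome with every primer and
mutates the 3'-seed of any annealing site it did not plant.

Everything is deterministic in the seed; regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annealing import HIGH_STRINGENCY, LOW_STRINGENCY, find_binding_sites
from .oligos import ForkPrimerSet, NSPSet, Oligo, build_nsp_set
from .reference_primers import FORK1

__all__ = ["Fixture", "FixtureError", "PlantedSite", "make_fixture"]

_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: nt of exact 3' match in a planted partial site (low passes at 7, high needs 18)
PARTIAL_RUN = 10
#: additional matched positions inside the 21-nt identity window
PARTIAL_EXTRA = 6

#: interior spacing (nt between the paired 3' ends) of each decoy category
_DECOY_GAPS = {"I": 200, "II": 250, "III": 300}


class FixtureError(ValueError):
    """Requested plants collide spatially or cannot be made clean."""


@dataclass(frozen=True)
class PlantedSite:
    primer: str
    strand: str  # '+' or '-'
    three_prime_pos: int
    matched_run: int
    length: int

    @property
    def span(self) -> tuple[int, int]:
        e = self.three_prime_pos
        if self.strand == "+":
            return (e - self.length + 1, e + 1)
        return (e, e + self.length)


@dataclass(frozen=True)
class ExpectedAmplicon:
    category: str
    length: int
    left_primer: str
    right_primer: str


@dataclass
class Fixture:
    genome: str
    known_seq: str
    fork: ForkPrimerSet
    nsp: NSPSet
    seed: int
    walk_distance: int
    locus_span: tuple[int, int]
    junction: int
    planted: list[PlantedSite]
    expected_round1: list[ExpectedAmplicon]
    expected_secondary_len: int | None
    expected_tertiary_len: int | None
    genome_id: str = "fixture"

    def genome_records(self) -> dict[str, str]:
        return {self.genome_id: self.genome}


def _partial_patch(
    primer: str, run: int, extra: int, window: int, rng: np.random.Generator
) -> list[str]:
    """Template bases (5'->3' along the primer, index 0 = the 3'-pairing base)
    for a partial site: exact ``run``, a forced mismatch capping it, ``extra``
    scattered matches inside the identity window, mismatches elsewhere."""
    lp = len(primer)
    w = min(window, lp)
    extra_pos = set(rng.choice(np.arange(run + 1, w), size=extra, replace=False).tolist())
    out = []
    for t in range(lp):
        want = _COMP[primer[-1 - t]]  # template base that would pair
        if t < run or t in extra_pos:
            out.append(want)
        else:
            alts = [b for b in _BASES if b != want]
            out.append(alts[int(rng.integers(0, 3))])
    return out


def _write_site(
    genome: list[str], site: PlantedSite, patch: list[str]
) -> None:
    """patch[t] is the template base paired with primer[-1-t]."""
    e = site.three_prime_pos
    for t, base in enumerate(patch):
        pos = e + t if site.strand == "-" else e - t
        genome[pos] = base if site.strand == "-" else _COMP[base]


def make_fixture(
    genome_len: int,
    walk_distance: int,
    categories_to_plant: tuple[str, ...] = ("target",),
    fork_set: ForkPrimerSet | None = None,
    nsp_source: str | None = None,
    seed: int = 0,
    max_amplicon_len: int = 5000,
) -> Fixture:
    """Build a seeded fixture genome with planted sites and truth metadata.

    ``nsp_source`` optionally supplies the known locus sequence (>= 150 nt);
    by default a random 300-nt locus is generated.  NSP windows sit at fixed
    offsets 0/40/80 (25-mers) so the nesting offsets — and therefore the
    expected secondary and tertiary band lengths — are closed-form.
    """
    if genome_len < walk_distance + 1000:
        raise FixtureError("genome_len must be >= walk_distance + 1000")
    for cat in categories_to_plant:
        if cat not in ("target", "I", "II", "III"):
            raise FixtureError(f"unknown category {cat!r}")
    fork = fork_set or FORK1
    rng = np.random.default_rng(seed)

    for attempt in range(20):
        fx = _build_once(
            genome_len, walk_distance, tuple(categories_to_plant), fork,
            nsp_source, seed, rng, max_amplicon_len,
        )
        if fx is not None:
            return fx
    raise FixtureError(
        "could not scrub the genome background after 20 attempts; "
        "plants likely collide with required clean regions"
    )


def _build_once(
    genome_len, walk_distance, categories, fork, nsp_source, seed, rng, max_len
) -> Fixture | None:
    pfp, onsp_len = fork.pfp, 25
    known = (
        nsp_source.upper()
        if nsp_source is not None
        else "".join(_BASES[i] for i in rng.integers(0, 4, 300))
    )
    if len(known) < 150:
        raise FixtureError("known locus must be >= 150 nt")
    coords = {"oNSP": (0, 25), "mNSP": (40, 65), "iNSP": (80, 105)}

    planted: list[PlantedSite] = []
    patches: list[tuple[PlantedSite, list[str]]] = []

    # --- decoy zone (left of the locus) ---
    b = 60
    decoys: list[tuple[str, PlantedSite, PlantedSite]] = []
    for cat in ("I", "II", "III"):
        if cat not in categories:
            continue
        gap = _DECOY_GAPS[cat]
        len1 = 41 if cat == "III" else 25
        len2 = 25 if cat == "I" else 41
        e_l = b + len1 - 1
        e_r = e_l + gap
        name1 = fork.pfp.name if cat == "III" else "oNSP"
        name2 = "oNSP" if cat == "I" else fork.pfp.name
        s_plus = PlantedSite(name1, "+", e_l, PARTIAL_RUN, len1)
        s_minus = PlantedSite(name2, "-", e_r, PARTIAL_RUN, len2)
        decoys.append((cat, s_plus, s_minus))
        planted += [s_plus, s_minus]
        b = e_r + len2 + 43

    g0 = max(200, b + 60)
    K = len(known)
    junction = g0 + K
    e_p = junction + walk_distance

    if "target" in categories:
        target_site = PlantedSite(pfp.name, "-", e_p, PARTIAL_RUN, 41)
        planted.append(target_site)
        need = e_p + 41 + 50
    else:
        target_site = None
        need = junction + 50
    if need > genome_len:
        raise FixtureError(
            f"genome_len {genome_len} too small for the requested layout "
            f"(needs >= {need})"
        )

    # locus oNSP site is a designed full-length match
    onsp_site = PlantedSite("oNSP", "+", g0 + coords["oNSP"][1] - 1, 25, 25)

    genome = list("".join(_BASES[i] for i in rng.integers(0, 4, genome_len)))
    genome[g0 : g0 + K] = list(known)

    nsp = build_nsp_set(known, coords, "right", "fix")
    primer_seqs = {
        fork.pfp.name: fork.pfp.seq,
        "oNSP": nsp.onsp.seq,
        "mNSP": nsp.mnsp.seq,
        "iNSP": nsp.insp.seq,
    }

    for site in planted:
        patch = _partial_patch(
            primer_seqs[site.primer], PARTIAL_RUN, PARTIAL_EXTRA,
            LOW_STRINGENCY.window, rng,
        )
        patches.append((site, patch))

    # spatial collision check among plants and the locus
    spans = [s.span for s in planted] + [(g0, g0 + K)]
    spans.sort()
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0:
            raise FixtureError(f"planted regions collide: [{s0},{e0}) and [{s1},{e1})")

    for site, patch in patches:
        _write_site(genome, site, patch)

    # --- scrub unplanned background sites ---
    reserved: list[tuple[int, int]] = [s.span for s in planted]
    reserved += [(g0 + s, g0 + e) for s, e in coords.values()]
    planned_keys = {(s.primer, s.strand, s.three_prime_pos) for s in planted}
    planned_keys.add(("oNSP", "+", onsp_site.three_prime_pos))
    planned_keys.add(("mNSP", "+", g0 + coords["mNSP"][1] - 1))
    planned_keys.add(("iNSP", "+", g0 + coords["iNSP"][1] - 1))

    def in_reserved(pos: int) -> bool:
        return any(s <= pos < e for s, e in reserved)

    for _ in range(60):
        text = "".join(genome)
        spurious = []
        for name, model in (
            (fork.pfp.name, LOW_STRINGENCY),
            ("oNSP", LOW_STRINGENCY),
            ("mNSP", HIGH_STRINGENCY),
            ("iNSP", HIGH_STRINGENCY),
        ):
            for s in find_binding_sites(text, primer_seqs[name], model, "g", name):
                if (name, s.strand, s.three_prime_pos) not in planned_keys:
                    spurious.append(s)
        if not spurious:
            break
        for s in spurious:
            pos = s.three_prime_pos
            if in_reserved(pos):
                return None  # cannot scrub without damaging a plant; retry
            cur = genome[pos]
            repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
            genome[pos] = repl
    else:
        return None

    text = "".join(genome)
    known_final = text[g0 : g0 + K]
    nsp = build_nsp_set(known_final, coords, "right", "fix")

    # --- closed-form expected products ---
    def classify(a: PlantedSite, bsite: PlantedSite) -> str:
        ka = "onsp" if a.primer == "oNSP" else "pfp"
        kb = "onsp" if bsite.primer == "oNSP" else "pfp"
        if ka == kb == "onsp":
            return "I"
        if ka == kb == "pfp":
            return "III"
        nsp_site = a if ka == "onsp" else bsite
        return "target" if nsp_site.matched_run >= 25 else "II"

    all_sites = planted + [onsp_site]
    names = {"oNSP": nsp.onsp.name, "mNSP": nsp.mnsp.name, "iNSP": nsp.insp.name,
             fork.pfp.name: fork.pfp.name}
    expected: list[ExpectedAmplicon] = []
    for a in [s for s in all_sites if s.strand == "+"]:
        for m in [s for s in all_sites if s.strand == "-"]:
            if m.three_prime_pos <= a.three_prime_pos:
                continue
            L = a.length + m.length + m.three_prime_pos - a.three_prime_pos - 1
            if L > max_len:
                continue
            cat = classify(a, m)
            left = a.primer if cat in ("I", "III") or a.primer == "oNSP" else m.primer
            right = m.primer if left == a.primer else a.primer
            expected.append(ExpectedAmplicon(cat, L, names[left], names[right]))

    l2 = l3 = None
    if target_site is not None:
        # the planted-walk product: oNSP end at the locus, PFP end at e_p
        L1 = onsp_site.length + (e_p - onsp_site.three_prime_pos - 1) + 41
        l2 = L1 - (coords["mNSP"][0] - coords["oNSP"][0])
        l3 = l2 - (coords["iNSP"][0] - coords["mNSP"][0])

    return Fixture(
        genome=text,
        known_seq=known_final,
        fork=fork,
        nsp=nsp,
        seed=seed,
        walk_distance=walk_distance,
        locus_span=(g0, g0 + K),
        junction=junction,
        planted=planted + [onsp_site],
        expected_round1=expected,
        expected_secondary_len=l2,
        expected_tertiary_len=l3,
    )
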