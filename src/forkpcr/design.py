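"""De-novo design of fork primer sets and selection of NSP triples.

Fork primers are random oligomers: candidate stems and branches are drawn
by rejection sampling and kept only when they clear every design rule —
base alphabet/balance, homopolymer runs, Tm windows, structure screens,
and branch heterology against the universal BP.  A per-rule rejection
counter makes an unsatisfiable constraint set fail loudly, naming the rule
that exhausted the candidate budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annealing import HIGH_STRINGENCY
from .oligos import (
    BRANCH_LEN,
    STEM_LEN,
    ForkPrimerSet,
    NSPSet,
    Oligo,
    RuleVerdict,
    ValidationConstraints,
    ValidationReport,
    build_nsp_set,
    decompose_fork,
    longest_common_substring,
    longest_common_suffix,
    revcomp,
    validate_oligo,
)
from .thermo import (
    StructureThresholds,
    ThermoConditions,
    melt_temp,
    severe_hits,
)

__all__ = [
    "DesignConstraints",
    "DesignError",
    "design_fork_sets",
    "select_nsp_set",
    "check_compatibility",
]


class DesignError(RuntimeError):
    """Constraint set exhausted the candidate budget."""


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable design constraints with the method's standard defaults."""

    stem_len: int = STEM_LEN
    branch_len: int = BRANCH_LEN
    stem_tm: tuple[float, float] = (60.0, 65.0)
    full_tm: tuple[float, float] = (71.0, 79.0)
    nsp_tm: tuple[float, float] = (60.0, 65.0)
    nsp_len: tuple[int, int] = (20, 32)
    max_run: int = 3
    balance: tuple[float, float] = (0.10, 0.40)
    heterology_cap: int = 10  # longest substring shared by two branches
    bp_suffix_cap: int = 10  # 3' identity allowed between a stem and BP
    structure: StructureThresholds = field(default_factory=StructureThresholds)
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    candidate_budget: int = 100_000

    def __post_init__(self) -> None:
        for w in (self.stem_tm, self.full_tm, self.nsp_tm, self.nsp_len, self.balance):
            if w[0] > w[1]:
                raise ValueError(f"empty window {w}")
        if self.stem_len <= 0 or self.branch_len <= 0:
            raise ValueError("lengths must be positive")


def _validation_constraints(c: DesignConstraints) -> ValidationConstraints:
    return ValidationConstraints(max_run=c.max_run, balance=c.balance)


class _Budget:
    """Per-rule rejection accounting over one design call."""

    def __init__(self, total: int) -> None:
        self.total = total
        self.spent = 0
        self.rejections: dict[str, int] = {}

    def charge(self, rule: str | None) -> None:
        self.spent += 1
        if rule is not None:
            self.rejections[rule] = self.rejections.get(rule, 0) + 1
        if self.spent >= self.total:
            worst = max(self.rejections, key=self.rejections.get, default="(none)")
            raise DesignError(
                f"candidate budget of {self.total} exhausted; most rejections "
                f"from rule {worst!r}: {dict(sorted(self.rejections.items()))}"
            )


def _random_mer(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _rule_failure(
    seq: str, role: str, tm_window: tuple[float, float], c: DesignConstraints
) -> str | None:
    """First design rule the candidate violates, or None if it is clean."""
    rep = validate_oligo(Oligo("cand", seq, role), _validation_constraints(c))
    fails = rep.failed_rules()
    if fails:
        return fails[0]
    tm = melt_temp(seq, c.conditions)
    if not tm_window[0] <= tm <= tm_window[1]:
        return "tm_window"
    if severe_hits(seq, thresholds=c.structure):
        return "structure"
    return None


def design_fork_sets(
    n_sets: int,
    constraints: DesignConstraints | None = None,
    seed: int = 0,
) -> list[ForkPrimerSet]:
    """Design ``n_sets`` fork primer sets sharing one universal BP.

    Deterministic for a given seed.  Each emitted set passes
    :func:`decompose_fork` and every per-oligo rule; stems differ pairwise
    across sets so parallel walks are independent.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    c = constraints or DesignConstraints()
    rng = np.random.default_rng(seed)
    budget = _Budget(c.candidate_budget)

    def draw(n: int, role: str, tm_window, extra=None) -> str:
        while True:
            cand = _random_mer(rng, n)
            rule = _rule_failure(cand, role, tm_window, c)
            if rule is None and extra is not None:
                rule = extra(cand)
            budget.charge(rule)
            if rule is None:
                return cand

    bp_seq = draw(c.branch_len, "BP", c.stem_tm)
    bp = Oligo("BP", bp_seq, "BP")

    sets: list[ForkPrimerSet] = []
    stems: list[str] = []
    for i in range(1, n_sets + 1):
        def stem_rule(cand: str) -> str | None:
            if longest_common_suffix(cand, bp_seq) > c.bp_suffix_cap:
                return "stem_bp_3prime_identity"
            if any(cand == s for s in stems):
                return "stem_uniqueness"
            return None

        def branch_rule(stem: str):
            def rule(cand: str) -> str | None:
                if longest_common_substring(cand, bp_seq) > c.heterology_cap:
                    return "branch_heterology"
                full = cand + stem
                if validate_oligo(
                    Oligo("cand", full, "PFP"), _validation_constraints(c)
                ).failed_rules():
                    return "full_primer_rules"
                tm = melt_temp(full, c.conditions)
                if not c.full_tm[0] <= tm <= c.full_tm[1]:
                    return "full_tm_window"
                if severe_hits(full, thresholds=c.structure):
                    return "full_structure"
                sfp_full = bp_seq + stem
                if severe_hits(full, sfp_full, thresholds=c.structure):
                    return "pfp_sfp_dimer"
                return None

            return rule

        while True:
            stem = draw(c.stem_len, "generic", c.stem_tm, stem_rule)
            sfp_seq = bp_seq + stem
            if _rule_failure(sfp_seq, "SFP", c.full_tm, c) is not None:
                budget.charge("sfp_rules")
                continue
            break
        branch = draw(c.branch_len, "generic", c.stem_tm, branch_rule(stem))
        fork = decompose_fork(
            Oligo(f"PFP{i}", branch + stem, "PFP"),
            Oligo(f"SFP{i}", sfp_seq, "SFP"),
            bp,
            set_id=f"fork{i}",
        )
        stems.append(stem)
        sets.append(fork)
    return sets


def select_nsp_set(
    known_seq: str,
    walk_end: str = "right",
    constraints: DesignConstraints | None = None,
    name_prefix: str = "nsp",
) -> NSPSet:
    """Select a nested oNSP/mNSP/iNSP triple from a known sequence.

    Primers lie on the strand pointing toward the unknown flank and nest
    successively closer to the junction without overlapping, so each inner
    primer sits inside the previous round's product.  Raises ``DesignError``
    with per-rule diagnostics when no valid triple exists.
    """
    c = constraints or DesignConstraints()
    if walk_end not in ("left", "right"):
        raise ValueError("walk_end must be 'left' or 'right'")
    known = known_seq.strip().upper()
    if len(known) < 150:
        raise ValueError(f"known sequence must be >= 150 nt (got {len(known)})")
    strand = known if walk_end == "right" else revcomp(known)
    n = len(strand)
    diagnostics: dict[str, int] = {}
    candidates: list[tuple[int, int]] = []  # (start, end) on `strand`
    for length in range(c.nsp_len[0], c.nsp_len[1] + 1):
        for s in range(0, n - length + 1):
            cand = strand[s : s + length]
            rule = _rule_failure(cand, "oNSP", c.nsp_tm, c)
            if rule is not None:
                diagnostics[rule] = diagnostics.get(rule, 0) + 1
                continue
            candidates.append((s, s + length))
    # prefer triples close to the junction (large end coordinate on `strand`)
    candidates.sort(key=lambda se: (-se[1], se[1] - se[0]))

    def compatible(a: tuple[int, int], b: tuple[int, int]) -> bool:
        pa, pb = strand[a[0] : a[1]], strand[b[0] : b[1]]
        return not severe_hits(pa, pb, thresholds=c.structure)

    for insp in candidates:
        inner = [m for m in candidates if m[1] <= insp[0] and compatible(m, insp)]
        for mnsp in inner:
            outer = [
                o
                for o in inner
                if o[1] <= mnsp[0] and compatible(o, mnsp) and compatible(o, insp)
            ]
            if outer:
                onsp = outer[0]
                if walk_end == "left":
                    conv = {  # back to coordinates on the given sequence
                        role: (n - e, n - s)
                        for role, (s, e) in
                        {"oNSP": onsp, "mNSP": mnsp, "iNSP": insp}.items()
                    }
                else:
                    conv = {"oNSP": onsp, "mNSP": mnsp, "iNSP": insp}
                return build_nsp_set(known, conv, walk_end, name_prefix)
    raise DesignError(
        f"no valid NSP triple in {len(known)}-nt known sequence; "
        f"per-rule window rejections: {dict(sorted(diagnostics.items()))}, "
        f"passing windows: {len(candidates)}"
    )


#: primer pairs that co-occur in some reaction round
_ROUND_PAIRS = [
    (1, "PFP", "oNSP"),
    (2, "SFP", "BP"),
    (2, "SFP", "mNSP"),
    (2, "BP", "mNSP"),
    (3, "BP", "iNSP"),
]


def check_compatibility(fork_set: ForkPrimerSet, nsp_set: NSPSet) -> ValidationReport:
    """Cross-dimer screen for every primer pair that shares a reaction."""
    by_role = {
        "PFP": fork_set.pfp,
        "SFP": fork_set.sfp,
        "BP": fork_set.bp,
        "oNSP": nsp_set.onsp,
        "mNSP": nsp_set.mnsp,
        "iNSP": nsp_set.insp,
    }
    verdicts = []
    thresholds = StructureThresholds()
    for round_no, ra, rb in _ROUND_PAIRS:
        a, b = by_role[ra], by_role[rb]
        hits = severe_hits(a.seq, b.seq, thresholds)
        worst = max((h.stem for h in hits), default=0)
        verdicts.append(
            RuleVerdict(
                f"round{round_no}_{ra}_x_{rb}",
                not hits,
                f"severe duplex of {worst} bp" if hits else "no severe duplex",
            )
        )
    return ValidationReport(f"{fork_set.set_id}+{nsp_set.onsp.name}", tuple(verdicts))
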