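"""Crossing-type classification, signature/crossing contingency tables, the
two-proportion chi-square test with continuity correction, and the
discordance breakdown."""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import chi2 as _chi2_dist

from .errors import TableError
from .repertoire import SignatureFlags

CROSSING_TYPES = ("compatible", "incompatible", "undetermined")
POSITIVE_RULES = ("any_variant", "both_variants")


@dataclass(frozen=True)
class CrossResult:
    """One cross: males of a line against females of a tester line."""

    male_line: str
    tester_line: str
    tester_group: str
    outcome: str                      # "+" hatch, "-" no hatch

    def __post_init__(self) -> None:
        if self.outcome not in ("+", "-"):
            raise TableError(f"outcome must be '+' or '-', got {self.outcome!r}")


@dataclass
class ContingencyTable:
    """2x2 of crossing type (rows) by signature positivity (columns)."""

    incompatible_positive: int
    incompatible_negative: int
    compatible_positive: int
    compatible_negative: int
    n_undetermined: int = 0

    @property
    def counts(self) -> list[list[int]]:
        return [
            [self.incompatible_positive, self.incompatible_negative],
            [self.compatible_positive, self.compatible_negative],
        ]

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p: float
    corrected: bool
    table: ContingencyTable | None = None

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not (0 < self.p <= 1):
            raise TableError("invalid test output")


def classify_crossing_type(results: list[CrossResult]) -> str:
    """All-or-none classification: all '+' is compatible, all '-' is
    incompatible, mixed outcomes are undetermined."""
    if not results:
        raise TableError("classify_crossing_type requires >= 1 cross result")
    outcomes = {r.outcome for r in results}
    if outcomes == {"+"}:
        return "compatible"
    if outcomes == {"-"}:
        return "incompatible"
    return "undetermined"


def is_positive(flags: SignatureFlags, positive_rule: str = "any_variant") -> bool:
    if positive_rule == "any_variant":
        return flags.has_cidA_delta or flags.has_cidB_a2
    if positive_rule == "both_variants":
        return flags.has_cidA_delta and flags.has_cidB_a2
    raise TableError(f"unknown positive_rule {positive_rule!r}")


def build_contingency(
    panel: list[tuple[str, SignatureFlags]],
    positive_rule: str = "any_variant",
) -> ContingencyTable:
    """Count classified lines by crossing type x signature positivity;
    undetermined lines are excluded and counted separately."""
    if not panel:
        raise TableError("empty panel")
    cells = {"ip": 0, "in": 0, "cp": 0, "cn": 0}
    undetermined = 0
    for crossing, flags in panel:
        if crossing == "undetermined":
            undetermined += 1
            continue
        if crossing not in ("compatible", "incompatible"):
            raise TableError(f"unknown crossing type {crossing!r}")
        pos = is_positive(flags, positive_rule)
        key = ("i" if crossing == "incompatible" else "c") + ("p" if pos else "n")
        cells[key] += 1
    return ContingencyTable(
        cells["ip"], cells["in"], cells["cp"], cells["cn"], undetermined
    )


def prop_test_yates(table: ContingencyTable, correction: bool = True) -> AssociationResult:
    """Two-proportion chi-square test on a 2x2, with Yates continuity
    correction by default:

    ``chi2 = N * (max(|ad - bc| - N/2, 0))^2 / (r1 r2 c1 c2)``.
    """
    (a, b), (c, d) = table.counts
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0:
        raise TableError("both row totals must be positive")
    if c1 == 0 or c2 == 0:
        raise TableError("both column totals must be positive")
    cross = abs(a * d - b * c)
    if correction:
        cross = max(cross - n / 2, 0.0)
    chi2 = n * cross**2 / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(chi2, df=1))
    if p <= 0.0:
        p = 5e-324  # underflow guard; p is an upper-tail probability in (0,1]
    return AssociationResult(chi2=float(chi2), df=1, p=p, corrected=correction, table=table)


@dataclass
class DiscordanceReport:
    """Counts per (crossing type x signature category)."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def get(self, crossing: str, category: str) -> int:
        return self.counts.get((crossing, category), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def discordance_report(panel: list[tuple[str, SignatureFlags]]) -> DiscordanceReport:
    """Break the panel down by crossing type and signature category
    (both / cidA_only / cidB_only / neither)."""
    counts: dict[tuple[str, str], int] = {}
    for crossing, flags in panel:
        key = (crossing, flags.category)
        counts[key] = counts.get(key, 0) + 1
    return DiscordanceReport(counts)
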