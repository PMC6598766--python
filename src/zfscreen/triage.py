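"""Decision logic of the rescue screen.

The primary assay scores in-situ staining of the ear marker (vcanb) in
three embryos per well on an ordinal 0-3 scale, 0 meaning full rescue
(wild-type-like down-regulation) and 3 no effect. Well sums 0-9 map to
categories A-G; A-C compounds are cherry-picked, retested twice, counter
screened for restoration of mbp expression, and finally re-screened on
the strong (truncating) allele to separate compounds acting downstream
of the receptor from candidate receptor-level agonists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Assay(str, enum.Enum):
    """The three ISH assays: primary/retest, counter screen, strong allele."""

    VCANB_TB233C = "vcanb_tb233c"
    MBP_TB233C = "mbp_tb233c"
    VCANB_FR24 = "vcanb_fr24"


class Category(str, enum.Enum):
    """Primary-screen category from the combined three-embryo score.

    A is the strongest rescue, E no effect, F toxic, G no embryos found.
    """

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"


class MbpClass(str, enum.Enum):
    RESCUE = "rescue"
    NO_RESCUE = "no_rescue"
    DOWNREGULATED = "downregulated"


class MechanismClass(str, enum.Enum):
    DOWNSTREAM = "downstream"
    RECEPTOR_CANDIDATE = "receptor_candidate"
    INCONCLUSIVE = "inconclusive"


#: Missing-data codes used in the strong-allele assay column.
ND = "ND"  # no data
DE = "DE"  # dead embryos

# Default category bins on the 0-9 well sum. Only the A upper bound (2)
# is fixed by the assay definition; the rest are configurable.
DEFAULT_CATEGORY_BINS: dict[Category, tuple[int, int]] = {
    Category.A: (0, 2),
    Category.B: (3, 4),
    Category.C: (5, 6),
    Category.D: (7, 8),
    Category.E: (9, 9),
}


def validate_category_bins(bins: dict[Category, tuple[int, int]]) -> None:
    """Check that the configured score bins partition 0..9 exactly once."""
    covered = sorted(s for lo, hi in bins.values() for s in range(lo, hi + 1))
    if covered != list(range(10)):
        raise ValueError(f"category bins do not partition 0-9: {bins}")


@dataclass
class WellResult:
    """One assay well: up to three embryos, ordinal scores for the live ones."""

    compound_id: str
    assay: Assay
    embryo_scores: list[int]
    n_embryos_found: int = 3
    n_dead_or_abnormal: int = 0
    concentration: float = 25.0

    def __post_init__(self):
        self.assay = Assay(self.assay)
        if any(s not in (0, 1, 2, 3) for s in self.embryo_scores):
            raise ValueError(f"embryo scores must be in 0..3: {self.embryo_scores}")
        if not (0 <= self.n_embryos_found <= 3):
            raise ValueError("n_embryos_found must be 0..3")
        if len(self.embryo_scores) + self.n_dead_or_abnormal > self.n_embryos_found:
            raise ValueError("scored + dead embryos exceed embryos found")


class WellOutcome(str, enum.Enum):
    SCORED = "scored"
    TOXIC = "toxic"
    EMPTY = "empty"


@dataclass(frozen=True)
class WellScore:
    """Outcome of scoring one well: a 0-9 sum, or a toxicity/empty flag."""

    outcome: WellOutcome
    total: int | None = None


@dataclass
class TriageRecord:
    """Per-compound aggregate across the whole screening cascade."""

    compound_id: str
    plate: str = ""
    well: str = ""
    name: str = ""
    primary_sum: int | None = None
    primary_category: Category | None = None
    retest_sums: list[int] = field(default_factory=list)
    vcanb_average: float | None = None
    is_hit: bool = False
    incomplete: bool = False
    mbp_average: float | None = None
    mbp_class: MbpClass | None = None
    fr24_sum: float | str | None = None
    mechanism_class: MechanismClass | None = None

    @property
    def library_prefix(self) -> str:
        return self.plate[:1]


def score_well(w: WellResult, toxicity_rule: str = "any") -> WellScore:
    """Sum the embryo scores of a well, or flag it toxic/empty.

    toxicity_rule "any" (default) marks the well toxic if any embryo died
    or was severely abnormal; "majority" requires more than half of the
    embryos found.
    """
    if w.n_embryos_found == 0:
        return WellScore(WellOutcome.EMPTY)
    if toxicity_rule == "any":
        toxic = w.n_dead_or_abnormal > 0
    elif toxicity_rule == "majority":
        toxic = w.n_dead_or_abnormal * 2 > w.n_embryos_found
    else:
        raise ValueError(f"unknown toxicity rule {toxicity_rule!r}")
    if toxic:
        return WellScore(WellOutcome.TOXIC)
    if not w.embryo_scores:
        return WellScore(WellOutcome.EMPTY)
    return WellScore(WellOutcome.SCORED, total=sum(w.embryo_scores))


def categorize_primary(
    score: WellScore | int | float,
    bins: dict[Category, tuple[int, int]] = DEFAULT_CATEGORY_BINS,
) -> Category:
    """Map a well sum (or flag) to a category A-G.

    Defaults: A 0-2, B 3-4, C 5-6, D 7-8, E 9; toxic -> F; empty -> G.
    Float inputs (retest averages) fall in the bin whose range contains
    them after comparing against inclusive edges.
    """
    if isinstance(score, WellScore):
        if score.outcome is WellOutcome.TOXIC:
            return Category.F
        if score.outcome is WellOutcome.EMPTY:
            return Category.G
        score = score.total
    validate_category_bins(bins)
    for cat, (lo, hi) in bins.items():
        if lo <= score <= hi:
            return cat
    # float between integer bins, e.g. average 2.33 with A=(0,2), B=(3,4):
    # assign to the bin whose lower edge is the ceiling neighbour.
    for cat, (lo, hi) in sorted(bins.items(), key=lambda kv: kv[1][0]):
        if score <= hi:
            return cat
    raise ValueError(f"score {score} outside 0-9")


def select_hits(
    primary_sum: int,
    retest_sums: list[int],
    bins: dict[Category, tuple[int, int]] = DEFAULT_CATEGORY_BINS,
) -> tuple[float | None, bool, bool]:
    """Apply the hit rule across primary + two retests (nine embryos).

    Returns (vcanb_average, is_hit, incomplete). A compound is a hit iff
    the average of its three well sums falls in category A-C and no
    individual well sum exceeds 7. With fewer than two retest sums the
    record is flagged incomplete and is not a hit.
    """
    if len(retest_sums) < 2:
        return (None, False, True)
    sums = [primary_sum] + list(retest_sums[:2])
    avg = sum(sums) / 3.0
    cat = categorize_primary(avg, bins)
    is_hit = cat in (Category.A, Category.B, Category.C) and max(sums) <= 7
    return (avg, is_hit, False)


def classify_mbp(mbp_average: float) -> MbpClass:
    """Bin the counter-screen average (six embryos over two repeats).

    rescue: average > 3.5; no_rescue: 1.5 < average <= 3.5;
    downregulated (both markers suppressed, presumed transcription
    inhibitor): average <= 1.5. Upper edges are inclusive.
    """
    if not 0.0 <= mbp_average <= 9.0:
        raise ValueError(f"mbp average {mbp_average} outside [0, 9]")
    if mbp_average > 3.5:
        return MbpClass.RESCUE
    if mbp_average > 1.5:
        return MbpClass.NO_RESCUE
    return MbpClass.DOWNREGULATED


def classify_fr24(fr24_sum: float | str | None) -> MechanismClass:
    """Mechanism class from the strong-allele (truncating) re-screen.

    A compound that still rescues the strong allele (sum 0-7) must act
    downstream of the receptor; one with no effect at all (sum 9) is a
    candidate for acting at the receptor itself; a partial score (8) or
    missing data (ND/DE) is inconclusive.
    """
    if fr24_sum is None or (isinstance(fr24_sum, str) and fr24_sum in (ND, DE)):
        return MechanismClass.INCONCLUSIVE
    value = float(fr24_sum)
    if not 0.0 <= value <= 9.0:
        raise ValueError(f"fr24 sum {value} outside [0, 9]")
    if value <= 7.0:
        return MechanismClass.DOWNSTREAM
    if value >= 9.0:
        return MechanismClass.RECEPTOR_CANDIDATE
    return MechanismClass.INCONCLUSIVE


DIFFERENCE_BINS = ("0", "1-2", "3-6", "7-9")


def reconcile_duplicates(avg_a: float, avg_b: float) -> str:
    """Bin the absolute difference of two duplicate-compound averages.

    Bins: exactly 0; (0, 2]; (2, 6]; (6, 9] — the printed integer labels
    taken as inclusive upper edges on |avg_a - avg_b|.
    """
    d = abs(avg_a - avg_b)
    if d == 0:
        return "0"
    if d <= 2:
        return "1-2"
    if d <= 6:
        return "3-6"
    return "7-9"


def screen_average(record: TriageRecord) -> float | None:
    """Best available 0-9 score average for cross-library comparison.

    The nine-embryo retest average where the compound was retested,
    otherwise the single primary well sum; None when the primary well
    was toxic or empty.
    """
    if record.vcanb_average is not None:
        return record.vcanb_average
    if record.primary_sum is not None:
        return float(record.primary_sum)
    return None


def mechanism_report(records: list[TriageRecord]) -> dict:
    """Count mechanism classes, overall and per library (plate prefix)."""
    counts = {m: 0 for m in MechanismClass}
    per_library: dict[str, dict[MechanismClass, int]] = {}
    for r in records:
        m = r.mechanism_class
        if m is None:
            m = classify_fr24(r.fr24_sum)
        counts[m] += 1
        lib = r.library_prefix or "?"
        per_library.setdefault(lib, {mm: 0 for mm in MechanismClass})[m] += 1
    return {
        "total": len(records),
        "counts": {m.value: n for m, n in counts.items()},
        "per_library": {
            lib: {m.value: n for m, n in d.items()} for lib, d in per_library.items()
        },
    }


def triage_wells(
    wells: list[WellResult],
    bins: dict[Category, tuple[int, int]] = DEFAULT_CATEGORY_BINS,
    toxicity_rule: str = "any",
) -> list[TriageRecord]:
    """Run the full decision cascade over raw well results.

    Expects, per compound: one primary well plus up to two retest wells
    for the weak-allele vcanb assay; up to two counter-screen (mbp)
    wells; and optionally one strong-allele well. Produces one
    TriageRecord per compound in first-seen order.
    """
    order: list[str] = []
    by_compound: dict[str, dict[Assay, list[WellResult]]] = {}
    for w in wells:
        if w.compound_id not in by_compound:
            order.append(w.compound_id)
            by_compound[w.compound_id] = {a: [] for a in Assay}
        by_compound[w.compound_id][w.assay].append(w)

    records = []
    for cid in order:
        groups = by_compound[cid]
        rec = TriageRecord(compound_id=cid)
        vcanb = groups[Assay.VCANB_TB233C]
        if not vcanb:
            records.append(rec)
            continue
        primary = score_well(vcanb[0], toxicity_rule)
        rec.primary_category = categorize_primary(primary, bins)
        if primary.outcome is WellOutcome.SCORED:
            rec.primary_sum = primary.total
        retests = [score_well(w, toxicity_rule) for w in vcanb[1:3]]
        scored = [s.total for s in retests if s.outcome is WellOutcome.SCORED]
        if len(retests) > len(scored):
            # a toxic or empty retest well fails the compound outright
            rec.incomplete = False
            rec.is_hit = False
            rec.retest_sums = scored
        elif primary.outcome is WellOutcome.SCORED and len(scored) == 2:
            rec.retest_sums = scored
            rec.vcanb_average, rec.is_hit, rec.incomplete = select_hits(
                primary.total, scored, bins
            )
        elif rec.primary_category in (Category.A, Category.B, Category.C):
            rec.incomplete = True

        mbp_wells = groups[Assay.MBP_TB233C]
        if rec.is_hit and mbp_wells:
            mbp_scores = [score_well(w, toxicity_rule) for w in mbp_wells]
            totals = [s.total for s in mbp_scores if s.outcome is WellOutcome.SCORED]
            if totals:
                rec.mbp_average = sum(totals) / len(totals)
                rec.mbp_class = classify_mbp(rec.mbp_average)

        fr24_wells = groups[Assay.VCANB_FR24]
        if rec.mbp_class is MbpClass.RESCUE:
            if fr24_wells:
                s = score_well(fr24_wells[0], toxicity_rule)
                if s.outcome is WellOutcome.SCORED:
                    rec.fr24_sum = float(s.total)
                elif s.outcome is WellOutcome.TOXIC:
                    rec.fr24_sum = DE
                else:
                    rec.fr24_sum = ND
            else:
                rec.fr24_sum = ND
            rec.mechanism_class = classify_fr24(rec.fr24_sum)
        records.append(rec)
    return records
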