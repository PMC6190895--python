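"""Multi-stage de novo variant filter cascade for parent-offspring trios.

A candidate de novo variant must be called concordantly by two independent
callers, be carried by the focal offspring and no other cohort member, be
absent from a known-variant database, satisfy depth and allelic-balance
bounds, show the genotype-likelihood pattern of a heterozygous offspring
with homozygous-reference parents, and carry little soft-clipped read
support.  A final review stage flags (but by default does not remove)
candidates in alignment-hostile contexts: variant clusters, homopolymer
runs, and ambiguous-base neighborhoods.

Every run emits a :class:`FilterTrace` — the ordered surviving-variant
count per stage — so losses are attributable to a specific criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from triomut.core_io import (
    GenomeSequence,
    KnownVariantDatabase,
    RoleError,
    SampleCall,
    TrioContext,
    VariantRecord,
    intersect_callsets,
)

#: ordered stage labels as they appear in a full cascade trace
STAGE_LABELS = (
    "caller_a",
    "caller_b",
    "caller_intersection",
    "cohort_unique",
    "known_db",
    "depth",
    "pl_pattern",
    "softclip",
    "review_flagged",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the cascade stages.

    Parents need depth >= ``min_parent_depth``; the offspring needs at least
    ``offspring_depth_fraction`` of the summed parental depth.  PL patterns:
    offspring (AA > 20, AB == 0, BB > 0), each parent (AA == 0, AB > 20,
    BB > 20).  Offspring soft-clip fraction above ``max_softclip`` removes
    the variant; equality passes (removal conditions are strict).
    """

    min_parent_depth: int = 12
    offspring_depth_fraction: Fraction = Fraction(1, 10)
    min_pl_gap: int = 20
    max_softclip: float = 0.10
    # review-stage context thresholds
    cluster_window: int = 10
    homopolymer_min_run: int = 10
    ambiguous_window: int = 10

    def __post_init__(self) -> None:
        if self.min_parent_depth < 0 or self.min_pl_gap < 0:
            raise ValueError("thresholds must be non-negative")
        frac = Fraction(self.offspring_depth_fraction)
        if not (0 < frac <= 1):
            raise ValueError("offspring_depth_fraction must be in (0, 1]")
        object.__setattr__(self, "offspring_depth_fraction", frac)


@dataclass
class FilterTrace:
    """Ordered (stage label, surviving count) pairs for one cascade run."""

    offspring_id: str
    vclass: str
    caller_a: str = "caller_a"
    caller_b: str = "caller_b"
    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, label: str, count: int) -> None:
        self.stages.append((label, count))

    def counts(self) -> dict[str, int]:
        return dict(self.stages)

    def is_monotone(self) -> bool:
        """Counts never increase from the caller intersection onward."""
        core = [n for label, n in self.stages if label not in ("caller_a", "caller_b")]
        return all(a >= b for a, b in zip(core, core[1:]))


@dataclass
class CandidateDeNovo:
    """A surviving variant plus its trio evidence and review annotations."""

    variant: VariantRecord
    sire_call: SampleCall
    dam_call: SampleCall
    offspring_call: SampleCall
    flags: tuple[str, ...] = ()

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def _role_calls(
    v: VariantRecord, trio: TrioContext
) -> tuple[SampleCall | None, SampleCall | None, SampleCall | None]:
    return (
        v.calls.get(trio.sire_id),
        v.calls.get(trio.dam_id),
        v.calls.get(trio.offspring_id),
    )


# ---------------------------------------------------------------------------
# stage predicates
# ---------------------------------------------------------------------------


def stage_cohort_unique(
    variants: set[VariantRecord], trio: TrioContext
) -> set[VariantRecord]:
    """Keep variants whose alternate allele is carried by the focal
    offspring and by no other cohort member (parents included).

    A missing offspring genotype excludes the variant here; other cohort
    members with missing genotypes are treated as non-carriers.
    """
    kept = set()
    for v in variants:
        off = v.calls.get(trio.offspring_id)
        if off is None:
            raise RoleError(
                f"offspring {trio.offspring_id!r} has no call at {v.chrom}:{v.pos}"
            )
        if off.genotype not in ("AB", "BB"):
            continue
        carried_elsewhere = any(
            v.calls.get(sid) is not None
            and v.calls[sid].genotype in ("AB", "BB")
            for sid in trio.cohort_ids
            if sid != trio.offspring_id
        )
        if not carried_elsewhere:
            kept.add(v)
    return kept


def stage_known_db(
    variants: set[VariantRecord], db: KnownVariantDatabase
) -> set[VariantRecord]:
    """Remove variants whose key exists in the known-variant database."""
    return {v for v in variants if v.key not in db}


def stage_depth(
    variants: set[VariantRecord], trio: TrioContext, criteria: FilterCriteria
) -> set[VariantRecord]:
    """Depth and allelic-balance filter.

    Removes variants with either parent's depth below ``min_parent_depth``
    or the offspring's depth below ``offspring_depth_fraction`` of the
    summed parental depth.  The fractional comparison is exact rational
    arithmetic, so a depth exactly at the bound passes.
    """
    frac = criteria.offspring_depth_fraction
    kept = set()
    for v in variants:
        sire, dam, off = _role_calls(v, trio)
        if sire is None or dam is None or off is None:
            continue
        if sire.depth < criteria.min_parent_depth or dam.depth < criteria.min_parent_depth:
            continue
        if Fraction(off.depth) < frac * (sire.depth + dam.depth):
            continue
        kept.add(v)
    return kept


def _offspring_pl_ok(pl: tuple[int, int, int], gap: int) -> bool:
    aa, ab, bb = pl
    return aa > gap and ab == 0 and bb > 0


def _parent_pl_ok(pl: tuple[int, int, int], gap: int) -> bool:
    aa, ab, bb = pl
    return aa == 0 and ab > gap and bb > gap


def stage_pl(
    variants: set[VariantRecord], trio: TrioContext, criteria: FilterCriteria
) -> set[VariantRecord]:
    """Genotype-likelihood pattern filter.

    Keeps variants where the offspring PL triple supports a confident
    heterozygote — (AA > 20, AB == 0, BB > 0) — and each parent a confident
    homozygous reference — (AA == 0, AB > 20, BB > 20).  Missing or
    non-normalized triples exclude the variant with a warning.
    """
    gap = criteria.min_pl_gap
    kept = set()
    for v in variants:
        sire, dam, off = _role_calls(v, trio)
        if sire is None or dam is None or off is None:
            continue
        triples = (sire.pl, dam.pl, off.pl)
        if any(t is None for t in triples):
            continue
        if any(min(t) != 0 for t in triples):
            warnings.warn(
                f"non-normalized PL at {v.chrom}:{v.pos}; variant excluded",
                stacklevel=2,
            )
            continue
        if (
            _offspring_pl_ok(off.pl, gap)
            and _parent_pl_ok(sire.pl, gap)
            and _parent_pl_ok(dam.pl, gap)
        ):
            kept.add(v)
    return kept


def stage_softclip(
    variants: set[VariantRecord], trio: TrioContext, criteria: FilterCriteria
) -> set[VariantRecord]:
    """Remove variants whose offspring soft-clip fraction exceeds the bound.

    The offspring carries the putative de novo allele, so its reads are the
    ones tested.  Equality at the bound passes; a missing fraction passes
    with a warning.
    """
    kept = set()
    for v in variants:
        off = v.calls.get(trio.offspring_id)
        if off is None:
            continue
        if off.softclip_fraction is None:
            warnings.warn(
                f"missing soft-clip fraction at {v.chrom}:{v.pos}; variant kept",
                stacklevel=2,
            )
            kept.add(v)
        elif off.softclip_fraction <= criteria.max_softclip:
            kept.add(v)
    return kept


# ---------------------------------------------------------------------------
# review stage
# ---------------------------------------------------------------------------


def _homopolymer_run_at(seq: str, pos0: int) -> int:
    """Longest homopolymer run containing or immediately flanking pos0."""
    best = 0
    for anchor in (pos0 - 1, pos0, pos0 + 1):
        if not (0 <= anchor < len(seq)):
            continue
        base = seq[anchor]
        if base == "N":
            continue
        left = anchor
        while left > 0 and seq[left - 1] == base:
            left -= 1
        right = anchor
        while right < len(seq) - 1 and seq[right + 1] == base:
            right += 1
        best = max(best, right - left + 1)
    return best


def review_flags(
    v: VariantRecord,
    variants: set[VariantRecord],
    genome: GenomeSequence,
    criteria: FilterCriteria,
) -> tuple[str, ...]:
    """Automated proxies for manual review of alignment-hostile contexts."""
    flags = []
    w = criteria.cluster_window
    if any(
        o is not v and o.chrom == v.chrom and abs(o.pos - v.pos) <= w for o in variants
    ):
        flags.append("variant_cluster")
    seq = genome.sequences.get(v.chrom, "")
    pos0 = v.pos - 1
    if _homopolymer_run_at(seq, pos0) >= criteria.homopolymer_min_run:
        flags.append("homopolymer")
    a = criteria.ambiguous_window
    if "N" in seq[max(0, pos0 - a) : pos0 + a + 1]:
        flags.append("ambiguous_base")
    return tuple(flags)


def stage_review(
    variants: set[VariantRecord],
    genome: GenomeSequence,
    criteria: FilterCriteria,
    strict: bool = False,
) -> tuple[set[VariantRecord], dict[tuple, tuple[str, ...]]]:
    """Flag candidates in suspicious contexts; remove them only in strict mode.

    Returns the surviving set and a map from variant key to flags.
    """
    annotations = {
        v.key: review_flags(v, variants, genome, criteria) for v in variants
    }
    if strict:
        survivors = {v for v in variants if not annotations[v.key]}
    else:
        survivors = set(variants)
    return survivors, annotations


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    candidates: list[CandidateDeNovo]
    trace: FilterTrace
    #: count entering the review stage; numerator of the mutation-rate
    #: estimator (matches the post-soft-clip tabulated counts)
    mu_alpha: int = 0


def run_cascade(
    callset_a: set[VariantRecord],
    callset_b: set[VariantRecord],
    trio: TrioContext,
    db: KnownVariantDatabase,
    criteria: FilterCriteria,
    genome: GenomeSequence,
    vclass: str = "SNV",
    caller_a_label: str = "caller_a",
    caller_b_label: str = "caller_b",
    strict_review: bool = False,
) -> CascadeResult:
    """Run the full filter cascade for one trio and one variant class.

    Stage order: caller intersection, cohort uniqueness, known-database
    subtraction, depth/allelic balance, PL pattern, soft clipping, context
    review.  The trace records the surviving count after every stage; the
    count entering review is exported as ``mu_alpha`` for rate estimation.
    """
    if vclass not in ("SNV", "INDEL"):
        raise ValueError(f"vclass must be SNV or INDEL, got {vclass!r}")
    a = {v for v in callset_a if v.vclass == vclass}
    b = {v for v in callset_b if v.vclass == vclass}
    trace = FilterTrace(
        offspring_id=trio.offspring_id,
        vclass=vclass,
        caller_a=caller_a_label,
        caller_b=caller_b_label,
    )
    trace.record("caller_a", len(a))
    trace.record("caller_b", len(b))

    current = intersect_callsets(a, b, genome)
    trace.record("caller_intersection", len(current))
    current = stage_cohort_unique(current, trio)
    trace.record("cohort_unique", len(current))
    current = stage_known_db(current, db)
    trace.record("known_db", len(current))
    current = stage_depth(current, trio, criteria)
    trace.record("depth", len(current))
    current = stage_pl(current, trio, criteria)
    trace.record("pl_pattern", len(current))
    current = stage_softclip(current, trio, criteria)
    trace.record("softclip", len(current))
    mu_alpha = len(current)

    survivors, annotations = stage_review(current, genome, criteria, strict=strict_review)
    n_flagged = sum(1 for f in annotations.values() if f)
    trace.record("review_flagged", n_flagged)

    candidates = []
    for v in sorted(survivors, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        sire, dam, off = _role_calls(v, trio)
        candidates.append(
            CandidateDeNovo(
                variant=v,
                sire_call=sire,
                dam_call=dam,
                offspring_call=off,
                flags=annotations[v.key],
            )
        )
    return CascadeResult(candidates=candidates, trace=trace, mu_alpha=mu_alpha)
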