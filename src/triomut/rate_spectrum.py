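"""Mutation-rate estimation and substitution-spectrum analysis.

The per-generation, per-base-pair germline mutation rate for one offspring
is

    mu_g = mu_alpha / (2 * R)

where ``mu_alpha`` is the candidate de novo count surviving the filter
cascade and ``R`` is the effective genome size: the total bases in
autosomal coverage windows (default 10 kb) whose mean depth lies in a
confidently-callable band (default 13x-130x, both ends inclusive).  The
factor 2 accounts for diploidy.

Single-base substitutions are classified into nine strand-folded classes:
T>G, T>C, T>A, G>T, G>A, C>T, A>T, A>G, A>C.  The three ordered types not
listed fold as follows: C>A joins its reverse complement G>T; the
complementary pair C>G / G>C has no listed representative and folds to a
configurable target (default G>A, the listed class sharing the G reference
base).  The fold affects spectrum labels only, never rates or filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FOLD9_CLASSES = ("T>G", "T>C", "T>A", "G>T", "G>A", "C>T", "A>T", "A>G", "A>C")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ClassificationError(ValueError):
    """Raised for substitutions outside the unambiguous A/C/G/T alphabet."""


@dataclass(frozen=True)
class EffectiveGenome:
    """Callable genome fraction used as the rate denominator."""

    window_size: int = 10_000
    min_cov: float = 13.0
    max_cov: float = 130.0
    n_windows_pass: int = 0
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not self.min_cov < self.max_cov:
            raise ValueError("min_cov must be below max_cov")

    @property
    def R(self) -> int:
        """Effective base pairs: an exact multiple of the window size."""
        return self.n_windows_pass * self.window_size


@dataclass(frozen=True)
class MutationRateEstimate:
    offspring_id: str
    mu_alpha: int
    R: int
    mu_g: float

    @property
    def mu_g_1e8(self) -> float:
        """Rate in units of 1e-8 per bp per generation (2 d.p., half-up)."""
        import decimal

        scaled = decimal.Decimal(self.mu_g) * decimal.Decimal(10) ** 8
        return float(scaled.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def effective_genome(
    windows: pd.DataFrame,
    autosome_flags: Mapping[str, bool],
    window_size: int = 10_000,
    min_cov: float = 13.0,
    max_cov: float = 130.0,
    autosomes_only: bool = True,
) -> EffectiveGenome:
    """Count autosomal windows with mean coverage inside [min_cov, max_cov].

    ``windows`` needs columns ``chrom``, ``start``, ``end``, ``mean_depth``
    (intervals 0-based half-open).  Every window must span exactly
    ``window_size`` bases.
    """
    required = {"chrom", "start", "end", "mean_depth"}
    missing = required - set(windows.columns)
    if missing:
        raise ValueError(f"window table lacks columns {sorted(missing)}")
    spans = windows["end"] - windows["start"]
    if len(windows) and not (spans == window_size).all():
        bad = windows.loc[spans != window_size].iloc[0]
        raise ValueError(
            f"window {bad['chrom']}:{bad['start']}-{bad['end']} does not span "
            f"{window_size} bp"
        )
    keep = (windows["mean_depth"] >= min_cov) & (windows["mean_depth"] <= max_cov)
    if autosomes_only:
        keep &= windows["chrom"].map(lambda c: bool(autosome_flags.get(c, False)))
    return EffectiveGenome(
        window_size=window_size,
        min_cov=min_cov,
        max_cov=max_cov,
        n_windows_pass=int(keep.sum()),
        autosomes_only=autosomes_only,
    )


def mutation_rate(
    mu_alpha: int, eg: EffectiveGenome, offspring_id: str = ""
) -> MutationRateEstimate:
    """Per-bp per-generation rate mu_alpha / (2 R)."""
    if mu_alpha < 0:
        raise ValueError("mu_alpha must be non-negative")
    if eg.R <= 0:
        raise ZeroDivisionError("effective genome size R is zero; rate undefined")
    return MutationRateEstimate(
        offspring_id=offspring_id, mu_alpha=mu_alpha, R=eg.R, mu_g=mu_alpha / (2 * eg.R)
    )


def mean_rate(estimates: Sequence[MutationRateEstimate]) -> float:
    """Arithmetic mean of per-offspring rates."""
    if not estimates:
        raise ValueError("no estimates to average")
    return float(np.mean([e.mu_g for e in estimates]))


# ---------------------------------------------------------------------------
# substitution spectrum
# ---------------------------------------------------------------------------


def _default_fold_table(unpaired_target: str = "G>A") -> dict[str, str]:
    table = {}
    for ref in "ACGT":
        for alt in "ACGT":
            if ref == alt:
                continue
            label = f"{ref}>{alt}"
            if label in FOLD9_CLASSES:
                table[label] = label
                continue
            rc = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
            table[label] = rc if rc in FOLD9_CLASSES else unpaired_target
    return table


def classify_substitution(
    ref: str, alt: str, scheme: str = "fold9", fold_table: Mapping[str, str] | None = None
) -> str:
    """Map an ordered single-base substitution to its spectrum class.

    ``fold9`` folds onto the nine listed classes; ``full12`` returns the
    raw ordered type.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ClassificationError(f"ambiguous or non-SNV substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ClassificationError("ref and alt are identical")
    raw = f"{ref}>{alt}"
    if scheme == "full12":
        return raw
    if scheme != "fold9":
        raise ValueError(f"unknown scheme {scheme!r}")
    table = dict(fold_table) if fold_table is not None else _default_fold_table()
    return table[raw]


@dataclass
class SpectrumProfile:
    """Per-class counts and proportions for one group of SNVs."""

    grouping: str
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float] | None:
        """Class proportions summing to 1, or None for an empty profile."""
        total = self.total
        if total == 0:
            return None
        return {k: v / total for k, v in self.counts.items()}

    def as_vector(self, classes: Sequence[str] = FOLD9_CLASSES) -> np.ndarray:
        props = self.proportions
        if props is None:
            raise ValueError(f"empty spectrum profile {self.grouping!r}")
        return np.array([props.get(c, 0.0) for c in classes])


def spectrum(
    substitutions: Iterable[tuple[str, str]],
    grouping: str = "all",
    scheme: str = "fold9",
    fold_table: Mapping[str, str] | None = None,
) -> SpectrumProfile:
    """Build a spectrum profile from (ref, alt) pairs; non-SNVs are skipped."""
    classes = (
        FOLD9_CLASSES
        if scheme == "fold9"
        else tuple(f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a)
    )
    profile = SpectrumProfile(grouping=grouping, counts={c: 0 for c in classes})
    for ref, alt in substitutions:
        try:
            label = classify_substitution(ref, alt, scheme=scheme, fold_table=fold_table)
        except ClassificationError:
            profile.n_skipped += 1
            continue
        profile.counts[label] += 1
    return profile


def spectrum_by_carrier(
    variants: Iterable, sample_ids: Sequence[str], scheme: str = "fold9"
) -> dict[str, SpectrumProfile]:
    """Per-animal spectra: each SNV counts for every sample carrying the
    alternate allele (genotype AB or BB)."""
    subs: dict[str, list[tuple[str, str]]] = {sid: [] for sid in sample_ids}
    for v in variants:
        if v.vclass != "SNV":
            continue
        for sid in sample_ids:
            call = v.calls.get(sid)
            if call is not None and call.genotype in ("AB", "BB"):
                subs[sid].append((v.ref, v.alt))
    return {sid: spectrum(subs[sid], grouping=sid, scheme=scheme) for sid in sample_ids}


def compare_spectra(
    parent: SpectrumProfile,
    offspring: SpectrumProfile,
    classes: Sequence[str] | None = None,
) -> tuple[float, int, float]:
    """Paired two-sided t-test across per-class proportion pairs.

    Returns (statistic, degrees of freedom, p).  Identical profiles give a
    statistic of 0 and p = 1.

    Note that complete proportion vectors are compositional: both sum to 1,
    so the mean paired difference over all classes is identically zero and
    the full-vector test is extremely insensitive (it detects only
    asymmetry in how the differences spread, not a shift).  Passing a
    ``classes`` subset — e.g. the predominant transition classes — yields a
    non-degenerate comparison; proportions are still computed over the full
    profile.
    """
    if set(parent.counts) != set(offspring.counts):
        raise ValueError("profiles are on different class sets")
    all_classes = sorted(parent.counts)
    if classes is None:
        classes = all_classes
    else:
        unknown = set(classes) - set(all_classes)
        if unknown:
            raise ValueError(f"classes not in profiles: {sorted(unknown)}")
    x = parent.as_vector(classes)
    y = offspring.as_vector(classes)
    diffs = x - y
    dof = len(classes) - 1
    if np.allclose(diffs, 0.0) or np.std(diffs, ddof=1) == 0.0:
        return 0.0, dof, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), dof, float(res.pvalue)
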