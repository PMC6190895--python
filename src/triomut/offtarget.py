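"""PAM-aware CRISPR off-target site search and distance-null analysis.

A Cas9 guide recognizes a 20-nt protospacer followed 3' by a protospacer
adjacent motif (PAM; NGG, or relaxed NRG).  A candidate off-target site is
any length-20 genomic window, on either strand, with a PAM-compatible
3'-adjacent triplet and Hamming distance to the protospacer within a total
mismatch budget, with a separate, tighter budget inside the PAM-proximal
seed region (default 12 bp) where mismatches most strongly abolish
cleavage.  N bases never match.

To ask whether observed variants lie unusually close to such sites, the
least distance from each variant to any site is compared with the same
statistic for positions drawn at random from a null pool, via a two-sample
Kolmogorov-Smirnov test, with a bootstrap band around the null CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from triomut.core_io import FormatError, GenomeSequence, VariantRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PROTOSPACER_LEN = 20
PAM_LEN = 3

#: parameterization behind the distance-to-site null analysis: one mismatch
#: in the seed, up to four elsewhere (five total), canonical NGG PAM
DISTANCE_PRESET = dict(pam_pattern="NGG", max_mismatch_total=5,
                       seed_length=12, max_seed_mismatch=1)
#: relaxed screen for direct variant/site intersection: NRG PAM, three
#: total mismatches, no separate seed budget
NRG3_PRESET = dict(pam_pattern="NRG", max_mismatch_total=3,
                   seed_length=12, max_seed_mismatch=3)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideQuery:
    """A guide RNA protospacer plus its search budgets."""

    name: str
    protospacer: str
    pam_pattern: str = "NGG"
    max_mismatch_total: int = 5
    seed_length: int = 12
    max_seed_mismatch: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be unambiguous ACGT")
        if len(self.pam_pattern) != PAM_LEN:
            raise ValueError("PAM pattern must be 3 characters")
        if set(self.pam_pattern) - set(IUPAC):
            raise ValueError("PAM pattern must be IUPAC")
        if self.max_mismatch_total < 0 or self.max_seed_mismatch < 0:
            raise ValueError("mismatch budgets must be non-negative")
        if self.max_seed_mismatch > self.max_mismatch_total:
            raise ValueError("seed budget cannot exceed total budget")
        if not 0 <= self.seed_length <= PROTOSPACER_LEN:
            raise ValueError("seed length must be within the protospacer")


@dataclass(frozen=True)
class OffTargetSite:
    """One protospacer match: 0-based half-open interval plus mismatch info."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatch_total: int
    mismatch_seed: int
    matched_sequence: str
    guide_name: str

    def __post_init__(self) -> None:
        if self.end - self.start != PROTOSPACER_LEN:
            raise ValueError("site interval must span 20 bp")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.mismatch_seed > self.mismatch_total:
            raise ValueError("seed mismatches cannot exceed total")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.start, self.strand, self.guide_name)


def _scan_strand(seq: str, guide: GuideQuery):
    """Yield (start, mm_total, mm_seed, matched) for one strand orientation."""
    L = len(seq)
    n = L - (PROTOSPACER_LEN + PAM_LEN) + 1
    if n <= 0:
        return
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    proto = np.frombuffer(guide.protospacer.encode("ascii"), dtype=np.uint8)
    mm_total = np.zeros(n, dtype=np.int16)
    mm_seed = np.zeros(n, dtype=np.int16)
    seed_start = PROTOSPACER_LEN - guide.seed_length  # PAM-proximal segment
    for j in range(PROTOSPACER_LEN):
        neq = arr[j : j + n] != proto[j]
        mm_total += neq
        if j >= seed_start:
            mm_seed += neq
    pam_ok = np.ones(n, dtype=bool)
    for j, ch in enumerate(guide.pam_pattern):
        allowed = np.frombuffer(IUPAC[ch].encode("ascii"), dtype=np.uint8)
        pam_ok &= np.isin(arr[PROTOSPACER_LEN + j : PROTOSPACER_LEN + j + n], allowed)
        # an N in the genome never satisfies a PAM position
        pam_ok &= arr[PROTOSPACER_LEN + j : PROTOSPACER_LEN + j + n] != ord("N")
    hits = np.nonzero(
        pam_ok
        & (mm_total <= guide.max_mismatch_total)
        & (mm_seed <= guide.max_seed_mismatch)
    )[0]
    for i in hits:
        yield int(i), int(mm_total[i]), int(mm_seed[i]), seq[i : i + PROTOSPACER_LEN]


def predict_offtargets(genome: GenomeSequence, guide: GuideQuery) -> list[OffTargetSite]:
    """Exhaustively scan both strands for PAM-adjacent protospacer matches.

    Every qualifying window is reported exactly once, including perfect
    on-target matches (mismatch_total 0).  Results are sorted by
    (chrom, start, strand).
    """
    if not genome.sequences:
        raise FormatError("empty genome")
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        for start, mt, ms, matched in _scan_strand(seq, guide):
            sites.append(
                OffTargetSite(
                    chrom=chrom, start=start, end=start + PROTOSPACER_LEN,
                    strand="+", mismatch_total=mt, mismatch_seed=ms,
                    matched_sequence=matched, guide_name=guide.name,
                )
            )
        for rc_start, mt, ms, matched in _scan_strand(revcomp(seq), guide):
            start = L - (rc_start + PROTOSPACER_LEN)
            sites.append(
                OffTargetSite(
                    chrom=chrom, start=start, end=start + PROTOSPACER_LEN,
                    strand="-", mismatch_total=mt, mismatch_seed=ms,
                    matched_sequence=matched, guide_name=guide.name,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def consensus_sites(
    a: Sequence[OffTargetSite], b: Sequence[OffTargetSite]
) -> list[OffTargetSite]:
    """Sites reported by both predictors (matched on chrom/start/strand/guide).

    Emulates a two-tool consensus by intersecting two parameterizations of
    the search; mismatch annotations are taken from ``a``.
    """
    keys_b = {s.key for s in b}
    return [s for s in a if s.key in keys_b]


def write_sites_bed(path, sites: Sequence[OffTargetSite]) -> None:
    """BED6+1: chrom start end guide mismatch_total strand mismatch_seed."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.guide_name}\t"
                f"{s.mismatch_total}\t{s.strand}\t{s.mismatch_seed}\n"
            )


def read_sites_bed(path, guide_name: str | None = None) -> list[OffTargetSite]:
    sites = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{line_no}: expected >=6 BED columns")
            sites.append(
                OffTargetSite(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    strand=f[5], mismatch_total=int(f[4]),
                    mismatch_seed=int(f[6]) if len(f) > 6 else int(f[4]),
                    matched_sequence="", guide_name=guide_name or f[3],
                )
            )
    return sites


# ---------------------------------------------------------------------------
# distance-to-site null analysis
# ---------------------------------------------------------------------------


def nearest_distances(
    positions: Iterable[tuple[str, int]], sites: Sequence[OffTargetSite]
) -> tuple[list[int], int]:
    """Least distance (bp) from each 0-based position to any site interval.

    A position inside a site interval has distance 0; otherwise the distance
    is to the nearest base of the half-open interval.  Positions on
    chromosomes without any site are excluded; the second return value
    counts them.
    """
    if not sites:
        raise ValueError("no off-target sites supplied")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {s.chrom for s in sites}:
        starts = np.sort(np.array([s.start for s in sites if s.chrom == chrom]))
        by_chrom[chrom] = starts
    distances: list[int] = []
    n_excluded = 0
    for chrom, pos in positions:
        starts = by_chrom.get(chrom)
        if starts is None:
            n_excluded += 1
            continue
        # all site intervals span 20 bp, so the flanking starts suffice
        idx = int(np.searchsorted(starts, pos))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(starts):
                s = int(starts[j])
                e = s + PROTOSPACER_LEN
                d = 0 if s <= pos < e else (s - pos if pos < s else pos - (e - 1))
                best = d if best is None else min(best, d)
        distances.append(best)
    return distances, n_excluded


def sample_null_positions(
    pool: Sequence[tuple[str, int]],
    n: int,
    seed: int,
    replace: bool = True,
) -> list[tuple[str, int]]:
    """Sample positions uniformly from the pool (with replacement by default).

    Without replacement and n equal to the pool size, this returns the pool
    itself.
    """
    if not pool:
        raise ValueError("empty null pool")
    rng = np.random.default_rng(seed)
    if not replace:
        if n > len(pool):
            raise ValueError("cannot sample more than pool size without replacement")
        if n == len(pool):
            return list(pool)
    idx = rng.choice(len(pool), size=n, replace=replace)
    return [pool[i] for i in idx]


def ks_compare(observed: Sequence[float], null: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov statistic and asymptotic p."""
    if len(observed) == 0 or len(null) == 0:
        raise ValueError("empty distance sample")
    res = stats.ks_2samp(observed, null, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class CIBand:
    """Pointwise bootstrap band around the null empirical CDF."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


def ci_band(
    null: Sequence[float],
    level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
    n_grid: int = 101,
) -> CIBand:
    """Bootstrap percentile band of the null ECDF on a fixed quantile grid."""
    null_arr = np.asarray(null, dtype=float)
    if null_arr.size == 0:
        raise ValueError("empty null sample")
    rng = np.random.default_rng(seed)
    grid = np.quantile(null_arr, np.linspace(0.0, 1.0, n_grid))
    sorted_boots = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        resample = rng.choice(null_arr, size=null_arr.size, replace=True)
        resample.sort()
        sorted_boots[b] = np.searchsorted(resample, grid, side="right") / null_arr.size
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(sorted_boots, alpha, axis=0)
    upper = np.quantile(sorted_boots, 1.0 - alpha, axis=0)
    return CIBand(grid=grid, lower=lower, upper=upper, level=level)


@dataclass
class DistanceAnalysis:
    """Observed vs null least-distance comparison for one variant set."""

    observed: list[int]
    null: list[int]
    n_null: int
    ks_statistic: float
    p_value: float
    band: CIBand | None = None
    n_excluded_observed: int = 0
    n_excluded_null: int = 0


def distance_analysis(
    observed_positions: Sequence[tuple[str, int]],
    null_pool: Sequence[tuple[str, int]],
    sites: Sequence[OffTargetSite],
    n_null: int = 100_000,
    seed: int = 0,
    with_band: bool = True,
) -> DistanceAnalysis:
    """Compare variant-to-site distances against a random-position null.

    Null positions are drawn with replacement from the pool (by default the
    cohort's called-SNV positions), the least distance to any site is taken
    per position, and the two distance samples are compared with a KS test.
    """
    null_positions = sample_null_positions(null_pool, n_null, seed=seed)
    observed, n_exc_obs = nearest_distances(observed_positions, sites)
    null_d, n_exc_null = nearest_distances(null_positions, sites)
    statistic, p = ks_compare(observed, null_d)
    band = ci_band(null_d, seed=seed) if with_band else None
    return DistanceAnalysis(
        observed=observed, null=null_d, n_null=n_null,
        ks_statistic=statistic, p_value=p, band=band,
        n_excluded_observed=n_exc_obs, n_excluded_null=n_exc_null,
    )


def annotate_variant_site_overlap(
    variants: Iterable[VariantRecord], sites: Sequence[OffTargetSite]
) -> tuple[dict[tuple, list[OffTargetSite]], dict[str, int]]:
    """Mark variants falling inside any off-target site interval.

    Returns (variant key -> overlapping sites) for overlapping variants
    only, plus per-guide overlap counts.
    """
    by_chrom: dict[str, list[OffTargetSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    annotations: dict[tuple, list[OffTargetSite]] = {}
    per_guide: dict[str, int] = {}
    for v in variants:
        pos0 = v.pos - 1
        hits = [
            s for s in by_chrom.get(v.chrom, ()) if s.start <= pos0 < s.end
        ]
        if hits:
            annotations[v.key] = hits
            for s in hits:
                per_guide[s.guide_name] = per_guide.get(s.guide_name, 0) + 1
    return annotations, per_guide
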