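"""Synthetic trio cohort generator with known ground truth.

Emulates the inputs the de novo pipeline consumes — a reference genome
with planted guide targets and off-target sites, a multi-trio pedigree,
two caller callsets with configurable discordance, a known-variant
database, and per-window coverage — entirely in memory, with every planted
event recorded in a :class:`GroundTruth` object so downstream stages can
be tested against exact expectations.

Design notes
------------
* Genotype evidence (depth, PL triple) is synthesized from a binomial
  read-sampling model: alt-read counts are drawn per genotype, and the
  phred-scaled likelihoods of (AA, AB, BB) are computed from those counts
  and renormalized so the minimum is 0.
* True de novo events are planted as clean heterozygous offspring calls:
  evidence is redrawn until the site passes every cascade criterion, so a
  zero-artifact simulation has recall 1 by construction.
* Artifact variants violate exactly one cascade criterion each (orthogonal
  design), so stage-level removals are unambiguously attributable.
* All randomness flows from one generator seeded by ``rng_seed``; the draw
  order is genome, guides and planted sites, population SNPs, per-offspring
  de novo events, artifacts, caller discordance, coverage windows.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from triomut.core_io import (
    GenomeSequence,
    KnownVariantDatabase,
    SampleCall,
    TrioContext,
    TrioMutError,
    VariantRecord,
    normalize_variant,
    write_genome,
    write_table,
    write_variants,
)
from triomut.offtarget import PROTOSPACER_LEN, GuideQuery, revcomp

ARTIFACT_TYPES = (
    "low_depth",
    "allelic_imbalance",
    "bad_pl",
    "high_softclip",
    "in_database",
    "cohort_shared",
)

_ERR = 1e-3  # per-read base error used by the PL model
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class CapacityError(TrioMutError):
    """The genome cannot host the requested planted events."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the sequencing study the pipeline is built for: a
    cohort of eleven animals forming five trios (two sires, one dam mated
    twice producing twins), ~37x mean depth, and a per-offspring candidate
    de novo count in the tens.  The genome is desk-scale (a few hundred kb
    per chromosome) so every test runs from scratch in seconds.
    """

    n_autosomes: int = 2
    chromosome_length: int = 200_000
    include_sex_chromosome: bool = True
    population_snp_rate: float = 1e-3
    true_denovo_count: int = 20
    true_denovo_indel_count: int = 3
    mean_depth: float = 36.8
    depth_dispersion: float = 0.1
    caller_discordance_rate: float = 0.05
    artifact_rates: dict = field(
        default_factory=lambda: {t: 0.2 for t in ARTIFACT_TYPES}
    )
    db_inclusion_rate: float = 0.9
    guide_count: int = 2
    planted_offtarget_spec: tuple = ((2, 0), (3, 1))
    window_size: int = 10_000
    coverage_outlier_fraction: float = 0.1
    n_trios: int | None = None  # None = the default 11-animal layout
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.population_snp_rate,
            self.caller_discordance_rate,
            self.db_inclusion_rate,
            self.coverage_outlier_fraction,
            *self.artifact_rates.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all rates must be probabilities in [0, 1]")
        unknown = set(self.artifact_rates) - set(ARTIFACT_TYPES)
        if unknown:
            raise ValueError(f"unknown artifact types {sorted(unknown)}")
        if self.chromosome_length < 10 * self.window_size:
            raise ValueError("chromosome_length must be >= 10 x window_size")
        for mt, ms in self.planted_offtarget_spec:
            if ms > mt:
                raise ValueError("seed mismatches cannot exceed total mismatches")

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        lengths = {
            f"chr{i}": self.chromosome_length for i in range(1, self.n_autosomes + 1)
        }
        if self.include_sex_chromosome:
            lengths["chrX"] = max(self.chromosome_length // 2, 10 * self.window_size)
        return lengths


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth location of a planted (off-)target match."""

    guide_name: str
    chrom: str
    start: int  # 0-based half-open protospacer interval
    end: int
    strand: str
    mismatch_total: int
    mismatch_seed: int


@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    guides: list[GuideQuery]
    planted_sites: list[PlantedSite]


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream attribution."""

    true_denovo_keys: dict[str, set] = field(default_factory=dict)
    inherited_keys: set = field(default_factory=set)
    artifact_keys: dict[str, dict[str, set]] = field(default_factory=dict)
    planted_offtarget_sites: list[PlantedSite] = field(default_factory=list)
    coverage_windows_in_bounds: int = 0
    coverage_windows_total: int = 0

    def denovo_snv_keys(self, offspring: str) -> set:
        return {
            k for k in self.true_denovo_keys.get(offspring, set())
            if len(k[2]) == 1 and len(k[3]) == 1
        }

    def denovo_indel_keys(self, offspring: str) -> set:
        return self.true_denovo_keys.get(offspring, set()) - self.denovo_snv_keys(offspring)


@dataclass
class CohortSim:
    """A complete synthetic study: inputs plus ground truth."""

    config: SimulationConfig
    synthetic_genome: SyntheticGenome
    trios: list[TrioContext]
    caller_a: set
    caller_b: set
    db: KnownVariantDatabase
    windows: pd.DataFrame
    truth: GroundTruth

    @property
    def genome(self) -> GenomeSequence:
        return self.synthetic_genome.genome


# ---------------------------------------------------------------------------
# genome and guide planting
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_protospacer(
    rng: np.random.Generator, protospacer: str, mt: int, ms: int, seed_length: int
) -> str:
    """Introduce mt mismatches, ms of them in the PAM-proximal seed."""
    seed_start = PROTOSPACER_LEN - seed_length
    non_seed = list(range(0, seed_start))
    seed_pos = list(range(seed_start, PROTOSPACER_LEN))
    if ms > len(seed_pos) or (mt - ms) > len(non_seed):
        raise CapacityError(
            f"cannot place {mt} mismatches ({ms} in seed) in a "
            f"{PROTOSPACER_LEN}-nt protospacer with seed {seed_length}"
        )
    chosen = list(rng.choice(seed_pos, size=ms, replace=False)) + list(
        rng.choice(non_seed, size=mt - ms, replace=False)
    )
    out = list(protospacer)
    for i in chosen:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticGenome:
    """Random genome with planted guide on-targets and off-target sites.

    Each guide gets one perfect protospacer+NGG match and, per entry of
    ``planted_offtarget_spec``, one mismatched match on a random strand.
    Placements never overlap.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    lengths = cfg.chromosome_lengths
    if not lengths:
        return SyntheticGenome(
            genome=GenomeSequence(name="synthetic", sequences={}, autosome_flags={}),
            guides=[], planted_sites=[],
        )
    arrays = {c: _random_seq(rng, n) for c, n in lengths.items()}
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}

    def place(chrom_choices: list[str], span: int) -> tuple[str, int]:
        for _ in range(200):
            chrom = chrom_choices[rng.integers(0, len(chrom_choices))]
            limit = lengths[chrom] - span
            if limit <= 0:
                continue
            pos = int(rng.integers(0, limit))
            pad = 30
            if all(
                pos + span + pad <= s or pos >= e + pad for s, e in reserved[chrom]
            ):
                reserved[chrom].append((pos, pos + span))
                return chrom, pos
        raise CapacityError("genome too short to host the requested planted sites")

    chroms = list(lengths)
    guides: list[GuideQuery] = []
    planted: list[PlantedSite] = []
    site_span = PROTOSPACER_LEN + 3
    for g in range(cfg.guide_count):
        protospacer = "".join(chr(b) for b in _random_seq(rng, PROTOSPACER_LEN))
        guide = GuideQuery(name=f"guide{g + 1}", protospacer=protospacer)
        guides.append(guide)
        specs = [(0, 0)] + list(cfg.planted_offtarget_spec)
        for mt, ms in specs:
            variant = (
                protospacer if mt == 0
                else _mutate_protospacer(rng, protospacer, mt, ms, guide.seed_length)
            )
            pam = "ACGT"[rng.integers(0, 4)] + "GG"
            cassette = variant + pam
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, pos = place(chroms, site_span)
            if strand == "+":
                ins, start = cassette, pos
            else:
                ins, start = revcomp(cassette), pos + 3
            arrays[chrom][pos : pos + site_span] = np.frombuffer(
                ins.encode("ascii"), dtype=np.uint8
            )
            planted.append(
                PlantedSite(
                    guide_name=guide.name, chrom=chrom, start=start,
                    end=start + PROTOSPACER_LEN, strand=strand,
                    mismatch_total=mt, mismatch_seed=ms,
                )
            )
    sequences = {c: arr.tobytes().decode("ascii") for c, arr in arrays.items()}
    flags = {c: not c.endswith("X") for c in sequences}
    genome = GenomeSequence(name="synthetic", sequences=sequences, autosome_flags=flags)
    return SyntheticGenome(genome=genome, guides=guides, planted_sites=planted)


# ---------------------------------------------------------------------------
# evidence synthesis
# ---------------------------------------------------------------------------


def _pl_from_reads(n_ref: int, n_alt: int) -> tuple[int, int, int]:
    """Phred-scaled binomial genotype likelihoods, renormalized to min 0."""
    ll = (
        n_alt * math.log10(_ERR) + n_ref * math.log10(1 - _ERR),  # AA
        (n_ref + n_alt) * math.log10(0.5),  # AB
        n_ref * math.log10(_ERR) + n_alt * math.log10(1 - _ERR),  # BB
    )
    raw = [-10.0 * v for v in ll]
    m = min(raw)
    return tuple(int(round(v - m)) for v in raw)


_ALT_P = {"AA": _ERR, "AB": 0.5, "BB": 1 - _ERR}


def _sample_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if cfg.depth_dispersion <= 0:
        return max(1, int(rng.poisson(cfg.mean_depth)))
    shape = 1.0 / cfg.depth_dispersion
    lam = rng.gamma(shape, cfg.mean_depth / shape)
    return max(1, int(rng.poisson(lam)))


def _draw_call(
    rng: np.random.Generator, cfg: SimulationConfig, genotype: str,
    max_tries: int = 200,
) -> SampleCall:
    """Sample a call whose PL-argmin agrees with the intended genotype."""
    for _ in range(max_tries):
        depth = _sample_depth(rng, cfg)
        n_alt = int(rng.binomial(depth, _ALT_P[genotype]))
        pl = _pl_from_reads(depth - n_alt, n_alt)
        if ("AA", "AB", "BB")[int(np.argmin(pl))] != genotype:
            continue
        scf = round(float(rng.beta(2, 60)), 4)
        return SampleCall(genotype=genotype, depth=depth, pl=pl, softclip_fraction=scf)
    raise CapacityError(f"could not synthesize a consistent {genotype} call")


def _passes_cascade(sire: SampleCall, dam: SampleCall, off: SampleCall) -> bool:
    if sire.depth < 12 or dam.depth < 12:
        return False
    if 10 * off.depth < sire.depth + dam.depth:
        return False
    for p in (sire, dam):
        if not (p.pl[0] == 0 and p.pl[1] > 20 and p.pl[2] > 20):
            return False
    if not (off.pl[0] > 20 and off.pl[1] == 0 and off.pl[2] > 0):
        return False
    return off.softclip_fraction is not None and off.softclip_fraction <= 0.10


def _clean_trio_calls(rng, cfg) -> tuple[SampleCall, SampleCall, SampleCall]:
    """Trio evidence for a de novo site, conditioned on cascade detectability."""
    for _ in range(500):
        sire = _draw_call(rng, cfg, "AA")
        dam = _draw_call(rng, cfg, "AA")
        off = _draw_call(rng, cfg, "AB")
        if _passes_cascade(sire, dam, off):
            return sire, dam, off
    raise CapacityError("could not synthesize a cascade-passing de novo site")


# ---------------------------------------------------------------------------
# cohort layout
# ---------------------------------------------------------------------------


def default_pedigree(cfg: SimulationConfig) -> list[TrioContext]:
    """Five trios over eleven animals (two sires, twins on one dam), or
    ``n_trios`` independent trios when configured."""
    if cfg.n_trios is not None:
        cohort = []
        specs = []
        for i in range(1, cfg.n_trios + 1):
            specs.append((f"S{i}", f"D{i}", f"O{i}"))
            cohort += [f"S{i}", f"D{i}", f"O{i}"]
        return [
            TrioContext(sire_id=s, dam_id=d, offspring_id=o, cohort_ids=tuple(cohort))
            for s, d, o in specs
        ]
    specs = [
        ("S1", "D1", "O1"),
        ("S1", "D2", "O2"),
        ("S1", "D3", "O3"),
        ("S2", "D4", "O4"),
        ("S2", "D4", "O5"),
    ]
    cohort = ("S1", "S2", "D1", "D2", "D3", "D4", "O1", "O2", "O3", "O4", "O5")
    return [
        TrioContext(sire_id=s, dam_id=d, offspring_id=o, cohort_ids=cohort)
        for s, d, o in specs
    ]


# ---------------------------------------------------------------------------
# callset simulation
# ---------------------------------------------------------------------------


def _free_position(rng, lengths, used, margin: int = 110) -> tuple[str, int]:
    chroms = list(lengths)
    for _ in range(1000):
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(1, lengths[chrom] - margin))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos
    raise CapacityError("no free positions left for requested variants")


def _mendelian_genotype(rng, sire_gt: str, dam_gt: str) -> str:
    def transmit(gt: str) -> int:
        if gt == "AA":
            return 0
        if gt == "BB":
            return 1
        return int(rng.random() < 0.5)

    n_alt = transmit(sire_gt) + transmit(dam_gt)
    return ("AA", "AB", "BB")[n_alt]


def _hwe_genotype(rng, p_alt: float) -> str:
    return ("AA", "AB", "BB")[int(rng.binomial(2, p_alt))]


def simulate_trio_callsets(
    cfg: SimulationConfig,
    syn: SyntheticGenome,
    trios: list[TrioContext] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[set, set, KnownVariantDatabase, pd.DataFrame, GroundTruth]:
    """Two cohort callsets, known-variant database, coverage, ground truth.

    Inherited variants follow Mendelian transmission; true de novo events
    are heterozygous in exactly one offspring; each artifact class violates
    exactly one cascade criterion.  Caller A is the primary caller; each
    variant is dropped from caller B with the discordance probability, and
    caller B additionally gains an equal expected number of private calls.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    if trios is None:
        trios = default_pedigree(cfg)
    genome = syn.genome
    cohort = list(trios[0].cohort_ids)
    offspring_ids = [t.offspring_id for t in trios]
    parents_of = {t.offspring_id: (t.sire_id, t.dam_id) for t in trios}
    lengths = {c: len(s) for c, s in genome.sequences.items()}
    used: set[tuple[str, int]] = set()
    truth = GroundTruth(planted_offtarget_sites=list(syn.planted_sites))
    caller_a: set = set()
    caller_b: set = set()
    db_keys: set = set()
    discord = cfg.caller_discordance_rate

    def emit(rec: VariantRecord) -> VariantRecord:
        rec = normalize_variant(rec, genome)
        caller_a.add(rec)
        if rng.random() >= discord:
            caller_b.add(rec)
        return rec

    # --- inherited population SNPs --------------------------------------
    total_bp = sum(lengths.values())
    n_pop = int(rng.binomial(total_bp, cfg.population_snp_rate))
    founders = sorted(set(cohort) - set(offspring_ids))
    for _ in range(n_pop):
        chrom, pos = _free_position(rng, lengths, used)
        ref = genome.sequences[chrom][pos - 1]
        alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        p_alt = float(rng.uniform(0.05, 0.95))
        gts = {sid: _hwe_genotype(rng, p_alt) for sid in founders}
        for t in trios:
            gts[t.offspring_id] = _mendelian_genotype(
                rng, gts[t.sire_id], gts[t.dam_id]
            )
        calls = {sid: _draw_call(rng, cfg, gts[sid]) for sid in cohort}
        rec = emit(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, calls=calls))
        truth.inherited_keys.add(rec.key)
        if rng.random() < cfg.db_inclusion_rate:
            db_keys.add(rec.key)

    # --- true de novo events ---------------------------------------------
    def denovo_record(offspring: str, indel: bool) -> VariantRecord:
        chrom, pos = _free_position(rng, lengths, used)
        seq = genome.sequences[chrom]
        if indel:
            k = int(rng.integers(2, 6))
            if rng.random() < 0.5:
                ref = seq[pos - 1 : pos + k]
                alt = ref[0]
            else:
                ref = seq[pos - 1]
                alt = ref + "".join(
                    chr(b) for b in _random_seq(rng, k)
                )
        else:
            ref = seq[pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        sire_id, dam_id = parents_of[offspring]
        sire, dam, off = _clean_trio_calls(rng, cfg)
        calls = {sid: _draw_call(rng, cfg, "AA") for sid in cohort}
        calls[sire_id], calls[dam_id], calls[offspring] = sire, dam, off
        return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, calls=calls)

    for offspring in offspring_ids:
        truth.true_denovo_keys[offspring] = set()
        for _ in range(cfg.true_denovo_count):
            rec = emit(denovo_record(offspring, indel=False))
            truth.true_denovo_keys[offspring].add(rec.key)
        for _ in range(cfg.true_denovo_indel_count):
            rec = emit(denovo_record(offspring, indel=True))
            truth.true_denovo_keys[offspring].add(rec.key)

    # --- artifact variants (one violated criterion each) -----------------
    for offspring in offspring_ids:
        truth.artifact_keys[offspring] = {t: set() for t in ARTIFACT_TYPES}
        sire_id, dam_id = parents_of[offspring]
        for atype in ARTIFACT_TYPES:
            rate = cfg.artifact_rates.get(atype, 0.0)
            n = int(rng.poisson(rate * cfg.true_denovo_count))
            for _ in range(n):
                rec = denovo_record(offspring, indel=False)
                calls = dict(rec.calls)
                if atype == "low_depth":
                    victim = sire_id if rng.random() < 0.5 else dam_id
                    d = int(rng.integers(7, 12))  # PL pattern still passes
                    calls[victim] = dataclasses.replace(
                        calls[victim], depth=d, pl=_pl_from_reads(d, 0)
                    )
                elif atype == "allelic_imbalance":
                    ds = calls[sire_id].depth + calls[dam_id].depth
                    hi = max(3, math.ceil(ds / 10))
                    d = int(rng.integers(2, hi))
                    n_alt = max(1, d // 2)
                    calls[offspring] = dataclasses.replace(
                        calls[offspring], depth=d, pl=_pl_from_reads(d - n_alt, n_alt)
                    )
                elif atype == "bad_pl":
                    victim = sire_id if rng.random() < 0.5 else dam_id
                    # weak hom-ref evidence: PL(AB) below the 20 gap while
                    # the called genotype stays AA
                    weak = (0, int(rng.integers(1, 20)), int(rng.integers(40, 90)))
                    calls[victim] = dataclasses.replace(calls[victim], pl=weak)
                elif atype == "high_softclip":
                    calls[offspring] = dataclasses.replace(
                        calls[offspring],
                        softclip_fraction=round(float(rng.uniform(0.12, 0.30)), 4),
                    )
                elif atype == "cohort_shared":
                    others = [o for o in cohort if o not in (sire_id, dam_id, offspring)]
                    if not others:
                        raise CapacityError(
                            "cohort too small for a shared-variant artifact"
                        )
                    sharer = others[rng.integers(0, len(others))]
                    calls[sharer] = _draw_call(rng, cfg, "AB")
                rec = emit(dataclasses.replace(rec, calls=calls))
                if atype == "in_database":
                    db_keys.add(rec.key)
                truth.artifact_keys[offspring][atype].add(rec.key)

    # --- caller-B private noise ------------------------------------------
    n_noise = int(rng.poisson(discord * (cfg.true_denovo_count * len(offspring_ids))))
    for _ in range(n_noise):
        offspring = offspring_ids[rng.integers(0, len(offspring_ids))]
        rec = normalize_variant(denovo_record(offspring, indel=False), genome)
        caller_b.add(rec)

    db = KnownVariantDatabase(
        keys=frozenset(db_keys), source_label="synthetic-goat-db", n_individuals=234
    )
    windows = simulate_coverage_windows(cfg, genome, rng=rng, truth=truth)
    for offspring, keys in truth.true_denovo_keys.items():
        overlap = (keys & truth.inherited_keys) | (keys & db.keys)
        if overlap:
            raise CapacityError(f"ground-truth collision at {sorted(overlap)[:3]}")
    return caller_a, caller_b, db, windows, truth


def simulate_coverage_windows(
    cfg: SimulationConfig,
    genome: GenomeSequence,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
    min_cov: float = 13.0,
    max_cov: float = 130.0,
) -> pd.DataFrame:
    """Per-window mean coverage, with a fraction forced out of bounds.

    Windows tile each chromosome; a final partial window is dropped.  Depths
    are gamma-distributed around ``mean_depth``; with probability
    ``coverage_outlier_fraction`` a window is forced outside
    [min_cov, max_cov] to exercise the effective-genome filter.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 2)
    rows = []
    n_in = 0
    for chrom, seq in genome.sequences.items():
        for start in range(0, len(seq) - cfg.window_size + 1, cfg.window_size):
            if rng.random() < cfg.coverage_outlier_fraction:
                depth = (
                    float(rng.uniform(0.0, min_cov - 0.5))
                    if rng.random() < 0.5
                    else float(rng.uniform(max_cov + 0.5, 2.0 * max_cov))
                )
            else:
                shape = 10.0
                depth = float(rng.gamma(shape, cfg.mean_depth / shape))
            depth = round(depth, 2)
            if min_cov <= depth <= max_cov:
                n_in += 1
            rows.append(
                {"chrom": chrom, "start": start, "end": start + cfg.window_size,
                 "mean_depth": depth}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth"])
    if truth is not None:
        truth.coverage_windows_total = len(df)
        truth.coverage_windows_in_bounds = n_in
    return df


# ---------------------------------------------------------------------------
# top-level convenience + file export
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig | None = None) -> CohortSim:
    """Generate a complete synthetic study from one seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    syn = simulate_genome(cfg, rng=rng)
    trios = default_pedigree(cfg)
    caller_a, caller_b, db, windows, truth = simulate_trio_callsets(
        cfg, syn, trios=trios, rng=rng
    )
    return CohortSim(
        config=cfg, synthetic_genome=syn, trios=trios,
        caller_a=caller_a, caller_b=caller_b, db=db, windows=windows, truth=truth,
    )


def write_cohort(sim: CohortSim, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "caller_a": outdir / "caller_a.vcf",
        "caller_b": outdir / "caller_b.vcf",
        "pedigree": outdir / "pedigree.tsv",
        "known_db": outdir / "known_db.tsv",
        "coverage": outdir / "coverage.tsv",
        "guides": outdir / "guides.tsv",
        "truth": outdir / "truth.tsv",
        "metadata": outdir / "metadata.yaml",
    }
    genome = sim.genome
    write_genome(paths["genome"], genome)
    lengths = {c: len(s) for c, s in genome.sequences.items()}
    cohort = list(sim.trios[0].cohort_ids)
    write_variants(paths["caller_a"], sim.caller_a, cohort, lengths, source="sim-callerA")
    write_variants(paths["caller_b"], sim.caller_b, cohort, lengths, source="sim-callerB")
    with open(paths["pedigree"], "w") as fh:
        fh.write("offspring\tsire\tdam\n")
        for t in sim.trios:
            fh.write(f"{t.offspring_id}\t{t.sire_id}\t{t.dam_id}\n")
    with open(paths["known_db"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(sim.db.keys):
            fh.write("\t".join(str(x) for x in key) + "\n")
    sim.windows.to_csv(paths["coverage"], sep="\t", index=False)
    with open(paths["guides"], "w") as fh:
        fh.write("name\tprotospacer\tpam_pattern\n")
        for g in sim.synthetic_genome.guides:
            fh.write(f"{g.name}\t{g.protospacer}\t{g.pam_pattern}\n")
    rows = []
    for off, keys in sim.truth.true_denovo_keys.items():
        for key in sorted(keys):
            rows.append({"category": "denovo", "sample": off, "detail": "",
                         "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3]})
    for off, per_type in sim.truth.artifact_keys.items():
        for atype, keys in per_type.items():
            for key in sorted(keys):
                rows.append({"category": "artifact", "sample": off, "detail": atype,
                             "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3]})
    if rows:
        write_table(paths["truth"], rows)
    meta = dataclasses.asdict(sim.config)
    meta["planted_offtarget_spec"] = [list(x) for x in sim.config.planted_offtarget_spec]
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump({"simulation_config": meta}, fh, sort_keys=True)
    return paths
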