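"""Domain types, standard-format readers/writers, and variant normalization.

Coordinates follow each format's native convention: variant positions are
1-based (VCF), genomic intervals are 0-based half-open (BED).  Conversion
happens only inside readers and writers.

Genotypes are expressed in the biallelic frame ``AA`` / ``AB`` / ``BB``
(A = reference allele, B = alternate allele) or ``missing``.  Multiallelic
VCF rows are split into biallelic records on read; the phred-scaled
genotype-likelihood (PL) triple of a split record is the diploid subset for
the (ref, alt) pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

GENOTYPES = ("AA", "AB", "BB", "missing")

#: decimal places kept for the soft-clip fraction (SCF) FORMAT field; VCF
#: floats travel as float32, so values are quantized for exact round trips
_SCF_DECIMALS = 4

# indel length gate: alternate/reference length difference, in bp, kept
# after normalization (1-bp indels and very long events are discarded)
INDEL_MIN_BP = 2
INDEL_MAX_BP = 100


class TrioMutError(Exception):
    """Base class for all package errors."""


class FormatError(TrioMutError):
    """A file violates its declared format."""


class ReferenceMismatchError(TrioMutError):
    """A variant's REF allele disagrees with the genome sequence."""


class ContigError(TrioMutError):
    """A record references a contig absent from the genome in use."""


class RoleError(TrioMutError):
    """A pedigree role cannot be resolved against the available samples."""


class PedigreeError(TrioMutError):
    """A pedigree file is internally inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A named reference genome held in memory.

    ``sequences`` maps chromosome name to uppercase DNA (A/C/G/T/N only);
    ``autosome_flags`` marks which chromosomes count toward autosomal
    analyses such as the effective-genome computation.
    """

    name: str
    sequences: Mapping[str, str]
    autosome_flags: Mapping[str, bool]

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for chrom, seq in self.sequences.items():
            if set(seq) - allowed:
                bad = sorted(set(seq) - allowed)
                raise FormatError(
                    f"contig {chrom!r} contains non-ACGTN characters: {bad}"
                )
            if chrom not in self.autosome_flags:
                raise FormatError(f"contig {chrom!r} has no autosome flag")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the subsequence for the 0-based half-open interval."""
        if chrom not in self.sequences:
            raise ContigError(f"unknown contig {chrom!r}")
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class SampleCall:
    """One sample's evidence at a biallelic site.

    ``pl`` is the normalized phred-scaled likelihood triple ordered
    (AA, AB, BB); ``softclip_fraction`` is the mean fraction of soft-clipped
    bases per read over reads covering the site, or ``None`` when unknown.
    """

    genotype: str
    depth: int
    pl: tuple[int, int, int] | None = None
    softclip_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.softclip_fraction is not None and not (
            0.0 <= self.softclip_fraction <= 1.0
        ):
            raise ValueError("softclip_fraction outside [0, 1]")

    @property
    def pl_normalized(self) -> bool:
        """True when the PL triple exists and its minimum is zero."""
        return self.pl is not None and min(self.pl) == 0


@dataclass(frozen=True)
class VariantRecord:
    """A normalized biallelic variant with per-sample calls.

    Identity (equality/hashing) is by the key ``(chrom, pos, ref, alt)``
    so that callset algebra ignores per-sample evidence.
    """

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    calls: Mapping[str, SampleCall] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not self.ref or not self.alt:
            raise ValueError("empty allele (records must be VCF-padded)")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vclass(self) -> str:
        """``SNV`` when both alleles are single bases, else ``INDEL``."""
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantRecord):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(frozen=True)
class TrioContext:
    """Pedigree roles bound to sample ids, plus the full cohort."""

    sire_id: str
    dam_id: str
    offspring_id: str
    cohort_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        roles = {self.sire_id, self.dam_id, self.offspring_id}
        if len(roles) != 3:
            raise PedigreeError(
                f"trio roles must be distinct: sire={self.sire_id} "
                f"dam={self.dam_id} offspring={self.offspring_id}"
            )
        missing = roles - set(self.cohort_ids)
        if missing:
            raise PedigreeError(f"trio members absent from cohort: {sorted(missing)}")

    @property
    def role_ids(self) -> tuple[str, str, str]:
        return (self.sire_id, self.dam_id, self.offspring_id)


@dataclass(frozen=True)
class KnownVariantDatabase:
    """A set of known-variant keys used to remove standing polymorphism."""

    keys: frozenset[tuple[str, int, str, str]]
    source_label: str = "known-db"
    n_individuals: int = 0

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_GT_TO_TUPLE = {"AA": (0, 0), "AB": (0, 1), "BB": (1, 1), "missing": (None, None)}


def _split_pl(pl: Sequence[int] | None, n_alleles: int, alt_index: int):
    """Diploid PL subset for the biallelic (ref, alt_index) pair.

    VCF orders diploid genotype likelihoods with index k(k+1)/2 + j for the
    allele pair (j, k), j <= k.
    """
    if pl is None:
        return None
    expected = n_alleles * (n_alleles + 1) // 2
    if len(pl) != expected:
        raise FormatError(
            f"PL arity {len(pl)} does not match {n_alleles} alleles "
            f"(expected {expected})"
        )
    a = alt_index
    idx = (0, a * (a + 1) // 2, a * (a + 1) // 2 + a)
    vals = tuple(pl[i] for i in idx)
    if any(v is None for v in vals):
        return None
    return tuple(int(v) for v in vals)


def _genotype_from_gt(alleles: tuple, alt_index: int) -> str:
    if alleles is None or any(a is None for a in alleles) or len(alleles) != 2:
        return "missing"
    if not set(alleles) <= {0, alt_index}:
        # carries a third allele: undefined in this biallelic frame
        return "missing"
    n_alt = sum(1 for a in alleles if a == alt_index)
    return ("AA", "AB", "BB")[n_alt]


def read_variants(path: str | Path, caller_label: str = "") -> set[VariantRecord]:
    """Read a VCF into a set of biallelic :class:`VariantRecord`.

    Multiallelic rows are split into one record per alternate allele.
    SNVs and indels with a length difference of 2-100 bp are kept; other
    records (1-bp indels, MNPs, symbolic alleles, oversized events) are
    dropped.  An optional FORMAT field ``SCF`` carries the per-sample
    soft-clip fraction.
    """
    records: set[VariantRecord] = set()
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        has_scf = "SCF" in vcf.header.formats
        for row_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            if rec.alts is None:
                continue
            n_alleles = 1 + len(rec.alts)
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or alt.startswith("<") or "*" in alt:
                    continue
                ref = rec.ref.upper()
                alt = alt.upper()
                if ref == alt:
                    continue
                is_snv = len(ref) == 1 and len(alt) == 1
                diff = abs(len(ref) - len(alt))
                if not is_snv and not (
                    len(ref) != len(alt) and INDEL_MIN_BP <= diff <= INDEL_MAX_BP
                ):
                    continue
                calls: dict[str, SampleCall] = {}
                for sample in samples:
                    sv = rec.samples[sample]
                    try:
                        gt = sv.get("GT")
                        pl = _split_pl(sv.get("PL"), n_alleles, alt_index)
                    except FormatError as exc:
                        raise FormatError(
                            f"{path}: record {row_no} ({rec.chrom}:{rec.pos}): {exc}"
                        ) from exc
                    dp = sv.get("DP")
                    scf = sv.get("SCF") if has_scf else None
                    if isinstance(scf, tuple):
                        scf = scf[0] if scf else None
                    calls[sample] = SampleCall(
                        genotype=_genotype_from_gt(gt, alt_index),
                        depth=int(dp) if dp is not None else 0,
                        pl=pl,
                        softclip_fraction=(
                            round(float(scf), _SCF_DECIMALS) if scf is not None else None
                        ),
                    )
                records.add(
                    VariantRecord(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, calls=calls)
                )
    return records


def write_variants(
    path: str | Path,
    variants: Iterable[VariantRecord],
    sample_ids: Sequence[str],
    contig_lengths: Mapping[str, int],
    source: str = "triomut",
) -> None:
    """Write records as an uncompressed VCF 4.2 with GT/DP/PL/SCF fields.

    Output is sorted by (chrom, pos, ref, alt) for determinism.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##source={source}")
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    header.formats.add(
        "SCF", 1, "Float", "Mean soft-clipped fraction per read over the site"
    )
    for sid in sample_ids:
        header.add_sample(sid)
    order = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (order.get(v.chrom, 1 << 30), v.pos, v.ref, v.alt)):
            if v.chrom not in contig_lengths:
                raise ContigError(f"variant contig {v.chrom!r} not in header contigs")
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for sid in sample_ids:
                call = v.calls.get(sid)
                sv = rec.samples[sid]
                if call is None:
                    sv["GT"] = (None, None)
                    continue
                sv["GT"] = _GT_TO_TUPLE[call.genotype]
                sv["DP"] = call.depth
                if call.pl is not None:
                    sv["PL"] = list(call.pl)
                if call.softclip_fraction is not None:
                    sv["SCF"] = round(call.softclip_fraction, _SCF_DECIMALS)
            out.write(rec)


# ---------------------------------------------------------------------------
# normalization and callset algebra
# ---------------------------------------------------------------------------


def normalize_variant(v: VariantRecord, genome: GenomeSequence) -> VariantRecord:
    """Left-align and parsimony-trim an indel against the reference genome.

    SNVs are returned unchanged.  The operation is idempotent, so two VCF
    spellings of one indel map to a single key.
    """
    if v.chrom not in genome.sequences:
        raise ContigError(f"variant contig {v.chrom!r} not in genome {genome.name!r}")
    seq = genome.sequences[v.chrom]
    if seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} REF {v.ref!r} does not match genome "
            f"{seq[v.pos - 1 : v.pos - 1 + len(v.ref)]!r}"
        )
    if v.vclass == "SNV":
        return v
    ref, alt, pos = v.ref, v.alt, v.pos
    # right-trim shared trailing bases, extending left from the reference
    # whenever an allele would become empty
    while ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                ref, alt = seq[pos - 1] + ref, seq[pos - 1] + alt  # pragma: no cover
                break
            pos -= 1
            base = seq[pos - 1]
            ref, alt = base + ref, base + alt
    # left-trim shared leading bases
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return dataclasses.replace(v, chrom=v.chrom, pos=pos, ref=ref, alt=alt)


def intersect_callsets(
    a: set[VariantRecord],
    b: set[VariantRecord],
    genome: GenomeSequence | None = None,
) -> set[VariantRecord]:
    """Keys present in both callsets; per-sample calls taken from ``a``.

    When ``genome`` is given, any record naming an unknown contig raises
    :class:`ContigError` (a guard against intersecting callsets normalized
    to different references).
    """
    if genome is not None:
        for rec in list(a) + list(b):
            if rec.chrom not in genome.sequences:
                raise ContigError(
                    f"callset contig {rec.chrom!r} not in genome {genome.name!r}"
                )
    keys_b = {v.key for v in b}
    return {v for v in a if v.key in keys_b}


# ---------------------------------------------------------------------------
# FASTA / tables
# ---------------------------------------------------------------------------

_NON_AUTOSOME_NAMES = {"X", "Y", "M", "MT", "W", "Z"}


def infer_autosome_flag(chrom: str) -> bool:
    """Heuristic autosome flag: sex/mitochondrial names are non-autosomal."""
    stripped = chrom.removeprefix("chr").removeprefix("Chr").upper()
    return stripped not in _NON_AUTOSOME_NAMES


def read_genome(
    path: str | Path,
    name: str | None = None,
    autosome_flags: Mapping[str, bool] | None = None,
) -> GenomeSequence:
    """Load a FASTA into memory, inferring autosome flags from names."""
    sequences: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            if entry.name in sequences:
                raise FormatError(f"{path}: duplicate contig {entry.name!r}")
            sequences[entry.name] = entry.sequence.upper()
    flags = {
        chrom: (
            autosome_flags[chrom]
            if autosome_flags and chrom in autosome_flags
            else infer_autosome_flag(chrom)
        )
        for chrom in sequences
    }
    return GenomeSequence(
        name=name or Path(path).stem, sequences=sequences, autosome_flags=flags
    )


def write_genome(path: str | Path, genome: GenomeSequence, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pedigree(
    path: str | Path, cohort_ids: Sequence[str] | None = None
) -> list[TrioContext]:
    """Read a tab-separated pedigree (offspring, sire, dam; optional header).

    The cohort defaults to every id mentioned in the file.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: expected >=3 columns")
            if line_no == 1 and fields[0].lower() in {"offspring", "child", "id"}:
                continue
            rows.append((fields[0], fields[1], fields[2]))
    if not rows:
        raise FormatError(f"{path}: no pedigree rows")
    if cohort_ids is None:
        cohort: list[str] = []
        for off, sire, dam in rows:
            for sid in (sire, dam, off):
                if sid not in cohort:
                    cohort.append(sid)
        cohort_ids = cohort
    trios = []
    for off, sire, dam in rows:
        if off in (sire, dam):
            raise PedigreeError(f"{path}: offspring {off!r} listed as its own parent")
        trios.append(
            TrioContext(
                sire_id=sire, dam_id=dam, offspring_id=off, cohort_ids=tuple(cohort_ids)
            )
        )
    return trios


def read_known_db(
    path: str | Path, source_label: str = "known-db", n_individuals: int = 0
) -> KnownVariantDatabase:
    """Read known-variant keys from a VCF or a 4-column TSV (chrom pos ref alt)."""
    keys: set[tuple[str, int, str, str]] = set()
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        with pysam.VariantFile(p) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if alt and not alt.startswith("<"):
                        keys.add((rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
    else:
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(f"{path}:{line_no}: expected 4 columns")
                if line_no == 1 and fields[0].lower() in {"chrom", "chr", "#chrom"}:
                    continue
                try:
                    pos = int(fields[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{line_no}: bad position {fields[1]!r}") from exc
                keys.add((fields[0], pos, fields[2].upper(), fields[3].upper()))
    return KnownVariantDatabase(
        keys=frozenset(keys), source_label=source_label, n_individuals=n_individuals
    )


def write_table(path: str | Path, rows: Iterable[Mapping[str, object]]) -> None:
    """Write dict rows as a tab-separated table with a header line."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    columns = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
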