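"""Kinship-based pedigree validation.

Before trusting a declared trio, pairwise kinship coefficients are
estimated from cohort genotypes with the within-pair robust estimator
(the KING-robust family), which needs no allele-frequency estimates:

    phi_hat = (N_het,het - 2 * N_opp_hom) / (N_het_i + N_het_j)

where N_het,het counts sites at which both samples are heterozygous,
N_opp_hom counts opposite homozygotes, and the denominator sums each
sample's heterozygous-site counts over the shared non-missing sites.
Expected values: ~0.5 for duplicates, ~0.25 for parent-offspring, ~0.125
for half-siblings, ~0 for unrelated pairs.  The estimator is invariant to
allele-label flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from triomut.core_io import TrioContext, VariantRecord

_DOSAGE = {"AA": 0, "AB": 1, "BB": 2, "missing": -1}

#: first-degree relationship window (powers-of-two inference bins)
FIRST_DEGREE_BOUNDS = (0.177, 0.354)


@dataclass
class KinshipMatrix:
    """Pairwise kinship estimates with per-pair informative-site counts."""

    sample_ids: tuple[str, ...]
    phi: pd.DataFrame
    n_sites: pd.DataFrame

    def get(self, a: str, b: str) -> float:
        return float(self.phi.loc[a, b])


def genotype_matrix(
    variants: Iterable[VariantRecord], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Sites x samples dosage matrix (0/1/2 alt copies; NaN missing)."""
    rows = []
    index = []
    for v in variants:
        index.append(f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}")
        row = []
        for sid in sample_ids:
            call = v.calls.get(sid)
            d = _DOSAGE[call.genotype] if call is not None else -1
            row.append(np.nan if d < 0 else d)
        rows.append(row)
    return pd.DataFrame(rows, index=index, columns=list(sample_ids))


def kinship(genotypes: pd.DataFrame, min_informative: int = 100) -> KinshipMatrix:
    """Robust pairwise kinship from a sites x samples dosage matrix.

    Pairs with no shared non-missing sites get NaN with a warning; pairs
    below ``min_informative`` shared sites are estimated but warned about.
    Self-kinship is reported as 0.5 by convention.
    """
    samples = list(genotypes.columns)
    g = genotypes.to_numpy(dtype=float)
    n = len(samples)
    phi = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    np.fill_diagonal(phi, 0.5)
    for i in range(n):
        counts[i, i] = int(np.sum(~np.isnan(g[:, i])))
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = g[:, i], g[:, j]
            both = ~np.isnan(gi) & ~np.isnan(gj)
            m = int(both.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                warnings.warn(
                    f"no shared genotyped sites for pair ({samples[i]}, {samples[j]})",
                    stacklevel=2,
                )
                continue
            if m < min_informative:
                warnings.warn(
                    f"only {m} shared sites for pair ({samples[i]}, {samples[j]}); "
                    "kinship estimate is unreliable",
                    stacklevel=2,
                )
            a, b = gi[both], gj[both]
            n_hh = int(np.sum((a == 1) & (b == 1)))
            n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
            n_het = int(np.sum(a == 1)) + int(np.sum(b == 1))
            if n_het == 0:
                continue
            phi[i, j] = phi[j, i] = (n_hh - 2 * n_opp) / n_het
    return KinshipMatrix(
        sample_ids=tuple(samples),
        phi=pd.DataFrame(phi, index=samples, columns=samples),
        n_sites=pd.DataFrame(counts, index=samples, columns=samples),
    )


@dataclass
class TrioValidation:
    """Per-trio pedigree check: both parent links must look first-degree."""

    trio: TrioContext
    sire_offspring_phi: float
    dam_offspring_phi: float
    sire_dam_phi: float
    status: str  # pass | warn | fail | inconclusive
    messages: tuple[str, ...] = ()


def validate_trio(
    matrix: KinshipMatrix,
    trio: TrioContext,
    first_degree_bounds: tuple[float, float] = FIRST_DEGREE_BOUNDS,
    max_parental_kinship: float | None = None,
) -> TrioValidation:
    """Check both parent-offspring links against the first-degree window.

    The sire-dam kinship is reported and, when ``max_parental_kinship`` is
    unset, only warned about when elevated (related matings occur in edited
    herds and are not a pedigree error by themselves).
    """
    for sid in trio.role_ids:
        if sid not in matrix.sample_ids:
            raise KeyError(f"sample {sid!r} absent from kinship matrix")
    lo, hi = first_degree_bounds
    po1 = matrix.get(trio.sire_id, trio.offspring_id)
    po2 = matrix.get(trio.dam_id, trio.offspring_id)
    pp = matrix.get(trio.sire_id, trio.dam_id)
    messages = []
    if np.isnan(po1) or np.isnan(po2):
        return TrioValidation(
            trio=trio, sire_offspring_phi=po1, dam_offspring_phi=po2,
            sire_dam_phi=pp, status="inconclusive",
            messages=("missing kinship entry for a parent-offspring pair",),
        )
    status = "pass"
    if not (lo <= po1 <= hi):
        status = "fail"
        messages.append(
            f"sire-offspring kinship {po1:.3f} outside first-degree window [{lo}, {hi}]"
        )
    if not (lo <= po2 <= hi):
        status = "fail"
        messages.append(
            f"dam-offspring kinship {po2:.3f} outside first-degree window [{lo}, {hi}]"
        )
    if max_parental_kinship is not None and not np.isnan(pp) and pp > max_parental_kinship:
        status = "fail"
        messages.append(f"sire-dam kinship {pp:.3f} above {max_parental_kinship}")
    elif not np.isnan(pp) and pp > hi and status == "pass":
        status = "warn"
        messages.append(f"sire-dam kinship {pp:.3f} is elevated (related mating?)")
    return TrioValidation(
        trio=trio, sire_offspring_phi=po1, dam_offspring_phi=po2,
        sire_dam_phi=pp, status=status, messages=tuple(messages),
    )
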