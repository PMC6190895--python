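"""Independent brute-force off-target oracle used only by tests.

A plain per-position sliding-window scan, deliberately sharing no code
with the package's vectorized search.  The PAM is checked first purely as
an early exit; the mismatch count is a character-by-character comparison.
"""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def brute_force_sites(genome_sequences: dict[str, str], guide) -> list[tuple]:
    """All (chrom, start, strand, mm_total, mm_seed) qualifying windows."""
    proto = guide.protospacer
    seed_start = 20 - guide.seed_length
    hits = []
    for chrom, seq in genome_sequences.items():
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else _rc(seq)
            for i in range(L - 22):
                pam = s[i + 20 : i + 23]
                if any(
                    p == "N" or p not in IUPAC[c]
                    for p, c in zip(pam, guide.pam_pattern)
                ):
                    continue
                win = s[i : i + 20]
                mm = sum(1 for a, b in zip(win, proto) if a != b)
                if mm > guide.max_mismatch_total:
                    continue
                ms = sum(
                    1
                    for a, b in zip(win[seed_start:], proto[seed_start:])
                    if a != b
                )
                if ms > guide.max_seed_mismatch:
                    continue
                start = i if strand == "+" else L - (i + 20)
                hits.append((chrom, start, strand, mm, ms))
    return sorted(hits)
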