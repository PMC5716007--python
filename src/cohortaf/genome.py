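"""Chromosome naming and pseudoautosomal-region conventions.

All positions in the package are 1-based (VCF convention); BED input is
converted at the parsing boundary. PAR defaults are the GRCh37 PAR1/PAR2
spans on X; SNPs inside them are carried in two copies by males and are
therefore treated as autosomal for allele counting and excluded from sex
inference.
"""

from __future__ import annotations

#: GRCh37 X-chromosome pseudoautosomal intervals, 1-based inclusive.
PAR_X_GRCH37: tuple[tuple[int, int], ...] = (
    (60_001, 2_699_520),
    (154_931_044, 155_260_560),
)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"


def normalise_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and upper-case X/Y/MT labels."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.lower() in ("x", "y", "mt", "m") else c


def is_x(chrom: str) -> bool:
    return normalise_chrom(chrom) == "X"


def is_y(chrom: str) -> bool:
    return normalise_chrom(chrom) == "Y"


def in_par(
    chrom: str, pos: int, par_intervals: tuple[tuple[int, int], ...] = PAR_X_GRCH37
) -> bool:
    """True when an X-chromosome position lies in a pseudoautosomal region."""
    if not is_x(chrom):
        return False
    return any(start <= pos <= end for start, end in par_intervals)
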