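"""Restrict significant SNPs to protein-altering consequences.

Alleles expected to underlie highly penetrant, environmentally
triggered phenotypes should unequivocally alter the protein: nonsense,
start-loss, stop-loss, canonical splice-site changes (the +/-2 intronic
dinucleotides), and missense changes predicted damaging by an external
tool. The prediction is consumed as a boolean annotation column, never
computed here. Users wanting every SNP can bypass the filter.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .catalogue import SNP_KEY

logger = logging.getLogger(__name__)

NONSENSE = "nonsense"
START_LOST = "start_lost"
STOP_LOST = "stop_lost"
CANONICAL_SPLICE = "canonical_splice"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
OTHER = "other"

CONSEQUENCES = frozenset(
    {NONSENSE, START_LOST, STOP_LOST, CANONICAL_SPLICE, MISSENSE, SYNONYMOUS, OTHER}
)

#: Consequences retained unconditionally (missense needs damaging_flag).
ALWAYS_ALTERING = frozenset({NONSENSE, START_LOST, STOP_LOST, CANONICAL_SPLICE})

ANNOTATION_COLUMNS = ["chrom", "pos", "rare_allele", "consequence", "damaging_flag", "gene"]


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read a consequence-annotation TSV keyed by (chrom, pos, rare_allele)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "rare_allele": str, "consequence": str, "gene": str},
    )
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    df["damaging_flag"] = df["damaging_flag"].astype(bool)
    _validate_consequences(df)
    return df[ANNOTATION_COLUMNS]


def _validate_consequences(annotations: pd.DataFrame) -> None:
    unknown = set(annotations["consequence"]) - CONSEQUENCES
    if unknown:
        raise ValueError(
            f"unknown consequence value(s): {sorted(unknown)}; "
            f"expected one of {sorted(CONSEQUENCES)}"
        )


def filter_protein_altering(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    include_all: bool = False,
) -> pd.DataFrame:
    """Keep only SNPs that unequivocally alter the protein.

    Retained: nonsense, start_lost, stop_lost, canonical_splice, and
    missense with ``damaging_flag``. SNPs without an annotation are
    dropped with a logged count. ``include_all=True`` bypasses the
    filter entirely and returns the input (annotations merged where
    available).
    """
    _validate_consequences(annotations)
    merged = results.merge(
        annotations[ANNOTATION_COLUMNS], on=SNP_KEY, how="left"
    )
    if include_all:
        return merged
    unannotated = merged["consequence"].isna()
    if unannotated.any():
        logger.info(
            "consequence filter: dropped %d unannotated SNP(s)",
            int(unannotated.sum()),
        )
    keep = merged["consequence"].isin(ALWAYS_ALTERING) | (
        (merged["consequence"] == MISSENSE) & merged["damaging_flag"].eq(True)
    )
    return merged[keep].reset_index(drop=True)
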