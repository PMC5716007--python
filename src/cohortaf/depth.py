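"""Per-base sequencing depth checks and exon/gene coverage census.

Below about 20 reads a site cannot reliably distinguish heterozygous
from homozygous genotypes, so calls at under-covered sites are demoted
to ``unknown`` rather than contributing alleles. The census summarises,
per exon and per gene, how much of the exome reaches that depth — which
genes' SNPs an exome cohort can be expected to interrogate at all.

Depth input is a 3-column table (chrom, 1-based position, depth), the
dialect emitted by ``samtools depth``; positions absent from the table
count as depth 0.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome
from .cohort_io import STATUS_UNKNOWN, Sample

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_CUTOFF = 20

EXON_COLUMNS = ["gene", "exon_id", "chrom", "start", "end", "mean_depth", "fraction_ge_cutoff", "cutoff"]
GENE_COLUMNS = ["gene", "mean_depth", "adequately_covered"]


class DepthTable:
    """Per-base depths for one sample, keyed by (chrom, 1-based pos)."""

    def __init__(self, depths: dict[tuple[str, int], int]):
        self._depths = depths

    @classmethod
    def load(cls, path: str | Path) -> "DepthTable":
        """Load a chrom/pos/depth TSV (headerless or with a header line)."""
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=["chrom", "pos", "depth"],
                dtype={"chrom": str},
                comment="#",
            )
        except Exception as exc:
            raise OSError(f"cannot read depth table {path}") from exc
        # tolerate a header line
        if len(df) and not str(df.iloc[0]["pos"]).lstrip("-").isdigit():
            df = df.iloc[1:]
        depths = {
            (genome.normalise_chrom(c), int(p)): int(d)
            for c, p, d in zip(df["chrom"], df["pos"], df["depth"])
        }
        return cls(depths)

    def get(self, chrom: str, pos: int) -> int | None:
        """Depth at a site, or None when the position is absent (depth 0)."""
        return self._depths.get((genome.normalise_chrom(chrom), int(pos)))

    def __len__(self) -> int:
        return len(self._depths)


def site_depth(source: DepthTable | Sample, chrom: str, pos: int) -> int | None:
    """Per-base depth at (chrom, pos); None when absent (treat as 0)."""
    table = _as_table(source)
    return table.get(chrom, pos)


def _as_table(source: DepthTable | Sample) -> DepthTable:
    if isinstance(source, DepthTable):
        return source
    if source.depth_path is None:
        raise ValueError(f"sample {source.sample_id} has no depth source")
    return DepthTable.load(source.depth_path)


def apply_depth_filter(
    calls: pd.DataFrame,
    samples: list[Sample],
    cutoff: int = DEFAULT_DEPTH_CUTOFF,
) -> tuple[pd.DataFrame, int]:
    """Demote calls at under-covered sites to ``unknown``.

    Any call (``called`` or ``ref_assumed``) whose site depth is below
    ``cutoff`` in its sample's depth table becomes ``unknown``; missing
    positions count as depth 0. Samples without a depth source are left
    untouched. Idempotent. Returns the updated frame and the number of
    demoted calls.
    """
    calls = calls.copy()
    tables = {
        s.sample_id: _as_table(s) for s in samples if s.depth_path is not None
    }
    n_demoted = 0
    for sample_id, table in tables.items():
        mask = (calls["sample_id"] == sample_id) & (calls["status"] != STATUS_UNKNOWN)
        idx = calls.index[mask]
        if not len(idx):
            continue
        depths = np.array(
            [
                table.get(c, p) or 0
                for c, p in zip(calls.loc[idx, "chrom"], calls.loc[idx, "pos"])
            ]
        )
        low = idx[depths < cutoff]
        calls.loc[low, "status"] = STATUS_UNKNOWN
        calls.loc[low, "rare_count"] = 0
        n_demoted += len(low)
    if n_demoted:
        logger.info("depth filter: demoted %d calls below %dx", n_demoted, cutoff)
    return calls, n_demoted


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read exon definitions: BED (0-based half-open) with gene and exon id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "exon_id"],
        dtype={"chrom": str, "gene": str, "exon_id": str},
        comment="#",
    )
    if len(df) and not str(df.iloc[0]["start"]).isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def exon_coverage_census(
    depth_tables: dict[str, DepthTable],
    exons: pd.DataFrame,
    cutoff: int = DEFAULT_DEPTH_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-exon and per-gene coverage over one or more samples.

    For each exon: mean depth over all (base, sample) pairs and the
    fraction of those pairs at or above ``cutoff``. For each gene: mean
    depth over the union of its exonic bases (bases shared by
    overlapping exons counted once), flagged ``adequately_covered`` when
    the mean strictly exceeds ``cutoff - 1`` (>19 reads at the default).

    Returns (exon frame, gene frame, summary dict with the
    adequately-covered gene fraction).
    """
    if not depth_tables:
        raise ValueError("at least one depth source is required")
    tables = list(depth_tables.values())

    def base_depths(chrom: str, start: int, end: int) -> np.ndarray:
        # rows: samples, cols: bases (1-based positions start+1..end)
        return np.array(
            [
                [t.get(chrom, pos) or 0 for pos in range(start + 1, end + 1)]
                for t in tables
            ],
            dtype=float,
        )

    exon_rows = []
    gene_bases: dict[str, set[tuple[str, int]]] = {}
    for row in exons.itertuples(index=False):
        d = base_depths(row.chrom, row.start, row.end)
        exon_rows.append(
            {
                "gene": row.gene,
                "exon_id": row.exon_id,
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "mean_depth": float(d.mean()),
                "fraction_ge_cutoff": float((d >= cutoff).mean()),
                "cutoff": cutoff,
            }
        )
        gene_bases.setdefault(row.gene, set()).update(
            (genome.normalise_chrom(row.chrom), pos)
            for pos in range(row.start + 1, row.end + 1)
        )

    gene_rows = []
    for gene, bases in sorted(gene_bases.items()):
        depths = np.array(
            [[t.get(c, p) or 0 for (c, p) in sorted(bases)] for t in tables],
            dtype=float,
        )
        mean = float(depths.mean())
        gene_rows.append(
            {
                "gene": gene,
                "mean_depth": mean,
                "adequately_covered": mean > cutoff - 1,
            }
        )

    exon_df = pd.DataFrame(exon_rows, columns=EXON_COLUMNS)
    gene_df = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    n_genes = len(gene_df)
    n_adequate = int(gene_df["adequately_covered"].sum()) if n_genes else 0
    summary = {
        "n_genes": n_genes,
        "n_adequately_covered": n_adequate,
        "fraction_adequately_covered": n_adequate / n_genes if n_genes else 0.0,
        "cutoff": cutoff,
    }
    return exon_df, gene_df, summary
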