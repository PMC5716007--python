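"""Reference SNP frequency catalogues.

A catalogue assigns each SNP a *rare-allele* frequency in a reference
population (e.g. a continental subset of a large sequencing project).
Cohort allele frequencies are later tested against these expectations,
so the catalogue also fixes the universe of sites that are examined and
the multiple-testing denominator.

Catalogues are held as :class:`pandas.DataFrame` objects with the columns
in :data:`CATALOGUE_COLUMNS`; :class:`CatalogueEntry` is the per-row view
used for validation and record-level work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of a catalogue frame.
CATALOGUE_COLUMNS = [
    "chrom",
    "pos",
    "snp_id",
    "ref_allele",
    "rare_allele",
    "rare_freq",
    "allele_number",
    "source",
]

#: Columns identifying one catalogue site-allele.
SNP_KEY = ["chrom", "pos", "rare_allele"]


@dataclass(frozen=True)
class CatalogueEntry:
    """One reference SNP with its population rare-allele frequency.

    Parameters
    ----------
    chrom, pos
        Chromosome label and 1-based position (VCF convention).
    snp_id
        rsID or synthetic identifier.
    ref_allele, rare_allele
        Reference and rare (lower-frequency) allele sequences.
    rare_freq
        Rare-allele fraction in the reference population, in [0, 0.5]
        after normalisation.
    allele_number
        Number of alleles the catalogue counted at this site (optional;
        enables the two-sample test mode).
    source
        Catalogue label, e.g. ``"1000G-EUR"``.
    """

    chrom: str
    pos: int
    snp_id: str
    ref_allele: str
    rare_allele: str
    rare_freq: float
    allele_number: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_freq <= 1.0:
            raise ValueError(
                f"rare_freq {self.rare_freq} outside [0, 1] for {self.snp_id}"
            )
        if self.allele_number is not None and self.allele_number <= 0:
            raise ValueError(f"allele_number must be > 0 for {self.snp_id}")


@dataclass(frozen=True)
class CatalogueComparison:
    """Result of comparing two catalogues over their shared SNPs."""

    n_shared: int
    n_discordant: int
    threshold: float
    discordant_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def discordant_fraction(self) -> float:
        """Fraction of shared SNPs whose frequencies disagree."""
        return self.n_discordant / self.n_shared if self.n_shared else 0.0


def _looks_like_vcf(path: Path) -> bool:
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return True
    try:
        opener = open(path, "rb")
        with opener as fh:
            head = fh.read(2)
            if head == b"\x1f\x8b":  # bgzip
                return True
            rest = fh.read(14)
        return (head + rest).startswith(b"##fileformat=VCF")
    except OSError:
        return False


def _normalise_frame(df: pd.DataFrame, source_label: str) -> pd.DataFrame:
    """Validate invariants and orient every row to the rare allele."""
    bad = df[(df["rare_freq"] < 0) | (df["rare_freq"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"catalogue frequency {row['rare_freq']} outside [0, 1] "
            f"at {row['chrom']}:{row['pos']} ({row['snp_id']})"
        )
    flip = df["rare_freq"] > 0.5
    if flip.any():
        logger.warning(
            "%d catalogue rows had rare_freq > 0.5; alleles swapped and "
            "frequency flipped to 1 - f",
            int(flip.sum()),
        )
        df = df.copy()
        ref = df.loc[flip, "ref_allele"].copy()
        df.loc[flip, "ref_allele"] = df.loc[flip, "rare_allele"]
        df.loc[flip, "rare_allele"] = ref
        df.loc[flip, "rare_freq"] = 1.0 - df.loc[flip, "rare_freq"]
    df["source"] = source_label
    dup = df.duplicated(subset=SNP_KEY)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate catalogue entry {row['chrom']}:{row['pos']} "
            f"allele {row['rare_allele']} in source {source_label!r}"
        )
    return df.reset_index(drop=True)[CATALOGUE_COLUMNS]


def _load_tsv(path: Path, source_label: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_an = len(header) >= 7
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                pos = int(parts[1])
                freq = float(parts[5])
                an = int(parts[6]) if has_an and len(parts) > 6 and parts[6] else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable number: {exc}") from exc
            rows.append(
                {
                    "chrom": parts[0],
                    "pos": pos,
                    "snp_id": parts[2],
                    "ref_allele": parts[3],
                    "rare_allele": parts[4],
                    "rare_freq": freq,
                    "allele_number": an,
                }
            )
    return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS[:-1])


def _load_vcf(
    path: Path,
    source_label: str,
    af_key: str,
    an_key: str,
    evs_lowest_allele: bool,
) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows: list[dict] = []
    n_missing_af = 0
    vcf = VCF(str(path))
    try:
        for variant in vcf:
            af = variant.INFO.get(af_key)
            if af is None:
                n_missing_af += 1
                continue
            afs = list(af) if isinstance(af, (tuple, list, np.ndarray)) else [af]
            alts = variant.ALT
            if len(afs) != len(alts):
                raise ValueError(
                    f"{path}: {variant.CHROM}:{variant.POS}: {len(alts)} ALT "
                    f"alleles but {len(afs)} {af_key} values"
                )
            an = variant.INFO.get(an_key)
            pairs = list(zip(alts, (float(a) for a in afs)))
            if evs_lowest_allele and len(pairs) > 1:
                # Compatibility mode replicating a known historical defect of
                # one upstream catalogue's parser: only the lowest-frequency
                # alternate allele of a multi-allelic site is recorded.
                pairs = [min(pairs, key=lambda p: p[1])]
            for alt, freq in pairs:
                rows.append(
                    {
                        "chrom": variant.CHROM,
                        "pos": variant.POS,
                        "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}:{alt}",
                        "ref_allele": variant.REF,
                        "rare_allele": alt,
                        "rare_freq": freq,
                        "allele_number": int(an) if an is not None else None,
                    }
                )
    finally:
        vcf.close()
    if n_missing_af:
        logger.info(
            "%s: dropped %d sites with no %s INFO field", path, n_missing_af, af_key
        )
    return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS[:-1])


def load_catalogue(
    path: str | Path,
    source_label: str,
    *,
    af_key: str = "AF",
    an_key: str = "AN",
    evs_lowest_allele: bool = False,
) -> pd.DataFrame:
    """Load a reference frequency catalogue from TSV or sites-VCF.

    Multi-allelic VCF sites are expanded to one entry per alternate
    allele, each with its own frequency (``evs_lowest_allele=True``
    instead keeps only the lowest-frequency alternate, replicating a
    historical catalogue parser defect for fidelity testing). Rows whose
    frequency exceeds 0.5 are re-oriented (alleles swapped, f -> 1-f)
    with a warning: the catalogued first allele is normally the commoner
    one, so a larger value indicates a swapped row. Sites without a
    frequency are dropped and counted in the log.

    Parameters
    ----------
    path
        Catalogue file: tab-separated (header line; columns chrom, pos,
        id, ref, alt, rare_freq, optional allele_number) or VCF 4.x with
        an allele-frequency INFO key.
    source_label
        Name recorded in the ``source`` column (e.g. ``"1000G-EUR"``).
    af_key, an_key
        INFO keys for allele frequency and total allele number (VCF input).

    Returns
    -------
    pandas.DataFrame
        Validated catalogue with columns :data:`CATALOGUE_COLUMNS`.
    """
    path = Path(path)
    if _looks_like_vcf(path):
        df = _load_vcf(path, source_label, af_key, an_key, evs_lowest_allele)
    else:
        df = _load_tsv(path, source_label)
    if df.empty:
        df = pd.DataFrame(columns=CATALOGUE_COLUMNS[:-1])
    df["pos"] = df["pos"].astype(np.int64) if len(df) else df.get("pos", pd.Series(dtype=np.int64))
    return _normalise_frame(df, source_label)


def write_catalogue(catalogue: pd.DataFrame, path: str | Path) -> None:
    """Write a catalogue frame as the tab-separated interchange format."""
    out = catalogue[CATALOGUE_COLUMNS[:-1]].copy()
    out.columns = ["chrom", "pos", "id", "ref", "alt", "rare_freq", "allele_number"]
    an = out["allele_number"]
    out["allele_number"] = an.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def compare_catalogues(
    a: pd.DataFrame, b: pd.DataFrame, threshold: float = 0.05
) -> CatalogueComparison:
    """Compare rare-allele frequencies of two catalogues over shared SNPs.

    SNPs are matched by (chrom, pos, rare_allele). A shared SNP is
    *discordant* when the absolute frequency difference strictly exceeds
    ``threshold``; a difference of exactly ``threshold`` is concordant.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    merged = a.merge(b, on=SNP_KEY, suffixes=("_a", "_b"))
    delta = (merged["rare_freq_a"] - merged["rare_freq_b"]).abs()
    discordant = merged[delta > threshold]
    return CatalogueComparison(
        n_shared=len(merged),
        n_discordant=len(discordant),
        threshold=threshold,
        discordant_ids=tuple(discordant["snp_id_a"]),
    )
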