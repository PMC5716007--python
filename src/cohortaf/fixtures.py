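"""Synthetic cohorts with known ground truth.

Generates everything the pipeline consumes — a reference catalogue
(TSV and sites-VCF), one variant-calling VCF per sample, per-base depth
tables, an exon BED, consequence annotations — plus the generating
truth, so that every stage can be verified offline against known
frequencies.

What is emulated: per-individual sites-only VCFs over a shared SNP
catalogue; sex-consistent X genotypes (males are hemizygous outside the
pseudoautosomal regions and can never be heterozygous there); missing
genotypes backed by low sequencing depth; a null cohort drawn at the
catalogue frequencies with optional *spiked* SNPs whose cohort
frequency deviates by construction. What is not emulated: linkage
disequilibrium, read-level errors, batch effects between capture kits.

All randomness flows from ``FixtureSpec.seed``; the same spec writes
byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome
from .catalogue import CATALOGUE_COLUMNS, write_catalogue
from .cohort_io import (
    CALL_COLUMNS,
    STATUS_CALLED,
    STATUS_REF_ASSUMED,
    STATUS_UNKNOWN,
    Sample,
)
from .consequence import (
    ANNOTATION_COLUMNS,
    CANONICAL_SPLICE,
    MISSENSE,
    NONSENSE,
    OTHER,
    SYNONYMOUS,
)
from .frequency import ploidy

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Spike:
    """A SNP whose cohort frequency deliberately departs from the catalogue."""

    cohort_freq: float
    catalogue_freq: float
    consequence: str = NONSENSE
    damaging_flag: bool = True


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cohort.

    ``x_fraction``/``y_fraction`` set the sex-chromosome share of the
    catalogue; remaining SNPs go on autosomes 1..22. Catalogue
    frequencies are uniform over ``freq_range``; unspiked SNPs use the
    catalogue frequency as the true cohort frequency (a null cohort).
    ``missingness`` is the per-genotype probability of an unknown call
    (absent from the VCF and under-covered in the depth table). Depths
    at usable sites are ``depth_cutoff + Poisson(depth_mean -
    depth_cutoff)`` so that coverage never contradicts call status.
    """

    n_samples: int = 20
    n_males: int | None = None  # default: half the cohort
    n_snps: int = 100
    x_fraction: float = 0.15
    y_fraction: float = 0.05
    freq_range: tuple[float, float] = (0.05, 0.40)
    missingness: float = 0.0
    depth_mean: float = 40.0
    depth_cutoff: int = 20
    allele_number: int = 10_000
    n_coverage_genes: int = 4
    spikes: tuple[Spike, ...] = ()
    emit_homref: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males is None:
            object.__setattr__(self, "n_males", self.n_samples // 2)
        if not 0 <= self.n_males <= self.n_samples:
            raise ValueError("n_males must be within the cohort size")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if len(self.spikes) > self.n_snps:
            raise ValueError("more spikes than SNPs")


@dataclass
class Fixture:
    """In-memory synthetic cohort: inputs plus generating truth."""

    spec: FixtureSpec
    catalogue: pd.DataFrame
    samples: list[Sample]
    calls: pd.DataFrame  # as cohort_io would produce after depth filtering
    truth: pd.DataFrame  # chrom, pos, rare_allele, true_freq
    annotations: pd.DataFrame
    rare_counts: np.ndarray = field(repr=False, default=None)  # (n_samples, n_snps)
    unknown: np.ndarray = field(repr=False, default=None)  # bool, same shape


def _make_catalogue(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_snps
    n_x = int(round(n * spec.x_fraction))
    n_y = int(round(n * spec.y_fraction))
    n_auto = n - n_x - n_y
    chroms = (
        [str(c) for c in rng.integers(1, 23, size=n_auto)]
        + ["X"] * n_x
        + ["Y"] * n_y
    )
    # X positions start beyond PAR1 and stay below PAR2
    rows = []
    pos_counter: dict[str, int] = {}
    for chrom in chroms:
        base = 3_000_000 if chrom in ("X", "Y") else 100_000
        pos_counter[chrom] = pos_counter.get(chrom, base) + int(rng.integers(500, 5_000))
        rows.append((chrom, pos_counter[chrom]))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    freqs = rng.uniform(*spec.freq_range, size=n)
    df = pd.DataFrame(
        {
            "chrom": [c for c, _ in rows],
            "pos": [p for _, p in rows],
            "snp_id": [f"rs{900000 + i}" for i in range(n)],
            "ref_allele": _BASES[ref_idx],
            "rare_allele": _BASES[alt_idx],
            "rare_freq": freqs,
            "allele_number": spec.allele_number,
            "source": "synthetic",
        }
    )
    # spikes occupy the first autosomal SNPs, deterministically
    auto_idx = df.index[~df["chrom"].isin(["X", "Y"])].to_numpy()
    for j, spike in enumerate(spec.spikes):
        df.loc[auto_idx[j], "rare_freq"] = spike.catalogue_freq
    return df[CATALOGUE_COLUMNS]


def generate(spec: FixtureSpec) -> Fixture:
    """Draw a synthetic cohort in memory.

    Genotype rare-allele counts are Binomial(ploidy, true frequency)
    per sample and SNP, with ploidy set by sex and chromosome — male
    non-PAR X draws are haploid, so males have zero X heterozygosity by
    construction. With ``missingness`` > 0, genotypes are independently
    replaced by unknown calls.
    """
    rng = np.random.default_rng(spec.seed)
    catalogue = _make_catalogue(spec, rng)
    sexes = [genome.MALE] * spec.n_males + [genome.FEMALE] * (
        spec.n_samples - spec.n_males
    )
    samples = [
        Sample(sample_id=f"S{i + 1:03d}", declared_sex=sex)
        for i, sex in enumerate(sexes)
    ]

    true_freq = catalogue["rare_freq"].to_numpy().copy()
    auto_idx = catalogue.index[~catalogue["chrom"].isin(["X", "Y"])].to_numpy()
    for j, spike in enumerate(spec.spikes):
        true_freq[auto_idx[j]] = spike.cohort_freq

    n_s, n_v = spec.n_samples, spec.n_snps
    ploidies = np.array(
        [
            [
                ploidy(sex, chrom, pos)
                for chrom, pos in zip(catalogue["chrom"], catalogue["pos"])
            ]
            for sex in sexes
        ],
        dtype=np.int64,
    )
    rare_counts = rng.binomial(ploidies, true_freq[None, :])
    unknown = rng.random((n_s, n_v)) < spec.missingness
    unknown |= ploidies == 0  # females carry no Y alleles

    call_frames = []
    for i, sample in enumerate(samples):
        status = np.where(
            unknown[i],
            STATUS_UNKNOWN,
            np.where(rare_counts[i] > 0, STATUS_CALLED, STATUS_REF_ASSUMED),
        )
        call_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample.sample_id,
                    "chrom": catalogue["chrom"].to_numpy(),
                    "pos": catalogue["pos"].to_numpy(),
                    "rare_allele": catalogue["rare_allele"].to_numpy(),
                    "rare_count": np.where(unknown[i], 0, rare_counts[i]),
                    "status": status,
                    "het": (~unknown[i]) & (rare_counts[i] == 1) & (ploidies[i] == 2),
                }
            )
        )
    calls = pd.concat(call_frames, ignore_index=True)[CALL_COLUMNS]

    truth = pd.DataFrame(
        {
            "chrom": catalogue["chrom"],
            "pos": catalogue["pos"],
            "rare_allele": catalogue["rare_allele"],
            "true_freq": true_freq,
        }
    )
    annotations = _make_annotations(spec, catalogue, rng)
    return Fixture(
        spec=spec,
        catalogue=catalogue,
        samples=samples,
        calls=calls,
        truth=truth,
        annotations=annotations,
        rare_counts=rare_counts,
        unknown=unknown,
    )


def _make_annotations(
    spec: FixtureSpec, catalogue: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    vocab = np.array([SYNONYMOUS, MISSENSE, OTHER, NONSENSE, CANONICAL_SPLICE])
    weights = np.array([0.40, 0.30, 0.15, 0.08, 0.07])
    cons = rng.choice(vocab, size=len(catalogue), p=weights)
    damaging = (cons == MISSENSE) & (rng.random(len(catalogue)) < 0.5)
    auto_idx = catalogue.index[~catalogue["chrom"].isin(["X", "Y"])].to_numpy()
    for j, spike in enumerate(spec.spikes):
        cons[auto_idx[j]] = spike.consequence
        damaging[auto_idx[j]] = spike.damaging_flag
    return pd.DataFrame(
        {
            "chrom": catalogue["chrom"],
            "pos": catalogue["pos"],
            "rare_allele": catalogue["rare_allele"],
            "consequence": cons,
            "damaging_flag": damaging,
            "gene": [f"GENE{i % 10 + 1}" for i in range(len(catalogue))],
        }
    )[ANNOTATION_COLUMNS]


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write_sample_vcf(
    path: Path,
    sample: Sample,
    catalogue: pd.DataFrame,
    rare_counts: np.ndarray,
    unknown: np.ndarray,
    ploidies: np.ndarray,
    emit_homref: bool,
) -> None:
    contigs = list(dict.fromkeys(catalogue["chrom"]))
    lines = [_VCF_HEADER]
    lines += [f"##contig=<ID={c}>\n" for c in contigs]
    lines.append(
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample.sample_id}\n"
    )
    order = catalogue.sort_values(["chrom", "pos"], kind="stable").index
    for i in order:
        if unknown[i] or ploidies[i] == 0:
            continue
        count, pl = int(rare_counts[i]), int(ploidies[i])
        if count == 0 and not emit_homref:
            continue
        if pl == 1:
            gt = str(min(count, 1))
        else:
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(count, 2)]
        row = catalogue.loc[i]
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref_allele']}\t"
            f"{row['rare_allele']}\t.\tPASS\t.\tGT\t{gt}\n"
        )
    path.write_text("".join(lines))


def _write_sites_vcf(path: Path, catalogue: pd.DataFrame) -> None:
    contigs = list(dict.fromkeys(catalogue["chrom"]))
    lines = [
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total Alleles">\n'
    ]
    lines += [f"##contig=<ID={c}>\n" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for row in catalogue.sort_values(["chrom", "pos"], kind="stable").itertuples():
        an = "" if pd.isna(row.allele_number) else f";AN={int(row.allele_number)}"
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref_allele}\t"
            f"{row.rare_allele}\t.\tPASS\tAF={row.rare_freq:.6f}{an}\n"
        )
    path.write_text("".join(lines))


def _make_exons(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exon BED plus per-base depth means (half the genes deliberately shallow)."""
    rows, depth_rows = [], []
    start = 10_000_000
    for g in range(spec.n_coverage_genes):
        gene = f"COV{g + 1}"
        gene_mean = spec.depth_mean if g % 2 == 0 else spec.depth_cutoff / 2
        for e in range(2):
            s = start + g * 10_000 + e * 200
            end = s + int(rng.integers(20, 40))
            rows.append(
                {"chrom": "2", "start": s, "end": end, "gene": gene, "exon_id": f"{gene}.e{e + 1}"}
            )
            depth_rows.append((s, end, gene_mean))
    return pd.DataFrame(rows), pd.DataFrame(
        depth_rows, columns=["start", "end", "mean"]
    )


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> pd.DataFrame:
    """Write a complete synthetic cohort under ``outdir``.

    Emits the catalogue (TSV and sites-VCF), one VCF per sample, one
    depth TSV per sample, an exon BED, annotation and ground-truth
    TSVs, and a sample manifest; returns a manifest frame listing every
    file with its SHA-256 checksum. Running the same spec twice yields
    identical checksums.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable") from exc

    fx = generate(spec)
    rng = np.random.default_rng(spec.seed + 1)  # depths/exons, separate stream
    catalogue, samples = fx.catalogue, fx.samples

    sexes = [s.declared_sex for s in samples]
    ploidies = np.array(
        [
            [
                ploidy(sex, chrom, pos)
                for chrom, pos in zip(catalogue["chrom"], catalogue["pos"])
            ]
            for sex in sexes
        ],
        dtype=np.int64,
    )

    exons, exon_depth_means = _make_exons(spec, rng)
    files: list[Path] = []

    cat_tsv = outdir / "catalogue.tsv"
    write_catalogue(catalogue, cat_tsv)
    cat_vcf = outdir / "catalogue.sites.vcf"
    _write_sites_vcf(cat_vcf, catalogue)
    files += [cat_tsv, cat_vcf]

    manifest_rows = []
    for i, sample in enumerate(samples):
        vcf_path = outdir / f"{sample.sample_id}.vcf"
        _write_sample_vcf(
            vcf_path,
            sample,
            catalogue,
            fx.rare_counts[i],
            fx.unknown[i],
            ploidies[i],
            spec.emit_homref,
        )
        depth_path = outdir / f"{sample.sample_id}.depth.tsv"
        _write_depth_table(
            depth_path, catalogue, fx.unknown[i], ploidies[i], exon_depth_means, spec, rng
        )
        sample.vcf_path = vcf_path
        sample.depth_path = depth_path
        files += [vcf_path, depth_path]
        manifest_rows.append(
            {
                "sample_id": sample.sample_id,
                "vcf_path": vcf_path.name,
                "depth_path": depth_path.name,
                "sex": {"male": "M", "female": "F"}.get(sample.declared_sex, "U"),
            }
        )

    bed_path = outdir / "exons.bed"
    exons.to_csv(bed_path, sep="\t", index=False, header=False)
    ann_path = outdir / "annotations.tsv"
    fx.annotations.to_csv(ann_path, sep="\t", index=False)
    truth_path = outdir / "truth.tsv"
    fx.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    samples_path = outdir / "samples.tsv"
    pd.DataFrame(manifest_rows).to_csv(samples_path, sep="\t", index=False)
    files += [bed_path, ann_path, truth_path, samples_path]

    manifest = pd.DataFrame(
        {
            "path": [f.name for f in files],
            "sha256": [hashlib.sha256(f.read_bytes()).hexdigest() for f in files],
        }
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def _write_depth_table(
    path: Path,
    catalogue: pd.DataFrame,
    unknown: np.ndarray,
    ploidies: np.ndarray,
    exon_depth_means: pd.DataFrame,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> None:
    cutoff = spec.depth_cutoff
    lines = []
    order = catalogue.sort_values(["chrom", "pos"], kind="stable").index
    for i in order:
        row = catalogue.loc[i]
        if unknown[i] or ploidies[i] == 0:
            d = int(rng.integers(0, cutoff))
        else:
            d = cutoff + int(rng.poisson(max(spec.depth_mean - cutoff, 1)))
        lines.append(f"{row['chrom']}\t{row['pos']}\t{d}\n")
    for er in exon_depth_means.itertuples(index=False):
        for pos in range(int(er.start) + 1, int(er.end) + 1):
            lines.append(f"2\t{pos}\t{int(rng.poisson(er.mean))}\n")
    path.write_text("".join(lines))


def load_sample_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[Sample]:
    """Read a sample manifest TSV (sample_id, vcf_path, depth_path, sex)."""
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, sep="\t", dtype=str)
    sex_map = {"M": genome.MALE, "F": genome.FEMALE, "U": genome.UNKNOWN}
    samples = []
    for row in df.itertuples(index=False):
        depth = getattr(row, "depth_path", None)
        samples.append(
            Sample(
                sample_id=row.sample_id,
                vcf_path=base / row.vcf_path,
                depth_path=(base / depth) if isinstance(depth, str) and depth else None,
                declared_sex=sex_map.get(str(getattr(row, "sex", "U")), genome.UNKNOWN),
            )
        )
    return samples
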