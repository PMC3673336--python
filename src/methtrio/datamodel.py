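"""Core data containers, file I/O and genomic-interval arithmetic.

All coordinates are 0-based, half-open (BED convention).  VCF positions are
converted from 1-based on read.  Matrices are pandas DataFrames with feature
ids on the rows and individual ids on the columns; tab-delimited writers and
readers round-trip them exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenotypeMatrix:
    """Additive dosages (count of alternate allele) for individuals x SNPs.

    ``dosage`` is individuals x SNPs with values in {0, 1, 2} or NaN for
    missing.  ``snps`` carries one row per SNP: chrom, pos (0-based), ref, alt.
    """

    dosage: pd.DataFrame
    snps: pd.DataFrame  # index: snp_id; columns: chrom, pos, ref, alt

    def __post_init__(self):
        if not self.dosage.columns.equals(self.snps.index):
            raise ValueError("dosage columns must match snps index")
        if self.dosage.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        if self.snps.index.has_duplicates:
            raise ValueError("duplicate SNP ids")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def individuals(self) -> pd.Index:
        return self.dosage.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def positions(self) -> pd.DataFrame:
        return self.snps[["chrom", "pos"]]

    def subset_snps(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[list(ids)], self.snps.loc[list(ids)])


@dataclass
class GeneModel:
    """Merged exon units of one gene; TSS is the 5'-most transcript start."""

    gene_id: str
    tss: int
    strand: str
    chrom: str
    exon_units: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def exonic_bp(self) -> int:
        return sum(len(e) for e in self.exon_units)


@dataclass
class ExpressionData:
    """Exon-unit read counts with the owning gene annotation.

    ``counts``: exon units x individuals, non-negative.  ``exons``: one row per
    exon unit (gene_id, chrom, start, end, length).  ``normalized`` is filled
    by preprocessing and has the same shape as ``counts``.
    """

    counts: pd.DataFrame
    exons: pd.DataFrame  # index: exon_id; columns gene_id, chrom, start, end, length
    genes: dict[str, GeneModel] = field(default_factory=dict)
    normalized: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.counts.index.equals(self.exons.index):
            raise ValueError("counts index must match exon annotation index")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def individuals(self) -> pd.Index:
        return self.counts.columns

    def exon_values(self) -> pd.DataFrame:
        """Normalized values when present, raw counts otherwise."""
        return self.normalized if self.normalized is not None else self.counts


@dataclass
class MethylationData:
    """CpG sites x individuals methylation levels.

    ``sites``: per-CpG annotation (chrom, pos, probe_type in {1, 2}, channel in
    {green, red} for type-1 probes).  ``meth``/``unmeth`` are the raw
    fluorescence intensity matrices when available; ``beta`` is the proportion
    methylated in [0, 1].
    """

    sites: pd.DataFrame
    beta: pd.DataFrame | None = None
    meth: pd.DataFrame | None = None
    unmeth: pd.DataFrame | None = None

    def __post_init__(self):
        if self.beta is not None:
            vals = self.beta.to_numpy(dtype=float)
            finite = vals[~np.isnan(vals)]
            if ((finite < 0) | (finite > 1)).any():
                raise ValueError("beta values must lie in [0, 1]")
        for m in (self.meth, self.unmeth):
            if m is not None and (m.to_numpy() < 0).any():
                raise ValueError("negative intensity")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.sites.index

    def compute_beta(self, eps: float = 0.0) -> pd.DataFrame:
        """beta = M / (M + U + eps) from raw intensities."""
        if self.meth is None or self.unmeth is None:
            raise ValueError("intensities not present")
        return self.meth / (self.meth + self.unmeth + eps)


ASSOCIATION_COLUMNS = ["feature_id", "target_id", "rho", "p", "distance", "significant"]


def association_frame(records=None) -> pd.DataFrame:
    """Empty or populated table of association records (one row per tested pair)."""
    df = pd.DataFrame(records, columns=ASSOCIATION_COLUMNS) if records is not None else (
        pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    )
    if len(df):
        if ((df["rho"].abs() > 1 + 1e-12) & df["rho"].notna()).any():
            raise ValueError("rho out of [-1, 1]")
        if ((df["p"] < 0) | (df["p"] > 1)).any():
            raise ValueError("p out of [0, 1]")
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_matrix(path) -> pd.DataFrame:
    """Tab-delimited matrix: first column feature id, header individual ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (v4.x) or a dosage matrix.

    Dosages are coded as the count of the alternate allele; multiallelic VCF
    records are dropped (with a logged count) and ``./.`` genotypes become
    missing.  The matrix format is individuals in columns, SNPs in rows, with
    a sidecar ``<path>.snps`` annotation written by :func:`write_genotypes`.
    """
    if format == "matrix":
        dosage = read_matrix(path).T
        dosage.index.name = "individual"
        dosage.columns.name = "snp_id"
        snps = pd.read_csv(f"{path}.snps", sep="\t", index_col=0)
        snps.index = snps.index.astype(str)
        snps.index.name = "snp_id"
        return GenotypeMatrix(dosage, snps)
    if format != "vcf":
        raise ValueError(f"unknown genotype format: {format}")

    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        snp_id = rec.ID or f"{rec.CHROM}_{rec.POS}"
        if snp_id in set(ids):
            raise ValueError(f"duplicate SNP id: {snp_id}")
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        gts = np.asarray(rec.gt_types, dtype=float)
        gts[gts == 3] = np.nan
        ids.append(snp_id)
        rows.append(gts)
        meta.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
    if n_multiallelic:
        log.info("read_genotypes: dropped %d multiallelic records", n_multiallelic)
    dosage = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="individual"),
        columns=pd.Index(ids, name="snp_id"),
    )
    snps = pd.DataFrame(
        meta, index=pd.Index(ids, name="snp_id"), columns=["chrom", "pos", "ref", "alt"]
    )
    g = GenotypeMatrix(dosage, snps)
    g.n_multiallelic_dropped = n_multiallelic
    return g


def write_genotypes(g: GenotypeMatrix, path) -> None:
    write_matrix(g.dosage.T, path)
    g.snps.to_csv(f"{path}.snps", sep="\t", index_label="snp_id")


def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6 reader (strand from column 6 when present)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {i}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in STRANDS else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_annotation(path) -> pd.DataFrame:
    """GTF-like tab file: gene_id, transcript_id, biotype, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "transcript_id", "biotype", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

RETAINED_BIOTYPES = {"protein_coding", "lincRNA"}


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of (start, end) pairs as maximal disjoint sorted intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_exon_units(transcripts: pd.DataFrame) -> dict[str, GeneModel]:
    """Collapse transcript exons into non-redundant merged exon units per gene.

    ``transcripts`` is the annotation frame from :func:`read_annotation` with
    one row per exon.  Only protein-coding and lincRNA transcripts are
    retained; genes left without any retained transcript are omitted (logged).
    The TSS is the 5'-most transcript start: minimum exon start for + strand
    genes, maximum exon end for - strand genes.
    """
    genes: dict[str, GeneModel] = {}
    for gene_id, sub in transcripts.groupby("gene_id", sort=True):
        keep = sub[sub["biotype"].isin(RETAINED_BIOTYPES)]
        if keep.empty:
            log.info("merge_exon_units: gene %s has no retained transcripts", gene_id)
            continue
        chrom = keep["chrom"].iloc[0]
        strand = keep["strand"].iloc[0]
        units = merge_intervals(zip(keep["start"], keep["end"]))
        tss = int(keep["start"].min()) if strand == "+" else int(keep["end"].max())
        genes[str(gene_id)] = GeneModel(
            gene_id=str(gene_id),
            tss=tss,
            strand=strand,
            chrom=chrom,
            exon_units=[GenomicInterval(chrom, s, e, strand) for s, e in units],
            biotype="/".join(sorted(keep["biotype"].unique())),
        )
    return genes


def cis_pairs(
    anchors: pd.DataFrame, targets: pd.DataFrame, window_bp: int
) -> pd.DataFrame:
    """All (anchor, target) pairs within ``window_bp`` on the same chromosome.

    ``anchors`` and ``targets`` are frames indexed by feature id with columns
    ``chrom`` and ``pos`` (targets may carry ``strand``).  The window test is
    inclusive at both edges (|anchor - target| <= window_bp).  Distance is
    anchor - target, sign flipped for - strand targets so that positive means
    downstream of the target.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    out = []
    a_by_chrom = {c: sub.sort_values("pos") for c, sub in anchors.groupby("chrom")}
    for t_id, t in targets.iterrows():
        sub = a_by_chrom.get(t["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, t["pos"] - window_bp, side="left")
        hi = np.searchsorted(pos, t["pos"] + window_bp, side="right")
        strand_sign = -1 if t.get("strand", ".") == "-" else 1
        for a_id, a_pos in zip(sub.index[lo:hi], pos[lo:hi]):
            out.append((a_id, t_id, strand_sign * int(a_pos - t["pos"])))
    return pd.DataFrame(out, columns=["anchor_id", "target_id", "distance"])


def intersect_features(sites: pd.DataFrame, features) -> pd.Series:
    """Flag each site (chrom, pos) lying inside any half-open feature interval.

    ``features`` is an iterable of :class:`GenomicInterval`.  Sites on
    chromosomes absent from the features are flagged False with a warning.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {c: merge_intervals(v) for c, v in by_chrom.items()}
    flags = np.zeros(len(sites), dtype=bool)
    unknown = set()
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        ivs = merged.get(chrom)
        if ivs is None:
            unknown.add(chrom)
            continue
        starts = [s for s, _ in ivs]
        j = np.searchsorted(starts, pos, side="right") - 1
        flags[i] = j >= 0 and pos < ivs[j][1]
    if unknown:
        log.warning("intersect_features: unknown chromosomes %s", sorted(unknown))
    return pd.Series(flags, index=sites.index, name="in_feature")
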