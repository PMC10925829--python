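"""Readers/writers for the formats the pipeline touches, and SNP-to-gene mapping.

Genotypes travel as a dense dosage matrix (0/1/2 copies of the ALT allele)
with genomic positions; the minor allele is defined panel-wide when a matrix
is constructed and frozen thereafter, so per-subset frequencies of that
allele may exceed 0.5. Gene annotation uses GFF3 conventions: 1-based,
inclusive coordinates. A SNP belongs to a gene iff its position falls within
``[start - window_bp, end + window_bp]`` (boundaries inclusive).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_GENE_WINDOW_BP = 2500


def _chrom_sort_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of accessions.

    Attributes
    ----------
    accessions : list of sample identifiers (rows of ``dosage``).
    snp_ids, chrom, pos : per-SNP identifier, chromosome label and 1-based
        position; positions are strictly increasing within each chromosome.
    dosage : float array (n_accessions, n_snps), ALT-allele counts in
        {0, 1, 2}; missing calls are mean-imputed at load time.
    minor_is_alt : bool per SNP; True when the panel-wide minor allele is
        the ALT allele.  Frozen at construction.
    imputed_fraction : fraction of genotypes that were missing and imputed.
    """

    accessions: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    minor_is_alt: np.ndarray = field(default=None)
    imputed_fraction: float = 0.0

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.accessions) or m != len(self.snp_ids):
            raise SchemaError("dosage matrix shape inconsistent with ids")
        self._sort_by_position()
        if self.minor_is_alt is None:
            f_alt = self.dosage.mean(axis=0) / 2.0
            self.minor_is_alt = f_alt <= 0.5
        self.minor_is_alt = np.asarray(self.minor_is_alt, dtype=bool)

    def _sort_by_position(self):
        order = sorted(
            range(len(self.snp_ids)),
            key=lambda i: (_chrom_sort_key(self.chrom[i]), self.pos[i]),
        )
        order = np.asarray(order)
        self.snp_ids = self.snp_ids[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.dosage = self.dosage[:, order]
        if self.minor_is_alt is not None:
            self.minor_is_alt = np.asarray(self.minor_is_alt)[order]
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"duplicate or unsorted positions on chromosome {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def maf(self) -> np.ndarray:
        """Panel-wide minor allele frequency per SNP."""
        f_alt = self.dosage.mean(axis=0) / 2.0
        return np.minimum(f_alt, 1.0 - f_alt)

    def minor_allele_dosage(self) -> np.ndarray:
        """Dosage matrix counting copies of the frozen panel-wide minor allele."""
        d = self.dosage.copy()
        flip = ~self.minor_is_alt
        d[:, flip] = 2.0 - d[:, flip]
        return d

    def minor_allele_freq(self, row_idx=None) -> np.ndarray:
        """Frequency of the frozen minor allele, optionally in a row subset."""
        d = self.minor_allele_dosage()
        if row_idx is not None:
            d = d[np.asarray(row_idx)]
        return d.mean(axis=0) / 2.0

    def subset_accessions(self, keep: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accessions)}
        missing = [a for a in keep if a not in index]
        if missing:
            raise DataError(f"accessions absent from genotype matrix: {missing[:5]}")
        rows = [index[a] for a in keep]
        return GenotypeMatrix(
            accessions=list(keep),
            snp_ids=self.snp_ids.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosage=self.dosage[rows].copy(),
            minor_is_alt=self.minor_is_alt.copy(),
            imputed_fraction=self.imputed_fraction,
        )


def _filter_maf(gm: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    keep = gm.maf > maf_min
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("MAF filter (> %.3g) removed %d of %d SNPs", maf_min, n_drop, gm.n_snps)
    if not keep.any():
        raise DataError("no SNPs remain after MAF filtering")
    return GenotypeMatrix(
        accessions=gm.accessions,
        snp_ids=gm.snp_ids[keep],
        chrom=gm.chrom[keep],
        pos=gm.pos[keep],
        dosage=gm.dosage[:, keep],
        minor_is_alt=None,  # redefine panel-wide minor allele on the filtered set
        imputed_fraction=gm.imputed_fraction,
    )


def read_genotypes(path, format: str = "vcf", maf_min: float = 0.01) -> GenotypeMatrix:
    """Load genotypes from a VCF (v4.2, GT fields) or a dosage CSV.

    Multi-allelic sites are dropped (logged), missing genotypes are
    mean-imputed per SNP, and SNPs with MAF <= ``maf_min`` are removed.
    The returned matrix is sorted by (chromosome, position).
    """
    if format == "vcf":
        gm = _read_vcf(str(path))
    elif format == "dosage_csv":
        gm = _read_dosage_csv(str(path))
    else:
        raise SchemaError(f"unknown genotype format: {format!r}")
    return _filter_maf(gm, maf_min)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # htslib raises bare OSError on malformed input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, positions, ids, rows = [], [], [], []
    n_multi = 0
    n_missing = 0
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = np.asarray(var.gt_types, dtype=float)
        miss = g == 3
        if miss.all():
            raise ParseError(f"record {k + 1} ({var.CHROM}:{var.POS}): all genotypes missing")
        if miss.any():
            n_missing += int(miss.sum())
            g[miss] = g[~miss].mean()
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"S{var.CHROM}_{var.POS}")
        rows.append(g)
    if n_multi:
        logger.info("dropped %d multi-allelic sites from %s", n_multi, path)
    if not rows:
        raise DataError(f"no biallelic SNPs in {path}")
    dosage = np.vstack(rows).T
    gm = GenotypeMatrix(samples, np.array(ids, dtype=object),
                        np.array(chroms, dtype=object), np.array(positions), dosage)
    gm.imputed_fraction = n_missing / dosage.size
    return gm


def _read_dosage_csv(path: str) -> GenotypeMatrix:
    """Dosage CSV dialect: columns snp_id, chrom, pos, then one column per
    accession holding 0/1/2 (blank for missing)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse dosage CSV {path}: {exc}") from exc
    required = ["snp_id", "chrom", "pos"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"dosage CSV missing mandatory column {col!r}")
    samples = [c for c in df.columns if c not in required]
    if not samples:
        raise SchemaError("dosage CSV has no accession columns")
    dosage = df[samples].to_numpy(dtype=float).T
    n_missing = int(np.isnan(dosage).sum())
    if n_missing:
        col_mean = np.nanmean(dosage, axis=0)
        idx = np.where(np.isnan(dosage))
        dosage[idx] = np.take(col_mean, idx[1])
    gm = GenotypeMatrix(samples, df["snp_id"].to_numpy(dtype=object),
                        df["chrom"].astype(str).to_numpy(dtype=object),
                        df["pos"].to_numpy(), dosage)
    gm.imputed_fraction = n_missing / dosage.size
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF v4.2 with GT-only genotype fields.

    Dosages must be integral; the writer is intended for the synthetic study
    and for round-trip tests, not as a general-purpose VCF emitter.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rootclines\n")
        for c in sorted(set(gm.chrom), key=_chrom_sort_key):
            length = int(gm.pos[gm.chrom == c].max()) + 10000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accessions) + "\n")
        for j in range(gm.n_snps):
            col = gm.dosage[:, j]
            gts = "\t".join(gt_code[int(round(v))] for v in col)
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.snp_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_dosage_csv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame({"snp_id": gm.snp_ids, "chrom": gm.chrom, "pos": gm.pos})
    dos = pd.DataFrame(gm.dosage.T, columns=gm.accessions)
    pd.concat([df, dos.round(6)], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene annotation and SNP->gene windows
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene intervals (1-based, inclusive) plus the flank used for SNP windows."""

    gene_ids: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    window_bp: int = DEFAULT_GENE_WINDOW_BP

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SchemaError("gene ids are not unique")
        if np.any(self.start > self.end):
            raise SchemaError("gene with start > end")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_gff3(cls, path, window_bp: int = DEFAULT_GENE_WINDOW_BP) -> "GeneAnnotation":
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        ids, chroms, starts, ends = [], [], [], []
        with opener(path, "rt") as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ParseError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
                if parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{ln}: gene feature without ID attribute")
                ids.append(gid)
                chroms.append(parts[0])
                try:
                    starts.append(int(parts[3]))
                    ends.append(int(parts[4]))
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
        if not ids:
            raise DataError(f"no gene features in {path}")
        return cls(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                   np.array(starts), np.array(ends), window_bp=window_bp)

    def to_gff3(self, path) -> None:
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("##gff-version 3\n")
            order = sorted(range(self.n_genes),
                           key=lambda i: (_chrom_sort_key(self.chrom[i]), self.start[i]))
            for i in order:
                fh.write(f"{self.chrom[i]}\trootclines\tgene\t{self.start[i]}\t"
                         f"{self.end[i]}\t.\t+\t.\tID={self.gene_ids[i]}\n")


@dataclass
class SnpGeneMap:
    """Exhaustive (snp, gene) membership under the inclusive-window rule."""

    pairs: pd.DataFrame  # columns: snp_id, gene_id
    empty_genes: list[str]

    def snps_for_gene(self, gene_id: str) -> list[str]:
        return self.pairs.loc[self.pairs["gene_id"] == gene_id, "snp_id"].tolist()

    def gene_groups(self) -> dict[str, list[str]]:
        return {g: sub["snp_id"].tolist() for g, sub in self.pairs.groupby("gene_id", sort=True)}


def assign_snps_to_genes(genos: GenotypeMatrix, ann: GeneAnnotation) -> SnpGeneMap:
    """Map every SNP to every gene whose window contains it.

    A SNP at position p belongs to gene g iff
    ``g.start - window_bp <= p <= g.end + window_bp``.  SNPs may map to
    several overlapping genes; genes without SNPs are reported separately.
    """
    geno_chroms = set(map(str, genos.chrom))
    ann_chroms = set(map(str, ann.chrom))
    if not geno_chroms & ann_chroms:
        raise DataError(
            f"no shared chromosome labels between genotypes ({sorted(geno_chroms)[:5]}) "
            f"and annotation ({sorted(ann_chroms)[:5]})"
        )
    w = ann.window_bp
    snp_col, gene_col, empty = [], [], []
    for c in sorted(ann_chroms, key=_chrom_sort_key):
        on_c = genos.chrom == c
        pos = genos.pos[on_c]
        ids = genos.snp_ids[on_c]
        for i in np.where(ann.chrom == c)[0]:
            lo = np.searchsorted(pos, ann.start[i] - w, side="left")
            hi = np.searchsorted(pos, ann.end[i] + w, side="right")
            if hi > lo:
                snp_col.extend(ids[lo:hi])
                gene_col.extend([ann.gene_ids[i]] * (hi - lo))
            else:
                empty.append(ann.gene_ids[i])
    pairs = pd.DataFrame({"snp_id": snp_col, "gene_id": gene_col})
    return SnpGeneMap(pairs=pairs, empty_genes=sorted(empty))


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def read_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a headered CSV; ``schema`` lists mandatory columns."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse table {path}: {exc}") from exc
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a headered CSV with locale-independent decimal points."""
    df.to_csv(path, index=False, float_format=float_format)
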