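"""Readers and writers for every external representation the pipeline touches.

Association summary statistics use the PLINK logistic-regression text dialect
(whitespace-delimited, header ``CHR SNP BP A1 TEST NMISS OR STAT P``); genotypes
come from VCF or a plain tab-delimited dosage table; gene models from BED4;
region reports go out as TSV and prioritized summary statistics back out in the
PLINK dialect.

Coordinate conventions: association records and regions are 1-based inclusive
(PLINK/VCF); BED is 0-based half-open. Conversion between the two happens only
inside the annotation step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)}


class FormatError(ValueError):
    """Raised when an input file violates its dialect contract."""


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix so 'chr4' and PLINK-style '4' compare equal."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def chrom_sort_key(label: str):
    """Numeric chromosomes sort numerically, others lexicographically after."""
    c = normalize_chrom(label)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


class Direction(Enum):
    """Direction of effect of the A1 allele under the additive model."""

    UP = "UP"          # OR > 1
    DOWN = "DOWN"      # OR < 1
    NEUTRAL = "NEUTRAL"  # OR == 1 exactly; cannot anchor or join a signal group


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association record.

    ``neg_log_p`` is the -log10 p-value (the "s" entering consistency scoring).
    """

    chrom: str
    bp: int
    snp_id: str
    a1: str
    odds_ratio: float
    p_value: float

    def __post_init__(self):
        if self.bp < 1:
            raise ValueError(f"bp must be >= 1, got {self.bp}")
        if not self.odds_ratio > 0:
            raise ValueError(f"odds_ratio must be positive, got {self.odds_ratio}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    @property
    def neg_log_p(self) -> float:
        return -math.log10(self.p_value)

    @property
    def direction(self) -> Direction:
        if self.odds_ratio > 1:
            return Direction.UP
        if self.odds_ratio < 1:
            return Direction.DOWN
        return Direction.NEUTRAL

    @property
    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.bp)


@dataclass(frozen=True)
class GeneInterval:
    """A gene model interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    gene_name: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"gene interval requires start < end, got [{self.start}, {self.end})"
            )


class GenotypeTable:
    """Samples x variants additive alt-allele dosages with variant metadata.

    Dosages are stored as float with NaN marking missing genotypes; observed
    values are exactly 0, 1 or 2. Variants are kept sorted by (chrom, bp) and
    duplicated (chrom, bp, ref, alt) tuples are rejected.
    """

    def __init__(self, sample_ids: Sequence[str], variants: pd.DataFrame,
                 dosages: np.ndarray):
        variants = variants.reset_index(drop=True)
        required = {"chrom", "bp", "snp_id", "ref", "alt"}
        if not required.issubset(variants.columns):
            raise ValueError(f"variant metadata needs columns {sorted(required)}")
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(sample_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(variants)} variants"
            )
        observed = dosages[~np.isnan(dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        variants = variants.copy()
        variants["chrom"] = variants["chrom"].map(normalize_chrom)
        dup = variants.duplicated(subset=["chrom", "bp", "ref", "alt"])
        if dup.any():
            first = variants[dup].iloc[0]
            raise ValueError(
                f"duplicated variant {first['chrom']}:{first['bp']} "
                f"{first['ref']}>{first['alt']}"
            )
        order = sorted(range(len(variants)),
                       key=lambda i: (*chrom_sort_key(variants["chrom"].iat[i]),
                                      int(variants["bp"].iat[i])))
        self.sample_ids = list(sample_ids)
        self.variants = variants.iloc[order].reset_index(drop=True)
        self.dosages = dosages[:, order]
        self._col = {sid: i for i, sid in enumerate(self.variants["snp_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def has_variant(self, snp_id: str) -> bool:
        return snp_id in self._col

    def dosages_for(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._col[snp_id]]
        except KeyError:
            raise KeyError(f"unknown variant id {snp_id!r}") from None

    def subset_samples(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        sids = [s for s, k in zip(self.sample_ids, keep) if k]
        return GenotypeTable(sids, self.variants, self.dosages[keep])

    def subset_variants(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(self.sample_ids, self.variants[keep], self.dosages[:, keep])


# ---------------------------------------------------------------------------
# association summary statistics (PLINK logistic dialect)
# ---------------------------------------------------------------------------

def read_assoc(path, p_column: str = "P", or_column: str = "OR",
               bp_column: str = "BP", autosomes_only: bool = True) -> list[SnpAssociation]:
    """Read PLINK-style logistic association output.

    Keeps only rows whose TEST column (when present) equals "ADD"; rows with
    "NA" in the OR or P column are dropped with a logged count. Output is
    sorted by (chrom, bp).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    for col in ("CHR", bp_column, "A1", or_column, p_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    # remember original line numbers before any filtering (header is line 1)
    df = df.assign(_line=df.index + 2)
    if "TEST" in df.columns:
        non_add = int((df["TEST"] != "ADD").sum())
        if non_add:
            log.info("read_assoc: excluded %d non-ADD test rows", non_add)
        df = df[df["TEST"] == "ADD"]
    na_mask = df[or_column].isin(("NA", "nan")) | df[p_column].isin(("NA", "nan"))
    n_na = int(na_mask.sum())
    if n_na:
        log.warning("read_assoc: dropped %d rows with NA OR/P", n_na)
    df = df[~na_mask]

    def _numeric(col, caster):
        out = []
        for raw, line in zip(df[col], df["_line"]):
            try:
                out.append(caster(raw))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: line {line}: unparsable value {raw!r} in column {col}"
                ) from None
        return out

    records = []
    bps = _numeric(bp_column, int)
    ors = _numeric(or_column, float)
    ps = _numeric(p_column, float)
    has_snp = "SNP" in df.columns
    for i, (_, row) in enumerate(df.iterrows()):
        chrom = normalize_chrom(row["CHR"])
        if autosomes_only and chrom not in AUTOSOMES:
            continue
        records.append(SnpAssociation(
            chrom=chrom, bp=bps[i],
            snp_id=row["SNP"] if has_snp else ".",
            a1=row["A1"], odds_ratio=ors[i], p_value=ps[i],
        ))
    records.sort(key=lambda r: r.sort_key)
    return records


def write_prioritized_assoc(assocs: Iterable[SnpAssociation], path) -> None:
    """Write association records in the PLINK dialect (CHR SNP BP A1 OR P).

    Floats are printed with ``repr`` so a subsequent ``read_assoc`` round-trips
    every record exactly.
    """
    rows = [("CHR", "SNP", "BP", "A1", "OR", "P")]
    for a in assocs:
        rows.append((a.chrom, a.snp_id, str(a.bp), a.a1,
                     repr(a.odds_ratio), repr(a.p_value)))
    widths = [max(len(r[c]) for r in rows) for c in range(6)]
    with open(path, "w") as fh:
        for r in rows:
            fh.write("  ".join(v.rjust(w) for v, w in zip(r, widths)) + "\n")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path) -> GenotypeTable:
    """Load biallelic SNVs from a VCF as alt-allele dosages.

    Multi-allelic sites and non-SNVs are skipped (counts logged); missing
    genotypes become NaN dosages. Phase is ignored.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"{path}: malformed VCF ({exc})") from exc
    sample_ids = list(vcf.samples)
    meta, cols = [], []
    n_multi = n_nonsnv = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_nonsnv += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types, dtype=float)
        dos = np.full(gt.shape, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 1] = 1.0
        dos[gt == 3] = 2.0
        meta.append((normalize_chrom(v.CHROM), v.POS,
                     v.ID if v.ID else f"{normalize_chrom(v.CHROM)}:{v.POS}",
                     v.REF, v.ALT[0]))
        cols.append(dos)
    if n_multi:
        log.info("read_genotypes_vcf: skipped %d multi-allelic sites", n_multi)
    if n_nonsnv:
        log.info("read_genotypes_vcf: skipped %d non-SNV sites", n_nonsnv)
    variants = pd.DataFrame(meta, columns=["chrom", "bp", "snp_id", "ref", "alt"])
    dosages = (np.column_stack(cols) if cols
               else np.empty((len(sample_ids), 0)))
    return GenotypeTable(sample_ids, variants, dosages)


def _parse_variant_id(vid: str, fallback_bp: int):
    """Variant ids of the form 'chrom:bp[:name[:ref:alt]]' carry their own
    coordinates; anything else gets placeholder metadata in input order."""
    parts = str(vid).split(":")
    if len(parts) >= 2 and parts[1].isdigit():
        chrom, bp = normalize_chrom(parts[0]), int(parts[1])
        if len(parts) >= 5:
            return chrom, bp, parts[2], parts[3], parts[4]
        return chrom, bp, vid, "N", "A"
    return "0", fallback_bp, vid, "N", "A"


def read_genotypes_table(path) -> GenotypeTable:
    """Read the plain dosage-table dialect: a header of variant ids (first
    column ``sample_id``), one row per sample, cells in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    var_ids = list(df.columns[1:])
    dosages = np.full((len(sample_ids), len(var_ids)), np.nan)
    for j, vid in enumerate(var_ids):
        for i, cell in enumerate(df[vid]):
            if cell == "NA":
                continue
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: line {i + 2}: unparsable dosage {cell!r}") from None
            if val not in (0.0, 1.0, 2.0):
                raise FormatError(
                    f"{path}: line {i + 2}: dosage out of range: {cell!r}")
            dosages[i, j] = val
    meta = [_parse_variant_id(vid, j + 1) for j, vid in enumerate(var_ids)]
    variants = pd.DataFrame(meta, columns=["chrom", "bp", "snp_id", "ref", "alt"])
    return GenotypeTable(sample_ids, variants, dosages)


def write_genotypes_table(table: GenotypeTable, path) -> None:
    """Inverse of :func:`read_genotypes_table`; ids are written as
    'chrom:bp:name:ref:alt' so coordinates survive the round trip."""
    ids = [f"{r.chrom}:{r.bp}:{r.snp_id}:{r.ref}:{r.alt}"
           for r in table.variants.itertuples()]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for sid, row in zip(table.sample_ids, table.dosages):
            cells = ["NA" if np.isnan(d) else str(int(d)) for d in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# gene models (BED4) and region reports (TSV)
# ---------------------------------------------------------------------------

def read_bed_genes(path) -> list[GeneInterval]:
    """Read BED4 gene models (0-based half-open; name in column 4)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: BED4 requires a name column")
            chrom, start, end, name = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: unparsable coordinates") from None
            if start_i >= end_i:
                raise FormatError(
                    f"{path}: line {lineno}: start {start_i} >= end {end_i}")
            genes.append(GeneInterval(normalize_chrom(chrom), start_i, end_i, name))
    return genes


REGION_TSV_COLUMNS = [
    "chrom", "start_bp", "end_bp", "n_snps_total", "n_snps_significant",
    "n_signal_groups", "best_mae", "top_snp_id", "top_snp_p", "prioritized",
]


def write_region_tsv(regions, path) -> None:
    """Write the per-region summary TSV, ordered by (chrom, start_bp)."""
    rows = []
    for r in sorted(regions, key=lambda r: (*chrom_sort_key(r.chrom), r.start_bp)):
        # best MAE among groups with corroborating LD partners (>= 2 members)
        maes = [g.mae for g in r.signal_groups
                if len(g.members) >= 2 and not math.isnan(g.mae)]
        best = repr(min(maes)) if maes else "NA"
        top = min(r.significant_snps, key=lambda s: (s.p_value, s.bp, s.snp_id))
        rows.append([r.chrom, r.start_bp, r.end_bp, len(r.all_snps),
                     len(r.significant_snps), len(r.signal_groups), best,
                     top.snp_id, repr(top.p_value), int(r.prioritized)])
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_region_tsv(path) -> pd.DataFrame:
    """Read a region summary TSV back as a DataFrame (for annotation input)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REGION_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing region TSV columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df
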