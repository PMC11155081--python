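"""Pairwise linkage disequilibrium (r²) from genotype dosages.

r² is the squared Pearson correlation of unphased additive dosages over
pairwise-complete samples — the allele-count r² PLINK 1.9 reports for unphased
data by default — not the EM-haplotype r². Pairs without usable LD information
(fewer than two pairwise-complete samples, or zero dosage variance at either
site) return NaN, a sentinel deliberately distinct from 0: "no information" is
never the same claim as "no correlation", and downstream consistency scoring
must fail safe on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GenotypeTable

#: sentinel for "no LD information" (propagates through ŝ and MAE).
R2_MISSING = float("nan")


def is_r2_missing(value: float) -> bool:
    return np.isnan(value)


@dataclass(frozen=True)
class LdToTop:
    """r² between a signal group's anchor (top SNP) and one member."""

    top_snp_id: str
    member_snp_id: str
    r2: float


def r2_pair(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing values are handled by pairwise-complete deletion. Values are
    clamped into [0, 1] (floating-point excursions above 1 by <= 1e-12 are
    truncated). Returns the NaN sentinel when LD is undefined.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dosage vectors differ in length: {a.shape} vs {b.shape}")
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 2:
        return R2_MISSING
    a, b = a[mask], b[mask]
    da, db = a - a.mean(), b - b.mean()
    va, vb = np.dot(da, da), np.dot(db, db)
    if va == 0.0 or vb == 0.0:
        return R2_MISSING
    r2 = np.dot(da, db) ** 2 / (va * vb)
    return float(min(max(r2, 0.0), 1.0))


def r2_to_anchor(table: GenotypeTable, anchor_id: str,
                 member_ids) -> list[LdToTop]:
    """r² between one anchor variant and each member (anchor included: 1.0,
    provided its dosage variance is non-zero)."""
    anchor = table.dosages_for(anchor_id)
    out = []
    for mid in member_ids:
        out.append(LdToTop(anchor_id, mid, r2_pair(anchor, table.dosages_for(mid))))
    return out


class GenotypeLdSource:
    """LD provider backed by a genotype table (computes r² on demand)."""

    def __init__(self, table: GenotypeTable):
        self.table = table
        self._cache: dict[tuple[str, str], float] = {}

    def r2(self, snp_a: str, snp_b: str) -> float:
        key = (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)
        if key not in self._cache:
            self._cache[key] = r2_pair(self.table.dosages_for(snp_a),
                                       self.table.dosages_for(snp_b))
        return self._cache[key]


class PlinkLdTable:
    """LD provider backed by a precomputed PLINK ``.ld`` table
    (columns SNP_A, SNP_B, R2); pairs absent from the table — including
    self-pairs unless listed — yield the NaN sentinel."""

    def __init__(self, pairs: dict[tuple[str, str], float]):
        self._pairs = pairs

    @classmethod
    def from_file(cls, path) -> "PlinkLdTable":
        df = pd.read_csv(path, sep=r"\s+", dtype={"SNP_A": str, "SNP_B": str})
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing PLINK .ld column {col!r}")
        pairs: dict[tuple[str, str], float] = {}
        for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"].astype(float)):
            pairs[(a, b)] = r2
            pairs[(b, a)] = r2
            pairs.setdefault((a, a), 1.0)
            pairs.setdefault((b, b), 1.0)
        return cls(pairs)

    def r2(self, snp_a: str, snp_b: str) -> float:
        return self._pairs.get((snp_a, snp_b), R2_MISSING)
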