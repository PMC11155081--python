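"""Upstream GWAS statistics: QC filters, HWE exact test, covariate-adjusted
additive logistic association, genomic inflation factor, and Manhattan/QQ
coordinate preparation.

QC thresholds default to the standard operating point for a small case-control
WGS scan: variant and sample missingness <= 10%, MAF >= 1% (strictly below 1%
is removed), HWE exact p >= 1e-4 (strictly below is removed), autosomes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats import AUTOSOMES, GenotypeTable, SnpAssociation, chrom_sort_key

log = logging.getLogger(__name__)


@dataclass
class QcReport:
    n_input_variants: int = 0
    n_removed_nonautosomal: int = 0
    n_removed_sample_missing: int = 0   # samples, not variants
    n_removed_geno_missing: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_output_variants: int = 0

    def variant_removals(self) -> int:
        return (self.n_removed_nonautosomal + self.n_removed_geno_missing
                + self.n_removed_maf + self.n_removed_hwe)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one (the
    probability-ordering two-sided rule, as in PLINK's --hwe). The chi-square
    approximation misbehaves exactly where this matters — rare alleles in a
    few hundred samples — so the test is exact.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    m = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)  # minor allele count
    if m == 0:
        return 1.0
    # attainable heterozygote counts share the parity of the minor allele count
    hets = np.arange(m % 2, m + 1, 2)
    # unnormalized probabilities by upward recurrence:
    # P(h+2)/P(h) = 4 * hom_minor(h) * hom_major(h) / ((h+1)(h+2))
    hom_minor = (m - hets) / 2
    hom_major = n - hets - hom_minor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (4.0 * hom_minor[:-1] * hom_major[:-1]
                  / ((hets[:-1] + 1.0) * (hets[:-1] + 2.0)))
    logp = np.concatenate(([0.0], np.cumsum(np.log(ratios))))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_idx = int(np.searchsorted(hets, n_het))
    if obs_idx >= len(hets) or hets[obs_idx] != n_het:
        raise ValueError(
            f"heterozygote count {n_het} unattainable with allele counts "
            f"({m} minor of {2 * n})")
    p = float(probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = dosages[~np.isnan(dosages)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def qc_filter(table: GenotypeTable, geno_miss_max: float = 0.10,
              sample_miss_max: float = 0.10, maf_min: float = 0.01,
              hwe_p_min: float = 1e-4, phenotype: np.ndarray | None = None,
              hwe_controls_only: bool = False, autosomes_only: bool = True,
              ) -> tuple[GenotypeTable, QcReport]:
    """Apply variant/sample QC in a fixed order: non-autosomal variants,
    sample missingness, variant missingness, MAF, HWE.

    Boundary semantics follow the stated thresholds verbatim: a variant is
    removed when missingness is *greater than* the cap, when MAF is *less
    than* the floor, or when the HWE p-value is *below* the cutoff — so MAF
    exactly 0.01 and HWE p exactly 1e-4 are retained.
    """
    report = QcReport(n_input_variants=table.n_variants)
    if table.n_variants == 0:
        raise ValueError("genotype table is empty")
    if hwe_controls_only and phenotype is None:
        raise ValueError("controls-only HWE requires case/control labels")

    if autosomes_only:
        keep = table.variants["chrom"].isin(AUTOSOMES).to_numpy()
        report.n_removed_nonautosomal = int((~keep).sum())
        table = table.subset_variants(keep)

    miss_by_sample = np.isnan(table.dosages).mean(axis=1)
    keep_samples = miss_by_sample <= sample_miss_max
    report.n_removed_sample_missing = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValueError("sample missingness filter removed every sample")
    if report.n_removed_sample_missing:
        table = table.subset_samples(keep_samples)
        if phenotype is not None:
            phenotype = np.asarray(phenotype)[keep_samples]

    miss_by_variant = np.isnan(table.dosages).mean(axis=0)
    keep = miss_by_variant <= geno_miss_max
    report.n_removed_geno_missing = int((~keep).sum())
    table = table.subset_variants(keep)

    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(table.dosages, axis=0) / 2.0
    alt_freq = np.nan_to_num(alt_freq, nan=0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = maf >= maf_min
    report.n_removed_maf = int((~keep).sum())
    table = table.subset_variants(keep)

    if hwe_controls_only:
        hwe_dosages = table.dosages[np.asarray(phenotype) == 0]
    else:
        hwe_dosages = table.dosages
    keep = np.array([hwe_exact_p(*_genotype_counts(hwe_dosages[:, j])) >= hwe_p_min
                     for j in range(table.n_variants)], dtype=bool)
    report.n_removed_hwe = int((~keep).sum())
    table = table.subset_variants(keep)

    report.n_output_variants = table.n_variants
    log.info("QC: %d -> %d variants (nonautosomal %d, variant missingness %d, "
             "MAF %d, HWE %d); %d samples removed",
             report.n_input_variants, report.n_output_variants,
             report.n_removed_nonautosomal, report.n_removed_geno_missing,
             report.n_removed_maf, report.n_removed_hwe,
             report.n_removed_sample_missing)
    return table, report


# ---------------------------------------------------------------------------
# additive logistic association
# ---------------------------------------------------------------------------

MAX_IRLS_ITER = 25
IRLS_TOL = 1e-8


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def fit_logistic(X: np.ndarray, y: np.ndarray):
    """Newton/IRLS fit of a logistic regression.

    Returns (beta, standard errors) or None on failure: singular information
    matrix, no convergence within 25 iterations (the usual symptom of complete
    separation), or a diverging coefficient.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            return None
        beta = beta + delta
        if np.max(np.abs(delta)) < IRLS_TOL:
            if np.max(np.abs(beta)) > 1e2:
                return None
            try:
                cov = np.linalg.inv(X.T @ (X * (( _expit(X @ beta)
                                                 * (1 - _expit(X @ beta)))[:, None])))
            except np.linalg.LinAlgError:
                return None
            se = np.sqrt(np.diag(cov))
            if not np.isfinite(se).all():
                return None
            return beta, se
    return None


def logistic_assoc_additive(table: GenotypeTable, phenotype,
                            covariates=None) -> list[SnpAssociation]:
    """Per-variant additive logistic association with optional covariates.

    Fits logit P(case) ~ dosage + covariates per variant on pairwise-complete
    samples and reports the dosage odds ratio and two-sided Wald p-value.
    Non-converged or separated fits are dropped (count logged). Output is
    sorted by (chrom, bp).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != table.n_samples:
        raise ValueError("phenotype length does not match sample count")
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != table.n_samples:
            raise ValueError("covariate rows do not match sample count")

    out: list[SnpAssociation] = []
    n_failed = 0
    for j in range(table.n_variants):
        d = table.dosages[:, j]
        ok = ~np.isnan(d) & ~np.isnan(y)
        if covariates is not None:
            ok &= ~np.isnan(covariates).any(axis=1)
        dj, yj = d[ok], y[ok]
        if len(np.unique(yj)) < 2 or np.ptp(dj) == 0:
            n_failed += 1
            continue
        cols = [np.ones(ok.sum()), dj]
        if covariates is not None:
            cols.extend(covariates[ok].T)
        X = np.column_stack(cols)
        fit = fit_logistic(X, yj)
        if fit is None:
            n_failed += 1
            continue
        beta, se = fit
        z = beta[1] / se[1]
        p = 2.0 * sps.norm.sf(abs(z))
        p = float(min(max(p, 5e-324), 1.0))
        v = table.variants.iloc[j]
        out.append(SnpAssociation(chrom=v["chrom"], bp=int(v["bp"]),
                                  snp_id=v["snp_id"], a1=v["alt"],
                                  odds_ratio=float(np.exp(beta[1])), p_value=p))
    if n_failed:
        log.info("association: dropped %d variants (monomorphic, separated, "
                 "or non-converged)", n_failed)
    out.sort(key=lambda a: a.sort_key)
    return out


# ---------------------------------------------------------------------------
# genomic inflation factor and plot coordinates
# ---------------------------------------------------------------------------

def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed 1-df association chi-square
    divided by the null median (chi2.ppf(0.5, 1), computed, not hard-coded)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p-value set is empty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = sps.chi2.isf(p, df=1)
    return float(np.median(chi) / sps.chi2.isf(0.5, df=1))


def plot_data(assocs: list[SnpAssociation]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan and QQ coordinates.

    Manhattan: per-chromosome cumulative bp offsets (each chromosome starts
    after the previous one's largest position), y = -log10 p.
    QQ: expected_i = -log10((i - 0.5)/n) for ascending p-value rank i, paired
    with observed order statistics; rows sorted ascending in expected.
    """
    if not assocs:
        raise ValueError("no association records")
    chroms = sorted({a.chrom for a in assocs}, key=chrom_sort_key)
    max_bp = {c: max(a.bp for a in assocs if a.chrom == c) for c in chroms}
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += max_bp[c]
    manhattan = pd.DataFrame({
        "chrom": [a.chrom for a in assocs],
        "bp": [a.bp for a in assocs],
        "x": [offsets[a.chrom] + a.bp for a in assocs],
        "neg_log_p": [a.neg_log_p for a in assocs],
    })
    n = len(assocs)
    obs = np.sort([a.neg_log_p for a in assocs])          # ascending observed
    ranks = np.arange(n, 0, -1)                           # i = n ... 1
    expected = -np.log10((ranks - 0.5) / n)               # ascending expected
    qq = pd.DataFrame({"expected": expected, "observed": obs})
    return manhattan, qq
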