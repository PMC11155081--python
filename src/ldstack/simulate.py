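"""Desk-scale case-control genotype simulator with known truth.

The generator emulates the data regime the prioritization method was built
for: a small case-control cohort (default 35 cases / 478 controls), common
variants organized in haplotype blocks, one planted causal variant of known
odds ratio, and isolated "spike" artifacts — significant SNPs without LD
support, the signature of genotyping error.

LD is induced by a thresholded Gaussian chain: within a block, a latent
standard-normal AR(1) process with per-step correlation ``block_r2_decay`` is
thresholded at each site's allele-frequency quantile (frequencies drawn
U(0.05, 0.5)) to give haplotypes; two haplotypes sum to a dosage. Blocks are
independent and laid out > 50 kb apart with within-block spacing < 5 kb, so
chained regions can never span blocks. Spikes are calibrated by bisection on
a corruption strength (phenotype-correlated dosage miscalls) until their
marginal association p-value lands at a log-uniform target inside
``spike_p_range``.

Everything is deterministic under ``config.seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formats import GenotypeTable, SnpAssociation
from .stats import fit_logistic
from scipy import stats as sps

log = logging.getLogger(__name__)

LABEL_CAUSAL_LINKED = "CAUSAL_LINKED"
LABEL_NULL = "NULL"
LABEL_SPIKE = "SPIKE"

_BLOCK_SPACING_BP = 200_000      # > 50 kb isolation between blocks and spikes
_FIRST_BP = 1_000_000


class CalibrationError(RuntimeError):
    """Spike corruption could not reach the requested significance range."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the motivating cohort: 35 cases vs 478 controls, a causal
    variant of OR 3 in one block, and 20 isolated artifact spikes whose
    significance is drawn log-uniformly from ``spike_p_range`` — WGS batch
    artifacts routinely reach far beyond genome-wide significance, hence the
    wide default range.
    """

    n_cases: int = 35
    n_controls: int = 478
    n_blocks: int = 12
    snps_per_block: int = 20
    block_r2_decay: float = 0.95
    causal_block_index: int = 0
    causal_or: float = 3.0
    baseline_prevalence: float = 0.01
    n_spike_snps: int = 20
    spike_p_range: tuple[float, float] = (1e-30, 0.04)
    spike_clustered: bool = False          # stress mode: one 5 kb spike stack
    spike_block_r2_decay: float = 1.0      # latent decay of the stress stack
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 samples per class")
        if not (0 < self.block_r2_decay <= 1):
            raise ValueError("block_r2_decay must lie in (0, 1]")
        if not self.causal_or > 0:
            raise ValueError("causal_or must be positive")
        lo, hi = self.spike_p_range
        if not (0 < lo < hi < 1):
            raise ValueError("spike_p_range must satisfy 0 < lo < hi < 1")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class SyntheticTruth:
    """Per-variant generator-side labels for recovery benchmarking."""

    labels: dict[str, str]                 # snp_id -> CAUSAL_LINKED/NULL/SPIKE
    r2_to_causal: dict[str, float]         # structural r² for linked variants
    causal_snp_id: str
    causal_block_span: tuple[int, int]     # (start_bp, end_bp) of the causal block
    spike_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    table: GenotypeTable
    phenotype: np.ndarray
    truth: SyntheticTruth
    config: SimulationConfig


def _block_id(block: int, snp: int) -> str:
    return f"blk{block}_{snp}"


def causal_snp_id(config: SimulationConfig) -> str:
    return _block_id(config.causal_block_index, config.snps_per_block // 2)


def _threshold_haplotypes(latent: np.ndarray, freqs: np.ndarray,
                          n_samples: int) -> np.ndarray:
    """Threshold a (2N, L) latent matrix at allele-frequency quantiles and
    fold haplotype pairs into dosages."""
    alleles = (latent < norm.ppf(freqs)[None, :]).astype(float)
    return alleles[:n_samples] + alleles[n_samples:]


def _latent_chain(rng: np.random.Generator, n_rows: int, n_sites: int,
                  rho: float) -> np.ndarray:
    z = np.empty((n_rows, n_sites))
    z[:, 0] = rng.standard_normal(n_rows)
    scale = math.sqrt(max(0.0, 1.0 - rho * rho))
    for j in range(1, n_sites):
        z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(n_rows)
    return z


def _block_freqs(rng: np.random.Generator, n_sites: int) -> np.ndarray:
    """Per-site alt-allele frequencies for one block: a block-level base
    frequency drawn U(0.05, 0.5) with small per-site jitter. Variants on a
    shared haplotype background have near-equal frequencies; wildly different
    thresholds would destroy dosage LD even at perfect latent correlation."""
    base = rng.uniform(0.06, 0.49)
    return np.clip(base + rng.uniform(-0.01, 0.01, size=n_sites), 0.05, 0.5)


def simulate_haplotype_blocks(config: SimulationConfig,
                              rng: np.random.Generator | None = None
                              ) -> GenotypeTable:
    """Generate the block-structured genotype table (no spikes yet)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_samples
    meta, cols = [], []
    for b in range(config.n_blocks):
        L = config.snps_per_block
        freqs = _block_freqs(rng, L)
        latent = _latent_chain(rng, 2 * n, L, config.block_r2_decay)
        dosages = _threshold_haplotypes(latent, freqs, n)
        bp = _FIRST_BP + b * _BLOCK_SPACING_BP
        for j in range(L):
            bp += int(rng.integers(200, 2000))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            meta.append(("1", bp, _block_id(b, j), ref, alt))
            cols.append(dosages[:, j])
    variants = pd.DataFrame(meta, columns=["chrom", "bp", "snp_id", "ref", "alt"])
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeTable(sample_ids, variants, np.column_stack(cols))


def assign_phenotype(table: GenotypeTable, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Assign exact case/control counts under a logistic disease model.

    Disease odds are exp(alpha + log(causal_or) * dosage) at the causal
    variant; cases are drawn without replacement with probability
    proportional to those odds (retrospective case-control sampling, which
    preserves the dosage log-OR up to the intercept), so the returned vector
    has exactly ``n_cases`` ones and ``n_controls`` zeros. With causal_or = 1
    the phenotype is independent of every dosage.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if table.n_samples != config.n_samples:
        raise ValueError("table sample count does not match config")
    cid = causal_snp_id(config)
    if not table.has_variant(cid):
        raise ValueError(f"causal variant {cid!r} not present in table")
    d = table.dosages_for(cid)
    if np.isnan(d).any():
        raise ValueError("causal variant has missing dosages")
    beta = math.log(config.causal_or)
    w = np.exp(beta * (d - d.mean()))      # odds up to a constant factor
    cases = rng.choice(table.n_samples, size=config.n_cases, replace=False,
                       p=w / w.sum())
    y = np.zeros(table.n_samples)
    y[cases] = 1.0
    return y


# ---------------------------------------------------------------------------
# spike injection
# ---------------------------------------------------------------------------

def _wald_p(d: np.ndarray, y: np.ndarray) -> float:
    """Marginal additive Wald p of a dosage vector (0.0 stands for a
    separated/diverged fit, i.e. 'beyond any finite significance')."""
    if np.ptp(d) == 0:
        return 1.0
    fit = fit_logistic(np.column_stack([np.ones_like(d), d]), y)
    if fit is None:
        return 0.0
    beta, se = fit
    return float(2.0 * sps.norm.sf(abs(beta[1] / se[1])))


def _corrupt(base: np.ndarray, t: float, case_order: np.ndarray,
             ctrl_order: np.ndarray) -> np.ndarray:
    """Phenotype-correlated miscalls of strength t in [0, 2]: the first unit
    bumps a growing share of case dosages up, the second lowers controls."""
    d = base.copy()
    k_case = int(round(min(t, 1.0) * len(case_order)))
    if k_case:
        idx = case_order[:k_case]
        d[idx] = np.minimum(d[idx] + 1, 2)
    if t > 1.0:
        k_ctrl = int(round((t - 1.0) * len(ctrl_order)))
        if k_ctrl:
            idx = ctrl_order[:k_ctrl]
            d[idx] = np.maximum(d[idx] - 1, 0)
    return d


def _calibrate_spike(base: np.ndarray, y: np.ndarray, target_p: float,
                     p_range: tuple[float, float],
                     rng: np.random.Generator,
                     orders: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> np.ndarray:
    """Bisection (<= 30 iterations) on corruption strength until the marginal
    Wald p lands within half a decade of ``target_p`` (always inside
    ``p_range``). ``orders`` fixes which samples are miscalled first; sharing
    it across a stack of sites models a systematic artifact hitting the same
    samples with varying penetrance."""
    lo, hi = p_range
    if orders is not None:
        case_order, ctrl_order = orders
    else:
        case_order = rng.permutation(np.flatnonzero(y == 1))
        ctrl_order = rng.permutation(np.flatnonzero(y == 0))
    p0 = _wald_p(base, y)
    if p0 < lo:
        raise CalibrationError("base variant already beyond the target range")
    if p0 <= hi and abs(math.log10(p0) - math.log10(target_p)) < 0.5:
        return base
    log_t = math.log10(target_p)
    t_lo, t_hi = 0.0, 2.0
    best, best_gap = None, float("inf")
    for _ in range(30):
        mid = 0.5 * (t_lo + t_hi)
        d = _corrupt(base, mid, case_order, ctrl_order)
        pm = _wald_p(d, y)
        if pm > 0:
            gap = abs(math.log10(pm) - log_t)
            if lo <= pm <= hi and gap < best_gap:
                best, best_gap = d, gap
            if gap < 0.5 and lo <= pm <= hi:
                return d
        if pm > target_p:
            t_lo = mid          # not significant enough yet
        else:
            t_hi = mid
    if best is not None:
        return best
    raise CalibrationError(
        f"could not reach p ~ {target_p:.2g} within {p_range}")


def inject_spikes(table: GenotypeTable, phenotype: np.ndarray,
                  config: SimulationConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[GenotypeTable, SyntheticTruth]:
    """Add artifact spike variants and assemble the truth labels.

    Isolated mode (default) places each spike > 50 kb from every block and
    from each other, so no spike can ever contribute to a region. Clustered
    stress mode instead packs them into one 5 kb window as a high-LD stack
    (latent decay ``spike_block_r2_decay``) whose members are corrupted
    *independently* — mutual r² stays high while the p-values are decoupled
    from it, the exact pattern the MAE score exists to reject.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    y = np.asarray(phenotype, dtype=float)

    truth = _base_truth(table, config)
    if config.n_spike_snps == 0:
        return table, truth

    n = table.n_samples
    k = config.n_spike_snps
    lo, hi = config.spike_p_range
    # keep targets half a decade inside the range so the +-0.5-decade
    # calibration tolerance cannot push a realized p outside it
    tlo, thi = math.log10(lo) + 0.5, math.log10(hi) - 0.5

    start_bp = _FIRST_BP + (config.n_blocks + 1) * _BLOCK_SPACING_BP
    spike_cols, spike_meta, spike_ids = [], [], []
    for attempt in range(10):
        try:
            orders = None
            if config.spike_clustered:
                freqs = np.clip(rng.uniform(0.3, 0.45)
                                + rng.uniform(-0.01, 0.01, size=k), 0.05, 0.5)
                latent = _latent_chain(rng, 2 * n, k, config.spike_block_r2_decay)
                bases = _threshold_haplotypes(latent, freqs, n)
                # one systematic artifact: the same samples are miscalled
                # across the whole stack, with per-site penetrance
                orders = (rng.permutation(np.flatnonzero(y == 1)),
                          rng.permutation(np.flatnonzero(y == 0)))
            else:
                freqs = rng.uniform(0.1, 0.4, size=k)
                bases = rng.binomial(2, freqs[None, :], size=(n, k)).astype(float)
            spike_cols = []
            for j in range(k):
                target = 10.0 ** rng.uniform(tlo, thi)
                spike_cols.append(
                    _calibrate_spike(bases[:, j], y, target,
                                     config.spike_p_range, rng, orders))
            break
        except CalibrationError:
            if attempt == 9:
                raise
            continue

    bp = start_bp
    for j in range(k):
        bp += int(rng.integers(200, 450)) if config.spike_clustered \
            else _BLOCK_SPACING_BP
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        sid = f"spike{j}"
        spike_meta.append(("1", bp, sid, ref, alt))
        spike_ids.append(sid)

    variants = pd.concat([
        table.variants,
        pd.DataFrame(spike_meta, columns=["chrom", "bp", "snp_id", "ref", "alt"]),
    ], ignore_index=True)
    dosages = np.column_stack([table.dosages] + spike_cols)
    out = GenotypeTable(table.sample_ids, variants, dosages)

    for sid in spike_ids:
        truth.labels[sid] = LABEL_SPIKE
    truth.spike_ids = spike_ids
    return out, truth


def _base_truth(table: GenotypeTable, config: SimulationConfig) -> SyntheticTruth:
    cid = causal_snp_id(config)
    c_block = config.causal_block_index
    c_idx = config.snps_per_block // 2
    labels, r2 = {}, {}
    span = [None, None]
    for row in table.variants.itertuples():
        sid = row.snp_id
        if sid.startswith(f"blk{c_block}_"):
            j = int(sid.rsplit("_", 1)[1])
            labels[sid] = LABEL_CAUSAL_LINKED
            # structural squared correlation of the latent chain
            r2[sid] = config.block_r2_decay ** (2 * abs(j - c_idx))
            span[0] = row.bp if span[0] is None else min(span[0], row.bp)
            span[1] = row.bp if span[1] is None else max(span[1], row.bp)
        else:
            labels[sid] = LABEL_NULL
    return SyntheticTruth(labels=labels, r2_to_causal=r2, causal_snp_id=cid,
                          causal_block_span=(span[0], span[1]))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate genotypes, phenotype and truth labels in one deterministic run."""
    rng = np.random.default_rng(config.seed)
    table = simulate_haplotype_blocks(config, rng)
    phenotype = assign_phenotype(table, config, rng)
    table, truth = inject_spikes(table, phenotype, config, rng)
    return SimulatedDataset(table, phenotype, truth, config)


def permute_pvalues_in_window(assocs: list[SnpAssociation], chrom: str,
                              start_bp: int, end_bp: int,
                              rng: np.random.Generator) -> list[SnpAssociation]:
    """Permute (OR, p) pairs among the records inside a window.

    This destroys any p-value/LD consistency while preserving positions and
    the LD structure — the canonical negative control for the MAE score.
    """
    from .formats import normalize_chrom
    chrom = normalize_chrom(chrom)
    idx = [i for i, a in enumerate(assocs)
           if a.chrom == chrom and start_bp <= a.bp <= end_bp]
    perm = rng.permutation(len(idx))
    out = list(assocs)
    for slot, src in zip(idx, (idx[j] for j in perm)):
        a, b = assocs[slot], assocs[src]
        out[slot] = SnpAssociation(chrom=a.chrom, bp=a.bp, snp_id=a.snp_id,
                                   a1=a.a1, odds_ratio=b.odds_ratio,
                                   p_value=b.p_value)
    return out
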