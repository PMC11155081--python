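"""LD-consistency prioritization of GWAS association signals.

A genome scan with few cases produces two kinds of significant hits: "stacked"
regions, where many SNPs in mutual LD reach comparable significance, and
isolated spikes with no LD support, typically genotyping artifacts. This module
separates the two:

1. significant SNPs (p < 0.05) are chained by genomic distance into
   non-overlapping regions (consecutive significant SNPs <= 5 kb apart join;
   regions need >= 10 significant SNPs);
2. within a region, SNPs are split by direction of effect (OR > 1 vs OR < 1)
   and grouped by LD (r² > 0.4) to the strongest unassigned SNP, iteratively,
   so independent signals are evaluated separately;
3. each group's p-value consistency is scored against the prediction
   s_hat = s_max * r², where s is -log10(p) and s_max that of the top SNP, as
   the mean absolute error MAE = sum_k |s_k - s_hat_k| / K;
4. regions with at least one multi-SNP group with MAE < 3.0 are prioritized.

The rationale for the prediction line: under an additive model the expected
association chi-square of a SNP in LD r² with a causal variant scales by r²,
so -log10 p of genuinely linked SNPs tracks s_max * r², while artifacts do not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .formats import Direction, SnpAssociation
from .ld import R2_MISSING, is_r2_missing

log = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    """Tuning surface of the prioritization algorithm.

    Defaults are the published operating point: p < 0.05 significance,
    5 kb chaining distance, >= 10 significant SNPs per region, r² > 0.4 group
    membership, MAE < 3.0 prioritization, -log10 scale.
    """

    p_threshold: float = 0.05
    max_gap_bp: int = 5000
    min_significant: int = 10
    r2_threshold: float = 0.4
    mae_threshold: float = 3.0
    log_base: float = 10.0
    #: a group needs this many members for its MAE to qualify a region;
    #: a singleton's MAE is identically 0 and carries no LD corroboration.
    min_group_size: int = 2
    #: when True, all region SNPs (not only significant ones) enter groups.
    score_all_region_snps: bool = False

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        for name in ("max_gap_bp", "min_significant", "mae_threshold",
                     "log_base", "min_group_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def neg_log(self, p: float) -> float:
        return -math.log(p) / math.log(self.log_base)


@dataclass
class SignalGroup:
    """A same-direction, LD-linked set of SNPs anchored on its top SNP."""

    direction: Direction
    top_snp: SnpAssociation
    members: list[SnpAssociation]
    r2_values: list[float]       # r² of each member to the top SNP
    predicted: list[float]       # s_hat = s_max * r² per member
    residuals: list[float]       # |s - s_hat| per member
    mae: float                   # mean residual, or NaN when LD is unavailable

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Region:
    """A non-overlapping cluster of SNPs anchored by chained significant SNPs.

    Boundaries are the min/max position (1-based inclusive) of the member
    significant SNPs; ``all_snps`` holds every input SNP inside them.
    """

    chrom: str
    start_bp: int
    end_bp: int
    significant_snps: list[SnpAssociation]
    all_snps: list[SnpAssociation] = field(default_factory=list)
    signal_groups: list[SignalGroup] = field(default_factory=list)
    prioritized: bool = False

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


def chain_regions(assocs: list[SnpAssociation], config: ClusterConfig) -> list[Region]:
    """Chain significant SNPs into candidate regions (single linkage on bp).

    Input must be sorted by (chrom, bp) — the readers' contract. Chaining
    distance is measured between significant SNPs only: non-significant SNPs
    neither bridge nor break a chain, but every SNP falling inside the final
    boundaries is recorded in ``all_snps``.
    """
    keys = [a.sort_key for a in assocs]
    if keys != sorted(keys):
        raise ValueError("associations must be sorted by (chrom, bp)")

    regions: list[Region] = []
    chain: list[SnpAssociation] = []

    def flush():
        if len(chain) >= config.min_significant:
            regions.append(Region(chain[0].chrom, chain[0].bp, chain[-1].bp,
                                  significant_snps=list(chain)))
        chain.clear()

    for a in assocs:
        if not (a.p_value < config.p_threshold):
            continue
        if chain and (a.chrom != chain[-1].chrom
                      or a.bp - chain[-1].bp > config.max_gap_bp):
            flush()
        chain.append(a)
    flush()

    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for a in assocs:
        for r in by_chrom.get(a.chrom, ()):
            if r.start_bp <= a.bp <= r.end_bp:
                r.all_snps.append(a)
                break
    return regions


def predicted_neglogp(s_max: float, r2: float) -> float:
    """Predicted -log10 p of a member SNP: s_hat = s_max * r².

    The NaN no-LD-information sentinel propagates.
    """
    if is_r2_missing(r2):
        return R2_MISSING
    if s_max < 0:
        raise ValueError("s_max must be non-negative")
    if not (0 <= r2 <= 1):
        raise ValueError("r2 must lie in [0, 1]")
    return s_max * r2


def group_mae(member_neglogps, member_r2s) -> float:
    """MAE = sum_k |s_k - s_max * r²_k| / K over the group's members.

    s_max is the maximum of the supplied -log10 p-values. Any member with the
    no-LD-information sentinel makes the whole group unscoreable (NaN).
    """
    s = np.asarray(member_neglogps, dtype=float)
    r2 = np.asarray(member_r2s, dtype=float)
    if s.size == 0:
        raise ValueError("group must contain at least one member")
    if s.shape != r2.shape:
        raise ValueError("s and r² vectors differ in length")
    if np.isnan(s).any() or (s < 0).any():
        raise ValueError("-log10 p-values must be finite and non-negative")
    if np.isnan(r2).any():
        return R2_MISSING
    s_max = float(s.max())
    return float(np.mean(np.abs(s - s_max * r2)))


def _top_key(snp: SnpAssociation):
    # strongest first; ties broken by smaller bp, then lexicographic id
    return (-snp.neg_log_p, snp.bp, snp.snp_id)


def form_signal_groups(region: Region, ld_source, config: ClusterConfig) -> Region:
    """Populate a region's signal groups by iterative greedy re-anchoring.

    Per direction of effect, the strongest unassigned SNP becomes a top SNP
    and claims every unassigned same-direction SNP with r² above threshold to
    it; this repeats until each SNP belongs to exactly one group. SNPs with
    OR exactly 1 stay in the region but are never grouped or scored. An
    anchor without usable LD (monomorphic, absent from the LD source) yields
    a group with the sentinel MAE, which can never satisfy the threshold.
    """
    pool_source = region.all_snps if config.score_all_region_snps else region.significant_snps
    region.signal_groups = []
    for direction in (Direction.UP, Direction.DOWN):
        pool = sorted((s for s in pool_source if s.direction is direction),
                      key=_top_key)
        while pool:
            top = pool.pop(0)
            r2s = {}
            for s in pool + [top]:
                try:
                    r2s[s.snp_id] = ld_source.r2(top.snp_id, s.snp_id)
                except KeyError:
                    r2s[s.snp_id] = R2_MISSING
            members = [top]
            rest = []
            for s in pool:
                r2 = r2s[s.snp_id]
                if not is_r2_missing(r2) and r2 > config.r2_threshold:
                    members.append(s)
                else:
                    rest.append(s)
            pool = rest
            r2_vals = [r2s[s.snp_id] for s in members]
            s_vals = [s.neg_log_p for s in members]
            mae = group_mae(s_vals, r2_vals)
            if math.isnan(mae):
                predicted = [R2_MISSING] * len(members)
                residuals = [R2_MISSING] * len(members)
            else:
                s_max = max(s_vals)
                predicted = [predicted_neglogp(s_max, r2) for r2 in r2_vals]
                residuals = [abs(s - p) for s, p in zip(s_vals, predicted)]
            region.signal_groups.append(SignalGroup(
                direction=direction, top_snp=top, members=members,
                r2_values=r2_vals, predicted=predicted, residuals=residuals,
                mae=mae))
    return region


def prioritize(regions: list[Region], config: ClusterConfig) -> list[Region]:
    """Flag regions containing at least one qualifying signal group.

    A group qualifies when its MAE is a real number strictly below the
    threshold (the boundary MAE == threshold does not qualify) and it has at
    least ``min_group_size`` members.
    """
    for r in regions:
        r.prioritized = any(
            g.size >= config.min_group_size
            and not math.isnan(g.mae)
            and g.mae < config.mae_threshold
            for g in r.signal_groups)
    n_prio = sum(r.prioritized for r in regions)
    n_snps = sum(len(r.all_snps) for r in regions if r.prioritized)
    log.info("prioritized %d/%d regions containing %d SNPs",
             n_prio, len(regions), n_snps)
    return regions


def run_cluster_analysis(assocs: list[SnpAssociation], ld_source,
                         config: ClusterConfig | None = None
                         ) -> tuple[list[Region], list[SnpAssociation]]:
    """Full chain: region chaining -> signal grouping -> prioritization.

    Returns all regions (flagged) plus the association records inside
    prioritized region boundaries.
    """
    config = config or ClusterConfig()
    regions = chain_regions(assocs, config)
    for r in regions:
        form_signal_groups(r, ld_source, config)
    prioritize(regions, config)
    prioritized_assocs = [a for r in regions if r.prioritized for a in r.all_snps]
    prioritized_assocs.sort(key=lambda a: a.sort_key)
    return regions, prioritized_assocs
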