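"""Instrument selection from an exposure GWAS, and instrument-strength metrics.

Selection follows the conventional clumping pipeline, with a fixed stage
order: (1) genome-wide significance filter (default p < 5e-8); (2) greedy
LD pruning by ascending p-value (r2 < 0.001 within a 10,000 kb window);
(3) minor-allele-frequency filter (default MAF > 1%); (4) removal of
variants on a confounder-association exclusion list.  Each stage logs the
counts entering and leaving, so the familiar "21 extracted, 1 pruned,
1 confounder-excluded, 19 kept" style of accounting can be reproduced
exactly from the audit trail.

Strength is summarised per variant by the variance explained
R2_j = beta_j^2 / (beta_j^2 + N * se_j^2) (equivalently t^2 / (t^2 + N)),
summed under the independence assumption, and converted to an F-statistic
F = R2 (N - 2) / (1 - R2); F < 10 conventionally flags weak-instrument bias.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .sumstats import LDTable, SummaryDataset, VariantRecord

log = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


@dataclass
class SelectionConfig:
    """Thresholds for the instrument-selection pipeline."""

    p_threshold: float = 5e-8
    ld_r2_max: float = 0.001
    ld_window_kb: int = 10_000
    maf_min: float = 0.01
    exclusion_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 <= self.ld_r2_max <= 1):
            raise ValueError("ld_r2_max must be in [0, 1]")
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.ld_window_kb <= 0:
            raise ValueError("ld_window_kb must be positive")


@dataclass(frozen=True)
class StageAudit:
    stage: str
    n_in: int
    n_out: int
    removed_ids: tuple[str, ...]


@dataclass
class SelectionResult:
    selected: list[str]
    audit: list[StageAudit]


@dataclass
class StrengthReport:
    """Variance explained and F-statistics for a set of instruments."""

    per_snp_r2: dict[str, float]
    per_snp_f: dict[str, float]
    total_r2: float
    f_stat: float
    n: int

    @property
    def weak_ids(self) -> list[str]:
        return [vid for vid, f in self.per_snp_f.items() if f < WEAK_F_THRESHOLD]

    @property
    def any_weak(self) -> bool:
        return bool(self.weak_ids)


def _colocated(a: VariantRecord, b: VariantRecord, window_kb: int) -> bool | None:
    """Whether two variants fall within the LD window; None when unknowable."""
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return None
    if a.chrom != b.chrom:
        return False
    return abs(a.pos - b.pos) <= window_kb * 1000


def select_instruments(
    exposure: SummaryDataset,
    ld: LDTable | None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the four-stage selection pipeline and return ids plus audit trail.

    LD pruning is greedy by ascending p-value (ties broken by variant id):
    a candidate is kept only if its r2 with every already-kept variant in
    the same window is below ``ld_r2_max``.  An unknown r2 between
    co-located variants counts as failing (the candidate is pruned); pairs
    on different chromosomes or beyond the window are treated as
    independent.  When positions are unavailable, only an explicit LD-table
    entry can prune.
    """
    config = config or SelectionConfig()
    if len(exposure) == 0:
        raise ValueError("exposure dataset is empty")
    ld = ld or LDTable()
    audit: list[StageAudit] = []

    candidates = list(exposure)

    # stage 1: significance
    survivors = [r for r in candidates if r.pval < config.p_threshold]
    audit.append(_stage("significance", candidates, survivors))

    # stage 2: greedy LD pruning, best p first
    ordered = sorted(survivors, key=lambda r: (r.pval, r.variant_id))
    kept: list[VariantRecord] = []
    for rec in ordered:
        pruned = False
        for prior in kept:
            near = _colocated(rec, prior, config.ld_window_kb)
            r2 = ld.query(rec.variant_id, prior.variant_id)
            if near is False:
                continue
            if near is True:
                if r2 is None or r2 >= config.ld_r2_max:
                    pruned = True
                    break
            else:  # location unknown: prune only on explicit evidence
                if r2 is not None and r2 >= config.ld_r2_max:
                    pruned = True
                    break
        if not pruned:
            kept.append(rec)
        else:
            log.debug("LD-pruned %s", rec.variant_id)
    if any(
        _colocated(a, b, config.ld_window_kb) is None
        for i, a in enumerate(kept)
        for b in kept[i + 1 :]
        if ld.query(a.variant_id, b.variant_id) is None
    ):
        log.warning("some kept pairs have unknown position and unknown LD; treated as independent")
    audit.append(_stage("ld_prune", ordered, kept))

    # stage 3: MAF
    maf_pass = []
    for rec in kept:
        maf = rec.maf
        if maf is None:
            log.warning("%s: no EAF, MAF filter skipped for this variant", rec.variant_id)
            maf_pass.append(rec)
        elif maf > config.maf_min:
            maf_pass.append(rec)
    audit.append(_stage("maf", kept, maf_pass))

    # stage 4: confounder exclusion list
    final = [r for r in maf_pass if r.variant_id not in config.exclusion_ids]
    audit.append(_stage("exclusion", maf_pass, final))

    if not final:
        counts = "; ".join(f"{a.stage}: {a.n_in}->{a.n_out}" for a in audit)
        raise ValueError(f"no instruments survive selection ({counts})")

    final_sorted = sorted(final, key=lambda r: (r.pval, r.variant_id))
    return SelectionResult(selected=[r.variant_id for r in final_sorted], audit=audit)


def _stage(name: str, before: Sequence[VariantRecord], after: Sequence[VariantRecord]) -> StageAudit:
    after_ids = {r.variant_id for r in after}
    removed = tuple(sorted(r.variant_id for r in before if r.variant_id not in after_ids))
    return StageAudit(stage=name, n_in=len(before), n_out=len(after), removed_ids=removed)


def variance_explained(record: VariantRecord, n: int | None = None) -> float:
    """Per-variant proportion of exposure variance explained.

    R2 = beta^2 / (beta^2 + n * se^2), the standard summary-statistics
    approximation; ``n`` falls back to the record's own sample size.
    """
    n = n if n is not None else record.n
    if n is None:
        raise ValueError(
            f"{record.variant_id}: sample size required to compute variance explained; "
            "supply n explicitly or set it on the record"
        )
    b2 = record.beta**2
    return b2 / (b2 + n * record.se**2)


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F-statistic, F = R2 (N - 2) / (1 - R2)."""
    if not (0 <= r2 < 1):
        raise ValueError("r2 must be in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return r2 * (n - 2) / (1 - r2)


def strength_report(
    exposure: SummaryDataset, instrument_ids: Sequence[str], n: int | None = None
) -> StrengthReport:
    """Variance explained and F per instrument, plus totals.

    ``total_r2`` sums per-variant contributions, valid under the mutual
    independence the LD-pruning stage enforces.
    """
    per_r2: dict[str, float] = {}
    per_f: dict[str, float] = {}
    n_eff: int | None = None
    for vid in instrument_ids:
        rec = exposure.records[vid]
        n_j = n if n is not None else rec.n
        r2 = variance_explained(rec, n_j)
        per_r2[vid] = r2
        per_f[vid] = f_statistic(r2, n_j)
        n_eff = n_j if n_eff is None else max(n_eff, n_j)
    total = sum(per_r2.values())
    return StrengthReport(
        per_snp_r2=per_r2,
        per_snp_f=per_f,
        total_r2=total,
        f_stat=f_statistic(total, n_eff),
        n=n_eff,
    )


def write_audit_trail(audit: Sequence[StageAudit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "stage": a.stage,
                "n_in": a.n_in,
                "n_out": a.n_out,
                "removed_ids": ";".join(a.removed_ids),
            }
            for a in audit
        ]
    )
    df.to_csv(path, sep="\t", index=False)
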