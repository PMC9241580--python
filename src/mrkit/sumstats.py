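"""Reading, validating and writing GWAS summary-statistic tables.

The canonical column schema is ``variant_id, effect_allele, other_allele,
eaf, beta, se, pval, n`` (optionally ``chrom, pos``).  Files using other
header names are mapped onto this schema with a ``column_map``; parsing is
always column-name driven, never positional.  Auxiliary inputs — a pairwise
LD r-squared table, a confounder-exclusion list and a proxy-variant map —
use small fixed TSV dialects described in the reader docstrings.

Effect sizes (``beta``) are per effect-allele and, for binary traits, on
the log-odds scale.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("eaf", "n", "chrom", "pos")

#: Palindromic allele pairs: strand cannot be resolved from alleles alone.
_PALINDROMES = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class VariantRecord:
    """One variant's summary association with a single trait.

    ``beta`` is the additive per-allele effect of ``effect_allele``; for a
    binary trait it is a log odds ratio.  ``eaf`` is the effect-allele
    frequency and ``n`` the total sample size of the contributing GWAS.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be single bases in ACGT")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be finite and > 0")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta must be finite")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must be in (0, 1)")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos is 1-based and must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in _PALINDROMES

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency derived from the effect-allele frequency."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryDataset:
    """A GWAS summary-statistics table for one trait, keyed by variant id."""

    trait_name: str
    records: dict[str, VariantRecord] = field(default_factory=dict)
    trait_type: str = "binary"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records.values())

    def get(self, variant_id: str) -> VariantRecord | None:
        return self.records.get(variant_id)

    @property
    def n_total(self) -> int | None:
        if self.n_cases is not None and self.n_controls is not None:
            return self.n_cases + self.n_controls
        return None

    @classmethod
    def from_records(
        cls, trait_name: str, records: Iterable[VariantRecord], **kwargs
    ) -> "SummaryDataset":
        out: dict[str, VariantRecord] = {}
        for rec in records:
            if rec.variant_id in out:
                raise ValueError(f"duplicate variant_id {rec.variant_id}")
            out[rec.variant_id] = rec
        return cls(trait_name=trait_name, records=out, **kwargs)


@dataclass(frozen=True)
class ProxyEntry:
    original: str
    proxy: str
    r2: float

    def __post_init__(self) -> None:
        if not (0 < self.r2 <= 1):
            raise ValueError(f"proxy r2 for {self.original} must be in (0, 1]")


@dataclass
class ProxyMap:
    """Map from an instrument id to a substitute variant in high LD with it."""

    entries: dict[str, ProxyEntry] = field(default_factory=dict)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.entries

    def get(self, variant_id: str) -> ProxyEntry | None:
        return self.entries.get(variant_id)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, str, float]]) -> "ProxyMap":
        return cls({orig: ProxyEntry(orig, proxy, r2) for orig, proxy, r2 in tuples})


class LDTable:
    """Symmetric pairwise r-squared lookup.

    A missing pair returns ``None`` ("unknown"), never an implicit 0: the
    caller decides how to treat unknown correlation.  Self-queries return 1.
    """

    def __init__(self) -> None:
        self._r2: dict[frozenset, float] = {}

    def add(self, id_a: str, id_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 for ({id_a}, {id_b}) outside [0, 1]: {r2}")
        if id_a == id_b:
            return
        self._r2[frozenset((id_a, id_b))] = r2

    def query(self, id_a: str, id_b: str) -> float | None:
        if id_a == id_b:
            return 1.0
        return self._r2.get(frozenset((id_a, id_b)))

    def __len__(self) -> int:
        return len(self._r2)

    def items(self) -> Iterator[tuple[str, str, float]]:
        for pair, r2 in self._r2.items():
            a, b = sorted(pair)
            yield a, b, r2


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns onto the canonical schema.

    ``column_map`` maps canonical name -> column name in the file.
    """
    if not column_map:
        return df
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise ValueError(f"column_map refers to absent file column(s): {missing}")
    return df.rename(columns={src: canon for canon, src in column_map.items()})


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "binary",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryDataset:
    """Read a TSV of summary statistics into a validated :class:`SummaryDataset`.

    Rows violating the record invariants (non-positive SE, identical
    alleles, out-of-range p or frequency, ...) are dropped with a logged
    count rather than aborting the run; the remaining instrument list is
    small and re-checked downstream.  Gzip input is handled by extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    df = _apply_column_map(df, column_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path.name}")

    records: dict[str, VariantRecord] = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            rec = VariantRecord(
                variant_id=str(d["variant_id"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                eaf=_opt_float(d.get("eaf")),
                n=_opt_int(d.get("n")),
                chrom=_opt_str(d.get("chrom")),
                pos=_opt_int(d.get("pos")),
            )
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            log.warning("dropping invalid row in %s: %s", path.name, exc)
            continue
        if rec.variant_id in records:
            n_dropped += 1
            log.warning("dropping duplicate variant_id %s in %s", rec.variant_id, path.name)
            continue
        records[rec.variant_id] = rec
    if n_dropped:
        log.info("%s: dropped %d invalid row(s), kept %d", path.name, n_dropped, len(records))
    if not records:
        raise ValueError(f"{path}: no valid rows after validation")
    return SummaryDataset(
        trait_name=trait_name or path.stem,
        records=records,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return int(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return str(v)


def read_ld_table(path: str | Path) -> LDTable:
    """Read a 3-column TSV ``id_a  id_b  r2`` into a symmetric lookup."""
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    for col in ("id_a", "id_b", "r2"):
        if col not in df.columns:
            raise ValueError(f"LD table missing column {col!r}")
    table = LDTable()
    for row in df.itertuples(index=False):
        table.add(str(row.id_a), str(row.id_b), float(row.r2))
    return table


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a 1- or 2-column TSV ``variant_id[  reason]`` of instruments to drop."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "variant_id" not in df.columns:
        raise ValueError("exclusion list missing column 'variant_id'")
    reasons = df["reason"] if "reason" in df.columns else pd.Series([""] * len(df))
    return {str(v): ("" if pd.isna(r) else str(r)) for v, r in zip(df["variant_id"], reasons)}


def read_proxy_map(path: str | Path) -> ProxyMap:
    """Read a 3-column TSV ``original  proxy  r2``."""
    df = pd.read_csv(path, sep="\t", dtype={"original": str, "proxy": str})
    for col in ("original", "proxy", "r2"):
        if col not in df.columns:
            raise ValueError(f"proxy map missing column {col!r}")
    return ProxyMap.from_tuples(
        (str(r.original), str(r.proxy), float(r.r2)) for r in df.itertuples(index=False)
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_WRITE_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS


def write_sumstats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical TSV dialect (lossless round-trip)."""
    rows = []
    for rec in dataset:
        rows.append({col: getattr(rec, col) for col in _WRITE_COLUMNS})
    df = pd.DataFrame(rows, columns=list(_WRITE_COLUMNS))
    # default float formatting is shortest-round-trip, so floats survive re-reading
    df.to_csv(path, sep="\t", index=False)


def write_results_table(
    estimates: Iterable[tuple[str, "object"]],
    path: str | Path,
    or_decimals: int = 2,
) -> None:
    """Write causal estimates as an odds-ratio table (tabular forest plot).

    ``estimates`` is an iterable of ``(outcome_name, MREstimate)``.  Betas
    are exponentiated to odds ratios and rounded to ``or_decimals``;
    p-values are written unrounded.
    """
    rows = []
    for outcome, est in estimates:
        rows.append(
            {
                "method": est.method,
                "outcome": outcome,
                "n_snps": est.k,
                "or": round(float(np.exp(est.beta)), or_decimals),
                "ci_low": round(float(np.exp(est.ci_low)), or_decimals),
                "ci_high": round(float(np.exp(est.ci_high)), or_decimals),
                "pval": est.pval,
            }
        )
    df = pd.DataFrame(rows, columns=["method", "outcome", "n_snps", "or", "ci_low", "ci_high", "pval"])
    df.to_csv(path, sep="\t", index=False)
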