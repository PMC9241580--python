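"""Harmonization of exposure and outcome associations to a shared effect allele.

Two-sample MR combines, per variant, the exposure association (gamma_hat,
se_exp) with the outcome association (Gamma_hat, se_out).  The two GWAS may
report the same variant with the alleles swapped or on opposite strands, so
before any estimator runs the outcome effect must be re-expressed relative
to the exposure's effect allele.  Exactly one sign flip is ever applied.

Palindromic variants (A/T, C/G) cannot be strand-resolved from alleles; they
are kept only when both allele frequencies sit on the same clearly
informative side of 0.5, and dropped otherwise — a deliberately conservative
rule that trades instrument count for safety.  Instruments missing from the
outcome dataset may be replaced by a user-supplied proxy in high LD
(default r2 > 0.8); the proxy's own outcome association is used unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sumstats import ProxyMap, SummaryDataset, VariantRecord

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUS_OK = "ok"
STATUS_PROXIED = "proxied"
STATUS_DROPPED_PALINDROMIC = "dropped_palindromic"
STATUS_DROPPED_MISSING = "dropped_missing"
#: statuses whose instruments feed the estimators
USABLE_STATUSES = frozenset({STATUS_OK, STATUS_PROXIED})


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome associations aligned to one shared effect allele."""

    variant_id: str
    used_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flipped: bool = False
    palindromic: bool = False
    status: str = STATUS_OK

    @property
    def usable(self) -> bool:
        return self.status in USABLE_STATUSES

    @property
    def wald(self) -> float:
        """Per-variant causal ratio Gamma_hat / gamma_hat."""
        return self.beta_out / self.beta_exp


@dataclass(frozen=True)
class ProxySubstitution:
    original: str
    proxy: str
    r2: float


@dataclass
class ProxyReport:
    substitutions: list[ProxySubstitution]
    rejected: list[tuple[str, str]]  # (variant_id, reason)


def _reverse_complement_pair(a: str, b: str) -> tuple[str, str]:
    return _COMPLEMENT[a], _COMPLEMENT[b]


def substitute_proxies(
    missing_ids: Sequence[str],
    proxies: ProxyMap | None,
    outcome: SummaryDataset,
    r2_min: float = 0.8,
) -> ProxyReport:
    """Resolve instruments absent from the outcome via the proxy map.

    A proxy is accepted only if its LD with the original reaches ``r2_min``
    and the proxy itself is present in the outcome dataset; failures are
    reported with a reason, never silently discarded.
    """
    subs: list[ProxySubstitution] = []
    rejected: list[tuple[str, str]] = []
    for vid in missing_ids:
        entry = proxies.get(vid) if proxies is not None else None
        if entry is None:
            rejected.append((vid, "no proxy available"))
        elif entry.r2 < r2_min:
            rejected.append((vid, f"proxy {entry.proxy} r2={entry.r2} below threshold {r2_min}"))
        elif entry.proxy not in outcome:
            rejected.append((vid, f"proxy {entry.proxy} absent from outcome"))
        else:
            subs.append(ProxySubstitution(vid, entry.proxy, entry.r2))
    return ProxyReport(substitutions=subs, rejected=rejected)


def _palindromic_alignment(
    eaf_exp: float | None, eaf_out: float | None, limit: float
) -> bool:
    """Whether a palindromic pair can be kept (aligned, unflipped).

    True only when both frequencies are informative and on the same side:
    both below ``limit`` or both above ``1 - limit``.
    """
    if eaf_exp is None or eaf_out is None:
        return False
    both_low = eaf_exp < limit and eaf_out < limit
    both_high = eaf_exp > 1.0 - limit and eaf_out > 1.0 - limit
    return both_low or both_high


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    instrument_ids: Sequence[str],
    proxies: ProxyMap | None = None,
    palindrome_eaf_limit: float = 0.42,
    proxy_r2_min: float = 0.8,
) -> list[HarmonizedInstrument]:
    """Align each instrument's outcome association to the exposure effect allele.

    Returns one :class:`HarmonizedInstrument` per requested instrument; no
    exclusion is fatal — every drop is carried in ``status``.
    """
    missing = [vid for vid in instrument_ids if vid not in exposure]
    if missing:
        raise KeyError(f"instrument ids absent from exposure dataset: {missing}")

    absent = [vid for vid in instrument_ids if vid not in outcome]
    proxy_report = substitute_proxies(absent, proxies, outcome, r2_min=proxy_r2_min)
    proxy_for = {s.original: s.proxy for s in proxy_report.substitutions}

    out: list[HarmonizedInstrument] = []
    for vid in instrument_ids:
        exp = exposure.records[vid]
        used_id = vid
        status = STATUS_OK
        out_rec = outcome.get(vid)
        if out_rec is None:
            if vid in proxy_for:
                used_id = proxy_for[vid]
                out_rec = outcome.records[used_id]
                status = STATUS_PROXIED
            else:
                out.append(_dropped(exp, STATUS_DROPPED_MISSING))
                continue
        out.append(_align(exp, out_rec, used_id, status, palindrome_eaf_limit))
    return out


def _dropped(exp: VariantRecord, status: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=exp.variant_id,
        used_id=exp.variant_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=float("nan"),
        se_out=float("nan"),
        eaf_exp=exp.eaf,
        eaf_out=None,
        flipped=False,
        palindromic=exp.is_palindromic,
        status=status,
    )


def _align(
    exp: VariantRecord,
    out_rec: VariantRecord,
    used_id: str,
    status: str,
    limit: float,
) -> HarmonizedInstrument:
    ea, oa = exp.effect_allele, exp.other_allele
    ea2, oa2 = out_rec.effect_allele, out_rec.other_allele

    if exp.is_palindromic:
        if {ea2, oa2} != {ea, oa}:
            return _dropped(exp, STATUS_DROPPED_MISSING)
        # effect alleles may still differ within the pair; compare outcome EAF
        # for the exposure's effect allele
        eaf_out = out_rec.eaf
        if eaf_out is not None and ea2 != ea:
            eaf_out = 1.0 - eaf_out
        if not _palindromic_alignment(exp.eaf, eaf_out, limit):
            hi = _dropped(exp, STATUS_DROPPED_PALINDROMIC)
            return hi
        # frequencies agree on strand: outcome beta oriented to exposure EA
        beta_out = out_rec.beta if ea2 == ea else -out_rec.beta
        return HarmonizedInstrument(
            variant_id=exp.variant_id,
            used_id=used_id,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out_rec.se,
            eaf_exp=exp.eaf,
            eaf_out=eaf_out,
            flipped=ea2 != ea,
            palindromic=True,
            status=status,
        )

    rc_ea2, rc_oa2 = _reverse_complement_pair(ea2, oa2)
    if (ea2, oa2) == (ea, oa) or (rc_ea2, rc_oa2) == (ea, oa):
        flipped = False
    elif (ea2, oa2) == (oa, ea) or (rc_ea2, rc_oa2) == (oa, ea):
        flipped = True
    else:
        return _dropped(exp, STATUS_DROPPED_MISSING)

    beta_out = -out_rec.beta if flipped else out_rec.beta
    eaf_out = out_rec.eaf
    if eaf_out is not None and flipped:
        eaf_out = 1.0 - eaf_out
    return HarmonizedInstrument(
        variant_id=exp.variant_id,
        used_id=used_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out_rec.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        flipped=flipped,
        palindromic=False,
        status=status,
    )


def write_harmonization_report(
    instruments: Iterable[HarmonizedInstrument], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": h.variant_id,
                "used_id": h.used_id,
                "status": h.status,
                "flipped": h.flipped,
                "palindromic": h.palindromic,
            }
            for h in instruments
        ],
        columns=["variant_id", "used_id", "status", "flipped", "palindromic"],
    )
    df.to_csv(path, sep="\t", index=False)
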