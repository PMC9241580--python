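"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws per-variant true exposure effects gamma_j (log-uniform,
so one instrument can dominate the way a single strong locus often does in
real instrument sets) and effect-allele frequencies, forms standard errors
with the 1/sqrt(2 p (1-p) N) approximation for a standardized trait, and
emits noisy estimates gamma_hat_j ~ N(gamma_j, se_exp_j).  True outcome
effects follow the linear causal model Gamma_j = theta * gamma_j + alpha_j,
where the pleiotropic term alpha_j is 0 (``none``), zero-centred
(``balanced``) or shifted by ``pl_mean`` for a ``pl_frac`` subset
(``directional`` — the scenario under which IVW is biased but the Egger
intercept recovers the mean pleiotropic effect).

Defaults mirror a large eczema-exposure / heart-failure-outcome design:
19 instruments, exposure N = 116,863, outcome N = 977,323, theta = 0.07 on
the log-odds scale.

``make_reference_fixture`` builds a fixed 21-candidate selection fixture
(one LD-correlated pair, one confounder-excluded variant, two variants
missing from the outcome but rescued by proxies) that exercises every
stage of the pipeline deterministically.  Variants other than the five
named ones are synthetic, with sequential placeholder rsIDs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    LDTable,
    ProxyMap,
    SummaryDataset,
    VariantRecord,
)

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SyntheticTruth:
    """Generating parameters for one synthetic two-sample dataset pair."""

    seed: int
    theta: float = 0.07
    k: int = 19
    gamma_range: tuple[float, float] = (0.03, 0.3)
    eaf_range: tuple[float, float] = (0.1, 0.9)
    n_exp: int = 116_863
    n_out: int = 977_323
    pleiotropy: str = "none"  # none | balanced | directional
    pl_mean: float = 0.0
    pl_sd: float = 0.0
    pl_frac: float = 0.0
    palindromic_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 <= self.pl_frac <= 1):
            raise ValueError("pl_frac must be in [0, 1]")
        if not (0 <= self.palindromic_frac <= 1):
            raise ValueError("palindromic_frac must be in [0, 1]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy scenario {self.pleiotropy!r}")


@dataclass
class TruthRecord:
    """What was actually drawn: the ground truth behind one generated pair."""

    params: SyntheticTruth
    variant_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    eaf: np.ndarray
    pleiotropic_ids: list[str]


def _se_approx(eaf: np.ndarray, n: int) -> np.ndarray:
    """SE of a per-allele effect on a standardized trait: 1/sqrt(2 p (1-p) N)."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, 5e-324)


def generate(truth: SyntheticTruth) -> tuple[SummaryDataset, SummaryDataset, TruthRecord]:
    """Draw one exposure/outcome summary-statistics pair under ``truth``.

    All randomness flows from one generator seeded with ``truth.seed``;
    repeated calls with the same parameters are bit-identical.
    """
    rng = np.random.default_rng(truth.seed)
    k = truth.k
    lo, hi = truth.gamma_range
    gamma = np.exp(rng.uniform(np.log(lo), np.log(hi), k))
    eaf = rng.uniform(*truth.eaf_range, k)

    se_x = _se_approx(eaf, truth.n_exp)
    gamma_hat = rng.normal(gamma, se_x)

    alpha = np.zeros(k)
    pleio_idx: np.ndarray = np.array([], dtype=int)
    if truth.pleiotropy == "balanced":
        alpha = rng.normal(0.0, truth.pl_sd, k)
        pleio_idx = np.arange(k)
    elif truth.pleiotropy == "directional":
        m = int(round(truth.pl_frac * k))
        pleio_idx = rng.choice(k, size=m, replace=False)
        alpha[pleio_idx] = rng.normal(truth.pl_mean, truth.pl_sd, m)
    Gamma = truth.theta * gamma + alpha

    se_y = _se_approx(eaf, truth.n_out)
    Gamma_hat = rng.normal(Gamma, se_y)

    n_pal = int(round(truth.palindromic_frac * k))
    pal_mask = np.zeros(k, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(k, size=n_pal, replace=False)] = True
    alleles = []
    for j in range(k):
        pool = _PALINDROMIC_PAIRS if pal_mask[j] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])

    ids = [f"rs{9_000_000 + j}" for j in range(k)]
    p_exp = _two_sided_p(gamma_hat, se_x)
    p_out = _two_sided_p(Gamma_hat, se_y)

    exp_records = [
        VariantRecord(
            variant_id=ids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            beta=float(gamma_hat[j]),
            se=float(se_x[j]),
            pval=float(p_exp[j]),
            eaf=float(eaf[j]),
            n=truth.n_exp,
            chrom=str(j % 22 + 1),
            pos=1_000_000 + 2_000_000 * j,
        )
        for j in range(k)
    ]
    out_records = [
        VariantRecord(
            variant_id=ids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            beta=float(Gamma_hat[j]),
            se=float(se_y[j]),
            pval=float(p_out[j]),
            eaf=float(eaf[j]),
            n=truth.n_out,
            chrom=str(j % 22 + 1),
            pos=1_000_000 + 2_000_000 * j,
        )
        for j in range(k)
    ]
    exposure = SummaryDataset.from_records("synthetic_exposure", exp_records)
    outcome = SummaryDataset.from_records("synthetic_outcome", out_records)
    record = TruthRecord(
        params=truth,
        variant_ids=ids,
        gamma=gamma,
        alpha=alpha,
        eaf=eaf,
        pleiotropic_ids=[ids[j] for j in sorted(pleio_idx.tolist())],
    )
    return exposure, outcome, record


# ---------------------------------------------------------------------------
# deterministic selection / harmonization fixture
# ---------------------------------------------------------------------------

#: instruments absent from the fixture outcome and their high-LD proxies
FIXTURE_PROXIES = (("rs12188917", "rs3091307", 0.92), ("rs6419573", "rs1035127", 0.88))
FIXTURE_EXCLUDED = "rs4713555"
FIXTURE_LD_PRUNED = "rs12730935"
FIXTURE_DOMINANT = "rs61813875"

_FIXTURE_SEED = 1903
_FIXTURE_THETA = 0.0953  # log(1.10): replication-study scale
_FIXTURE_N_EXP = 116_863
_FIXTURE_N_OUT = 394_156


@dataclass
class FixtureBundle:
    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: LDTable
    exclusions: dict[str, str]
    proxies: ProxyMap
    instrument_truth: float = _FIXTURE_THETA


def make_reference_fixture() -> FixtureBundle:
    """Deterministic 21-candidate fixture exercising every selection stage.

    All 21 exposure variants are genome-wide significant; exactly one pair
    is in LD (r2 = 0.5, the later-ranked member is pruned), one survivor
    sits on the confounder exclusion list, and two instruments are missing
    from the outcome but carried by proxies with r2 > 0.8 — so selection
    returns 19 ids and harmonization reports exactly 2 proxied instruments.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    named = [FIXTURE_DOMINANT, FIXTURE_LD_PRUNED, FIXTURE_EXCLUDED,
             FIXTURE_PROXIES[0][0], FIXTURE_PROXIES[1][0]]
    synthetic = [f"rs{1_000_001 + j}" for j in range(16)]
    ids = named + synthetic  # 21 candidates
    ld_partner = synthetic[0]

    k = len(ids)
    gamma = rng.uniform(0.045, 0.15, k)
    gamma[0] = 0.35  # the dominant locus
    eaf = rng.uniform(0.1, 0.6, k)
    se_x = _se_approx(eaf, _FIXTURE_N_EXP)
    pvals = _two_sided_p(gamma, se_x)

    # chromosome layout: LD pair co-located on chr1, everyone else isolated
    chrom = {vid: str(c) for vid, c in zip(ids, range(2, 2 + k))}
    pos = {vid: 1_500_000 for vid in ids}
    chrom[FIXTURE_LD_PRUNED] = chrom[ld_partner] = "1"
    pos[FIXTURE_LD_PRUNED], pos[ld_partner] = 1_000_000, 1_450_000

    alleles = [_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))] for _ in ids]

    exp_records = []
    for j, vid in enumerate(ids):
        exp_records.append(
            VariantRecord(
                variant_id=vid,
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(gamma[j]),
                se=float(se_x[j]),
                pval=float(pvals[j]),
                eaf=float(eaf[j]),
                n=_FIXTURE_N_EXP,
                chrom=chrom[vid],
                pos=pos[vid],
            )
        )
    exposure = SummaryDataset.from_records(
        "eczema_synthetic", exp_records, n_cases=21_399, n_controls=95_464
    )

    # enforce the partner's better rank after drawing, deterministically
    i_partner, i_pruned = ids.index(ld_partner), ids.index(FIXTURE_LD_PRUNED)
    if exposure.records[ld_partner].pval > exposure.records[FIXTURE_LD_PRUNED].pval:
        a, b = exp_records[i_partner], exp_records[i_pruned]
        exposure.records[ld_partner] = VariantRecord(
            variant_id=ld_partner, effect_allele=a.effect_allele, other_allele=a.other_allele,
            beta=b.beta, se=b.se, pval=b.pval, eaf=a.eaf, n=a.n, chrom=a.chrom, pos=a.pos,
        )
        exposure.records[FIXTURE_LD_PRUNED] = VariantRecord(
            variant_id=FIXTURE_LD_PRUNED, effect_allele=b.effect_allele, other_allele=b.other_allele,
            beta=a.beta, se=a.se, pval=a.pval, eaf=b.eaf, n=b.n, chrom=b.chrom, pos=b.pos,
        )

    # outcome: heart-failure-like, same alleles, two instruments replaced by proxies
    missing = {orig for orig, _, _ in FIXTURE_PROXIES}
    se_y = _se_approx(eaf, _FIXTURE_N_OUT)
    Gamma = _FIXTURE_THETA * gamma + rng.normal(0.0, 0.3 * se_y, k)
    out_records = []
    for j, vid in enumerate(ids):
        out_id = vid
        if vid in missing:
            out_id = dict((o, p) for o, p, _ in FIXTURE_PROXIES)[vid]
        out_records.append(
            VariantRecord(
                variant_id=out_id,
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(Gamma[j]),
                se=float(se_y[j]),
                pval=float(_two_sided_p(np.array([Gamma[j]]), np.array([se_y[j]]))[0]),
                eaf=float(eaf[j]),
                n=_FIXTURE_N_OUT,
                chrom=chrom[vid],
                pos=pos[vid],
            )
        )
    outcome = SummaryDataset.from_records(
        "heart_failure_synthetic", out_records, n_cases=6_504, n_controls=387_652
    )

    ld = LDTable()
    ld.add(FIXTURE_LD_PRUNED, ld_partner, 0.5)
    exclusions = {FIXTURE_EXCLUDED: "associated with autoimmune/thyroid confounders"}
    proxies = ProxyMap.from_tuples(FIXTURE_PROXIES)
    return FixtureBundle(exposure, outcome, ld, exclusions, proxies)


def make_companion_outcome(seed: int = 7, theta: float = 0.0583, n_out: int = 977_323) -> SummaryDataset:
    """A second, larger heart-failure-like outcome over the fixture instruments.

    Complete (no missing instruments), so it pairs with the fixture outcome
    for a two-study meta-analysis.
    """
    bundle = make_reference_fixture()
    rng = np.random.default_rng(seed)
    records = []
    for rec in bundle.exposure:
        se_y = float(_se_approx(np.array([rec.eaf]), n_out)[0])
        beta = theta * rec.beta + float(rng.normal(0.0, 0.3 * se_y))
        records.append(
            VariantRecord(
                variant_id=rec.variant_id,
                effect_allele=rec.effect_allele,
                other_allele=rec.other_allele,
                beta=beta,
                se=se_y,
                pval=float(_two_sided_p(np.array([beta]), np.array([se_y]))[0]),
                eaf=rec.eaf,
                n=n_out,
                chrom=rec.chrom,
                pos=rec.pos,
            )
        )
    return SummaryDataset.from_records(
        "heart_failure_synthetic_2", records, n_cases=47_309, n_controls=930_014
    )


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as the TSV dialects the readers consume."""
    from .sumstats import write_sumstats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
        "ld": out_dir / "ld.tsv",
        "exclusions": out_dir / "exclusions.tsv",
        "proxies": out_dir / "proxies.tsv",
    }
    write_sumstats(bundle.exposure, paths["exposure"])
    write_sumstats(bundle.outcome, paths["outcome"])
    pd.DataFrame(
        list(bundle.ld.items()), columns=["id_a", "id_b", "r2"]
    ).to_csv(paths["ld"], sep="\t", index=False)
    pd.DataFrame(
        sorted(bundle.exclusions.items()), columns=["variant_id", "reason"]
    ).to_csv(paths["exclusions"], sep="\t", index=False)
    pd.DataFrame(
        [(e.original, e.proxy, e.r2) for e in bundle.proxies.entries.values()],
        columns=["original", "proxy", "r2"],
    ).to_csv(paths["proxies"], sep="\t", index=False)
    return paths
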