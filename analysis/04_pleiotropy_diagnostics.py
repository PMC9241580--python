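#!/usr/bin/env python
"""Pleiotropy and sensitivity battery for each outcome: Cochran's Q, the
MR-Egger intercept test, MR-PRESSO (global / outlier / distortion), and
leave-one-out IVW — including the single-variant sensitivity run without
the dominant instrument.

Writes results/diagnostics.tsv and one leave-one-out TSV per outcome.
"""
from pathlib import Path

import pandas as pd

from mrkit.diagnostics import leave_one_out, pleiotropy_report, write_diagnostics_table
from mrkit.harmonize import harmonize
from mrkit.instruments import SelectionConfig, select_instruments
from mrkit.simulate import FIXTURE_DOMINANT
from mrkit.sumstats import (
    read_exclusion_list,
    read_ld_table,
    read_proxy_map,
    read_sumstats,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
SEED = 20_220_615

OUTCOMES = [
    ("hf_replication", "outcome.tsv"),
    ("hf_discovery", "outcome_large.tsv"),
]


def main() -> None:
    exposure = read_sumstats(DATA / "exposure.tsv", trait_name="eczema",
                             n_cases=21_399, n_controls=95_464)
    ld = read_ld_table(DATA / "ld.tsv")
    exclusions = read_exclusion_list(DATA / "exclusions.tsv")
    proxies = read_proxy_map(DATA / "proxies.tsv")
    selected = select_instruments(
        exposure, ld, SelectionConfig(exclusion_ids=exclusions)
    ).selected

    reports = []
    for name, fname in OUTCOMES:
        outcome = read_sumstats(DATA / fname, trait_name=name)
        usable = [h for h in harmonize(exposure, outcome, selected, proxies=proxies)
                  if h.usable]
        rep = pleiotropy_report(usable, n_sim=1000, seed=SEED)
        reports.append((name, rep))
        print(f"{name}:")
        print(f"  Cochran's Q = {rep.q_stat:.2f} (df {rep.q_df}), p = {rep.q_pval:.2f}")
        print(f"  Egger intercept = {rep.egger_intercept:+.4f}, p = {rep.egger_intercept_pval:.2f}")
        print(f"  MR-PRESSO global p = {rep.presso.global_pval:.3f}; "
              f"outliers: {rep.presso.outliers or 'none'}")

        loo = leave_one_out(usable)
        pd.DataFrame(
            [
                {"excluded_id": e.excluded_id, "or": e.estimate.odds_ratio,
                 "pval": e.estimate.pval}
                for e in loo
            ]
        ).to_csv(ROOT / "results" / f"leave_one_out_{name}.tsv", sep="\t", index=False)
        (entry,) = leave_one_out(usable, exclude=FIXTURE_DOMINANT)
        print(f"  without {FIXTURE_DOMINANT}: OR {entry.estimate.odds_ratio:.3f}, "
              f"p = {entry.estimate.pval:.2e}")

    write_diagnostics_table(reports, ROOT / "results" / "diagnostics.tsv")
    print("wrote results/diagnostics.tsv")


if __name__ == "__main__":
    main()
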