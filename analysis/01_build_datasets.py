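#!/usr/bin/env python
"""Build the study datasets: a deterministic 21-candidate exposure GWAS
(eczema-like), two heart-failure-like outcome GWASs of different size, and
the auxiliary inputs (LD table, confounder exclusion list, proxy map).

The smaller outcome is missing two instruments that carry high-LD proxies;
the larger outcome is complete.  Writes everything under results/data/.
"""
from pathlib import Path

from mrkit.simulate import make_companion_outcome, make_reference_fixture, write_fixture
from mrkit.sumstats import write_sumstats

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    bundle = make_reference_fixture()
    paths = write_fixture(bundle, OUT)
    companion = make_companion_outcome()
    write_sumstats(companion, OUT / "outcome_large.tsv")

    print(f"exposure: {len(bundle.exposure)} genome-wide-significant candidates "
          f"({bundle.exposure.n_cases:,} cases / {bundle.exposure.n_controls:,} controls)")
    print(f"outcome (replication-scale): {len(bundle.outcome)} variants, "
          f"n = {bundle.outcome.n_total:,}; two instruments only reachable via proxies")
    print(f"outcome (discovery-scale):   {len(companion)} variants, n = {companion.n_total:,}")
    print(f"LD table: {len(bundle.ld)} correlated pair(s); "
          f"exclusion list: {list(bundle.exclusions)}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p.relative_to(OUT.parent.parent)}")
    print(f"  wrote outcome_large: results/data/outcome_large.tsv")


if __name__ == "__main__":
    main()
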