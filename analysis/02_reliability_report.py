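#!/usr/bin/env python
"""Estimate per-measure test-retest reliability from the simulated study.

For each group, estimates Persons / Occasion / Persons x Occasion (+ error)
variance components per measure, the G-coefficient (n_o = 1, equal to
ICC(3,1)) with its poor/fair/good/excellent category, and the paired t-test
of month-2 minus baseline. Prints the per-group mean G and writes
results/reliability_{chr,con}.tsv.

Run analysis/01_simulate_study.py first.
"""

from pathlib import Path

from eegtrt import io as eio
from eegtrt import reliability as rel

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for group in ("chr", "con"):
        measures = eio.read_measures(RESULTS / f"measures_{group}.tsv")
        report = rel.reliability_report(measures)
        out = RESULTS / f"reliability_{group}.tsv"
        report.to_csv(out, sep="\t", index=False, float_format="%.4f")
        print(f"\n== {group.upper()} (n = {report.n.iloc[0]}) ==")
        print(report[["measure", "G", "category", "t", "p"]]
              .to_string(index=False))
        print(f"mean G = {report.G.mean():.2f}  "
              f"(range {report.G.min():.2f}-{report.G.max():.2f}) -> {out}")


if __name__ == "__main__":
    main()
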