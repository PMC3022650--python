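#!/usr/bin/env python
"""Reaction-set comparison of the two core models by functional category.

Reactions are matched by canonical stoichiometry signature (sorted metabolite
ids, smallest-integer coefficients, direction-insensitive). The shared
fermentative core is common; the glycol/formate branches are unique to
P. carbinolicus and the methylmalonyl-CoA propionate route to P. propionicus.
"""

from pathlib import Path

from pelocore import build_pcar_core, build_ppro_core, compare_models

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main():
    report = compare_models([build_pcar_core(), build_ppro_core()])
    report.per_category.to_csv(OUT / "network_comparison.tsv", sep="\t")
    print(report.per_category.to_string())
    print(report.totals.to_string(index=False))
    print(f"common reactions across both core models: {report.common}")
    print(f"wrote {OUT / 'network_comparison.tsv'}")


if __name__ == "__main__":
    main()
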