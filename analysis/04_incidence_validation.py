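#!/usr/bin/env python
"""Predicted clinical CRC incidence by age (model validation curve).

Runs the no-screening cohort and writes the model's annual clinical
incidence per 100,000 living persons for ages 50-85 to
results/incidence_by_age.csv — the quantity registries publish, for
qualitative comparison against national data.  Pass a registry CSV
(columns age,incidence_per_100k) to print difference summaries.
"""

import sys
from pathlib import Path

from crcscreen import base_case_parameter_set, compare_to_registry, default_life_table
from crcscreen.validation import predicted_incidence_curve, read_registry_curve

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = base_case_parameter_set()
    curve = predicted_incidence_curve(params, default_life_table())
    curve.frame().to_csv(OUT / "incidence_by_age.csv", index=False)

    print("predicted clinical CRC incidence per 100,000/year (no screening):")
    for age in (50, 55, 60, 65, 70, 75, 80, 85):
        rate = curve.incidence_per_100k[curve.ages == age][0]
        print(f"  age {age}: {rate:7.1f}")
    print(f"wrote {OUT / 'incidence_by_age.csv'}")

    if len(sys.argv) > 1:
        registry = read_registry_curve(sys.argv[1])
        summary = compare_to_registry(curve, registry)
        print("comparison against registry curve:")
        for key, val in summary.items():
            print(f"  {key}: {val:.3f}" if isinstance(val, float)
                  else f"  {key}: {val}")


if __name__ == "__main__":
    main()
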