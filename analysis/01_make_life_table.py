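#!/usr/bin/env python
"""Generate the background-mortality input: a synthetic Ukraine-like life table.

The cohort model needs an annual all-cause death probability for every age;
no national table is bundled, so this driver writes the package's synthetic
Gompertz–Makeham table, calibrated to period life expectancy ~71 years at
birth and ~25 years at age 50, to results/life_table.csv.  Any real table
in the same `age,qx` CSV format can be substituted downstream.
"""

from pathlib import Path

from crcscreen import write_life_table
from crcscreen.synthetic import DEFAULT_LIFE_TABLE_SPEC, default_life_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    lt = default_life_table()
    write_life_table(lt, OUT / "life_table.csv")
    spec = DEFAULT_LIFE_TABLE_SPEC
    print("synthetic Gompertz-Makeham life table")
    print(f"  hazard: {spec.makeham_a:.2e} + {spec.gompertz_b:.2e}"
          f" * exp({spec.gompertz_c} * age)")
    print(f"  life expectancy at birth : {lt.life_expectancy(0):6.2f} y")
    print(f"  life expectancy at 50    : {lt.life_expectancy(50):6.2f} y")
    print(f"  q50 = {lt.q(50):.5f}   q70 = {lt.q(70):.5f}   q85 = {lt.q(85):.5f}")
    print(f"wrote {OUT / 'life_table.csv'}")


if __name__ == "__main__":
    main()
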