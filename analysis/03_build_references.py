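#!/usr/bin/env python
"""Build the sex-stratified normative references from the simulated controls.

Writes one JSON reference per sex (sorted control samples plus mean/SD
per tract and metric) under results/references/, so single subjects can
later be rated without re-reading the control cohort.
"""

from pathlib import Path

import tractnorm as tn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    controls = tn.read_metrics_table(
        ROOT / "results" / "synthetic" / "controls.csv")
    out = ROOT / "results" / "references"
    out.mkdir(parents=True, exist_ok=True)
    for sex in (tn.Sex.MALE, tn.Sex.FEMALE):
        ref = tn.build_reference(controls.select(sex=sex), sex)
        ref.to_json(out / f"reference_{sex.value}.json")
        unusable = ref.unusable_entries()
        print(f"{sex.value}: n = {ref.n_controls} controls, "
              f"{len(ref.tracts)} tracts, {len(unusable)} unusable entries")


if __name__ == "__main__":
    main()
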