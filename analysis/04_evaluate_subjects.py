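#!/usr/bin/env python
"""Rate every simulated patient against the matched normative reference.

For each of the 60 patients this produces the dual output: a text file
listing the affected tracts with z- and p-values, and a JSON report for
downstream tooling, under results/reports/.  Prints one representative
report per phenotype.
"""

from pathlib import Path

import tractnorm as tn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    patients = tn.read_metrics_table(
        ROOT / "results" / "synthetic" / "patients.csv")
    refs = {
        sex: tn.NormativeReference.from_json(
            ROOT / "results" / "references" / f"reference_{sex.value}.json")
        for sex in (tn.Sex.MALE, tn.Sex.FEMALE)
    }
    out = ROOT / "results" / "reports"
    out.mkdir(parents=True, exist_ok=True)

    shown: set[str] = set()
    registry = tn.default_tract_registry()
    for patient in patients:
        report = tn.evaluate_subject(patient, refs[patient.sex])
        (out / f"{patient.subject_id}.txt").write_text(
            tn.render_report(report, "text"))
        (out / f"{patient.subject_id}.json").write_text(
            tn.render_report(report, "json"))
        if patient.phenotype not in shown:
            shown.add(patient.phenotype)
            lat = tn.laterality_summary(report, registry)
            print(tn.render_report(report, "text"))
            print(f"laterality: {lat.n_left} left / {lat.n_right} right / "
                  f"{lat.n_commissural} commissural\n{'-' * 60}")
    print(f"wrote {2 * len(patients)} report files to {out}")


if __name__ == "__main__":
    main()
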