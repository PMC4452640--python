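"""Study-sized simulated group comparison.

Simulates the four-group cohort at the study's size (n = 8 per group,
between-subject SD reconstructed from the reported SEMs as SEM*sqrt(8)),
quantifies every subject with the full pipeline, and runs the group
analysis: tumour-vs-sham percent changes per sex with propagated SEM,
and male-vs-female Welch tests with significance stars.

Writes results/cohort_summary.csv and results/cohort_deltas.csv.
"""

from pathlib import Path

import pandas as pd

from gliomri.groupstats import build_report
from gliomri.pipeline import quantify_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    measured, _ = quantify_cohort(n_per_group=8, seed=2, snr=None,
                                  subject_sd="sem")
    summary, deltas = build_report(measured)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    deltas.to_csv(RESULTS / "cohort_deltas.csv", index=False)

    print(f"quantified {measured.subject.nunique()} subjects, "
          f"{len(summary)} region/parameter cells")
    for _, r in deltas.iterrows():
        print(f"  {r.region:9s} {r.parameter:3s}  "
              f"male {r.delta_male:+7.2f}% +/- {r.sem_male:4.2f}   "
              f"female {r.delta_female:+7.2f}% +/- {r.sem_female:4.2f}   "
              f"male-vs-female p={r.p:.3g} {r.stars}")
    sig = deltas[deltas.p < 0.05]
    print(f"{len(sig)}/{len(deltas)} male-vs-female comparisons significant "
          "at 0.05 in this realization")


if __name__ == "__main__":
    main()
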