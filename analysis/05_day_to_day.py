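"""Day-to-day validation: train the SVM ensemble on 1 DAT, test on 2 DAT.

Probes temporal robustness: every fitted parameter (preprocessing
chains, hyperparameters, support vectors, calibrations) is frozen on
day-1 data before any day-2 spectrum is seen.  Because treated plants
drift toward a common damaged-leaf spectrum -- and the paraquat- and
glyphosate-specific signals fade -- transfer accuracy drops well below
the same-day leave-one-out accuracy.
"""

import os
import warnings

from hsisoa.classify import REDUCED_GRID
from hsisoa.evaluate import day_to_day, exclude_outliers, render_report
from hsisoa.preprocess import SpectraTable

OUT = "results"
SPECTRA = os.path.join(OUT, "study_spectra.csv")


def main() -> None:
    table = exclude_outliers(SpectraTable.from_csv(SPECTRA))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = day_to_day(table, 1, 2, learner="svm", grid=REDUCED_GRID)
    render_report(report, OUT, name="day1_to_day2_svm")
    print(f"day-to-day OA (train 1 DAT, test 2 DAT): {report.overall_accuracy:.1%} "
          f"(n = {report.total})")
    for cls, acc in zip(report.classes, report.per_class_accuracy):
        print(f"  {cls:12s} {acc:.1%}")
    print(f"report under {OUT}/day1_to_day2_svm.*")


if __name__ == "__main__":
    main()
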