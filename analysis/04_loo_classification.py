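"""Leave-one-out OVO classification on 1 DAT for both learner families.

Runs the one-vs-one soft-voting ensemble with PLS-DA (1-3 latent
variables by RMSEcv) and with SVM (linear/RBF over a coarse C-gamma
grid by RMSEcv) on day-1 spectra, outliers excluded, both rounds
combined, and writes confusion-matrix reports (CSV + PNG + JSON).
"""

import os
import warnings

from hsisoa.classify import REDUCED_GRID
from hsisoa.evaluate import exclude_outliers, loo_experiment, render_report
from hsisoa.preprocess import SpectraTable

OUT = "results"
SPECTRA = os.path.join(OUT, "study_spectra.csv")


def main() -> None:
    table = exclude_outliers(SpectraTable.from_csv(SPECTRA))
    for learner, grid in (("plsda", None), ("svm", REDUCED_GRID)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = loo_experiment(table, learner=learner, dat=1, grid=grid)
        render_report(report, OUT, name=f"loo_{learner}_1dat")
        print(f"{learner.upper():5s} LOO 1 DAT: OA = {report.overall_accuracy:.1%} "
              f"(n = {report.total})")
        worst = min(zip(report.per_class_accuracy, report.classes))
        print(f"      weakest class: {worst[1]} at {worst[0]:.1%}")
    print(f"confusion reports under {OUT}/")


if __name__ == "__main__":
    main()
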