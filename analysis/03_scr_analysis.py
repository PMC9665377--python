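"""Analyze the threat-evoked SCR data: robust mixed model and planned contrasts.

Range-normalizes each participant's magnitudes, fits the robust linear
mixed model (repetition + visuo-tactile congruence + visuo-vestibular
congruence + interaction, participant random intercept, Huber weights),
runs the six planned one-/two-sided t contrasts, and repeats the fit
under the robustness variants (no normalization, null-responder
exclusion).  Expects results/scr.csv from 01.
"""

import sys
import warnings

from trisense.datasets import read_dataset
from trisense.scr import analysis_variants


def main() -> None:
    scr = read_dataset("results/scr.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, report = analysis_variants(scr)
        print("robust LMM (normalized magnitude):")
        for name, b in fit.coefficients.items():
            print(f"  {name:<16} beta={b:+.4f}  t={fit.tvalues[name]:+.2f}")
        print(f"  random-intercept var={fit.random_intercept_var:.4f}, "
              f"residual var={fit.residual_var:.4f}")
        print("\nplanned comparisons (five one-sided, one two-sided):")
        print(report.round(4).to_string(index=False))

        for label, kwargs in [
            ("no normalization", dict(normalize=False)),
            ("excluding null responders", dict(exclude_null_responders=True)),
        ]:
            vfit, _ = analysis_variants(scr, **kwargs)
            print(f"\nvariant - {label}:")
            print("  " + ", ".join(f"{k}={v:+.4f}" for k, v in vfit.coefficients.items()))
    report.to_csv("results/scr_planned_comparisons.csv", index=False)
    print("\ncomparisons table: results/scr_planned_comparisons.csv")


if __name__ == "__main__":
    main()
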