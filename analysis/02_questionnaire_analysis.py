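"""Analyze the questionnaire data: ordinal mixed models and planned comparisons.

For every statement S1-S7: a cumulative link mixed model (participant
random intercept, adaptive Gauss-Hermite quadrature), likelihood-ratio
tests for the two congruence factors and their interaction, and
Shapiro-gated planned pairwise comparisons (Wilcoxon signed-rank with
rank-biserial r_C, or paired t with d_z) with JZS Bayes factors.
Expects results/questionnaire.csv and results/scr.csv from 01.
"""

import json
import sys

from trisense.config import load_config
from trisense.pipeline import run_analyze


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    config = load_config(seed=seed, outdir="results")
    report = run_analyze(config, "results/questionnaire.csv", "results/scr.csv")
    for st in report["questionnaire"]:
        name = st["statement"]
        if "lrt" not in st:
            print(f"{name}: {st.get('clmm_error', 'no model')}")
            continue
        lrts = ", ".join(
            f"{term}: chi2={r['statistic']:.2f} p={r['p']:.4f}"
            for term, r in st["lrt"].items()
        )
        print(f"{name}  {lrts}")
    print("\nS1 planned comparisons:")
    s1 = next(s for s in report["questionnaire"] if s["statement"] == "S1")
    for label, c in s1["planned_comparisons"].items():
        if "note" in c:
            print(f"  {label}: {c['note']}")
            continue
        print(f"  {label}: {c['test']} stat={c['statistic']:.1f} p={c['p']:.4f} "
              f"{c['effect_size_name']}={c['effect_size']:.3f}"
              + (f" BF10={c['bf10']:.2f}" if c.get("bf10") else ""))
    print("\nfull report: results/analysis_report.json")


if __name__ == "__main__":
    main()
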