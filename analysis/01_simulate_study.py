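"""Generate the synthetic study datasets.

Draws the default study: 80 questionnaire participants (4 conditions x
7 statements each) and 50 SCR participants (16 threat trials each,
pseudorandomized condition orders), and writes the two long-format CSVs
plus a provenance record under results/.
"""

import sys

from trisense.config import load_config
from trisense.datasets import read_dataset
from trisense.pipeline import run_simulate


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    config = load_config(seed=seed, outdir="results")
    files = run_simulate(config)
    q = read_dataset(files["questionnaire"])
    s = read_dataset(files["scr"])
    print(f"questionnaire: {len(q)} rows "
          f"({q['participant'].nunique()} participants x 4 conditions x 7 statements)")
    print(f"scr:           {len(s)} rows "
          f"({s['participant'].nunique()} participants x 16 trials)")
    n_null = int((s['raw'] < 0.01).sum())
    print(f"null responses (< 0.01 mmho): {n_null}/{len(s)}")
    print(f"written to: {files}")


if __name__ == "__main__":
    main()
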