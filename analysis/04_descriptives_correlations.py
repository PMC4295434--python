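"""Normative descriptives and the Bonferroni-corrected correlation table.

Reads the screened measure table written by 03_screen_measures.py (running
the screening in-process if absent) and writes per-measure descriptives and
the pairwise-complete Pearson correlation table with Bonferroni flags
(m = 55 unique pairs over the 11 tabulated variables).
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from tvasem.study import correlation_table, descriptives

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    path = ROOT / "results" / "measure_table.csv"
    if not path.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "03_screen_measures.py")], check=True)
    table = pd.read_csv(path, index_col=0)

    desc = descriptives(table)
    corr = correlation_table(table)
    resdir = ROOT / "results"
    desc.to_csv(resdir / "descriptives.csv")
    corr.r.round(4).to_csv(resdir / "correlations_r.csv")
    corr.n.to_csv(resdir / "correlations_n.csv")
    print(desc.round(2).to_string())
    print(f"\nBonferroni m = {corr.m_comparisons}")
    print("significant at corrected 0.05:", corr.significant_pairs(0.05))
    print("significant at corrected 0.01:", corr.significant_pairs(0.01))


if __name__ == "__main__":
    main()
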