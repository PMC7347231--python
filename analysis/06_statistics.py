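"""Statistical summary across analyses: exact-test sanity checks and the
chance-level arithmetic for individual identification, plus a binomial
above-chance assessment of the classifier results from 04_classify.py.

Reads results/classification.csv if present; prints everything and writes
results/statistics.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from usvsex import stats as st

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    rows = []

    _, p = st.compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0],
                             "ranksum")
    rows.append({"check": "ranksum_extreme_n3", "value": p,
                 "expected": 0.1})
    rows.append({"check": "binomial_10_of_10",
                 "value": st.binomial_above_chance(10, 10, 0.5),
                 "expected": 2.0 ** -10})
    rows.append({"check": "chance_individual_pct", "value": 100 / 17,
                 "expected": 5.9})
    rows.append({"check": "chance_individual_sex_known_pct",
                 "value": 100 / 8, "expected": 12.5})

    cls_path = ROOT / "classification.csv"
    if cls_path.exists():
        res = pd.read_csv(cls_path)
        true = res[res["labels"] == "true"]
        for model, grp in true.groupby("model"):
            acc = grp["percent_correct"].mean()
            n_test = 1000  # per fold
            correct = int(round(acc / 100 * n_test))
            p = st.binomial_above_chance(correct, n_test, 0.5)
            rows.append({"check": f"{model}_above_chance_p", "value": p,
                         "expected": np.nan})
            print(f"{model}: {acc:.1f} % correct, "
                  f"binomial p vs chance = {p:.3g}")

    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "statistics.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
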