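"""Extract vocalizations from the generated recording and score detection
against the generator's annotations (>= 50 % overlap rule).

Reads results/data/recording.wav; writes results/segments.csv and prints
precision/recall/F1.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from usvsex import io as uio
from usvsex import segment as sg

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    _, wave = uio.read_wav(ROOT / "data" / "recording.wav")
    images, table, _ = sg.segment_recording(wave)
    table.to_csv(ROOT / "segments.csv", index=False, float_format="%.4f")

    ann = pd.read_csv(ROOT / "data" / "recording.csv")
    _, prec, recall, f1 = sg.match_intervals(
        table[["onset_ms", "offset_ms"]].to_numpy(),
        ann[["onset_ms", "offset_ms"]].to_numpy())
    print(f"detected {len(table)} calls "
          f"({int(table['truncated'].sum())} truncated at 100 ms)")
    print(f"vs {len(ann)} annotated: precision {prec:.3f} "
          f"recall {recall:.3f} F1 {f1:.3f}")
    print(f"segment table -> {ROOT / 'segments.csv'}")


if __name__ == "__main__":
    main()
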