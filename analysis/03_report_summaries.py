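#!/usr/bin/env python
"""Descriptive summaries: per-group/per-test metric tables and a KR chart.

From results/metrics.csv, writes per-group per-run-label summary
statistics (mean, median, quartiles) of the four outcome metrics to
results/summary.csv, and renders one participant's knowledge-of-results
chart — mean spatial and velocity error per test, in protocol order, the
feedback each participant saw after every test — to scratch/.
"""

import argparse
from pathlib import Path

import pandas as pd

from rowsim import io as rio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/summary.csv"))
    parser.add_argument("--kr-participant", default="VD01")
    args = parser.parse_args()

    table = pd.read_csv(args.metrics)
    summary = rio.report_summary(table, ("group", "run_label"))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out, index=False, float_format="%.6g")
    print(f"summary over {len(summary)} group x run cells -> {args.out}")

    series = rio.kr_chart_series(table, args.kr_participant)
    print(f"\nKR chart series for {args.kr_participant}:")
    print(series.round(3).to_string(index=False))
    png = Path("scratch") / f"kr_chart_{args.kr_participant}.png"
    png.parent.mkdir(exist_ok=True)
    rio.plot_kr_chart(series, png)
    print(f"chart -> {png}")


if __name__ == "__main__":
    main()
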