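#!/usr/bin/env python
"""Screen the pooled array: detection, normalization, adaptive cutoff.

Reads the simulated Cq table, runs the full screen, reports the Venn
summary, and checks how many of the planted 2-cycle effects were flagged
as up-regulated.  Writes the per-assay table, the Venn JSON and an MA plot
under results/screen/.
"""

import json
from pathlib import Path

from placmir import qpcr_screen
from placmir.synthetic import SimulationTruth

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cq = qpcr_screen.read_cq_table(DATA / "cq_table.tsv")
    truth = SimulationTruth.from_json(DATA / "truth_array.json")

    results, venn = qpcr_screen.classify_and_summarize(cq)
    qpcr_screen.write_screen_results(results, OUT / "screen_results.tsv")
    venn.to_json(OUT / "venn_summary.json")
    qpcr_screen.ma_plot(results, OUT / "ma_plot.png")

    call = {r.assay_id: r.call for r in results}
    recovered = sum(call[a] == "up" for a in truth.planted_de)
    print(json.dumps(venn.percentages, indent=2))
    print(f"detected: Con {venn.n_det_con}, N3 {venn.n_det_n3}, "
          f"common {venn.n_common}, union {venn.n_union}")
    print(f"differential: {venn.n_diff_total} total "
          f"({venn.n_up} up, {venn.n_down} down, "
          f"{venn.n_unique_con + venn.n_unique_n3} group-unique)")
    print(f"planted effects flagged up: {recovered}/{len(truth.planted_de)}")


if __name__ == "__main__":
    main()
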