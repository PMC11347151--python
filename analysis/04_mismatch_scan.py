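#!/usr/bin/env python
"""Terminator mismatch scan through the full pipeline.

Simulates one ensemble per 3-bp-mismatch position (+112 ... +134, the
termination site sitting at +130), classifies each, and locates the
position of strongest termination impairment.  The generator plants the
efficiency minimum at +120, emulating a mismatch that blocks transcription-
bubble rewinding just upstream of the release site; the analysis should
recover a 10-bp-upstream peak.  Writes results/mismatch_scan.tsv and
results/mismatch_peak.json.
"""

import json
from pathlib import Path

from smterm.classify import classify_ensemble
from smterm.kinetics import MismatchScan, mismatch_peak, termination_efficiency
from smterm.synthetic_data import mismatch_series, simulate_ensemble, preset

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_PER_POSITION = 120
SEED = 50
WILDTYPE = 0.54


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    base = preset("T7_Tphi", n_traces=N_PER_POSITION, p_active=1.0)
    configs = mismatch_series(base_config=base, seed=SEED, wildtype_efficiency=WILDTYPE)
    positions, efficiencies = [], []
    for pos, cfg in sorted(configs.items()):
        traces, truth = simulate_ensemble(cfg)
        cls = classify_ensemble(traces, cfg, replicate_ids=truth.replicate_ids)
        rep = termination_efficiency(cls)
        positions.append(pos)
        efficiencies.append(rep.efficiency_mean)
        print(f"+{pos}: planted {cfg.p_termination:.2f}, "
              f"measured {rep.efficiency_mean:.2f}")

    scan = MismatchScan(tuple(positions), tuple(efficiencies), WILDTYPE,
                        termination_site=130)
    peak = mismatch_peak(scan)
    print(f"peak at +{peak.peak_position}, "
          f"{peak.offset_from_termination_site} bp upstream of +130; "
          f"{sum(peak.impaired.values())}/{len(positions)} positions impaired")

    with (RESULTS / "mismatch_scan.tsv").open("w") as fh:
        fh.write("position\tefficiency\timpaired\n")
        for pos, eff in zip(positions, efficiencies):
            fh.write(f"{pos}\t{eff:.4f}\t{int(peak.impaired[pos])}\n")
    (RESULTS / "mismatch_peak.json").write_text(json.dumps({
        "peak_position": peak.peak_position,
        "offset_from_termination_site": peak.offset_from_termination_site,
        "wildtype_efficiency": WILDTYPE,
        "n_per_position": N_PER_POSITION,
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
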