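#!/usr/bin/env python
"""Timing statistics of the classified reference ensemble.

Reads results/classifications.tsv (written by 01_simulate_and_classify.py),
summarizes the Cy5-end arrival time tau_e and the termination time tau_t,
reports the fold delay of termination relative to readthrough, and runs a
rank-sum comparison of tau_t between replicate groups (two halves of the
same condition, so the expected outcome is a non-significant p).
"""

import json
from pathlib import Path

from smterm.kinetics import rank_sum_test, timing_stats
from smterm.trace_model import Label, read_classifications

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    classifications = read_classifications(RESULTS / "classifications.tsv")
    t = timing_stats(classifications)
    te, tt = t["tau_e"], t["tau_t"]
    print(f"tau_e: {te.mean:.1f} +/- {te.sd:.1f} s (n={te.n}, median {te.median:.1f})")
    print(f"tau_t: {tt.mean:.1f} +/- {tt.sd:.1f} s (n={tt.n}, median {tt.median:.1f})")
    print(f"fold delay (means): {t['fold_delay']:.1f}")

    tau_t_by_rep = {}
    for c in classifications:
        if c.outcome in (Label.DECOMPOSING, Label.RECYCLING):
            tau_t_by_rep.setdefault(c.replicate_id, []).append(c.tau_t_hat_s)
    reps = sorted(tau_t_by_rep)
    res = rank_sum_test(tau_t_by_rep[reps[0]], tau_t_by_rep[reps[1]])
    print(f"rank-sum tau_t replicate {reps[0]} vs {reps[1]}: "
          f"W={res.statistic:.0f}, z={res.z:.2f}, p={res.p_two_sided:.2f}")

    payload = {
        "tau_e": vars(te).copy(),
        "tau_t": vars(tt).copy(),
        "fold_delay": t["fold_delay"],
        "fold_delay_median": t["fold_delay_median"],
        "rank_sum_between_replicates": {
            "W": res.statistic, "z": res.z, "p_two_sided": res.p_two_sided,
            "n1": res.n1, "n2": res.n2,
        },
    }
    (RESULTS / "kinetics.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
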