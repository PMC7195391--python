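#!/usr/bin/env python
"""K+ crossing detection and ionic currents for every replicate.

Counts full traversals of the selectivity-filter slab per replicate,
converts net crossings to pA, and aggregates mean +/- SEM per preset —
the current-versus-condition comparison at the heart of the lipid screen.
"""

import pandas as pd

from _common import RESULTS, ensure_dirs, replicate_specs

from kinkgate.permeation import (
    aggregate_current,
    analyze_permeation,
    events_table,
    voltage_from_field,
)
from kinkgate.synthetic import generate


def main():
    ensure_dirs()
    spec0 = next(iter(replicate_specs()))[2]
    v_mv = voltage_from_field(spec0.field_v_per_nm, spec0.box[2])
    print(f"applied voltage: {v_mv:.1f} mV "
          f"({spec0.field_v_per_nm} V/nm x {spec0.box[2]} nm)\n")

    rows, all_events, by_preset = [], [], {}
    for preset, rep_id, spec in replicate_specs():
        topo, frames, truth = generate(spec)
        records, current = analyze_permeation(frames, topo)
        n_plus = sum(1 for r in records if r.direction > 0)
        rows.append(
            {
                "replicate": rep_id,
                "preset": preset,
                "n_plus": n_plus,
                "n_minus": len(records) - n_plus,
                "t_ns": frames.duration_ns,
                "I_pA": current,
                "true_n_events": truth.n_events,
            }
        )
        all_events.append(events_table(records, replicate=rep_id))
        by_preset.setdefault(preset, []).append(current)
        print(f"{rep_id:28s} {len(records):4d} crossings "
              f"(truth {truth.n_events:4d})  I = {current:5.2f} pA")

    pd.DataFrame(rows).to_csv(RESULTS / "currents.csv", index=False)
    pd.concat(all_events, ignore_index=True).to_csv(
        RESULTS / "events.csv", index=False
    )
    summary = []
    print()
    for preset, currents in by_preset.items():
        est = aggregate_current(currents)
        summary.append(
            {
                "preset": preset,
                "I_mean_pA": est.mean_pA,
                "I_sem_pA": est.sem_pA,
                "n": est.n_replicates,
            }
        )
        print(f"{preset:20s} I = {est.mean_pA:5.2f} +/- "
              f"{est.sem_pA if est.sem_pA is not None else float('nan'):4.2f} pA "
              f"(n={est.n_replicates})")
    pd.DataFrame(summary).to_csv(RESULTS / "current_by_preset.csv", index=False)
    print(f"\ntables in {RESULTS}: currents.csv, events.csv, current_by_preset.csv")


if __name__ == "__main__":
    main()
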