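#!/usr/bin/env python
"""Oxygen-gap analysis of the toy metabolic model.

Loads the reaction table written by 01_simulate.py, simulates aerobic and
anoxic growth, enumerates biomass precursors blocked by oxygen removal (with
the insertable denitrification pathway enabled), traces each block to the
reactions/genes whose relief removes it, and searches for minimal medium
supplements. Writes results/fba_*.tsv.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from anaerodesign import fba, synthetic

IN = Path("results/inputs")
OUT = Path("results")


def main() -> None:
    with open(IN / "toy_model.tsv") as fh:
        model = fba.load_model(fh)
    medium = synthetic.toy_medium()
    anoxic = fba.set_anoxic(medium)
    denit = frozenset(synthetic.DENITRIFICATION_REACTIONS)

    growth = {
        "aerobic": fba.fba(model, medium).growth,
        "anoxic": fba.fba(model, anoxic).growth,
        "anoxic+denitrification": fba.fba(model, anoxic, enabled=denit).growth,
    }
    vitamins = {ex: fba.OPEN_UPTAKE for ex in synthetic.VITAMIN_EXCHANGES}
    supplemented = replace(anoxic, uptakes={**anoxic.uptakes, **vitamins})
    growth["anoxic+denitrification+vitamins"] = fba.fba(
        model, supplemented, enabled=denit
    ).growth
    for k, v in growth.items():
        print(f"growth {k}: {v:.4f}")
    pd.DataFrame(sorted(growth.items()), columns=["condition", "growth"]).to_csv(
        OUT / "fba_growth.tsv", sep="\t", index=False, float_format="%.6g"
    )

    blocked = fba.blocked_biomass_precursors(model, anoxic, enabled=denit)
    blocked.to_csv(OUT / "fba_blocked_precursors.tsv", sep="\t", float_format="%.6g")
    blocked_mets = list(blocked.index[blocked["blocked"]])
    print(f"blocked biomass precursors under anoxia: {blocked_mets}")

    traces = []
    for met in blocked_mets:
        tr = fba.trace_oxygen_dependencies(model, anoxic, met, enabled=denit)
        tr.insert(0, "precursor", met)
        traces.append(tr)
    trace_table = pd.concat(traces, ignore_index=True)
    trace_table.to_csv(OUT / "fba_oxygen_traces.tsv", sep="\t", index=False,
                       float_format="%.6g")
    print(f"{len(trace_table)} single reliefs found "
          f"(oxygen-independent syntheses or uptake exchanges)")

    minimal = fba.propose_media_supplements(
        model, anoxic, synthetic.VITAMIN_EXCHANGES, enabled=denit
    )
    print(f"minimal supplement sets restoring growth: "
          f"{[sorted(s) for s in minimal]}")


if __name__ == "__main__":
    main()
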