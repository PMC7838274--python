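"""Group cells by octanol fold change and test the grouped drug pattern.

Pairs each cell's pre- and post-octanol per-neuron mean amplitude,
splits cells by the sign of the fold change (increase vs decrease), and
runs the two-way repeated-measures ANOVA with Sidak-adjusted pre-vs-post
contrasts within each group — the analysis layout of the grouped
gap-junction-blocker experiment.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fibsinet import stats as fstats
from fibsinet.calcium import fold_change_grouping
from fibsinet.io import RunConfig, read_traces
from fibsinet.pipeline import calcium_cell_summaries, detect_calcium_events

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "drug"
OUT.mkdir(parents=True, exist_ok=True)
CFG = RunConfig(seed=2024)


def summaries_for(name):
    table = read_traces(DATA / f"calcium_{name}.csv")
    events = detect_calcium_events(table.traces, CFG)
    summ = calcium_cell_summaries(events, table.traces[0].duration_s,
                                  condition=name,
                                  cell_ids=[t.cell_id for t in table.traces],
                                  config=CFG)
    return summ.set_index("cell_id")


def main() -> None:
    pre = summaries_for("pre_octanol")
    post = summaries_for("post_octanol")
    from fibsinet.calcium import CellSummary

    groups = []
    for cid in pre.index:
        a = CellSummary(cid, "pre", int(pre.loc[cid, "n_events"]),
                        pre.loc[cid, "mean_amplitude"], None, None, None,
                        pre.loc[cid, "frequency"])
        b = CellSummary(cid, "post", int(post.loc[cid, "n_events"]),
                        post.loc[cid, "mean_amplitude"], None, None, None,
                        post.loc[cid, "frequency"])
        g = fold_change_grouping(a, b)
        if g is not None:
            groups.append(g)
    df = pd.DataFrame([vars(g) for g in groups])
    df.to_csv(OUT / "fold_change_groups.csv", index=False)
    n_up = int((df.group == "increase").sum())
    n_down = int((df.group == "decrease").sum())
    print(f"fold-change split: increase n = {n_up}, decrease n = {n_down}")

    res = fstats.paired_compare(df.pre_mean.to_numpy(), df.post_mean.to_numpy(),
                                method="rm_anova_2way_sidak",
                                group=df.group.to_numpy())
    print(f"two-way RM ANOVA interaction: F = {res.statistic:.2f}, p = {res.p:.3g}")
    print(res.posthoc.to_string(index=False))
    res.posthoc.to_csv(OUT / "sidak_contrasts.csv", index=False)


if __name__ == "__main__":
    main()
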