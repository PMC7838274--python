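"""Detect calcium fluctuations, summarize per neuron, classify silent cells.

Runs the waveform detector over the naive and treated cultures from
step 01, applies the 10%-of-max noise cutoff, classifies silent cells on
the no-cutoff mean amplitude, compares the silent proportions with
Fisher's exact test and the per-neuron mean amplitudes with
Kruskal-Wallis + Dunn, and writes the event and summary tables.
"""

from pathlib import Path

import pandas as pd

from fibsinet import stats as fstats
from fibsinet.io import RunConfig, read_traces, write_events
from fibsinet.pipeline import calcium_cell_summaries, detect_calcium_events

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "calcium"
OUT.mkdir(parents=True, exist_ok=True)
CFG = RunConfig(seed=2024)


def main() -> None:
    summaries = {}
    for cond in ("naive", "treated"):
        table = read_traces(DATA / f"calcium_{cond}.csv")
        events = detect_calcium_events(table.traces, CFG)
        write_events(events, OUT / f"events_{cond}.csv", config=CFG)
        summ = calcium_cell_summaries(events, table.traces[0].duration_s,
                                      condition=cond,
                                      cell_ids=[t.cell_id for t in table.traces],
                                      config=CFG)
        summ.to_csv(OUT / f"cell_summaries_{cond}.csv", index=False)
        summaries[cond] = summ
        print(f"{cond}: {len(events)} events, "
              f"{int(summ.is_silent.sum())}/{len(summ)} silent, "
              f"mean active amplitude "
              f"{summ.loc[~summ.is_silent, 'mean_amplitude'].mean():.1f} AU")

    a = summaries["naive"]; b = summaries["treated"]
    table = [[int(a.is_silent.sum()), int((~a.is_silent).sum())],
             [int(b.is_silent.sum()), int((~b.is_silent).sum())]]
    fisher = fstats.fisher_exact_2x2(table)
    print(f"silent proportion naive vs treated: {table}, "
          f"Fisher two-sided p = {fisher.p:.2e}")

    active = {c: s.loc[~s.is_silent & s.mean_amplitude.notna(), "mean_amplitude"]
              for c, s in summaries.items()}
    silent_amp = a.loc[a.is_silent, "mean_amplitude_nocutoff"].dropna()
    kw = fstats.omnibus_compare(
        [silent_amp, active["naive"], active["treated"]],
        "kruskal_wallis", names=["silent", "naive", "treated"])
    print(f"mean amplitude by group: KW = {kw.statistic:.1f}, p = {kw.p:.2e}")
    print(kw.posthoc.to_string(index=False))

    rows = [{"test": "fisher_exact", "groups": "naive|treated",
             "statistic": fisher.statistic, "p": fisher.p},
            {"test": "kruskal_wallis", "groups": "silent|naive|treated",
             "statistic": kw.statistic, "p": kw.p}]
    pd.DataFrame(rows).to_csv(OUT / "group_tests.csv", index=False)


if __name__ == "__main__":
    main()
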