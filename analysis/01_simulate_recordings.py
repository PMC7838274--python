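"""Simulate the study's recording conditions with known ground truth.

Generates (a) a naive calcium-imaging culture with a 20% silent
subpopulation and weak wave coupling, (b) a chronically treated culture
in which the silent cells are unmasked, fluctuation amplitudes are
halved and wave coupling is strengthened, (c) a paired pre/post
gap-junction-blocker (octanol) experiment that quarters the coupling,
and (d) control and treated sEPSC voltage-clamp recordings from the
planted three-component mixture. Traces and ground truth go to
results/data/.
"""

from pathlib import Path

from fibsinet.io import RunConfig, TraceTable, write_traces
from fibsinet.synthetic import (
    CalciumNetworkParams,
    ConditionEffect,
    EpscClusterSpec,
    EpscParams,
    apply_condition_effect,
    generate_calcium_network,
    generate_epsc_recording,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
CFG = RunConfig(seed=2024)

NAIVE = CalciumNetworkParams(n_cells=30, frac_silent=0.2, coupling_p=0.2,
                             seed=CFG.seed, condition="naive")
TREATED = apply_condition_effect(
    NAIVE,
    ConditionEffect(amplitude_factor=0.5, activate_silent=True,
                    coupling_factor=3.0, label="treated"),
)
OCTANOL_PRE = CalciumNetworkParams(n_cells=30, frac_silent=0.0, coupling_p=0.8,
                                   seed=CFG.seed + 1, condition="pre_octanol")
OCTANOL_POST = apply_condition_effect(
    OCTANOL_PRE, ConditionEffect(coupling_factor=0.25, label="post_octanol"))

TREATED_EPSC_SPECS = [  # depressed large-amplitude component, shorter IEIs
    EpscClusterSpec(1 / 3, 15.0, 3.0, 20.0),
    EpscClusterSpec(1 / 3, 15.0, 3.0, 1400.0),
    EpscClusterSpec(1 / 3, 55.0, 11.0, 150.0),
]


def main() -> None:
    for params, name in ((NAIVE, "calcium_naive"), (TREATED, "calcium_treated"),
                         (OCTANOL_PRE, "calcium_pre_octanol"),
                         (OCTANOL_POST, "calcium_post_octanol")):
        traces, truth = generate_calcium_network(params)
        write_traces(TraceTable(traces, recording_id=name), OUT / f"{name}.csv",
                     config=CFG)
        truth.events.to_csv(OUT / f"{name}_truth.csv", index=False)
        n_silent = sum(truth.silent.values())
        print(f"{name}: {len(traces)} cells, {len(truth.events)} planted events, "
              f"{n_silent} silent, {len(truth.wave_times)} waves")

    for cond, specs in (("control", None), ("treated", TREATED_EPSC_SPECS)):
        for i in range(3):
            kwargs = {"cluster_specs": specs} if specs else {}
            p = EpscParams(seed=CFG.seed + 10 * (cond == "treated") + i,
                           cell_id=f"{cond}_neuron{i}", **kwargs)
            trace, truth = generate_epsc_recording(p)
            write_traces(TraceTable([trace], recording_id=trace.cell_id,
                                    units="pA", modality="current"),
                         OUT / f"epsc_{cond}_{i}.csv", config=CFG)
            truth.events.to_csv(OUT / f"epsc_{cond}_{i}_truth.csv", index=False)
            print(f"epsc_{cond}_{i}: {len(truth.events)} planted sEPSCs")


if __name__ == "__main__":
    main()
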