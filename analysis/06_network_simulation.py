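"""Stochastic network-growth simulations: load adaptation in silico.

Runs the event-driven simulator along a stress ladder twice — once with
matched monomer/capping gap sizes (wildtype) and once with a bulky capping
gap — and verifies the study's central mechanism: free-end density rises
and velocity falls under load, flux balance holds at stationarity, the
stationary free-end density sits on the mean-field fixed point, and mean
filament length is load-invariant only when the gaps match.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import dendritic as d
from dendritic import io as dio
from dendritic.simulate import (
    SimParams,
    load_series_experiment,
    mean_field_barbed_end_density,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "simulation"
STRESSES = (0.0, 250.0, 600.0, 1000.0)


def run(tag, ratchet):
    p = SimParams(area=1.0, k_on0=20.0, seed=5, ratchet=ratchet)
    summaries = load_series_experiment(p, STRESSES, hold=120.0, burn_in=50.0)
    rows = []
    for s in summaries:
        rows.append(dict(
            variant=tag, stress_pa=s.stress,
            free_end_density=s.mean_free_end_density, se_e=s.se_free_end_density,
            velocity_um_min=s.velocity, mean_capped_length=s.mean_capped_length,
            se_len=s.se_capped_length, balance_residual=s.balance_residual,
            wh2_occupancy=s.wh2_occupancy,
        ))
    lr = stats.linregress([r["stress_pa"] for r in rows],
                          [r["mean_capped_length"] for r in rows])
    e0_star = mean_field_barbed_end_density(p, stress=0.0)
    print(f"\n{tag}: E rises {rows[0]['free_end_density']:.0f} → "
          f"{rows[-1]['free_end_density']:.0f} µm⁻²; "
          f"velocity falls {rows[0]['velocity_um_min']:.2f} → "
          f"{rows[-1]['velocity_um_min']:.2f} µm/min")
    print(f"  mean-field E* at zero stress: {e0_star:.0f} µm⁻² "
          f"(simulated {rows[0]['free_end_density']:.0f} ± {rows[0]['se_e']:.0f})")
    print(f"  capped-length slope vs stress: {lr.slope:.4f} ± {lr.stderr:.4f} "
          f"subunits/Pa; max flux residual "
          f"{max(r['balance_residual'] for r in rows):.3f}")
    return rows


def main():
    wt = run("matched gaps (wt)", d.RatchetParams())  # δ_cap = δ_actin = 2.7 nm
    bulky = run("bulky capping gap", dataclasses.replace(
        d.RatchetParams(), delta_cap_wt=5.4, delta_cap_bulky=5.4))
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(wt + bulky).to_csv(OUT / "load_series.csv", index=False)
    dio.write_run_log(OUT / "run_log.txt", "06_network_simulation", seed=5,
                      extra={"stresses": list(STRESSES)})


if __name__ == "__main__":
    main()
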