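"""Generate the synthetic measurement tables consumed by the later stages.

Emulates one force-clamp experiment (stress staircase 0→1020 Pa with an
extra stall-proximal 1200 Pa hold), the aligned TIRF density traces, the
relative barbed-end series, single-molecule Arp2/3 tracks at three
velocities, FRET quench curves at the three conditions, and the
wildtype/bulky capping-protein ratio dataset.  Everything is seeded and
lands under results/synthetic/.
"""

from pathlib import Path

import dendritic as d
from dendritic import io as dio

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

def main():
    cfg = d.GeneratorConfig(
        seed=SEED,
        stress_steps=((0.0, 360.0), (25.0, 360.0), (255.0, 360.0),
                      (510.0, 360.0), (1020.0, 360.0), (1200.0, 360.0)),
    )
    note = f"synthetic measurement tables, seed={SEED}"
    dio.write_afm_csv(d.gen_afm_trace(cfg), OUT / "afm_trace.csv", note)
    dio.write_intensity_csv(d.gen_intensity_traces(cfg), OUT / "intensity.csv", note)
    d.gen_barbed_end_series(cfg).to_csv(OUT / "barbed_ends.csv", index=False)

    params = d.RatchetParams(f_tether=0.3)
    stresses = [0, 25, 150, 300, 510, 750, 1020, 1300]
    states = d.network_states(cfg, stresses)
    d.gen_ratio_dataset(states, params, noise_cv=0.05, n_replicates=100,
                        seed=SEED).to_csv(OUT / "wt_bulky_ratio.csv", index=False)

    curves = {
        "no-network": d.simulate_quench_curve(0.0, 1.0, 0.02, 0.01, duration=12.0,
                                              seed=SEED, condition="no-network"),
        "unloaded": d.simulate_quench_curve(0.073, 1.0, 0.02, 0.01, duration=12.0,
                                            seed=SEED + 1, condition="unloaded"),
        "loaded": d.simulate_quench_curve(0.27, 1.0, 0.02, 0.01, duration=12.0,
                                          seed=SEED + 2, condition="loaded"),
    }
    dio.write_quench_csv(curves, OUT / "quench.csv", note)

    # demo track tables: unloaded, two slowed (loaded) conditions with an
    # abortive subpopulation, and a velocity-matched loss control for the
    # high-load condition (no abortive events, bleaching/tracking loss only)
    # acquisition interval lengthened for slow-growing (loaded) networks,
    # as in imaging practice, which also keeps frames per track comparable
    conditions = [
        ("tracks_v7.3.csv", 7.3, 0.0, 0.1),
        ("tracks_v3.6.csv", 3.6, 0.1, 0.2),
        ("tracks_v1.8.csv", 1.8, 0.2, 0.4),
        ("tracks_v1.8_control.csv", 1.8, 0.0, 0.4),
    ]
    for i, (fname, v, abort, dt) in enumerate(conditions):
        tracks = d.simulate_tracks(
            80, velocity=v, abortive_fraction=abort, abortive_hazard=1.0,
            noise_sd=0.05, frame_dt=dt, seed=SEED + 10 + i,
        )
        dio.write_tracks_csv(tracks, OUT / fname, note)
    dio.write_run_log(OUT / "run_log.txt", "01_generate_datasets", seed=SEED, config=cfg)
    print(f"wrote synthetic tables to {OUT}")


if __name__ == "__main__":
    main()
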