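"""Exercise the raw-signal path: synthesis, artifact rejection, band power.

Synthesizes five-minute 19-channel recordings from band-limited noise
with injected blink and movement artifacts, runs 20-s-window artifact
rejection and the 60-s minimum-clean-data gate, and checks that the
band powers recovered by Welch spectral estimation match the synthesis
targets.  Writes the calibration table to results/signal_calibration.csv.
"""

from pathlib import Path

import pandas as pd

import qeegnorm as q

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = q.SignalSpec(duration_seconds=300.0, artifacts=[
        q.ArtifactEvent(time_seconds=35.0, kind="blink"),
        q.ArtifactEvent(time_seconds=150.0, kind="movement"),
        q.ArtifactEvent(time_seconds=290.0, kind="blink"),
    ])
    rows = []
    for i in range(3):
        rec = q.generate_signal(spec, seed=SEED + i)
        segs = q.enforce_minimum_clean(q.reject_artifacts(rec))
        bp = q.band_power(rec, segs)
        for band, target in spec.band_targets.items():
            realized = bp.power[("Pz", band)]
            rows.append({"recording": rec.subject_id, "band": band,
                         "target_uv2": target, "realized_uv2": realized,
                         "relative_error": realized / target - 1,
                         "clean_seconds": segs.total_clean_seconds})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "signal_calibration.csv", index=False)
    worst = table["relative_error"].abs().max()
    clean = table["clean_seconds"].iloc[0]
    print(f"three 300-s recordings with 3 artifacts each: "
          f"{clean:.0f} s retained per recording (3 windows dropped)")
    print(f"worst band-power calibration error at Pz: {worst * 100:.2f}% "
          f"(target within 5%)")
    print(f"wrote {OUT / 'signal_calibration.csv'}")


if __name__ == "__main__":
    main()
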