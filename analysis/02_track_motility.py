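#!/usr/bin/env python
"""Per-track average speeds and the ensemble MSD of the simulated
macrophages; writes results/motility/ and reports the speed summary and
the MSD log-log slope (between 1 and 2 for a persistent random walk)."""

from pathlib import Path

from tmequant.motility import ensemble_msd, msd_loglog_slope, speed_table
from tmequant.track_io import read_tracks

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ts = read_tracks(ROOT / "sim" / "tracks.csv")
    out = ROOT / "motility"
    out.mkdir(parents=True, exist_ok=True)

    speeds = speed_table(ts)
    speeds.to_csv(out / "speeds.csv", index=False, float_format="%.9g")
    mac = speeds[speeds.cell_type == "macrophage"]
    print(f"{len(mac)} macrophage tracks, mean speed "
          f"{mac.average_speed.mean():.2f} µm/h (sd {mac.average_speed.std():.2f})")

    curve = ensemble_msd(ts.by_type("macrophage"))
    curve.as_frame().to_csv(out / "msd_ensemble.csv", index=False,
                            float_format="%.9g")
    slope = msd_loglog_slope(curve, max_lag=int(curve.lags.max() // 2) or None)
    print(f"ensemble MSD log-log slope {slope:.2f} "
          "(1 = diffusive, 2 = ballistic)")


if __name__ == "__main__":
    main()
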