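"""Detect behavioral events in the simulated session and summarize behavior.

Runs the 3 g cross detector (30 Hz frame rule with the touch precondition),
flags 0.5 s isolation, detects low-force touch events and lick bouts, and
writes the event table plus per-identity rates/proportions.

Reads results/session.h5 (from 01_simulate_session.py); writes
results/events.csv and results/behavior_summary.csv.
"""

import argparse
import pathlib

import pandas as pd

from striadec import events, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.results)
    session = io.load_session(out / "session.h5")

    detected = events.detect_3g_cross_actions(session.force, session.touch,
                                              fs_hz=session.force_rate,
                                              frame_rate_hz=session.frame_rate)
    detected = events.flag_isolation(detected, window_s=0.5, reference="peak")
    other = events.detect_touch_and_lick_events(session.touch, session.force,
                                                session.lick_times, detected,
                                                fs_hz=session.force_rate)
    all_events = sorted(detected + other, key=lambda e: e.onset_s)
    io.save_events_csv(all_events, out / "events.csv")

    summary = events.summarize_behavior(all_events, session.duration_s)
    rows = [{"identity": k, "count": summary["counts"][k],
             "rate_per_min": summary["rates_per_min"][k],
             "proportion": summary["proportions"].get(k, float("nan"))}
            for k in summary["counts"]]
    pd.DataFrame(rows).to_csv(out / "behavior_summary.csv", index=False)

    n6 = sum(e.is_6g for e in detected)
    iso = sum(bool(e.pre_isolated and e.post_isolated) for e in detected)
    print(f"3 g cross actions: {len(detected)} ({n6} peaking above 6 g, "
          f"{iso} isolated both ways)")
    print(f"touch events: {sum(e.identity == 'touch' for e in other)}, "
          f"lick bouts: {sum(e.identity == 'lick' for e in other)}")
    for row in rows:
        print(f"  {row['identity']}: {row['count']} events, "
              f"{row['rate_per_min']:.2f}/min")
    print(f"wrote {out / 'events.csv'}, behavior_summary.csv")


if __name__ == "__main__":
    main()
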