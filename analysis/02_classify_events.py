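#!/usr/bin/env python
"""Segment the rainfall record into rain events and flag sampled ones.

An episode becomes a rain event when more than 1 mm falls within some 8-h
window; 8 h of dry record ends an event.  An event is sampled when at
least one instrumented inlet exceeded its stage trigger; the collector
shaft and stream samplers require two triggering inlets.
"""

import argparse
from pathlib import Path

import pandas as pd

from shortcutflux.config import PipelineConfig
from shortcutflux.events import classify_events, events_to_frame, flag_sampling_events
from shortcutflux.pipeline import read_layers

ap = argparse.ArgumentParser()
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

cfg = PipelineConfig(data_dir=str(args.data))
ds = read_layers(cfg)
events = classify_events(ds.rainfall)
events, triggers = flag_sampling_events(events, ds.stages, ds.thresholds)

df = events_to_frame(events)
args.out.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out / "events.csv", index=False)
triggers.to_csv(args.out / "triggers.csv")

dur_h = (df["end"] - df["start"]).dt.total_seconds() / 3600
print(f"{len(df)} rain events; median duration {dur_h.median():.1f} h, "
      f"totals {df['total_mm'].min():.1f}-{df['total_mm'].max():.1f} mm")
print(f"{int(df['is_sampling_event'].sum())} events triggered sampling in >=1 inlet")
print(f"tables written to {args.out}/events.csv and triggers.csv")
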