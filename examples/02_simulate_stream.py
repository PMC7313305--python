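"""Simulate a two-patient vital-sign stream with a planted emergency.

The planted predicate (Perf < 0.5 and NBP_Sys < 105) is driven true, with a
safety margin, during randomly scheduled episodes; the annotation table is
the ground truth a monitoring run should re-detect.
"""

from vitalwatch import PlantedEmergency, SignalModel, generate_stream

models = [SignalModel("Perf", mean=1.4, sd=0.25),
          SignalModel("NBP_Sys", mean=120.0, sd=8.0)]
planted = PlantedEmergency(
    label="SpO2 LOW PERF",
    predicate=(("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)),
    episode_rate_per_day=24.0, episode_duration_s=240.0, margin=0.2)

obs, ann = generate_stream(2, models, [planted], duration_hours=6.0, seed=42)
print(f"{len(obs)} observations, {len(ann)} planted episodes")
print("\nfirst episodes:")
print(ann.head(3).to_string(index=False))
first = ann.iloc[0]
in_episode = obs[(obs.patient_id == first["patient_id"])
                 & obs["timestamp"].between(first["start"], first["end"])]
perf = in_episode[in_episode.sign_code == "Perf"]["value"].astype(float)
print(f"\nPerf during the first episode: min={perf.min():.3f} "
      f"max={perf.max():.3f}  (all < 0.5 - margin = 0.3)")
# Every in-episode Perf value sits at least `margin` below the 0.5
# threshold, and every out-of-episode value at least `margin` above it.
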