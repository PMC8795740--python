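"""Generate a synthetic arena roam and its boundary-contact events.

The roam mimics a rat's free exploration: per-step speeds uniform in
(0, 0.5) m/s and heading increments uniform in (-pi/2, pi/2).
"""

from hippocan import Arena, detect_boundary_events, generate_random_walk

arena = Arena(4.0, 4.0)
traj = generate_random_walk(arena, duration=300.0, dt=0.1, seed=42)
events = detect_boundary_events(traj, arena, sensing_distance=0.2, segment_length=1.0)

print(f"samples: {len(traj)}, mean speed: {traj.speed.mean():.3f} m/s")
print(f"wall-band entries: {len(events)} "
      f"(first at t={events[0].t:.1f}s on segment {events[0].segment_id})"
      if events else "no wall contact in this roam")
# Every sample stays inside the arena; the events mark where the robot's
# wall sensor would fire, which the boundary cells later use for correction.
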