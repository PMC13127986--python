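"""One rotating-arena avoidance session: entrances, shocks and distances.

Simulates a 20-min session on the 82 cm arena rotating at 1 rpm with a
room-stable 60-degree punished sector, for a passive agent and an avoider,
and prints the session metrics in both reference frames with 5-min bins.
"""

from neurocarousel import (ArenaConfig, Bounds, WalkParams, carousel_metrics,
                           generate_walk)

arena = ArenaConfig()
for label, gain in (("passive agent ", 0.0), ("avoider       ", 60.0)):
    wp = WalkParams(mean_speed=10.0, bounds=Bounds("disc", 41.0),
                    avoidance_gain=gain, seed=3)
    traj = generate_walk(wp, arena.session_length, 0.05)
    m = carousel_metrics(traj, arena)
    print(f"{label}: {m.entrances:3d} entrances, {m.shocks:4d} shocks, "
          f"{m.time_in_sector:6.1f} s in sector")
    print(f"{'':14s}  distance arena frame {m.distance_arena:7.0f} cm, "
          f"room frame {m.distance_room:7.0f} cm")
    print(f"{'':14s}  entrances per 5-min bin: "
          f"{m.per_interval['entrances'].astype(int).tolist()}")
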