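"""Independent brute-force re-implementation of the trajectory features.

Deliberately naive: plain Python loops and the math module only, no shared
code with the package, so it can serve as an oracle for the vectorised
implementation.
"""

import math


def naive_features(rows, fps):
    """rows: list of dicts with frame, x, y, area, perimeter, major, minor, ar."""
    rows = sorted(rows, key=lambda r: r["frame"])
    n = len(rows)
    assert n >= 2
    out = {}
    for col in ("area", "perimeter", "major", "minor", "ar"):
        vals = [r[col] for r in rows]
        m = sum(vals) / n
        out[f"mean_{col}"] = m
        out[f"sd_{col}"] = math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))

    disps, speeds, headings = [], [], []
    for a, b in zip(rows[:-1], rows[1:]):
        dx, dy = b["x"] - a["x"], b["y"] - a["y"]
        d = math.hypot(dx, dy)
        dt = (b["frame"] - a["frame"]) / fps
        disps.append(d)
        speeds.append(d / dt)
        headings.append(math.atan2(dy, dx))

    turnings = []
    for h1, h2 in zip(headings[:-1], headings[1:]):
        t = h2 - h1
        while t <= -math.pi:
            t += 2 * math.pi
        while t > math.pi:
            t -= 2 * math.pi
        turnings.append(t)
    if turnings:
        c = sum(math.cos(t) for t in turnings) / len(turnings)
        s = sum(math.sin(t) for t in turnings) / len(turnings)
        rbar = min(1.0, math.hypot(c, s))
        out["sd_turning"] = (
            math.sqrt(-2.0 * math.log(rbar)) if rbar > 0 else float("inf")
        )
    else:
        out["sd_turning"] = float("nan")

    ms = sum(speeds) / len(speeds)
    out["gross_speed"] = ms
    out["sd_gross_speed"] = (
        math.sqrt(sum((v - ms) ** 2 for v in speeds) / (len(speeds) - 1))
        if len(speeds) >= 2
        else float("nan")
    )
    out["max_gross_speed"] = max(speeds)
    out["min_gross_speed"] = min(speeds)

    out["duration"] = (rows[-1]["frame"] - rows[0]["frame"]) / fps
    out["n_frames"] = n
    out["net_displacement"] = math.hypot(
        rows[-1]["x"] - rows[0]["x"], rows[-1]["y"] - rows[0]["y"]
    )
    sd = sorted(disps)
    k = len(sd)
    out["median_step"] = (
        sd[k // 2] if k % 2 else (sd[k // 2 - 1] + sd[k // 2]) / 2.0
    )
    out["detection_rate"] = n / (rows[-1]["frame"] - rows[0]["frame"] + 1)
    return out


def random_trajectory(rng, min_frames=3, max_frames=40):
    """A random (possibly gappy) trajectory as a list of row dicts."""
    n = int(rng.integers(min_frames, max_frames + 1))
    frames = sorted(rng.choice(3 * n, size=n, replace=False))
    rows = []
    for f in frames:
        major = float(rng.uniform(5, 200))
        ar = float(rng.uniform(1.0, 6.0))
        rows.append(
            {
                "frame": int(f),
                "x": float(rng.uniform(-1e3, 1e3)),
                "y": float(rng.uniform(-1e3, 1e3)),
                "area": float(rng.uniform(10, 5e4)),
                "perimeter": float(rng.uniform(5, 2e3)),
                "major": major,
                "minor": major / ar,
                "ar": ar,
            }
        )
    return rows
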