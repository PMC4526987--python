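"""Brute-force reference implementations used to cross-check the scorers.

These deliberately re-derive positioning and substantiation from first
principles (explicit enumeration over readings and treatments) without
touching the production code paths.
"""

import random

from pathforge.core import Activity, Pathway

RADICAL = set("SRCOH")


def oracle_positioning(pathway: Pathway) -> int:
    readings = [a for a in pathway.activities if a.code == "P" and isinstance(a.value, float)]
    treatments = [a for a in pathway.activities if a.code in RADICAL]
    if len(readings) == 0:
        return 0
    if len(treatments) == 0:
        return 1
    ref = min(t.time for t in treatments)
    n_before = sum(1 for r in readings if r.time <= ref)
    n_after = sum(1 for r in readings if r.time > ref)
    if n_before > 0 and n_after > 0:
        return 3
    if n_after > 0:
        return 2
    return 1


def oracle_substantiation(pathway: Pathway) -> str:
    readings = [a for a in pathway.activities if a.code == "P" and isinstance(a.value, float)]
    if len(readings) < 2 or oracle_positioning(pathway) in (0, 1):
        return "not_applicable"
    # maximum decline over adjacent reading pairs, earliest-first tie-break
    drops = []
    for i in range(len(readings) - 1):
        magnitude = readings[i].value - readings[i + 1].value
        if magnitude > 0:
            drops.append((magnitude, -readings[i].time, -readings[i + 1].time, i))
    if not drops:
        return "yes"  # never falls: constant or rising trend
    best = max(drops)
    i = best[3]
    lo, hi = readings[i].time, readings[i + 1].time
    for a in pathway.activities:
        if a.code in RADICAL and lo <= a.time <= hi:
            return "yes"
    return "no"


def random_pathway(rng: random.Random, max_len: int = 12) -> Pathway:
    """A random (possibly degenerate) pathway over the reference codes."""
    n = rng.randint(1, max_len)
    acts = []
    for _ in range(n):
        code = rng.choice("PPPDHSWRCOGXI")
        t = rng.randint(-50, 600)
        if code == "P":
            value = round(rng.uniform(0, 30), 1)  # 1 d.p. so exact ties occur
        else:
            value = "v"
        acts.append((t, code, value))
    acts.sort(key=lambda a: (a[0], a[1]))
    return Pathway(
        patient_id="r",
        activities=tuple(
            Activity("r", t, c, float(v) if c == "P" else v) for t, c, v in acts
        ),
    )
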