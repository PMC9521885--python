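"""Independent straight-loop reference implementation of the scoring math.

Pure-Python loops, no pandas group-bys and no code shared with the package:
used to cross-check A, D, SS, SDS and zip aggregation on small fixtures.
"""

from __future__ import annotations

import math


def oracle_scores(
    intervals: list[dict],
    areas: dict[str, float],
    zips: dict[str, str],
    min_baseline: int = 4,
    log_base: float = 10.0,
) -> dict[str, dict]:
    """intervals: dicts with unit_id, visits, open, complaint."""
    per_unit: dict[str, dict] = {}
    for row in intervals:
        u = row["unit_id"]
        if not row["open"]:
            continue
        d = per_unit.setdefault(u, {"comp": [], "base": []})
        intensity = row["visits"] * 10_000.0 / areas[u]
        if row["complaint"]:
            if row["visits"] > 0:
                d["comp"].append(intensity)
        else:
            d["base"].append(intensity)

    est: dict[str, dict] = {}
    for u, d in per_unit.items():
        if not d["comp"] or len(d["base"]) < min_baseline:
            continue
        A = sum(d["comp"]) / len(d["comp"])
        bm = sum(d["base"]) / len(d["base"])
        if bm <= 0 or A <= 0:
            continue
        D = (A - bm) / bm
        SS = D * math.log(A) / math.log(log_base)
        est[u] = {"A": A, "D": D, "SS": SS, "zip": zips[u]}

    ss = [e["SS"] for e in est.values()]
    if len(ss) >= 2 and max(ss) > min(ss):
        lo, hi = min(ss), max(ss)
        for e in est.values():
            e["SDS"] = abs(1.0 - (e["SS"] - lo) / (hi - lo)) * 100.0
    return est


def oracle_zip_means(est: dict[str, dict]) -> dict[str, float]:
    sums: dict[str, list] = {}
    for e in est.values():
        sums.setdefault(e["zip"], []).append(e["SDS"])
    return {z: sum(v) / len(v) for z, v in sums.items()}
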