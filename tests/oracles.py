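"""Independent oracles for the route search.

Exhaustive depth-first path enumeration with an admissible lower bound
(remaining great-circle distance at the best possible groundspeed), kept
deliberately independent of the Dijkstra implementation: the only shared
primitives are the kinematics functions whose closed forms are tested
separately.
"""

from __future__ import annotations

import math

from windcross.kinematics import AirspeedPolicy, edge_travel_time, great_circle


def exhaustive_minimal_route(grid, wind_at, departure, arrival, policy: AirspeedPolicy,
                             max_wind: float = 0.0):
    """Best (time_s, n_edges, path) by exhaustive simple-path search.

    ``wind_at`` maps a node to its (u, v); ``max_wind`` bounds the wind
    speed norm over the field, making dist/(airspeed+max_wind) an
    admissible remaining-time bound.  Ordering matches the route search
    contract: total time, then edge count, then lexicographic node order.
    """
    vmax = policy.airspeed + max_wind
    best: list = [math.inf, math.inf, None]

    def lb(node) -> float:
        dist, _ = great_circle((node.lat, node.lon), (arrival.lat, arrival.lon))
        return dist / vmax

    def dfs(path, time_s):
        node = path[-1]
        if node == arrival:
            cand = [time_s, len(path) - 1, tuple(path)]
            if (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2] or ()):
                best[0], best[1], best[2] = cand
            return
        for nxt in sorted(grid.successors(node)):
            if nxt in path_set:
                continue
            dt = edge_travel_time(
                (node.lat, node.lon), (nxt.lat, nxt.lon), wind_at(node), policy
            )
            if not math.isfinite(dt):
                continue
            t2 = time_s + dt
            if t2 + lb(nxt) > best[0]:
                continue  # cannot beat or tie the incumbent on time
            path.append(nxt)
            path_set.add(nxt)
            dfs(path, t2)
            path.pop()
            path_set.remove(nxt)

    path_set = {departure}
    dfs([departure], 0.0)
    return best[0], best[1], best[2]
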