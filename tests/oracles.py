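"""Brute-force oracles, written independently of the engine modules.

These operate on plain edge lists / event logs only, never on the engine's
graph or scheduler types, so they can arbitrate disagreements.
"""

from __future__ import annotations


def reachable_from(edges, seed, include_seed=True):
    """Exhaustive DFS over (src, dst) pairs: all nodes reachable from seed."""
    adj = {}
    for src, dst in edges:
        adj.setdefault(src, []).append(dst)
    seen = set()
    stack = [seed]
    while stack:
        node = stack.pop()
        for nxt in adj.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    if include_seed:
        seen.add(seed)
    return seen


def reachable_to(edges, seed, include_seed=True):
    """All nodes that can reach seed (ancestors closure)."""
    return reachable_from([(b, a) for a, b in edges], seed, include_seed)


def expected_selection(nodes, edges, from_ids=(), after_ids=(), until_ids=(),
                       before_ids=(), single_task=None):
    """Reference semantics of the sub-pipeline modifiers."""
    if single_task is not None:
        return {single_task}
    down = None
    if from_ids or after_ids:
        down = set()
        for s in from_ids:
            down |= reachable_from(edges, s, include_seed=True)
        for s in after_ids:
            down |= reachable_from(edges, s, include_seed=False)
    up = None
    if until_ids or before_ids:
        up = set()
        for s in until_ids:
            up |= reachable_to(edges, s, include_seed=True)
        for s in before_ids:
            up |= reachable_to(edges, s, include_seed=False)
    if down is None and up is None:
        return set(nodes)
    if down is None:
        return up
    if up is None:
        return down
    return down & up


def start_order(events):
    """Unit ids in the order their 'start' events appear."""
    return [uid for _, uid, ev in events if ev == "start"]


def is_topological(order, edges):
    """Every edge (a, b) has a's start before b's start (both present)."""
    pos = {u: i for i, u in enumerate(order)}
    return all(
        pos[a] < pos[b] for a, b in edges if a in pos and b in pos
    )


def max_concurrency(events):
    """Peak number of units simultaneously in flight, from the event log."""
    deltas = []
    for t, _, ev in events:
        if ev == "start":
            deltas.append((t, 1))
        elif ev in ("done", "failed"):
            deltas.append((t, -1))
    deltas.sort(key=lambda p: (p[0], p[1]))
    cur = peak = 0
    for _, d in deltas:
        cur += d
        peak = max(peak, cur)
    return peak


def ordering_violations(report_units, edges, binding_edges=()):
    """Dependency-safety violations in a finished report.

    ``edges``: task-level (a, b) pairs meaning every unit of b must start at
    or after the max end of a's units.  ``binding_edges``: (a, b) pairs where
    b[i] must start at or after a[i]'s end.  Returns a list of offending
    (unit_id, dep_unit_or_task) pairs.
    """
    import re

    by_task = {}
    for uid, rec in report_units.items():
        task = uid.split("[", 1)[0]
        by_task.setdefault(task, []).append(rec)
    bad = []
    binding = set(binding_edges)
    for a, b in edges:
        if (a, b) in binding:
            continue
        a_ends = [r.end for r in by_task.get(a, []) if r.end is not None]
        if not a_ends:
            continue
        barrier = max(a_ends)
        for rec in by_task.get(b, []):
            if rec.start is not None and rec.start < barrier:
                bad.append((rec.unit.unit_id, a))
    for a, b in binding:
        a_recs = sorted(
            (r for r in by_task.get(a, []) if r.unit.item_index is not None),
            key=lambda r: r.unit.item_index,
        )
        for rec in by_task.get(b, []):
            i = rec.unit.item_index
            if rec.start is None or i is None or i >= len(a_recs):
                continue
            a_end = a_recs[i].end
            if a_end is not None and rec.start < a_end:
                bad.append((rec.unit.unit_id, f"{a}[{i}]"))
    return bad
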