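"""Dependency DAG: construction, sub-pipeline selection and DOT export.

The engine computes the directed acyclic graph of task dependencies before
scheduling anything.  Edges point from a prerequisite to its dependent
(``to_id`` runs after ``from_id``); an edge carries ``binding=True`` when the
dependency was declared with the ``*`` prefix, i.e. iteration *i* of the
dependent foreach may start as soon as iteration *i* of the prerequisite
foreach finishes, instead of waiting for the whole loop.

Sub-pipeline selection implements the ``--from`` / ``--after`` / ``--until`` /
``--before`` / ``--single-task`` execution modifiers: downstream modifiers
take the descendants-closure of their seeds (inclusive for ``from``,
exclusive for ``after``), upstream modifiers the ancestors-closure
(``until`` inclusive, ``before`` exclusive); when both directions are given
the two closures are intersected, which on a chain yields exactly the tasks
on the path between the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Optional

import networkx as nx

from .errors import BindingError, CycleError, SelectionError
from .model import ForeachSpec, PipelineDoc

__all__ = ["DepGraph", "SubgraphQuery", "build_graph", "select_subgraph", "export_graph"]


@dataclass(frozen=True)
class DepGraph:
    """Immutable dependency DAG over task identifiers (document order kept)."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, bool], ...]  # (from_id, to_id, binding)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for src, dst, binding in self.edges:
            g.add_edge(src, dst, binding=binding)
        return g

    def dependencies_of(self, task_id: str) -> list[tuple[str, bool]]:
        """(prerequisite, binding) pairs for one task."""
        return [(src, b) for src, dst, b in self.edges if dst == task_id]


@dataclass(frozen=True)
class SubgraphQuery:
    """A sub-pipeline request; ``single_task`` excludes the four closures."""

    from_ids: FrozenSet[str] = frozenset()
    after_ids: FrozenSet[str] = frozenset()
    until_ids: FrozenSet[str] = frozenset()
    before_ids: FrozenSet[str] = frozenset()
    single_task: Optional[str] = None

    def is_empty(self) -> bool:
        return not (
            self.from_ids or self.after_ids or self.until_ids
            or self.before_ids or self.single_task
        )


def build_graph(doc: PipelineDoc) -> DepGraph:
    """Build the DAG from a validated pipeline.

    Raises :class:`CycleError` (listing one offending cycle) if the
    dependencies are circular, and :class:`BindingError` if a ``*`` mark sits
    on a dependency whose endpoints are not both foreach tasks.
    """
    tasks = doc.task_map()
    edges: list[tuple[str, str, bool]] = []
    for task in doc.tasks:
        for dep in task.after:
            if dep.binding:
                src = tasks.get(dep.task_id)
                if not isinstance(src, ForeachSpec) or not isinstance(task, ForeachSpec):
                    raise BindingError(
                        f"'*{dep.task_id}' in task '{task.id}': iteration binding "
                        "requires both endpoints to be foreach tasks"
                    )
            edges.append((dep.task_id, task.id, dep.binding))
    g = nx.DiGraph()
    g.add_nodes_from(t.id for t in doc.tasks)
    g.add_edges_from((s, d) for s, d, _ in edges)
    try:
        cycle_edges = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        pass
    else:
        raise CycleError([src for src, _ in cycle_edges])
    return DepGraph(nodes=tuple(t.id for t in doc.tasks), edges=tuple(edges))


def select_subgraph(g: DepGraph, q: SubgraphQuery) -> set[str]:
    """Resolve an execution-modifier query to the set of tasks to run.

    No modifiers selects every task.  Raises :class:`SelectionError` for
    unknown ids or for ``single_task`` combined with any closure modifier.
    """
    known = set(g.nodes)
    named = q.from_ids | q.after_ids | q.until_ids | q.before_ids
    if q.single_task is not None:
        if named:
            raise SelectionError(
                "--single-task is not compatible with --from/--after/--until/--before"
            )
        if q.single_task not in known:
            raise SelectionError(f"unknown task '{q.single_task}'")
        return {q.single_task}
    unknown = sorted(named - known)
    if unknown:
        raise SelectionError("unknown task(s): " + ", ".join(unknown))
    if q.is_empty():
        return known

    nxg = g.to_networkx()
    downstream: Optional[set[str]] = None
    if q.from_ids or q.after_ids:
        downstream = set()
        for seed in q.from_ids:
            downstream |= {seed} | nx.descendants(nxg, seed)
        for seed in q.after_ids:
            downstream |= nx.descendants(nxg, seed)
    upstream: Optional[set[str]] = None
    if q.until_ids or q.before_ids:
        upstream = set()
        for seed in q.until_ids:
            upstream |= {seed} | nx.ancestors(nxg, seed)
        for seed in q.before_ids:
            upstream |= nx.ancestors(nxg, seed)
    if downstream is not None and upstream is not None:
        return downstream & upstream
    return downstream if downstream is not None else upstream  # type: ignore[return-value]


def export_graph(doc: PipelineDoc) -> str:
    """Render the pipeline DAG as Graphviz DOT text.

    Nodes and edges are emitted in document order, so the output is
    deterministic.  Foreach tasks get a dashed border; iteration-binding
    edges are labelled ``*``.
    """
    g = build_graph(doc)  # enforces acyclicity / binding rules
    foreach_ids = {t.id for t in doc.tasks if isinstance(t, ForeachSpec)}
    lines = ["digraph pipeline {"]
    for node in g.nodes:
        attrs = [f'label="{node}"']
        if node in foreach_ids:
            attrs.append("style=dashed")
        lines.append(f'  "{node}" [{", ".join(attrs)}];')
    for src, dst, binding in g.edges:
        attr = ' [label="*"]' if binding else ""
        lines.append(f'  "{src}" -> "{dst}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"
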