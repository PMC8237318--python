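"""Self-contained example and randomized pipelines for tests and demos.

Everything here is generated programmatically — no external data or services
— and every generated pipeline validates cleanly.  Task bodies only touch
files inside a caller-supplied directory, so tests stay hermetic.  The
randomized generator ships its own edge list so reachability and
topological-order checks can be made against an oracle that never consults
the engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    DependencyRef,
    ForeachSpec,
    ParamDef,
    PipelineDoc,
    TaskDef,
    serialize_pipeline,
)

__all__ = [
    "GeneratedPipeline",
    "minimal_pipeline",
    "foreach_pipeline",
    "random_dag_pipeline",
]


@dataclass(frozen=True)
class GeneratedPipeline:
    xml_text: str
    expected_graph: tuple  # ((from_id, to_id, binding), ...)
    expected_param_names: tuple
    seed: int = 0


def minimal_pipeline() -> GeneratedPipeline:
    """A two-task hello/goodbye pipeline exercising the core contracts.

    Two parameters (``name``, ``output``); task ``greetings`` runs as a plain
    shell command, task ``bye`` is written in AWK and declares an interpreter
    that feeds the task code (via the ``task_code`` environment variable) to
    the AWK interpreter.  Both append a line mentioning ``$name`` to the
    ``$output`` path, so a successful run leaves exactly two lines in
    dependency order.
    """
    doc = PipelineDoc(
        params=(
            ParamDef("name", "name of the person to greet"),
            ParamDef("output", "file path the greetings are appended to"),
        ),
        tasks=(
            TaskDef(
                id="greetings",
                params=("name", "output"),
                code='echo "Hello $name" >> "$output"\n',
                metadata_description="appends a hello line to the output file",
            ),
            TaskDef(
                id="bye",
                params=("name", "output"),
                after=(DependencyRef("greetings"),),
                interpreter='awk "$task_code"',
                code='BEGIN { printf "Bye %s\\n", ENVIRON["name"] >> ENVIRON["output"] }',
                metadata_description="appends a goodbye line, written in AWK",
            ),
        ),
    )
    return GeneratedPipeline(
        xml_text=serialize_pipeline(doc),
        expected_graph=(("greetings", "bye", False),),
        expected_param_names=("name", "output"),
    )


DEFAULT_SAMPLES = ("case-1", "case-2", "control-1", "control-2")


def foreach_pipeline(
    samples=DEFAULT_SAMPLES,
    binding: bool = True,
    pre_sleeps=None,
    analyze_sleep: float = 0.05,
) -> GeneratedPipeline:
    """Two consecutive foreach loops (preprocess → analyze) over samples.

    With ``binding=True`` the analyze loop depends on preprocess at the
    iteration level (``after="*preprocess"``), so analyze[i] may start as
    soon as preprocess[i] is done.  Each iteration writes a timestamped
    marker file ``pre-<sample>`` / ``ana-<sample>`` under the global
    ``workdir`` parameter, and sleeps a configurable per-sample duration so
    ordering tests can observe loop overlap.  By default the *last*
    preprocess iteration is slow and the rest fast, which under binding lets
    early analyze iterations start before the preprocess loop has drained.
    """
    samples = tuple(samples)
    if not samples:
        raise ValueError("samples must be non-empty")
    if pre_sleeps is None:
        pre_sleeps = [0.05] * (len(samples) - 1) + [0.4]
    if len(pre_sleeps) != len(samples):
        raise ValueError("pre_sleeps must align with samples")

    cases = "\n".join(
        f'  {s}) s={dur};;' for s, dur in zip(samples, pre_sleeps)
    )
    pre_code = (
        f'\ncase "$sample" in\n{cases}\n  *) s=0;;\nesac\n'
        'sleep "$s"\n'
        'date +%s.%N > "$workdir/pre-$sample"\n'
    )
    ana_code = (
        f'\nsleep {analyze_sleep}\n'
        'date +%s.%N > "$workdir/ana-$sample"\n'
    )
    sample_list = ",".join(samples)
    doc = PipelineDoc(
        params=(ParamDef("workdir", "directory for iteration marker files",
                         is_global=True),),
        tasks=(
            ForeachSpec(
                id="preprocess",
                code=pre_code,
                source_kind="list",
                source_arg=sample_list,
                item_var="sample",
                metadata_description="per-sample preprocessing (marker + sleep)",
            ),
            ForeachSpec(
                id="analyze",
                code=ana_code,
                after=(DependencyRef("preprocess", binding=binding),),
                source_kind="list",
                source_arg=sample_list,
                item_var="sample",
                metadata_description="per-sample analysis, bound to preprocess",
            ),
        ),
    )
    return GeneratedPipeline(
        xml_text=serialize_pipeline(doc),
        expected_graph=(("preprocess", "analyze", binding),),
        expected_param_names=("workdir",),
    )


def random_dag_pipeline(
    n: int, edge_prob: float, seed: int
) -> GeneratedPipeline:
    """``n`` trivial tasks with random forward edges (acyclic by construction).

    Task ``t<i>`` may depend on ``t<j>`` only for ``j < i``, so any edge set
    is a DAG.  Deterministic for a given seed; the returned edge list is the
    oracle input for reachability and topological-order checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    edges = []
    tasks = []
    for i in range(n):
        deps = tuple(
            DependencyRef(f"t{j}") for j in range(i) if rng.random() < edge_prob
        )
        edges.extend((d.task_id, f"t{i}", False) for d in deps)
        tasks.append(TaskDef(id=f"t{i}", code=":\n", after=deps))
    doc = PipelineDoc(params=(), tasks=tuple(tasks))
    return GeneratedPipeline(
        xml_text=serialize_pipeline(doc),
        expected_graph=tuple(edges),
        expected_param_names=(),
        seed=seed,
    )
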