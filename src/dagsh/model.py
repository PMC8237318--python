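"""Pipeline definition language: parsing, in-memory model and validation.

A pipeline is a single XML document with three order-independent sections:

``<params>``
    ``<param name="..." global="true|false" defaultValue="...">description</param>``
    entries declaring the user-facing parameters.  Parameter values reach task
    scripts exclusively through environment variables, so names are restricted
    to shell-safe identifiers.

``<tasks>``
    ``<task>`` and ``<foreach>`` elements.  The element body is the task
    script, normally wrapped in a CDATA block so that arbitrary source code
    (any language) survives byte-for-byte — the engine never rewrites or
    substitutes into task code.  ``params`` and ``after`` attributes hold
    whitespace/comma separated identifier lists; an ``after`` entry may carry
    a ``*`` prefix marking an iteration-level (per-item) dependency between
    two foreach loops.  ``interpreter`` is a shell fragment that receives the
    script via the ``task_code`` environment variable; ``if`` is a guard
    command evaluated just before the task runs.

``<metadata>``
    ``<task-description id="...">`` human-readable task descriptions used for
    generated help; purely documentary.

Foreach item sources (``of`` attribute): ``list`` (comma-separated literal),
``range`` (``start..end``, inclusive integers), ``files_in_dir`` (lexicographic
file listing), ``param_values`` (comma-split of a parameter's value) and
``command`` (stdout lines of a shell command run when the loop becomes ready).
Each item is bound to the environment variable named by ``as``.

Validation is data, not exceptions: :func:`validate` returns a deterministic
list of :class:`ValidationIssue`.  Errors always block execution; warnings
block only under ``--abort-if-warnings``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

from lxml import etree

from .errors import ParamsFileError, PipelineParseError, PipelineSchemaError

__all__ = [
    "NAME_RE",
    "ParamDef",
    "DependencyRef",
    "TaskDef",
    "ForeachSpec",
    "PipelineDoc",
    "ValidationIssue",
    "SOURCE_KINDS",
    "parse_pipeline",
    "serialize_pipeline",
    "validate",
    "parse_params_file",
]

#: Shell-safe identifier: usable verbatim as an environment variable name.
NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

SOURCE_KINDS = ("list", "range", "files_in_dir", "param_values", "command")

#: Variables the engine itself injects into every task environment.
ENGINE_VARIABLES = ("task_id", "working_dir")


@dataclass(frozen=True)
class ParamDef:
    """A declared pipeline parameter.

    ``is_global`` parameters are visible to every task; non-global ones only
    to tasks listing them in their ``params`` attribute.
    """

    name: str
    description: str = ""
    default_value: Optional[str] = None
    is_global: bool = False


@dataclass(frozen=True)
class DependencyRef:
    """One entry of a task's ``after`` list; ``binding`` for ``*``-prefixed entries."""

    task_id: str
    binding: bool = False


@dataclass(frozen=True)
class TaskDef:
    """A plain task: a script run once, by the shell or a declared interpreter."""

    id: str
    code: str = ""
    params: tuple[str, ...] = ()
    after: tuple[DependencyRef, ...] = ()
    interpreter: Optional[str] = None
    if_guard: Optional[str] = None
    metadata_description: str = ""

    @property
    def is_foreach(self) -> bool:
        return isinstance(self, ForeachSpec)


@dataclass(frozen=True)
class ForeachSpec(TaskDef):
    """A loop task expanded into one iteration unit per resolved item."""

    source_kind: str = "list"
    source_arg: str = ""
    item_var: str = "item"


@dataclass(frozen=True)
class PipelineDoc:
    """The parsed pipeline: parameters and tasks in document order."""

    params: tuple[ParamDef, ...] = ()
    tasks: tuple[TaskDef, ...] = ()
    version: Optional[str] = None

    def param_map(self) -> dict[str, ParamDef]:
        return {p.name: p for p in self.params}

    def task_map(self) -> dict[str, TaskDef]:
        return {t.id: t for t in self.tasks}

    def global_param_names(self) -> set[str]:
        return {p.name for p in self.params if p.is_global}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    task_id: Optional[str]
    message: str

    def __str__(self) -> str:
        where = f" [task {self.task_id}]" if self.task_id else ""
        return f"{self.severity}: {self.code}{where}: {self.message}"


_schema_cache: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        with resources.files(__package__).joinpath("pipeline.xsd").open("rb") as fh:
            _schema_cache = etree.XMLSchema(etree.parse(fh))
    return _schema_cache


def _split_ids(value: Optional[str]) -> list[str]:
    if not value:
        return []
    return [tok for tok in re.split(r"[\s,]+", value.strip()) if tok]


def parse_pipeline(xml_text: str | bytes) -> PipelineDoc:
    """Parse and schema-check a pipeline document.

    Task code bodies are returned byte-identical to their CDATA/text content;
    no substitution or whitespace normalisation is applied.  Section order in
    the document does not affect the result.

    Raises :class:`PipelineParseError` for malformed XML (message carries
    line/column) and :class:`PipelineSchemaError` for well-formed documents
    that violate the dialect (unknown elements, bad attributes...).
    """
    if isinstance(xml_text, str):
        data = xml_text.encode("utf-8")
    else:
        data = xml_text
    if not data.strip():
        raise PipelineParseError("empty pipeline document")
    try:
        root = etree.parse(io.BytesIO(data)).getroot()
    except etree.XMLSyntaxError as exc:
        raise PipelineParseError(f"malformed XML: {exc}") from exc
    schema = _schema()
    if not schema.validate(root):
        msgs = "; ".join(
            f"line {e.line}: {e.message}" for e in schema.error_log
        )
        raise PipelineSchemaError(f"pipeline does not match schema: {msgs}")

    descriptions: dict[str, str] = {}
    meta = root.find("metadata")
    if meta is not None:
        for el in meta.findall("task-description"):
            descriptions[el.get("id")] = (el.text or "").strip()

    params: list[ParamDef] = []
    params_el = root.find("params")
    if params_el is not None:
        for el in params_el.findall("param"):
            params.append(
                ParamDef(
                    name=el.get("name"),
                    description=(el.text or "").strip(),
                    default_value=el.get("defaultValue"),
                    is_global=el.get("global", "false") in ("true", "1"),
                )
            )

    tasks: list[TaskDef] = []
    tasks_el = root.find("tasks")
    if tasks_el is not None:
        for el in tasks_el:
            if el.tag is etree.Comment:
                continue
            common = dict(
                id=el.get("id"),
                code=el.text or "",
                params=tuple(_split_ids(el.get("params"))),
                after=tuple(
                    DependencyRef(tok.lstrip("*"), binding=tok.startswith("*"))
                    for tok in _split_ids(el.get("after"))
                ),
                interpreter=el.get("interpreter"),
                if_guard=el.get("if"),
                metadata_description=descriptions.get(el.get("id"), ""),
            )
            if el.tag == "foreach":
                tasks.append(
                    ForeachSpec(
                        **common,
                        source_kind=el.get("of"),
                        source_arg=el.get("in"),
                        item_var=el.get("as"),
                    )
                )
            else:
                tasks.append(TaskDef(**common))

    return PipelineDoc(
        params=tuple(params), tasks=tuple(tasks), version=root.get("version")
    )


def serialize_pipeline(doc: PipelineDoc) -> str:
    """Render a document back to XML; ``parse_pipeline(serialize_pipeline(d)) == d``.

    Code bodies are emitted as CDATA where possible (falling back to entity
    escaping when the body itself contains a CDATA terminator).
    """
    root = etree.Element("pipeline")
    if doc.version is not None:
        root.set("version", doc.version)
    params_el = etree.SubElement(root, "params")
    for p in doc.params:
        el = etree.SubElement(params_el, "param", name=p.name)
        if p.is_global:
            el.set("global", "true")
        if p.default_value is not None:
            el.set("defaultValue", p.default_value)
        el.text = p.description
    tasks_el = etree.SubElement(root, "tasks")
    described = []
    for t in doc.tasks:
        if isinstance(t, ForeachSpec):
            el = etree.SubElement(
                tasks_el, "foreach", id=t.id, of=t.source_kind
            )
            el.set("in", t.source_arg)
            el.set("as", t.item_var)
        else:
            el = etree.SubElement(tasks_el, "task", id=t.id)
        if t.params:
            el.set("params", " ".join(t.params))
        if t.after:
            el.set(
                "after",
                " ".join(("*" if d.binding else "") + d.task_id for d in t.after),
            )
        if t.interpreter is not None:
            el.set("interpreter", t.interpreter)
        if t.if_guard is not None:
            el.set("if", t.if_guard)
        if t.code:
            if "]]>" in t.code:
                el.text = t.code  # escaped; CDATA cannot contain its own terminator
            else:
                el.text = etree.CDATA(t.code)
        if t.metadata_description:
            described.append(t)
    if described:
        meta = etree.SubElement(root, "metadata")
        for t in described:
            el = etree.SubElement(meta, "task-description", id=t.id)
            el.text = t.metadata_description
    return etree.tostring(root, encoding="unicode", pretty_print=False)


def _accessible_names(task: TaskDef, doc: PipelineDoc) -> set[str]:
    names = set(task.params) | doc.global_param_names() | set(ENGINE_VARIABLES)
    if isinstance(task, ForeachSpec):
        names.add(task.item_var)
    return names


def _param_token_re(name: str) -> re.Pattern:
    # whole-token match of $name or ${name}; $nameX must not count
    return re.compile(r"\$\{" + re.escape(name) + r"\}|\$" + re.escape(name) + r"\b")


def validate(doc: PipelineDoc) -> list[ValidationIssue]:
    """Check a parsed pipeline; returns all issues, never raises.

    Errors: invalid identifiers, duplicate parameter names or task ids,
    references to unknown parameters or tasks, self-dependencies, dependency
    cycles, and a foreach item variable shadowing a declared parameter.

    Warnings: a declared parameter's name appearing as a ``$name``/``${name}``
    token inside a task's code while that task has no access to it (not listed
    in its ``params`` and not global) — a typical authoring slip.

    The list is ordered by (task position in the document, issue code,
    message); document-level issues sort first.  The function is pure:
    repeated calls return identical lists.
    """
    issues: list[tuple[int, ValidationIssue]] = []

    def add(pos: int, severity: str, code: str, task_id: Optional[str], msg: str):
        issues.append((pos, ValidationIssue(severity, code, task_id, msg)))

    seen_params: set[str] = set()
    for p in doc.params:
        if not NAME_RE.match(p.name or ""):
            add(-1, "error", "invalid-param-name", None,
                f"parameter name {p.name!r} is not a shell-safe identifier")
        if p.name in seen_params:
            add(-1, "error", "duplicate-param-name", None,
                f"parameter '{p.name}' declared more than once")
        seen_params.add(p.name)

    declared_params = {p.name for p in doc.params}
    task_ids = [t.id for t in doc.tasks]
    seen_tasks: set[str] = set()

    for pos, task in enumerate(doc.tasks):
        if not NAME_RE.match(task.id or ""):
            add(pos, "error", "invalid-task-id", task.id,
                f"task id {task.id!r} is not a shell-safe identifier")
        if task.id in seen_tasks:
            add(pos, "error", "duplicate-task-id", task.id,
                f"task id '{task.id}' declared more than once")
        seen_tasks.add(task.id)

        for name in task.params:
            if name not in declared_params:
                add(pos, "error", "unknown-param", task.id,
                    f"task lists undeclared parameter '{name}'")
        for dep in task.after:
            if dep.task_id == task.id:
                add(pos, "error", "self-dependency", task.id,
                    "task depends on itself")
            elif dep.task_id not in task_ids:
                add(pos, "error", "unknown-dependency", task.id,
                    f"dependency target '{dep.task_id}' does not exist")
        if isinstance(task, ForeachSpec):
            if task.source_kind not in SOURCE_KINDS:
                add(pos, "error", "invalid-source-kind", task.id,
                    f"unknown item source kind {task.source_kind!r}")
            if not NAME_RE.match(task.item_var or ""):
                add(pos, "error", "invalid-item-var", task.id,
                    f"item variable {task.item_var!r} is not a shell-safe identifier")
            elif task.item_var in declared_params:
                add(pos, "error", "item-var-collides-param", task.id,
                    f"item variable '{task.item_var}' shadows a declared parameter")

        accessible = _accessible_names(task, doc)
        for name in sorted(declared_params - accessible):
            if _param_token_re(name).search(task.code):
                add(pos, "warning", "param-not-accessible", task.id,
                    f"parameter '{name}' appears in the task code but the task "
                    "has no access to it (not global, not in the task's params)")

    # cycle detection over resolvable edges only
    known = set(task_ids)
    adj: dict[str, list[str]] = {}
    for t in doc.tasks:  # first occurrence wins under duplicate ids
        adj.setdefault(
            t.id,
            [d.task_id for d in t.after if d.task_id in known and d.task_id != t.id],
        )
    cycle = _find_cycle(task_ids, adj)
    if cycle:
        pos = min(task_ids.index(tid) for tid in cycle)
        add(pos, "error", "dependency-cycle", cycle[0],
            "dependency cycle: " + " -> ".join(cycle + cycle[:1]))

    issues.sort(key=lambda pair: (pair[0], pair[1].code, pair[1].message))
    return [iss for _, iss in issues]


def _find_cycle(nodes: list[str], adj: Mapping[str, list[str]]) -> list[str]:
    """Iterative DFS returning one cycle as a node list, or [] if acyclic."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}
    parent: dict[str, str] = {}
    for start in nodes:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(adj[start]))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    parent[nxt] = node
                    stack.append((nxt, iter(adj[nxt])))
                    advanced = True
                    break
                if color[nxt] == GREY:
                    cycle = [node]
                    cur = node
                    while cur != nxt:
                        cur = parent[cur]
                        cycle.append(cur)
                    cycle.reverse()
                    return cycle
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return []


def parse_params_file(text: str) -> dict[str, str]:
    """Parse a plain-text ``KEY=VALUE`` parameters file.

    Blank lines and ``#`` comment lines are ignored.  The value is everything
    after the first ``=``, whitespace preserved; duplicate keys: last wins.

    Raises :class:`ParamsFileError` naming the offending line for any other
    content.
    """
    values: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "=" not in line:
            raise ParamsFileError(
                f"expected KEY=VALUE, got {line!r}", line_number=lineno
            )
        key, _, value = line.partition("=")
        key = key.strip()
        if not key:
            raise ParamsFileError("empty key", line_number=lineno)
        values[key] = value
    return values
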