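"""Reactive DAG scheduler with bounded concurrency and iteration-level binding.

Execution is organised around *iteration units*: a plain task is one unit, a
foreach task expands into one unit per resolved item.  Right after starting,
and whenever a unit finishes, the engine reacts: every unit whose dependency
obligations are now met is handed to a worker pool whose size is the
``--num-tasks`` bound, so at most ``max_parallel`` units run at any instant.

Dependency obligations:

* a non-binding edge A→B holds back *every* unit of B until *all* units of A
  are done;
* an iteration-binding edge A→*B (both foreach, same collection) releases
  B[i] as soon as A[i] is done, so consecutive loops overlap item-wise;
* a task skipped by its ``if`` guard counts as satisfied for its dependents.

Foreach item sources of kind ``command`` and ``files_in_dir`` are evaluated
only when the loop becomes ready, never earlier, enabling dynamic scheduling
(the item count may depend on a previous task's output).  Iteration-bound
loops must resolve collections of equal length; a mismatch is a
:class:`BindingCardinalityError`.

On a unit failure no new dependent unit starts (dependents are *aborted*),
but independent eligible branches run to completion, maximising the work a
later ``resume`` can reuse.  Completed unit ids are appended to a plain-text
state file as they finish; ``resume`` reads it back and executes only the
remainder, treating recorded units as satisfied.

Ties among simultaneously ready units are broken by task document order,
then item index, which makes single-worker runs fully deterministic.
"""

from __future__ import annotations

import logging
import re
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from . import execution
from .errors import (
    BindingCardinalityError,
    DagshError,
    GuardError,
    ItemResolutionError,
    StateFileError,
    ValidationFailedError,
)
from .execution import RunnerDef, build_environment, run_shell_text
from .graph import DepGraph, SubgraphQuery, build_graph, select_subgraph
from .model import ForeachSpec, PipelineDoc, TaskDef, validate

__all__ = [
    "IterationUnit",
    "RunSettings",
    "UnitRecord",
    "ExecutionReport",
    "resolve_items",
    "expand_foreach",
    "evaluate_guard",
    "run",
    "save_state",
    "load_state",
    "default_state_path",
]

log = logging.getLogger("dagsh")

DEFAULT_MAX_PARALLEL = 6

# unit / task states
PENDING = "pending"
RUNNING = "running"
DONE = "done"
FAILED = "failed"
ABORTED = "aborted"
SKIPPED = "skipped-by-guard"

_WAITING = "waiting"
_PREPARING = "preparing"
_EXPANDED = "expanded"


@dataclass(frozen=True)
class IterationUnit:
    """One schedulable unit: a plain task, or one item-iteration of a foreach."""

    task_id: str
    item_index: Optional[int] = None
    item_value: Optional[str] = None

    @property
    def unit_id(self) -> str:
        if self.item_index is None:
            return self.task_id
        return f"{self.task_id}[{self.item_index}]"


@dataclass(frozen=True)
class RunSettings:
    """Everything that controls one execution besides the pipeline itself."""

    max_parallel: int = DEFAULT_MAX_PARALLEL
    log_dir: Optional[str] = None
    log_only: frozenset = frozenset()
    log_exclude: frozenset = frozenset()
    quiet: bool = False
    show_std_outs: bool = False
    abort_if_warnings: bool = False
    selection: SubgraphQuery = field(default_factory=SubgraphQuery)
    runners: tuple = ()
    working_dir: str = "."
    shell: Optional[str] = None
    state_file: Optional[str] = None

    def __post_init__(self):
        if self.max_parallel < 1:
            raise ValueError("max_parallel must be >= 1")
        if self.log_only and self.log_exclude:
            raise ValueError("log_only and log_exclude are mutually exclusive")


@dataclass
class UnitRecord:
    unit: IterationUnit
    state: str = PENDING
    start: Optional[float] = None
    end: Optional[float] = None
    exit_status: Optional[int] = None

    @property
    def unit_id(self) -> str:
        return self.unit.unit_id


@dataclass
class ExecutionReport:
    """Observable outcome of one run: per-unit records and a total event order.

    Events are ``(timestamp, unit_id, event)`` with event one of ``start``,
    ``done``, ``failed``, ``aborted``, ``skipped-by-guard`` or ``resumed``
    (completed in a previous run, not re-executed).  Task-level events (guard
    skips, whole-task aborts) use the task id as unit id.
    """

    units: dict = field(default_factory=dict)  # unit_id -> UnitRecord
    events: list = field(default_factory=list)  # (timestamp, unit_id, event)
    task_states: dict = field(default_factory=dict)  # task_id -> state
    success: bool = True

    def done_unit_ids(self) -> set:
        return {uid for uid, rec in self.units.items() if rec.state == DONE}

    def state_lines(self) -> list:
        """Unit/task ids a later resume may treat as completed, sorted."""
        lines = set(self.done_unit_ids())
        for tid, st in self.task_states.items():
            if st == SKIPPED:
                lines.add(tid)
        return sorted(lines)


_RANGE_RE = re.compile(r"^\s*(-?\d+)\s*\.\.\s*(-?\d+)\s*$")


def resolve_items(
    spec: ForeachSpec,
    param_values: Mapping,
    working_dir: str = ".",
    env: Optional[Mapping] = None,
    shell: Optional[str] = None,
) -> list:
    """Evaluate a foreach item source into an ordered list of text items.

    ``list``: comma-split, whitespace-trimmed (empty tokens dropped).
    ``range``: ``start..end`` inclusive, rendered as decimal strings.
    ``files_in_dir``: lexicographically sorted paths of the files directly in
    the directory.  ``param_values``: comma-split of the named parameter's
    value.  ``command``: stdout lines of the command, run by the shell in the
    working directory under the task's environment; the trailing empty line
    is dropped.  A failing command or missing directory raises
    :class:`ItemResolutionError`.
    """
    kind, arg = spec.source_kind, spec.source_arg
    if kind == "list":
        return [tok.strip() for tok in arg.split(",") if tok.strip()]
    if kind == "range":
        m = _RANGE_RE.match(arg)
        if not m:
            raise ItemResolutionError(
                f"foreach '{spec.id}': bad range {arg!r}, expected 'start..end'"
            )
        lo, hi = int(m.group(1)), int(m.group(2))
        return [str(i) for i in range(lo, hi + 1)]
    if kind == "files_in_dir":
        d = Path(arg)
        if not d.is_absolute():
            d = Path(working_dir) / d
        if not d.is_dir():
            raise ItemResolutionError(
                f"foreach '{spec.id}': directory {d} does not exist"
            )
        return sorted(str(p) for p in d.iterdir() if p.is_file())
    if kind == "param_values":
        if arg not in param_values:
            raise ItemResolutionError(
                f"foreach '{spec.id}': parameter '{arg}' has no value"
            )
        return [tok.strip() for tok in str(param_values[arg]).split(",") if tok.strip()]
    if kind == "command":
        rc, out, err, _ = run_shell_text(arg, env or {}, working_dir, shell)
        if rc != 0:
            raise ItemResolutionError(
                f"foreach '{spec.id}': item command exited {rc}: {err.strip()}"
            )
        lines = out.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
        return lines
    raise ItemResolutionError(f"foreach '{spec.id}': unknown source kind {kind!r}")


def expand_foreach(spec: ForeachSpec, items: Iterable) -> list:
    """One :class:`IterationUnit` per item, indexes following item order."""
    return [
        IterationUnit(task_id=spec.id, item_index=i, item_value=str(item))
        for i, item in enumerate(items)
    ]


def evaluate_guard(
    task: TaskDef,
    env: Mapping,
    working_dir: str = ".",
    shell: Optional[str] = None,
) -> bool:
    """Run a task's ``if`` guard under the task's environment contract.

    Exit status 0 means run; any other means skip — except 126/127 (command
    not executable / not found), which raise :class:`GuardError` and fail the
    task rather than silently skipping it.
    """
    assert task.if_guard is not None
    rc, _, err, _ = run_shell_text(task.if_guard, env, working_dir, shell)
    if rc in (126, 127):
        raise GuardError(
            f"task '{task.id}': guard command not executable (exit {rc}): {err.strip()}"
        )
    return rc == 0


def default_state_path(settings: RunSettings) -> Path:
    if settings.state_file:
        return Path(settings.state_file)
    if settings.log_dir:
        return Path(settings.log_dir) / "dagsh.state"
    return Path(settings.working_dir) / ".dagsh-state"


_STATE_LINE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*(\[\d+\])?$")


def save_state(report: ExecutionReport, path) -> None:
    """Write the resume state: one completed unit/task id per line."""
    Path(path).write_text("".join(line + "\n" for line in report.state_lines()))


def load_state(path) -> set:
    """Read a resume-state file back into a set of completed unit ids.

    Raises :class:`StateFileError` on unreadable or corrupt content.
    """
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise StateFileError(f"cannot read state file {path}: {exc}") from exc
    completed = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if not _STATE_LINE_RE.match(line):
            raise StateFileError(
                f"corrupt state file {path}, line {lineno}: {line!r}"
            )
        completed.add(line)
    return completed


def run(
    doc: PipelineDoc,
    param_values: Mapping,
    settings: Optional[RunSettings] = None,
    completed: Iterable = (),
) -> ExecutionReport:
    """Validate, schedule and execute a pipeline; returns the execution report.

    Raises :class:`ValidationFailedError` before any unit starts when
    validation yields errors — or warnings under ``abort_if_warnings``.
    ``completed`` is the resume set from :func:`load_state`; those units are
    marked done without re-execution.
    """
    settings = settings or RunSettings()
    issues = validate(doc)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValidationFailedError(errors)
    if settings.abort_if_warnings and issues:
        raise ValidationFailedError(issues)
    return _Engine(doc, dict(param_values), settings, set(completed)).execute()


class _Engine:
    def __init__(self, doc, param_values, settings, completed):
        self.doc = doc
        self.params = param_values
        self.settings = settings
        self.completed = completed
        self.graph: DepGraph = build_graph(doc)
        self.selected = select_subgraph(self.graph, settings.selection)
        self.order = {t.id: i for i, t in enumerate(doc.tasks)}
        self.tasks = doc.task_map()
        # per-task in-selection dependencies; out-of-selection deps are
        # assumed satisfied (their outputs presumed present) with a notice
        self.deps: dict = {}
        for tid in self.selected:
            kept = []
            for dep_id, binding in self.graph.dependencies_of(tid):
                if dep_id in self.selected:
                    kept.append((dep_id, binding))
                else:
                    log.info(
                        "task %s: dependency %s is outside the selection; "
                        "assuming its outputs are present", tid, dep_id,
                    )
            self.deps[tid] = kept

        bad = {
            u for u in completed
            if u.split("[", 1)[0] not in self.tasks or not _STATE_LINE_RE.match(u)
        }
        if bad:
            raise StateFileError(
                "state entries do not match this pipeline: " + ", ".join(sorted(bad))
            )

        self.task_status = {tid: _WAITING for tid in self.selected}
        self.units: dict = {}        # unit_id -> UnitRecord
        self.task_units: dict = {}   # task_id -> [unit_id]
        self.events: list = []
        self.running: set = set()
        self.fatal: Optional[BaseException] = None
        self.cond = threading.Condition()
        self.state_fh = None

    # ---- locked helpers -------------------------------------------------

    def _event(self, unit_id, event):
        self.events.append((time.monotonic(), unit_id, event))

    def _record_completed_line(self, line):
        if self.state_fh:
            self.state_fh.write(line + "\n")
            self.state_fh.flush()

    def _satisfied(self, dep_id, binding):
        st = self.task_status[dep_id]
        if st in (DONE, SKIPPED):
            return True
        if binding and st == _EXPANDED:
            return True  # per-unit gating takes over
        return False

    def _deps_blocked(self, tid):
        """A dep failed or aborted -> this task can never run."""
        return any(
            self.task_status[d] in (FAILED, ABORTED) for d, _ in self.deps[tid]
        )

    def _abort_task(self, tid):
        if self.task_status[tid] in (DONE, FAILED, ABORTED, SKIPPED):
            return
        self.task_status[tid] = ABORTED
        if tid in self.task_units:
            for uid in self.task_units[tid]:
                rec = self.units[uid]
                if rec.state == PENDING:
                    rec.state = ABORTED
                    self._event(uid, ABORTED)
        elif not isinstance(self.tasks[tid], ForeachSpec):
            # never expanded: still give the report a record of the lost unit
            unit = IterationUnit(task_id=tid)
            self.units[unit.unit_id] = UnitRecord(unit=unit, state=ABORTED)
            self.task_units[tid] = [unit.unit_id]
            self._event(tid, ABORTED)
        else:
            self._event(tid, ABORTED)  # foreach aborted before item resolution
        self._propagate_failure(tid)

    def _propagate_failure(self, tid):
        """Abort every in-selection dependent reachable through non-binding
        edges (binding dependents abort per unit through eligibility)."""
        for dep_tid in self.selected:
            for d, binding in self.deps[dep_tid]:
                if d == tid and not binding:
                    self._abort_task(dep_tid)
                elif d == tid and binding and self.task_status[tid] in (FAILED, ABORTED) \
                        and self.task_status[dep_tid] == _WAITING:
                    # bound loop that never expanded cannot pair up items
                    self._abort_task(dep_tid)

    def _maybe_finish_task(self, tid):
        if self.task_status[tid] != _EXPANDED:
            return
        states = [self.units[u].state for u in self.task_units[tid]]
        if any(s in (PENDING, RUNNING) for s in states):
            return
        if all(s == DONE for s in states):
            self.task_status[tid] = DONE
        else:
            self.task_status[tid] = FAILED
            self._propagate_failure(tid)

    def _unit_eligible(self, rec: UnitRecord):
        """For a pending unit: ready / blocked / aborted."""
        tid = rec.unit.task_id
        for dep_id, binding in self.deps[tid]:
            st = self.task_status[dep_id]
            if st in (DONE, SKIPPED):
                continue
            if not binding:
                if st in (FAILED, ABORTED):
                    return "aborted"
                return "blocked"
            # binding edge: pair item-wise with the upstream loop's unit
            if st in (FAILED, ABORTED):
                dep_units = self.task_units.get(dep_id, [])
                i = rec.unit.item_index
                if i is not None and i < len(dep_units):
                    dst = self.units[dep_units[i]].state
                    if dst == DONE:
                        continue
                return "aborted"
            if st != _EXPANDED:
                return "blocked"
            i = rec.unit.item_index
            dep_units = self.task_units[dep_id]
            if i is None or i >= len(dep_units):
                return "blocked"
            dst = self.units[dep_units[i]].state
            if dst == DONE:
                continue
            if dst in (FAILED, ABORTED):
                return "aborted"
            return "blocked"
        return "ready"

    def _ready_units(self):
        ready = []
        for uid, rec in self.units.items():
            if rec.state != PENDING or uid in self.running:
                continue
            verdict = self._unit_eligible(rec)
            if verdict == "ready":
                ready.append(rec)
            elif verdict == "aborted":
                rec.state = ABORTED
                self._event(uid, ABORTED)
                self._maybe_finish_task(rec.unit.task_id)
        ready.sort(key=lambda r: (self.order[r.unit.task_id], r.unit.item_index or 0))
        return ready

    def _collect_preparable(self):
        """Tasks whose obligations allow guard evaluation / expansion now."""
        out = []
        for tid in sorted(self.selected, key=self.order.get):
            if self.task_status[tid] != _WAITING:
                continue
            if self._deps_blocked(tid):
                self._abort_task(tid)
                continue
            if all(self._satisfied(d, b) for d, b in self.deps[tid]):
                self.task_status[tid] = _PREPARING
                out.append(tid)
        return out

    def _finished(self):
        return all(
            st in (DONE, FAILED, ABORTED, SKIPPED) for st in self.task_status.values()
        ) and not self.running

    # ---- unlocked task preparation (guards, item resolution) ------------

    def _prepare_task(self, tid):
        task = self.tasks[tid]
        if tid in self.completed:
            # whole task recorded as completed in a previous run (plain task
            # done, foreach skipped or empty): satisfied, nothing to execute
            with self.cond:
                self.task_status[tid] = DONE
                self._event(tid, "resumed")
                self._record_completed_line(tid)
                self.cond.notify_all()
            return
        try:
            base_env = build_environment(
                IterationUnit(task_id=tid), self.doc, self.params,
                self.settings.working_dir,
            )
            if task.if_guard is not None:
                keep = evaluate_guard(
                    task, base_env, self.settings.working_dir, self.settings.shell
                )
                if not keep:
                    with self.cond:
                        self.task_status[tid] = SKIPPED
                        self._event(tid, SKIPPED)
                        self._record_completed_line(tid)
                        self.cond.notify_all()
                    return
            if isinstance(task, ForeachSpec):
                items = resolve_items(
                    task, self.params, self.settings.working_dir,
                    env=base_env, shell=self.settings.shell,
                )
                units = expand_foreach(task, items)
            else:
                units = [IterationUnit(task_id=tid)]
        except (GuardError, ItemResolutionError, DagshError) as exc:
            if isinstance(exc, (GuardError, ItemResolutionError)):
                log.error("%s", exc)
                with self.cond:
                    self.task_status[tid] = FAILED
                    self.task_units[tid] = []
                    self._event(tid, FAILED)
                    self._propagate_failure(tid)
                    self.cond.notify_all()
                return
            with self.cond:
                self.fatal = exc
                self.cond.notify_all()
            return

        with self.cond:
            if isinstance(task, ForeachSpec):
                for dep_id, binding in self.deps[tid]:
                    if binding and self.task_status[dep_id] in (_EXPANDED, DONE, FAILED):
                        dep_units = self.task_units.get(dep_id)
                        if dep_units is not None and len(dep_units) != len(units):
                            self.fatal = BindingCardinalityError(
                                f"foreach '{tid}' resolved {len(units)} item(s) but "
                                f"its bound dependency '{dep_id}' resolved "
                                f"{len(dep_units)}; bound loops must iterate over "
                                "the same collection"
                            )
                            self.cond.notify_all()
                            return
            self.task_units[tid] = []
            for unit in units:
                rec = UnitRecord(unit=unit)
                if unit.unit_id in self.completed or tid in self.completed:
                    rec.state = DONE
                    self._event(unit.unit_id, "resumed")
                self.units[unit.unit_id] = rec
                self.task_units[tid].append(unit.unit_id)
            self.task_status[tid] = _EXPANDED
            if not units:
                self.task_status[tid] = DONE  # empty loop completes immediately
                self._record_completed_line(tid)
            else:
                self._maybe_finish_task(tid)
            self.cond.notify_all()

    # ---- worker ----------------------------------------------------------

    def _execute_unit(self, rec: UnitRecord):
        unit = rec.unit
        task = self.tasks[unit.task_id]
        try:
            env = build_environment(
                unit, self.doc, self.params, self.settings.working_dir
            )
            runner = execution.runner_for_task(self.settings.runners, unit.task_id)
            if runner is not None:
                result = execution.run_with_runner(
                    runner, unit, task.code, env,
                    self.settings.working_dir, self.settings.shell,
                )
            else:
                result = execution.run_script(
                    unit, task.code, env, task.interpreter,
                    self.settings.working_dir, self.settings.shell,
                )
        except DagshError as exc:
            with self.cond:
                rec.state = FAILED
                rec.end = time.monotonic()
                self._event(unit.unit_id, FAILED)
                self.running.discard(unit.unit_id)
                log.error("%s", exc)
                self._maybe_finish_task(unit.task_id)
                self.cond.notify_all()
            return
        with self.cond:
            rec.end = time.monotonic()
            rec.exit_status = result.exit_status
            rec.state = DONE if result.ok else FAILED
            self._event(unit.unit_id, rec.state)
            self.running.discard(unit.unit_id)
            execution.write_logs(result, unit, self.settings)
            if self.settings.show_std_outs:
                import sys

                if result.stdout_text:
                    sys.stdout.write(result.stdout_text)
                if result.stderr_text:
                    sys.stderr.write(result.stderr_text)
            if rec.state == DONE:
                self._record_completed_line(unit.unit_id)
            else:
                log.error(
                    "unit %s failed with exit status %s",
                    unit.unit_id, result.exit_status,
                )
            self._maybe_finish_task(unit.task_id)
            self.cond.notify_all()

    # ---- main loop -------------------------------------------------------

    def execute(self) -> ExecutionReport:
        execution.prepare_log_dir(
            self.settings,
            [
                tid for tid in sorted(self.selected, key=self.order.get)
                if not any(
                    u == tid or u.startswith(tid + "[") for u in self.completed
                )
            ],
        )
        state_path = default_state_path(self.settings)
        state_path.parent.mkdir(parents=True, exist_ok=True)
        mode = "a" if self.completed else "w"
        self.state_fh = open(state_path, mode)
        if not self.settings.quiet:
            log.info(
                "running %d task(s), up to %d in parallel",
                len(self.selected), self.settings.max_parallel,
            )
        try:
            with ThreadPoolExecutor(
                max_workers=self.settings.max_parallel
            ) as pool:
                while True:
                    with self.cond:
                        if self.fatal is not None:
                            break
                        to_prepare = self._collect_preparable()
                        dispatched = []
                        if not to_prepare:
                            for rec in self._ready_units():
                                if len(self.running) >= self.settings.max_parallel:
                                    break
                                rec.state = RUNNING
                                rec.start = time.monotonic()
                                self._event(rec.unit_id, "start")
                                self.running.add(rec.unit_id)
                                dispatched.append(rec)
                            if not dispatched:
                                if self._finished():
                                    break
                                if not self.running:
                                    # nothing runnable and nothing in flight:
                                    # remaining tasks can never proceed
                                    for tid, st in list(self.task_status.items()):
                                        if st not in (DONE, FAILED, ABORTED, SKIPPED):
                                            self._abort_task(tid)
                                    break
                                self.cond.wait()
                                continue
                    for rec in dispatched:
                        pool.submit(self._execute_unit, rec)
                    for tid in to_prepare:
                        self._prepare_task(tid)
                # drain in-flight work before reporting / raising
                with self.cond:
                    while self.running:
                        self.cond.wait()
                    if self.fatal is not None:
                        for tid, st in list(self.task_status.items()):
                            if st not in (DONE, FAILED, ABORTED, SKIPPED):
                                self._abort_task(tid)
        finally:
            self.state_fh.close()
            self.state_fh = None
        if self.fatal is not None:
            raise self.fatal
        report = ExecutionReport(
            units=self.units,
            events=self.events,
            task_states=dict(self.task_status),
            success=all(
                st in (DONE, SKIPPED) for st in self.task_status.values()
            ),
        )
        if not self.settings.quiet:
            done = len(report.done_unit_ids())
            log.info(
                "pipeline %s: %d unit(s) done",
                "succeeded" if report.success else "FAILED", done,
            )
        return report
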