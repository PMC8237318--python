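"""Task execution: environment materialisation, shell invocation, logging.

Parameters reach task scripts exclusively through environment variables, so
any language that can read its process environment can be used for task code;
the engine never rewrites or substitutes into the script text.  A task's
environment contains exactly:

* its declared parameters, with value precedence command line > params file >
  declared default;
* every global parameter;
* for an iteration unit, the foreach item variable;
* the engine-provided variables ``task_id`` and ``working_dir``.

Nothing else — an undeclared, non-global parameter is invisible to the task
(its appearance in the code is what the ``param-not-accessible`` validation
warning flags).

Three execution paths share the same contract: the system shell runs the code
directly; a declared *interpreter* (a shell fragment) runs with the code in
the ``task_code`` environment variable and delegates to another language; a
*runner* (an execution-time shell script from a runners file) does the same
but is chosen per task at launch time, e.g. to submit to a cluster queue or a
container instead of running locally.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional

from lxml import etree

from .errors import (
    LogDirError,
    MissingParameterError,
    RunnerConfigError,
)
from .model import ForeachSpec, PipelineDoc, TaskDef

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .scheduler import IterationUnit, RunSettings

__all__ = [
    "TaskResult",
    "RunnerDef",
    "find_shell",
    "build_environment",
    "run_shell_text",
    "run_script",
    "run_with_runner",
    "parse_runners_file",
    "runner_for_task",
    "prepare_log_dir",
    "write_logs",
]

#: dict mapping variable name -> value; see module docstring for the contract.
TaskEnvironment = dict


@dataclass(frozen=True)
class RunnerDef:
    """An execution-time override script bound to a set of task identifiers."""

    task_ids: frozenset
    script: str


@dataclass
class TaskResult:
    unit_id: str
    exit_status: int
    stdout_text: str
    stderr_text: str
    duration: float
    env: dict = field(default_factory=dict)  # the TaskEnvironment used

    @property
    def ok(self) -> bool:
        return self.exit_status == 0


def find_shell(override: Optional[str] = None) -> str:
    """Locate the system shell (bash preferred, sh fallback) on the search path."""
    if override:
        return override
    for name in ("bash", "sh"):
        path = shutil.which(name)
        if path:
            return path
    raise FileNotFoundError("no usable shell (bash/sh) found on PATH")


def resolve_param_values(
    doc: PipelineDoc, cli_args: Mapping, file_values: Mapping
) -> dict:
    """Merge parameter sources by precedence: command line > file > default."""
    merged: dict = {}
    for p in doc.params:
        if p.default_value is not None:
            merged[p.name] = p.default_value
    merged.update(file_values)
    merged.update(cli_args)
    return merged


def build_environment(
    unit: "IterationUnit",
    doc: PipelineDoc,
    param_values: Mapping,
    working_dir: str = ".",
) -> TaskEnvironment:
    """Materialise the environment for one iteration unit.

    ``param_values`` is the already-merged mapping (see
    :func:`resolve_param_values`).  Raises :class:`MissingParameterError` if a
    declared parameter of the task has no value from any source.
    """
    task = doc.task_map()[unit.task_id]
    env: TaskEnvironment = {}
    wanted = set(task.params) | doc.global_param_names()
    for name in sorted(wanted):
        if name not in param_values:
            raise MissingParameterError(unit.task_id, name)
        env[name] = str(param_values[name])
    if unit.item_value is not None and isinstance(task, ForeachSpec):
        env[task.item_var] = unit.item_value
    env["task_id"] = task.id
    env["working_dir"] = str(Path(working_dir).resolve())
    return env


def run_shell_text(
    script: str,
    env: Mapping,
    working_dir: str = ".",
    shell: Optional[str] = None,
    extra_env: Optional[Mapping] = None,
) -> tuple[int, str, str, float]:
    """Run a shell script text; returns (exit_status, stdout, stderr, duration).

    The task environment is overlaid on the engine's own process environment
    so that PATH et al. remain available to the script.
    """
    full_env = dict(os.environ)
    full_env.update({k: str(v) for k, v in env.items()})
    if extra_env:
        full_env.update({k: str(v) for k, v in extra_env.items()})
    t0 = time.monotonic()
    proc = subprocess.run(
        [find_shell(shell), "-c", script],
        env=full_env,
        cwd=working_dir,
        capture_output=True,
        text=True,
    )
    return proc.returncode, proc.stdout, proc.stderr, time.monotonic() - t0


def run_script(
    unit: "IterationUnit",
    code: str,
    env: TaskEnvironment,
    interpreter: Optional[str] = None,
    working_dir: str = ".",
    shell: Optional[str] = None,
) -> TaskResult:
    """Execute a unit's code via the system shell or its declared interpreter.

    On the interpreter path the interpreter fragment itself is what the shell
    runs, with the task's code exposed byte-identical in ``task_code``.  A
    nonzero exit status yields a failed :class:`TaskResult`, not an exception.
    """
    if interpreter is not None:
        rc, out, err, dt = run_shell_text(
            interpreter, env, working_dir, shell, extra_env={"task_code": code}
        )
    else:
        rc, out, err, dt = run_shell_text(code, env, working_dir, shell)
    return TaskResult(unit.unit_id, rc, out, err, dt, env=dict(env))


def run_with_runner(
    runner: RunnerDef,
    unit: "IterationUnit",
    code: str,
    env: TaskEnvironment,
    working_dir: str = ".",
    shell: Optional[str] = None,
) -> TaskResult:
    """Execute a unit through a runner script instead of the local shell path.

    The runner runs once per unit (so the item variable is bound for foreach
    iterations) with the task's code in ``task_code``; the unit's outcome is
    the runner's exit status.
    """
    assert unit.task_id in runner.task_ids
    rc, out, err, dt = run_shell_text(
        runner.script, env, working_dir, shell, extra_env={"task_code": code}
    )
    return TaskResult(unit.unit_id, rc, out, err, dt, env=dict(env))


def parse_runners_file(
    xml_text: str, doc: Optional[PipelineDoc] = None
) -> list[RunnerDef]:
    """Parse a runners XML file: ``<runners><runner tasks="a b">script</runner></runners>``.

    When ``doc`` is given, every referenced task id must exist in the
    pipeline; violations raise :class:`RunnerConfigError` before any unit runs.
    """
    try:
        root = etree.fromstring(
            xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
        )
    except etree.XMLSyntaxError as exc:
        raise RunnerConfigError(f"malformed runners file: {exc}") from exc
    if root.tag != "runners":
        raise RunnerConfigError(f"expected <runners> root, got <{root.tag}>")
    runners: list[RunnerDef] = []
    for el in root:
        if el.tag is etree.Comment:
            continue
        if el.tag != "runner":
            raise RunnerConfigError(f"unexpected element <{el.tag}> in runners file")
        ids = frozenset((el.get("tasks") or "").split())
        if not ids:
            raise RunnerConfigError("runner with empty 'tasks' attribute")
        runners.append(RunnerDef(task_ids=ids, script=el.text or ""))
    if doc is not None:
        known = set(doc.task_map())
        for r in runners:
            missing = sorted(r.task_ids - known)
            if missing:
                raise RunnerConfigError(
                    "runner references unknown task(s): " + ", ".join(missing)
                )
    return runners


def runner_for_task(runners, task_id: str) -> Optional[RunnerDef]:
    """First runner (file order) claiming the task, or None for local execution."""
    for r in runners:
        if task_id in r.task_ids:
            return r
    return None


def _log_admitted(task_id: str, settings: "RunSettings") -> bool:
    if settings.log_dir is None:
        return False
    if settings.log_only and task_id not in settings.log_only:
        return False
    if settings.log_exclude and task_id in settings.log_exclude:
        return False
    return True


def _log_paths(task_id: str, log_dir) -> tuple[Path, Path, Path]:
    d = Path(log_dir)
    return (
        d / f"{task_id}.out.log",
        d / f"{task_id}.err.log",
        d / f"{task_id}.params",
    )


def prepare_log_dir(settings: "RunSettings", task_ids) -> None:
    """Create the log directory and truncate stale logs for admitted tasks.

    Raises :class:`LogDirError` if the directory cannot be created/written —
    checked before the run starts so a bad path never wastes an execution.
    """
    if settings.log_dir is None:
        return
    d = Path(settings.log_dir)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".dagsh-writable"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise LogDirError(f"log directory {d} is not writable: {exc}") from exc
    for task_id in task_ids:
        if _log_admitted(task_id, settings):
            for p in _log_paths(task_id, d):
                p.unlink(missing_ok=True)


def write_logs(
    result: TaskResult, unit: "IterationUnit", settings: "RunSettings"
) -> list[Path]:
    """Persist one unit's outputs as the three per-task log files.

    With a log directory set and the task admitted by the
    ``--log-only-task`` / ``--no-log-task`` filters, exactly three files are
    (created and) appended to: ``<task>.out.log``, ``<task>.err.log`` and
    ``<task>.params`` — the last holding ``name=value`` lines of the unit's
    environment, sorted by name.  Iteration units of one foreach append to
    the same three task-prefixed files in unit order.  Without ``--logs``
    nothing is written.
    """
    if not _log_admitted(unit.task_id, settings):
        return []
    out_p, err_p, params_p = _log_paths(unit.task_id, settings.log_dir)
    with open(out_p, "a") as fh:
        fh.write(result.stdout_text)
    with open(err_p, "a") as fh:
        fh.write(result.stderr_text)
    with open(params_p, "a") as fh:
        for name in sorted(result.env):
            fh.write(f"{name}={result.env[name]}\n")
    return [out_p, err_p, params_p]
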