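"""Exception hierarchy for the engine.

All engine failures derive from :class:`DagshError` so the CLI can map any of
them to a message on stderr and a nonzero exit status.  Task-script failures
are *not* exceptions: a nonzero exit status is ordinary data carried in a
``TaskResult`` / ``ExecutionReport``.
"""


class DagshError(Exception):
    """Base class for all engine errors."""


class PipelineParseError(DagshError):
    """Malformed pipeline XML (syntax error, carries line/column when known)."""


class PipelineSchemaError(DagshError):
    """Well-formed XML that violates the pipeline schema."""


class ParamsFileError(DagshError):
    """A parameters file line that is neither blank, comment nor KEY=VALUE."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ValidationFailedError(DagshError):
    """Execution was requested on a pipeline whose validation produced blocking issues."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "pipeline validation failed: " + "; ".join(str(i) for i in self.issues)
        )


class CycleError(DagshError):
    """The dependency graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("dependency cycle: " + " -> ".join(self.cycle + self.cycle[:1]))


class BindingError(DagshError):
    """A '*' iteration-binding mark on a dependency whose endpoints are not both foreach tasks."""


class BindingCardinalityError(DagshError):
    """Two iteration-bound foreach loops resolved item lists of different lengths."""


class SelectionError(DagshError):
    """A sub-pipeline query names an unknown task or mixes incompatible modifiers."""


class ItemResolutionError(DagshError):
    """A foreach item source could not be evaluated (bad directory, failing command...)."""


class GuardError(DagshError):
    """An ``if`` guard command was not executable (as opposed to exiting nonzero)."""


class MissingParameterError(DagshError):
    """A task declares a parameter that has no value from any source."""

    def __init__(self, task_id: str, param: str):
        super().__init__(
            f"task '{task_id}' requires parameter '{param}' but no value was supplied "
            "(command line, params file or default)"
        )
        self.task_id = task_id
        self.param = param


class RunnerConfigError(DagshError):
    """Bad runners file: unreadable, malformed, or referencing unknown tasks."""


class StateFileError(DagshError):
    """Corrupt or mismatched resume-state file."""


class LogDirError(DagshError):
    """The requested log directory cannot be created or written."""


class UsageError(DagshError):
    """Bad command-line invocation."""
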