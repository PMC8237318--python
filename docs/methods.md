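# Methods

## The execution model

A pipeline is a set of tasks with a strict partial order given by `after`
declarations. The engine builds the dependency DAG up front (cycles and
malformed `*` marks are rejected before anything runs), optionally restricts
it to a sub-pipeline, and then schedules *iteration units*: a plain task is
one unit; a `foreach` task contributes one unit per item of its resolved
collection. Scheduling is reactive rather than phase-based — after start-up
and after every unit completion the engine re-examines eligibility and
dispatches every ready unit to a thread pool bounded by `--num-tasks`
(default 6). Worker threads only supervise subprocesses (each unit is a
`bash -c` invocation), so the bound limits *task* concurrency, not engine
CPU; tasks that are internally parallel multiply beyond it, which is the
pipeline author's concern.

Obligations are edge-typed. A plain edge A→B holds every unit of B until all
units of A are done. An iteration-binding edge A→*B (both endpoints foreach)
releases B[i] when A[i] is done — pipelining consecutive per-sample loops.
A task skipped by its `if` guard counts as satisfied for dependents; this
follows the shell convention (guard exit 0 = run, nonzero = skip) with one
exception: exit 126/127 (not executable / not found) marks the task failed
rather than silently skipped, since that is almost always an authoring error.

### Dynamic behaviour and its consequences

`command` and `files_in_dir` item sources are evaluated only when the loop
becomes ready, so the iteration count can depend on upstream outputs. The
price is that equal-cardinality enforcement for bound loops can only happen
when the *dependent* loop expands — by then the upstream loop has started.
The engine therefore checks cardinality at expansion time, before the
dependent loop starts any unit, and raises a fatal error on mismatch (fail
fast beats silent index mispairing). Guards on foreach tasks apply once to
the whole loop and run before item resolution; per-item guards would belong
in the task code itself.

### Failure and resume

On a unit failure no new dependent unit starts: non-binding dependents are
aborted transitively; binding dependents lose only the matching index and
drain their remaining items. Independent branches run to completion. This
drain policy maximises the work available to `resume`; the alternative
(global stop on first failure) loses otherwise-finished branches. Completed
unit ids (plus guard-skipped and empty-expanded task ids) are appended to a
plain-text state file — one id per line, inspectable and diff-friendly —
as they finish, so a crash loses nothing. `resume` reads the file, treats
recorded ids as satisfied, and re-runs the rest. Resume granularity is the
iteration unit, not the whole loop. Item sources are re-evaluated on resume;
if a command source yields a different collection than the failed run, the
recorded indices refer to the new collection — resuming a pipeline whose
item sources are not stable across runs is the author's risk. No cleanup of
a failed unit's partial outputs is attempted.

### Determinism

Among simultaneously ready units the engine prefers task document order,
then item index. With `--num-tasks 1` this makes the start order fully
deterministic and a topological order of the selected subgraph; with more
workers the event log remains totally ordered (a single lock serialises
bookkeeping) but interleaving depends on task durations.

## The pipeline dialect

The paper-style sections `params`/`tasks`/`metadata` are fixed concretely as
an XSD (shipped with the package, enforced at parse time by lxml):
`<param name global? defaultValue?>description</param>`;
`<task id params? after? interpreter? if?>code</task>`;
`<foreach id of in as ...>` where `of` names the item-source kind, `in` its
argument and `as` the item environment variable. `params`/`after` attribute
values are whitespace/comma-separated identifier lists. Identifiers are
shell-safe (`[A-Za-z_][A-Za-z0-9_]*`) because every one of them becomes an
environment variable name. Ranges are written `start..end`, inclusive.
Parameter files are `KEY=VALUE` lines with `#` comments; duplicate keys:
last wins (conventional for config overlays). Value precedence is command
line > params file > declared default.

Validation is data, not control flow: `validate()` returns ordered issues.
The one warning class — a declared parameter appearing as a `$name`/`${name}`
token in code the task cannot see — uses shell-expansion token rules
(`$genomes` does not match `genome`; `${genome}x` does), which bounds false
positives without parsing the script language. `--abort-if-warnings`
upgrades warnings to a zero-execution abort.

## Environment contract

A task sees exactly: its declared parameters, all global parameters, the
item variable (iteration units), and the engine variables `task_id` and
`working_dir` — overlaid on the engine's own process environment (PATH must
survive). `task_code` is added only on the interpreter and runner paths,
where the script to run *is* the interpreter/runner text and the task's code
is data. Runner scripts run once per unit, so cluster-submission or
container runners see the same per-iteration bindings a local run would.
Log files follow the three-file contract `<task>.out.log`, `<task>.err.log`,
`<task>.params` (sorted `name=value` lines); foreach iterations append to
their task's files in unit order, preserving the naming contract without
inventing per-item files.

## Sub-pipeline semantics

`--from`/`--after` take descendant closures (seed-inclusive/exclusive),
`--until`/`--before` ancestor closures; multiple ids per modifier union
before the downstream and upstream closures intersect. On a chain this gives
exactly the path between the endpoints; on general DAGs the intersection
rule retains nodes lying in both closures even when not on a seed-to-seed
path — the simplest rule consistent with the chain behaviour. A selection
may exclude a dependency of an included task: the dependency is assumed
satisfied (its outputs presumed present) and a notice is logged, since
re-adding it would defeat partial execution.

## What the generators emulate — and what they don't

`minimal_pipeline` reproduces the canonical two-task hello/goodbye shape
(shell task + interpreter task via `task_code`; the interpreter language is
AWK, chosen because a POSIX AWK is guaranteed wherever a POSIX shell is).
`foreach_pipeline` is the two-loop per-sample pattern over the four samples
case-1/case-2/control-1/control-2, with per-sample sleeps (default: last
preprocess iteration 0.4 s, the rest 50 ms) sized so that binding produces
observable loop overlap while keeping ordering assertions far from timer
resolution. `random_dag_pipeline` draws forward-only edges, acyclic by
construction, and ships its edge list for oracle checks; its task bodies are
no-ops, so randomized suites measure scheduling, not script behaviour.

None of the generators emulate real tool invocations, long-running jobs,
filesystem contention or cluster latency. Passing tests therefore establish
the *ordering, selection, environment and logging contracts* — not
performance or robustness under external-tool failure modes, which runner
scripts deliberately leave outside the engine.

Test and acceptance problem sizes — 200 randomized DAGs of 2–25 tasks for
scheduling and selection checks, 8 fault-injection trials for resume — were
chosen so the whole randomized battery executes thousands of real `bash`
subprocesses in a few seconds while covering wide, deep and sparse graph
shapes; violation counts are exact (asserted zero), not sampled estimates
with tolerance.

## Numerical and edge-case choices

* Timestamps are monotonic-clock floats; interval assertions compare only
  within one process, so wall-clock jumps cannot produce false orderings.
* Empty foreach collections complete immediately as done (zero units), and
  `list`/`param_values` sources drop empty tokens after trimming — an empty
  string means "no items", not one empty item. `command` sources keep
  interior empty lines and drop only the trailing newline's empty remnant.
* A reversed range (`5..2`) yields zero items rather than an error, matching
  empty-collection semantics.
* Code bodies round-trip byte-for-byte through CDATA; a body containing the
  CDATA terminator `]]>` falls back to entity escaping (XML 1.0 cannot carry
  C0 control characters other than tab/newline in any encoding — the only
  representability limit).
* Task-level events (guard skips, aborts of never-expanded tasks) enter the
  event log under the task id, so the log remains a single total order.

## Known limitations

Parallelism is bounded local concurrency plus whatever runners do
externally; there is no distributed scheduling or work stealing. The XML
dialect's attribute inventory beyond the core names is this package's own
(documented above), not a compatibility claim against any other engine's
files. Stdout/stderr of a unit are captured in memory before logging, which
is the wrong trade-off for tasks emitting gigabytes — redirect inside the
task script instead.
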