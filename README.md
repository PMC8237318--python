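# dagsh

An XML-defined shell pipeline engine for researchers who write their analyses
as shell scripts and want workflow-engine behaviour — dependency-aware
scheduling, bounded parallelism, per-task logging, partial execution and
resume-from-failure — without learning a new programming language.

A pipeline is one XML file declaring **parameters**, **tasks** and
**metadata**. Task bodies live in CDATA blocks and are executed byte-for-byte
by the system shell (or by a declared interpreter for other languages); the
engine never rewrites task code. Parameter values reach scripts exclusively
through environment variables (`$name`), so any language that can read its
environment can be a task language.

The engine computes the DAG of task dependencies and reacts: right after
starting, and whenever a unit finishes, every unit whose dependencies are
complete is dispatched to a worker pool of parameterizable size
(`--num-tasks`). `foreach` loop tasks expand into one *iteration unit* per
item of a resolved collection (a comma list, an integer range, the files of a
directory, a parameter's comma-separated value, or the output lines of a
command evaluated just before the loop runs). Two consecutive loops over the
same collection can be *iteration-bound* by prefixing the dependency with `*`
(`after="*preprocess"`): iteration *i* of the second loop starts as soon as
iteration *i* of the first finishes, instead of waiting for the whole loop.

Execution can be tailored without touching the pipeline: *runners* are shell
scripts, declared in a separate XML file, that replace local execution for
assigned tasks (the task's code arrives in the `task_code` environment
variable — the same contract interpreters use), which is how tasks are routed
to a cluster submission command or a container. Sub-pipelines are selected
with `--from/--after/--until/--before/--single-task`, and `resume` re-runs
only the units a previous execution did not complete.

## Worked example

```xml
<!-- pipeline.xml -->
<pipeline>
  <params>
    <param name="name">who to greet</param>
    <param name="output">file the lines are appended to</param>
  </params>
  <tasks>
    <task id="greetings" params="name output">
      <![CDATA[echo "Hello $name" >> "$output"]]></task>
    <task id="bye" params="name output" after="greetings"
          interpreter='awk "$task_code"'>
      <![CDATA[BEGIN { printf "Bye %s\n", ENVIRON["name"] >> ENVIRON["output"] }]]></task>
  </tasks>
</pipeline>
```

```
$ dagsh run --quiet -- name World output salutes.txt
$ cat salutes.txt
Hello World
Bye World
```

Two lines, in dependency order: `greetings` ran first as a plain shell
command; `bye` ran second, its AWK program handed to the interpreter via
`task_code`. With `--logs logdir/` the run would also leave exactly three
files per task: `greetings.out.log`, `greetings.err.log`, `greetings.params`
(and the same for `bye`). `dagsh export-graph` prints the DAG as Graphviz DOT
with foreach tasks drawn dashed and `*` edges labelled; `dagsh run --help`
prints help generated from the pipeline's own parameter and task
descriptions.

The same pipelines can be produced programmatically — see
`dagsh.fixtures.minimal_pipeline`, `foreach_pipeline` and
`random_dag_pipeline`, which the test suite uses throughout.

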