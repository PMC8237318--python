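"""Scheduling: item resolution, guards, ordering, binding, failure, resume."""

import random

import pytest

from dagsh import parse_pipeline, run
from dagsh.errors import (
    BindingCardinalityError,
    ItemResolutionError,
    StateFileError,
    ValidationFailedError,
)
from dagsh.fixtures import foreach_pipeline, random_dag_pipeline
from dagsh.model import DependencyRef, ForeachSpec, ParamDef, PipelineDoc, TaskDef
from dagsh.scheduler import (
    ExecutionReport,
    IterationUnit,
    RunSettings,
    default_state_path,
    evaluate_guard,
    expand_foreach,
    load_state,
    resolve_items,
    save_state,
)

from oracles import is_topological, max_concurrency, ordering_violations, start_order


def fe(id="f", kind="list", arg="", var="item", **kw):
    return ForeachSpec(id=id, source_kind=kind, source_arg=arg, item_var=var, **kw)


class TestResolveItems:
    def test_list_source_order_and_trim(self):
        items = resolve_items(fe(arg="case-1, case-2,control-1,control-2"), {})
        assert items == ["case-1", "case-2", "control-1", "control-2"]

    def test_range_inclusive(self):
        assert resolve_items(fe(kind="range", arg="1..4"), {}) == ["1", "2", "3", "4"]

    def test_command_lines(self, workdir):
        items = resolve_items(
            fe(kind="command", arg="printf 'A\\nB\\nC\\n'"), {}, str(workdir)
        )
        assert items == ["A", "B", "C"]

    def test_command_failure_raises(self, workdir):
        with pytest.raises(ItemResolutionError):
            resolve_items(fe(kind="command", arg="exit 9"), {}, str(workdir))

    def test_files_in_dir_sorted(self, workdir):
        for name in ("b.txt", "a.txt", "c.txt"):
            (workdir / name).write_text("")
        (workdir / "subdir").mkdir()
        items = resolve_items(fe(kind="files_in_dir", arg=str(workdir)), {})
        assert [p.rsplit("/", 1)[-1] for p in items] == ["a.txt", "b.txt", "c.txt"]

    def test_missing_dir_raises(self, workdir):
        with pytest.raises(ItemResolutionError):
            resolve_items(fe(kind="files_in_dir", arg=str(workdir / "nope")), {})

    def test_param_values_source(self):
        items = resolve_items(fe(kind="param_values", arg="samples"),
                              {"samples": "x, y,z"})
        assert items == ["x", "y", "z"]


class TestExpandForeach:
    def test_cardinality_and_indexes(self):
        units = expand_foreach(fe(var="sample"), ["a", "b", "c", "d"])
        assert [u.unit_id for u in units] == ["f[0]", "f[1]", "f[2]", "f[3]"]
        assert [u.item_value for u in units] == ["a", "b", "c", "d"]

    def test_empty_items(self):
        assert expand_foreach(fe(), []) == []

    def test_single_item(self):
        (unit,) = expand_foreach(fe(), ["x"])
        assert unit.unit_id == "f[0]" and unit.item_value == "x"


class TestEvaluateGuard:
    def test_guard_true_when_file_present(self, workdir):
        probe = workdir / "flag"
        probe.write_text("")
        task = TaskDef(id="t", if_guard=f'test -f "{probe}"')
        assert evaluate_guard(task, {}, str(workdir)) is True

    def test_guard_false(self, workdir):
        task = TaskDef(id="t", if_guard="false")
        assert evaluate_guard(task, {}, str(workdir)) is False

    def test_guard_sees_task_environment(self, workdir):
        task = TaskDef(id="t", if_guard='test "$mode" = go')
        assert evaluate_guard(task, {"mode": "go"}, str(workdir)) is True
        assert evaluate_guard(task, {"mode": "stop"}, str(workdir)) is False


def run_random_dag(n, edge_prob, seed, workdir, max_parallel):
    gen = random_dag_pipeline(n, edge_prob, seed)
    doc = parse_pipeline(gen.xml_text)
    report = run(doc, {}, RunSettings(working_dir=str(workdir),
                                      max_parallel=max_parallel))
    return gen, report


class TestRun:
    def test_serial_start_order_is_topological(self, workdir):
        gen, report = run_random_dag(15, 0.3, seed=11, workdir=workdir,
                                     max_parallel=1)
        assert report.success
        order = start_order(report.events)
        assert len(order) == 15
        edges = [(a, b) for a, b, _ in gen.expected_graph]
        assert is_topological(order, edges)

    def test_serial_order_is_reproducible(self, workdir):
        orders = []
        for _ in range(3):
            _, report = run_random_dag(12, 0.25, seed=3, workdir=workdir,
                                       max_parallel=1)
            orders.append(start_order(report.events))
        assert orders[0] == orders[1] == orders[2]

    def test_concurrency_bound_respected(self, workdir):
        gen, report = run_random_dag(12, 0.05, seed=21, workdir=workdir,
                                     max_parallel=3)
        assert report.success
        assert max_concurrency(report.events) <= 3

    def test_no_dependency_violations_in_parallel_run(self, workdir):
        gen, report = run_random_dag(18, 0.2, seed=5, workdir=workdir,
                                     max_parallel=4)
        edges = [(a, b) for a, b, _ in gen.expected_graph]
        assert ordering_violations(report.units, edges) == []

    def test_binding_allows_itemwise_overlap(self, workdir):
        doc = parse_pipeline(foreach_pipeline().xml_text)
        report = run(doc, {"workdir": str(workdir)},
                     RunSettings(working_dir=str(workdir), max_parallel=6))
        assert report.success
        units = report.units
        n = 4
        for i in range(n):
            assert units[f"analyze[{i}]"].start >= units[f"preprocess[{i}]"].end
        last_pre_end = max(units[f"preprocess[{i}]"].end for i in range(n))
        assert any(
            units[f"analyze[{i}]"].start < last_pre_end for i in range(n)
        ), "binding should let analyze overlap the preprocess loop"

    def test_without_binding_loops_are_sequential(self, workdir):
        doc = parse_pipeline(foreach_pipeline(binding=False).xml_text)
        report = run(doc, {"workdir": str(workdir)},
                     RunSettings(working_dir=str(workdir), max_parallel=6))
        assert report.success
        units = report.units
        last_pre_end = max(units[f"preprocess[{i}]"].end for i in range(4))
        for i in range(4):
            assert units[f"analyze[{i}]"].start >= last_pre_end

    def test_guard_skip_counts_as_satisfied(self, workdir):
        doc = PipelineDoc(
            tasks=(
                TaskDef(id="a", code=":", if_guard="false"),
                TaskDef(id="b", code=":", after=(DependencyRef("a"),)),
            )
        )
        report = run(doc, {}, RunSettings(working_dir=str(workdir)))
        assert report.success
        assert report.task_states["a"] == "skipped-by-guard"
        assert report.units["b"].state == "done"

    def test_failure_aborts_dependents_but_drains_independents(self, workdir):
        doc = PipelineDoc(
            tasks=(
                TaskDef(id="boom", code="exit 3"),
                TaskDef(id="child", code=":", after=(DependencyRef("boom"),)),
                TaskDef(id="bystander", code=":"),
            )
        )
        report = run(doc, {}, RunSettings(working_dir=str(workdir)))
        assert not report.success
        assert report.units["boom"].state == "failed"
        assert report.units["boom"].exit_status == 3
        assert report.units["child"].state == "aborted"
        assert report.units["child"].start is None
        assert report.units["bystander"].state == "done"

    def test_empty_foreach_completes_immediately(self, workdir):
        doc = PipelineDoc(
            params=(ParamDef("samples", default_value=""),),
            tasks=(
                fe(id="loop", kind="param_values", arg="samples", code=":"),
                TaskDef(id="next", code=":", after=(DependencyRef("loop"),)),
            ),
        )
        report = run(doc, {"samples": ""}, RunSettings(working_dir=str(workdir)))
        assert report.success
        assert report.task_states["loop"] == "done"
        assert report.units["next"].state == "done"

    def test_binding_cardinality_mismatch_raises(self, workdir):
        doc = PipelineDoc(
            tasks=(
                fe(id="pre", arg="a,b,c", var="s", code=":"),
                ForeachSpec(id="ana", source_kind="list", source_arg="a,b",
                            item_var="s", code=":",
                            after=(DependencyRef("pre", binding=True),)),
            )
        )
        with pytest.raises(BindingCardinalityError):
            run(doc, {}, RunSettings(working_dir=str(workdir)))

    def test_validation_errors_block_execution(self, workdir):
        doc = PipelineDoc(tasks=(TaskDef(id="a", after=(DependencyRef("ghost"),)),))
        with pytest.raises(ValidationFailedError):
            run(doc, {}, RunSettings(working_dir=str(workdir)))

    def test_abort_if_warnings_blocks_before_any_unit(self, workdir):
        marker = workdir / "ran"
        doc = PipelineDoc(
            params=(ParamDef("hidden"),),
            tasks=(TaskDef(id="t", code=f'touch "{marker}"; echo $hidden'),),
        )
        with pytest.raises(ValidationFailedError):
            run(doc, {"hidden": "x"},
                RunSettings(working_dir=str(workdir), abort_if_warnings=True))
        assert not marker.exists()

    def test_guard_skipped_single_task_selection(self, workdir):
        from dagsh.graph import SubgraphQuery

        doc = PipelineDoc(
            tasks=(TaskDef(id="a", code=":", if_guard="false"), TaskDef(id="b", code=":"))
        )
        report = run(
            doc, {},
            RunSettings(working_dir=str(workdir),
                        selection=SubgraphQuery(single_task="a")),
        )
        assert report.success
        assert report.done_unit_ids() == set()


class TestResume:
    def make_chain(self, workdir, fail_b=True):
        b_code = "exit 1" if fail_b else f'echo b >> "{workdir}/b.count"'
        return PipelineDoc(
            tasks=(
                TaskDef(id="a", code=f'echo a >> "{workdir}/a.count"'),
                TaskDef(id="b", code=b_code, after=(DependencyRef("a"),)),
                TaskDef(id="c", code=f'echo c >> "{workdir}/c.count"',
                        after=(DependencyRef("b"),)),
            )
        )

    def test_state_after_midchain_failure_lists_only_done(self, workdir):
        doc = self.make_chain(workdir, fail_b=True)
        settings = RunSettings(working_dir=str(workdir))
        report = run(doc, {}, settings)
        assert not report.success
        assert set(load_state(default_state_path(settings))) == {"a"}

    def test_resume_runs_only_remaining_units(self, workdir):
        settings = RunSettings(working_dir=str(workdir))
        run(self.make_chain(workdir, fail_b=True), {}, settings)
        fixed = self.make_chain(workdir, fail_b=False)
        completed = load_state(default_state_path(settings))
        report = run(fixed, {}, settings, completed=completed)
        assert report.success
        # a ran exactly once across both runs; b and c exactly once
        assert (workdir / "a.count").read_text() == "a\n"
        assert (workdir / "b.count").read_text() == "b\n"
        assert (workdir / "c.count").read_text() == "c\n"

    def test_resume_with_everything_done_runs_nothing(self, workdir):
        settings = RunSettings(working_dir=str(workdir))
        doc = self.make_chain(workdir, fail_b=False)
        run(doc, {}, settings)
        completed = load_state(default_state_path(settings))
        report = run(doc, {}, settings, completed=completed)
        assert report.success
        assert report.done_unit_ids() == set()  # everything resumed, not re-run
        assert (workdir / "a.count").read_text() == "a\n"

    def test_unknown_unit_in_state_is_mismatch_error(self, workdir):
        doc = self.make_chain(workdir)
        with pytest.raises(StateFileError):
            run(doc, {}, RunSettings(working_dir=str(workdir)),
                completed={"not_a_task"})

    def test_corrupt_state_file_refused(self, workdir):
        p = workdir / "state"
        p.write_text("ok\nbad unit id!\n")
        with pytest.raises(StateFileError):
            load_state(p)

    def test_save_and_load_round_trip(self, workdir):
        settings = RunSettings(working_dir=str(workdir))
        doc = self.make_chain(workdir, fail_b=False)
        report = run(doc, {}, settings)
        p = workdir / "explicit.state"
        save_state(report, p)
        assert load_state(p) == {"a", "b", "c"}

    def test_resume_idempotent_on_random_dags_with_fault_injection(self, tmp_path):
        """Run-to-failure + resume reaches the same done-set as a clean run,
        without re-executing completed units (marker-file counts)."""
        rng = random.Random(99)
        for trial in range(5):
            wd = tmp_path / f"trial{trial}"
            wd.mkdir()
            gen = random_dag_pipeline(rng.randint(4, 10), 0.3, seed=200 + trial)
            doc = parse_pipeline(gen.xml_text)
            ids = [t.id for t in doc.tasks]
            victim = rng.choice(ids)
            # every task counts its executions; the victim fails on first run
            tasks = []
            for t in doc.tasks:
                flag = wd / f"failed-once-{victim}"
                if t.id == victim:
                    code = (
                        f'echo x >> "{wd}/{t.id}.count"\n'
                        f'if [ ! -e "{flag}" ]; then touch "{flag}"; exit 1; fi\n'
                    )
                else:
                    code = f'echo x >> "{wd}/{t.id}.count"\n'
                tasks.append(TaskDef(id=t.id, code=code, after=t.after))
            doc = PipelineDoc(tasks=tuple(tasks))
            settings = RunSettings(working_dir=str(wd), max_parallel=2)
            first = run(doc, {}, settings)
            assert not first.success
            completed = load_state(default_state_path(settings))
            second = run(doc, {}, settings, completed=completed)
            assert second.success
            for tid in ids:
                count = (wd / f"{tid}.count").read_text().count("x")
                expected = 2 if tid == victim else 1
                assert count == expected, (tid, victim, count)
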