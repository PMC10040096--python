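"""Job state machine, local executor and shutdown monitor."""

import gzip
import json

import pytest

import batchblast as bb
from batchblast.orchestrator import StateMachineError, result_object_name
from batchblast.runs import MOCK_COMMAND
from conftest import sim_plan

E = bb.JobEvent


def drive(job, events):
    for ev in events:
        job = bb.next_state(job, ev)
    return job


class TestStateMachine:
    def test_three_generic_failures_then_success(self):
        job = drive(bb.Job("j", 0),
                    [E.start, E.failure_generic] * 3 + [E.start, E.success])
        assert job.state is bb.JobState.SUCCEEDED
        assert job.attempts == 4

    def test_fourth_failure_is_terminal(self):
        job = drive(bb.Job("j", 0), [E.start, E.failure_generic] * 4)
        assert job.state is bb.JobState.FAILED
        assert job.last_failure is bb.FailureKind.generic
        assert job.attempts == 4

    def test_oom_fails_fast_no_retry(self):
        job = drive(bb.Job("j", 0), [E.start, E.failure_oom])
        assert job.state is bb.JobState.FAILED
        assert job.last_failure is bb.FailureKind.oom
        assert job.attempts == 1
        with pytest.raises(StateMachineError):
            bb.next_state(job, E.start)

    def test_preempted_job_requeues(self):
        job = drive(bb.Job("j", 0), [E.start, E.preempted])
        assert job.state is bb.JobState.PENDING
        assert job.last_failure is bb.FailureKind.preempted

    @pytest.mark.parametrize("events", [
        [E.success],                       # success before start
        [E.start, E.start],                # double start
        [E.start, E.success, E.success],   # event after terminal
        [E.start, E.failure_oom, E.failure_generic],
    ])
    def test_illegal_transitions_raise(self, events):
        with pytest.raises(StateMachineError):
            drive(bb.Job("j", 0), events)

    def test_attempts_capped_at_four(self):
        with pytest.raises(ValueError):
            bb.Job("j", 0, attempts=5)


class TestMonitor:
    def _jobs(self, *states):
        return [bb.Job(f"j{i}", i, state=bb.JobState(s), attempts=1)
                for i, s in enumerate(states)]

    def test_all_succeeded_tears_down(self):
        jobs = self._jobs("SUCCEEDED", "SUCCEEDED")
        assert bb.monitor_step(jobs) is bb.MonitorAction.teardown
        # idempotent: a second tick decides the same
        assert bb.monitor_step(jobs) is bb.MonitorAction.teardown

    def test_any_failure_tears_down(self):
        assert bb.monitor_step(self._jobs("RUNNING", "FAILED")) is \
            bb.MonitorAction.teardown

    @pytest.mark.parametrize("states", [
        ("SUCCEEDED", "RUNNING"), ("PENDING", "PENDING"), ()])
    def test_otherwise_no_action(self, states):
        assert bb.monitor_step(self._jobs(*states)) is bb.MonitorAction.none


@pytest.fixture
def batch_setup(store):
    """Four written batches plus a plan, ready for run_local."""
    fa = bb.generate_fixture_fasta(16, (50, 100), seed=8)
    store.write_text("gs://bkt/q.fa", fa)
    recs = list(bb.read_sequences("gs://bkt/q.fa", store))
    split = bb.split_queries(recs, sum(r.length for r in recs) // 4)
    locs = bb.write_batches(split, "gs://bkt/batches", store)
    assert len(locs) == 4
    return store, locs, sim_plan(max_nodes=2), recs


def mock_command(behavior_path=None, state_dir=None):
    cmd = MOCK_COMMAND
    if behavior_path:
        cmd += f" --behavior {behavior_path} --state-dir {state_dir}"
    return cmd


class TestRunLocal:
    def test_all_succeed_results_complete(self, batch_setup):
        store, locs, plan, recs = batch_setup
        jobs = bb.make_jobs(4)
        res = bb.run_local(jobs, plan, mock_command(), locs, "gs://bkt/out",
                           db="db", workers=2, store=store)
        assert res.phase == "succeeded"
        assert sorted(store.list_objects("gs://bkt/out")) == \
            [result_object_name(i) for i in range(4)]
        # union of result lines covers every query exactly once
        ids = []
        for loc in res.result_locators:
            text = gzip.decompress(store.read_bytes(loc)).decode()
            ids += [line.split("\t")[0] for line in text.splitlines()]
        assert sorted(ids) == sorted(r.id for r in recs)

    def test_transient_failure_retried_to_success(self, batch_setup, tmp_path):
        store, locs, plan, _ = batch_setup
        behavior = tmp_path / "b.json"
        behavior.write_text(json.dumps({"2": {"fail_times": 2}}))
        res = bb.run_local(bb.make_jobs(4), plan,
                           mock_command(behavior, tmp_path / "state"),
                           locs, "gs://bkt/out", db="db", store=store)
        assert res.phase == "succeeded"
        assert {j.batch_index: j.attempts for j in res.jobs} == \
            {0: 1, 1: 1, 2: 3, 3: 1}

    def test_persistent_failure_fails_run_keeps_other_results(
            self, batch_setup, tmp_path):
        store, locs, plan, _ = batch_setup
        behavior = tmp_path / "b.json"
        behavior.write_text(json.dumps({"1": {"fail_times": 99}}))
        res = bb.run_local(bb.make_jobs(4), plan,
                           mock_command(behavior, tmp_path / "state"),
                           locs, "gs://bkt/out", db="db", store=store)
        assert res.phase == "failed"
        failed = [j for j in res.jobs if j.state is bb.JobState.FAILED]
        assert [j.batch_index for j in failed] == [1]
        assert failed[0].attempts == 4
        for idx in (0, 2, 3):
            assert store.exists(f"gs://bkt/out/{result_object_name(idx)}")

    def test_oom_fails_without_retry(self, batch_setup, tmp_path):
        store, locs, plan, _ = batch_setup
        behavior = tmp_path / "b.json"
        behavior.write_text(json.dumps({"0": {"oom": True}}))
        res = bb.run_local(bb.make_jobs(4), plan,
                           mock_command(behavior, tmp_path / "state"),
                           locs, "gs://bkt/out", db="db", store=store)
        oom = res.jobs[0]
        assert oom.state is bb.JobState.FAILED
        assert oom.last_failure is bb.FailureKind.oom
        assert oom.attempts == 1

    def test_missing_executable_fails_before_any_job(self, batch_setup):
        store, locs, plan, _ = batch_setup
        with pytest.raises(FileNotFoundError):
            bb.run_local(bb.make_jobs(4), plan,
                         "no-such-binary {batch} {db} {threads} {options}",
                         locs, "gs://bkt/out", db="db", store=store)
        assert store.list_objects("gs://bkt/out") == []


class TestMockExecutable:
    def test_output_one_line_per_query(self, tmp_path, capsys):
        from batchblast import mock_blast
        fa = tmp_path / "batch_003.fa"
        fa.write_text(">q1\nACGT\n>q2\nTTTT\n")
        assert mock_blast.run(["-query", str(fa)]) == 0
        lines = capsys.readouterr().out.splitlines()
        assert [l.split("\t")[:2] for l in lines] == \
            [["q1", "3"], ["q2", "3"]]

    def test_oom_spec_returns_reserved_code(self, tmp_path):
        from batchblast import mock_blast
        fa = tmp_path / "batch_000.fa"
        fa.write_text(">q\nAC\n")
        spec = tmp_path / "b.json"
        spec.write_text(json.dumps({"0": {"oom": True}}))
        assert mock_blast.run(["-query", str(fa), "--behavior", str(spec)]) \
            == bb.OOM_EXIT_CODE

    def test_fail_twice_then_succeed(self, tmp_path):
        from batchblast import mock_blast
        fa = tmp_path / "batch_001.fa"
        fa.write_text(">q\nAC\n")
        spec = tmp_path / "b.json"
        spec.write_text(json.dumps({"1": {"fail_times": 2}}))
        args = ["-query", str(fa), "--behavior", str(spec),
                "--state-dir", str(tmp_path / "s")]
        assert [mock_blast.run(args) for _ in range(3)] == [1, 1, 0]
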