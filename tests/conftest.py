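import pytest

import batchblast as bb


@pytest.fixture
def store(tmp_path):
    return bb.ObjectStore(tmp_path / "store")


@pytest.fixture(scope="session")
def catalog():
    return bb.load_catalog()


@pytest.fixture(scope="session")
def refseq_meta():
    """Metadata shaped like refseq_protein: 135 GB on disk, 96 GB cached."""
    return bb.DbMetadata(
        name="refseq_protein", molecule="protein",
        num_letters=55_000_000_000, num_sequences=250_000_000,
        total_bytes=135 * bb.GIB, bytes_to_cache=96 * bb.GIB)


@pytest.fixture(scope="session")
def small_meta():
    return bb.synth_metadata(10**7, "nucleotide", seed=11, name="smalldb")


def sim_plan(max_nodes=1, processes=1, preemptible=False, batch_len=100):
    """Minimal SearchPlan for simulator tests: one slot per process."""
    instance = bb.InstanceType(
        name="sim-16", provider="gcp", vcpus=16 * processes,
        ram_bytes=128 * bb.GIB, hourly_price=1.0, spot_discount=0.2)
    return bb.SearchPlan(
        instance=instance,
        thread_plan=bb.ThreadPlan(processes=processes, threads_per_process=16,
                                  mode="db_partition"),
        batch_len=batch_len, max_nodes=max_nodes, preemptible=preemptible,
        memory=bb.MemoryRequirement(bytes_needed=1, margin=1.0))


CONFIG_TEMPLATE = """\
[cloud-provider]
cloud = gcp
region = us-east4

[cluster]
num-nodes = {num_nodes}
use-preemptible = no

[blast]
program = blastp
db = {db}
queries = {queries}
results = {results}
batch-len = {batch_len}
"""


@pytest.fixture
def submitted_run(store):
    """A submitted (not yet executed) run over a 50-sequence fixture."""
    store.write_text("gs://bkt/queries.fa",
                     bb.generate_fixture_fasta(50, (100, 300), seed=42))
    meta = bb.synth_metadata(10**8, "protein", seed=1, name="fixturedb")
    store.write_text("gs://bkt/fixturedb.json", meta.render())
    config = bb.parse_config(CONFIG_TEMPLATE.format(
        num_nodes=2, db="gs://bkt/fixturedb", queries="gs://bkt/queries.fa",
        results="gs://bkt/results", batch_len=2000))
    handle = bb.submit(config, store)
    return handle, store
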