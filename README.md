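# batchblast

Cloud-agnostic orchestration of distributed BLAST searches — without a
cloud account.

Large sequence-similarity searches (millions of RNA-Seq reads against a
multi-hundred-GB database, say) parallelise naturally: split the query
set into batches, run one search job per batch on a pool of virtual
machines, and collect the per-batch results. Doing this well requires
answering the questions that trip up most users of cloud BLAST: *how
big should a batch be, which instance type can actually hold the
database in memory, what happens when a discounted (spot/preemptible)
instance is reclaimed mid-job, and what will all of this cost?*

`batchblast` implements that orchestration layer as an ordinary Python
library and CLI:

- **Query batching** — a one-pass greedy splitter groups FASTA queries
  (plain or gzipped) into batches whose summed length reaches a
  configurable `batch-len`; a sequence is never split across batches.
- **Resource planning** — BLAST database metadata records
  `bytes_to_cache`, the portion of the database that must be resident in
  RAM for an efficient search. The planner provisions
  `ceil(bytes_to_cache × margin)` bytes (default margin 1.1) and picks
  the *smallest* catalog instance with that much memory; search
  processes use at most 16 threads each, with larger instances running
  `⌊vCPUs/16⌋` processes side by side.
- **Job orchestration** — each batch is a job in a small state machine:
  up to 3 retries after the first attempt for generic failures and
  preemptions, immediate failure on out-of-memory, and a 5-minute
  monitor that tears everything down once all jobs succeed or any job
  fails (results already written survive). Jobs run either through a
  local process executor (real `blastn`/`blastx`/… or a bundled mock)
  or through a seeded discrete-event **cluster simulator** that models
  startup delay, horizontal scaling up to a node ceiling, Poisson
  preemption, idle scale-down lag and per-instance billing.
- **Cost model** — compute cost is
  `hours × instances × hourly_price × (spot_discount if preemptible)`,
  storage is `GB × months × $0.023`; totals round half-up to cents,
  sub-cent amounts keep full precision, per-unit figures (cost per
  read) use 2 significant figures.

Bucket-style locators (`gs://…`, `s3://…`) are accepted everywhere and
mapped onto a local directory tree, so the full submit/status/delete
lifecycle runs on a laptop.

## Worked example

Write a three-section configuration file `run.ini`:

```ini
[cloud-provider]
cloud = gcp
region = us-east4

[cluster]
num-nodes = 1

[blast]
program = blastn
db = gs://b/db.json
queries = gs://b/q.fa
results = gs://b/out
batch-len = 200
```

then drive the run (here against generated fixtures and the bundled
mock search executable; `--store-root` chooses the directory backing
the bucket locators):

```
$ batchblast submit --cfg run.ini --store-root store
run d83d7291275e: 3 job(s) enqueued (3 pending)
$ batchblast run --cfg run.ini --store-root store
run d83d7291275e: succeeded, 3 result object(s) written
$ batchblast status --cfg run.ini --store-root store
run d83d7291275e: phase=succeeded (pending=0, running=0, succeeded=3, failed=0)
$ batchblast delete --cfg run.ini --store-root store
run d83d7291275e: deleted, 3 result object(s) retained
```

The 10 fixture queries were split into 3 batches of ≥ 200 bases each;
every batch produced one gzipped result object
(`batch_000.out.gz`, …), which `delete` leaves in place. `batchblast
plan` prints the same resource decisions without submitting:

```
$ batchblast plan --cfg run.ini --store-root store
database:   ntdb (10,000,000 letters, 0.0 GiB to cache)
memory:     0.0 GiB needed (margin 1.1)
instance:   e2-highmem-8 (8 vCPUs, 64 GiB, $0.40716/h)
threads:    1 process(es) x 8 threads, mode query_batch
batch-len:  200
cluster:    up to 1 node(s), on-demand
```

and the cost calculator answers what-if questions directly — a single
on-demand instance at $0.81432/h for 8.07 hours:

```
$ batchblast cost --hours 8.07 --num-instances 1 --hourly-price 0.81432
compute: $6.57 (1 instance(s) x 8.07 h)
```

For a database needing ~96 GiB of resident memory, the planner selects
`e2-highmem-16` (16 vCPUs, 128 GiB) from the bundled GCP catalog — the
smallest machine that fits the working set with the default 1.1 margin.

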