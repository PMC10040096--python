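"""Instance selection, thread layout and batch-length defaults."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import batchblast as bb
from batchblast.planner import (LARGE_DB_THRESHOLD_BYTES,
                                SMALL_DB_THRESHOLD_BYTES, PlannerError,
                                parse_catalog)
from conftest import CONFIG_TEMPLATE


def _req(nbytes):
    return bb.MemoryRequirement(bytes_needed=nbytes, margin=1.0)


def _itype(name, ram_gib, provider="gcp", vcpus=16, price=1.0, spot=0.2):
    return bb.InstanceType(name=name, provider=provider, vcpus=vcpus,
                           ram_bytes=ram_gib * bb.GIB, hourly_price=price,
                           spot_discount=spot)


class TestCatalog:
    def test_bundled_fixture_has_named_machines(self, catalog):
        assert len(catalog) >= 5
        by_name = {e.name: e for e in catalog}
        r5 = by_name["r5ad.4xlarge"]
        assert (r5.vcpus, r5.ram_bytes, r5.hourly_price) == \
            (16, 128 * bb.GIB, 1.048)
        assert by_name["c5ad.4xlarge"].hourly_price == 0.688
        assert by_name["e2-highmem-16"].hourly_price == 0.81432
        assert by_name["r5ad.24xlarge"].ram_bytes == 768 * bb.GIB
        assert by_name["n1-highmem-96"].ram_bytes == 624 * bb.GIB

    def test_empty_catalog_is_valid(self):
        assert parse_catalog("[]") == []

    def test_duplicate_names_rejected(self):
        text = ('[{"name":"a","provider":"aws","vcpus":1,"ram_gib":1,'
                '"hourly_price":1,"spot_discount":0.5},'
                '{"name":"a","provider":"gcp","vcpus":2,"ram_gib":2,'
                '"hourly_price":2,"spot_discount":0.5}]')
        with pytest.raises(PlannerError, match="duplicate"):
            parse_catalog(text)

    @pytest.mark.parametrize("field,value", [
        ("spot_discount", 0), ("hourly_price", -1), ("vcpus", 0)])
    def test_invalid_entries_rejected(self, field, value):
        row = {"name": "a", "provider": "aws", "vcpus": 1, "ram_gib": 1,
               "hourly_price": 1, "spot_discount": 0.5, field: value}
        import json
        with pytest.raises(ValueError):
            parse_catalog(json.dumps([row]))

    def test_csv_catalog_parses(self):
        text = ("name,provider,vcpus,ram_gib,hourly_price,spot_discount\n"
                "tiny,aws,4,8,0.1,0.3\n")
        [entry] = parse_catalog(text)
        assert entry.ram_bytes == 8 * bb.GIB


class TestSelectInstance:
    def test_96gb_requirement_picks_e2_highmem_16(self):
        cat = [_itype("e2-highmem-8", 64), _itype("e2-highmem-16", 128)]
        chosen = bb.select_instance(_req(96 * bb.GIB), cat,
                                    provider=bb.Provider.gcp)
        assert chosen.name == "e2-highmem-16"

    def test_tiny_requirement_picks_smallest_ram(self, catalog):
        chosen = bb.select_instance(_req(1), catalog)
        assert chosen.ram_bytes == min(e.ram_bytes for e in catalog)

    def test_insufficient_capacity_reports_largest(self, catalog):
        with pytest.raises(PlannerError, match="768"):
            bb.select_instance(_req(1024 * bb.GIB), catalog)

    def test_provider_filter_applies(self, catalog):
        chosen = bb.select_instance(_req(300 * bb.GIB), catalog,
                                    provider=bb.Provider.aws)
        assert chosen.name == "r5ad.24xlarge"

    def test_ties_break_on_price_then_name(self):
        cat = [_itype("b", 64, price=2.0), _itype("a", 64, price=1.0),
               _itype("c", 64, price=1.0)]
        assert bb.select_instance(_req(1), cat).name == "a"

    @settings(derandomize=True, max_examples=150)
    @given(data=st.data())
    def test_agrees_with_exhaustive_oracle(self, data):
        n = data.draw(st.integers(1, 8))
        cat = [_itype(f"i{k}", data.draw(st.integers(1, 512)),
                      price=data.draw(st.floats(0.1, 10.0)))
               for k in range(n)]
        need = data.draw(st.integers(1, 600)) * bb.GIB
        sufficient = [e for e in cat if e.ram_bytes >= need]
        if not sufficient:
            with pytest.raises(PlannerError):
                bb.select_instance(_req(need), cat)
        else:
            best = min(sufficient,
                       key=lambda e: (e.ram_bytes, e.hourly_price, e.name))
            assert bb.select_instance(_req(need), cat) == best


class TestThreadPlan:
    def test_16_vcpus_large_db(self, refseq_meta):
        tp = bb.thread_plan(_itype("x", 128, vcpus=16), refseq_meta)
        assert (tp.processes, tp.threads_per_process) == (1, 16)
        assert tp.mode is bb.ThreadMode.db_partition

    def test_32_vcpus_runs_two_processes(self, refseq_meta):
        tp = bb.thread_plan(_itype("x", 128, vcpus=32), refseq_meta)
        assert (tp.processes, tp.threads_per_process) == (2, 16)

    def test_small_db_uses_query_batch_mode(self, small_meta):
        assert small_meta.bytes_to_cache < SMALL_DB_THRESHOLD_BYTES
        tp = bb.thread_plan(_itype("x", 16, vcpus=8), small_meta)
        assert (tp.processes, tp.threads_per_process) == (1, 8)
        assert tp.mode is bb.ThreadMode.query_batch

    @settings(derandomize=True, max_examples=60)
    @given(vcpus=st.integers(1, 256))
    def test_never_exceeds_vcpus_or_16_threads(self, vcpus, refseq_meta):
        tp = bb.thread_plan(_itype("x", 128, vcpus=vcpus), refseq_meta)
        assert tp.threads_per_process <= 16
        assert tp.processes * tp.threads_per_process <= vcpus


class TestDefaultBatchLen:
    def test_deterministic(self, refseq_meta):
        a = bb.default_batch_len(bb.Program.blastn, refseq_meta, 10**6)
        assert a == bb.default_batch_len(bb.Program.blastn, refseq_meta, 10**6)

    def test_small_db_gets_longer_batches_than_large(self, small_meta,
                                                     refseq_meta):
        assert refseq_meta.bytes_to_cache >= LARGE_DB_THRESHOLD_BYTES
        small = bb.default_batch_len(bb.Program.blastn, small_meta)
        large = bb.default_batch_len(bb.Program.blastn, refseq_meta)
        assert small >= large

    def test_nucleotide_batches_longer_than_protein(self, refseq_meta):
        assert bb.default_batch_len(bb.Program.megablast, refseq_meta) > \
            bb.default_batch_len(bb.Program.blastx, refseq_meta)


class TestMakePlan:
    def _config(self, **kw):
        text = CONFIG_TEMPLATE.format(num_nodes=kw.pop("num_nodes", 1),
                                      db="db", queries="q", results="r",
                                      batch_len=kw.pop("batch_len", 1000))
        return bb.parse_config(text, overrides=kw)

    def test_refseq_gcp_plan_selects_e2_highmem_16(self, refseq_meta, catalog):
        plan = bb.make_plan(self._config(), refseq_meta, catalog)
        assert plan.instance.name == "e2-highmem-16"
        assert plan.instance.ram_bytes >= plan.memory.bytes_needed
        assert plan.batch_len == 1000      # explicit batch-len wins

    def test_override_honored_even_if_oversized(self, refseq_meta, catalog):
        cfg = self._config(**{"machine-type": "n1-highmem-96"})
        plan = bb.make_plan(cfg, refseq_meta, catalog)
        assert plan.instance.name == "n1-highmem-96"

    def test_override_too_small_rejected(self, refseq_meta, catalog):
        cfg = self._config(**{"machine-type": "e2-highmem-8"})
        with pytest.raises(PlannerError, match="needs"):
            bb.make_plan(cfg, refseq_meta, catalog)

    def test_default_batch_len_used_when_unset(self, refseq_meta, catalog):
        cfg = self._config()
        cfg = cfg.model_copy(update={"batch_len": None})
        plan = bb.make_plan(cfg, refseq_meta, catalog)
        assert plan.batch_len == bb.default_batch_len(cfg.program, refseq_meta)
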