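"""Beacon client: request construction, envelopes, federation semantics."""

import pytest

from pgxbeacon import (
    BeaconQuery,
    TransportPolicy,
    build_request,
    fetch_counts,
    fetch_entity,
    fetch_filtering_terms,
    fetch_multi_domain,
)
from pgxbeacon.mock import FaultPlan, MockBeaconServer

from conftest import FAST_POLICY


class TestBuildRequest:
    def test_biosamples_with_and_filters(self):
        q = BeaconQuery("biosamples", filters=("NCIT:C20197", "NCIT:C3512"))
        req = build_request(q, "progenetix.org", "beacon")
        assert req.url == "https://progenetix.org/beacon/biosamples"
        assert req.params["filters"] == "NCIT:C20197,NCIT:C3512"

    def test_custom_entry_point(self):
        q = BeaconQuery("individuals", filters=("NCIT:C189227",))
        req = build_request(q, "beacon-spain.ega-archive.org", "api")
        assert req.url == "https://beacon-spain.ega-archive.org/api/individuals"

    def test_counts_maps_to_entity_endpoint_with_count_flag(self):
        q = BeaconQuery("counts", filters=("NCIT:C16576",), count_entity="individuals")
        req = build_request(q, "progenetix.org")
        assert req.url.endswith("/beacon/individuals")
        assert req.params["requestedGranularity"] == "count"

    def test_counts_without_filter_or_id_rejected(self):
        with pytest.raises(ValueError, match="at least one filter"):
            BeaconQuery("counts")

    def test_unknown_entity_rejected_with_enumeration(self):
        with pytest.raises(ValueError, match="g_variants"):
            BeaconQuery("bogus")

    def test_unpaired_domains_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            BeaconQuery("biosamples", domains=("a", "b"), entry_points=("api",))

    def test_non_curie_filter_flagged(self):
        with pytest.warns(UserWarning, match="CURIE"):
            BeaconQuery("biosamples", filters=("freetext",))


class TestFetchEntity:
    def test_record_granularity_against_oracle(self, dataset, server):
        q = BeaconQuery("biosamples", filters=("NCIT:C3512",))
        env = fetch_entity(q, server.domain, policy=FAST_POLICY)
        assert env.ok and env.granularity == "record"
        expected = dataset.matching_records("biosamples", ["NCIT:C3512"])
        assert len(env.records) == len(expected)
        assert {r["id"] for r in env.records} == {r["id"] for r in expected}

    def test_and_logic_is_set_intersection(self, dataset, server):
        q = BeaconQuery("individuals", filters=("NCIT:C3512", "NCIT:C16576"))
        env = fetch_entity(q, server.domain, policy=FAST_POLICY)
        both = {
            r["id"]
            for r in dataset.individuals
            if {"NCIT:C3512", "NCIT:C16576"} <= dataset.carried_terms(r["id"])
        }
        assert {r["id"] for r in env.records} == both

    def test_and_monotonicity(self, server):
        base = fetch_entity(
            BeaconQuery("biosamples", filters=("NCIT:C3512",)), server.domain,
            policy=FAST_POLICY,
        )
        narrowed = fetch_entity(
            BeaconQuery("biosamples", filters=("NCIT:C3512", "NCIT:C20197")),
            server.domain, policy=FAST_POLICY,
        )
        base_ids = {r["id"] for r in base.records}
        assert {r["id"] for r in narrowed.records} <= base_ids

    def test_unreachable_domain_yields_error_envelope(self):
        q = BeaconQuery("biosamples")
        env = fetch_entity(q, "localhost:1", policy=FAST_POLICY)
        assert not env.ok
        assert env.records == [] and env.total_count is None

    def test_limit_and_skip_paging(self, dataset, server):
        all_env = fetch_entity(BeaconQuery("biosamples"), server.domain, policy=FAST_POLICY)
        page = fetch_entity(
            BeaconQuery("biosamples", limit=5, skip=5), server.domain, policy=FAST_POLICY
        )
        assert len(page.records) == 5
        assert page.total_count == len(dataset.biosamples)
        assert [r["id"] for r in page.records] == [r["id"] for r in all_env.records[5:10]]

    def test_id_lookup(self, dataset, server):
        wanted = dataset.biosamples[3]["id"]
        q = BeaconQuery("biosamples", biosample_ids=(wanted,))
        env = fetch_entity(q, server.domain, policy=FAST_POLICY)
        assert [r["id"] for r in env.records] == [wanted]


class TestCounts:
    def test_count_equals_record_mode_length(self, dataset, server):
        q = BeaconQuery(
            "counts", count_entity="individuals", filters=("NCIT:C16576",),
            domains=(server.domain,),
        )
        table = fetch_counts(q, policy=FAST_POLICY)
        records = fetch_entity(
            BeaconQuery("individuals", filters=("NCIT:C16576",)),
            server.domain, policy=FAST_POLICY,
        )
        assert table.iloc[0]["count"] == len(records.records)

    def test_filter_matching_nothing_counts_zero(self, server):
        q = BeaconQuery("counts", filters=("NCIT:C9999999",), domains=(server.domain,))
        table = fetch_counts(q, policy=FAST_POLICY)
        assert table.iloc[0]["count"] == 0

    def test_failed_domain_gives_null_count_row(self, server):
        q = BeaconQuery(
            "counts", filters=("NCIT:C16576",), domains=(server.domain, "localhost:1")
        )
        with pytest.warns(UserWarning, match="failed"):
            table = fetch_counts(q, policy=FAST_POLICY)
        assert len(table) == 2
        assert table.iloc[0]["count"] is not None
        assert table.iloc[1]["count"] is None


class TestFilteringTerms:
    def test_or_pattern_match_includes_substring_hits(self, server):
        terms = fetch_filtering_terms(
            server.domain, patterns=["male", "lung adenocarcinoma"], policy=FAST_POLICY
        )
        labels = {t.label for t in terms}
        # "male" is a substring of "Female": both sexes match, plus the diagnosis
        assert {"Male", "Female", "Lung Adenocarcinoma"} <= labels
        assert "Glioblastoma" not in labels

    def test_empty_patterns_return_all_terms(self, dataset, server):
        terms = fetch_filtering_terms(server.domain, policy=FAST_POLICY)
        assert len(terms) == len(dataset.filtering_terms)

    def test_no_match_returns_empty(self, server):
        assert fetch_filtering_terms(server.domain, patterns=["zzz"], policy=FAST_POLICY) == []

    def test_unsupported_endpoint_raises(self):
        with pytest.raises(RuntimeError, match="unsupported"):
            fetch_filtering_terms("localhost:1", policy=FAST_POLICY)


class TestFederation:
    def _three_domains(self, dataset):
        servers = [MockBeaconServer(dataset).start() for _ in range(3)]
        return servers

    def test_merge_invariant_to_workers_and_equals_sequential(self, dataset):
        servers = self._three_domains(dataset)
        try:
            q = BeaconQuery(
                "biosamples", filters=("NCIT:C3512",),
                domains=tuple(s.domain for s in servers),
            )
            _, merged1 = fetch_multi_domain(q, num_workers=1, policy=FAST_POLICY)
            _, merged3 = fetch_multi_domain(q, num_workers=3, policy=FAST_POLICY)
            assert merged1.equals(merged3)
            per_domain = [
                fetch_entity(q, s.domain, policy=FAST_POLICY) for s in servers
            ]
            assert len(merged1) == sum(len(e.records) for e in per_domain)
            assert list(merged1["domain"].unique()) == [s.domain for s in servers]
        finally:
            for s in servers:
                s.stop()

    def test_partial_failure_isolated(self, dataset, server):
        bad = MockBeaconServer(dataset, fault=FaultPlan("http500")).start()
        try:
            q = BeaconQuery("biosamples", domains=(server.domain, bad.domain))
            envelopes, merged = fetch_multi_domain(q, num_workers=2, policy=FAST_POLICY)
            assert envelopes[0].ok and not envelopes[1].ok
            assert set(merged["domain"]) == {server.domain}
            assert len(merged) == len(dataset.biosamples)
        finally:
            bad.stop()

    def test_malformed_json_lands_in_envelope(self, dataset):
        bad = MockBeaconServer(dataset, fault=FaultPlan("malformed")).start()
        try:
            env = fetch_entity(BeaconQuery("biosamples"), bad.domain, policy=FAST_POLICY)
            assert not env.ok and "JSONDecodeError" in env.error
        finally:
            bad.stop()

    def test_retry_recovers_from_transient_fault(self, dataset):
        flaky = MockBeaconServer(dataset, fault=FaultPlan("http500", first_n=1)).start()
        try:
            env = fetch_entity(
                BeaconQuery("biosamples"), flaky.domain,
                policy=TransportPolicy(timeout=5, retries=2, backoff=0.0),
            )
            assert env.ok and len(env.records) == len(dataset.biosamples)
        finally:
            flaky.stop()
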