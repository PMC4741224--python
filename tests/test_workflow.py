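import json
from dataclasses import replace

import pytest

from conftest import ARTICLE_LINK, PUB_DATE, gen, make_store
from nomenreg.acts import Code
from nomenreg.fixtures import FixtureSpec
from nomenreg.registry import NEW_AUTHOR, RecordState, _record_to_json
from nomenreg.taxpub import AuthorName, Manuscript, OutcomeStatus, StructuralError
from nomenreg.workflow import (
    PublicationMetadata,
    WorkflowError,
    finalize_publication,
    register_manuscript,
    resolve_report_pending,
    reupload,
)


def publication(m, **overrides):
    kwargs = dict(
        publication_date=PUB_DATE,
        article_link=ARTICLE_LINK,
        final_meta=m.article_meta,
        archive_name="Synthetic Digital Archive",
        issn_or_isbn="2000-0001",
    )
    kwargs.update(overrides)
    return PublicationMetadata(**kwargs)


class TestRegister:
    def test_valid_acts_get_distinct_identifiers(self, zoobank):
        _, _, m = gen(FixtureSpec(n_acts=2, seed=3))
        report = register_manuscript(m, zoobank)
        ids = [o.identifier for o in report.act_outcomes]
        assert all(o.status is OutcomeStatus.REGISTERED for o in report.act_outcomes)
        assert len(set(ids)) == 2

    def test_out_of_scope_act_errors_siblings_register(self, zoobank):
        _, manifest, m = gen(
            FixtureSpec(n_acts=4, seed=3, planted_invalid=(("typification/epitype", "zoobank"),))
        )
        report = register_manuscript(m, zoobank)
        planted = [a["index"] for a in manifest["acts"] if "zoobank" in a["invalid_for"]]
        assert len(planted) == 1
        for o in report.act_outcomes:
            if o.index in planted:
                assert o.status is OutcomeStatus.ERROR
                assert "not_applicable" in o.message
            else:
                assert o.status is OutcomeStatus.REGISTERED

    def test_planted_homonym_yields_pending_and_blocks_injection(self, zoobank):
        xml, manifest, m = gen(FixtureSpec(n_acts=3, seed=3, n_author_homonyms=1))
        for raw in manifest["preload_authors"]:
            zoobank.insert_author(AuthorName(**raw))
        report = register_manuscript(m, zoobank)
        assert report.has_pending
        with pytest.raises(WorkflowError):
            finalize_publication(xml, m, report, publication(m), zoobank)

    def test_resolving_pending_unblocks_finalization(self, zoobank):
        xml, manifest, m = gen(FixtureSpec(n_acts=3, seed=3, n_author_homonyms=1))
        for raw in manifest["preload_authors"]:
            zoobank.insert_author(AuthorName(**raw))
        report = register_manuscript(m, zoobank)
        pending_idx = [
            o.index for o in report.author_outcomes if o.status is OutcomeStatus.PENDING
        ]
        report = resolve_report_pending(report, m, zoobank, {i: NEW_AUTHOR for i in pending_idx})
        assert not report.has_pending
        _, summary = finalize_publication(xml, m, report, publication(m), zoobank)
        assert summary.injected == 3

    def test_manuscript_without_metadata_rejected_atomically(self, zoobank):
        _, _, m = gen(FixtureSpec(n_acts=2, seed=1))
        broken = Manuscript(
            article_meta=replace(m.article_meta, title=""),
            contributors=m.contributors,
            treatments=m.treatments,
            code=m.code,
        )
        with pytest.raises(StructuralError):
            register_manuscript(broken, zoobank)
        assert len(zoobank) == 0


class TestReupload:
    def test_identical_reupload_keeps_all_identifiers(self, zoobank):
        _, _, m = gen(FixtureSpec(n_acts=5, seed=9))
        first = register_manuscript(m, zoobank)
        second = reupload(m, zoobank)
        assert [o.identifier for o in second.act_outcomes] == [
            o.identifier for o in first.act_outcomes
        ]
        assert all(o.action == "updated" for o in second.act_outcomes)

    def test_added_act_is_the_only_insertion(self, zoobank):
        _, _, small = gen(FixtureSpec(n_acts=4, seed=9))
        register_manuscript(small, zoobank)
        grown = Manuscript(
            article_meta=small.article_meta,
            contributors=small.contributors,
            treatments=gen(FixtureSpec(n_acts=5, seed=9))[2].treatments,
            code=small.code,
        )
        report = reupload(grown, zoobank)
        actions = [o.action for o in report.act_outcomes]
        assert actions.count("inserted") == 1

    def test_removed_act_is_superseded(self, zoobank):
        _, _, m = gen(FixtureSpec(n_acts=5, seed=9))
        first = register_manuscript(m, zoobank)
        shrunk = Manuscript(
            article_meta=m.article_meta,
            contributors=m.contributors,
            treatments=m.treatments[:-1],
            code=m.code,
        )
        reupload(shrunk, zoobank)
        dropped = first.act_outcomes[-1].identifier
        assert zoobank.get(dropped).state is RecordState.SUPERSEDED

    def test_reupload_after_release_is_a_conflict(self, zoobank):
        xml, _, m = gen(FixtureSpec(n_acts=3, seed=9))
        report = register_manuscript(m, zoobank)
        finalize_publication(xml, m, report, publication(m), zoobank)
        with pytest.raises(WorkflowError):
            reupload(m, zoobank)

    def test_planted_duplicates_update_in_place(self, zoobank):
        _, manifest, m = gen(FixtureSpec(n_acts=6, seed=2, n_duplicate_acts=2))
        report = register_manuscript(m, zoobank)
        actions = [o.action for o in report.act_outcomes]
        assert actions.count("updated") == 2
        # the duplicate resolves to the identifier of its source act
        for entry in manifest["acts"]:
            if entry["duplicate_of"] is not None:
                assert (
                    report.act_outcomes[entry["index"]].identifier
                    == report.act_outcomes[entry["duplicate_of"]].identifier
                )


class TestFinalize:
    def test_clean_run_injects_releases_and_diffs_empty(self, zoobank):
        xml, _, m = gen(FixtureSpec(n_acts=3, seed=4))
        report = register_manuscript(m, zoobank)
        final_xml, summary = finalize_publication(xml, m, report, publication(m), zoobank)
        assert summary.injected == 3
        assert summary.released == len(zoobank)  # every record of the run
        assert summary.metadata_diff == []
        assert final_xml.count("<tp:registration-id>") == 3

    def test_zoobank_route_without_issn_refused(self, zoobank):
        xml, _, m = gen(FixtureSpec(n_acts=2, seed=4))
        meta = replace(m.article_meta, issn_or_isbn=None)
        report = register_manuscript(m, zoobank)
        with pytest.raises(WorkflowError) as err:
            finalize_publication(
                xml, m, report,
                publication(m, final_meta=meta, issn_or_isbn=None), zoobank,
            )
        assert "ISSN" in str(err.value)

    def test_botanical_route_needs_no_archive_metadata(self, mycobank):
        xml, _, m = gen(FixtureSpec(n_acts=2, seed=4, code=Code.ICNAFP))
        meta = replace(m.article_meta, issn_or_isbn=None, archive_name=None)
        report = register_manuscript(m, mycobank)
        _, summary = finalize_publication(
            xml, m, report,
            publication(m, final_meta=meta, issn_or_isbn=None, archive_name=None),
            mycobank,
        )
        assert summary.injected == 2

    def test_title_change_shows_up_in_metadata_diff(self, zoobank):
        xml, _, m = gen(FixtureSpec(n_acts=2, seed=4))
        report = register_manuscript(m, zoobank)
        final = replace(m.article_meta, title="Corrected title at publication")
        _, summary = finalize_publication(
            xml, m, report, publication(m, final_meta=final), zoobank
        )
        assert summary.metadata_diff == ["title"]


class TestPipelineProperties:
    def test_conservation_acts_outcomes_injections_releases(self, zoobank):
        for seed in (0, 5, 11):
            store = make_store(seed=seed)
            xml, manifest, m = gen(FixtureSpec(n_acts=4 + seed % 3, seed=seed))
            report = register_manuscript(m, store)
            final_xml, summary = finalize_publication(
                xml, m, report, publication(m), store
            )
            n = len(m.acts)
            assert len(report.act_outcomes) == n
            assert summary.injected == n
            released_acts = store.search_records(
                {"payload_type": "act", "state": "public"}, context="public"
            )
            assert len(released_acts) == n

    def test_no_public_leak_before_release(self, zoobank):
        xml, _, m = gen(FixtureSpec(n_acts=4, seed=6))
        report = register_manuscript(m, zoobank)
        assert zoobank.search_records({}, context="public") == []
        finalize_publication(xml, m, report, publication(m), zoobank)
        assert len(zoobank.search_records({}, context="public")) == len(zoobank)

    def test_replay_determinism_of_report_and_store(self):
        def run():
            store = make_store(seed=42)
            xml, _, m = gen(FixtureSpec(n_acts=5, seed=42))
            report = register_manuscript(m, store)
            final_xml, _ = finalize_publication(xml, m, report, publication(m), store)
            dump = json.dumps(
                sorted(
                    (json.dumps(_record_to_json(r), sort_keys=True) for r in store.search_records({})),
                )
            )
            return report, final_xml, dump

        assert run() == run()
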