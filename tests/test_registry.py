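import re
from datetime import timedelta

import pytest

from conftest import ARTICLE_LINK, PUB_DATE, make_store
from nomenreg.acts import ActKind, Code, Rank, Registry, ScientificName, NomenclaturalAct, TypeKind
from nomenreg.registry import (
    ConflictError,
    EmbargoViolationError,
    InvalidChoiceError,
    MatchKind,
    NEW_AUTHOR,
    NotFoundError,
    QueryError,
    RecordState,
    propagate,
)
from nomenreg.taxpub import AuthorName

URN_UUID = re.compile(
    r"^urn:uuid:[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[89ab][0-9a-f]{3}-[0-9a-f]{12}$"
)


def species(genus="Aus", epithet="bus", code=Code.ICZN, authorship="Smith"):
    return NomenclaturalAct(
        ActKind.NEW_TAXON,
        ScientificName(genus=genus, species=epithet, authorship=authorship),
        code,
        rank=Rank.SPECIFIC,
    )


class TestMinting:
    def test_consecutive_identifiers_differ_and_match_urn_uuid(self, zoobank):
        a, b = zoobank.mint_identifier(), zoobank.mint_identifier()
        assert a != b
        assert URN_UUID.match(a.value) and URN_UUID.match(b.value)

    def test_ten_thousand_identifiers_are_all_distinct(self, zoobank):
        minted = {zoobank.mint_identifier().value for _ in range(10_000)}
        assert len(minted) == 10_000

    def test_minting_is_deterministic_per_seed(self):
        a = make_store(seed=7).mint_identifier()
        b = make_store(seed=7).mint_identifier()
        c = make_store(seed=8).mint_identifier()
        assert a == b != c


class TestSearch:
    def test_empty_store_matches_nothing(self, zoobank):
        assert zoobank.search_records({"payload_type": "act"}) == []

    def test_insert_then_find_by_name(self, zoobank):
        act = species()
        zoobank.upsert_record(act, act.dedup_key)
        found = zoobank.search_records({"name": "Aus bus"})
        assert len(found) == 1
        assert found[0].payload == act

    def test_unknown_filter_field_is_a_query_error(self, zoobank):
        with pytest.raises(QueryError):
            zoobank.search_records({"flavour": "new"})

    def test_public_context_hides_embargoed_records(self, zoobank):
        act = species()
        zoobank.upsert_record(act, act.dedup_key)
        assert zoobank.search_records({"name": "Aus bus"}, context="public") == []
        assert len(zoobank.search_records({"name": "Aus bus"})) == 1


class TestUpsert:
    def test_first_upsert_inserts(self, zoobank):
        act = species()
        record, action = zoobank.upsert_record(act, act.dedup_key)
        assert action == "inserted"
        assert record.state is RecordState.EMBARGOED

    def test_identical_reupload_updates_same_identifier(self, zoobank):
        act = species()
        first, _ = zoobank.upsert_record(act, act.dedup_key)
        second, action = zoobank.upsert_record(act, act.dedup_key)
        assert action == "updated"
        assert second.id == first.id

    def test_changed_payload_read_back(self, zoobank):
        act = species()
        zoobank.upsert_record(act, act.dedup_key)
        revised = species(authorship="Smith & Jones")
        record, action = zoobank.upsert_record(revised, act.dedup_key)
        assert action == "updated"
        assert zoobank.get(record.id).payload.name.authorship == "Smith & Jones"

    def test_upsert_is_idempotent_on_store_state(self, zoobank):
        act = species()
        zoobank.upsert_record(act, act.dedup_key)
        once = {r.id.value: (r.payload, r.state) for r in zoobank.search_records({})}
        zoobank.upsert_record(act, act.dedup_key)
        twice = {r.id.value: (r.payload, r.state) for r in zoobank.search_records({})}
        assert once == twice

    def test_conflicting_update_of_public_record_refused(self, zoobank):
        act = species()
        record, _ = zoobank.upsert_record(act, act.dedup_key, article_id=record_article(zoobank))
        zoobank.release_records(record.article_id, PUB_DATE, ARTICLE_LINK)
        with pytest.raises(ConflictError):
            zoobank.upsert_record(species(authorship="Else"), act.dedup_key)

    def test_superseded_record_revives_on_upsert(self, zoobank):
        act = species()
        record, _ = zoobank.upsert_record(act, act.dedup_key)
        zoobank.supersede(record.id)
        revived, action = zoobank.upsert_record(act, act.dedup_key)
        assert action == "updated"
        assert revived.id == record.id
        assert revived.state is RecordState.EMBARGOED


def record_article(store):
    from nomenreg.taxpub import ArticleMeta

    record, _ = store.upsert_record(ArticleMeta(title="T"), "article:title:t")
    return record.id


class TestAuthorMatching:
    def test_empty_store_no_match(self, zoobank):
        assert zoobank.match_authors(AuthorName("Smith", "J.")).kind is MatchKind.NO_MATCH

    def test_single_registered_author_unique_match(self, zoobank):
        record = zoobank.insert_author(AuthorName("Smith", "J."))
        match = zoobank.match_authors(AuthorName("Smith", "John"))
        assert match.kind is MatchKind.UNIQUE_MATCH
        assert match.record.id == record.id

    def test_two_records_sharing_key_queue_homonyms(self, zoobank):
        zoobank.insert_author(AuthorName("Smith", "J."))
        zoobank.insert_author(AuthorName("Šmith", "John"))
        match = zoobank.match_authors(AuthorName("Smith", "J."))
        assert match.kind is MatchKind.HOMONYMS
        assert len(match.pending.candidates) == 2

    def test_resolving_with_candidate_links_that_record(self, zoobank):
        zoobank.insert_author(AuthorName("Smith", "J."))
        zoobank.insert_author(AuthorName("Smith", "John"))
        pending = zoobank.match_authors(AuthorName("Smith", "J.")).pending
        chosen = zoobank.resolve_disambiguation(pending, pending.candidates[0].id)
        assert chosen is pending.candidates[0]

    def test_resolving_with_new_mints_a_fresh_author(self, zoobank):
        zoobank.insert_author(AuthorName("Smith", "J."))
        zoobank.insert_author(AuthorName("Smith", "John"))
        pending = zoobank.match_authors(AuthorName("Smith", "Jane")).pending
        record = zoobank.resolve_disambiguation(pending, NEW_AUTHOR)
        assert record.payload.normalized_key == "smith j"
        assert record.id not in [c.id for c in pending.candidates]

    def test_choice_outside_candidates_is_invalid(self, zoobank):
        zoobank.insert_author(AuthorName("Smith", "J."))
        zoobank.insert_author(AuthorName("Smith", "John"))
        pending = zoobank.match_authors(AuthorName("Smith", "J.")).pending
        with pytest.raises(InvalidChoiceError):
            zoobank.resolve_disambiguation(pending, zoobank.mint_identifier())


class TestRelease:
    def seed_article(self, store, n_acts=3):
        article_id = record_article(store)
        for i in range(n_acts):
            act = species(epithet=f"bus{i}")
            store.upsert_record(act, act.dedup_key, article_id=article_id)
        return article_id

    def test_all_records_released_with_link(self, zoobank):
        article_id = self.seed_article(zoobank)
        released = zoobank.release_records(article_id, PUB_DATE, ARTICLE_LINK)
        assert released == 4  # 3 acts + the article record itself
        for record in zoobank.records_of_article(article_id):
            assert record.state is RecordState.PUBLIC
            assert record.article_link == ARTICLE_LINK

    def test_second_release_is_idempotent(self, zoobank):
        article_id = self.seed_article(zoobank)
        zoobank.release_records(article_id, PUB_DATE, ARTICLE_LINK)
        assert zoobank.release_records(article_id, PUB_DATE, ARTICLE_LINK) == 0

    def test_release_before_publication_date_refused_states_unchanged(self, zoobank):
        article_id = self.seed_article(zoobank)
        with pytest.raises(EmbargoViolationError):
            zoobank.release_records(article_id, PUB_DATE + timedelta(days=1), ARTICLE_LINK)
        states = {r.state for r in zoobank.records_of_article(article_id)}
        assert states == {RecordState.EMBARGOED}

    def test_unknown_article_is_not_found(self, zoobank):
        with pytest.raises(NotFoundError):
            zoobank.release_records(zoobank.mint_identifier(), PUB_DATE, ARTICLE_LINK)


class TestPersistence:
    def test_store_reloads_from_jsonl_log(self, tmp_path):
        path = tmp_path / "zoobank.jsonl"
        store = make_store(Registry.ZOOBANK, path=path)
        act = species()
        record, _ = store.upsert_record(act, act.dedup_key)
        store.insert_author(AuthorName("Smith", "J."))

        reloaded = make_store(Registry.ZOOBANK, path=path)
        assert len(reloaded) == 2
        assert reloaded.get(record.id).payload == act
        # dedup survives reload: same key updates, does not duplicate
        _, action = reloaded.upsert_record(act, act.dedup_key)
        assert action == "updated"


class TestPropagation:
    def fungal_stores(self):
        return (
            make_store(Registry.MYCOBANK, seed=1),
            make_store(Registry.INDEX_FUNGORUM, seed=2),
            make_store(Registry.FUNGAL_NAMES, seed=3),
        )

    def test_fungal_act_reaches_both_sibling_registries(self):
        mycobank, index_fungorum, fungal_names = self.fungal_stores()
        act = species(code=Code.ICNAFP)
        record, _ = mycobank.upsert_record(act, act.dedup_key)
        results = propagate(record, mycobank, [index_fungorum, fungal_names])
        assert results[Registry.INDEX_FUNGORUM][0] == "inserted"
        assert results[Registry.FUNGAL_NAMES][0] == "inserted"
        for target in (index_fungorum, fungal_names):
            (twin,) = target.search_records({"dedup_key": act.dedup_key})
            assert twin.payload == act
            assert twin.xrefs == {"mycobank": record.id.value}

    def test_repeat_propagation_updates_without_duplicates(self):
        mycobank, index_fungorum, fungal_names = self.fungal_stores()
        act = species(code=Code.ICNAFP)
        record, _ = mycobank.upsert_record(act, act.dedup_key)
        propagate(record, mycobank, [index_fungorum, fungal_names])
        results = propagate(record, mycobank, [index_fungorum, fungal_names])
        assert {r[0] for r in results.values()} == {"updated"}
        for store in (mycobank, index_fungorum, fungal_names):
            assert len(store.search_records({"dedup_key": act.dedup_key})) == 1

    def test_lectotypification_propagates_to_registries_that_record_it(self):
        mycobank, index_fungorum, fungal_names = self.fungal_stores()
        act = NomenclaturalAct(
            ActKind.TYPIFICATION,
            ScientificName(genus="Aus", species="bus"),
            Code.ICNAFP,
            type_kind=TypeKind.LECTOTYPE,
        )
        record, _ = mycobank.upsert_record(act, act.dedup_key)
        results = propagate(record, mycobank, [index_fungorum, fungal_names])
        assert {r[0] for r in results.values()} == {"inserted"}

    def test_out_of_scope_target_rejects_others_unaffected(self):
        mycobank, index_fungorum, _ = self.fungal_stores()
        ipni = make_store(Registry.IPNI, seed=4)
        act = NomenclaturalAct(
            ActKind.TYPIFICATION,
            ScientificName(genus="Aus", species="bus"),
            Code.ICNAFP,
            type_kind=TypeKind.LECTOTYPE,
        )
        record, _ = mycobank.upsert_record(act, act.dedup_key)
        results = propagate(record, mycobank, [ipni, index_fungorum])
        assert results[Registry.IPNI][0] == "rejected"
        assert results[Registry.INDEX_FUNGORUM][0] == "inserted"
        assert len(ipni) == 0
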