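"""Learning anamorphisms, trial encodings, rote learning, ablation."""

import random

import pytest

from coalearn import (
    AblatedModelError,
    AssociationNetwork,
    LearningModel,
    MergeRule,
    PairList,
    TrainingEvent,
    TypeViolationError,
    ablate_common_component,
    conjunction_id,
    encode_trial,
    fixture,
    ilearn_loop,
    learn_ext,
    learn_int,
    recall,
    rlearn_fold,
    train_to_criterion,
)
from coalearn.fixtures import CONFIGURAL_TYPE, ELEMENTAL_TYPE, RAT_TYPE

from conftest import random_network, random_pairlist

BREAD_BUTTER = [("bread", "butter"), ("knife", "fork"), ("knife", "butter")]


class TestLearnExt:
    def test_bread_butter_trace(self, halfway_model):
        pairs = PairList.from_pairs(BREAD_BUTTER)
        stream = learn_ext(halfway_model, pairs, AssociationNetwork.empty())
        assert len(stream) == 3 and stream.terminated
        g1, g2, g3 = stream
        assert g1.edges == {("bread", "butter"): 0.5}
        assert g2.n_edges == 2
        assert g3.n_edges == 3
        assert g3.out_degree("knife") == 2

    def test_empty_pair_list_yields_empty_stream(self, halfway_model):
        g0 = AssociationNetwork.from_edges([("a", "b", 0.5)])
        stream = learn_ext(halfway_model, PairList(()), g0)
        assert len(stream) == 0 and stream.terminated

    def test_ws1_four_snapshots_one_edge_per_word(self):
        fxt = fixture("ws1")
        model = LearningModel(network_type=fxt.network_type)
        stream = learn_ext(model, fxt.pair_list, AssociationNetwork.empty())
        assert len(stream) == 4
        assert stream[-1].n_edges == 4

    def test_snapshot_k_depends_only_on_first_k_events(self, halfway_model):
        rng = random.Random(2)
        pairs = random_pairlist(rng, 12)
        full = learn_ext(halfway_model, pairs, AssociationNetwork.empty())
        for k in (0, 3, 7, 12):
            prefix = learn_ext(halfway_model, pairs[:k], AssociationNetwork.empty())
            assert tuple(prefix) == tuple(full)[:k]

    def test_type_violation_refused_before_any_learning(self):
        model = LearningModel(network_type=RAT_TYPE)
        pairs = PairList.from_pairs(
            [("odour:almond", "food:pellet"), ("colour:red", "food:pellet")])
        with pytest.raises(TypeViolationError, match="colour"):
            learn_ext(model, pairs, AssociationNetwork.empty())

    def test_budget_below_list_length_rejected(self, halfway_rule):
        model = LearningModel(merge=halfway_rule, budget=2)
        pairs = PairList.from_pairs(BREAD_BUTTER)
        with pytest.raises(ValueError):
            learn_ext(model, pairs, AssociationNetwork.empty())


class TestLearnInt:
    def test_transpose_equivalence_on_bread_butter(self, halfway_model):
        pairs = PairList.from_pairs(BREAD_BUTTER)
        curried = learn_int(halfway_model, pairs)
        ext = learn_ext(halfway_model, pairs, AssociationNetwork.empty())
        assert tuple(curried(AssociationNetwork.empty())) == tuple(ext)

    def test_transpose_equivalence_from_random_prior(self, halfway_model):
        rng = random.Random(23)
        for _ in range(5):
            pairs = random_pairlist(rng, 8)
            prior = random_network(rng)
            assert tuple(learn_int(halfway_model, pairs)(prior)) == tuple(
                learn_ext(halfway_model, pairs, prior))

    def test_empty_list_gives_constant_empty_stream(self, halfway_model):
        f = learn_int(halfway_model, PairList(()))
        for g in (AssociationNetwork.empty(), random_network(random.Random(1))):
            assert len(f(g)) == 0


class TestEncodeTrial:
    def test_elemental_single_cue(self):
        (ev,) = encode_trial("elemental", "bell", "□")
        assert ev.cues == ("bell",) and ev.target == "□"

    def test_elemental_multi_attribute_one_event_per_attribute(self):
        events = encode_trial("elemental", ("black", "square"), "+")
        assert [(e.cues[0], e.target) for e in events] == [
            ("black", "+"), ("square", "+")]

    def test_configural_builds_conjunction_vertex(self):
        (ev,) = encode_trial("configural", ("black", "square"), "+",
                             CONFIGURAL_TYPE)
        assert ev.cues == ("black∧square",)

    def test_configural_canonical_under_reversed_attribute_order(self):
        a = encode_trial("configural", ("black", "square"), "+", CONFIGURAL_TYPE)
        b = encode_trial("configural", ("square", "black"), "+", CONFIGURAL_TYPE)
        assert a == b

    def test_configural_refused_by_nonconfigural_type(self):
        with pytest.raises(TypeViolationError, match="conjunction"):
            encode_trial("configural", ("black", "square"), "+", ELEMENTAL_TYPE)


class TestTrainToCriterion:
    def test_ws1_learned_in_one_block(self):
        fxt = fixture("ws1")
        model = LearningModel(network_type=fxt.network_type)
        mapping = [(ev.cues[0], ev.target) for ev in fxt.pair_list]
        res = train_to_criterion(model, mapping, criterion=1.0, seed=0)
        assert res.succeeded and res.blocks_used == 1
        assert res.accuracy == 1.0

    def test_xor_mapping_unlearnable_elementally_every_cue_ties(self):
        """Each colour and shape co-occurs equally with + and −, so recall
        ties everywhere and the criterion is never reached."""
        mapping = fixture("configural_ca").expected["mapping"]
        model = LearningModel(network_type=ELEMENTAL_TYPE)
        res = train_to_criterion(model, list(mapping), schema="elemental",
                                 max_blocks=5, seed=0)
        assert not res.succeeded
        assert res.accuracy == 0.0
        for cue in ("black", "white", "square", "triangle"):
            assert recall(res.network, cue).is_tie

    def test_xor_mapping_learned_configurally_in_one_block(self):
        mapping = fixture("configural_ca").expected["mapping"]
        model = LearningModel(network_type=CONFIGURAL_TYPE)
        res = train_to_criterion(model, list(mapping), schema="configural",
                                 seed=0)
        assert res.succeeded and res.blocks_used == 1

    def test_second_order_systematicity_equal_blocks_for_structural_twins(self):
        """Any two functional distinct-cue mappings of equal size are
        learnable in the same number of blocks under the halfway rule."""
        rng = random.Random(41)
        model = LearningModel()
        for trial in range(10):
            n = rng.randrange(2, 7)
            m1 = [(f"a{i}_{trial}", f"x{rng.randrange(100)}_{i}") for i in range(n)]
            m2 = [(f"b{i}_{trial}", f"y{rng.randrange(100)}_{i}") for i in range(n)]
            r1 = train_to_criterion(model, m1, seed=trial)
            r2 = train_to_criterion(model, m2, seed=trial)
            assert r1.succeeded == r2.succeeded
            assert r1.blocks_used == r2.blocks_used

    def test_nonfunctional_mapping_rejected(self, halfway_model):
        with pytest.raises(ValueError, match="functional"):
            train_to_criterion(halfway_model, [("a", "x"), ("a", "y")])


class TestClassicalProductions:
    def test_empty_list_returns_network_unchanged(self, halfway_rule):
        g = random_network(random.Random(4))
        assert rlearn_fold(PairList(()), g, halfway_rule) == g
        assert ilearn_loop(PairList(()), g, halfway_rule) == g

    def test_single_pair_equals_one_merge(self, halfway_rule, halfway_model):
        pairs = PairList.from_pairs([("a", "b")])
        expected = learn_ext(halfway_model, pairs, AssociationNetwork.empty())[-1]
        assert rlearn_fold(pairs, AssociationNetwork.empty(), halfway_rule) == expected

    def test_final_state_equivalence_on_200_random_lists(self, halfway_rule,
                                                          halfway_model):
        """learn_ext, rlearn_fold and ilearn_loop agree on the final network
        for hundreds of random finite inputs."""
        rng = random.Random(99)
        for case in range(200):
            pairs = random_pairlist(rng, rng.randrange(0, 15))
            g0 = random_network(rng, n_edges=rng.randrange(0, 5))
            stream = learn_ext(halfway_model, pairs, g0)
            final_ext = stream[-1] if len(stream) else g0
            assert final_ext == rlearn_fold(pairs, g0, halfway_rule)
            assert final_ext == ilearn_loop(pairs, g0, halfway_rule)

    def test_equivalence_holds_for_rescorla_wagner_rule(self, rw_rule):
        rng = random.Random(7)
        model = LearningModel(merge=rw_rule)
        pairs = PairList(tuple(
            TrainingEvent(
                tuple({f"c{rng.randrange(4)}" for _ in range(rng.randrange(1, 3))}),
                f"o{rng.randrange(2)}")
            for _ in range(20)))
        g0 = AssociationNetwork.empty()
        final_ext = learn_ext(model, pairs, g0)[-1]
        assert final_ext == rlearn_fold(pairs, g0, rw_rule)
        assert final_ext == ilearn_loop(pairs, g0, rw_rule)


class TestAblation:
    def test_ablated_model_cannot_learn_any_fixture_list(self):
        for name in ("ws1", "ws2"):
            fxt = fixture(name)
            model = ablate_common_component(
                LearningModel(network_type=fxt.network_type))
            assert model.ablated
            with pytest.raises(AblatedModelError):
                learn_ext(model, fxt.pair_list, AssociationNetwork.empty())
            with pytest.raises(AblatedModelError):
                learn_int(model, fxt.pair_list)

    def test_recall_survives_ablation_of_the_learning_component(self):
        fxt = fixture("ws1")
        model = LearningModel(network_type=fxt.network_type)
        trained = learn_ext(model, fxt.pair_list, AssociationNetwork.empty())[-1]
        ablate_common_component(model)  # does not touch the trained network
        assert recall(trained, "bell").prediction == "□"


class TestRWBlocking:
    def test_pretrained_cue_blocks_novel_partner(self, rw_rule):
        """Train A to within 1e-6 of asymptote, then ten A+B compound
        trials leave B with negligible strength."""
        model = LearningModel(merge=rw_rule)
        pretrain = PairList(tuple(TrainingEvent(("A",), "US") for _ in range(60)))
        g = learn_ext(model, pretrain, AssociationNetwork.empty())[-1]
        assert abs(rw_rule.lam - g.strength("A", "US")) < 1e-6
        compound = PairList(tuple(TrainingEvent(("A", "B"), "US") for _ in range(10)))
        g = learn_ext(model, compound, g)[-1]
        assert abs(g.strength("B", "US")) < 1e-5
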