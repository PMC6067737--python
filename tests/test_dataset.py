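"""Training-set construction, fold plans, and the synthetic generator."""

import numpy as np
import pytest

from wholemir.dataset import (
    EXCLUDED,
    TEST,
    TRAIN,
    FoldPlan,
    SyntheticGrammar,
    build_negative_sites,
    build_positive_sites,
    encode_examples,
    family_map,
    fold_indices,
    generate_synthetic_dataset,
    make_cv_folds,
    read_examples,
    write_examples,
)
from wholemir.errors import ValidationError
from wholemir.seqio import GeneUTR, LabeledPair, MatureMiRNA
from wholemir.thermo import cofold_duplex
from wholemir.cssm import count_region_pairs

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
LET7_RC = "AACUAUACAACCUACUACCUCA"


class TestBuildNegativeSites:
    def test_no_stable_window_yields_nothing(self, toy_backend):
        mirnas = [MatureMiRNA(id="m", seq="A" * 20)]
        utrs = [GeneUTR(gene_id="g", seq="A" * 80)]
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="negative")]
        assert build_negative_sites(pairs, mirnas, utrs, toy_backend) == []

    def test_stable_windows_become_negative_examples(self, toy_backend):
        mirnas = [MatureMiRNA(id="m", seq=LET7)]
        utrs = [GeneUTR(gene_id="g", seq="A" * 20 + LET7_RC + "A" * 18)]
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="negative")]
        out = build_negative_sites(pairs, mirnas, utrs, toy_backend)
        assert out and all(e.label == -1 and e.provenance == "mined_window" for e in out)

    def test_missing_ids_reported(self, toy_backend):
        pairs = [LabeledPair(mirna_id="mx", gene_id="gx", label="negative")]
        with pytest.raises(ValidationError, match="mx"):
            build_negative_sites(pairs, [], [], toy_backend)

    def test_positive_pair_rejected(self, toy_backend):
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="positive")]
        mirnas = [MatureMiRNA(id="m", seq=LET7)]
        utrs = [GeneUTR(gene_id="g", seq="A" * 60)]
        with pytest.raises(ValidationError):
            build_negative_sites(pairs, mirnas, utrs, toy_backend)


class TestBuildPositiveSites:
    def test_annotated_stable_site_kept_with_flanks(self, toy_backend):
        mirnas = [MatureMiRNA(id="m", seq=LET7)]
        seq = "C" * 20 + LET7_RC + "C" * 20
        utrs = [GeneUTR(gene_id="g", seq=seq)]
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="positive", sites=((20, 42),))]
        (ex,) = build_positive_sites(pairs, mirnas, utrs, toy_backend)
        assert ex.label == 1 and ex.provenance == "annotated_site"
        assert ex.site_seq == LET7_RC
        assert ex.up_flank == "C" * 5 and ex.down_flank == "C" * 5

    def test_unstable_annotated_site_dropped_with_warning(self, toy_backend):
        mirnas = [MatureMiRNA(id="m", seq="A" * 20)]
        utrs = [GeneUTR(gene_id="g", seq="A" * 60)]
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="positive", sites=((10, 30),))]
        with pytest.warns(UserWarning, match="not stable"):
            out = build_positive_sites(pairs, mirnas, utrs, toy_backend)
        assert out == []

    def test_pair_without_intervals_mined_under_cssm(self, toy_backend):
        mirnas = [MatureMiRNA(id="m", seq=LET7)]
        utrs = [GeneUTR(gene_id="g", seq="A" * 20 + LET7_RC + "A" * 18)]
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="positive")]
        out = build_positive_sites(pairs, mirnas, utrs, toy_backend, cssm="7-1:10")
        assert out and all(e.provenance == "mined_window" and e.label == 1 for e in out)

    def test_pair_without_intervals_requires_cssm(self, toy_backend):
        mirnas = [MatureMiRNA(id="m", seq=LET7)]
        utrs = [GeneUTR(gene_id="g", seq="A" * 60)]
        pairs = [LabeledPair(mirna_id="m", gene_id="g", label="positive")]
        with pytest.raises(ValidationError, match="CSSM"):
            build_positive_sites(pairs, mirnas, utrs, toy_backend)


class TestSyntheticGenerator:
    def test_balanced_and_deterministic(self):
        a = generate_synthetic_dataset(200, seed=42)
        b = generate_synthetic_dataset(200, seed=42)
        labels = [e.label for e in a[3]]
        assert labels.count(1) == labels.count(-1) == 100
        assert [e.site_seq for e in a[3]] == [e.site_seq for e in b[3]]
        assert [m.seq for m in a[0]] == [m.seq for m in b[0]]

    def test_different_seed_differs(self):
        a = generate_synthetic_dataset(50, seed=1)
        b = generate_synthetic_dataset(50, seed=2)
        assert [e.site_seq for e in a[3]] != [e.site_seq for e in b[3]]

    def test_positives_satisfy_extended_seed_grammar(self, toy_backend, small_corpus):
        mirnas, _, _, examples = small_corpus
        by_id = {m.id: m for m in mirnas}
        for ex in examples:
            duplex = cofold_duplex(by_id[ex.mirna_id], ex.site_seq, toy_backend)
            n_seed = count_region_pairs(duplex, 1, 10)
            if ex.label == 1:
                assert n_seed >= 7, ex.mirna_id
                assert duplex.dg_duplex < 0
            else:
                assert duplex.dg_duplex < 0  # near-misses still bind stably

    def test_canonical_grammar_passes_targetscan(self, toy_backend):
        from wholemir.cssm import accept_targetscan

        g = SyntheticGrammar(kind="canonical")
        mirnas, _, _, examples = generate_synthetic_dataset(60, g, seed=9)
        by_id = {m.id: m for m in mirnas}
        for ex in examples:
            if ex.label == 1:
                duplex = cofold_duplex(by_id[ex.mirna_id], ex.site_seq, toy_backend)
                assert accept_targetscan(duplex)

    def test_sites_implanted_on_scan_grid_inside_utr(self, small_corpus):
        _, utrs, pairs, examples = small_corpus
        by_gene = {u.gene_id: u for u in utrs}
        for ex, pair in zip(examples, pairs):
            assert ex.window_start % 5 == 0
            utr = by_gene[ex.gene_id]
            assert utr.seq[ex.window_start:ex.window_start + 30] == ex.site_seq
            assert pair.sites == ((ex.window_start, ex.window_start + 30),)

    def test_label_noise_flips_labels(self):
        g0 = SyntheticGrammar(label_noise=0.0)
        g3 = SyntheticGrammar(label_noise=0.3)
        a = generate_synthetic_dataset(400, g0, seed=4)[3]
        b = generate_synthetic_dataset(400, g3, seed=4)[3]
        flipped = sum(1 for x, y in zip(a, b) if x.label != y.label)
        assert 60 <= flipped <= 180  # ~30% of 400

    def test_bad_grammar_rejected(self):
        with pytest.raises(ValidationError):
            generate_synthetic_dataset(10, SyntheticGrammar(kind="mystery"))
        with pytest.raises(ValidationError):
            generate_synthetic_dataset(10, SyntheticGrammar(neg_max_seed_pairs=9))

    def test_family_structure(self, small_corpus):
        mirnas = small_corpus[0]
        fams = family_map(mirnas)
        assert len(set(fams.values())) > 1
        by_fam = {}
        for m in mirnas:
            by_fam.setdefault(m.family, []).append(m.seq)
        for members in by_fam.values():
            seeds = {s[:10] for s in members}
            assert len(seeds) == 1  # families share the extended seed


@pytest.fixture(scope="module")
def folded(small_corpus):
    mirnas, _, _, examples = small_corpus
    plan = make_cv_folds(examples, family_map(mirnas), FoldPlan(n_folds=5, seed=11))
    return examples, family_map(mirnas), plan


class TestFolds:

    def test_roles_partition(self, folded):
        examples, _, plan = folded
        for roles in plan.assignments:
            assert len(roles) == len(examples)
            assert set(roles.tolist()) <= {TRAIN, TEST, EXCLUDED}

    def test_train_fraction_within_one_example(self, folded):
        examples, _, plan = folded
        for roles in plan.assignments:
            n_train = int((roles == TRAIN).sum())
            assert abs(n_train - (2 / 3) * len(examples)) <= 1

    def test_class_balance_preserved(self, folded):
        examples, _, plan = folded
        labels = np.array([e.label for e in examples])
        global_pos = (labels == 1).sum() / len(labels)
        for roles in plan.assignments:
            tr = labels[roles == TRAIN]
            assert abs((tr == 1).sum() - global_pos * len(tr)) <= 1

    def test_no_family_or_site_overlap_between_train_and_test(self, folded):
        examples, fams, plan = folded
        for fold in range(plan.n_folds):
            tr, te, _ = fold_indices(plan, fold)
            train_fams = {fams[examples[i].mirna_id] for i in tr}
            train_sites = {examples[i].site_seq for i in tr}
            for i in te:
                assert fams[examples[i].mirna_id] not in train_fams
                assert examples[i].site_seq not in train_sites

    def test_training_families_contribute_both_classes(self, folded):
        examples, fams, plan = folded
        labels = np.array([e.label for e in examples])
        fam_arr = np.array([fams[e.mirna_id] for e in examples])
        for roles in plan.assignments:
            tr = roles == TRAIN
            exceptions = 0
            for f in set(fam_arr[tr].tolist()):
                in_train = tr & (fam_arr == f)
                has_both_globally = len(set(labels[fam_arr == f].tolist())) == 2
                if has_both_globally and len(set(labels[in_train].tolist())) < 2:
                    exceptions += 1
            assert exceptions <= 1  # at most the quota-boundary family

    def test_deterministic_given_seed(self, small_corpus):
        mirnas, _, _, examples = small_corpus
        fams = family_map(mirnas)
        p1 = make_cv_folds(examples, fams, FoldPlan(n_folds=3, seed=7))
        p2 = make_cv_folds(examples, fams, FoldPlan(n_folds=3, seed=7))
        for a, b in zip(p1.assignments, p2.assignments):
            assert np.array_equal(a, b)

    def test_missing_family_mapping_rejected(self, small_corpus):
        examples = small_corpus[3]
        with pytest.raises(ValidationError, match="family"):
            make_cv_folds(examples, {}, FoldPlan(n_folds=1))

    def test_single_class_family_confined_to_training(self):
        mirnas, _, _, examples = generate_synthetic_dataset(
            40, SyntheticGrammar(n_mirnas=4, family_size=1), seed=2
        )
        # force one miRNA's examples all-positive to create a one-class family
        skewed = [e for e in examples if not (e.mirna_id == mirnas[0].id and e.label == -1)]
        fams = family_map(mirnas)
        with pytest.warns(UserWarning, match="single class"):
            plan = make_cv_folds(skewed, fams, FoldPlan(n_folds=2, seed=1))
        fam_arr = np.array([fams[e.mirna_id] for e in skewed])
        for roles in plan.assignments:
            assert all(roles[fam_arr == fams[mirnas[0].id]] == TRAIN)


class TestExampleIO:
    def test_round_trip(self, small_corpus, tmp_path):
        examples = small_corpus[3][:25]
        path = tmp_path / "ex.tsv"
        write_examples(examples, path)
        assert read_examples(path) == examples

    def test_encode_examples_shapes(self, small_corpus):
        mirnas, _, _, examples = small_corpus
        X, y = encode_examples(examples[:10], mirnas)
        assert X.shape == (10, 280)
        assert set(y.tolist()) <= {-1, 1}
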