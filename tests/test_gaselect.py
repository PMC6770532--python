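import dataclasses

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from lncstack.gaselect import (
    GAConfig,
    GeneticFeatureSelector,
    decode,
    evolve,
    fitness,
    init_population,
    load_selection_report,
    save_selection_report,
    subset_intersection,
)

TINY = GAConfig(pop_size=12, generations=3, cv_folds=3, rf_trees=10, seed=5)


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 8))
    y = (X[:, 0] + 0.3 * rng.standard_normal(60) > 0).astype(int)
    return X, y


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(crossover_prob=1.5)
    with pytest.raises(ValueError):
        GAConfig(pop_size=5, top_n=10)
    with pytest.raises(ValueError):
        GAConfig(cv_folds=1)


def test_init_population_seeded_and_balanced():
    rng1 = np.random.default_rng(3)
    rng2 = np.random.default_rng(3)
    cfg = GAConfig(pop_size=100)
    p1 = init_population(260, cfg, rng1)
    p2 = init_population(260, cfg, rng2)
    assert np.array_equal(p1, p2)
    assert p1.shape == (100, 260)
    # mean gene count ~ Binomial(260, 0.5); 4 sigma over the population mean
    mean_ones = p1.sum(axis=1).mean()
    sigma = np.sqrt(260 * 0.25 / 100)
    assert abs(mean_ones - 130) < 4 * sigma


def test_all_zero_chromosome_has_zero_fitness(toy_data):
    X, y = toy_data
    assert fitness(np.zeros(8, dtype=np.uint8), X, y, TINY) == 0.0


def test_fitness_requires_two_classes(toy_data):
    X, _ = toy_data
    with pytest.raises(ValueError):
        fitness(np.ones(8, dtype=np.uint8), X, np.zeros(len(X)), TINY)


def test_perfect_separator_column_reaches_auc_one(toy_data):
    X, y = toy_data
    X = X.copy()
    X[:, 3] = y  # plant a perfect separator
    mask = np.zeros(8, dtype=np.uint8)
    mask[3] = 1
    assert fitness(mask, X, y, TINY) >= 0.99


def test_fitness_cache_returns_identical_value(toy_data):
    X, y = toy_data
    cache = {}
    mask = np.ones(8, dtype=np.uint8)
    v1 = fitness(mask, X, y, TINY, cache=cache)
    v2 = fitness(mask, X, y, TINY, cache=cache)
    assert v1 == v2 and len(cache) == 1


def test_fitness_equals_independent_cv_rerun(toy_data):
    """The GA's fitness must equal a from-scratch CV outside the GA."""
    X, y = toy_data
    mask = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
    got = fitness(mask.astype(np.uint8), X, y, TINY)
    Xm = X[:, mask]
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=TINY.seed)
    aucs = []
    for tr, te in skf.split(Xm, y):
        rf = RandomForestClassifier(n_estimators=10, random_state=TINY.seed)
        rf.fit(Xm[tr], y[tr])
        aucs.append(roc_auc_score(y[te], rf.predict_proba(Xm[te])[:, 1]))
    assert got == pytest.approx(np.mean(aucs))


def test_evolve_fixed_point_without_variation(toy_data):
    X, y = toy_data
    cfg = dataclasses.replace(
        TINY, crossover_prob=0.0, individual_mutation_prob=0.0, generations=4,
        top_n=12,
    )
    chrom = np.array([1, 1, 0, 0, 1, 0, 0, 1], dtype=np.uint8)
    pop = np.tile(chrom, (cfg.pop_size, 1))
    hall, history = evolve(X, y, cfg, initial_population=pop)
    assert len(hall) == 1  # only one distinct chromosome ever existed
    assert np.array_equal(hall[0][0], chrom)
    assert len(set(history["best"])) == 1


def test_evolve_reproducible_and_monotone(toy_data):
    X, y = toy_data
    h1, hist1 = evolve(X, y, TINY)
    h2, hist2 = evolve(X, y, TINY)
    assert hist1 == hist2
    assert all(np.array_equal(a[0], b[0]) and a[1] == b[1]
               for a, b in zip(h1, h2))
    assert hist1["best_ever"] == sorted(hist1["best_ever"])
    # hall of fame sorted by decreasing fitness
    fits = [f for _, f in h1]
    assert fits == sorted(fits, reverse=True)


def test_evolve_returns_top_n_subsets(toy_data):
    X, y = toy_data
    hall, _ = evolve(X, y, dataclasses.replace(TINY, top_n=10))
    assert len(hall) == 10
    keys = {m.tobytes() for m, _ in hall}
    assert len(keys) == 10  # distinct chromosomes


def test_decode_and_intersection(schema):
    zero = np.zeros(260, dtype=np.uint8)
    assert decode(zero, schema) == []
    one = np.ones(260, dtype=np.uint8)
    assert decode(one, schema) == list(schema.names)
    single = zero.copy()
    single[7] = 1
    assert decode(single, schema) == [schema.names[7]]
    assert subset_intersection([["A", "B", "C"], ["B", "C", "D"], ["C"]]) == ["C"]
    assert subset_intersection([["A"], ["B"]]) == []
    assert subset_intersection([list("AB"), list("BA")]) == ["A", "B"]


def test_selection_report_round_trip(tmp_path, toy_data, schema):
    X, y = toy_data
    # fake 260-wide masks for schema-aligned serialization
    rng = np.random.default_rng(1)
    masks = (rng.random((3, 260)) < 0.5).astype(np.uint8)
    hall = [(m, 0.9 - 0.1 * i) for i, m in enumerate(masks)]
    path = tmp_path / "subsets.json"
    save_selection_report(hall, {"best": [0.9]}, schema, TINY, path)
    back_masks, fits, report = load_selection_report(path, schema)
    assert fits == [0.9, 0.8, 0.7]
    for a, (b, _) in zip(back_masks, hall):
        assert np.array_equal(a, b)


def test_selector_estimator_api(toy_data):
    X, y = toy_data
    sel = GeneticFeatureSelector(config=TINY, random_state=9)
    sel.fit(X, y)
    assert len(sel.subsets_) == 10
    assert sel.support_.shape == (8,)
    Xt = sel.transform(X)
    assert Xt.shape == (60, sel.support_.sum())
    assert sel.config_.seed == 9
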