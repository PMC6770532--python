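"""End-to-end orchestration used by the CLI examples, the test suite
and the reproduction script.

The synthetic benchmark mirrors the intended data discipline of the
full pipeline: the hexamer table is trained on a *disjoint* batch of
transcripts (scoring sequences against a table trained on themselves
leaks label information and inflates CV estimates), GA-RF selection
runs on a small stratified selection split, and the stacked ensemble is
evaluated by 10-fold cross-validation on the full labelled set.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from sklearn.model_selection import train_test_split

from .assemble import TranscriptFeatureExtractor
from .ensemble import StackedForestClassifier
from .gaselect import DESK_PROFILE, GAConfig, evolve
from .metrics import cross_validate
from .synthdata import SynthConfig, generate_dataset

#: seed offset for the disjoint hexamer-table training batch
_HEXAMER_BATCH_OFFSET = 10_007
#: stratified subset used for GA-RF selection (paper-style independent
#: selection split, desk scale)
SELECTION_SPLIT = 200


def synthetic_features(
    cfg: SynthConfig,
    hexamer_batch_size: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a labelled synthetic dataset and its feature matrix.

    The in-frame hexamer table is trained on a separate batch drawn
    with an offset seed so that no scored transcript contributed to it.
    """
    transcripts, y = generate_dataset(cfg)
    hex_cfg = dataclasses.replace(
        cfg,
        n_coding=hexamer_batch_size,
        n_noncoding=hexamer_batch_size,
        seed=(cfg.seed + _HEXAMER_BATCH_OFFSET) % (2**31),
    )
    hex_transcripts, hex_y = generate_dataset(hex_cfg)
    extractor = TranscriptFeatureExtractor().fit(hex_transcripts, hex_y)
    X = extractor.transform(transcripts)
    return X, y


def synthetic_end_to_end(
    seed: int,
    codon_bias_strength: float = 0.75,
    n_per_class: int = 500,
    ga_config: Optional[GAConfig] = None,
    cv_folds: int = 10,
) -> dict:
    """Full pipeline on synthetic data: generate, extract, select, stack,
    cross-validate. Returns the selection hall of fame, the CV report
    and the fitted masks."""
    cfg = SynthConfig(
        n_coding=n_per_class,
        n_noncoding=n_per_class,
        codon_bias_strength=codon_bias_strength,
        seed=seed,
    )
    X, y = synthetic_features(cfg)
    ga_cfg = dataclasses.replace(ga_config or DESK_PROFILE, seed=seed)
    idx_sel, _ = train_test_split(
        np.arange(len(y)),
        train_size=min(SELECTION_SPLIT, len(y) - 2),
        stratify=y,
        random_state=seed % (2**31),
    )
    hall, history = evolve(X[idx_sel], y[idx_sel], ga_cfg)
    masks = [m.astype(bool) for m, _ in hall]
    cv = cross_validate(
        X,
        y,
        lambda: StackedForestClassifier(masks=masks, random_state=seed),
        folds=cv_folds,
        seed=seed,
    )
    return {
        "config": cfg,
        "hall": hall,
        "history": history,
        "masks": masks,
        "cv": cv,
        "X_shape": X.shape,
    }


def recovery_data(
    seed: int,
    n: int = 400,
    n_features: int = 20,
    n_informative: int = 5,
    noise: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Tabular benchmark for GA-RF recovery: standard-normal features,
    label = sign of the scaled sum of the informative block plus noise,
    so dropping any informative feature costs measurable AUC."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    signal = X[:, :n_informative].sum(axis=1) / np.sqrt(n_informative)
    y = (signal + noise * rng.standard_normal(n) > 0).astype(int)
    return X, y


def feature_recovery_benchmark(
    seed: int, ga_config: Optional[GAConfig] = None
) -> dict:
    """Run GA-RF on the recovery benchmark; report how often each
    informative feature appears among the returned subsets."""
    X, y = recovery_data(seed)
    cfg = dataclasses.replace(ga_config or DESK_PROFILE, seed=seed)
    hall, history = evolve(X, y, cfg)
    occurrences = np.sum([m[:5].astype(bool) for m, _ in hall], axis=0)
    return {
        "hall": hall,
        "history": history,
        "informative_occurrences": occurrences,
        "n_subsets": len(hall),
    }
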