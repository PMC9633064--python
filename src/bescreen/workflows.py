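"""End-to-end simulated-screen workflows.

Compositions of the simulator, quantification and statistics modules that run
a complete in-silico experiment: a null sort-seq screen (calibration), a
screen with planted protein effects (parameter recovery), a fitness time
course with a deleterious stop-in-essential class, and a sequence-context
model fit on simulated dropout. These are the workhorses of the package's
self-validation and of the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import context as ctx
from . import quantify as qnt
from . import stats as st
from .simulate import (
    EffParams,
    SimConfig,
    make_truth,
    simulate_context_dataset,
    simulate_fitness_screen,
    simulate_protein_screen,
)

_BASES = np.array(list("ACGT"))


def random_screen_library(n_guides: int, seed: int) -> pd.DataFrame:
    """A library of random protospacers/contexts for stats-level simulations."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "guide_id": [f"g{i:04d}" for i in range(n_guides)],
            "protospacer": ["".join(rng.choice(_BASES, 20)) for _ in range(n_guides)],
            "context30": ["".join(rng.choice(_BASES, 30)) for _ in range(n_guides)],
        }
    )


def _screen_count_matrix(lib, truth, cfg, seed, collapse: bool) -> qnt.CountMatrix:
    samples = simulate_protein_screen(lib, truth, cfg, seed)
    gbc = qnt.GuideBarcodeCounts(counts=samples)
    if collapse:
        gbc = qnt.collapse_all(gbc)
    controls = [f"ctrl_r{i}" for i in range(1, cfg.n_control_replicates + 1)]
    filtered, _ = qnt.apply_count_filters(gbc, controls)
    return qnt.barcode_count_matrix(filtered)


def null_screen_pvalues(
    n_guides: int = 2000,
    n_cells: int = 1_000_000,
    barcodes_per_guide: int = 1500,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a sort-seq screen with no true effects and return the
    per-guide GLM effect table (for calibration checks).

    Barcode pools are disjoint and error-free here, so the Hamming-collapse
    step is the identity and is skipped for speed.
    """
    lib = random_screen_library(n_guides, seed * 7 + 1)
    cfg = SimConfig(
        n_cells=n_cells,
        barcodes_per_guide=barcodes_per_guide,
        n_replicates=8,
        n_control_replicates=8,
    )
    truth = make_truth(lib, cfg, seed * 7 + 1)
    mat = _screen_count_matrix(lib, truth, cfg, seed * 11 + 3, collapse=False)
    highs = [f"high_r{i}" for i in range(1, 9)]
    lows = [f"low_r{i}" for i in range(1, 9)]
    return st.guide_effects_table(mat, highs, lows)


def planted_recovery_screen(
    n_guides: int = 1000,
    n_planted: int = 200,
    barcodes_per_guide: int = 100,
    n_cells: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sort-seq screen with planted protein effects, analyzed end to end.

    Half the planted effects raise protein level and half lower it
    (magnitudes in [1, 2]); effects are planted on guides whose simulated
    editing efficiency is at least 0.5. Returns the guide effect table joined
    with the ground truth.
    """
    rng = np.random.default_rng(seed + 101)
    lib = random_screen_library(n_guides, seed * 13 + 5)
    cfg = SimConfig(
        n_cells=n_cells,
        barcodes_per_guide=barcodes_per_guide,
        n_replicates=8,
        n_control_replicates=8,
    )
    truth0 = make_truth(lib, cfg, seed * 17 + 7)
    eligible = truth0.efficiency[truth0.efficiency >= 0.5].index.to_numpy()
    if eligible.size < n_planted:
        raise ValueError("not enough efficient guides to plant effects on")
    planted = rng.choice(eligible, size=n_planted, replace=False)
    magnitudes = rng.uniform(1.0, 2.0, size=n_planted)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    effects = dict(zip(planted, signs * magnitudes))
    truth = make_truth(lib, cfg, seed * 17 + 7, protein_effects=effects)

    mat = _screen_count_matrix(lib, truth, cfg, seed * 19 + 9, collapse=True)
    highs = [f"high_r{i}" for i in range(1, 9)]
    lows = [f"low_r{i}" for i in range(1, 9)]
    eff = st.guide_effects_table(mat, highs, lows)
    eff["true_effect"] = eff["guide_id"].map(lambda g: effects.get(g, 0.0))
    eff["efficiency"] = eff["guide_id"].map(truth.efficiency)
    return eff


def fitness_dropout_fraction(
    n_guides: int = 300, n_lethal: int = 100, seed: int = 0
) -> float:
    """Fraction of a simulated stop-in-essential guide class with average
    log2FC < -0.5 at the 24 h time point.

    Lethal guides carry a fitness cost of 1 per generation when edited;
    efficiencies come from sequence context, so incompletely edited cultures
    deplete only partially — mirroring the behaviour of real stop guides.
    """
    lib = random_screen_library(n_guides, seed * 23 + 1)
    cfg = SimConfig()
    rng = np.random.default_rng(seed + 31)
    truth0 = make_truth(lib, cfg, seed * 29 + 3)
    editable = truth0.efficiency[truth0.efficiency > 0].index.to_numpy()
    lethal = rng.choice(editable, size=min(n_lethal, editable.size), replace=False)
    costs = {g: 1.0 for g in lethal}
    truth = make_truth(lib, cfg, seed * 29 + 3, fitness_costs=costs)
    counts = simulate_fitness_screen(lib, truth, cfg, seed * 31 + 5)

    controls = [g for g in lib["guide_id"] if g not in costs]
    mat = qnt.control_normalized_read_matrix(counts, controls)
    sample_map = {
        f"r{r}": {tp: f"{tp}_r{r}" for tp in cfg.fitness_generations}
        for r in range(1, cfg.fitness_replicates + 1)
    }
    guide_lfc, _ = st.fitness_effects(mat, sample_map)
    return float((guide_lfc.loc[list(lethal), "t24"] < -0.5).mean())


def context_model_recovery(
    n_train: int = 1500,
    n_test: int = 600,
    effect_scale: float = 3.0,
    noise_sd: float = 0.75,
    seed: int = 0,
) -> dict:
    """Fit the position-specific k-mer lasso on simulated dropout data.

    Returns the preceding-base coefficients, the test-set squared Pearson
    correlation, and the generative R^2 (signal variance over total variance
    on the test set).
    """
    contexts, y, signal = simulate_context_dataset(
        n_train + n_test, EffParams(), effect_scale, noise_sd, seed * 37 + 11
    )
    fm = ctx.featurize_contexts(contexts)
    X_train, X_test = fm.X[:n_train], fm.X[n_train:]
    y_train, y_test = y[:n_train], y[n_train:]
    params = ctx.ContextParams(cv_folds=10, n_alphas=12, rng_seed=seed)
    model = ctx.fit_context_model(
        ctx.FeatureMatrix(X=X_train, features=fm.features), y_train, "ordinary", params
    )
    r2 = ctx.evaluate_context_model(model, X_test, y_test)
    sig_test = signal[n_train:]
    generative_r2 = float(np.var(sig_test) / np.var(y_test))
    nz = model.nonzero()
    preceding = {b: nz.get((8, 1, b), 0.0) for b in "ACGT"}
    return {
        "preceding_base_coef": preceding,
        "r2_test": float(r2),
        "r2_generative": generative_r2,
        "n_nonzero": len(nz),
    }
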