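"""End-to-end study drivers: synthetic benchmark and morphometry surveys.

These functions wire the stages together exactly the way the CLI does —
phantoms → scatter patterns → pseudo-Zernike features → Fisher selection
→ SVM — but return in-memory results, which is what the test suite and
the reproduction script want.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .classify import SVMHyperparams, evaluate, train
from .features import (
    DEFAULT_N_MAX,
    DEFAULT_N_SELECTED,
    extract_features,
    fisher_scores,
    select_features,
)
from .morphometry import compare_heights, estimate_height
from .phantoms import BAD_PARAMS, GOOD_PARAMS, generate_dataset, phantom_to_zstack
from .scattering import OpticalConfig, simulate_pattern

__all__ = ["run_benchmark", "height_survey", "height_significance_replicates"]


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def run_benchmark(
    n_good: int = 100,
    n_bad: int = 100,
    seed: int | None = 42,
    good_params=GOOD_PARAMS,
    bad_params=BAD_PARAMS,
    config: OpticalConfig = OpticalConfig(),
    n_max: int = DEFAULT_N_MAX,
    n_selected: int = DEFAULT_N_SELECTED,
    test_fraction: float = 0.3,
    hyperparams: SVMHyperparams = SVMHyperparams(),
) -> dict:
    """Run the full synthetic classification benchmark.

    Generates a balanced labeled colony set, simulates the detector
    patterns, extracts pseudo-Zernike magnitudes, Fisher-selects features
    on the *training* portion of a stratified split, trains the SVM, and
    scores the held-out portion.  Returns the evaluation report plus the
    per-class held-out recalls in percent.
    """
    seed_ph, seed_noise, seed_split = _spawn_seeds(seed, 3)
    phantoms = generate_dataset(n_good, n_bad, good_params, bad_params, seed_ph)
    noise_rng = np.random.default_rng(seed_noise)
    vectors = [
        extract_features(simulate_pattern(ph, config, seed=noise_rng),
                         n_max=n_max, source_id=str(i))
        for i, ph in enumerate(phantoms)
    ]
    labels = np.array([v.label for v in vectors])
    idx = np.arange(len(vectors))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed_split
    )
    good_train = [vectors[i] for i in train_idx if labels[i] == "good"]
    bad_train = [vectors[i] for i in train_idx if labels[i] == "bad"]
    ranking = fisher_scores(good_train, bad_train)
    selected = select_features(ranking, vectors, k=n_selected)
    model = train([selected[i] for i in train_idx], hyperparams)
    report = evaluate(model, [selected[i] for i in test_idx])
    recalls = report.per_class_recall()
    return {
        "report": report,
        "model": model,
        "ranking": ranking,
        "n_features_total": vectors[0].values.size,
        "n_features_selected": selected[0].values.size,
        "good_recall_pct": recalls.get("good", float("nan")),
        "bad_recall_pct": recalls.get("bad", float("nan")),
        "accuracy_pct": 100.0 * np.trace(report.confusion) / report.n_test,
        "n_test": report.n_test,
    }


def height_survey(
    n_per_class: int = 100,
    seed: int | None = 0,
    z_step: float = 2.0,
    good_params=GOOD_PARAMS,
    bad_params=BAD_PARAMS,
) -> dict:
    """Estimate colony heights from noiseless z-stacks for both classes."""
    phantoms = generate_dataset(n_per_class, n_per_class, good_params, bad_params, seed)
    heights = {"good": [], "bad": []}
    for ph in phantoms:
        stack = phantom_to_zstack(ph, z_step=z_step)
        heights[ph.label].append(estimate_height(stack))
    good = np.array(heights["good"])
    bad = np.array(heights["bad"])
    return {
        "good_heights": good,
        "bad_heights": bad,
        "good_mean": float(good.mean()),
        "good_se": float(good.std(ddof=1) / np.sqrt(good.size)),
        "bad_mean": float(bad.mean()),
        "bad_se": float(bad.std(ddof=1) / np.sqrt(bad.size)),
    }


def height_significance_replicates(
    n_replicates: int = 100,
    n_per_class: int = 18,
    seed: int | None = 0,
    z_step: float = 2.0,
    good_params=GOOD_PARAMS,
    bad_params=BAD_PARAMS,
    alpha: float = 0.01,
    variant: str = "student",
) -> float:
    """Fraction of replicate experiments whose height t-test has p < alpha.

    Each replicate draws fresh colonies per class, measures their heights
    from noiseless z-stacks, and runs the two-sample t-test.
    """
    seeds = _spawn_seeds(seed, n_replicates)
    hits = 0
    for s in seeds:
        survey = height_survey(n_per_class, s, z_step, good_params, bad_params)
        result = compare_heights(survey["good_heights"], survey["bad_heights"], variant)
        hits += result.p_value < alpha
    return hits / n_replicates
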