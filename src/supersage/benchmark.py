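"""Validation experiments run against the generator's ground truth.

These are the package's calibration/recovery experiments: the type-I error
of the count test under a pure sampling null, and sensitivity / empirical
FDR of UR-DR detection on composition-balanced spike-in datasets.  Both are
deterministic given their seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from supersage import de
from supersage.simulate import (
    SimulationConfig,
    generate_genome,
    generate_transcripts,
    simulate_libraries,
    spike_recovery_config,
)
from supersage.tags import UnitagTable, exclude_singlets, normalize_tpm


def null_type1_rate(
    n_tags: int = 10_000,
    depth: int = 1_000_000,
    sigma: float = 1.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of tags called significant under the null.

    Two libraries with identical per-tag means (lognormal abundance profile
    summing to ``depth``) and pure Poisson sampling — the count model the
    conditional test itself assumes.  The discrete test is conservative, so
    the fraction with p <= alpha should not exceed alpha by more than
    binomial noise.
    """
    rng = np.random.default_rng(seed)
    shares = rng.lognormal(0.0, sigma, n_tags)
    shares /= shares.sum()
    mu = shares * depth
    x = rng.poisson(mu)
    y = rng.poisson(mu)
    keep = (x >= 2) | (y >= 2)  # mirror the singlet-exclusion rule
    p = de.ac_pvalue(x[keep], int(x.sum()), y[keep], int(y.sum()))
    return {
        "rate": float((p <= alpha).mean()),
        "n_tags_tested": int(keep.sum()),
        "alpha": alpha,
    }


def _normalised_tables(counts: dict[str, dict[str, int]]) -> dict[str, UnitagTable]:
    return {
        lib: normalize_tpm(exclude_singlets(UnitagTable(library=lib, counts=c)))
        for lib, c in counts.items()
    }


def simulate_and_contrast(
    config: SimulationConfig, contrasts: list[tuple[str, str]], alpha: float = 0.05
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate a dataset and run the requested contrasts against it."""
    genome = generate_genome(config)
    transcripts = generate_transcripts(genome, config)
    counts, truth = simulate_libraries(transcripts, config)
    tables = _normalised_tables(counts)
    results = {}
    for lib_a, lib_b in contrasts:
        result, _ = de.run_contrast(tables[lib_a], tables[lib_b], alpha)
        results[f"{lib_a}_vs_{lib_b}"] = result
    return results, truth


def spike_recovery(
    seeds: tuple[int, ...] = (101, 102, 103),
    min_baseline_tpm: float = 50.0,
    min_abs_fc: float = 4.0,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity and empirical FDR of UR/DR detection on spike-in data.

    Runs the deep spike-in benchmark (1e6-tag libraries, paired
    composition-balanced spikes) for each seed, evaluates the two
    stress-vs-control contrasts, and pools.  Sensitivity is the fraction of
    unitags with true |FC| >= ``min_abs_fc`` (and truth baseline abundance
    >= ``min_baseline_tpm``) detected with the correct direction; FDR is the
    fraction of UR/DR calls, over the same abundance-eligible set, whose
    truth class is ns.
    """
    tp_strong = 0
    n_strong = 0
    false_calls = 0
    n_calls = 0
    for seed in seeds:
        config = spike_recovery_config(seed=seed)
        results, truth = simulate_and_contrast(
            config, [("TS", "TC"), ("SS", "SC")], alpha
        )
        truth = truth.set_index("tag")
        for contrast, result in results.items():
            merged = result.join(
                truth[
                    ["baseline_tpm", f"true_fc_{contrast}", f"true_class_{contrast}"]
                ],
                on="tag",
                how="inner",
            )
            eligible = merged[merged.baseline_tpm >= min_baseline_tpm]
            strong = eligible[eligible[f"true_fc_{contrast}"].abs() >= min_abs_fc]
            tp_strong += int(
                (strong.regulation == strong[f"true_class_{contrast}"]).sum()
            )
            n_strong += len(strong)
            calls = eligible[eligible.regulation != "ns"]
            n_calls += len(calls)
            false_calls += int((calls[f"true_class_{contrast}"] == "ns").sum())
    return {
        "sensitivity": tp_strong / n_strong if n_strong else float("nan"),
        "fdr": false_calls / n_calls if n_calls else float("nan"),
        "n_strong_spikes": n_strong,
        "n_calls": n_calls,
        "seeds": list(seeds),
    }
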