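"""Selection-frequency validation of the group-Lasso pipeline.

Two resampling scenarios, each run at several sample sizes N with B
replicates:

* **bootstrap** — draw N records with replacement, re-encode,
  re-standardize, re-tune lambda by CV and record which covariate groups the
  selected model keeps.  Robust risk factors are selected in a large
  fraction of replicates.
* **permutation** — draw a stratified subsample of N records that preserves
  the overall elevated/non-elevated proportion, then randomly permute the
  outcome labels within the subsample (class counts fixed exactly) before
  running the identical pipeline.  Any selection on such data is spurious,
  so no group's frequency should stand out; this is the negative control.

Replicate seeds are spawned from the master seed by a counter, so results
are reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .encode import encode_dummies
from .model_selection import fit_cv_tuned
from .simulate import SurveyDataset


@dataclass
class StabilityResult:
    """Per-group selection frequencies over resampling replicates."""

    scenario: str  # "bootstrap" or "permutation"
    sample_size: int
    replicates: int
    frequencies: dict  # group name -> selected fraction in [0, 1]
    selection_counts: dict  # group name -> integer count
    selected_lambdas: list
    seed: int
    n_redrawn: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "N": self.sample_size,
                "group": list(self.frequencies),
                "frequency": list(self.frequencies.values()),
            }
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "sample_size": self.sample_size,
            "replicates": self.replicates,
            "frequencies": self.frequencies,
            "selected_lambdas": [float(v) for v in self.selected_lambdas],
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
        }

    def top_groups(self, k: int = 2) -> list:
        order = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return [name for name, _ in order[:k]]


_SCENARIO_CODE = {"bootstrap": 1, "permutation": 2}


def _replicate_rng(master_seed: int, scenario: str, b: int) -> np.random.Generator:
    # counter-derived replicate seed: reproducible and order-independent
    return np.random.default_rng([master_seed, _SCENARIO_CODE[scenario], b])


def _run_replicate(
    dataset: SurveyDataset,
    idx: np.ndarray,
    permute_y_rng: np.random.Generator | None,
    cv_kwargs: dict,
    cv_seed: int,
):
    sub = SurveyDataset(dataset.data.iloc[idx].reset_index(drop=True), dataset.codebook)
    # resampling duplicates ids; re-key so encoding invariants hold
    sub.data = sub.data.assign(child_id=np.arange(1, len(sub.data) + 1))
    enc = encode_dummies(sub, drop_constant_columns=True)
    if permute_y_rng is not None:
        enc.y = permute_y_rng.permutation(enc.y)
    if enc.y.min() == enc.y.max():
        return None  # single-class replicate; caller redraws
    # copies of the same source record must share a CV fold, or duplicated
    # observations leak across the split and CV overfits lambda
    source = np.asarray(idx)[enc.row_ids - 1]
    cv, fit, _ = fit_cv_tuned(enc, seed=cv_seed, fold_groups=source, **cv_kwargs)
    return cv, fit


def _stability(
    dataset: SurveyDataset,
    scenario: str,
    sample_size: int,
    replicates: int,
    seed: int,
    cv_kwargs: dict,
    max_redraws: int = 50,
) -> StabilityResult:
    all_groups = [e.name for e in dataset.codebook]
    counts = {g: 0 for g in all_groups}
    lambdas = []
    n = dataset.n
    y_all = None
    if scenario == "permutation":
        from .encode import classify_bll

        bll = dataset.data["bll"].to_numpy(dtype=float)
        keep = ~np.isnan(bll)
        y_all = np.zeros(n, dtype=int)
        y_all[keep] = classify_bll(bll[keep])
        hi_idx = np.flatnonzero(keep & (y_all == 1))
        lo_idx = np.flatnonzero(keep & (y_all == 0))
        prop_hi = len(hi_idx) / (len(hi_idx) + len(lo_idx))

    n_redrawn = 0
    for b in range(replicates):
        rng = _replicate_rng(seed, scenario, b)
        cv_seed = int(rng.integers(2**31 - 1))
        out = None
        for attempt in range(max_redraws):
            if scenario == "bootstrap":
                idx = rng.integers(0, n, size=sample_size)
                out = _run_replicate(dataset, idx, None, cv_kwargs, cv_seed)
            else:
                n_hi = int(round(sample_size * prop_hi))
                n_hi = min(max(n_hi, 1), sample_size - 1)
                take_hi = rng.choice(hi_idx, size=n_hi, replace=n_hi > len(hi_idx))
                take_lo = rng.choice(
                    lo_idx, size=sample_size - n_hi, replace=(sample_size - n_hi) > len(lo_idx)
                )
                idx = np.concatenate([take_hi, take_lo])
                out = _run_replicate(dataset, idx, rng, cv_kwargs, cv_seed)
            if out is not None:
                break
            n_redrawn += 1
        if out is None:
            raise RuntimeError(
                f"{scenario} replicate {b}: could not draw a two-class sample"
            )
        cv, fit = out
        for g in fit.active_groups:
            counts[g] += 1
        lambdas.append(cv.selected_lambda)

    freqs = {g: counts[g] / replicates for g in all_groups}
    return StabilityResult(
        scenario=scenario,
        sample_size=sample_size,
        replicates=replicates,
        frequencies=freqs,
        selection_counts=counts,
        selected_lambdas=lambdas,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def bootstrap_stability(
    dataset: SurveyDataset,
    sample_size: int,
    replicates: int = 100,
    seed: int = 0,
    n_lambda: int = 40,
    lambda_min_ratio: float = 0.01,
    k: int = 10,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> StabilityResult:
    """Selection frequencies over B bootstrap resamples of size N."""
    cv_kwargs = dict(
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio, k=k, tol=tol, max_iter=max_iter
    )
    return _stability(dataset, "bootstrap", sample_size, replicates, seed, cv_kwargs)


def permutation_stability(
    dataset: SurveyDataset,
    sample_size: int,
    replicates: int = 100,
    seed: int = 0,
    n_lambda: int = 40,
    lambda_min_ratio: float = 0.01,
    k: int = 10,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> StabilityResult:
    """Selection frequencies on label-permuted stratified subsamples of size N."""
    cv_kwargs = dict(
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio, k=k, tol=tol, max_iter=max_iter
    )
    return _stability(dataset, "permutation", sample_size, replicates, seed, cv_kwargs)


def run_scenarios(
    dataset: SurveyDataset,
    sample_sizes=(150, 200, 250),
    replicates: int = 100,
    seed: int = 0,
    **cv_kwargs,
) -> pd.DataFrame:
    """All scenarios x sample sizes through the identical code path; tidy table."""
    tables = []
    for scenario_fn in (bootstrap_stability, permutation_stability):
        for n_s in sample_sizes:
            res = scenario_fn(dataset, n_s, replicates=replicates, seed=seed, **cv_kwargs)
            tables.append(res.table())
    return pd.concat(tables, ignore_index=True)


def excess_selection_pvalues(result: StabilityResult) -> dict:
    """Per-group one-sided binomial P(X >= count | B, mean frequency).

    Under exchangeable (null) selection no group should significantly exceed
    the across-group mean frequency; used as the permutation-scenario check.
    """
    mean_freq = float(np.mean(list(result.frequencies.values())))
    mean_freq = min(max(mean_freq, 1e-12), 1.0 - 1e-12)
    out = {}
    for g, c in result.selection_counts.items():
        out[g] = float(
            binomtest(c, result.replicates, mean_freq, alternative="greater").pvalue
        )
    return out
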