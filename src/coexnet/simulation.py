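"""Synthetic expression data with planted co-expression modules.

The generative model is one latent factor per module: for module m with
target within-module correlation rho, each sample draws a factor value
f_m ~ N(0, 1) and each member feature is

    x = lambda * f_m + noise_sd * eps,   lambda = noise_sd * sqrt(rho / (1 - rho)),

with eps ~ N(0, 1), so the expected correlation between any two member
features is exactly rho. Background features are pure noise. Traits are
linear (or thresholded binary) responses to chosen factors with a
stated effect size (the factor-trait correlation). An optional shared
component across factors (``factor_correlation``) produces correlated
modules for testing module merging; ``first_feature_loading_scale``
boosts the first feature of each module to plant a known hub.

All randomness derives from one master seed through numpy's
SeedSequence spawning, so sub-streams (factors, noise, traits) are
independently reproducible.

Defaults (50 samples, three modules of 100 features, 50 background
features, rho = 0.7, unit noise) mirror the conditions used throughout
the test bench.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from coexnet.core_data import ExpressionDataset
from coexnet.module_detection import ModuleAssignment


@dataclass
class TraitLink:
    """A sample trait driven by one module's latent factor."""

    module_index: int  # 0-based index into module_sizes
    name: str
    effect: float  # target |correlation| between factor and trait, in (0, 1]
    binary: bool = False


@dataclass
class SimulationDesign:
    n_samples: int = 50
    module_sizes: Sequence[int] = (100, 100, 100)
    n_background: int = 50
    within_module_cor: float | Sequence[float] = 0.7
    noise_sd: float = 1.0
    trait_links: Sequence[TraitLink] = field(default_factory=list)
    factor_correlation: float = 0.0
    first_feature_loading_scale: float = 1.0
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_features(self) -> int:
        return int(sum(self.module_sizes)) + self.n_background

    def rho(self, m: int) -> float:
        if np.isscalar(self.within_module_cor):
            return float(self.within_module_cor)  # type: ignore[arg-type]
        return float(self.within_module_cor[m])  # type: ignore[index]

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        for m in range(self.n_modules):
            if not 0.0 < self.rho(m) < 1.0:
                raise ValueError("within_module_cor must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.factor_correlation < 1.0:
            raise ValueError("factor_correlation must be in [0, 1)")
        for link in self.trait_links:
            if not 0 <= link.module_index < self.n_modules:
                raise ValueError(f"trait {link.name!r} links to unknown module {link.module_index}")
            if not 0.0 < link.effect <= 1.0:
                raise ValueError("trait effect sizes must be in (0, 1]")


def simulate_expression(
    design: SimulationDesign,
) -> tuple[ExpressionDataset, pd.Series, pd.DataFrame]:
    """Draw one dataset from the design.

    Returns ``(dataset, true_labels, true_factors)``: the expression
    dataset (traits attached as sample metadata), the planted feature ->
    module label map (0 = background), and the modules x samples latent
    factor matrix.
    """
    design.validate()
    ss = np.random.SeedSequence(design.seed)
    rng_factors, rng_noise, rng_traits = (np.random.default_rng(s) for s in ss.spawn(3))

    n, p, M = design.n_samples, design.n_features, design.n_modules
    sample_ids = [f"s{i+1:03d}" for i in range(n)]
    feature_ids = [f"g{j+1:05d}" for j in range(p)]

    raw = rng_factors.standard_normal((n, M))
    if design.factor_correlation > 0 and M > 1:
        shared = rng_factors.standard_normal((n, 1))
        c = design.factor_correlation
        factors = np.sqrt(1.0 - c) * raw + np.sqrt(c) * shared
    else:
        factors = raw

    X = np.empty((n, p))
    labels = np.zeros(p, dtype=int)
    col = 0
    for m, size in enumerate(design.module_sizes):
        rho = design.rho(m)
        lam = design.noise_sd * np.sqrt(rho / (1.0 - rho))
        loadings = np.full(size, lam)
        if size > 0:
            loadings[0] *= design.first_feature_loading_scale
        eps = rng_noise.standard_normal((n, size))
        X[:, col : col + size] = factors[:, [m]] * loadings + design.noise_sd * eps
        labels[col : col + size] = m + 1
        col += size
    if design.n_background:
        X[:, col:] = design.noise_sd * rng_noise.standard_normal((n, design.n_background))

    meta = pd.DataFrame(index=pd.Index(sample_ids, name="id"))
    for link in design.trait_links:
        f = factors[:, link.module_index]
        e = link.effect
        latent = e * f + np.sqrt(max(1.0 - e * e, 0.0)) * rng_traits.standard_normal(n)
        if link.binary:
            meta[link.name] = np.where(latent > np.median(latent), "case", "control")
        else:
            meta[link.name] = latent

    ds = ExpressionDataset(
        matrix=pd.DataFrame(X, index=sample_ids, columns=feature_ids),
        sample_meta=meta,
    )
    true_labels = pd.Series(labels, index=pd.Index(feature_ids, name="feature_id"), name="module")
    true_factors = pd.DataFrame(
        factors.T, index=pd.RangeIndex(1, M + 1, name="module"), columns=sample_ids
    )
    return ds, true_labels, true_factors


def evaluate_recovery(
    true_labels: pd.Series,
    detected: ModuleAssignment | pd.Series,
) -> dict:
    """Adjusted Rand index and per-planted-module best-match Jaccard.

    Background/unassigned (label 0) counts as its own class in the ARI.
    The two label maps must cover the same feature universe.
    """
    det = detected.labels if isinstance(detected, ModuleAssignment) else detected
    if set(true_labels.index) != set(det.index):
        raise ValueError("true and detected labels cover different feature universes")
    det = det.reindex(true_labels.index)
    ari = float(adjusted_rand_score(true_labels.to_numpy(), det.to_numpy()))
    best_jaccard: dict[int, float] = {}
    det_sets = {
        int(l): set(det.index[det == l]) for l in det.unique() if l != 0
    }
    for m in sorted(l for l in true_labels.unique() if l != 0):
        truth = set(true_labels.index[true_labels == m])
        best = 0.0
        for s in det_sets.values():
            j = len(truth & s) / len(truth | s)
            best = max(best, j)
        best_jaccard[int(m)] = best
    n_detected = len(det_sets)
    return {
        "ari": ari,
        "best_match_jaccard": best_jaccard,
        "n_modules_detected": n_detected,
    }
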