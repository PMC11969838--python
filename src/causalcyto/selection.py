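"""Causal factor selection against a class label.

Flattened CNN feature maps (or any feature table) are treated as candidate
causal factors of the label y.  Each factor can be a cause of y, an effect
of y, or independent of y.  Selection runs in two stages:

1. *Marginal screening* — an HSIC permutation test of each factor against y
   (delta kernel on y); factors with p >= alpha are removed as independent
   of the label.

2. *Cause-pair detection* — for every unordered pair of surviving factors,
   a marginal HSIC test of the pair and a conditional KCI test of the pair
   given y.  Two factors that are causes of y form a collider (X -> y <- Z):
   conditioning on their common effect *induces* dependence between them, so
   a pair is flagged as causes of y when its dependence is strengthened
   after conditioning (p_cond < p_marg) and the conditional dependence is
   significant (p_cond < alpha).  Pair tests are independent work items;
   seeds are derived from sorted factor ids so the outcome does not depend
   on column order or execution order.

Downstream fusion consumes all *kept* factors; the cause-pair flags are an
interpretability output identifying which kept factors act as causes rather
than effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .independence import KernelConfig, hsic_test, kci_test

__all__ = [
    "FactorTable",
    "CausalFactorSet",
    "SelectionConfig",
    "screen_independent_factors",
    "detect_cause_pairs",
    "select_causal_factors",
]

log = logging.getLogger(__name__)


@dataclass
class FactorTable:
    """n_samples x n_factors matrix of candidate factors plus the label y."""

    values: np.ndarray
    factor_ids: Sequence[str]
    label: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.label = np.asarray(self.label).ravel()
        if self.values.ndim != 2:
            raise ValidationError("factor values must be a 2-D matrix")
        if self.values.shape[0] != self.label.shape[0]:
            raise ValidationError("label length must match sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("factor values contain non-finite entries")
        if np.unique(self.label).size < 2:
            raise ValidationError("label must take at least 2 distinct values")
        if self.values.shape[1] != len(self.factor_ids):
            raise ValidationError("factor_ids length must match column count")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "y") -> "FactorTable":
        cols = [c for c in df.columns if c != label_col]
        return cls(
            values=df[cols].to_numpy(dtype=float),
            factor_ids=list(cols),
            label=df[label_col].to_numpy(),
        )

    def column(self, factor_id: str) -> np.ndarray:
        return self.values[:, list(self.factor_ids).index(factor_id)]


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    n_permutations: int = 199
    seed: int = 0
    adjust: str | None = None  # None (raw per-test alpha) or "bh"
    detect_pairs: bool = True
    strict_marginal_gate: bool = False  # additionally require p_marg >= alpha
    pair_max_n: int | None = None  # seeded subsample size for pair tests
    kernel: KernelConfig = field(default_factory=KernelConfig)


@dataclass
class CausalFactorSet:
    """Role assignment of every factor with a full audit trail."""

    kept: list[str]
    removed: list[str]
    cause_pairs: set[frozenset]
    per_factor: dict[str, dict]
    alpha: float
    seed: int

    def cause_members(self) -> set[str]:
        return set().union(*self.cause_pairs) if self.cause_pairs else set()

    def to_json(self, path=None) -> str:
        payload = {
            "kept": sorted(self.kept),
            "removed": sorted(self.removed),
            "cause_pairs": sorted(sorted(p) for p in self.cause_pairs),
            "per_factor": {k: self.per_factor[k] for k in sorted(self.per_factor)},
            "alpha": self.alpha,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections."""
    m = pvals.size
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1) / m)
    below = pvals[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        reject[order[: np.max(np.flatnonzero(below)) + 1]] = True
    return reject


def screen_independent_factors(
    table: FactorTable,
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int = 0,
    adjust: str | None = None,
    kernel: KernelConfig | None = None,
):
    """Marginal HSIC screen of every factor against the label.

    Returns ``(kept_ids, removed_ids, p_values)`` where p_values maps each
    factor id to its marginal permutation p-value.  Per-factor seeds are
    ``seed + rank`` with rank taken in sorted-id order, so the outcome is
    invariant to column permutation; a constant column is removed outright
    with p = 1.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    kernel = kernel or KernelConfig()
    ids = list(table.factor_ids)
    rank = {f: r for r, f in enumerate(sorted(ids))}
    pvals = {}
    for j, fid in enumerate(ids):
        col = table.values[:, j]
        if np.ptp(col) == 0:
            log.info("factor %s is constant; removed with p = 1", fid)
            pvals[fid] = 1.0
            continue
        res = hsic_test(
            col,
            table.label.astype(float),
            n_permutations=n_permutations,
            seed=seed + rank[fid],
            config=kernel,
            y_kind="discrete",
        )
        pvals[fid] = res.p_value
    parr = np.array([pvals[f] for f in ids])
    if adjust == "bh":
        keep_mask = _bh_reject(parr, alpha)
    else:
        keep_mask = parr < alpha
    kept = [f for f, k in zip(ids, keep_mask) if k]
    removed = [f for f, k in zip(ids, keep_mask) if not k]
    return kept, removed, pvals


def _pair_seed(base: int, rank_i: int, rank_j: int, n: int) -> int:
    # stable under column permutation: ranks come from sorted factor ids
    return int(base + 100_003 + rank_i * n + rank_j) % (2**31 - 1)


def detect_cause_pairs(
    table: FactorTable,
    kept: Sequence[str],
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int = 0,
    strict_marginal_gate: bool = False,
    max_n: int | None = None,
    kernel: KernelConfig | None = None,
):
    """Flag kept-factor pairs whose dependence strengthens given the label.

    For each unordered pair the marginal HSIC p-value and the conditional
    KCI p-value (given y) are compared; the pair is flagged iff
    ``p_cond < p_marg`` and ``p_cond < alpha``.  With
    ``strict_marginal_gate=True`` the classic collider signature is also
    required: the pair must look marginally independent (p_marg >= alpha).

    ``max_n`` subsamples rows (seeded) before testing to bound the
    O(n_permutations * n^2) cost per pair.

    Returns ``(cause_pairs, evidence)`` where evidence maps each tested pair
    to its p-values and statistics.
    """
    kernel = kernel or KernelConfig()
    kept_sorted = sorted(kept)
    if len(kept_sorted) < 2:
        log.info("fewer than 2 kept factors; no pairs to test")
        return set(), {}
    rank = {f: r for r, f in enumerate(kept_sorted)}
    rows = np.arange(table.values.shape[0])
    if max_n is not None and rows.size > max_n:
        sub_rng = np.random.default_rng(seed + 7)
        rows = np.sort(sub_rng.choice(rows, size=max_n, replace=False))
    y = table.label[rows].astype(float)
    cols = {f: table.column(f)[rows] for f in kept_sorted}

    pairs, evidence = set(), {}
    m = len(kept_sorted)
    for a in range(m):
        for b in range(a + 1, m):
            fi, fj = kept_sorted[a], kept_sorted[b]
            ps = _pair_seed(seed, rank[fi], rank[fj], m)
            marg = hsic_test(
                cols[fi], cols[fj], n_permutations=n_permutations, seed=ps,
                config=kernel,
            )
            cond = kci_test(
                cols[fi], cols[fj], y, n_permutations=n_permutations, seed=ps + 1,
                config=kernel,
            )
            flagged = cond.p_value < marg.p_value and cond.p_value < alpha
            if strict_marginal_gate:
                flagged = flagged and marg.p_value >= alpha
            key = frozenset((fi, fj))
            evidence[key] = {
                "p_marginal": marg.p_value,
                "p_conditional": cond.p_value,
                "stat_marginal": marg.statistic,
                "stat_conditional": cond.statistic,
                "seed": ps,
                "flagged": flagged,
            }
            if flagged:
                pairs.add(key)
    return pairs, evidence


def select_causal_factors(
    table: FactorTable, config: SelectionConfig | None = None
) -> CausalFactorSet:
    """Run the full two-stage selection and return the factor-role set."""
    config = config or SelectionConfig()
    kept, removed, pvals = screen_independent_factors(
        table,
        alpha=config.alpha,
        n_permutations=config.n_permutations,
        seed=config.seed,
        adjust=config.adjust,
        kernel=config.kernel,
    )
    per_factor = {f: {"p_marginal_vs_label": pvals[f]} for f in table.factor_ids}
    cause_pairs: set[frozenset] = set()
    if config.detect_pairs:
        cause_pairs, evidence = detect_cause_pairs(
            table,
            kept,
            alpha=config.alpha,
            n_permutations=config.n_permutations,
            seed=config.seed,
            strict_marginal_gate=config.strict_marginal_gate,
            max_n=config.pair_max_n,
            kernel=config.kernel,
        )
        for key, rec in evidence.items():
            for f in key:
                per_factor[f].setdefault("pair_tests", []).append(
                    {"pair": sorted(key), **{k: rec[k] for k in
                     ("p_marginal", "p_conditional", "flagged")}}
                )
    return CausalFactorSet(
        kept=kept,
        removed=removed,
        cause_pairs=cause_pairs,
        per_factor=per_factor,
        alpha=config.alpha,
        seed=config.seed,
    )
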