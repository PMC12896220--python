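r"""Shapley-value factor attribution for a fixed prediction model.

For an instance x, feature coalition S and background rows b, the value
function is the interventional expectation

    v(S) = mean_b f(x_S, b_{~S})

i.e. features in S are fixed to the instance's values and the rest are
replaced by background values; v(full set) is the model's probability at x
and v(empty set) the mean probability over the background.  Shapley values

    phi_i = sum_{S subset N\{i}} |S|! (|N|-|S|-1)! / |N|!  [v(S+i) - v(S)]

are computed by exact subset enumeration for small feature counts (the test
oracle) and by uniform-permutation sampling of marginal contributions at
full scale (unbiased, with Monte-Carlo standard errors).  Positive phi
pushes the prediction toward the depressed class; attribution is on the
class-1 probability scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

EXACT_LIMIT = 15  # 2^d enumeration beyond this is refused
DEFAULT_PERMUTATIONS = 200


PredictFn = Callable[[np.ndarray], np.ndarray]


def _as_predict_fn(model) -> PredictFn:
    if callable(model):
        return model
    from .model import predict_proba_batched

    return lambda rows: predict_proba_batched(rows, model)


@dataclass
class CoalitionValue:
    """Interventional value function v(S) for one instance."""

    predict: PredictFn
    x: np.ndarray
    background: np.ndarray
    chunk: int = 4096

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        self.background = np.atleast_2d(np.asarray(self.background, dtype=np.float64))
        if self.background.shape[0] == 0:
            raise ValueError("background must be non-empty")
        if self.background.shape[1] != self.x.shape[0]:
            raise ValueError("background width != instance width")

    @property
    def d(self) -> int:
        return self.x.shape[0]

    def values(self, masks: np.ndarray) -> np.ndarray:
        """v(S) for a stack of boolean masks (m, d), batched over the model."""
        masks = np.atleast_2d(np.asarray(masks, dtype=bool))
        m = masks.shape[0]
        B = self.background.shape[0]
        out = np.empty(m)
        rows_per = max(1, self.chunk // B)
        for start in range(0, m, rows_per):
            blk = masks[start:start + rows_per]           # (mb, d)
            hyb = np.where(blk[:, None, :], self.x, self.background[None, :, :])
            preds = self.predict(hyb.reshape(-1, self.d))
            out[start:start + rows_per] = preds.reshape(len(blk), B).mean(axis=1)
        return out

    def __call__(self, S: Sequence[int]) -> float:
        mask = np.zeros(self.d, dtype=bool)
        mask[list(S)] = True
        return float(self.values(mask[None, :])[0])


def value_function(model, x, S: Sequence[int], background) -> float:
    """Convenience wrapper: v(S) for one coalition."""
    return CoalitionValue(_as_predict_fn(model), x, background)(S)


@dataclass
class AttributionResult:
    phi: np.ndarray                 # (n_samples, n_columns)
    base_value: float               # v(empty set)
    columns: list[str]
    estimator: str                  # "exact" | "permutation"
    config: dict = field(default_factory=dict)
    standard_errors: np.ndarray | None = None

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)


def exact_shapley(value_fn: CoalitionValue, d: int | None = None,
                  limit: int = EXACT_LIMIT) -> np.ndarray:
    """phi by full 2^d subset enumeration with the factorial weights."""
    d = value_fn.d if d is None else d
    if d > limit:
        raise ValueError(
            f"exact enumeration refused for d={d} > {limit}; use sampled_shapley")
    masks = ((np.arange(2 ** d)[:, None] >> np.arange(d)) & 1).astype(bool)
    v = value_fn.values(masks)
    sizes = masks.sum(axis=1)
    fact = np.array([math.factorial(k) for k in range(d + 1)], dtype=np.float64)
    denom = fact[d]
    phi = np.zeros(d)
    for i in range(d):
        without = ~masks[:, i]
        s = sizes[without]
        w = fact[s] * fact[d - s - 1] / denom
        phi[i] = float(np.sum(w * (v[np.flatnonzero(without) | (1 << i)]
                                   - v[without])))
    return phi


def sampled_shapley(
    value_fn: CoalitionValue,
    M: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling estimate of phi plus Monte-Carlo SEs.

    Averages marginal contributions f(pred + i) - f(pred) over M feature
    orderings; unbiased for the exact Shapley value.  Orderings are drawn
    in antithetic pairs (each uniform permutation together with its
    reversal), which preserves unbiasedness and reduces variance for
    close-to-additive models.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    d = value_fn.d
    rng = np.random.default_rng(seed)
    perms = []
    while len(perms) < M:
        perm = rng.permutation(d)
        perms.append(perm)
        if len(perms) < M:
            perms.append(perm[::-1])
    contribs = np.empty((M, d))
    for m, perm in enumerate(perms):
        prefix = np.zeros((d + 1, d), dtype=bool)
        for j, col in enumerate(perm):
            prefix[j + 1] = prefix[j]
            prefix[j + 1, col] = True
        v = value_fn.values(prefix)
        contribs[m, perm] = np.diff(v)
    phi = contribs.mean(axis=0)
    se = (contribs.std(axis=0, ddof=1) / np.sqrt(M)) if M > 1 else np.full(d, np.nan)
    return phi, se


def attribute_dataset(
    model,
    rows: np.ndarray,
    background: np.ndarray,
    columns: Sequence[str],
    M: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    limit: int = EXACT_LIMIT,
    estimator: str = "auto",
    evaluation_rows: np.ndarray | None = None,
) -> AttributionResult:
    """Per-row Shapley attributions for a batch of instances.

    When *evaluation_rows* (e.g. the test partition) is given, a warning is
    raised if any background row also appears there — the explanation
    reference should not leak evaluation data.
    """
    predict = _as_predict_fn(model)
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if evaluation_rows is not None:
        ev = {r.tobytes() for r in np.atleast_2d(
            np.asarray(evaluation_rows, dtype=np.float64))}
        if any(b.tobytes() in ev for b in background):
            warnings.warn(
                "background contains evaluation rows; the explanation "
                "reference leaks test data", stacklevel=2)
    d = rows.shape[1]
    if estimator == "auto":
        estimator = "exact" if d <= limit else "permutation"
    base = float(predict(background).mean())
    phi = np.empty((rows.shape[0], d))
    ses = np.zeros_like(phi)
    child_seeds = np.random.SeedSequence(seed).generate_state(rows.shape[0]) % (2 ** 31)
    for r in range(rows.shape[0]):
        vf = CoalitionValue(predict, rows[r], background)
        if estimator == "exact":
            phi[r] = exact_shapley(vf, limit=limit)
        else:
            phi[r], ses[r] = sampled_shapley(vf, M=M, seed=int(child_seeds[r]))
    return AttributionResult(
        phi, base, list(columns), estimator,
        config={"M": M, "background_size": int(background.shape[0]),
                "seed": seed, "limit": limit},
        standard_errors=ses if estimator == "permutation" else None,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def parent_factor(column: str) -> str:
    """Map an encoded column name back to its raw factor ("city=Delhi" -> "city")."""
    return column.split("=", 1)[0]


def global_summary(result: AttributionResult,
                   values: np.ndarray | None = None) -> pd.DataFrame:
    """Factors ranked by mean |phi| (descending), with mean signed phi and,
    when the row values are supplied, the phi-vs-value correlation."""
    mean_abs = result.mean_abs()
    if np.allclose(mean_abs, 0):
        warnings.warn("all attributions are zero; ranking is empty of signal",
                      stacklevel=2)
    df = pd.DataFrame({
        "column": result.columns,
        "factor": [parent_factor(c) for c in result.columns],
        "mean_abs_phi": mean_abs,
        "mean_phi": result.phi.mean(axis=0),
    })
    if values is not None:
        values = np.atleast_2d(values)
        df["phi_value_corr"] = [
            _corr(values[:, j], result.phi[:, j]) for j in range(len(result.columns))
        ]
        df["phi_value_slope"] = [
            _slope(values[:, j], result.phi[:, j]) for j in range(len(result.columns))
        ]
    df = df.sort_values(["mean_abs_phi", "column"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def beeswarm_export(result: AttributionResult, values: np.ndarray) -> pd.DataFrame:
    """Long-format (sample, factor, phi, value) table for beeswarm plots."""
    values = np.atleast_2d(values)
    n, d = result.phi.shape
    return pd.DataFrame({
        "sample": np.repeat(np.arange(n), d),
        "factor": np.tile(np.asarray(result.columns, dtype=object), n),
        "phi": result.phi.ravel(),
        "value": values.ravel(),
    })


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of phi on the factor value; unlike the
    correlation it carries the magnitude of the effect."""
    vx = np.var(x)
    if vx < 1e-12:
        return float("nan")
    return float(np.cov(x, y, ddof=0)[0, 1] / vx)


@dataclass
class SubgroupSummary:
    description: str
    n: int
    ranking: pd.DataFrame            # global_summary on the subgroup rows
    associations: dict[str, float]   # column -> corr(value, phi) in subgroup
    slopes: dict[str, float] = field(default_factory=dict)  # column -> slope

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "n": self.n,
            "ranking": self.ranking.to_dict(orient="records"),
            "associations": self.associations,
            "slopes": self.slopes,
        }


def subgroup_attribution(
    result: AttributionResult,
    values: np.ndarray,
    member_mask: np.ndarray,
    description: str = "",
    min_size: int = 30,
) -> SubgroupSummary:
    """Attribution summary restricted to a subgroup of the attributed rows.

    *member_mask* selects the subgroup among the rows of *result* (it must
    have one entry per attributed row).  The signed association between each
    factor's value and its phi within the subgroup expresses findings like
    "the higher the CGPA, the larger its push toward the depressed class".
    """
    member_mask = np.asarray(member_mask, dtype=bool)
    if member_mask.shape[0] != result.phi.shape[0]:
        raise ValueError("member_mask must align with attributed rows")
    n = int(member_mask.sum())
    if n == 0:
        raise ValueError(f"subgroup {description!r} is empty")
    if n < min_size:
        raise ValueError(
            f"subgroup {description!r} has {n} rows < min_size={min_size}")
    sub = AttributionResult(result.phi[member_mask], result.base_value,
                            result.columns, result.estimator, result.config)
    values = np.atleast_2d(values)[member_mask]
    ranking = global_summary(sub, values)
    assoc = dict(zip(ranking["column"], ranking["phi_value_corr"]))
    slopes = dict(zip(ranking["column"], ranking["phi_value_slope"]))
    return SubgroupSummary(description, n, ranking, assoc, slopes)
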