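"""The M2f statistic: mean two-fold expression change across tissues.

For a set of >= 2 candidate genes, each library contributes the mean
absolute log2 fold change over all unordered gene pairs; M2f is the flat
mean of those per-library values over every selected library (biological
replicates enter as independent libraries).  Expression across fragments
of one true gene should track, giving low M2f; distinct genes wrongly
merged diverge across tissues, giving high M2f.

Libraries are restricted to the genotype whose annotation carries the
split (multiple) gene models, so the expression evidence matches the data
the annotation was built from and cross-genotype differential expression
cannot masquerade as a split signal.

Zero expression in individual libraries is handled with a small additive
pseudocount (default 0.01 TPM, the expression floor) on both sides of the
ratio; set ``epsilon=0`` for exact closed-form behaviour on positive data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .expression import GeneExpressionMatrix

DEFAULT_EPSILON = 0.01


@dataclass
class M2fConfig:
    epsilon: float = DEFAULT_EPSILON
    #: genotype whose libraries are used; None means all libraries
    genotype: str | None = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class M2fResult:
    candidate_id: str
    m2f: float
    per_library: list[tuple[str, float]]
    n_libraries: int


def abs_l2fc(a: float, b: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """|log2((a + eps) / (b + eps))| — symmetric, zero when a == b."""
    if a < 0 or b < 0:
        raise ValueError("TPM values must be >= 0")
    a, b = a + epsilon, b + epsilon
    if a == 0 or b == 0:
        raise ValueError("log2 fold change undefined at zero with epsilon = 0")
    return abs(math.log2(a / b))


def pairwise_mean_abs_l2fc(values: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Per-library mean |log2FC| over all unordered gene pairs.

    ``values`` has shape (n_genes, n_libraries); returns shape (n_libraries,).
    """
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    logged = np.log2(values + epsilon)
    if not np.isfinite(logged).all():
        raise ValueError("log2 fold change undefined at zero with epsilon = 0")
    i, j = np.triu_indices(values.shape[0], k=1)
    return np.abs(logged[i] - logged[j]).mean(axis=0)


def candidate_m2f(
    genes: list[str],
    expr: GeneExpressionMatrix,
    cfg: M2fConfig | None = None,
    candidate_id: str | None = None,
) -> M2fResult:
    """Compute M2f for a candidate gene set from a gene expression matrix."""
    cfg = cfg or M2fConfig()
    if len(genes) < 2:
        raise ValueError("M2f requires >= 2 genes")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    libs = (
        expr.select_genotype(cfg.genotype)
        if cfg.genotype is not None
        else list(expr.values.columns)
    )
    if not libs:
        raise ValueError(f"no libraries selected (genotype={cfg.genotype!r})")
    values = expr.values.loc[list(genes), libs].to_numpy(dtype=float)
    per_lib = pairwise_mean_abs_l2fc(values, cfg.epsilon)
    return M2fResult(
        candidate_id=candidate_id or "+".join(genes),
        m2f=float(per_lib.mean()),
        per_library=list(zip(libs, per_lib.tolist())),
        n_libraries=len(libs),
    )


def m2f_matrix(values: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """M2f of one candidate given its (n_genes, n_libraries) TPM array."""
    return float(pairwise_mean_abs_l2fc(values, epsilon).mean())


def m2f_pairs(a: np.ndarray, b: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Vectorized M2f for many 2-gene candidates at once.

    ``a`` and ``b`` have shape (n_candidates, n_libraries); returns the
    M2f value per candidate.  Used by the null simulations, where every
    simulated candidate is a pair.
    """
    fc = np.abs(np.log2((a + epsilon) / (b + epsilon)))
    return fc.mean(axis=1)
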