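"""Empirical null M2f distributions and classification thresholds.

Two nulls calibrate the M2f statistic:

* split null — real single genes (>= 4 exons, candidates excluded) are
  artificially split in two at a random internal exon junction; the M2f
  between the halves shows how large M2f gets when the merged (single)
  model is actually correct.  Candidates above its 90th percentile are
  unlikely to be fragments of one gene.
* merged null — real adjacent gene pairs (a sampled gene plus its
  upstream neighbour) show how small M2f gets when the split (multiple)
  model is correct.  Candidates below its 10th percentile are unlikely to
  be distinct genes.

Both simulations are driven by an explicit numpy Generator so a fixed
seed reproduces the sampled gene sets and values bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import Annotation
from .expression import GeneExpressionMatrix
from .m2f import DEFAULT_EPSILON, m2f_pairs

logger = logging.getLogger(__name__)


@dataclass
class NullConfig:
    split_fraction: float = 0.20
    merged_fraction: float = 0.30
    min_exons_for_split: int = 4
    split_percentile: float = 90.0
    merged_percentile: float = 10.0
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0

    def __post_init__(self):
        for f in (self.split_fraction, self.merged_fraction):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")
        for p in (self.split_percentile, self.merged_percentile):
            if not 0 < p < 100:
                raise ValueError("percentiles must be in (0, 100)")


@dataclass
class NullDistribution:
    kind: str  # "split_null" | "merged_null"
    values: np.ndarray
    annotation: str
    seed: int

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class Thresholds:
    """Classification cutoffs: merge below t_merge, split above t_split."""

    t_merge: float
    t_split: float
    pooled: bool
    n_split_null: int = 0
    n_merged_null: int = 0

    def __post_init__(self):
        if self.t_merge > self.t_split:
            logger.warning(
                "t_merge (%.4g) > t_split (%.4g): the null distributions are "
                "disjoint and values between the thresholds satisfy neither null; "
                "they will be called ambiguous",
                self.t_merge, self.t_split,
            )


def percentile(values, p: float) -> float:
    """Percentile by linear interpolation between order statistics.

    On sorted values x_(1..n) the rank is h = 1 + (n-1) p/100 and the
    result interpolates between x_(floor(h)) and x_(floor(h)+1) (numpy's
    default "linear" method).  The pooled 10th/90th-percentile thresholds
    depend on this convention, so it is pinned here.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty distribution")
    return float(np.percentile(arr, p))


def split_junctions(n_exons: int) -> list[int]:
    """Admissible split points for an n-exon gene: exon index j such that
    exons [0, j) and [j, n) each keep >= 2 exons."""
    return list(range(2, n_exons - 1))


def simulate_split_null(
    ann: Annotation,
    exon_tpm: pd.DataFrame,
    exon_meta: pd.DataFrame,
    expr: GeneExpressionMatrix,
    exclude: set[str],
    cfg: NullConfig,
    rng: np.random.Generator,
) -> NullDistribution:
    """M2f distribution of real genes artificially split at an exon junction.

    Eligible genes have >= ``cfg.min_exons_for_split`` retained exons and
    are not candidates (``exclude``).  Each sampled gene is cut at a
    uniformly random admissible junction; each half's expression per
    library is the mean of its exons' TPM, and M2f is computed between
    the halves over the annotation's own genotype's libraries.

    ``exon_meta`` maps each exon row of ``exon_tpm`` to its gene; exon
    rows are assumed to appear in transcript order within each gene.
    """
    libs = expr.select_genotype(ann.genotype_label) or list(exon_tpm.columns)
    gene_of = exon_meta.loc[exon_tpm.index, "gene_id"]
    exon_rows: dict[str, list[int]] = {}
    for pos, g in enumerate(gene_of.to_numpy()):
        exon_rows.setdefault(g, []).append(pos)

    eligible = sorted(
        g
        for g, rows in exon_rows.items()
        if len(rows) >= cfg.min_exons_for_split and g not in exclude and g in ann
    )
    if not eligible:
        raise ValueError("no genes eligible for the split null")
    n_sample = max(1, int(np.floor(cfg.split_fraction * len(eligible))))
    chosen = rng.choice(len(eligible), size=n_sample, replace=False)
    tpm_arr = exon_tpm[libs].to_numpy(dtype=float)

    left = np.empty((n_sample, len(libs)))
    right = np.empty((n_sample, len(libs)))
    for k, gi in enumerate(np.sort(chosen)):
        rows = exon_rows[eligible[gi]]
        junctions = split_junctions(len(rows))
        j = junctions[rng.integers(len(junctions))]
        left[k] = tpm_arr[rows[:j]].mean(axis=0)
        right[k] = tpm_arr[rows[j:]].mean(axis=0)
    values = m2f_pairs(left, right, cfg.epsilon)
    return NullDistribution("split_null", values, ann.genotype_label, cfg.seed)


def simulate_merged_null(
    ann: Annotation,
    expr: GeneExpressionMatrix,
    exclude: set[str],
    cfg: NullConfig,
    rng: np.random.Generator,
) -> NullDistribution:
    """M2f distribution of real adjacent gene pairs ("artificially merged").

    Genes are sampled without replacement from the expressed,
    non-candidate pool and paired with their upstream (next-lower-rank,
    same-chromosome) neighbour; pairs whose neighbour is missing,
    excluded or unexpressed are never drawn, and the realized sample size
    is reported in the distribution.  M2f is computed on the two original
    loci — no counts are actually merged.
    """
    libs = expr.select_genotype(ann.genotype_label) or list(expr.values.columns)
    floor = expr.expression_floor
    means = expr.values[libs].mean(axis=1)
    pool = {
        g for g in expr.values.index
        if g in ann and g not in exclude and means[g] >= floor
    }
    anchors = sorted(
        g for g in pool
        if (up := ann.upstream_neighbor(g)) is not None and up in pool
    )
    if not anchors:
        raise ValueError("no adjacent expressed gene pairs available for the merged null")
    n_target = max(1, int(np.floor(cfg.merged_fraction * len(pool))))
    n_sample = min(n_target, len(anchors))
    if n_sample < n_target:
        logger.info(
            "merged null: %d eligible adjacent pairs < target %d; realized n = %d",
            len(anchors), n_target, n_sample,
        )
    chosen = np.sort(rng.choice(len(anchors), size=n_sample, replace=False))
    a_genes = [anchors[i] for i in chosen]
    b_genes = [ann.upstream_neighbor(g) for g in a_genes]
    a = expr.values.loc[a_genes, libs].to_numpy(dtype=float)
    b = expr.values.loc[b_genes, libs].to_numpy(dtype=float)
    values = m2f_pairs(a, b, cfg.epsilon)
    return NullDistribution("merged_null", values, ann.genotype_label, cfg.seed)


def compute_thresholds(
    split_nulls: list[NullDistribution],
    merged_nulls: list[NullDistribution],
    cfg: NullConfig | None = None,
    pool: bool = True,
) -> Thresholds | dict[str, Thresholds]:
    """Derive t_split / t_merge from the simulated distributions.

    With ``pool=True`` (the default, and how the published thresholds were
    set) values are concatenated across annotations per kind before taking
    percentiles.  With ``pool=False`` a dict of per-annotation thresholds
    is returned instead.
    """
    cfg = cfg or NullConfig()
    if not split_nulls or not merged_nulls:
        raise ValueError("need at least one distribution of each kind")
    if pool:
        split_vals = np.concatenate([d.values for d in split_nulls])
        merged_vals = np.concatenate([d.values for d in merged_nulls])
        return Thresholds(
            t_merge=percentile(merged_vals, cfg.merged_percentile),
            t_split=percentile(split_vals, cfg.split_percentile),
            pooled=True,
            n_split_null=len(split_vals),
            n_merged_null=len(merged_vals),
        )
    out: dict[str, Thresholds] = {}
    by_ann_split = {d.annotation: d for d in split_nulls}
    by_ann_merged = {d.annotation: d for d in merged_nulls}
    for label in sorted(set(by_ann_split) & set(by_ann_merged)):
        out[label] = Thresholds(
            t_merge=percentile(by_ann_merged[label].values, cfg.merged_percentile),
            t_split=percentile(by_ann_split[label].values, cfg.split_percentile),
            pooled=False,
            n_split_null=by_ann_split[label].n,
            n_merged_null=by_ann_merged[label].n,
        )
    return out
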