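"""End-to-end orchestration: homology -> expression -> M2f -> nulls -> calls.

``run_pair`` drives one pairwise comparison of two annotations entirely
in memory; ``run_pipeline`` is the file-based front end used by the CLI,
reading a YAML/dict config that names every input and writing the output
TSVs plus a run manifest with per-stage record counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import homology
from .annotation_io import (
    Annotation,
    BlastHit,
    SyntenicBlock,
    read_blast_tab,
    read_gff3,
    read_show_coords,
)
from .classify import Call, classify
from .expression import (
    ExonCountMatrix,
    GeneExpressionMatrix,
    expressed_genes,
    gene_expression_from_counts,
)
from .homology import SplitCandidate
from .m2f import M2fConfig, M2fResult, candidate_m2f
from .nulls import (
    NullConfig,
    NullDistribution,
    Thresholds,
    compute_thresholds,
    simulate_merged_null,
    simulate_split_null,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An input or computation failed; the message names the stage."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {detail}")


@dataclass
class PipelineParams:
    max_evalue: float = 1e-4
    margin_bp: int = 500_000
    window: int = 5
    tandem_max: float = 0.1
    min_exon_len: int = 50
    expression_floor: float = 0.01
    epsilon: float = 0.01
    null: NullConfig = field(default_factory=NullConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    candidates: list[SplitCandidate]  # both directions, testable or not
    m2f: dict[str, M2fResult]  # keyed by candidate_id, testable only
    thresholds: Thresholds
    calls: dict[str, Call]
    nulls: list[NullDistribution]
    manifest: dict

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            cid = c.candidate_id
            call = self.calls.get(cid)
            rows.append(
                dict(
                    candidate_id=cid,
                    merged_annotation=c.merged_annotation,
                    merged_gene=c.merged_gene,
                    split_annotation=c.split_annotation,
                    split_genes=",".join(c.split_genes),
                    tandem_ratio=c.tandem_ratio,
                    testable=c.testable,
                    failed_filters=";".join(k for k, ok in c.filters.items() if not ok),
                    corroboration=c.corroboration,
                    m2f=self.m2f[cid].m2f if cid in self.m2f else np.nan,
                    call=call.call if call else "",
                    supported_annotation=(
                        {"merged": c.merged_annotation, "split": c.split_annotation}.get(
                            call.supported_annotation, "none"
                        )
                        if call
                        else ""
                    ),
                )
            )
        return pd.DataFrame(rows)


def _candidates_one_direction(
    merged_ann: Annotation,
    split_ann: Annotation,
    fwd_hits: list[BlastHit],
    rev_hits: list[BlastHit],
    expressed: set[str],
    params: PipelineParams,
) -> tuple[list[SplitCandidate], dict]:
    corr_fwd = homology.classify_correspondences(fwd_hits, split_ann, params.window)
    corr_rev = homology.classify_correspondences(rev_hits, merged_ann, params.window)
    one_to_one, one_to_many = homology.reciprocal_resolve(corr_fwd, corr_rev)
    cands = homology.build_split_candidates(
        one_to_many,
        merged_ann,
        split_ann,
        expressed,
        hits_to_merged=rev_hits,
        window=params.window,
        tandem_max=params.tandem_max,
    )
    counts = {
        "one_to_one": len(one_to_one),
        "one_to_many": len(one_to_many),
        "candidates": len(cands),
        "testable": sum(c.testable for c in cands),
        "filter_failures": {
            name: sum(not c.filters[name] for c in cands) for name in homology.FILTER_NAMES
        },
    }
    return cands, counts


def run_pair(
    ann_a: Annotation,
    ann_b: Annotation,
    hits_ab: list[BlastHit],
    hits_ba: list[BlastHit],
    blocks: list[SyntenicBlock],
    counts_a: ExonCountMatrix,
    counts_b: ExonCountMatrix,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full two-annotation comparison in memory.

    ``blocks`` are oriented with their reference side in annotation A.
    Split-gene candidates are extracted in both directions (A-merged /
    B-split and B-merged / A-split), M2f is computed per testable
    candidate on the split-side genotype's libraries, null distributions
    are simulated per annotation and pooled into thresholds, and every
    testable candidate receives a call.
    """
    params = params or PipelineParams()
    manifest: dict = {"params": {
        "max_evalue": params.max_evalue, "margin_bp": params.margin_bp,
        "window": params.window, "tandem_max": params.tandem_max,
        "min_exon_len": params.min_exon_len, "expression_floor": params.expression_floor,
        "epsilon": params.epsilon, "seed": params.seed,
        "split_fraction": params.null.split_fraction,
        "merged_fraction": params.null.merged_fraction,
    }}

    # --- homology stage: dedupe and synteny-restrict both directions
    manifest["raw_hits"] = {"a_to_b": len(hits_ab), "b_to_a": len(hits_ba)}
    best_ab = homology.best_hits(hits_ab, params.max_evalue)
    best_ba = homology.best_hits(hits_ba, params.max_evalue)
    flipped = [b.flipped() for b in blocks]
    syn_ab = homology.filter_by_synteny(best_ab, blocks, ann_a, ann_b, params.margin_bp)
    syn_ba = homology.filter_by_synteny(best_ba, flipped, ann_b, ann_a, params.margin_bp)
    manifest["best_hits"] = {"a_to_b": len(best_ab), "b_to_a": len(best_ba)}
    manifest["syntenic_hits"] = {"a_to_b": len(syn_ab), "b_to_a": len(syn_ba)}

    # --- expression stage
    try:
        expr_a, exon_tpm_a = gene_expression_from_counts(counts_a, params.min_exon_len)
        expr_b, exon_tpm_b = gene_expression_from_counts(counts_b, params.min_exon_len)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("expression", str(exc)) from exc
    expr_a.expression_floor = params.expression_floor
    expr_b.expression_floor = params.expression_floor
    expressed_a = expressed_genes(expr_a, params.expression_floor,
                                  expr_a.select_genotype(ann_a.genotype_label) or None)
    expressed_b = expressed_genes(expr_b, params.expression_floor,
                                  expr_b.select_genotype(ann_b.genotype_label) or None)
    manifest["expressed_genes"] = {
        ann_a.genotype_label: len(expressed_a),
        ann_b.genotype_label: len(expressed_b),
    }

    # --- candidates, both directions
    cands_ab, counts_ab = _candidates_one_direction(
        ann_a, ann_b, syn_ab, syn_ba, expressed_a | expressed_b, params
    )
    cands_ba, counts_ba = _candidates_one_direction(
        ann_b, ann_a, syn_ba, syn_ab, expressed_a | expressed_b, params
    )
    candidates = cands_ab + cands_ba
    manifest["funnel"] = {"a_merged": counts_ab, "b_merged": counts_ba}

    # --- M2f per testable candidate (split-side genotype's libraries)
    m2f_results: dict[str, M2fResult] = {}
    expr_by_label = {ann_a.genotype_label: expr_a, ann_b.genotype_label: expr_b}
    for c in candidates:
        if not c.testable:
            continue
        expr = expr_by_label[c.split_annotation]
        cfg = M2fConfig(epsilon=params.epsilon, genotype=c.split_annotation)
        m2f_results[c.candidate_id] = candidate_m2f(
            c.split_genes, expr, cfg, candidate_id=c.candidate_id
        )

    # --- nulls: exclude every gene involved in any candidate
    exclude_a = {c.merged_gene for c in cands_ab} | {
        g for c in cands_ba for g in c.split_genes
    }
    exclude_b = {c.merged_gene for c in cands_ba} | {
        g for c in cands_ab for g in c.split_genes
    }
    rng = np.random.default_rng(params.null.seed)
    nulls: list[NullDistribution] = []
    for ann, counts, expr, excl, exon_tpm in (
        (ann_a, counts_a, expr_a, exclude_a, exon_tpm_a),
        (ann_b, counts_b, expr_b, exclude_b, exon_tpm_b),
    ):
        try:
            from .expression import filter_short_exons

            filtered = filter_short_exons(counts, params.min_exon_len)
            nulls.append(
                simulate_split_null(ann, exon_tpm, filtered.exons, expr, excl,
                                    params.null, rng)
            )
            nulls.append(simulate_merged_null(ann, expr, excl, params.null, rng))
        except ValueError as exc:
            raise PipelineStageError("null_simulation", str(exc)) from exc
    thresholds = compute_thresholds(
        [d for d in nulls if d.kind == "split_null"],
        [d for d in nulls if d.kind == "merged_null"],
        params.null,
        pool=True,
    )
    manifest["thresholds"] = {
        "t_merge": thresholds.t_merge, "t_split": thresholds.t_split,
        "n_split_null": thresholds.n_split_null, "n_merged_null": thresholds.n_merged_null,
    }

    # --- calls
    calls = {
        cid: classify(res.m2f, thresholds, candidate_id=cid)
        for cid, res in m2f_results.items()
    }
    manifest["calls"] = {
        kind: sum(1 for c in calls.values() if c.call == kind)
        for kind in ("merge_supported", "split_supported", "ambiguous")
    }
    return PipelineResult(candidates, m2f_results, thresholds, calls, nulls, manifest)


def run_pipeline(config: dict | str, outdir: str | None = None) -> PipelineResult:
    """File-based pipeline: read inputs named in ``config``, run, write outputs.

    ``config`` is a dict or a YAML file path with keys: gff_a, gff_b,
    hits_ab, hits_ba, coords, counts_a, counts_b, libraries, genotype_a,
    genotype_b, and optional parameter overrides (max_evalue, margin_bp,
    window, tandem_max, min_exon_len, expression_floor, epsilon, seed,
    split_fraction, merged_fraction, min_exons_for_split).  Outputs (calls
    TSV, null values TSV, thresholds and manifest JSON) go to ``outdir``
    when given.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    def need(key: str, stage: str) -> str:
        if key not in config:
            raise PipelineStageError(stage, f"config key {key!r} missing")
        path = config[key]
        if not os.path.exists(path):
            raise PipelineStageError(stage, f"input file not found: {path}")
        return path

    seed = int(config.get("seed", 0))
    params = PipelineParams(
        max_evalue=float(config.get("max_evalue", 1e-4)),
        margin_bp=int(config.get("margin_bp", 500_000)),
        window=int(config.get("window", 5)),
        tandem_max=float(config.get("tandem_max", 0.1)),
        min_exon_len=int(config.get("min_exon_len", 50)),
        expression_floor=float(config.get("expression_floor", 0.01)),
        epsilon=float(config.get("epsilon", 0.01)),
        null=NullConfig(
            split_fraction=float(config.get("split_fraction", 0.20)),
            merged_fraction=float(config.get("merged_fraction", 0.30)),
            min_exons_for_split=int(config.get("min_exons_for_split", 4)),
            epsilon=float(config.get("epsilon", 0.01)),
            seed=seed,
        ),
        seed=seed,
    )

    try:
        ann_a = read_gff3(need("gff_a", "annotation"), config.get("genotype_a", "A"))
        ann_b = read_gff3(need("gff_b", "annotation"), config.get("genotype_b", "B"))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("annotation", str(exc)) from exc
    try:
        tmap = {**ann_a.transcript_to_gene(), **ann_b.transcript_to_gene()}
        hits_ab = read_blast_tab(need("hits_ab", "blast"), tmap)
        hits_ba = read_blast_tab(need("hits_ba", "blast"), tmap)
        blocks = read_show_coords(need("coords", "synteny"))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("blast", str(exc)) from exc
    try:
        counts_a = ExonCountMatrix.from_tsv(need("counts_a", "expression"),
                                            need("libraries", "expression"))
        counts_b = ExonCountMatrix.from_tsv(need("counts_b", "expression"),
                                            need("libraries", "expression"))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("expression", str(exc)) from exc

    result = run_pair(ann_a, ann_b, hits_ab, hits_ba, blocks, counts_a, counts_b, params)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        result.calls_frame().to_csv(os.path.join(outdir, "calls.tsv"), sep="\t", index=False)
        null_rows = [
            {"kind": d.kind, "annotation": d.annotation, "m2f": float(v)}
            for d in result.nulls
            for v in d.values
        ]
        pd.DataFrame(null_rows).to_csv(
            os.path.join(outdir, "null_values.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return result
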