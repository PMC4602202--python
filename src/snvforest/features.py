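"""Assembly of the 19-dimensional disease-variant feature vector.

A disease-variant pair is described by 11 variant-level deleteriousness
scores followed by 8 gene-level guilt-by-association scores of the
variant's host gene, in the canonical order of :data:`FEATURE_ORDER`.
All features are min-max normalized to [0, 1] against bounds taken from
the full reference score database, with SIFT and LRT flipped (1 - x)
first so that larger always means more damaging; a feature missing for a
pair is exactly 0.

The association score of a gene for a query disease under one genomic
source is the sum of transformed gene similarities between the gene and
every seed gene of the disease — the guilt-by-association principle:
proximity to many known disease genes is evidence of association.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .phenotype import SeedGeneSet
from .similarity import SOURCES, GeneSimilarityMatrix
from .variants import FLIPPED_SCORES, VARIANT_SCORES, VariantRecord

#: Canonical order of the 19 features: 11 variant scores, then 8 gene
#: association scores.
FEATURE_ORDER: tuple[str, ...] = VARIANT_SCORES + SOURCES


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ScoreBounds:
    """Per-feature (min, max) normalization bounds.

    Variant-score bounds are computed on the flipped scale for SIFT/LRT.
    Bounds come from the whole reference database, not from the candidate
    set being prioritized, so scores are comparable across runs.
    """

    bounds: Mapping[str, tuple[float, float]]

    def range(self, name: str) -> tuple[float, float]:
        if name not in self.bounds:
            raise ConfigurationError(f"no bounds recorded for feature {name!r}")
        lo, hi = self.bounds[name]
        if not hi > lo:
            raise ConfigurationError(
                f"degenerate bounds for feature {name!r}: min={lo}, max={hi}"
            )
        return lo, hi

    @classmethod
    def from_variant_table(cls, score_table: pd.DataFrame) -> "ScoreBounds":
        """Min/max of each variant score over a reference table.

        ``score_table`` must contain the 11 score columns; missing cells
        are ignored.  SIFT and LRT are flipped before taking bounds.
        """
        bounds = {}
        for name in VARIANT_SCORES:
            col = pd.to_numeric(score_table[name], errors="coerce")
            if name in FLIPPED_SCORES:
                col = 1.0 - col
            if col.notna().any():
                bounds[name] = (float(col.min()), float(col.max()))
        return cls(bounds=bounds)

    @classmethod
    def from_association_scores(
        cls,
        matrices: Mapping[str, GeneSimilarityMatrix],
        seed_sets: Mapping[str, SeedGeneSet],
    ) -> "ScoreBounds":
        """Min/max of association scores over all diseases x genes.

        For each source, raw scores are computed for every (disease,
        gene) combination from the given (unfiltered) seed sets.
        """
        bounds = {}
        for source, gsm in matrices.items():
            values = gsm.matrix.to_numpy()
            genes = list(gsm.matrix.index)
            gene_pos = {g: i for i, g in enumerate(genes)}
            lo, hi = math.inf, -math.inf
            for seeds in seed_sets.values():
                idx = [gene_pos[g] for g in seeds.seed_genes if g in gene_pos]
                scores = values[:, idx].sum(axis=1) if idx else np.zeros(len(genes))
                lo = min(lo, float(scores.min()), 0.0)
                hi = max(hi, float(scores.max()))
            if seed_sets:
                bounds[source] = (lo, hi)
        return cls(bounds=bounds)


def association_score(
    gene: str, seeds: SeedGeneSet, matrix: GeneSimilarityMatrix
) -> float:
    """Sum of similarities between ``gene`` and every seed gene.

    Pairs absent from the matrix contribute 0; an unknown gene scores 0.
    """
    if gene not in matrix.matrix.index:
        return 0.0
    row = matrix.matrix.loc[gene]
    return float(sum(row.get(s, 0.0) for s in seeds.seed_genes))


def normalize_variant_score(
    name: str, raw: float | None, bounds: ScoreBounds
) -> float:
    """Min-max normalize one raw variant score to [0, 1].

    SIFT and LRT are flipped (1 - raw) before normalization; missing
    values map to exactly 0; out-of-range values are clipped.
    """
    if name not in VARIANT_SCORES:
        raise InputError(f"unknown variant score {name!r}")
    if _is_missing(raw):
        return 0.0
    lo, hi = bounds.range(name)
    value = 1.0 - raw if name in FLIPPED_SCORES else raw
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def normalize_association_score(
    raw: float, lo: float, hi: float
) -> float:
    """Min-max normalize a gene association score to [0, 1], clipping."""
    if not hi > lo:
        raise ConfigurationError(f"degenerate association bounds: [{lo}, {hi}]")
    return float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))


def assemble_feature_vector(
    disease: str,
    variant: VariantRecord,
    scores: Mapping[str, float | None],
    seed_sets: Mapping[str, SeedGeneSet],
    matrices: Mapping[str, GeneSimilarityMatrix],
    variant_bounds: ScoreBounds,
    association_bounds: ScoreBounds,
) -> np.ndarray:
    """The 19-dimensional feature vector for one disease-variant pair.

    Variant scores absent from ``scores`` (or recorded as None/NaN) and
    genomic sources absent from ``matrices`` contribute 0.  The two
    association-score features of variants in the same gene are identical
    by construction.
    """
    if not variant.gene:
        raise InputError(f"variant {variant.chrom}:{variant.pos} has no host gene")
    vec = np.zeros(len(FEATURE_ORDER))
    for i, name in enumerate(VARIANT_SCORES):
        raw = scores.get(name)
        if not _is_missing(raw) and name in variant_bounds.bounds:
            vec[i] = normalize_variant_score(name, raw, variant_bounds)
    seeds = seed_sets.get(disease)
    if seeds is not None:
        for j, source in enumerate(SOURCES):
            gsm = matrices.get(source)
            if gsm is None or source not in association_bounds.bounds:
                continue
            raw = association_score(variant.gene, seeds, gsm)
            lo, hi = association_bounds.range(source)
            vec[len(VARIANT_SCORES) + j] = normalize_association_score(raw, lo, hi)
    return vec


class FeatureBuilder:
    """Vectorized feature assembly over a fixed score table and seed sets.

    Precomputes normalized variant-score rows and per-disease gene
    association profiles so cross-validation folds can build feature
    matrices for thousands of pairs cheaply.  Semantics are identical to
    :func:`assemble_feature_vector`.
    """

    def __init__(
        self,
        score_table: pd.DataFrame,
        matrices: Mapping[str, GeneSimilarityMatrix],
        seed_sets: Mapping[str, SeedGeneSet],
        variant_bounds: ScoreBounds,
        association_bounds: ScoreBounds,
    ) -> None:
        self.matrices = dict(matrices)
        self.seed_sets = dict(seed_sets)
        self.variant_bounds = variant_bounds
        self.association_bounds = association_bounds
        self._variant_features: dict[tuple, np.ndarray] = {}
        for _, row in score_table.iterrows():
            key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
            vec = np.zeros(len(VARIANT_SCORES))
            for i, name in enumerate(VARIANT_SCORES):
                raw = row.get(name)
                if not _is_missing(raw) and name in variant_bounds.bounds:
                    vec[i] = normalize_variant_score(name, float(raw), variant_bounds)
            self._variant_features[key] = vec
        self._assoc_cache: dict[str, dict[str, dict[str, float]]] = {}

    def _disease_assoc(self, disease: str) -> dict[str, dict[str, float]]:
        cached = self._assoc_cache.get(disease)
        if cached is not None:
            return cached
        seeds = self.seed_sets.get(disease)
        per_source: dict[str, dict[str, float]] = {}
        for source, gsm in self.matrices.items():
            if source not in self.association_bounds.bounds or seeds is None:
                per_source[source] = {}
                continue
            genes = list(gsm.matrix.index)
            gene_pos = {g: i for i, g in enumerate(genes)}
            idx = [gene_pos[g] for g in seeds.seed_genes if g in gene_pos]
            values = gsm.matrix.to_numpy()
            raw = values[:, idx].sum(axis=1) if idx else np.zeros(len(genes))
            lo, hi = self.association_bounds.range(source)
            norm = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
            per_source[source] = dict(zip(genes, norm.tolist()))
        self._assoc_cache[disease] = per_source
        return per_source

    def feature_vector(self, disease: str, variant: VariantRecord) -> np.ndarray:
        if not variant.gene:
            raise InputError(f"variant {variant.chrom}:{variant.pos} has no host gene")
        vec = np.zeros(len(FEATURE_ORDER))
        vfeat = self._variant_features.get(variant.key)
        if vfeat is not None:
            vec[: len(VARIANT_SCORES)] = vfeat
        assoc = self._disease_assoc(disease)
        for j, source in enumerate(SOURCES):
            table = assoc.get(source)
            if table:
                vec[len(VARIANT_SCORES) + j] = table.get(variant.gene, 0.0)
        return vec

    def feature_matrix(
        self, pairs: Sequence[tuple[str, VariantRecord]]
    ) -> np.ndarray:
        """Stack feature vectors for (disease, variant) pairs row-wise."""
        return np.array(
            [self.feature_vector(d, v) for d, v in pairs]
        ).reshape(len(pairs), len(FEATURE_ORDER))
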