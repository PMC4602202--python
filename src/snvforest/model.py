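"""Random-forest training, prioritization, and leakage-controlled CV.

Training units are labeled disease-variant pairs: positives are known
causative associations, negatives are sampled uniformly from the pool of
(training disease, neutral variant) combinations, the same number as
positives.  Two rules keep cross-validation unbiased: training variants
sharing a gene with any test variant are discarded, and seed genes
associated with test diseases or hosting test variants are removed
before association scores are computed.  Folds hold out whole diseases,
so train and test share no disease, gene or variant information.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import rank_of_positive, rank_roc_auc, ranks_in_list
from .exceptions import InputError
from .features import FEATURE_ORDER, FeatureBuilder, ScoreBounds
from .phenotype import (
    SeedGeneSet,
    collect_seed_genes,
    filter_seeds_unbiased,
    top_similar_diseases,
)
from .similarity import GeneSimilarityMatrix
from .variants import VariantRecord

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class DiseaseVariantPair:
    """A (query disease, candidate variant) unit with an optional label."""

    disease: str
    variant: VariantRecord
    label: int | None = None


@dataclass
class TrainedModel:
    """A fitted random forest over the canonical 19-feature order."""

    estimator: RandomForestClassifier
    feature_order: tuple[str, ...]
    hyperparams: dict
    fingerprint: str

    def predict(self, features: np.ndarray) -> np.ndarray:
        if features.shape[1] != len(self.feature_order):
            raise InputError(
                f"feature matrix has {features.shape[1]} columns; model "
                f"expects {len(self.feature_order)}"
            )
        proba = self.estimator.predict_proba(features)
        pos_col = list(self.estimator.classes_).index(POSITIVE)
        return proba[:, pos_col]


@dataclass
class RankingResult:
    """Prioritized candidates for one query disease.

    ``table`` columns: chrom, pos, ref, alt, gene, score, rank,
    rank_ratio — sorted by descending score, ties carrying average ranks.
    """

    disease: str
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# training-pair construction
# ---------------------------------------------------------------------------

def build_positive_pairs(
    associations: Iterable[tuple[str, VariantRecord]]
) -> list[DiseaseVariantPair]:
    """One positive pair per distinct (disease, causative variant)."""
    seen: set[tuple] = set()
    pairs = []
    for disease, variant in associations:
        key = (disease, variant.key)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(DiseaseVariantPair(disease, variant, POSITIVE))
    return pairs


def build_negative_pool(
    neutral_variants: Sequence[VariantRecord],
    training_diseases: Iterable[str],
) -> list[DiseaseVariantPair]:
    """Cartesian product of training diseases and neutral variants."""
    diseases = sorted(set(training_diseases))
    return [
        DiseaseVariantPair(d, v, NEGATIVE)
        for d in diseases
        for v in neutral_variants
    ]


def sample_negative_pairs(
    pool: Sequence[DiseaseVariantPair], n_positives: int, seed: int
) -> list[DiseaseVariantPair]:
    """Uniform sample without replacement of ``n_positives`` pairs."""
    if n_positives > len(pool):
        raise InputError(
            f"negative pool of {len(pool)} cannot supply {n_positives} pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_positives, replace=False)
    return [pool[i] for i in sorted(idx)]


def eliminate_leakage(
    train_pairs: Sequence[DiseaseVariantPair],
    test_variants: Iterable[VariantRecord],
) -> list[DiseaseVariantPair]:
    """Drop training pairs whose variant's gene hosts any test variant."""
    test_genes = {v.gene for v in test_variants}
    kept = [p for p in train_pairs if p.variant.gene not in test_genes]
    if train_pairs and not kept:
        warnings.warn(
            "leakage elimination removed every training pair", stacklevel=2
        )
    return kept


# ---------------------------------------------------------------------------
# model fitting and scoring
# ---------------------------------------------------------------------------

def _pair_fingerprint(pairs: Sequence[DiseaseVariantPair]) -> str:
    h = hashlib.sha256()
    for p in sorted(pairs, key=lambda p: (p.disease, p.variant.key)):
        h.update(repr((p.disease, p.variant.key, p.label)).encode())
    return h.hexdigest()[:16]


def train_model(
    pairs: Sequence[DiseaseVariantPair],
    builder: FeatureBuilder,
    n_trees: int = 500,
    max_features: str | int | float = "sqrt",
    seed: int = 0,
) -> TrainedModel:
    """Fit the random forest on labeled disease-variant pairs.

    The prediction score is the forest's positive-class probability; with
    a fixed seed, training and prediction are deterministic.
    """
    labels = {p.label for p in pairs}
    if labels != {POSITIVE, NEGATIVE}:
        raise InputError(
            "training needs at least one positive and one negative pair"
        )
    X = builder.feature_matrix([(p.disease, p.variant) for p in pairs])
    y = np.array([p.label for p in pairs])
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        feature_order=FEATURE_ORDER,
        hyperparams={"n_trees": n_trees, "max_features": max_features, "seed": seed},
        fingerprint=_pair_fingerprint(pairs),
    )


def score_pairs(
    model: TrainedModel,
    pairs: Sequence[DiseaseVariantPair | tuple[str, VariantRecord]],
    builder: FeatureBuilder,
) -> np.ndarray:
    """Positive-class probability for each pair, in [0, 1]."""
    norm = [
        (p.disease, p.variant) if isinstance(p, DiseaseVariantPair) else p
        for p in pairs
    ]
    return model.predict(builder.feature_matrix(norm))


def prioritize(
    model: TrainedModel,
    disease: str,
    candidates: Sequence[VariantRecord],
    builder: FeatureBuilder,
) -> RankingResult:
    """Rank candidate variants for a query disease by prediction score.

    Ties receive average ranks; the rank ratio is rank divided by the
    number of candidates.
    """
    if not candidates:
        raise InputError("no candidate variants to prioritize")
    scores = score_pairs(model, [(disease, v) for v in candidates], builder)
    ranks = ranks_in_list(scores)
    table = pd.DataFrame(
        {
            "chrom": [v.chrom for v in candidates],
            "pos": [v.pos for v in candidates],
            "ref": [v.ref for v in candidates],
            "alt": [v.alt for v in candidates],
            "gene": [v.gene for v in candidates],
            "score": scores,
            "rank": ranks,
            "rank_ratio": ranks / len(candidates),
        }
    ).sort_values(["rank", "chrom", "pos"], kind="stable").reset_index(drop=True)
    return RankingResult(disease=disease, table=table)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PipelineData:
    """Everything the pipeline needs, already parsed into memory.

    ``score_table`` is keyed by (chrom, pos, ref, alt) with a ``gene``
    column and the 11 raw score columns.  ``disease_control`` is an
    optional external set of variants causative for *other* diseases,
    used as the negative test sample of the "disease" and "combined"
    validation protocols.
    """

    score_table: pd.DataFrame
    matrices: Mapping[str, GeneSimilarityMatrix]
    phenotype: pd.DataFrame
    associations: Mapping[str, set[str]]
    positives: list[tuple[str, VariantRecord]]
    neutrals: list[VariantRecord]
    disease_control: list[VariantRecord] = field(default_factory=list)


@dataclass
class CVConfig:
    """Cross-validation settings (defaults mirror the standard protocol)."""

    n_folds: int = 5
    k_similar: int = 10
    negative_sample: str = "neutral"  # neutral | disease | combined
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    seed: int = 0
    feature_subset: str = "all"  # all | variant | gene


@dataclass
class CrossValidationResult:
    """Per-disease rank ratios and AUCs plus the two summary criteria."""

    mrr: float
    mean_auc: float
    per_disease: dict[str, dict]
    fold_of_disease: dict[str, int]
    neutral_scores: dict[str, np.ndarray]

    def summary(self) -> dict:
        return {"mrr": self.mrr, "mean_auc": self.mean_auc}


def _assign_folds(
    diseases: Sequence[str],
    pos_counts: Mapping[str, int],
    n_folds: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Seeded shuffle, stable sort by positive count, round-robin."""
    order = list(rng.permutation(np.array(sorted(diseases), dtype=object)))
    order.sort(key=lambda d: -pos_counts[d])  # stable: shuffle breaks ties
    return {d: i % n_folds for i, d in enumerate(order)}


def _restrict_features(X: np.ndarray, subset: str) -> np.ndarray:
    """Zero out the feature block excluded by an ablation subset."""
    if subset == "all":
        return X
    X = X.copy()
    if subset == "variant":
        X[:, 11:] = 0.0
    elif subset == "gene":
        X[:, :11] = 0.0
    else:
        raise InputError(f"unknown feature subset {subset!r}")
    return X


def run_cross_validation(
    data: PipelineData, config: CVConfig | None = None
) -> CrossValidationResult:
    """Disease-holdout cross-validation with both leakage rules.

    Diseases carrying positive variants are split into ``n_folds``
    subsets balanced by positive-variant count; neutral variants are
    split into two halves (train/test).  In each fold every positive test
    variant is prioritized against the configured negative test sample,
    and rank ratios / rank-ROC AUCs are aggregated per disease.
    """
    config = config or CVConfig()
    rng = np.random.default_rng(config.seed)

    pos_by_disease: dict[str, list[VariantRecord]] = {}
    for d, v in data.positives:
        pos_by_disease.setdefault(d, []).append(v)
    diseases = sorted(pos_by_disease)
    if len(diseases) < config.n_folds:
        raise InputError(
            f"{len(diseases)} diseases with positives cannot fill "
            f"{config.n_folds} folds"
        )
    fold_of = _assign_folds(
        diseases,
        {d: len(vs) for d, vs in pos_by_disease.items()},
        config.n_folds,
        rng,
    )

    neutral_perm = rng.permutation(len(data.neutrals))
    half = len(data.neutrals) // 2
    neutral_train = [data.neutrals[i] for i in neutral_perm[:half]]
    neutral_test = [data.neutrals[i] for i in neutral_perm[half:]]

    if config.negative_sample not in ("neutral", "disease", "combined"):
        raise InputError(f"unknown negative sample {config.negative_sample!r}")
    if config.negative_sample in ("disease", "combined") and not data.disease_control:
        raise InputError(
            "negative_sample requires an external disease-control variant set"
        )

    # seed sets from the full phenotype matrix; association bounds from the
    # whole disease x gene score table (unfiltered seeds)
    all_diseases = list(data.phenotype.index)
    base_seeds: dict[str, SeedGeneSet] = {}
    for d in all_diseases:
        similar = top_similar_diseases(d, data.phenotype, config.k_similar)
        base_seeds[d] = collect_seed_genes(d, similar, data.associations)
    variant_bounds = ScoreBounds.from_variant_table(data.score_table)
    assoc_bounds = ScoreBounds.from_association_scores(data.matrices, base_seeds)

    per_disease: dict[str, dict] = {}
    neutral_scores: dict[str, np.ndarray] = {}

    for fold in range(config.n_folds):
        test_diseases = {d for d in diseases if fold_of[d] == fold}
        test_pos = [(d, v) for d in sorted(test_diseases) for v in pos_by_disease[d]]

        if config.negative_sample == "neutral":
            neg_test = list(neutral_test)
        elif config.negative_sample == "disease":
            neg_test = list(data.disease_control)
        else:
            neg_test = list(neutral_test) + list(data.disease_control)
        test_variants = [v for _, v in test_pos] + neg_test
        test_genes = {v.gene for v in test_variants}

        train_pos_pairs = build_positive_pairs(
            (d, v) for d, v in data.positives if d not in test_diseases
        )
        train_pos_pairs = eliminate_leakage(train_pos_pairs, test_variants)
        if not train_pos_pairs:
            logger.warning("fold %d has no training positives after leakage", fold)
            continue
        train_diseases = {p.disease for p in train_pos_pairs}
        neutral_train_fold = [v for v in neutral_train if v.gene not in test_genes]
        pool = build_negative_pool(neutral_train_fold, train_diseases)
        neg_pairs = sample_negative_pairs(
            pool, len(train_pos_pairs), seed=int(rng.integers(2**31))
        )

        fold_seeds = {
            d: filter_seeds_unbiased(
                base_seeds[d], test_diseases, test_variants, data.associations
            )
            for d in all_diseases
        }
        builder = FeatureBuilder(
            data.score_table, data.matrices, fold_seeds, variant_bounds, assoc_bounds
        )

        train_pairs = train_pos_pairs + neg_pairs
        # post-hoc leakage assertion: training and test gene sets disjoint
        assert not ({p.variant.gene for p in train_pairs} & test_genes)

        X = _restrict_features(
            builder.feature_matrix([(p.disease, p.variant) for p in train_pairs]),
            config.feature_subset,
        )
        y = np.array([p.label for p in train_pairs])
        est = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        est.fit(X, y)
        model = TrainedModel(
            estimator=est,
            feature_order=FEATURE_ORDER,
            hyperparams={"n_trees": config.n_trees, "fold": fold},
            fingerprint=_pair_fingerprint(train_pairs),
        )

        n_neg = len(neg_test)
        for d in sorted(test_diseases):
            rows = [(d, v) for v in neg_test] + [(d, v) for v in pos_by_disease[d]]
            feats = _restrict_features(
                builder.feature_matrix(rows), config.feature_subset
            )
            scores = model.predict(feats)
            neg_scores = scores[:n_neg]
            pos_scores = scores[n_neg:]
            if config.negative_sample in ("neutral", "combined"):
                neutral_scores[d] = neg_scores[: len(neutral_test)]
            pos_rrs, neg_rrs = [], []
            for ps in pos_scores:
                rank = rank_of_positive(ps, neg_scores)
                total = n_neg + 1
                pos_rrs.append(rank / total)
                all_ranks = ranks_in_list(np.append(neg_scores, ps))
                neg_rrs.extend((all_ranks[:n_neg] / total).tolist())
            per_disease[d] = {
                "rank_ratios": pos_rrs,
                "auc": rank_roc_auc(pos_rrs, neg_rrs),
                "n_pos": len(pos_rrs),
            }

    if not per_disease:
        raise InputError("cross-validation produced no evaluable diseases")
    mrr = float(np.mean([np.mean(d["rank_ratios"]) for d in per_disease.values()]))
    mean_auc_val = float(np.mean([d["auc"] for d in per_disease.values()]))
    return CrossValidationResult(
        mrr=mrr,
        mean_auc=mean_auc_val,
        per_disease=per_disease,
        fold_of_disease=fold_of,
        neutral_scores=neutral_scores,
    )
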