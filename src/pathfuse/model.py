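"""Model/Results interface for pathway-masked multi-omics staging prediction.

:class:`StagingFusionModel` is constructed from aligned omics matrices, a
pathway hierarchy and a configuration; :meth:`StagingFusionModel.fit` runs
leakage-safe stratified K-fold cross-validation under the fixed training
protocol and returns a :class:`StagingFusionResults` carrying per-fold
accuracy and weighted F1, integrated pathway-importance vectors, their
fold-to-fold stability, structural resolution metrics and a ``summary()``
table.  A label-permutation sanity test and evidence-chain export hang off
the results object.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from . import interpret
from .hierarchy import MaskStack, PathwayHierarchy, build_masks
from .nn import FusionNetwork, Tensor
from .preprocess import (
    OmicsMatrix,
    apply_fold_transform,
    borderline_smote,
    fit_fold_transform,
    harmonize,
)
from .train import TrainProtocol, evaluate, predict_proba, train

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "StagingFusionModel", "StagingFusionResults", "FoldResult"]


@dataclass
class ModelConfig:
    """Architecture configuration shared across folds."""

    variant: str = "3F"
    leaky_slope: float = 0.01
    dropout_rate: float = 0.3
    modality_dropout: float = 1.0 / 3.0
    gate_hidden_dim: int | None = None  # defaults to the pathway dimension
    seed: int = 0

    def __post_init__(self):
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if self.variant not in ("3F", "5X"):
            raise ValueError("variant must be '3F' or '5X'")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass
class FoldResult:
    """One cross-validation fold: metrics, importances and bookkeeping."""

    fold_index: int
    accuracy: float
    weighted_f1: float
    importance: np.ndarray  # integrated pathway importance I^(k)
    history: dict
    predictions: np.ndarray
    labels: np.ndarray
    modality_weight_means: np.ndarray
    network: FusionNetwork | None = None
    transforms: list | None = None
    val_index: np.ndarray | None = None
    smote_added: int = 0


class StagingFusionModel:
    """Pathway-masked mid-fusion classifier for one binary staging endpoint.

    Parameters
    ----------
    omics : dict of modality name -> OmicsMatrix
        Harmonized matrices sharing identical sample order.
    labels : pandas.Series or array of {0,1}
        Binary endpoint labels indexed like the matrices' samples.
    hierarchy : PathwayHierarchy
        The pathway prior; masks are built once per model.
    config : ModelConfig, optional
    """

    def __init__(
        self,
        omics: dict[str, OmicsMatrix],
        labels,
        hierarchy: PathwayHierarchy,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        self.hierarchy = hierarchy
        self.mask_stack: MaskStack = build_masks(hierarchy, self.config.variant)
        self.modalities = list(omics)
        genes = list(self.mask_stack.gene_ids)
        aligned = {}
        n_excluded = 0
        for name, m in omics.items():
            extra = set(m.gene_ids) - set(genes)
            n_excluded += len(extra)
            aligned[name] = m.restrict_genes(genes)
        if n_excluded:
            logger.info(
                "%d gene column(s) absent from the pathway prior were excluded "
                "from the encoder input", n_excluded,
            )
        sample_sets = {tuple(m.sample_ids) for m in aligned.values()}
        if len(sample_sets) != 1:
            raise ValueError("omics matrices must share an identical sample order; "
                             "run preprocess.harmonize first")
        self.omics = aligned
        self.sample_ids = list(next(iter(aligned.values())).sample_ids)
        y = labels.loc[self.sample_ids].to_numpy() if isinstance(labels, pd.Series) \
            else np.asarray(labels)
        if len(y) != len(self.sample_ids):
            raise ValueError("labels do not match the sample set")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.y = y.astype(int)

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_cohort(cls, cohort, hierarchy, config=None) -> "StagingFusionModel":
        """Build from a synthetic cohort object."""
        mats, labels = harmonize(list(cohort.matrices.values()), cohort.labels)
        omics = {m.modality: m for m in mats}
        return cls(omics, labels, hierarchy, config)

    @classmethod
    def from_files(
        cls, expression, cnv, maf, clinical, gmt, relations, endpoint="T",
        n_levels=2, config=None,
    ) -> "StagingFusionModel":
        """Build from on-disk TSV/GMT inputs (see the preprocessing module)."""
        from .hierarchy import build_hierarchy, parse_gmt, parse_relations
        from .preprocess import (
            load_clinical, load_cnv, load_expression, load_maf,
            maf_to_binary_matrix, stage_labels,
        )

        hierarchy = build_hierarchy(parse_gmt(gmt), parse_relations(relations), n_levels)
        mats = [
            load_expression(expression),
            load_cnv(cnv),
            maf_to_binary_matrix(load_maf(maf)),
        ]
        labels = stage_labels(load_clinical(clinical), endpoint)
        mats, labels = harmonize(mats, labels)
        return cls({m.modality: m for m in mats}, labels, hierarchy, config)

    # ---------------------------------------------------------------- helpers
    def _values(self) -> list[np.ndarray]:
        return [self.omics[m].values for m in self.modalities]

    def _build_network(self, seed: int) -> FusionNetwork:
        return FusionNetwork(
            self.mask_stack.masks,
            n_modalities=len(self.modalities),
            seed=seed,
            slope=self.config.leaky_slope,
            dropout=self.config.dropout_rate,
            gate_hidden=self.config.gate_hidden_dim,
            modality_dropout=self.config.modality_dropout,
        )

    def _fold_arrays(self, train_idx, val_idx, fold_id, smote, seed):
        """Fit fold transforms on the training rows only and optionally SMOTE."""
        train_xs, val_xs, transforms = [], [], []
        for name in self.modalities:
            m = self.omics[name]
            tr = OmicsMatrix(
                [m.sample_ids[i] for i in train_idx], list(m.gene_ids),
                m.values[train_idx], name,
            )
            va_vals = m.values[val_idx]
            t = fit_fold_transform(tr, fold_id)
            transforms.append(t)
            train_xs.append(apply_fold_transform(t, tr).values)
            va = OmicsMatrix.__new__(OmicsMatrix)
            va.sample_ids = [m.sample_ids[i] for i in val_idx]
            va.gene_ids = list(m.gene_ids)
            va.values = va_vals
            va.modality = name
            val_xs.append(apply_fold_transform(t, va).values)
        y_tr = self.y[train_idx]
        smote_added = 0
        if smote:
            widths = [x.shape[1] for x in train_xs]
            stacked = np.hstack(train_xs)
            aug_x, aug_y = borderline_smote(stacked, y_tr, seed=seed)
            smote_added = len(aug_y) - len(y_tr)
            splits = np.cumsum(widths)[:-1]
            train_xs = np.hsplit(aug_x, splits)
            y_tr = aug_y
        return train_xs, y_tr, val_xs, transforms, smote_added

    # -------------------------------------------------------------------- fit
    def fit(
        self,
        k: int = 5,
        protocol: TrainProtocol | None = None,
        smote: bool = True,
        seed: int = 0,
        keep_networks: bool = True,
        n_attr_steps: int = 64,
    ) -> "StagingFusionResults":
        """Stratified K-fold cross-validation under the fixed protocol.

        Fold transforms and (optional) Borderline-SMOTE touch only each
        fold's training split.  Per fold, the trained network is explained
        on its held-out validation samples: integrated-gradient
        attributions against the training-mean baseline are aggregated to
        the attention-integrated pathway-importance vector I^(k).
        """
        protocol = protocol or TrainProtocol()
        counts = np.bincount(self.y, minlength=2)
        if counts.min() < k:
            raise ValueError(
                f"each class needs >= k={k} members, got counts {counts.tolist()}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        membership = self.mask_stack.gene_to_top().astype(float)
        folds: list[FoldResult] = []
        for fold_index, (train_idx, val_idx) in enumerate(skf.split(self.y, self.y)):
            fold_seed = seed + fold_index
            train_xs, y_tr, val_xs, transforms, smote_added = self._fold_arrays(
                train_idx, val_idx, f"fold{fold_index}", smote, fold_seed
            )
            # non-convex small-sample fit: keep the best of a few Kaiming
            # restarts by validation loss (same signal early stopping uses)
            net, history, best_val = None, None, np.inf
            for restart in range(max(protocol.n_restarts, 1)):
                cand = self._build_network(self.config.seed + fold_index + 100 * restart)
                hist = train(cand, train_xs, y_tr, val_xs, self.y[val_idx],
                             protocol, seed=fold_seed)
                if min(hist["val_loss"]) < best_val:
                    best_val = min(hist["val_loss"])
                    net, history = cand, hist
            proba = predict_proba(net, val_xs)
            preds = (proba >= 0.5).astype(int)
            acc, f1 = evaluate(preds, self.y[val_idx])
            # interpretation on the held-out fold
            baselines = [x.mean(axis=0) for x in train_xs]
            attrs = interpret.attribute_genes(
                net, val_xs, baselines, n_steps=n_attr_steps,
                dataset_id=f"fold{fold_index}",
            )
            S, _ = interpret.pathway_scores(attrs, membership)
            out = net([Tensor(x) for x in val_xs], training=False)
            weights = out["modality_weights"].data
            importance = interpret.integrated_importance(S, weights)
            folds.append(
                FoldResult(
                    fold_index=fold_index,
                    accuracy=acc,
                    weighted_f1=f1,
                    importance=importance,
                    history=history,
                    predictions=preds,
                    labels=self.y[val_idx],
                    modality_weight_means=weights.mean(axis=0),
                    network=net if keep_networks else None,
                    transforms=transforms if keep_networks else None,
                    val_index=val_idx,
                    smote_added=smote_added,
                )
            )
            logger.info("fold %d: ACC %.3f, F1 %.3f", fold_index, acc, f1)
        return StagingFusionResults(self, folds, protocol, seed, smote)

    def permutation_test(
        self,
        n_perm: int = 10,
        reference_importance: np.ndarray | None = None,
        protocol: TrainProtocol | None = None,
        k: int = 5,
        smote: bool = True,
        seed: int = 0,
    ) -> dict:
        """Label-permutation sanity test.

        Each replicate permutes the labels over the whole cohort, reruns
        the cross-validated fit, and records the mean accuracy and the
        fold-mean integrated importance vector.  The summary reports the
        mean null accuracy and (when a reference importance is given) the
        mean Spearman correlation between null and reference rankings.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        from scipy.stats import spearmanr

        rng = np.random.default_rng(seed)
        null_acc, null_rho, null_importances = [], [], []
        y_orig = self.y.copy()
        try:
            for r in range(n_perm):
                self.y = rng.permutation(y_orig)
                res = self.fit(k=k, protocol=protocol, smote=smote,
                               seed=seed + 1000 * (r + 1), keep_networks=False)
                null_acc.append(res.mean_accuracy)
                imp = res.importance_mean
                null_importances.append(imp)
                if reference_importance is not None:
                    null_rho.append(
                        float(spearmanr(np.abs(imp), np.abs(reference_importance)).statistic)
                    )
        finally:
            self.y = y_orig
        return {
            "null_accuracies": np.asarray(null_acc),
            "mean_null_accuracy": float(np.mean(null_acc)),
            "null_importances": np.asarray(null_importances),
            "null_reference_spearman": np.asarray(null_rho) if null_rho else None,
            "mean_spearman": float(np.mean(null_rho)) if null_rho else None,
            "mean_abs_spearman": float(np.mean(np.abs(null_rho))) if null_rho else None,
        }


class StagingFusionResults:
    """Cross-validated fit results with interpretation summaries."""

    def __init__(self, model: StagingFusionModel, folds: list[FoldResult],
                 protocol: TrainProtocol, seed: int, smote: bool):
        self.model = model
        self.folds = folds
        self.protocol = protocol
        self.seed = seed
        self.smote = smote

    # ------------------------------------------------------------- metrics
    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def weighted_f1s(self) -> np.ndarray:
        return np.array([f.weighted_f1 for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_weighted_f1(self) -> float:
        return float(self.weighted_f1s.mean())

    @property
    def importance_matrix(self) -> np.ndarray:
        """(K, P) integrated pathway importances, one row per fold."""
        return np.stack([f.importance for f in self.folds])

    @property
    def importance_mean(self) -> np.ndarray:
        return self.importance_matrix.mean(axis=0)

    @property
    def modality_weight_means(self) -> np.ndarray:
        """(K, m) fold-level mean attention-derived modality weights."""
        return np.stack([f.modality_weight_means for f in self.folds])

    def stability(self, absolute: bool = True) -> interpret.StabilityReport:
        """Fold-to-fold rank stability of the integrated pathway importances.

        By default ranks follow the reporting convention (absolute
        importance = evidence strength); ``absolute=False`` ranks the
        signed fold vectors instead.
        """
        mat = np.abs(self.importance_matrix) if absolute else self.importance_matrix
        return interpret.stability(mat)

    def structural_metrics(self, tau: float = 0.001) -> list[interpret.StructuralMetrics]:
        """Per-masked-layer resolution metrics, averaged over folds."""
        per_fold = []
        for f in self.folds:
            if f.network is None or f.val_index is None:
                raise ValueError("fit with keep_networks=True to compute structural metrics")
            val_xs = [
                apply_fold_transform(t, OmicsMatrix(
                    [self.model.sample_ids[i] for i in f.val_index],
                    list(self.model.omics[name].gene_ids),
                    self.model.omics[name].values[f.val_index], name,
                )).values
                for name, t in zip(self.model.modalities, f.transforms)
            ]
            per_fold.append(interpret.layer_node_importances(f.network, val_xs))
        n_layers = len(per_fold[0])
        metrics = []
        for ell in range(n_layers):
            w = np.mean([pf[ell] for pf in per_fold], axis=0)
            metrics.append(interpret.structural_metrics(w, tau))
        return metrics

    def pathway_ranking(self) -> pd.DataFrame:
        """Pathways ranked by fold-mean absolute integrated importance."""
        mean_abs = np.abs(self.importance_matrix).mean(axis=0)
        df = pd.DataFrame({
            "pathway": list(self.model.mask_stack.top_node_ids),
            "importance": mean_abs,
            "importance_sd": np.abs(self.importance_matrix).std(axis=0),
        }).sort_values("importance", ascending=False).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def driver_rank_per_fold(self, pathway: str) -> list[int]:
        """1-based rank of one pathway within each fold's |importance| vector."""
        names = list(self.model.mask_stack.top_node_ids)
        j = names.index(pathway)
        ranks = []
        for row in np.abs(self.importance_matrix):
            order = np.argsort(-row)
            ranks.append(int(np.where(order == j)[0][0]) + 1)
        return ranks

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = [
            "Pathway-masked multi-omics staging model — cross-validated fit",
            "=" * 62,
            f"variant: {self.model.config.variant}   folds: {len(self.folds)}   "
            f"samples: {len(self.model.y)}   smote: {self.smote}",
            f"pathway dim: {self.model.mask_stack.pathway_dim}   "
            f"modalities: {', '.join(self.model.modalities)}",
            "",
            f"accuracy     : {self.mean_accuracy:.3f} ± {self.accuracies.std():.3f}",
            f"weighted F1  : {self.mean_weighted_f1:.3f} ± {self.weighted_f1s.std():.3f}",
            f"stability    : {self.stability().value:.3f} "
            f"(avg pairwise Spearman over {self.stability().n_pairs} fold pairs)",
            "",
            "mean modality weights (attention-derived):",
        ]
        mw = self.modality_weight_means.mean(axis=0)
        for name, w in zip(self.model.modalities, mw):
            lines.append(f"  {name:<12} {w:.3f}")
        lines.append("")
        lines.append("top pathways by integrated importance:")
        top = self.pathway_ranking().head(5)
        for _, row in top.iterrows():
            lines.append(
                f"  {int(row['rank']):>2}. {row['pathway']:<10} "
                f"{row['importance']:.4f} ± {row['importance_sd']:.4f}"
            )
        return "\n".join(lines)

    # --------------------------------------------------------------- export
    def export(self, out_dir, endpoint: str = "T") -> dict:
        """Write metrics JSON plus the evidence-chain tables and Sankey records."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        # fold-mean global gene importance, recomputed from the stored fold
        # networks on their validation splits
        gi_folds = []
        for f in self.folds:
            if f.network is None or f.transforms is None:
                continue
            val_xs = [
                apply_fold_transform(t, OmicsMatrix(
                    [self.model.sample_ids[i] for i in f.val_index],
                    list(self.model.omics[name].gene_ids),
                    self.model.omics[name].values[f.val_index], name,
                )).values
                for name, t in zip(self.model.modalities, f.transforms)
            ]
            attrs = interpret.attribute_genes(f.network, val_xs, n_steps=32)
            gi_folds.append(interpret.gene_importance(attrs))
        gene_imp = np.mean(gi_folds, axis=0) if gi_folds else np.zeros(
            (len(self.model.modalities), len(self.model.mask_stack.gene_ids))
        )
        payload = interpret.export_evidence_chain(
            self.importance_matrix, gene_imp, self.model.mask_stack, out_dir,
            endpoint=endpoint, modalities=tuple(self.model.modalities),
        )
        metrics = {
            "per_fold": [
                {"fold": f.fold_index, "accuracy": f.accuracy,
                 "weighted_f1": f.weighted_f1, "smote_added": f.smote_added,
                 "early_stop_epoch": f.history["early_stop_epoch"],
                 "lr_reductions": f.history["lr_reductions"]}
                for f in self.folds
            ],
            "accuracy_mean": self.mean_accuracy,
            "accuracy_sd": float(self.accuracies.std()),
            "weighted_f1_mean": self.mean_weighted_f1,
            "weighted_f1_sd": float(self.weighted_f1s.std()),
            "stability": self.stability().value,
            "config": dict(self.model.config.__dict__),
            "protocol": dict(self.protocol.__dict__),
            "seed": self.seed,
            "smote": self.smote,
        }
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
        return payload

    def save_checkpoints(self, out_dir) -> None:
        """Serialize fold networks with the mask fingerprint for safe reload."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fp = self.model.mask_stack.fingerprint()
        for f in self.folds:
            if f.network is None:
                continue
            state = f.network.state_dict()
            np.savez(
                out_dir / f"fold{f.fold_index}.npz",
                mask_fingerprint=np.frombuffer(bytes.fromhex(fp), dtype=np.uint8),
                **state,
            )

    def load_checkpoint(self, path) -> FusionNetwork:
        """Load a fold checkpoint, verifying it matches this model's masks."""
        data = np.load(path)
        fp = bytes(data["mask_fingerprint"]).hex()
        if fp != self.model.mask_stack.fingerprint():
            raise ValueError("checkpoint mask fingerprint does not match model masks")
        net = self.model._build_network(self.model.config.seed)
        net.load_state_dict({k: data[k] for k in data.files if k.startswith("param_")})
        return net
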