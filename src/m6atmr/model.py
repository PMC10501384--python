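"""The M6ATMR model and results objects.

``M6ATMR`` bundles the whole pipeline behind a statsmodels-style interface:
construct it from a sequence set (or a FASTA file), call :meth:`fit` to run
the representation learning (similarity matrix, Transformer structure
graph, self-correlation GCN autoencoder, gated fusion) and — when labels
are present — the stratified 10-fold cross-validated random-forest
evaluation.  The returned :class:`M6ATMRResults` carries the embeddings,
the training log, the per-fold metric report and a ``summary()`` table, and
exposes ablation features, classifier sweeps and curve export.

The evaluation is transductive, as is standard for this family of methods:
the similarity matrix and embeddings are built over the full sequence set
with labels hidden from the representation learner; only the downstream
classifier is fold-restricted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gcn as gcn_mod
from .evaluate import CvPlan, classifier_sweep, cross_validate
from .fusion import ABLATION_MODES, FusionPipeline
from .gcn import GcnConfig
from .kmer import kmer_labels, kmer_matrix, token_matrix
from .metrics import curves
from .sequences import RnaSequence, read_fasta
from .similarity import build_distance_matrix, distance_to_similarity
from .transformer import TransformerConfig

__all__ = ["M6ATMR", "M6ATMRResults"]


class M6ATMR:
    """Sequence-only m6A site recognizer.

    Parameters
    ----------
    sequences : list of RnaSequence sharing one length.
    transformer, gcn : hyperparameter bundles; defaults follow the method's
        published configuration (d_model 32, feed-forward 128, 6 encoder
        blocks, 3 GCN layers, Adam at 1e-4).
    similarity_mode : distance-to-affinity transform for the Manhattan
        distance matrix ("rbf" with median bandwidth, or "max-complement").
    K : k-mer order for the frequency encoding and token streams.
    """

    def __init__(self, sequences: list[RnaSequence], *,
                 K: int = 3,
                 similarity_mode: str = "rbf",
                 bandwidth_quantile: float = 0.5,
                 transformer: TransformerConfig | None = None,
                 gcn: GcnConfig | None = None):
        if len(sequences) < 2:
            raise ValueError("need at least two sequences")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"mixed sequence lengths {sorted(lengths)}")
        self.sequences = list(sequences)
        self.K = K
        self.similarity_mode = similarity_mode
        self.bandwidth_quantile = bandwidth_quantile
        self.transformer = transformer or TransformerConfig()
        self.gcn = gcn or GcnConfig()
        labels = [s.label for s in sequences]
        self.labels = (np.array(labels, dtype=int)
                       if all(l is not None for l in labels) else None)

    @classmethod
    def from_fasta(cls, path: str | Path, labels: str | Path | None = None,
                   **kwargs) -> "M6ATMR":
        return cls(read_fasta(path, labels=labels), **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, *, cv: bool = True, classifier: str = "rf", folds: int = 10,
            verbose: bool = False) -> "M6ATMRResults":
        """Run representation learning (and CV evaluation when labeled)."""
        e_km = kmer_matrix(self.sequences, self.K)
        tokens = token_matrix(self.sequences, self.K)
        D = build_distance_matrix(e_km)
        S = distance_to_similarity(D, mode=self.similarity_mode,
                                   bandwidth_quantile=self.bandwidth_quantile)
        fusion = FusionPipeline(d_emb=self.gcn.hidden_dims[-1],
                                d_km=4 ** self.K, seed=self.gcn.seed)
        state = gcn_mod.train(S, tokens, self.gcn, self.transformer,
                              e_km=e_km, fusion=fusion, verbose=verbose)
        res = M6ATMRResults(model=self, similarity=S, distance=D,
                            e_km=e_km, state=state)
        if cv and self.labels is not None:
            res.fold_report = res.cross_validate(classifier=classifier,
                                                 folds=folds)
        return res


@dataclass
class M6ATMRResults:
    """Fitted embeddings, diagnostics and evaluation reports."""

    model: M6ATMR
    similarity: np.ndarray
    distance: np.ndarray
    e_km: np.ndarray
    state: gcn_mod.TrainingResult
    fold_report: pd.DataFrame | None = None

    # ------------------------------------------------------------- features
    @property
    def training_log(self) -> pd.DataFrame:
        return self.state.log

    @property
    def structure_graph(self) -> np.ndarray:
        return self.state.structure_graph

    def features(self, mode: str = "full") -> pd.DataFrame:
        """Final fused per-sequence features under an ablation mode."""
        F = self.state.fusion.ablate(self.state.e_sm, self.state.e_st,
                                     self.e_km, mode=mode)
        ids = [s.id for s in self.model.sequences]
        return pd.DataFrame(F, index=ids,
                            columns=[f"f{j}" for j in range(F.shape[1])])

    # ----------------------------------------------------------- evaluation
    def _xy(self, mode: str):
        if self.model.labels is None:
            raise ValueError("sequences carry no labels; classification unavailable")
        return self.features(mode).to_numpy(), self.model.labels

    def cross_validate(self, classifier: str = "rf", folds: int = 10,
                       mode: str = "full", seed: int | None = None,
                       literal: bool = False) -> pd.DataFrame:
        X, y = self._xy(mode)
        seed = self.model.gcn.seed if seed is None else seed
        plan = CvPlan(folds=folds, seed=seed)
        return cross_validate(X, y, plan, classifier=classifier, seed=seed,
                              literal=literal)

    def classifier_sweep(self, folds: int = 10, classifiers=None,
                         seed: int | None = None) -> pd.DataFrame:
        X, y = self._xy("full")
        seed = self.model.gcn.seed if seed is None else seed
        return classifier_sweep(X, y, CvPlan(folds=folds, seed=seed),
                                classifiers=classifiers, seed=seed)

    def ablation_report(self, classifier: str = "rf", folds: int = 10,
                        seed: int | None = None) -> pd.DataFrame:
        """Mean CV metrics for every ablation mode (rows)."""
        rows = {}
        for mode in ABLATION_MODES:
            rows[mode] = self.cross_validate(classifier=classifier,
                                             folds=folds, mode=mode,
                                             seed=seed).loc["Mean"]
        return pd.DataFrame(rows).T

    def oof_scores(self, classifier: str = "rf", folds: int = 10,
                   mode: str = "full", seed: int | None = None) -> np.ndarray:
        """Out-of-fold positive-class scores for curve plotting."""
        from .evaluate import make_classifier, _scores
        X, y = self._xy(mode)
        seed = self.model.gcn.seed if seed is None else seed
        fold_of = CvPlan(folds=folds, seed=seed).assignments(y)
        scores = np.zeros(len(y))
        for f in range(folds):
            test = fold_of == f
            clf = make_classifier(classifier, seed=seed)
            clf.fit(X[~test], y[~test])
            scores[test] = _scores(clf, X[test])
        return scores

    def roc_pr(self, **kwargs) -> dict:
        scores = self.oof_scores(**kwargs)
        return curves(scores, self.model.labels)

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        m = len(self.model.sequences)
        n = len(self.model.sequences[0])
        lines = [
            "                         M6ATMR Results",
            "=" * 66,
            f"Sequences:            {m} windows of length {n}",
            f"K-mer order:          {self.model.K} ({4 ** self.model.K} features)",
            f"Similarity transform: {self.model.similarity_mode}",
            f"Transformer:          d_model={self.model.transformer.d_model}, "
            f"heads={self.model.transformer.heads}, blocks={self.model.transformer.blocks}",
            f"GCN:                  layers={self.model.gcn.layers}, "
            f"dims={self.model.gcn.hidden_dims}, lr={self.model.gcn.learning_rate}",
            f"Training epochs:      {len(self.training_log)} "
            f"(loss {self.training_log['loss'].iloc[0]:.4f} -> "
            f"{self.training_log['loss'].iloc[-1]:.4f})",
            f"Structure graph:      {int(self.structure_graph.sum())} edges "
            f"(density {self.structure_graph.mean():.3f})",
        ]
        if self.fold_report is not None:
            lines += ["-" * 66,
                      "10-fold cross-validation (random forest, transductive "
                      "representation):", ""]
            lines.append(self.fold_report.round(4).to_string())
        lines.append("=" * 66)
        return "\n".join(lines)
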