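"""High-level modelling interface: a Model built from data whose fit() returns Results.

:class:`CalpainCleavageModel` holds the proteins, annotated sites and the
assembled window dataset; ``fit()`` trains the four-branch classifier and
returns a :class:`CalpainCleavageResults` carrying the trained weights,
training diagnostics, and methods for prediction, cross-validation, variant
impact classification and enrichment testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, mutation_impact
from .nn import Hyperparameters, TrainedModel, predict_scores, train
from .sequence_io import (
    CleavageSite,
    LabeledDataset,
    MissenseVariant,
    Protein,
    build_dataset,
    read_fasta,
    read_site_table,
)


class CalpainCleavageModel:
    """Cleavage-site classifier specification bound to a training corpus.

    Parameters
    ----------
    proteins, sites
        The training proteins and their annotated cleavage bonds.  Annotated
        bonds are positives; every other bond in the same proteins is a
        negative.
    flank
        Residues kept on each side of the bond (window length ``2 * flank``).
    kmax
        Largest pair spacing in the CKSAAP encoder.
    negative_subsample
        Optional seeded cap on the exhaustive negative set (training-time
        rebalancing).
    """

    def __init__(
        self,
        proteins: Sequence[Protein],
        sites: Sequence[CleavageSite],
        flank: int = 15,
        kmax: int = 3,
        negative_subsample: int | None = None,
        seed: int = 0,
    ):
        self.proteins = list(proteins)
        self.sites = list(sites)
        self.flank = flank
        self.kmax = kmax
        self.dataset: LabeledDataset = build_dataset(
            self.proteins,
            self.sites,
            flank=flank,
            negative_subsample=negative_subsample,
            seed=seed,
        )

    @classmethod
    def from_files(
        cls, fasta_path, site_path, flank: int = 15, kmax: int = 3, **kwargs
    ) -> "CalpainCleavageModel":
        """Build from a FASTA file and a ``protein_id<TAB>bond`` site table."""
        return cls(
            read_fasta(fasta_path), read_site_table(site_path), flank=flank,
            kmax=kmax, **kwargs,
        )

    @classmethod
    def from_dataset(
        cls, dataset: LabeledDataset, kmax: int = 3
    ) -> "CalpainCleavageModel":
        """Wrap an already-assembled window dataset (no protein sequences attached)."""
        obj = cls.__new__(cls)
        obj.proteins = []
        obj.sites = []
        obj.flank = len(dataset.windows[0]) // 2
        obj.kmax = kmax
        obj.dataset = dataset
        return obj

    def fit(
        self,
        hyper: Hyperparameters | None = None,
        seed: int = 0,
        class_balance_mode: str = "balanced",
    ) -> "CalpainCleavageResults":
        """Train the classifier on the full bound dataset."""
        trained = train(
            self.dataset,
            hyper=hyper,
            seed=seed,
            class_balance_mode=class_balance_mode,
            kmax=self.kmax,
        )
        return CalpainCleavageResults(model=self, trained=trained)

    def cross_validate(
        self, k: int, hyper: Hyperparameters | None = None, seed: int = 0
    ) -> evaluation.CVResult:
        """Stratified k-fold cross-validation of the full pipeline on the bound data."""
        return evaluation.kfold_cv(
            self.dataset, k=k, hyper=hyper, seed=seed, kmax=self.kmax
        )


@dataclass
class CalpainCleavageResults:
    """A fitted cleavage classifier with its diagnostics and downstream analyses."""

    model: CalpainCleavageModel
    trained: TrainedModel

    def predict(
        self,
        proteins: Sequence[Protein] | None = None,
        positions: dict[str, Sequence[int]] | None = None,
    ) -> pd.DataFrame:
        """Cleavage scores for all (or selected) bonds, as a tidy table."""
        proteins = self.model.proteins if proteins is None else list(proteins)
        records = predict_scores(self.trained, proteins, positions)
        return pd.DataFrame(
            {
                "protein_id": [r.protein_id for r in records],
                "bond": [r.bond for r in records],
                "score": [r.score for r in records],
            }
        )

    def classify_variants(
        self,
        variants: Sequence[MissenseVariant],
        proteins: Sequence[Protein] | None = None,
        threshold: float = 0.5,
    ) -> tuple[list[mutation_impact.ImpactCall], pd.DataFrame]:
        """Gain/loss/change/no-change call per variant plus the tidy table."""
        proteins = self.model.proteins if proteins is None else list(proteins)
        by_id = {p.id: p for p in proteins}
        calls = [
            mutation_impact.classify_impact(
                self.trained, by_id[v.protein_id], v, threshold=threshold
            )
            for v in variants
        ]
        return calls, mutation_impact.impact_table(calls)

    def site_enrichment(
        self,
        variants: Sequence[MissenseVariant],
        proteins: Sequence[Protein] | None = None,
        sites: Sequence[CleavageSite] | None = None,
        n_iterations: int = 10_000,
        seed: int = 0,
    ) -> mutation_impact.EnrichmentResult:
        """Bootstrap test for variant enrichment near the annotated cleavage bonds."""
        return mutation_impact.bootstrap_site_enrichment(
            variants,
            self.model.sites if sites is None else sites,
            self.model.proteins if proteins is None else proteins,
            flank=self.model.flank,
            n_iterations=n_iterations,
            seed=seed,
        )

    def training_auc(self) -> float:
        """Apparent (in-sample) AUC on the training windows — optimistic by design."""
        scores = self.trained.predict_windows(self.model.dataset.windows)
        return evaluation.roc_auc(scores, self.model.dataset.labels).auc

    def summary(self) -> str:
        """Human-readable fit summary."""
        ds = self.model.dataset
        h = self.trained.hyper
        lines = [
            "Calpain cleavage-site classifier",
            "=" * 48,
            f"windows:            {len(ds)} ({ds.n_positive} positive, {ds.n_negative} negative)",
            f"flank / window:     {self.model.flank} / {2 * self.model.flank} residues",
            f"kmax (CKSAAP):      {self.model.kmax}",
            f"branch layers:      {h.branch_layers}",
            f"merged layers:      {h.merged_layers}",
            f"dropout rate:       {h.dropout_rate}",
            f"learning rate:      {h.learning_rate}",
            f"epochs / batch:     {h.epochs} / {h.batch_size}",
            f"parameters:         {self.trained.net.n_parameters}",
            f"seed:               {self.trained.seed}",
        ]
        if self.trained.loss_trace:
            lines.append(
                f"loss (first->last): {self.trained.loss_trace[0]:.4f} -> "
                f"{self.trained.loss_trace[-1]:.4f}"
            )
        lines.append(f"training AUC:       {self.training_auc():.4f}")
        return "\n".join(lines)
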