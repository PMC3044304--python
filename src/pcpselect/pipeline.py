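"""End-to-end orchestration: cluster -> encode -> select -> analyze.

Ties the pieces together the way the command-line interface and the test
suite use them; every function is deterministic given its seed arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from . import encoding, svm_eval
from .aaindex import PropertyTable, assign_groups_nn, zscore_profiles
from .encoding import FeatureMatrix, SequenceRecord, build_matrix, scale_minmax
from .ensemble import Candidate, EnsembleReport, candidate_of_run, ensemble_report
from .fcm import FuzzyClustering, fcm
from .ibcga import GAConfig, SolutionSet, feature_subset_fitness, run_ibcga
from .svm_eval import SvmParams


def cluster_properties(
    table: PropertyTable,
    K: int = 20,
    s: float = 1.12,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[PropertyTable, FuzzyClustering]:
    """Fuzzy-cluster a (complete) property table; returns annotated copy."""
    clustering = fcm(zscore_profiles(table), K=K, s=s, tol=tol, max_iter=max_iter, seed=seed)
    annotated = PropertyTable(
        [
            replace(rec, cluster_id=int(clustering.hard_labels[i]))
            for i, rec in enumerate(table)
        ]
    )
    return annotated, clustering


def encode_dataset(
    seqs: list[SequenceRecord], table: PropertyTable
) -> FeatureMatrix:
    """Scaled feature matrix over all properties of the table."""
    return scale_minmax(build_matrix(seqs, list(table)))


def select_features(
    mat: FeatureMatrix,
    cfg: GAConfig,
    folds: int = 5,
) -> tuple[list[SolutionSet], EnsembleReport]:
    """R independent IBCGA runs plus the ensemble aggregation.

    Per-run seeds (GA and CV folds) are derived deterministically from
    ``cfg.seed`` so results are independent of execution order.
    """
    n = len(mat.property_accessions)
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=(cfg.runs, 2))
    sols = []
    for t in range(cfg.runs):
        eval_fn = feature_subset_fitness(
            mat.values, mat.labels, folds=folds, seed=int(seeds[t, 1])
        )
        sols.append(run_ibcga(n, cfg, eval_fn, seed=int(seeds[t, 0])))
    report = ensemble_report([candidate_of_run(s) for s in sols])
    return sols, report


@dataclass
class ModelArtifact:
    """Everything needed to re-apply a trained selection: features, SVM
    parameters, scaling, and the training data the SVM is refit on."""

    accessions: list[str]
    params: SvmParams
    scale_params: np.ndarray  # over the selected columns
    train_values: np.ndarray  # scaled, selected columns
    train_labels: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "accessions": self.accessions,
                "gamma": self.params.gamma,
                "cost": self.params.cost,
                "scale_params": self.scale_params.tolist(),
                "train_values": self.train_values.tolist(),
                "train_labels": self.train_labels.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelArtifact":
        d = json.loads(text)
        return cls(
            accessions=d["accessions"],
            params=SvmParams(gamma=d["gamma"], cost=d["cost"]),
            scale_params=np.array(d["scale_params"]),
            train_values=np.array(d["train_values"]),
            train_labels=np.array(d["train_labels"], dtype=int),
        )


def build_model(
    mat_unscaled: FeatureMatrix, candidate: Candidate
) -> ModelArtifact:
    """Freeze a candidate's selection into a reusable model artifact."""
    sub = mat_unscaled.select_columns(candidate.features)
    scaled = scale_minmax(sub)
    return ModelArtifact(
        accessions=scaled.property_accessions,
        params=SvmParams.from_codes(candidate.gamma_code, candidate.cost_code),
        scale_params=scaled.scale_params,
        train_values=scaled.values,
        train_labels=scaled.labels,
    )


def predict_sequences(
    model: ModelArtifact, seqs: list[SequenceRecord], table: PropertyTable
) -> tuple[np.ndarray, svm_eval.MetricsReport | None]:
    """Encode new sequences with the model's properties and scaling, predict."""
    props = [table.get(a) for a in model.accessions]
    if not seqs:
        return np.array([], dtype=int), None
    mat = build_matrix(seqs, props)
    scaled = encoding.transform_with_params(mat, model.scale_params)
    return svm_eval.predict(
        model.train_values,
        model.train_labels,
        scaled.values,
        model.params,
        y_test=scaled.labels,
    )


def prepare_table(table: PropertyTable) -> PropertyTable:
    """Filter incomplete records and fill unassigned groups by nearest neighbour."""
    from .aaindex import GROUPS, filter_complete

    table = filter_complete(table)
    if any(r.group in GROUPS for r in table) and any(
        r.group not in GROUPS for r in table
    ):
        table = assign_groups_nn(table)
    return table
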