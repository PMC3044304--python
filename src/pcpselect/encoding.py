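"""Fixed-length feature vectors from variable-length protein sequences.

A sequence of length *l* paired with one amino-acid index yields an
*l*-dimensional profile (the index value of each residue).  The simplest
fixed-length summary is the profile mean, so a sequence encoded with *m*
selected properties becomes an *m*-dimensional vector — a composition
statistic, invariant under residue permutation.  Feature columns are then
min-max scaled to [-1, 1] for the SVM.

Residues outside the 20-letter alphabet (X, B, Z, U, O, gaps) are dropped
before averaging; a sequence with no standard residues is rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aaindex import RESIDUES, PropertyRecord

_RES_INDEX = {a: i for i, a in enumerate(RESIDUES)}


@dataclass
class SequenceRecord:
    id: str
    residues: str
    label: int | None = None  # 1 = binding, 0 = non-binding

    def composition_counts(self) -> np.ndarray:
        """Counts of the 20 standard residues (non-standard ones ignored)."""
        counts = np.zeros(len(RESIDUES))
        for ch in self.residues.upper():
            i = _RES_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
        return counts


@dataclass
class FeatureMatrix:
    """Sequences x properties matrix of mean-profile features.

    ``scale_params`` holds the per-column (min, max) fitted by
    :func:`scale_minmax` so held-out data can be transformed consistently.
    """

    sequence_ids: list[str]
    property_accessions: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None
    scale_params: np.ndarray | None = None  # m x 2 of (min, max)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sequence_ids), len(self.property_accessions)):
            raise ValueError("values shape does not match ids/accessions")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)

    @property
    def scaled(self) -> bool:
        return self.scale_params is not None

    def select_columns(self, idx) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            sequence_ids=self.sequence_ids,
            property_accessions=[self.property_accessions[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels,
            scale_params=None if self.scale_params is None else self.scale_params[idx],
        )

    def to_tsv(self) -> str:
        df = pd.DataFrame(
            self.values, index=self.sequence_ids, columns=self.property_accessions
        )
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.index.name = "sequence"
        return df.to_csv(sep="\t")


def clean_residues(residues: str) -> str:
    return "".join(ch for ch in residues.upper() if ch in _RES_INDEX)


def encode_sequence(seq: SequenceRecord, prop: PropertyRecord) -> float:
    """Mean of the property profile over the sequence's standard residues."""
    if not prop.complete:
        raise ValueError(f"{prop.accession}: incomplete property profile")
    counts = seq.composition_counts()
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{seq.id}: no standard residues to encode")
    return float(counts @ prop.values / total)


def build_matrix(
    seqs: list[SequenceRecord], props: list[PropertyRecord]
) -> FeatureMatrix:
    """Unscaled feature matrix: values[i, j] = mean profile of seqs[i] under props[j]."""
    if not seqs or not props:
        raise ValueError("build_matrix needs at least one sequence and one property")
    P = np.array([p.values for p in props], dtype=float)  # m x 20
    if not np.all(np.isfinite(P)):
        bad = [p.accession for p in props if not p.complete]
        raise ValueError(f"incomplete property profiles: {bad}")
    C = np.array([s.composition_counts() for s in seqs], dtype=float)  # N x 20
    totals = C.sum(axis=1)
    empty = np.nonzero(totals == 0)[0]
    if empty.size:
        raise ValueError(f"{seqs[empty[0]].id}: no standard residues to encode")
    values = (C / totals[:, None]) @ P.T
    labels = None
    if all(s.label is not None for s in seqs):
        labels = np.array([s.label for s in seqs], dtype=int)
    return FeatureMatrix(
        sequence_ids=[s.id for s in seqs],
        property_accessions=[p.accession for p in props],
        values=values,
        labels=labels,
    )


def scale_minmax(mat: FeatureMatrix) -> FeatureMatrix:
    """Scale each column to [-1, 1]: x -> 2 (x - min) / (max - min) - 1.

    Constant columns map to zeros.  The fitted (min, max) are stored in
    ``scale_params`` for transforming held-out data.
    """
    lo = mat.values.min(axis=0)
    hi = mat.values.max(axis=0)
    params = np.stack([lo, hi], axis=1)
    return FeatureMatrix(
        sequence_ids=mat.sequence_ids,
        property_accessions=mat.property_accessions,
        values=_apply_scale(mat.values, params),
        labels=mat.labels,
        scale_params=params,
    )


def transform_with_params(mat: FeatureMatrix, scale_params: np.ndarray) -> FeatureMatrix:
    """Scale held-out data with previously fitted per-column (min, max).

    Values outside the fitted range are clipped to [-1, 1] to keep the SVM
    input contract.
    """
    scale_params = np.asarray(scale_params, dtype=float)
    if scale_params.shape != (len(mat.property_accessions), 2):
        raise ValueError("scale_params shape mismatch")
    return FeatureMatrix(
        sequence_ids=mat.sequence_ids,
        property_accessions=mat.property_accessions,
        values=_apply_scale(mat.values, scale_params),
        labels=mat.labels,
        scale_params=scale_params,
    )


def inverse_scale(values: np.ndarray, scale_params: np.ndarray) -> np.ndarray:
    lo, hi = scale_params[:, 0], scale_params[:, 1]
    return (values + 1.0) / 2.0 * (hi - lo) + lo


def _apply_scale(values: np.ndarray, params: np.ndarray) -> np.ndarray:
    lo, hi = params[:, 0], params[:, 1]
    span = hi - lo
    out = np.zeros_like(values)
    ok = span > 0
    out[:, ok] = 2.0 * (values[:, ok] - lo[ok]) / span[ok] - 1.0
    return np.clip(out, -1.0, 1.0)


def read_fasta(text: str, label: int | None = None) -> list[SequenceRecord]:
    """Parse FASTA text into sequence records, optionally tagging a class label."""
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), label=label))
    return records


def write_fasta(seqs: list[SequenceRecord], width: int = 60) -> str:
    lines = []
    for s in seqs:
        lines.append(f">{s.id}")
        for i in range(0, len(s.residues), width):
            lines.append(s.residues[i : i + width])
    return "\n".join(lines) + "\n"
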