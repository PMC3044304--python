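"""Amino-acid property index handling.

An amino-acid index assigns one numeric value to each of the 20 standard
residues and represents a physicochemical or biochemical property
(hydrophobicity, helix propensity, volume, ...).  The AAindex database
distributes hundreds of such indices in a flat-file format; entries whose
value block contains ``NA`` are unusable for encoding and are filtered out
before any downstream analysis.

This module parses and writes the AAindex1 flat-file format, validates and
z-normalizes the 20-value profiles, assigns the six functional groups
(Alpha/turn, Beta, Composition, Hydrophobicity, Physicochemical, Other) to
unlabeled indices by a nearest-neighbour rule, and tallies cluster-by-group
statistics.

Internally profiles are stored in alphabetical one-letter residue order
(A, C, D, ..., Y); the parser re-maps from the AAindex1 file order
(A R N D C Q E G H I L K M F P S T W Y V).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical internal residue order (alphabetical one-letter codes)
RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: residue order used by the I block of AAindex1 flat files
AAINDEX_FILE_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

#: the six functional group labels
GROUPS = ("A", "B", "C", "H", "P", "O")

UNASSIGNED = "unassigned"

_FILE_TO_CANON = [AAINDEX_FILE_ORDER.index(a) for a in RESIDUES]


class AAindexParseError(ValueError):
    """Raised when an AAindex1 record is malformed."""


@dataclass
class PropertyRecord:
    """One amino-acid index: an accession plus a 20-value residue profile."""

    accession: str
    values: np.ndarray  # length 20, canonical residue order; NaN marks "NA"
    group: str = UNASSIGNED
    cluster_id: int | None = None
    feature_id: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(RESIDUES),):
            raise ValueError(
                f"{self.accession}: profile must have {len(RESIDUES)} values, "
                f"got shape {self.values.shape}"
            )

    @property
    def complete(self) -> bool:
        """True when all 20 residue values are present and finite."""
        return bool(np.all(np.isfinite(self.values)))

    def value_map(self) -> dict[str, float]:
        return dict(zip(RESIDUES, self.values.tolist()))


@dataclass
class PropertyTable:
    """An ordered collection of property records with unique accessions."""

    records: list[PropertyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions: {dupes}")

    @property
    def n(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> PropertyRecord:
        return self.records[i]

    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def matrix(self) -> np.ndarray:
        """Raw profile matrix, n x 20, canonical residue order."""
        return np.array([r.values for r in self.records], dtype=float)

    def get(self, accession: str) -> PropertyRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)


def parse_aaindex1(text: str) -> PropertyTable:
    """Parse AAindex1 flat-file content into a :class:`PropertyTable`.

    Records are delimited by ``//``.  Each record must carry an ``H`` line
    (accession) and an ``I`` line followed by two rows of ten values in the
    order A R N D C Q E G H I L K M F P S T W Y V.  ``NA`` values are kept
    as NaN so that :func:`filter_complete` can drop the record later.

    Raises :class:`AAindexParseError` naming the offending accession for a
    missing block or a wrong value count.
    """
    records: list[PropertyRecord] = []
    chunks = [c for c in text.split("//") if c.strip()]
    for chunk in chunks:
        lines = chunk.strip("\n").split("\n")
        accession: str | None = None
        description = ""
        ivals: list[float] | None = None
        i = 0
        while i < len(lines):
            line = lines[i]
            code = line[:1]
            if code == "H":
                accession = line[1:].strip()
            elif code == "D":
                description = line[1:].strip()
            elif code == "I":
                # two continuation lines hold the 20 numbers
                raw: list[str] = []
                j = i + 1
                while j < len(lines) and lines[j][:1] == " ":
                    raw.extend(lines[j].split())
                    j += 1
                vals: list[float] = []
                for tok in raw:
                    if tok.upper() == "NA":
                        vals.append(math.nan)
                    else:
                        try:
                            vals.append(float(tok))
                        except ValueError as exc:
                            raise AAindexParseError(
                                f"{accession or '<no accession>'}: bad value {tok!r}"
                            ) from exc
                ivals = vals
                i = j - 1
            i += 1
        if accession is None:
            raise AAindexParseError("record without H (accession) line")
        if ivals is None:
            raise AAindexParseError(f"{accession}: record without I (value) block")
        if len(ivals) != len(RESIDUES):
            raise AAindexParseError(
                f"{accession}: expected {len(RESIDUES)} values, got {len(ivals)}"
            )
        canon = np.array(ivals, dtype=float)[_FILE_TO_CANON]
        records.append(
            PropertyRecord(accession=accession, values=canon, description=description)
        )
    return PropertyTable(records)


def write_aaindex1(table: PropertyTable) -> str:
    """Serialize a table back to AAindex1 flat-file text (inverse of parse)."""
    out: list[str] = []
    canon_to_file = [RESIDUES.index(a) for a in AAINDEX_FILE_ORDER]
    for rec in table:
        out.append(f"H {rec.accession}")
        if rec.description:
            out.append(f"D {rec.description}")
        file_vals = rec.values[canon_to_file]

        def fmt(v: float) -> str:
            return "NA" if not np.isfinite(v) else repr(float(v))

        out.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        out.append("  " + "  ".join(fmt(v) for v in file_vals[:10]))
        out.append("  " + "  ".join(fmt(v) for v in file_vals[10:]))
        out.append("//")
    return "\n".join(out) + "\n"


def filter_complete(table: PropertyTable) -> PropertyTable:
    """Drop records with any missing residue value; order preserved.

    Idempotent: a complete table passes through unchanged.
    """
    return PropertyTable([r for r in table if r.complete])


def zscore_profiles(table: PropertyTable) -> np.ndarray:
    """Standardize each property profile to mean 0, population SD 1.

    Each row of the returned n x 20 matrix is the record's profile after
    subtracting its mean and dividing by its population standard deviation
    (ddof=0).  A constant profile has no scale and maps to all zeros.
    """
    X = table.matrix()
    if not np.all(np.isfinite(X)):
        raise ValueError("zscore_profiles requires complete records; run filter_complete")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.zeros_like(X)
    ok = sd[:, 0] > 0
    out[ok] = (X[ok] - mu[ok]) / sd[ok]
    return out


def assign_groups_nn(table: PropertyTable) -> PropertyTable:
    """Assign a functional group to every unlabeled record by nearest neighbour.

    Records whose ``group`` is already one of the six labels act as the labeled
    reference set; each unassigned record receives the group of its nearest
    labeled record by Euclidean distance between z-scored profiles.  Ties are
    broken by the lexicographically smallest labeled accession.  Labeled
    records are never changed.
    """
    labeled_idx = [i for i, r in enumerate(table) if r.group in GROUPS]
    if not labeled_idx:
        raise ValueError("assign_groups_nn needs at least one labeled record")
    Z = zscore_profiles(table)
    # stable order: sort labeled refs by accession so the first argmin hit
    # is the lexicographic tie-winner
    labeled_idx.sort(key=lambda i: table[i].accession)
    ref = Z[labeled_idx]
    out: list[PropertyRecord] = []
    for j, rec in enumerate(table):
        if rec.group in GROUPS:
            out.append(rec)
            continue
        d = np.linalg.norm(ref - Z[j], axis=1)
        nearest = labeled_idx[int(np.argmin(d))]
        out.append(replace(rec, group=table[nearest].group))
    return PropertyTable(out)


def group_tally(table: PropertyTable) -> pd.DataFrame:
    """Cluster-by-group contingency table with TOTAL and RATE rows.

    Rows are cluster ids (plus TOTAL and RATE), columns the six groups plus a
    TOTAL column.  RATE is each group's share of all records; rates sum to 1
    before rounding.
    """
    clusters = sorted({r.cluster_id for r in table if r.cluster_id is not None})
    cols = list(GROUPS)
    data = pd.DataFrame(0, index=[f"C{c}" for c in clusters], columns=cols, dtype=int)
    for r in table:
        if r.cluster_id is None:
            raise ValueError(f"{r.accession}: cluster not assigned")
        if r.group not in GROUPS:
            raise ValueError(f"{r.accession}: group not assigned")
        data.loc[f"C{r.cluster_id}", r.group] += 1
    data["TOTAL"] = data.sum(axis=1)
    totals = data.sum(axis=0)
    n = int(totals["TOTAL"])
    out = data.astype(float)
    out.loc["TOTAL"] = totals.astype(float)
    rates = totals / n if n else totals * 0.0
    rates["TOTAL"] = math.nan
    out.loc["RATE"] = rates
    return out


def group_rates(totals: dict[str, int] | pd.Series) -> dict[str, float]:
    """Group rates from group totals: rate(g) = total(g) / n."""
    s = pd.Series(totals, dtype=float)
    return (s / s.sum()).to_dict()


def write_table_tsv(table: PropertyTable) -> str:
    """Property table as TSV: accession, group, cluster, 20 residue values."""
    rows = []
    for r in table:
        rows.append(
            {
                "accession": r.accession,
                "group": r.group,
                "cluster": "" if r.cluster_id is None else r.cluster_id,
                **{a: r.values[i] for i, a in enumerate(RESIDUES)},
            }
        )
    df = pd.DataFrame(rows, columns=["accession", "group", "cluster", *RESIDUES])
    return df.to_csv(sep="\t", index=False)


def load_groups_sidecar(text: str) -> dict[str, str]:
    """Read a two-column TSV mapping accession -> functional group label."""
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("accession\t"):
            continue
        accession, group = line.split("\t")[:2]
        if group not in GROUPS:
            raise ValueError(f"{accession}: unknown group {group!r}")
        mapping[accession] = group
    return mapping


def apply_groups(table: PropertyTable, mapping: dict[str, str]) -> PropertyTable:
    return PropertyTable(
        [replace(r, group=mapping.get(r.accession, r.group)) for r in table]
    )


def write_groups_sidecar(table: PropertyTable) -> str:
    lines = ["accession\tgroup"]
    for r in table:
        lines.append(f"{r.accession}\t{r.group}")
    return "\n".join(lines) + "\n"


def load_feature_id_sidecar(text: str) -> dict[str, str]:
    """Read an optional two-column TSV mapping feature_id <-> accession."""
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        feature_id, accession = line.split("\t")[:2]
        mapping[accession] = feature_id
    return mapping


def apply_feature_ids(table: PropertyTable, mapping: dict[str, str]) -> PropertyTable:
    return PropertyTable(
        [replace(r, feature_id=mapping.get(r.accession, r.feature_id)) for r in table]
    )
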