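"""Peptide sequence and multi-label dataset handling.

Domain types (:class:`Peptide`, :class:`LabelSpace`, :class:`PeptideDataset`),
FASTA and label-table I/O, the dataset preprocessing filters (alphabet,
length, minimum class size) and the random train/test split.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class DatasetError(ValueError):
    """Raised for invalid datasets or I/O contract violations."""


class FastaParseError(DatasetError):
    """Raised when a FASTA file is malformed; message names the line."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with an optional set of function labels."""

    id: str
    sequence: str
    labels: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "labels", frozenset(self.labels))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelSpace:
    """Ordered, fixed label universe; index i is graph node i."""

    names: tuple[str, ...]

    def __post_init__(self):
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise DatasetError("label names must be distinct")
        object.__setattr__(self, "names", names)

    @property
    def M(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return len(self.names)


@dataclass
class PeptideDataset:
    """A list of peptides sharing one label space."""

    peptides: list[Peptide]
    label_space: LabelSpace
    split_tag: str = "unsplit"

    def __post_init__(self):
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            raise DatasetError("peptide ids must be unique within a dataset")
        space = set(self.label_space.names)
        for p in self.peptides:
            if not p.labels <= space:
                raise DatasetError(
                    f"peptide {p.id!r} carries labels outside the label space: "
                    f"{sorted(p.labels - space)}"
                )

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def label_matrix(self) -> np.ndarray:
        """N x M binary indicator matrix in label-space order."""
        M = self.label_space.M
        mat = np.zeros((len(self.peptides), M), dtype=np.int64)
        idx = {name: i for i, name in enumerate(self.label_space.names)}
        for r, p in enumerate(self.peptides):
            for lab in p.labels:
                mat[r, idx[lab]] = 1
        return mat

    def label_sets(self) -> list[frozenset[str]]:
        return [p.labels for p in self.peptides]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[Peptide]:
    """Read peptides from a FASTA file (labels left empty).

    The id is the header token before the first whitespace.  Sequence
    validation is deferred to :func:`validate_sequence` /
    :func:`apply_dataset_filters`; records with non-standard residues are
    retained here.
    """
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected a FASTA header line starting with '>'"
            )
        break
    peptides = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        peptides.append(Peptide(id=rec.id, sequence=str(rec.seq).upper()))
    return peptides


def write_fasta(peptides, path) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.sequence}\n")


def read_label_table(path, label_space: LabelSpace | None = None) -> tuple[dict[str, frozenset[str]], LabelSpace]:
    """Read a per-peptide label table.

    Two layouts are accepted:

    * wide: header ``id,label1,...,labelM`` with 0/1 cells;
    * two-column: header ``id,labels`` where the second field is a
      comma-joined label list (quoted as needed).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = list(df.columns)
    if len(cols) < 2:
        raise DatasetError(f"{path}: label table needs an id column plus labels")
    if len(cols) == 2 and cols[1].lower() in {"labels", "label"}:
        mapping = {
            str(row[cols[0]]): frozenset(x for x in str(row[cols[1]]).split(",") if x)
            for _, row in df.iterrows()
        }
        if label_space is None:
            names = sorted({lab for labs in mapping.values() for lab in labs})
            label_space = LabelSpace(tuple(names))
    else:
        names = cols[1:]
        mapping = {}
        for _, row in df.iterrows():
            labs = frozenset(n for n in names if str(row[n]).strip() in {"1", "1.0", "True"})
            mapping[str(row[cols[0]])] = labs
        if label_space is None:
            label_space = LabelSpace(tuple(names))
    return mapping, label_space


def write_label_table(dataset: PeptideDataset, path) -> None:
    """Write the wide 0/1 label table (header ``id,label1,...,labelM``)."""
    names = list(dataset.label_space.names)
    rows = [
        {"id": p.id, **{n: int(n in p.labels) for n in names}} for p in dataset.peptides
    ]
    pd.DataFrame(rows, columns=["id"] + names).to_csv(path, index=False)


def load_dataset(fasta_path, label_table_path, label_space: LabelSpace | None = None) -> PeptideDataset:
    """Join a FASTA file with its label table into a dataset."""
    peptides = read_fasta(fasta_path)
    mapping, space = read_label_table(label_table_path, label_space)
    labelled = []
    for p in peptides:
        labs = mapping.get(p.id, frozenset())
        labelled.append(replace(p, labels=labs))
    return PeptideDataset(labelled, space)


# ---------------------------------------------------------------------------
# Filters and split
# ---------------------------------------------------------------------------


def validate_sequence(sequence: str) -> bool:
    """True iff non-empty and, after upper-casing, all residues are standard."""
    if not sequence:
        return False
    return set(sequence.upper()) <= _STANDARD_SET


def apply_dataset_filters(
    data: PeptideDataset,
    min_len: int = 5,
    max_len: int = 50,
    min_class_size: int = 40,
    keep_ids: set[str] | None = None,
) -> PeptideDataset:
    """Apply the standard preprocessing filters, returning a new dataset.

    Order of operations: drop sequences with non-standard residues, drop
    sequences outside ``[min_len, max_len]``, then remove from the label
    space any label with fewer than ``min_class_size`` remaining positives;
    peptides left without labels are dropped.  ``keep_ids`` optionally
    restricts to a precomputed redundancy-reduced id set (e.g. CD-HIT
    cluster representatives computed externally).
    """
    if min_len > max_len:
        raise DatasetError(f"min_len {min_len} > max_len {max_len}")
    if min_class_size < 0:
        raise DatasetError("min_class_size must be >= 0")
    kept = [
        p
        for p in data.peptides
        if validate_sequence(p.sequence)
        and min_len <= len(p.sequence) <= max_len
        and (keep_ids is None or p.id in keep_ids)
    ]
    counts = {name: 0 for name in data.label_space.names}
    for p in kept:
        for lab in p.labels:
            counts[lab] += 1
    surviving = tuple(n for n in data.label_space.names if counts[n] >= min_class_size)
    if surviving != data.label_space.names:
        kept = [
            replace(p, labels=p.labels & set(surviving))
            for p in kept
        ]
    had_labels = any(p.labels for p in data.peptides)
    if had_labels:
        kept = [p for p in kept if p.labels]
    if not kept:
        raise DatasetError("all peptides removed by filters: empty dataset")
    return PeptideDataset(kept, LabelSpace(surviving), split_tag=data.split_tag)


def split_dataset(
    data: PeptideDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[PeptideDataset, PeptideDataset]:
    """Random disjoint train/test split; train size = round(N * fraction).

    With ``stratify=True`` the split is drawn within groups of identical
    label sets, which keeps rare label combinations represented on both
    sides; the default is the plain unstratified random split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must be in (0, 1)")
    n = len(data.peptides)
    if n < 2:
        raise DatasetError("need at least 2 peptides to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    if stratify:
        groups: dict[frozenset, list[int]] = {}
        for i, p in enumerate(data.peptides):
            groups.setdefault(p.labels, []).append(i)
        train_idx: list[int] = []
        order = []
        for key in sorted(groups, key=lambda s: (len(s), sorted(s))):
            idx = np.array(groups[key])
            rng.shuffle(idx)
            k = int(round(len(idx) * train_fraction))
            train_idx.extend(idx[:k].tolist())
            order.extend(idx[k:].tolist())
        # adjust to the exact global train size
        pool = train_idx + order
        train_set = set(pool[:n_train])
    else:
        perm = rng.permutation(n)
        train_set = set(perm[:n_train].tolist())
    train = [p for i, p in enumerate(data.peptides) if i in train_set]
    test = [p for i, p in enumerate(data.peptides) if i not in train_set]
    return (
        PeptideDataset(train, data.label_space, split_tag="train"),
        PeptideDataset(test, data.label_space, split_tag="test"),
    )
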