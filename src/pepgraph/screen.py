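"""High-confidence screening for novel multi-functional peptides.

Pipeline: length/alphabet filter candidate sequences, predict with a
trained ensemble, keep candidates whose probability clears a high
threshold for every required function, drop exact duplicates of the
training set, and rank by the weakest required-label probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import Peptide, PeptideDataset, validate_sequence
from .training import ensemble_probabilities


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    min_len: int = 4
    max_len: int = 40
    threshold: float = 0.95
    required_labels: frozenset[str] = frozenset()
    exclusion_ids_or_seqs: frozenset[str] = frozenset()

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ScreenError("threshold must be in (0, 1)")
        if self.min_len > self.max_len:
            raise ScreenError("min_len must be <= max_len")
        object.__setattr__(self, "required_labels", frozenset(self.required_labels))
        object.__setattr__(
            self, "exclusion_ids_or_seqs", frozenset(self.exclusion_ids_or_seqs)
        )


def length_filter(peptides, config: ScreenConfig) -> list[Peptide]:
    """Keep valid-alphabet sequences with min_len <= L <= max_len."""
    return [
        p for p in peptides
        if validate_sequence(p.sequence)
        and config.min_len <= len(p.sequence) <= config.max_len
    ]


def screen(candidates, ensemble, config: ScreenConfig,
           training_set: PeptideDataset | None = None) -> pd.DataFrame:
    """Screen candidate peptides with a trained ensemble.

    Returns a table (id, sequence, length, one probability column per
    label, min_required_prob) of candidates that clear ``config.threshold``
    on every required label, are not exact-sequence duplicates of the
    training set or the exclusion set, sorted by min_required_prob
    descending.  Deterministic for fixed models and inputs.
    """
    space = ensemble[0].label_space
    missing = config.required_labels - set(space.names)
    if missing:
        raise ScreenError(f"required labels absent from the model: {sorted(missing)}")
    required = sorted(config.required_labels) or list(space.names)
    kept = length_filter(candidates, config)
    if not kept:
        return _empty_table(space, required)
    probs = ensemble_probabilities(ensemble, [p.sequence for p in kept])
    known = set()
    if training_set is not None:
        known |= {p.sequence.upper() for p in training_set.peptides}
    known |= {s.upper() for s in config.exclusion_ids_or_seqs}
    excluded_ids = {s for s in config.exclusion_ids_or_seqs}
    req_idx = [space.index(n) for n in required]
    rows = []
    for pep, row in zip(kept, probs):
        if pep.sequence.upper() in known or pep.id in excluded_ids:
            continue
        req_probs = row[req_idx]
        if (req_probs >= config.threshold).all():
            rows.append({
                "id": pep.id,
                "sequence": pep.sequence,
                "length": len(pep.sequence),
                **{n: row[i] for i, n in enumerate(space.names)},
                "min_required_prob": float(req_probs.min()),
            })
    df = pd.DataFrame(rows, columns=_columns(space))
    if len(df):
        df = df.sort_values("min_required_prob", ascending=False,
                            kind="mergesort").reset_index(drop=True)
    return df


def _columns(space):
    return ["id", "sequence", "length", *space.names, "min_required_prob"]


def _empty_table(space, required):
    return pd.DataFrame(columns=_columns(space))


def write_candidates(df: pd.DataFrame, table_path, fasta_path=None) -> None:
    df.to_csv(table_path, index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for _, row in df.iterrows():
                fh.write(f">{row['id']}\n{row['sequence']}\n")
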