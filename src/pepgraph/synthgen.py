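"""Synthetic multi-label peptide benchmark generator.

Emulates the statistical structure of curated bioactive-peptide corpora:
short sequences over the 20-residue alphabet, a handful of function
labels with strong class imbalance, and a minority of peptides carrying
exactly two correlated labels.  Each label is realized as a short motif
implanted into i.i.d. background sequence with per-residue mutation
noise; a manifest records ground-truth implant positions so that
interpretability statistics can be checked against a known signal.

It emulates label/motif structure only — not real peptide
physicochemistry, homology or length/composition couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._properties import AA_ORDER, UNIPROT_FREQUENCIES
from .seqdata import LabelSpace, Peptide, PeptideDataset, write_fasta, write_label_table


class SynthError(ValueError):
    pass


#: MFBP-like default: five labels, one co-occurring pair, imbalanced classes.
DEFAULT_MOTIFS = {
    "ACP": "KWKLF",
    "ADP": "CPYNC",
    "AHP": "VPPHG",
    "AIP": "DENMD",
    "AMP": "GIGAV",
}

DEFAULT_PROPORTIONS = {
    "ACP": 0.12, "ADP": 0.08, "AHP": 0.25, "AIP": 0.15, "AMP": 0.40,
}

DEFAULT_COOCCURRENCE = {("ACP", "AMP"): 0.05}


def uniprot_background() -> np.ndarray:
    """Swiss-Prot-like residue frequencies in AA_ORDER."""
    v = np.array([UNIPROT_FREQUENCIES[a] for a in AA_ORDER])
    return v / v.sum()


@dataclass(frozen=True)
class SynthConfig:
    n_samples: int = 2000
    label_motifs: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    cooccurrence: dict = field(default_factory=lambda: dict(DEFAULT_COOCCURRENCE))
    length_range: tuple[int, int] = (10, 40)
    background_frequencies: np.ndarray | None = None  # uniform when None
    motif_mutation_rate: float = 0.1
    seed: int = 0

    @property
    def n_labels(self) -> int:
        return len(self.label_motifs)

    def validate(self) -> None:
        labels = set(self.label_motifs)
        if not labels:
            raise SynthError("need at least one label motif")
        if set(self.class_proportions) != labels:
            raise SynthError("class_proportions must cover exactly the motif labels")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise SynthError("invalid length range")
        for lab, motif in self.label_motifs.items():
            if not set(motif) <= set(AA_ORDER):
                raise SynthError(f"motif for {lab!r} uses non-standard residues")
            if len(motif) > lo:
                raise SynthError(
                    f"motif for {lab!r} (length {len(motif)}) exceeds the "
                    f"minimum sequence length {lo}"
                )
        total_pair = 0.0
        for (a, b), p in self.cooccurrence.items():
            if a not in labels or b not in labels or a == b:
                raise SynthError(f"invalid co-occurrence pair ({a!r}, {b!r})")
            if p < 0:
                raise SynthError("pair probabilities must be >= 0")
            if len(self.label_motifs[a]) + len(self.label_motifs[b]) > lo:
                raise SynthError(
                    f"motifs for pair ({a}, {b}) cannot both fit in the "
                    f"minimum sequence length {lo}"
                )
            total_pair += p
        if total_pair >= 1.0:
            raise SynthError("pair probabilities must sum to < 1")
        if not 0.0 <= self.motif_mutation_rate <= 1.0:
            raise SynthError("motif_mutation_rate must be a probability")
        props = np.array([self.class_proportions[l] for l in sorted(labels)])
        if (props < 0).any() or props.sum() <= 0:
            raise SynthError("class proportions must be nonnegative, not all zero")

    def background(self) -> np.ndarray:
        if self.background_frequencies is None:
            return np.full(20, 1.0 / 20.0)
        v = np.asarray(self.background_frequencies, dtype=np.float64)
        if v.shape != (20,) or (v < 0).any():
            raise SynthError("background_frequencies must be a nonnegative 20-vector")
        if not np.isclose(v.sum(), 1.0):
            raise SynthError("background_frequencies must sum to 1")
        return v


def _mutate(motif: str, rate: float, rng: np.random.Generator,
            background: np.ndarray) -> str:
    if rate <= 0:
        return motif
    out = []
    for ch in motif:
        if rng.random() < rate:
            out.append(AA_ORDER[rng.choice(20, p=background)])
        else:
            out.append(ch)
    return "".join(out)


def _place_motifs(length: int, motif_lens: list[int],
                  rng: np.random.Generator) -> list[int]:
    """Uniform non-overlapping start positions (rejection sampling)."""
    for _ in range(1000):
        starts = [int(rng.integers(0, length - ml + 1)) for ml in motif_lens]
        spans = sorted(zip(starts, motif_lens))
        if all(
            spans[i][0] + spans[i][1] <= spans[i + 1][0]
            for i in range(len(spans) - 1)
        ):
            return starts
    raise SynthError(f"could not place motifs of lengths {motif_lens} in length {length}")


def _draw_label_set(config: SynthConfig, rng: np.random.Generator) -> frozenset[str]:
    pairs = sorted(config.cooccurrence.items())
    u = rng.random()
    acc = 0.0
    for (a, b), p in pairs:
        acc += p
        if u < acc:
            return frozenset((a, b))
    labels = sorted(config.label_motifs)
    props = np.array([config.class_proportions[l] for l in labels])
    props = props / props.sum()
    return frozenset((labels[rng.choice(len(labels), p=props)],))


def generate(config: SynthConfig | None = None) -> tuple[PeptideDataset, list[dict]]:
    """Generate a dataset plus a ground-truth manifest.

    The manifest has one record per peptide: id, labels, and per-label
    implant (start, end) half-open residue spans (0-based).
    Deterministic given ``config.seed``.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    background = config.background()
    lo, hi = config.length_range
    peptides, manifest = [], []
    for idx in range(config.n_samples):
        labels = _draw_label_set(config, rng)
        motifs = {lab: config.label_motifs[lab] for lab in sorted(labels)}
        length = int(rng.integers(lo, hi + 1))
        seq = list(AA_ORDER[i] for i in rng.choice(20, size=length, p=background))
        starts = _place_motifs(length, [len(m) for m in motifs.values()], rng)
        implants = {}
        for (lab, motif), start in zip(motifs.items(), starts):
            realized = _mutate(motif, config.motif_mutation_rate, rng, background)
            seq[start : start + len(motif)] = list(realized)
            implants[lab] = (start, start + len(motif))
        pid = f"synth_{idx:05d}"
        peptides.append(Peptide(id=pid, sequence="".join(seq), labels=labels))
        manifest.append({"id": pid, "labels": sorted(labels), "implants": implants})
    space = LabelSpace(tuple(sorted(config.label_motifs)))
    return PeptideDataset(peptides, space), manifest


def reference_fixture(seed: int = 20240501) -> tuple[PeptideDataset, list[dict], SynthConfig]:
    """The in-repo reference benchmark: 5 labels, n = 2000, 5% dual-label
    (ACP, AMP), 10% motif mutation, lengths 10-40."""
    config = SynthConfig(seed=seed)
    data, manifest = generate(config)
    return data, manifest, config


def motif_match_predict(sequences, label_motifs: dict) -> list[frozenset[str]]:
    """Trivial substring classifier used to calibrate learnability."""
    return [
        frozenset(lab for lab, motif in label_motifs.items() if motif in seq.upper())
        for seq in sequences
    ]


def write_fixture(dataset: PeptideDataset, manifest: list[dict], outdir) -> None:
    """Write FASTA + wide label table + manifest TSV into ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(dataset.peptides, os.path.join(outdir, "peptides.fasta"))
    write_label_table(dataset, os.path.join(outdir, "labels.csv"))
    rows = []
    for rec in manifest:
        for lab, (start, end) in rec["implants"].items():
            rows.append({"id": rec["id"], "label": lab, "start": start, "end": end})
    pd.DataFrame(rows, columns=["id", "label", "start", "end"]).to_csv(
        os.path.join(outdir, "manifest.tsv"), sep="\t", index=False
    )
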