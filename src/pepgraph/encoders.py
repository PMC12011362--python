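"""Peptide representation encoders.

Three families produce the fixed-dimension peptide representation ``p``
consumed by the graph classifier:

* composition features — AAC, PAAC, DP and CTDD descriptors, optionally
  passed through a learned linear projection;
* a small trainable transformer encoder (multi-head self-attention with a
  tanh pooler over a prepended start token), the in-package stand-in for a
  protein language model at desk scale;
* an adapter that looks up externally precomputed representations by
  peptide id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Parameter, Tensor
from ._properties import (
    AA_ORDER,
    CTD_GROUPS,
    PAAC_HYDROPHOBICITY,
    PAAC_HYDROPHILICITY,
    PAAC_SIDECHAIN_MASS,
)

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class EncoderError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRepresentation:
    """Fixed-dimension vector representation of one peptide."""

    vector: np.ndarray
    encoder_tag: str

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


# ---------------------------------------------------------------------------
# Composition features
# ---------------------------------------------------------------------------


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    if not sequence:
        raise EncoderError("empty sequence")
    bad = set(sequence) - set(AA_ORDER)
    if bad:
        raise EncoderError(f"non-standard residues in sequence: {sorted(bad)}")
    return sequence


def encode_aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: residue frequencies in AA_ORDER (sums to 1)."""
    sequence = _check_sequence(sequence)
    v = np.zeros(20)
    for ch in sequence:
        v[_AA_INDEX[ch]] += 1.0
    return v / len(sequence)


def _paac_normalized_properties() -> np.ndarray:
    """3 x 20 matrix of standardized property values (mean 0, population sd 1)."""
    props = []
    for table in (PAAC_HYDROPHOBICITY, PAAC_HYDROPHILICITY, PAAC_SIDECHAIN_MASS):
        vals = np.array([table[a] for a in AA_ORDER])
        props.append((vals - vals.mean()) / vals.std())
    return np.stack(props)


_PAAC_PROPS = _paac_normalized_properties()


def _paac_theta(a: str, b: str) -> float:
    """Mean squared difference of the three standardized properties."""
    ia, ib = _AA_INDEX[a], _AA_INDEX[b]
    return float(np.mean((_PAAC_PROPS[:, ia] - _PAAC_PROPS[:, ib]) ** 2))


def encode_paac(sequence: str, lam: int = 4, weight: float = 0.05) -> np.ndarray:
    """Pseudo-amino-acid composition (length ``20 + lam``, sums to 1).

    The first 20 entries are weighted residue frequencies; the last ``lam``
    are sequence-order correlation factors computed from tier-g averaged
    property differences, down-weighted by ``weight``.
    """
    sequence = _check_sequence(sequence)
    L = len(sequence)
    if lam < 1:
        raise EncoderError("lambda must be >= 1")
    if L <= lam:
        raise EncoderError(f"sequence length {L} must exceed lambda {lam}")
    if not 0.0 < weight <= 1.0:
        raise EncoderError("weight must be in (0, 1]")
    freqs = encode_aac(sequence)
    thetas = np.array(
        [
            np.mean([_paac_theta(sequence[i], sequence[i + g]) for i in range(L - g)])
            for g in range(1, lam + 1)
        ]
    )
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


def encode_dp(sequence: str, max_distance: int = 1) -> np.ndarray:
    """Distance-pair composition.

    For each gap ``g`` in ``0..max_distance`` (``g`` = number of intervening
    residues; ``g=0`` means adjacent), the 400 ordered residue-pair
    frequencies; each non-empty tier sums to 1.  Output length is
    ``400 * (max_distance + 1)``.
    """
    sequence = _check_sequence(sequence)
    L = len(sequence)
    if L <= max_distance:
        raise EncoderError(f"sequence length {L} must exceed max_distance {max_distance}")
    tiers = []
    for g in range(max_distance + 1):
        counts = np.zeros(400)
        step = g + 1
        for i in range(L - step):
            a, b = sequence[i], sequence[i + step]
            counts[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1.0
        total = counts.sum()
        if total > 0:
            counts /= total
        tiers.append(counts)
    return np.concatenate(tiers)


def encode_ctdd(sequence: str) -> np.ndarray:
    """Composition/transition/distribution "D" descriptor.

    For each of the 13 property partitions and each of its 3 residue
    groups, the relative sequence positions (percent of L) of the first,
    25%, 50%, 75% and last occurrence of a group residue; groups absent
    from the sequence contribute zeros.  Length ``13 * 3 * 5 = 195``.
    """
    sequence = _check_sequence(sequence)
    L = len(sequence)
    out = []
    for prop in CTD_GROUPS:
        for group in CTD_GROUPS[prop]:
            members = set(group)
            positions = [i + 1 for i, ch in enumerate(sequence) if ch in members]
            n = len(positions)
            if n == 0:
                out.extend([0.0] * 5)
                continue
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = 1 if frac == 0.0 else int(np.ceil(frac * n))
                out.append(positions[k - 1] / L * 100.0)
    return np.array(out)


@dataclass(frozen=True)
class CompositionFeatureConfig:
    """Which composition descriptor to compute, with its parameters."""

    # DP is the default: it retains residue adjacency, which motif-like
    # functional signals need; AAC/PAAC/CTDD marginalize order away.
    feature_kind: str = "DP"  # one of AAC, PAAC, DP, CTDD
    paac_lambda: int = 4
    paac_weight: float = 0.05
    dp_max_distance: int = 1

    def feature_fn(self):
        kind = self.feature_kind.upper()
        if kind == "AAC":
            return encode_aac
        if kind == "PAAC":
            return lambda s: encode_paac(s, self.paac_lambda, self.paac_weight)
        if kind == "DP":
            return lambda s: encode_dp(s, self.dp_max_distance)
        if kind == "CTDD":
            return encode_ctdd
        raise EncoderError(f"unknown feature kind {self.feature_kind!r}")

    @property
    def dim(self) -> int:
        kind = self.feature_kind.upper()
        return {
            "AAC": 20,
            "PAAC": 20 + self.paac_lambda,
            "DP": 400 * (self.dp_max_distance + 1),
            "CTDD": 195,
        }[kind]


# ---------------------------------------------------------------------------
# Composition encoder (feature vector + optional learned projection)
# ---------------------------------------------------------------------------


class CompositionEncoder:
    """Composition descriptor, optionally projected to ``d_repr``.

    Without a projection the representation equals the raw descriptor.
    With ``project_to`` set, a learned linear layer maps the descriptor to
    the requested dimension; that projection weight is also the designated
    adversarial perturbation site for composition models.
    """

    def __init__(self, config: CompositionFeatureConfig | None = None,
                 project_to: int | None = None, standardize: bool = False,
                 seed: int = 0):
        self.config = config or CompositionFeatureConfig()
        self._fn = self.config.feature_fn()
        self._cache: dict[str, np.ndarray] = {}
        self.tag = f"composition:{self.config.feature_kind}"
        self.standardize = standardize
        self.scaler_mu: np.ndarray | None = None
        self.scaler_sd: np.ndarray | None = None
        if project_to is None:
            self.d_repr = self.config.dim
            self.W = None
            self.b = None
        else:
            rng = np.random.default_rng(seed)
            f = self.config.dim
            self.d_repr = project_to
            self.W = Parameter(rng.normal(0.0, np.sqrt(1.0 / f), size=(f, project_to)))
            self.b = Parameter(np.zeros(project_to))

    def features(self, sequences) -> np.ndarray:
        rows = []
        for s in sequences:
            key = s.upper()
            if key not in self._cache:
                self._cache[key] = self._fn(key)
            rows.append(self._cache[key])
        return np.stack(rows)

    @property
    def needs_fit(self) -> bool:
        return self.standardize and self.scaler_mu is None

    def fit_scaler(self, sequences) -> None:
        """Fit the per-dimension z-score scaler on training sequences.

        Descriptor entries are tiny for high-dimensional features (each DP
        tier sums to 1 over 400 entries), which would starve the attention
        logits downstream; standardization keeps the model in a
        well-scaled regime.
        """
        X = self.features(sequences)
        self.scaler_mu = X.mean(axis=0)
        self.scaler_sd = np.maximum(X.std(axis=0), 1e-6)

    def encode_batch(self, sequences, training: bool = False,
                     rng: np.random.Generator | None = None,
                     trace: bool = False) -> tuple[Tensor, list]:
        x = self.features(sequences)
        if self.standardize:
            if self.scaler_mu is None:
                raise EncoderError(
                    "standardizing encoder used before fit_scaler(); "
                    "train() fits it on the training set automatically"
                )
            x = (x - self.scaler_mu) / self.scaler_sd
        x = Tensor(x)
        if self.W is not None:
            x = x @ self.W + self.b
        return x, []

    def parameters(self) -> list[Parameter]:
        return [p for p in (self.W, self.b) if p is not None]

    def perturbation_site(self) -> Parameter | None:
        return self.W


# ---------------------------------------------------------------------------
# Trainable transformer encoder
# ---------------------------------------------------------------------------

# token vocabulary: 20 residues plus special tokens
PAD, START, END, UNK = 0, 1, 2, 3
VOCAB = ["<pad>", "<start>", "<end>", "<unk>"] + list(AA_ORDER)
_TOKEN_INDEX = {t: i for i, t in enumerate(VOCAB)}


def tokenize(sequence: str, max_len: int) -> list[int]:
    """``<start> seq <end>`` token ids, truncated to ``max_len`` total."""
    ids = [START]
    for ch in sequence.upper():
        ids.append(_TOKEN_INDEX.get(ch, UNK))
    ids.append(END)
    return ids[:max_len]


@dataclass
class TransformerParams:
    """Hyperparameters of the internal attention encoder."""

    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    d_ff: int = 256
    max_len: int = 64
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise EncoderError("d_model must be divisible by n_heads")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


class TransformerEncoder:
    """Small BERT-style encoder over residue tokens with a tanh pooler.

    The peptide representation is the start-token state passed through a
    learned dense layer with tanh (the standard pooler contract).  Per-head
    attention maps (the softmax-normalized query-key products β) can be
    traced for interpretability.
    """

    def __init__(self, params: TransformerParams | None = None, seed: int = 0):
        self.params = params or TransformerParams()
        p = self.params
        self.d_repr = p.d_model
        self.tag = "transformer"
        rng = np.random.default_rng(seed)

        def init(*shape):
            return Parameter(rng.normal(0.0, np.sqrt(1.0 / shape[-2]), size=shape))

        dm, dh, H = p.d_model, p.d_head, p.n_heads
        self.token_emb = Parameter(rng.normal(0.0, 0.02, size=(len(VOCAB), dm)))
        self.pos_emb = Parameter(rng.normal(0.0, 0.02, size=(p.max_len, dm)))
        self.layers = []
        for _ in range(p.n_layers):
            layer = {
                "Wq": init(H, dm, dh), "Wk": init(H, dm, dh), "Wv": init(H, dm, dh),
                "Wo": init(H * dh, dm),
                "ln1_g": Parameter(np.ones(dm)), "ln1_b": Parameter(np.zeros(dm)),
                "W1": init(dm, p.d_ff), "b1": Parameter(np.zeros(p.d_ff)),
                "W2": init(p.d_ff, dm), "b2": Parameter(np.zeros(dm)),
                "ln2_g": Parameter(np.ones(dm)), "ln2_b": Parameter(np.zeros(dm)),
            }
            self.layers.append(layer)
        self.pool_W = init(dm, dm)
        self.pool_b = Parameter(np.zeros(dm))

    # -- building blocks ----------------------------------------------

    @staticmethod
    def _layer_norm(x: Tensor, gamma: Parameter, beta: Parameter, eps: float = 1e-5) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + eps).sqrt() * gamma + beta

    def attention_layer(self, x: Tensor, layer: int,
                        mask: np.ndarray | None = None,
                        training: bool = False,
                        rng: np.random.Generator | None = None) -> tuple[Tensor, np.ndarray]:
        """One encoder block: MHA + residual/LN + feed-forward + residual/LN.

        ``x`` is (B, L, d_model); ``mask`` is a (B, L) 1/0 key-validity
        mask.  Returns the updated states and the (B, H, L, L) attention
        maps β (each row softmax-normalized).
        """
        p = self.params
        lay = self.layers[layer]
        dh = p.d_head
        xb = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])  # (B,1,L,dm)
        q = xb @ lay["Wq"]  # (B,H,L,dh)
        k = xb @ lay["Wk"]
        v = xb @ lay["Wv"]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (B,H,L,L)
        if mask is not None:
            bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e9)
            scores = scores + bias
        beta = scores.softmax(axis=-1)
        heads = beta @ v  # (B,H,L,dh)
        B, H, L, _ = heads.shape
        merged = heads.swapaxes(1, 2).reshape(B, L, H * dh)
        attn_out = merged @ lay["Wo"]
        attn_out = self._dropout(attn_out, training, rng)
        x = self._layer_norm(x + attn_out, lay["ln1_g"], lay["ln1_b"])
        ff = (x @ lay["W1"] + lay["b1"]).relu() @ lay["W2"] + lay["b2"]
        ff = self._dropout(ff, training, rng)
        x = self._layer_norm(x + ff, lay["ln2_g"], lay["ln2_b"])
        return x, beta.data

    def _dropout(self, x: Tensor, training: bool, rng) -> Tensor:
        rate = self.params.dropout
        if not training or rate <= 0.0:
            return x
        if rng is None:
            rng = np.random.default_rng()
        keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
        return x * keep

    # -- public API ----------------------------------------------------

    def encode_batch(self, sequences, training: bool = False,
                     rng: np.random.Generator | None = None,
                     trace: bool = False) -> tuple[Tensor, list]:
        p = self.params
        toks = [tokenize(s, p.max_len) for s in sequences]
        L = max(len(t) for t in toks)
        ids = np.zeros((len(toks), L), dtype=np.int64)
        mask = np.zeros((len(toks), L))
        for i, t in enumerate(toks):
            ids[i, : len(t)] = t
            mask[i, : len(t)] = 1.0
        x = self.token_emb[ids] + self.pos_emb[np.arange(L)]
        x = self._dropout(x, training, rng)
        betas = []
        for li in range(p.n_layers):
            x, beta = self.attention_layer(x, li, mask=mask, training=training, rng=rng)
            if trace:
                betas.append(beta)
        pooled = (x[:, 0, :] @ self.pool_W + self.pool_b).tanh()
        return pooled, betas

    def parameters(self) -> list[Parameter]:
        out = [self.token_emb, self.pos_emb, self.pool_W, self.pool_b]
        for lay in self.layers:
            out.extend(lay.values())
        return out

    def perturbation_site(self) -> Parameter:
        return self.token_emb


# ---------------------------------------------------------------------------
# External-pLM adapter
# ---------------------------------------------------------------------------


class PLMAdapterEncoder:
    """Looks up externally precomputed representations by peptide id.

    The table maps id -> d_repr vector (e.g. the pooler output of a large
    protein language model computed offline).  This encoder is frozen: it
    has no trainable parameters and no perturbation site.
    """

    def __init__(self, table: dict[str, np.ndarray]):
        if not table:
            raise EncoderError("empty representation table")
        dims = {len(v) for v in table.values()}
        if len(dims) != 1:
            raise EncoderError(f"inconsistent representation dimensions: {sorted(dims)}")
        self.table = {k: np.asarray(v, dtype=np.float64) for k, v in table.items()}
        self.d_repr = dims.pop()
        self.tag = "plm-adapter"

    @classmethod
    def from_table_file(cls, path) -> "PLMAdapterEncoder":
        df = pd.read_csv(path)
        ids = df.iloc[:, 0].astype(str)
        mat = df.iloc[:, 1:].to_numpy(dtype=np.float64)
        return cls({i: row for i, row in zip(ids, mat)})

    def lookup(self, peptide_id: str) -> np.ndarray:
        if peptide_id not in self.table:
            raise EncoderError(f"no precomputed representation for id {peptide_id!r}")
        return self.table[peptide_id]

    def encode_batch(self, ids, training: bool = False,
                     rng: np.random.Generator | None = None,
                     trace: bool = False) -> tuple[Tensor, list]:
        return Tensor(np.stack([self.lookup(i) for i in ids])), []

    def parameters(self) -> list[Parameter]:
        return []

    def perturbation_site(self) -> None:
        return None


def encode_peptide(sequence_or_id: str, encoder) -> PeptideRepresentation:
    """Encode a single peptide with any encoder handle.

    For the adapter the argument is the peptide id; for all other encoders
    it is the sequence.
    """
    vec, _ = encoder.encode_batch([sequence_or_id])
    return PeptideRepresentation(vector=vec.data[0].copy(), encoder_tag=encoder.tag)
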