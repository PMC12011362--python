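import numpy as np
import pytest
from hypothesis import given, strategies as st

import pepgraph as pg
from pepgraph._autodiff import Tensor
from pepgraph._properties import AA_ORDER, CTD_GROUPS
from pepgraph.encoders import EncoderError, _paac_theta

SEQS = st.text(alphabet=AA_ORDER, min_size=1, max_size=40)


# ---------------------------------------------------------------- AAC ----

def test_aac_examples():
    v = pg.encode_aac("AAAA")
    assert v[AA_ORDER.index("A")] == 1.0 and v.sum() == 1.0
    v = pg.encode_aac("ACDE")
    for ch in "ACDE":
        assert v[AA_ORDER.index(ch)] == pytest.approx(0.25)


@given(SEQS)
def test_aac_normalized_and_shuffle_invariant(seq):
    v = pg.encode_aac(seq)
    assert abs(v.sum() - 1.0) < 1e-12
    shuffled = "".join(sorted(seq))
    assert np.allclose(pg.encode_aac(shuffled), v)


def test_aac_empty_raises():
    with pytest.raises(EncoderError):
        pg.encode_aac("")


# --------------------------------------------------------------- PAAC ----

def paac_oracle(seq, lam, weight):
    """Direct-summation pseudo-amino-acid composition, written from the
    definition: tier-g correlation = mean over residue pairs at gap g of
    the mean squared standardized-property difference."""
    L = len(seq)
    freqs = np.array([seq.count(a) for a in AA_ORDER], dtype=float) / L
    thetas = []
    for g in range(1, lam + 1):
        total = 0.0
        for i in range(L - g):
            total += _paac_theta(seq[i], seq[i + g])
        thetas.append(total / (L - g))
    thetas = np.array(thetas)
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


def test_paac_identical_residues_reduce_to_aac():
    v = pg.encode_paac("AAAA", lam=1, weight=0.05)
    assert np.allclose(v[:20], pg.encode_aac("AAAA"))
    assert v[20] == 0.0


def test_paac_matches_bruteforce_oracle():
    v = pg.encode_paac("ACACAC", lam=2, weight=0.05)
    assert np.allclose(v, paac_oracle("ACACAC", 2, 0.05), atol=1e-12)


@given(st.text(alphabet=AA_ORDER, min_size=5, max_size=30))
def test_paac_normalization(seq):
    v = pg.encode_paac(seq, lam=4, weight=0.05)
    assert v.shape == (24,)
    assert (v >= 0).all()
    assert abs(v.sum() - 1.0) < 1e-9


def test_paac_lambda_too_large_names_both_values():
    with pytest.raises(EncoderError, match="length 3 must exceed lambda 3"):
        pg.encode_paac("ACD", lam=3, weight=0.05)


# ----------------------------------------------------------------- DP ----

def test_dp_adjacent_pair():
    v = pg.encode_dp("AC", max_distance=0)
    assert v.shape == (400,)
    idx = AA_ORDER.index("A") * 20 + AA_ORDER.index("C")
    assert v[idx] == 1.0 and v.sum() == 1.0


def test_dp_two_tiers_enumeration():
    # "AAA": tier 0 has pairs (A,A),(A,A); tier 1 has (A,A)
    v = pg.encode_dp("AAA", max_distance=1)
    aa = AA_ORDER.index("A") * 20 + AA_ORDER.index("A")  # (A,A) within a tier
    assert v[aa] == 1.0
    assert v[400 + aa] == 1.0
    assert v.sum() == 2.0


@given(st.text(alphabet=AA_ORDER, min_size=3, max_size=30))
def test_dp_tiers_each_normalized(seq):
    v = pg.encode_dp(seq, max_distance=1).reshape(2, 400)
    for tier in v:
        assert abs(tier.sum() - 1.0) < 1e-12


def test_dp_order_sensitive():
    assert not np.allclose(pg.encode_dp("ACDE", 1), pg.encode_dp("EDCA", 1))


# --------------------------------------------------------------- CTDD ----

def test_ctd_groups_partition_alphabet():
    for prop, groups in CTD_GROUPS.items():
        joined = "".join(groups)
        assert len(joined) == 20, prop
        assert set(joined) == set(AA_ORDER), prop


def test_ctdd_positional_oracle_single_group():
    # all residues of "KRKR" are in group 1 of the charge property
    v = pg.encode_ctdd("KRKR")
    props = list(CTD_GROUPS)
    base = props.index("charge") * 15
    # occurrences at positions 1..4: quantile targets 1, ceil(1), ceil(2), ceil(3), 4
    expect = np.array([1, 1, 2, 3, 4]) / 4 * 100
    assert np.allclose(v[base : base + 5], expect)
    assert np.all(v[base + 5 : base + 15] == 0.0)  # groups 2-3 absent


def test_ctdd_shape():
    assert pg.encode_ctdd("ACDEFGHIKL").shape == (13 * 3 * 5,)


def test_ctdd_within_group_substitution_invariant():
    # D and E are both group-3 residues of the charge property; swapping
    # them leaves the charge descriptor unchanged
    v1, v2 = pg.encode_ctdd("ADAD"), pg.encode_ctdd("AEAE")
    base = list(CTD_GROUPS).index("charge") * 15
    assert np.allclose(v1[base : base + 15], v2[base : base + 15])


# -------------------------------------------------- transformer encoder ----

def test_attention_single_token_is_identity_weight():
    enc = pg.TransformerEncoder(
        pg.TransformerParams(n_layers=1, n_heads=2, d_model=8, d_ff=16, max_len=8),
        seed=0,
    )
    x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 8)))
    _, beta = enc.attention_layer(x, 0)
    assert np.allclose(beta, 1.0)


def test_attention_identical_tokens_give_uniform_rows():
    enc = pg.TransformerEncoder(
        pg.TransformerParams(n_layers=1, n_heads=2, d_model=8, d_ff=16, max_len=8),
        seed=0,
    )
    row = np.random.default_rng(1).normal(size=8)
    x = Tensor(np.tile(row, (1, 5, 1)))
    _, beta = enc.attention_layer(x, 0)
    assert np.allclose(beta, 1.0 / 5.0, atol=1e-12)


def test_attention_matches_scalar_oracle():
    """2-token, 1-head, 2-dim attention vs explicit scalar arithmetic."""
    enc = pg.TransformerEncoder(
        pg.TransformerParams(n_layers=1, n_heads=1, d_model=2, d_ff=4, max_len=4),
        seed=0,
    )
    lay = enc.layers[0]
    lay["Wq"].data = np.array([[[1.0, 0.0], [0.0, 1.0]]])
    lay["Wk"].data = np.array([[[0.0, 1.0], [1.0, 0.0]]])
    lay["Wv"].data = np.array([[[2.0, 0.0], [0.0, 2.0]]])
    x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    _, beta = enc.attention_layer(Tensor(x), 0)
    # q_i = x_i, k_1=(2,1), k_2=(4,3), v_i = 2 x_i; scores q.k/sqrt(2)
    s = np.array([
        [1 * 2 + 2 * 1, 1 * 4 + 2 * 3],
        [3 * 2 + 4 * 1, 3 * 4 + 4 * 3],
    ]) / np.sqrt(2.0)
    expect = np.exp(s) / np.exp(s).sum(axis=1, keepdims=True)
    assert np.allclose(beta[0, 0], expect, atol=1e-12)


@given(st.lists(st.text(alphabet=AA_ORDER, min_size=2, max_size=20), min_size=1, max_size=4))
def test_encoder_beta_rows_sum_to_one(seqs):
    enc = pg.TransformerEncoder(
        pg.TransformerParams(n_layers=2, n_heads=2, d_model=8, d_ff=16, max_len=24),
        seed=0,
    )
    _, betas = enc.encode_batch(seqs, trace=True)
    for beta in betas:
        assert np.allclose(beta.sum(axis=-1), 1.0, atol=1e-6)


def test_encoder_gradient_matches_finite_difference():
    """Autodiff gradient of a scalar loss w.r.t. token embeddings on a
    3-token toy, against central finite differences."""
    enc = pg.TransformerEncoder(
        pg.TransformerParams(n_layers=1, n_heads=2, d_model=8, d_ff=16, max_len=8),
        seed=3,
    )

    def loss_val():
        out, _ = enc.encode_batch(["ACD"])
        return float((out * out).sum().data)

    out, _ = enc.encode_batch(["ACD"])
    loss = (out * out).sum()
    for p in enc.parameters():
        p.zero_grad()
    loss.backward()
    g = enc.token_emb.grad
    rng = np.random.default_rng(0)
    for _ in range(3):
        i = int(rng.integers(4, 8))  # a residue token used by "ACD"
        j = int(rng.integers(0, 8))
        eps, orig = 1e-6, enc.token_emb.data[i, j]
        enc.token_emb.data[i, j] = orig + eps
        lp = loss_val()
        enc.token_emb.data[i, j] = orig - eps
        lm = loss_val()
        enc.token_emb.data[i, j] = orig
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - g[i, j]) <= 1e-4 * max(abs(fd), 1e-8)


# ------------------------------------------------------- encode_peptide ----

def test_composition_without_projection_is_raw_features():
    enc = pg.CompositionEncoder(pg.CompositionFeatureConfig("AAC"))
    rep = pg.encode_peptide("ACDE", enc)
    assert np.array_equal(rep.vector, pg.encode_aac("ACDE"))
    assert rep.encoder_tag == "composition:AAC"


def test_encode_peptide_deterministic():
    enc = pg.CompositionEncoder(pg.CompositionFeatureConfig("DP"), project_to=16)
    a = pg.encode_peptide("ACDEFG", enc)
    b = pg.encode_peptide("ACDEFG", enc)
    assert np.array_equal(a.vector, b.vector)


def test_standardizing_encoder_requires_fit():
    enc = pg.CompositionEncoder(pg.CompositionFeatureConfig("AAC"), standardize=True)
    with pytest.raises(EncoderError, match="fit_scaler"):
        enc.encode_batch(["ACDE"])
    enc.fit_scaler(["ACDE", "GGKK", "WWYY"])
    out, _ = enc.encode_batch(["ACDE"])
    assert out.shape == (1, 20)


def test_plm_adapter_lookup_and_missing_id():
    table = {"p1": np.arange(4.0), "p2": np.ones(4), "p3": np.zeros(4)}
    enc = pg.PLMAdapterEncoder(table)
    rep = pg.encode_peptide("p2", enc)
    assert np.array_equal(rep.vector, np.ones(4))
    with pytest.raises(EncoderError, match="p9"):
        pg.encode_peptide("p9", enc)


def test_plm_adapter_from_table_file(tmp_path):
    path = tmp_path / "reps.csv"
    path.write_text("id,f0,f1\npa,0.5,1.5\npb,2.5,3.5\n")
    enc = pg.PLMAdapterEncoder.from_table_file(path)
    assert enc.d_repr == 2
    assert np.array_equal(enc.lookup("pb"), np.array([2.5, 3.5]))
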