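"""Attention closed forms, GCN oracle, loss, gradients, checkpoints."""

import numpy as np
import pytest

from funcphos.autodiff import AdamW, Tensor
from funcphos.graphs import ResidueGraph
from funcphos.model import (
    CLASSIFIER_PREFIX,
    FusionConfig,
    Sample,
    bce_loss,
    classify,
    forward,
    graph_encode,
    init_params,
    load_checkpoint,
    normalized_adjacency,
    save_checkpoint,
    scaled_dot_attention,
)


def small_config(**overrides):
    defaults = dict(
        embed_dim=8, input_embed_dim=6, gcn_layers=2,
        classifier_widths=(8, 8, 8), dropout=0.0, node_feature_dim=35, seed=0,
    )
    defaults.update(overrides)
    return FusionConfig(**defaults)


def make_sample(rng, n_nodes=4, config=None, label=1.0):
    config = config or small_config()
    edges = {(i, i + 1): "peptide" for i in range(n_nodes - 1)}
    graph = ResidueGraph(np.arange(n_nodes), 0, edges)
    return Sample(
        node_features=rng.standard_normal((n_nodes, config.node_feature_dim)),
        norm_adjacency=normalized_adjacency(graph),
        query=rng.standard_normal((config.query_tokens, config.input_embed_dim)),
        label=label,
    )


# ---------------------------------------------------------------------------
# attention primitive
# ---------------------------------------------------------------------------

def test_single_key_returns_value_row_exactly():
    rng = np.random.default_rng(0)
    q = Tensor(rng.standard_normal((3, 8)))
    k = Tensor(rng.standard_normal((1, 8)))
    v = Tensor(rng.standard_normal((1, 8)))
    out = scaled_dot_attention(q, k, v, scale=np.sqrt(8.0))
    for row in out.data:
        np.testing.assert_allclose(row, v.data[0], atol=1e-12)


def test_identical_keys_average_values_independent_of_query():
    rng = np.random.default_rng(1)
    k = Tensor(np.tile(rng.standard_normal(8), (5, 1)))
    v = Tensor(np.tile(rng.standard_normal(8), (5, 1)))
    for _ in range(3):
        q = Tensor(rng.standard_normal((2, 8)))
        out = scaled_dot_attention(q, k, v, scale=np.sqrt(8.0))
        np.testing.assert_allclose(out.data, np.tile(v.data[0], (2, 1)), atol=1e-12)


def test_attention_matches_dense_oracle():
    rng = np.random.default_rng(2)
    C = 8
    q, k, v = (rng.standard_normal(s) for s in ((2, C), (5, C), (5, C)))
    out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v), scale=np.sqrt(C))
    logits = q @ k.T / np.sqrt(C)
    weights = np.exp(logits - logits.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(out.data, weights @ v, atol=1e-6)


def test_softmax_rows_stochastic():
    rng = np.random.default_rng(3)
    for _ in range(20):
        logits = Tensor(rng.standard_normal((4, 7)) * 10)
        rows = logits.softmax().data.sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)


def test_scale_divisor_grows_as_sqrt_embed_dim():
    # with a single head the divisor is sqrt(C)
    for C in (16, 64, 256):
        cfg = small_config(embed_dim=C, classifier_widths=(4,))
        assert cfg.scale_divisor == pytest.approx(np.sqrt(C))
    cfg = small_config(embed_dim=16, n_heads=4, classifier_widths=(4,))
    assert cfg.scale_divisor == pytest.approx(2.0)
    cfg = small_config(embed_dim=16, attention_scale="linear", classifier_widths=(4,))
    assert cfg.scale_divisor == pytest.approx(16.0)


def test_self_attention_symmetry():
    rng = np.random.default_rng(4)
    token = rng.standard_normal(8)
    tokens = Tensor(np.tile(token, (2, 1)))
    out = scaled_dot_attention(tokens, tokens, tokens, scale=np.sqrt(8.0))
    np.testing.assert_allclose(out.data[0], out.data[1], atol=1e-12)
    single = Tensor(token[None, :])
    out1 = scaled_dot_attention(single, single, single, scale=np.sqrt(8.0))
    np.testing.assert_allclose(out1.data[0], token, atol=1e-12)


def test_empty_key_set_rejected():
    q = Tensor(np.zeros((1, 4)))
    empty = Tensor(np.zeros((0, 4)))
    with pytest.raises(ValueError):
        scaled_dot_attention(q, empty, empty, scale=2.0)


# ---------------------------------------------------------------------------
# GCN encoder
# ---------------------------------------------------------------------------

def test_single_node_single_layer_is_affine():
    config = small_config(gcn_layers=1)
    params = init_params(config)
    x = np.random.default_rng(5).standard_normal((1, 35))
    graph = ResidueGraph(np.array([0]), 0, {})
    nodes, pooled = graph_encode(
        Tensor(x), normalized_adjacency(graph), params, config
    )
    expected = x @ params["gcn0.w"].data + params["gcn0.b"].data
    np.testing.assert_allclose(nodes.data, expected, atol=1e-12)
    np.testing.assert_allclose(pooled.data, expected[0], atol=1e-12)


def test_gcn_permutation_equivariance():
    rng = np.random.default_rng(6)
    config = small_config()
    params = init_params(config)
    x = rng.standard_normal((5, 35))
    edges = {(0, 1): "distance", (1, 2): "distance", (2, 3): "knn", (3, 4): "peptide"}
    graph = ResidueGraph(np.arange(5), 0, edges)
    a = normalized_adjacency(graph)
    nodes, _ = graph_encode(Tensor(x), a, params, config)
    perm = rng.permutation(5)
    p = np.eye(5)[perm]
    nodes_p, _ = graph_encode(Tensor(x[perm]), p @ a @ p.T, params, config)
    np.testing.assert_allclose(nodes_p.data, nodes.data[perm], atol=1e-10)


def test_gcn_matches_dense_oracle_on_path():
    config = small_config(gcn_layers=2)
    params = init_params(config)
    rng = np.random.default_rng(7)
    x = rng.standard_normal((4, 35))
    graph = ResidueGraph(np.arange(4), 0, {(0, 1): "peptide", (1, 2): "peptide", (2, 3): "peptide"})
    a_hat = normalized_adjacency(graph)
    nodes, _ = graph_encode(Tensor(x), a_hat, params, config)
    h = np.maximum(a_hat @ x @ params["gcn0.w"].data + params["gcn0.b"].data, 0)
    expected = a_hat @ h @ params["gcn1.w"].data + params["gcn1.b"].data
    np.testing.assert_allclose(nodes.data, expected, atol=1e-6)


def test_empty_graph_rejected():
    config = small_config()
    params = init_params(config)
    with pytest.raises(ValueError):
        graph_encode(Tensor(np.zeros((0, 35))), np.zeros((0, 0)), params, config)


# ---------------------------------------------------------------------------
# classifier and loss
# ---------------------------------------------------------------------------

def test_zero_classifier_outputs_half():
    config = small_config()
    params = init_params(config)
    for key in params:
        if key.startswith(CLASSIFIER_PREFIX):
            params[key].data[:] = 0.0
    tokens = Tensor(np.random.default_rng(8).standard_normal((2, 8)))
    prob = classify(tokens, params, config)
    assert prob.data[0] == pytest.approx(0.5)


def test_eval_mode_deterministic_despite_dropout_config():
    config = small_config(dropout=0.3)
    params = init_params(config)
    sample = make_sample(np.random.default_rng(9), config=config)
    p1 = forward(sample, params, config).data[0]
    p2 = forward(sample, params, config).data[0]
    assert p1 == p2
    assert 0.0 < p1 < 1.0


def test_bce_closed_forms():
    assert bce_loss(1.0, Tensor(np.array([1.0 - 1e-9]))).data == pytest.approx(0.0, abs=1e-6)
    assert bce_loss(1.0, Tensor(np.array([0.5]))).data == pytest.approx(np.log(2), abs=1e-9)
    # batch mean of two hand-computed terms
    probs = Tensor(np.array([0.9, 0.1]))
    expected = np.mean([-np.log(0.9), -np.log(0.9)])
    assert bce_loss(np.array([1.0, 0.0]), probs).data == pytest.approx(expected, abs=1e-12)


def test_ablation_variants_run():
    rng = np.random.default_rng(10)
    for ablation in ("none", "no_gcn", "no_esm", "no_cross_attention", "no_self_attention"):
        config = small_config(ablation=ablation)
        params = init_params(config)
        sample = make_sample(rng, config=config)
        prob = forward(sample, params, config).data[0]
        assert 0.0 < prob < 1.0


# ---------------------------------------------------------------------------
# gradients and optimization
# ---------------------------------------------------------------------------

def test_autodiff_matches_finite_differences():
    """Full-model gradient check on 10 randomly sampled parameters."""
    config = small_config()
    params = init_params(config)
    rng = np.random.default_rng(11)
    sample = make_sample(rng, config=config)

    def loss_value() -> float:
        prob = forward(sample, params, config)
        return float(bce_loss(sample.label, prob).data)

    prob = forward(sample, params, config)
    loss = bce_loss(sample.label, prob)
    loss.backward()

    eps = 1e-6
    names = list(params)
    for _ in range(10):
        name = names[rng.integers(len(names))]
        tensor = params[name]
        flat_index = int(rng.integers(tensor.data.size))
        idx = np.unravel_index(flat_index, tensor.data.shape)
        original = tensor.data[idx]
        tensor.data[idx] = original + eps
        up = loss_value()
        tensor.data[idx] = original - eps
        down = loss_value()
        tensor.data[idx] = original
        numeric = (up - down) / (2 * eps)
        analytic = tensor.grad[idx] if tensor.grad is not None else 0.0
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


def test_adamw_decoupled_weight_decay():
    # with zero gradient, AdamW still shrinks weights by lr * wd * w
    p = Tensor(np.array([2.0]), requires_grad=True)
    opt = AdamW({"p": p}, lr=0.1, weight_decay=0.5)
    p.grad = np.array([0.0])
    opt.step()
    assert p.data[0] == pytest.approx(2.0 - 0.1 * 0.5 * 2.0)


def test_training_reduces_loss_on_tiny_fixture():
    config = small_config()
    params = init_params(config)
    rng = np.random.default_rng(12)
    samples = [make_sample(rng, config=config, label=float(i % 2)) for i in range(8)]
    opt = AdamW(params, lr=1e-2, weight_decay=0.0)

    def total_loss():
        return float(
            np.mean([
                float(bce_loss(s.label, forward(s, params, config)).data)
                for s in samples
            ])
        )

    before = total_loss()
    for _ in range(30):
        opt.zero_grad()
        for s in samples:
            loss = bce_loss(s.label, forward(s, params, config))
            loss.backward(1.0 / len(samples))
        opt.step()
    assert total_loss() < before


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path):
    config = small_config()
    params = init_params(config)
    path = tmp_path / "model.npz"
    save_checkpoint(params, config, path, metadata={"val_auroc": 0.9})
    loaded, loaded_config, meta = load_checkpoint(path)
    assert loaded_config == config
    assert meta == {"val_auroc": 0.9}
    assert set(loaded) == set(params)
    for key in params:
        np.testing.assert_array_equal(loaded[key].data, params[key].data)
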