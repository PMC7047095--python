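import numpy as np
import pytest

from srna_augment import classify_dl, preprocess, simulate


@pytest.fixture(scope="session")
def tiny_config():
    return simulate.SimConfig(
        n_classes=3,
        datasets_per_class=2,
        samples_per_dataset=8,
        n_srna=200,
        n_contaminant=40,
        markers_per_class=8,
        marker_log2fc=3.0,
        batch_sd=0.1,
        zero_inflation=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """48-sample, 240-feature cohort shared across fast tests."""
    return simulate.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_scaled(tiny_cohort):
    """Preprocessed tiny cohort: samples x features in [0,1] plus labels."""
    matrix, md, truth = tiny_cohort
    matrix = preprocess.select_feature_kind(matrix, "srna")
    matrix = preprocess.rpm_normalize(matrix)
    matrix, _ = preprocess.filter_zero_features(matrix)
    scaled = preprocess.minmax_transform(matrix, preprocess.minmax_fit(matrix))
    return scaled, md["tissue"].to_numpy(), truth


@pytest.fixture(scope="session")
def tiny_trained_net(tiny_scaled):
    """Small dense net trained on the tiny cohort (fast, learnable)."""
    scaled, y, _ = tiny_scaled
    X = scaled.to_sample_matrix()
    net = classify_dl.build_network(
        X.shape[1], 3, hidden=[32, 16], dropout=[0.2, 0.2],
        seed=5, classes=np.unique(y),
    )
    classify_dl.train(net, X, y, classify_dl.TrainConfig(epochs=30, seed=5))
    return net, X, y


def random_relu_net(n_inputs, n_classes, hidden, seed):
    """Dense net with random nonzero weights/biases (no training)."""
    rng = np.random.default_rng(seed)
    net = classify_dl.build_network(
        n_inputs, n_classes, hidden=hidden, dropout=[0.0] * len(hidden), seed=seed
    )
    for i in range(net.n_layers):
        net.weights[i] = rng.normal(0, 0.6, net.weights[i].shape)
        net.biases[i] = rng.normal(0, 0.3, net.biases[i].shape)
    return net
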