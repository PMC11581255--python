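"""Feature extraction and autoencoder classification, stage by stage.

Preprocesses synthetic epochs, extracts dense-network features with SE
channel recalibration, trains the patch autoencoder with its softmax
head, and reports held-out accuracy.
"""

import numpy as np

from mihawk import (CAEClassifier, CAEConfig, DenseNetConfig, SynthConfig,
                    build_densenet, extract_features, generate_dataset,
                    preprocess_epoch, evaluate)

epochs = [preprocess_epoch(ep)
          for ep in generate_dataset(SynthConfig(erd_depth=0.8, snr_db=10.0,
                                                 seed=0), 200)]
labels = np.array([ep.label for ep in epochs])

shape = (1, epochs[0].n_channels, epochs[0].n_samples)
model = build_densenet(DenseNetConfig.from_preset("tiny", input_shape=shape),
                       seed=0)
feats = extract_features(model, epochs)
print(f"dense blocks: {model.config.block_layers}, "
      f"direct feeds per block: {model.n_direct_connections()}")
print(f"feature matrix: {feats.shape}")

# train/test split, standardize on train statistics only
rng = np.random.default_rng(0)
order = rng.permutation(len(epochs))
tr, te = order[:300], order[300:]
mu, sd = feats[tr].mean(axis=0), feats[tr].std(axis=0) + 1e-12
feats = (feats - mu) / sd

clf = CAEClassifier(CAEConfig(epochs=20, seed=0)).fit(feats[tr], labels[tr])
last = clf.loss_trace[-1]
print(f"final reconstruction cost J_cae = {last['j_cae']:.3f}, "
      f"cross-entropy = {last['cross_entropy']:.3f}")
report = evaluate(clf.predict(feats[te]), labels[te])
print(f"held-out accuracy {report.accuracy:.2f}, "
      f"precision {report.precision:.2f} (n={report.n_samples})")
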